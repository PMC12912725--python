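import numpy as np
import pytest

from wormalign import network as net
from wormalign import synthetic
from wormalign.losses import LossWeights, SlidingWindowSpec
from wormalign.volume import pad_centroids, valid_rows


@pytest.fixture(scope="module")
def tiny_problem():
    ph = synthetic.make_phantom(
        synthetic.PhantomSpec(dims=(32, 16, 8), n_cells=12, seed=2, margin=5, z_margin=2)
    )
    pair = synthetic.make_bent_pair(
        ph, synthetic.BendSpec(amplitude=2.0, wavelength=48.0, phase=0.4)
    )
    return net.RegistrationProblem(
        pair.fixed, pair.moving, pair.fixed_centroids, pair.moving_centroids
    )


TINY_CFG = dict(window=SlidingWindowSpec(n=8), weights=LossWeights.worm())


class TestForwardRegister:
    def test_ddf_shape_and_layout(self, tiny_problem):
        model = net.build_localnet(net.LocalNetSpec.desk(seed=0))
        d = net.forward_register(model, tiny_problem.fixed, tiny_problem.moving)
        assert d.shape == tiny_problem.fixed.shape + (3,)

    def test_jellyfish_variant_keeps_z_slices(self, tiny_problem):
        model = net.build_localnet(net.LocalNetSpec.desk(seed=0, mask_z=True))
        d = net.forward_register(model, tiny_problem.fixed, tiny_problem.moving)
        assert np.all(d[..., 2] == 0)

    def test_dim_mismatch_rejected(self, tiny_problem):
        model = net.build_localnet(net.LocalNetSpec.desk())
        with pytest.raises(ValueError):
            net.forward_register(
                model, tiny_problem.fixed, tiny_problem.moving[:-2]
            )


class TestAugmentation:
    def test_zero_magnitude_is_identity(self, tiny_problem, ):
        rng = np.random.default_rng(0)
        spec = net.AffineAugmentSpec(magnitude=0.0)
        f, m, fc, mc = net.random_affine_pair(
            tiny_problem.fixed, tiny_problem.moving,
            tiny_problem.fixed_centroids, tiny_problem.moving_centroids,
            spec, rng,
        )
        assert np.allclose(f, tiny_problem.fixed, atol=1e-9)
        assert np.allclose(fc, tiny_problem.fixed_centroids, atol=1e-9)

    def test_same_seed_bit_identical(self, tiny_problem):
        spec = net.AffineAugmentSpec(magnitude=1.5)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            outs.append(
                net.random_affine_pair(
                    tiny_problem.fixed, tiny_problem.moving,
                    tiny_problem.fixed_centroids, tiny_problem.moving_centroids,
                    spec, rng,
                )
            )
        for a, b in zip(outs[0], outs[1]):
            assert np.array_equal(a, b)

    def test_centroids_track_blobs(self):
        """After augmentation the transformed centroid still sits on the blob."""
        ph = synthetic.make_phantom(
            synthetic.PhantomSpec(dims=(32, 32, 8), n_cells=6, seed=4, margin=8, z_margin=3)
        )
        rng = np.random.default_rng(3)
        spec = net.AffineAugmentSpec(magnitude=1.0)
        pts = pad_centroids(ph.centers)
        f, _, fc, _ = net.random_affine_pair(ph.volume, ph.volume, pts, pts, spec, rng)
        from scipy import ndimage

        mask = valid_rows(fc)
        for p in fc[mask]:
            # intensity at the mapped centroid should be near a blob peak
            val = ndimage.map_coordinates(f, p.reshape(3, 1), order=1)[0]
            assert val > 0.1

    def test_rot90_requires_square_xy(self, tiny_problem):
        spec = net.AffineAugmentSpec(magnitude=0.0, rot90_z=True)
        rng = np.random.default_rng(0)  # this seed draws an odd quarter-turn
        with pytest.raises(ValueError):
            net.random_affine_pair(
                tiny_problem.fixed, tiny_problem.moving, None, None, spec, rng
            )

    def test_rot90_square_volume_round_trip(self):
        rng = np.random.default_rng(0)
        vol = np.random.default_rng(5).random((16, 16, 4))
        spec = net.AffineAugmentSpec(magnitude=0.0, rot90_z=True)
        pts = pad_centroids(np.array([[3.0, 5.0, 2.0]]))
        f, _, fc, _ = net.random_affine_pair(vol, vol, pts, pts, spec, rng)
        from scipy import ndimage

        # the rotated centroid indexes the rotated image at the same value
        orig = ndimage.map_coordinates(vol, pts[0].reshape(3, 1), order=1)[0]
        new = ndimage.map_coordinates(f, fc[0].reshape(3, 1), order=1)[0]
        assert new == pytest.approx(orig, abs=1e-9)


@pytest.fixture(scope="module")
def inputs():
    ph = synthetic.make_phantom(
        synthetic.PhantomSpec(dims=(24, 16, 8), n_cells=8, seed=9, margin=5, z_margin=2)
    )
    image = np.stack([ph.volume] * 4, axis=-1)
    label = (ph.rois > 0).astype(float)
    weight = np.where(ph.rois > 0, 5.0, 1.0)
    return image, label, weight


class TestLabelerAugmentation:
    def test_determinism(self, inputs):
        spec = net.LabelerAugmentSpec()
        outs = [
            net.random_labeler_augmentation(*inputs, spec, np.random.default_rng(4))
            for _ in range(2)
        ]
        for a, b in zip(outs[0], outs[1]):
            assert np.array_equal(a, b)

    def test_label_and_weight_values_preserved(self, inputs):
        """Nearest-neighbor interpolation: no new label/weight values appear."""
        spec = net.LabelerAugmentSpec(gaussian_noise=0.0, poisson_scale=0.0)
        _, label, weight = net.random_labeler_augmentation(
            *inputs, spec, np.random.default_rng(2)
        )
        assert set(np.unique(label)) <= {0.0, 1.0}
        assert set(np.unique(weight)) <= {0.0, 1.0, 5.0}

    def test_noise_only_touches_image(self, inputs):
        spec = net.LabelerAugmentSpec(
            bend_amplitude=0.0, affine_magnitude=0.0, rot180=False,
            contrast_range=(1.0, 1.0), blur_sigma_max=0.0,
            gaussian_noise=0.05, poisson_scale=0.0,
        )
        image, label, weight = net.random_labeler_augmentation(
            *inputs, spec, np.random.default_rng(3)
        )
        assert not np.array_equal(image, inputs[0])
        assert np.array_equal(label, inputs[1])
        assert np.array_equal(weight, inputs[2])


class TestTraining:
    def test_zero_epochs_leaves_model_unchanged(self, tiny_problem):
        model = net.build_localnet(net.LocalNetSpec.desk(seed=5))
        before = {k: v.copy() for k, v in model.state_dict().items()}
        history = net.train_alignment(
            model, [tiny_problem], net.TrainConfig(epochs=0, **TINY_CFG)
        )
        assert history["train"] == []
        for k, v in model.state_dict().items():
            assert np.array_equal(v, before[k])

    def test_smoke_training_reduces_loss(self, tiny_problem):
        model = net.build_localnet(
            net.LocalNetSpec(in_channels=2, base_channels=2, seed=5)
        )
        cfg = net.TrainConfig(lr=1e-3, epochs=8, batch_size=1, seed=0, **TINY_CFG)
        history = net.train_alignment(model, [tiny_problem], cfg)
        assert np.all(np.isfinite(history["train"]))
        assert history["train"][-1] < history["train"][0]

    def test_validation_history_recorded(self, tiny_problem):
        model = net.build_localnet(
            net.LocalNetSpec(in_channels=2, base_channels=2, seed=1)
        )
        cfg = net.TrainConfig(
            lr=1e-3, epochs=2, batch_size=1, seed=0,
            validation=[tiny_problem], **TINY_CFG,
        )
        history = net.train_alignment(model, [tiny_problem], cfg)
        assert len(history["validation"]) == 2

    def test_empty_dataset_rejected(self):
        model = net.build_localnet(net.LocalNetSpec.desk())
        with pytest.raises(ValueError):
            net.train_alignment(model, [], net.TrainConfig(epochs=1))

    def test_checkpoint_round_trip(self, tiny_problem, tmp_path):
        model = net.build_localnet(net.LocalNetSpec.desk(seed=3))
        path = tmp_path / "model.npz"
        net.save_checkpoint(model, path)
        clone = net.build_localnet(net.LocalNetSpec.desk(seed=99))
        net.load_checkpoint(clone, path)
        d1 = net.forward_register(model, tiny_problem.fixed, tiny_problem.moving)
        d2 = net.forward_register(clone, tiny_problem.fixed, tiny_problem.moving)
        assert np.array_equal(d1, d2)


class TestDiscoveryTraining:
    def test_multichannel_training_improves_alignment(self):
        """Unsupervised 4-channel training improves the channel-averaged NCC
        image loss on a held-out pair versus the untrained (identity-like)
        baseline."""
        import itertools

        cohort = synthetic.make_cohort(
            n_animals=8, n_types=10, dims=(32, 16, 8), bend_amplitude=2.0, seed=6
        )
        problems = [
            net.RegistrationProblem(
                cohort.animals[i].volume, cohort.animals[j].volume
            )
            for i, j in itertools.combinations(range(7), 2)
        ]
        heldout = [
            net.RegistrationProblem(
                cohort.animals[7].volume, cohort.animals[k].volume
            )
            for k in range(3)
        ]
        model = net.build_localnet(
            net.LocalNetSpec(in_channels=8, base_channels=2, seed=8)
        )
        cfg = net.TrainConfig(
            lr=1e-3, epochs=30, batch_size=7, seed=0,
            weights=LossWeights.discovery(), window=SlidingWindowSpec(n=8),
        )
        before = net.evaluate_loss(model, heldout, cfg)
        net.train_alignment(model, problems, cfg)
        after = net.evaluate_loss(model, heldout, cfg)
        assert after < before
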