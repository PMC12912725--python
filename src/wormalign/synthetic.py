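"""Synthetic deforming phantoms with exact ground truth.

The generator emulates the data the pipeline consumes: worm-like volumes
(Gaussian-blob nuclei scattered along a curved midline), smooth bending
deformations with analytically known displacement fields, time series with
planted identities / GFP patterns / identity swaps, and multi-animal
4-channel cohorts with per-cell-type color signatures.

Bending deformations displace ``y`` by a smooth function of ``x`` only
(optionally composed with a rigid transform).  Because the bend leaves
``x`` unchanged, the maps are exactly invertible and compose in closed
form, so every emitted ground-truth DDF is exact rather than numerically
inverted.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wormalign.volume import pad_centroids


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a worm-like blob phantom.

    ``n_cells`` defaults to 110, the typical number of matched neurons in a
    head-ganglia recording.  ``margin`` keeps blobs clear of the volume
    faces so that moderate bends keep them in bounds.
    """

    dims: tuple[int, int, int] = (64, 32, 16)
    n_cells: int = 110
    radius_range: tuple[float, float] = (1.2, 2.0)
    intensity_range: tuple[float, float] = (0.5, 1.0)
    midline_amplitude: float = 3.0
    midline_wavelength: float = 40.0
    lateral_sigma: tuple[float, float] = (3.0, 2.2)
    margin: float = 8.0
    z_margin: float = 3.0
    min_gap: float = 0.6
    seed: int = 0


@dataclass
class Phantom:
    """A rendered phantom: intensity volume, ROI labels, analytic centers."""

    volume: np.ndarray
    rois: np.ndarray
    centers: np.ndarray  # (n, 3) analytic blob centers
    radii: np.ndarray
    intensities: np.ndarray
    spec: PhantomSpec

    @property
    def centroids(self) -> np.ndarray:
        """Analytic centers padded to the canonical (200, 3) table."""
        return pad_centroids(self.centers)


@dataclass(frozen=True)
class BendSpec:
    """A smooth bend: sinusoidal y-displacement of amplitude ``amplitude``
    voxels and wavelength ``wavelength`` along x, plus an optional rigid
    component applied after the bend."""

    amplitude: float = 5.0
    wavelength: float = 96.0
    phase: float = 0.0
    theta_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)


class BendMap:
    """The deformation ``m(p) = Rigid(p + (0, u(p_x), 0))`` with exact inverse."""

    def __init__(self, spec: BendSpec, dims: tuple[int, int, int]):
        self.spec = spec
        self.dims = tuple(dims)
        self.center = (np.asarray(dims, dtype=float) - 1.0) / 2.0
        t = np.deg2rad(spec.theta_deg)
        self.rot = np.array(
            [
                [np.cos(t), -np.sin(t), 0.0],
                [np.sin(t), np.cos(t), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        self.translation = np.asarray(spec.translation, dtype=float)

    def displacement_y(self, x: np.ndarray) -> np.ndarray:
        s = self.spec
        return s.amplitude * np.sin(2.0 * np.pi * x / s.wavelength + s.phase)

    def forward(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        bent = p.copy()
        bent[..., 1] += self.displacement_y(p[..., 0])
        rel = bent - self.center
        return rel @ self.rot.T + self.center + self.translation

    def inverse(self, points: np.ndarray) -> np.ndarray:
        q = np.asarray(points, dtype=float) - self.translation
        rel = (q - self.center) @ self.rot
        bent = rel + self.center
        out = bent.copy()
        out[..., 1] -= self.displacement_y(bent[..., 0])
        return out

    def ddf(self) -> np.ndarray:
        """Exact fixed-to-moving DDF of this map sampled on the voxel grid."""
        grid = _grid(self.dims)
        return self.forward(grid) - grid


def _grid(dims: tuple[int, int, int]) -> np.ndarray:
    return np.stack(
        np.meshgrid(*(np.arange(d, dtype=float) for d in dims), indexing="ij"),
        axis=-1,
    )


def _render(
    centers: np.ndarray,
    radii: np.ndarray,
    intensities: np.ndarray,
    dims: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Render Gaussian blobs and their ball ROIs (index i+1 for cell i)."""
    vol = np.zeros(dims, dtype=float)
    rois = np.zeros(dims, dtype=np.int32)
    # closest-center wins inside overlapping balls, so ROIs stay disjoint
    best_d2 = np.full(dims, np.inf)
    for i, (c, r, a) in enumerate(zip(centers, radii, intensities)):
        lo = np.maximum(np.floor(c - 3.0 * r).astype(int), 0)
        hi = np.minimum(np.ceil(c + 3.0 * r).astype(int) + 1, dims)
        if np.any(lo >= hi):
            continue
        box = tuple(slice(a_, b_) for a_, b_ in zip(lo, hi))
        local = _grid(tuple(h - l for l, h in zip(lo, hi))) + lo
        d2 = ((local - c) ** 2).sum(axis=-1)
        sigma = r / 1.5
        vol[box] += a * np.exp(-d2 / (2.0 * sigma * sigma))
        inside = (d2 <= r * r) & (d2 < best_d2[box])
        rois[box][inside] = i + 1
        best_d2[box][inside] = d2[inside]
    # every cell keeps at least its center voxel, so no ROI index is empty
    # even when deformation pushes neighboring balls into each other
    for i, c in enumerate(centers):
        if not (rois == i + 1).any():
            v = tuple(np.clip(np.round(c).astype(int), 0, np.array(dims) - 1))
            rois[v] = i + 1
            best_d2[v] = 0.0
    return vol, rois


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Place non-overlapping blobs along a curved midline and render them."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    dims = np.asarray(spec.dims, dtype=float)
    centers: list[np.ndarray] = []
    radii: list[float] = []
    max_tries = 200 * spec.n_cells
    tries = 0
    while len(centers) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_cells} cells in {spec.dims} "
                f"(placed {len(centers)})"
            )
        x = rng.uniform(2.5, dims[0] - 2.5)
        midline_y = dims[1] / 2.0 + spec.midline_amplitude * np.sin(
            2.0 * np.pi * x / spec.midline_wavelength
        )
        y = midline_y + rng.normal(0.0, spec.lateral_sigma[0])
        z = dims[2] / 2.0 + rng.normal(0.0, spec.lateral_sigma[1])
        if not (spec.margin <= y <= dims[1] - spec.margin):
            continue
        if not (spec.z_margin <= z <= dims[2] - spec.z_margin):
            continue
        r = rng.uniform(*spec.radius_range)
        c = np.array([x, y, z])
        ok = True
        for cj, rj in zip(centers, radii):
            if np.linalg.norm(c - cj) < r + rj + spec.min_gap:
                ok = False
                break
        if ok:
            centers.append(c)
            radii.append(r)
    centers_arr = np.asarray(centers)
    radii_arr = np.asarray(radii)
    intensities = rng.uniform(*spec.intensity_range, size=spec.n_cells)
    vol, rois = _render(centers_arr, radii_arr, intensities, spec.dims)
    return Phantom(vol, rois, centers_arr, radii_arr, intensities, spec)


@dataclass
class BentPair:
    """A registration problem with exact ground truth."""

    fixed: np.ndarray
    moving: np.ndarray
    fixed_rois: np.ndarray
    moving_rois: np.ndarray
    ddf: np.ndarray  # exact fixed -> moving displacement field
    fixed_centroids: np.ndarray  # (200, 3) padded, matched row order
    moving_centroids: np.ndarray
    bend: BendMap


def make_bent_pair(phantom: Phantom, bend: BendSpec | None = None) -> BentPair:
    """Warp a phantom by an analytic bend; the phantom is the fixed image.

    The moving image is rendered analytically at the displaced blob centers
    (not resampled), so the pair behaves like two independent acquisitions
    related by the known deformation.
    """
    bend = bend or BendSpec()
    bmap = BendMap(bend, phantom.spec.dims)
    jac = 2.0 * np.pi * bend.amplitude / bend.wavelength
    if jac >= 1.0:
        raise ValueError("bend is not invertible: |du/dx| must stay below 1")
    moving_centers = bmap.forward(phantom.centers)
    moving, moving_rois = _render(
        moving_centers, phantom.radii, phantom.intensities, phantom.spec.dims
    )
    return BentPair(
        fixed=phantom.volume,
        moving=moving,
        fixed_rois=phantom.rois,
        moving_rois=moving_rois,
        ddf=bmap.ddf(),
        fixed_centroids=pad_centroids(phantom.centers),
        moving_centroids=pad_centroids(moving_centers),
        bend=bmap,
    )


@dataclass
class Frame:
    red: np.ndarray
    green: np.ndarray
    rois: np.ndarray  # ground-truth consistent indices (cell i -> index i+1)
    rois_observed: np.ndarray  # with injected identity swaps applied
    positions: np.ndarray


@dataclass
class SwapEvent:
    t_start: int
    duration: int
    cell_a: int  # 0-based cell ids; a is GFP+, b is GFP-
    cell_b: int


@dataclass
class ActivityStep:
    cell: int  # 0-based cell id
    t_start: int  # green ratio doubles from this frame onward



@dataclass
class TimeSeries:
    frames: list[Frame]
    gfp_positive: np.ndarray  # bool per cell
    green_ratio: np.ndarray  # planted baseline green/red ratio per cell
    swaps: list[SwapEvent]
    bends: list[BendMap]
    spec: PhantomSpec
    steps: list[ActivityStep] = None

    def true_ddf(self, fixed_t: int, moving_t: int) -> np.ndarray:
        """Exact DDF mapping fixed-frame coordinates to moving-frame ones."""
        grid = _grid(self.spec.dims)
        fw = self.bends[moving_t].forward(self.bends[fixed_t].inverse(grid))
        return fw - grid


def make_timeseries(
    phantom: Phantom,
    n_frames: int = 10,
    bend_amplitude: float = 4.0,
    bend_wavelength: float = 96.0,
    gfp_fraction: float = 0.5,
    n_swaps: int = 0,
    swap_duration: int = 2,
    n_activity_steps: int = 0,
    seed: int = 0,
) -> TimeSeries:
    """A deforming recording with planted identities and GFP pattern.

    Each frame bends the phantom with a smoothly varying amplitude/phase.
    The green channel scales each blob by a per-cell ratio: GFP-positive
    cells are bright (ratio ~3), negative ones dim (~0.5).  ``n_swaps``
    injects identity swaps between a GFP+ and a GFP- cell for
    ``swap_duration`` consecutive frames into ``rois_observed``, emulating
    tracking errors for error-rate validation.  ``n_activity_steps`` plants
    step-like activity events: the chosen cells' green ratio doubles from a
    random frame onward, so trace extraction can be validated against known
    dynamics.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    rng = np.random.default_rng(seed)
    n = len(phantom.centers)
    gfp = np.zeros(n, dtype=bool)
    gfp[rng.choice(n, size=int(round(gfp_fraction * n)), replace=False)] = True
    ratio = np.where(
        gfp, rng.normal(3.0, 0.2, size=n), np.abs(rng.normal(0.5, 0.1, size=n))
    )
    steps: list[ActivityStep] = []
    if n_activity_steps > 0:
        steps = [
            ActivityStep(cell=int(c), t_start=int(rng.integers(1, n_frames)))
            for c in rng.choice(n, size=n_activity_steps, replace=False)
        ]

    bends = []
    frames = []
    for t in range(n_frames):
        amp = bend_amplitude * np.sin(2.0 * np.pi * t / n_frames + rng.normal(0, 0.1))
        bmap = BendMap(
            BendSpec(amplitude=amp, wavelength=bend_wavelength, phase=rng.uniform(0, 0.3)),
            phantom.spec.dims,
        )
        pos = bmap.forward(phantom.centers)
        red, rois = _render(pos, phantom.radii, phantom.intensities, phantom.spec.dims)
        ratio_t = ratio.copy()
        for step in steps:
            if t >= step.t_start:
                ratio_t[step.cell] *= 2.0  # planted activity step
        green, _ = _render(
            pos, phantom.radii, phantom.intensities * ratio_t, phantom.spec.dims
        )
        frames.append(Frame(red, green, rois, rois.copy(), pos))
        bends.append(bmap)

    swaps: list[SwapEvent] = []
    # cells participate in at most one swap event so events never interact
    pos_ids = list(rng.permutation(np.flatnonzero(gfp)))
    neg_ids = list(rng.permutation(np.flatnonzero(~gfp)))
    if n_swaps > min(len(pos_ids), len(neg_ids)):
        raise ValueError("more swaps requested than disjoint GFP+/- pairs")
    for _ in range(n_swaps):
        a = int(pos_ids.pop())
        b = int(neg_ids.pop())
        t0 = int(rng.integers(0, n_frames - swap_duration + 1))
        swaps.append(SwapEvent(t0, swap_duration, a, b))
        for t in range(t0, t0 + swap_duration):
            obs = frames[t].rois_observed
            mask_a = frames[t].rois == a + 1
            mask_b = frames[t].rois == b + 1
            obs[mask_a] = b + 1
            obs[mask_b] = a + 1
    return TimeSeries(frames, gfp, ratio, swaps, bends, phantom.spec, steps)


@dataclass
class Animal:
    volume: np.ndarray  # (X, Y, Z, 4)
    rois: np.ndarray
    types: np.ndarray  # ROI index k -> type id types[k - 1]
    bend: BendMap


@dataclass
class Cohort:
    animals: list[Animal]
    palette: np.ndarray  # (n_types, 4) color signatures, mean 1 per row
    base: Phantom

    def true_ddf(self, fixed_animal: int, moving_animal: int) -> np.ndarray:
        grid = _grid(self.base.spec.dims)
        fw = self.animals[moving_animal].bend.forward(
            self.animals[fixed_animal].bend.inverse(grid)
        )
        return fw - grid


def make_cohort(
    n_animals: int = 6,
    n_types: int = 15,
    dims: tuple[int, int, int] = (64, 32, 16),
    position_jitter: float = 0.5,
    color_noise: float = 0.05,
    bend_amplitude: float = 4.0,
    seed: int = 0,
) -> Cohort:
    """Multi-animal 4-channel cohort with stereotyped per-type colors.

    Every animal carries one cell per type at an approximately stereotyped
    position (per-animal jitter plus a smooth per-animal bend).  Each type
    has a fixed 4-channel color signature, perturbed per animal by
    multiplicative noise.  Cross-animal ground-truth DDFs come from the
    bend maps; the per-cell jitter is the residual they cannot express.
    """
    rng = np.random.default_rng(seed)
    base = make_phantom(
        PhantomSpec(
            dims=dims,
            n_cells=n_types,
            seed=int(rng.integers(2**31)),
            # keep the placement band usable on small volumes
            margin=min(8.0, dims[1] / 4.0),
            z_margin=min(3.0, dims[2] / 4.0),
        )
    )
    palette = rng.uniform(0.2, 1.0, size=(n_types, 4))
    palette /= palette.mean(axis=1, keepdims=True)

    animals = []
    for _ in range(n_animals):
        bmap = BendMap(
            BendSpec(
                amplitude=rng.uniform(-bend_amplitude, bend_amplitude),
                wavelength=1.5 * dims[0],
                phase=rng.uniform(0, 2 * np.pi),
            ),
            dims,
        )
        jitter = rng.normal(0.0, position_jitter, size=base.centers.shape)
        pos = bmap.forward(base.centers + jitter)
        channels = []
        for k in range(4):
            gain = palette[:, k] * (1.0 + rng.normal(0.0, color_noise, size=n_types))
            ch, rois = _render(pos, base.radii, base.intensities * gain, dims)
            channels.append(ch)
        animals.append(
            Animal(
                volume=np.stack(channels, axis=-1),
                rois=rois,
                types=np.arange(n_types),
                bend=bmap,
            )
        )
    return Cohort(animals, palette, base)
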