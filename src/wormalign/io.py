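"""Reading and writing the pipeline's on-disk formats.

Volumes and ROI volumes live in HDF5 (one dataset per array, default name
``data``) or TIFF; centroid sets in CSV or HDF5; DDFs in HDF5; sparse
similarity matrices as coordinate triplets in HDF5; Euler parameters as
JSON.  Arrays on disk may use any axis-order tag supported by
:func:`wormalign.volume.convert_axis_order`; in memory everything is
canonical ``(x, y, z[, c])``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from wormalign.euler import EulerParams
from wormalign.tracking import SimilarityMatrix
from wormalign.volume import convert_axis_order


def read_volume(path, dataset: str = "data", order_tag: str | None = None) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            arr = f[dataset][()]
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    if order_tag:
        arr = convert_axis_order(arr, order_tag)
    return arr


def write_volume(path, vol: np.ndarray, dataset: str = "data") -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "a") as f:
            if dataset in f:
                del f[dataset]
            f.create_dataset(dataset, data=vol)
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(vol))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_centroids(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path, header=None).to_numpy(dtype=float)
    return read_volume(path, dataset="centroids")


def write_centroids(path, centroids: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        pd.DataFrame(np.asarray(centroids)).to_csv(path, header=False, index=False)
    else:
        write_volume(path, centroids, dataset="centroids")


def write_euler_params(path, params: EulerParams) -> None:
    payload = {
        "theta_deg": params.theta_deg,
        "tx": params.tx,
        "ty": params.ty,
        "tz": params.tz,
        "ncc": params.ncc,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_euler_params(path) -> EulerParams:
    payload = json.loads(Path(path).read_text())
    return EulerParams(**payload)


def write_similarity(path, sim: SimilarityMatrix) -> None:
    coo = sim.matrix.tocoo()
    with h5py.File(path, "w") as f:
        f.create_dataset("row", data=coo.row)
        f.create_dataset("col", data=coo.col)
        f.create_dataset("value", data=coo.data)
        f.attrs["n"] = sim.matrix.shape[0]
        f.create_dataset("roi_time", data=[t for t, _ in sim.roi_ids])
        f.create_dataset("roi_index", data=[k for _, k in sim.roi_ids])


def read_similarity(path) -> SimilarityMatrix:
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n"])
        mat = sparse.coo_matrix(
            (f["value"][()], (f["row"][()], f["col"][()])), shape=(n, n)
        ).tocsr()
        roi_ids = [
            (int(t), int(k))
            for t, k in zip(f["roi_time"][()], f["roi_index"][()])
        ]
    return SimilarityMatrix(mat, roi_ids)


def write_traces(path, traces: pd.DataFrame) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        traces.to_csv(path)
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=traces.to_numpy())
            f.create_dataset("timepoints", data=np.asarray(traces.index, dtype=int))


def write_report(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
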