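"""HDF5 / CSV plumbing for pipeline artifacts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spaces import BehaviorSpace

__all__ = [
    "save_curvature_h5", "load_curvature_h5",
    "save_space", "load_space",
    "save_distance_csv", "load_distance_csv",
]


def save_curvature_h5(path, curvature: np.ndarray, omitted: np.ndarray,
                      end1: np.ndarray, end2: np.ndarray,
                      distance_ratio: np.ndarray, group: str = "worm") -> None:
    """Per-individual posture outputs: curvature [T x 37], quality mask,
    end coordinates and distance ratios."""
    import h5py

    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("curvature", data=curvature)
        g.create_dataset("omitted", data=np.asarray(omitted, dtype=bool))
        g.create_dataset("end1", data=end1)
        g.create_dataset("end2", data=end2)
        g.create_dataset("distance_ratio", data=distance_ratio)


def load_curvature_h5(path, group: str = "worm") -> dict:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[group]
        return {k: g[k][...] for k in
                ("curvature", "omitted", "end1", "end2", "distance_ratio")}


def save_space(path, space: BehaviorSpace, group: str = "space") -> None:
    import h5py

    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("mean", data=space.mean)
        g.create_dataset("loadings", data=space.loadings)
        g.create_dataset("variances", data=space.variances)
        g.attrs["total_variance"] = space.total_variance
        g.attrs["n_windows"] = space.n_windows
        if space.d is not None:
            g.attrs["d"] = space.d
        if space.bin_index is not None:
            g.attrs["bin"] = space.bin_index
        if space.label is not None:
            g.attrs["who"] = space.label


def load_space(path, group: str = "space") -> BehaviorSpace:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[group]
        return BehaviorSpace(
            mean=g["mean"][...], loadings=g["loadings"][...],
            variances=g["variances"][...],
            total_variance=float(g.attrs["total_variance"]),
            n_windows=int(g.attrs["n_windows"]),
            d=int(g.attrs["d"]) if "d" in g.attrs else None,
            bin_index=int(g.attrs["bin"]) if "bin" in g.attrs else None,
            label=str(g.attrs["who"]) if "who" in g.attrs else None,
        )


def save_distance_csv(path, distmat: np.ndarray, labels) -> None:
    pd.DataFrame(distmat, index=labels, columns=labels).to_csv(path)


def load_distance_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
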