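"""I/O containers and file round-trips for voxel matrices and tabular artifacts.

The in-memory voxel container is :class:`GMVMatrix`: a dense ``(n_subjects,
n_voxels)`` array of grey-matter values restricted to an analysis mask on a
3-D voxel grid.  On disk a matrix is a ``.npy`` file plus a JSON sidecar
recording the grid shape, the mask and the voxel order (C-order over z, y, x),
so any matrix can be re-inflated into volumes or exported to NIfTI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GMVMatrix", "read_gmv", "write_gmv", "export_nifti", "read_table", "write_table"]


@dataclass
class GMVMatrix:
    """Subjects-by-voxels grey-matter matrix with grid geometry.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, n_voxels)
        One row per subject; columns are the in-mask voxels in C-order.
    grid_shape : tuple of int or None
        3-D voxel grid dimensions.  ``None`` for purely tabular feature
        matrices (no spatial structure, smoothing disabled).
    mask : ndarray of bool, shape (prod(grid_shape),) or None
        Analysis mask in C-order; ``None`` means all grid voxels are in-mask.
    """

    data: np.ndarray
    grid_shape: tuple[int, int, int] | None = None
    mask: np.ndarray | None = None
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("GMV data must be 2-D (subjects x voxels)")
        if self.grid_shape is not None:
            self.grid_shape = tuple(int(d) for d in self.grid_shape)
            n_grid = int(np.prod(self.grid_shape))
            if self.mask is None:
                self.mask = np.ones(n_grid, dtype=bool)
            else:
                self.mask = np.asarray(self.mask, dtype=bool).ravel()
                if self.mask.size != n_grid:
                    raise ValueError(
                        f"mask has {self.mask.size} entries but grid {self.grid_shape} "
                        f"has {n_grid} voxels"
                    )
            if int(self.mask.sum()) != self.data.shape[1]:
                raise ValueError(
                    f"data has {self.data.shape[1]} columns but mask selects "
                    f"{int(self.mask.sum())} voxels"
                )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def to_volumes(self) -> np.ndarray:
        """Inflate to a ``(n_subjects, nx, ny, nz)`` stack (NaN off-mask)."""
        if self.grid_shape is None:
            raise ValueError("matrix has no grid geometry")
        vols = np.full((self.n_subjects, int(np.prod(self.grid_shape))), np.nan)
        vols[:, self.mask] = self.data
        return vols.reshape((self.n_subjects, *self.grid_shape))

    def select(self, idx) -> "GMVMatrix":
        """Row subset preserving geometry."""
        ids = None if self.subject_ids is None else np.asarray(self.subject_ids)[idx]
        return GMVMatrix(self.data[idx], self.grid_shape, self.mask, ids)


def write_gmv(gmv: GMVMatrix, path: str | Path) -> Path:
    """Write matrix + JSON sidecar; returns the matrix path (``<path>.npy``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mat_path = path.with_suffix(".npy")
    np.save(mat_path, gmv.data)
    sidecar = {
        "grid_shape": None if gmv.grid_shape is None else list(gmv.grid_shape),
        "mask": None if gmv.mask is None else gmv.mask.astype(int).tolist(),
        "voxel_order": "C(z,y,x)",
        "n_subjects": gmv.n_subjects,
        "n_voxels": gmv.n_voxels,
        "subject_ids": None if gmv.subject_ids is None else list(map(str, gmv.subject_ids)),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return mat_path


def read_gmv(path: str | Path) -> GMVMatrix:
    """Read a matrix written by :func:`write_gmv` (bit-exact round trip)."""
    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    grid = sidecar.get("grid_shape")
    mask = sidecar.get("mask")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
    ids = sidecar.get("subject_ids")
    if ids is not None:
        ids = np.asarray(ids)
    if data.shape[0] != sidecar["n_subjects"] or data.shape[1] != sidecar["n_voxels"]:
        raise ValueError("sidecar/matrix shape mismatch")
    return GMVMatrix(data, None if grid is None else tuple(grid), mask, ids)


def export_nifti(values: np.ndarray, gmv: GMVMatrix, path: str | Path,
                 affine: np.ndarray | None = None) -> Path:
    """Export a per-voxel statistic vector as a NIfTI volume (off-mask = 0)."""
    import nibabel as nib

    if gmv.grid_shape is None:
        raise ValueError("cannot export NIfTI without grid geometry")
    vol = np.zeros(int(np.prod(gmv.grid_shape)))
    vol[gmv.mask] = np.asarray(values, dtype=float)
    img = nib.Nifti1Image(vol.reshape(gmv.grid_shape),
                          np.eye(4) if affine is None else affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


# CSV dialect is fixed (comma, UTF-8, '.' decimal, NA for missing) to avoid
# locale drift between runs.
_CSV_KW = dict(na_rep="NA", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, **_CSV_KW)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"])
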