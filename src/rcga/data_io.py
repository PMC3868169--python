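"""Reading and writing of volumetric images, ROI masks and subject tables.

Images and masks are exchanged as NIfTI-1 files on a common voxel grid;
subject tables are TSV with columns ``subject_id``, ``group``, ``image_path``.
Voxel indices are 0-based throughout; world (MNI) coordinates are produced
only through the image affine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

GROUPS = ("patient", "control")


@dataclass
class Image4D:
    """A 4D BOLD image: spatial grid (X, Y, Z) by time T.

    Parameters
    ----------
    values : ndarray, shape (X, Y, Z, T)
        BOLD intensities (arbitrary units).
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm transform; must be invertible.
    tr : float
        Repetition time in seconds.
    """

    values: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError(f"expected 4D image, got {self.values.ndim}D")
        if self.values.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if not (self.tr > 0):
            raise ValueError("tr must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[3]


@dataclass
class RoiMask:
    """A named binary 3D mask on the image grid."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got {arr.ndim}D")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                warnings.warn(
                    f"mask {self.name!r} has values outside {{0,1}}; "
                    "binarizing at > 0.5",
                    stacklevel=2,
                )
            arr = arr > 0.5
        self.values = arr
        if self.voxel_count < 1:
            raise ValueError(f"mask {self.name!r} is empty")

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class VoxelTimeSeriesMatrix:
    """T x V matrix of one subject's voxel time series inside one ROI.

    Columns follow ascending C-order linearized (x, y, z) index order, which
    makes the column layout deterministic and independent of how the mask was
    constructed.
    """

    values: np.ndarray
    voxel_coords: np.ndarray  # (V, 3) int, 0-based grid indices
    tr: float
    roi_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=np.intp)
        if self.values.ndim != 2:
            raise ValueError("values must be T x V")
        if self.voxel_coords.shape != (self.values.shape[1], 3):
            raise ValueError("voxel_coords must be (V, 3)")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def mean_series(self) -> np.ndarray:
        """ROI-mean ("coarse-grained") time series: mean over all columns."""
        return self.values.mean(axis=1)


@dataclass
class SubjectTable:
    """Cohort table: one row per subject with group label and image path."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"subject_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"subject table missing columns: {sorted(missing)}")
        if self.table["subject_id"].duplicated().any():
            dupes = self.table.loc[
                self.table["subject_id"].duplicated(), "subject_id"
            ].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}; expected {GROUPS}")

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    @property
    def groups(self) -> np.ndarray:
        return self.table["group"].to_numpy()

    @property
    def n_patients(self) -> int:
        return int((self.groups == "patient").sum())

    @property
    def n_controls(self) -> int:
        return int((self.groups == "control").sum())

    def require_both_groups(self) -> None:
        if self.n_patients == 0 or self.n_controls == 0:
            raise ValueError("group comparison needs both patients and controls")


def load_image_4d(path: str | Path, tr: float | None = None) -> Image4D:
    """Load a 4D NIfTI image.

    TR is read from the header (4th zoom); an explicit ``tr`` argument
    overrides it (a mismatch emits a warning, the argument wins).
    Non-finite voxels are a hard error naming the first offending location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4D image, got {data.ndim}D: {path}")
    if not np.all(np.isfinite(data)):
        x, y, z, t = (int(i[0]) for i in np.nonzero(~np.isfinite(data)))
        raise ValueError(
            f"non-finite value at voxel ({x}, {y}, {z}), volume {t} in {path}"
        )
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr is None:
        if header_tr <= 0:
            raise ValueError(f"no TR in header of {path}; pass tr= explicitly")
        tr = header_tr
    elif header_tr > 0 and abs(header_tr - tr) > 1e-6:
        warnings.warn(
            f"header TR {header_tr:g}s != configured TR {tr:g}s; using configured",
            stacklevel=2,
        )
    return Image4D(values=data, affine=np.asarray(img.affine), tr=float(tr))


def save_image_4d(img: Image4D, path: str | Path, dtype=np.float32) -> None:
    """Write an :class:`Image4D` as NIfTI-1, recording TR in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = nib.Nifti1Image(img.values.astype(dtype), img.affine)
    zooms = list(out.header.get_zooms())
    zooms[3] = img.tr
    out.header.set_zooms(zooms)
    out.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(out, path)


def load_roi_mask(path: str | Path, name: str | None = None) -> RoiMask:
    """Load a 3D binary ROI mask from NIfTI."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D: {path}")
    return RoiMask(name=name or path.stem.removesuffix(".nii"), values=data)


def save_roi_mask(mask: RoiMask, affine: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), affine), path)


def extract_roi_matrix(img: Image4D, mask: RoiMask) -> VoxelTimeSeriesMatrix:
    """Extract the T x V time-series matrix of the voxels inside ``mask``.

    Column order is the ascending C-order linearized (x, y, z) index, so the
    result does not depend on mask construction order.
    """
    if mask.shape != img.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} != image spatial shape {img.spatial_shape}"
        )
    coords = np.argwhere(mask.values)  # already sorted in C order
    mat = img.values[mask.values]  # (V, T) in C order, matching coords
    return VoxelTimeSeriesMatrix(
        values=mat.T, voxel_coords=coords, tr=img.tr, roi_name=mask.name
    )


def read_subject_table(path: str | Path) -> SubjectTable:
    """Read a TSV subject table (subject_id, group[, image_path])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SubjectTable(table=df)


def write_subject_table(table: SubjectTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.table.to_csv(path, sep="\t", index=False)
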