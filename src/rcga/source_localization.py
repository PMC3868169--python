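"""Locating source voxels behind altered inter-regional connectivity.

The dysfunction intensity of voxel i in region A, probed against region B,
is the fraction of B's voxels whose link with i differs between groups at
P < alpha:

    I_i = N_i^B(P < alpha) / N^B,   I_i in [0, 1].

Aggregating many noisy single-link tests into this per-voxel fraction is
what makes the localization robust. Voxels with intensity strictly above a
threshold (0.15 for reporting; 0.1 inside classification training splits)
form the source mask; an ROI probed by several links takes the elementwise
maximum of its per-link intensities. Source masks are summarized by their
18-connected clusters (face and edge neighbors, corners excluded) with peak
voxels reported in world (MNI) coordinates via the image affine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_io import VoxelTimeSeriesMatrix
from .link_stats import LinkPValueMatrix

DEFAULT_THETA = 0.15
CLASSIFY_THETA = 0.10

# 18-connectivity: offsets with each |d| <= 1 and |dx|+|dy|+|dz| <= 2
STRUCTURE_18 = ndimage.generate_binary_structure(3, 2)


@dataclass
class IntensityMap:
    """Per-voxel dysfunction intensity, aligned to a ROI's voxel columns."""

    values: np.ndarray
    n_other: np.ndarray  # per-voxel denominator N^B (the winning link's, if combined)
    alpha: float
    link_label: str
    voxel_coords: np.ndarray | None = None  # (V, 3), optional grid alignment

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.n_other = np.broadcast_to(
            np.asarray(self.n_other, dtype=np.int64), self.values.shape
        ).copy()
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("intensities must lie in [0, 1]")
        counts = self.values * self.n_other
        if not np.allclose(counts, np.round(counts), atol=1e-6):
            raise ValueError("intensity * denominator must be integer counts")

    @property
    def counts(self) -> np.ndarray:
        """Significant-link counts N_i^B recovered from the fractions."""
        return np.round(self.values * self.n_other).astype(np.int64)


@dataclass
class SourceMask:
    """Boolean per-voxel selection at intensity threshold theta (strict >)."""

    values: np.ndarray
    threshold: float
    voxel_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")

    @property
    def source_count(self) -> int:
        return int(self.values.sum())


def intensity_from_pvalues(
    pmat: LinkPValueMatrix,
    side: str = "rows",
    alpha: float | None = None,
    voxel_coords: np.ndarray | None = None,
) -> IntensityMap:
    """Dysfunction intensity of each voxel on one side of a link p-matrix.

    ``side="rows"`` scores region-A voxels against region B (denominator Vb);
    ``side="cols"`` scores region-B voxels (denominator Va).
    """
    if alpha is None:
        alpha = pmat.alpha
    p = np.asarray(pmat.p, dtype=np.float64)
    if not np.all(np.isfinite(p)):
        raise ValueError("p-value matrix contains non-finite entries")
    sig = p < alpha
    if side == "rows":
        counts, denom = sig.sum(axis=1), p.shape[1]
        label = f"{pmat.roi_a}|{pmat.roi_a}-{pmat.roi_b}"
    elif side == "cols":
        counts, denom = sig.sum(axis=0), p.shape[0]
        label = f"{pmat.roi_b}|{pmat.roi_a}-{pmat.roi_b}"
    else:
        raise ValueError("side must be 'rows' or 'cols'")
    return IntensityMap(
        values=counts / denom,
        n_other=np.full(counts.shape, denom, dtype=np.int64),
        alpha=alpha,
        link_label=label,
        voxel_coords=voxel_coords,
    )


def combine_max(maps: list[IntensityMap]) -> IntensityMap:
    """Elementwise maximum of per-link intensities on a shared ROI.

    This generalizes the rule used for an ROI probed by two links (take, per
    voxel, the larger of the two link intensities) to any number of links.
    The denominator recorded per voxel is the winning link's.
    """
    if not maps:
        raise ValueError("need at least one intensity map")
    shape = maps[0].values.shape
    for m in maps[1:]:
        if m.values.shape != shape:
            raise ValueError("intensity maps are not aligned on the same voxel set")
        if maps[0].voxel_coords is not None and m.voxel_coords is not None:
            if not np.array_equal(maps[0].voxel_coords, m.voxel_coords):
                raise ValueError("intensity maps have different voxel coordinates")
    stacked = np.stack([m.values for m in maps])
    winner = np.argmax(stacked, axis=0)  # ties -> first map, deterministic
    idx = np.arange(stacked.shape[1])
    values = stacked[winner, idx]
    n_other = np.stack([m.n_other for m in maps])[winner, idx]
    return IntensityMap(
        values=values,
        n_other=n_other,
        alpha=maps[0].alpha,
        link_label="max(" + ",".join(m.link_label for m in maps) + ")",
        voxel_coords=maps[0].voxel_coords,
    )


def threshold_mask(imap: IntensityMap, theta: float = DEFAULT_THETA) -> SourceMask:
    """Select source voxels with intensity strictly greater than ``theta``."""
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must be in (0, 1)")
    values = imap.values > theta
    if not values.any():
        warnings.warn(
            f"no voxel exceeds intensity threshold {theta}; "
            "consider lowering theta",
            stacklevel=2,
        )
    return SourceMask(values=values, threshold=theta, voxel_coords=imap.voxel_coords)


def _labels_from_coords(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """18-connected component label per voxel, from (N, 3) integer coords."""
    coords = np.asarray(coords, dtype=np.intp)
    origin = coords.min(axis=0)
    local = coords - origin
    grid = np.zeros(local.max(axis=0) + 1, dtype=bool)
    grid[tuple(local.T)] = True
    lab, _ = ndimage.label(grid, structure=STRUCTURE_18)
    return lab[tuple(local.T)], origin


def connected_components_18(coords: np.ndarray) -> np.ndarray:
    """Cluster ids for mask voxels given as (N, 3) integer coordinates.

    Two voxels are neighbors iff they differ by at most 1 on each axis and
    share a face or an edge (the 8 corner offsets are not neighbors).
    Ids are 1..K ordered by descending cluster size, ties broken by the
    lowest member linearized coordinate.
    """
    coords = np.asarray(coords, dtype=np.intp)
    if coords.size == 0:
        return np.zeros(0, dtype=np.int64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    raw, _ = _labels_from_coords(coords)
    sizes = np.bincount(raw)
    # canonical ordering: size desc, then lowest first-member index (coords
    # are in ascending linearized order already for our extraction pipeline,
    # but re-derive the linear index to stay order-independent)
    span = coords.max(axis=0) - coords.min(axis=0) + 1
    lin = np.ravel_multi_index((coords - coords.min(axis=0)).T, span)
    first_lin = np.full(sizes.shape, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(first_lin, raw, lin)
    ids = np.arange(sizes.shape[0])
    ids = ids[ids > 0]
    ranked = sorted(ids, key=lambda k: (-sizes[k], first_lin[k]))
    remap = np.zeros(sizes.shape[0], dtype=np.int64)
    for new, old in enumerate(ranked, start=1):
        remap[old] = new
    return remap[raw]


def voxel_to_world(index, affine: np.ndarray) -> np.ndarray:
    """Map a 0-based voxel index (i, j, k) to world mm via the affine."""
    index = np.asarray(index, dtype=np.float64)
    hom = np.append(index, 1.0)
    return (np.asarray(affine, dtype=np.float64) @ hom)[:3]


def peak_voxel(
    imap: IntensityMap, member_indices: np.ndarray
) -> tuple[int, float]:
    """Arg-max intensity within a cluster (indices into the voxel columns).

    Ties are broken by the lowest linear voxel index, i.e. the first member
    in canonical column order.
    """
    member_indices = np.asarray(member_indices, dtype=np.intp)
    if member_indices.size == 0:
        raise ValueError("cluster is empty")
    member_indices = np.sort(member_indices)
    vals = imap.values[member_indices]
    best = member_indices[int(np.argmax(vals))]  # argmax returns first max
    return int(best), float(imap.values[best])


def cluster_table(
    imap: IntensityMap,
    mask: SourceMask,
    affine: np.ndarray | None = None,
    link_p: np.ndarray | None = None,
) -> pd.DataFrame:
    """18-connected cluster summary of a source mask.

    Columns: cluster_id, size, peak voxel grid index, peak world mm
    (NaN without an affine), peak_intensity, and — when a per-voxel link
    p-value summary is supplied — ``min_link_p`` at the peak voxel (reported
    as an interpretation of a per-peak p-value; the choice is documented).
    Cluster ids are ordered by descending size, ties by lowest linear index.
    """
    cols = [
        "cluster_id", "size", "peak_i", "peak_j", "peak_k",
        "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_intensity", "min_link_p",
    ]
    if mask.source_count == 0:
        return pd.DataFrame(columns=cols)
    if imap.voxel_coords is None:
        raise ValueError("intensity map needs voxel_coords for clustering")
    sel = np.flatnonzero(mask.values)
    coords = np.asarray(imap.voxel_coords)[sel]
    labels = connected_components_18(coords)
    rows = []
    for cid in range(1, labels.max() + 1):
        members = sel[labels == cid]
        peak, peak_val = peak_voxel(imap, members)
        ijk = np.asarray(imap.voxel_coords)[peak]
        world = voxel_to_world(ijk, affine) if affine is not None else [np.nan] * 3
        rows.append({
            "cluster_id": cid,
            "size": int(members.size),
            "peak_i": int(ijk[0]), "peak_j": int(ijk[1]), "peak_k": int(ijk[2]),
            "peak_x_mm": float(world[0]), "peak_y_mm": float(world[1]),
            "peak_z_mm": float(world[2]),
            "peak_intensity": peak_val,
            "min_link_p": float(link_p[peak]) if link_p is not None else np.nan,
        })
    df = pd.DataFrame(rows, columns=cols)
    total = int(df["size"].sum())
    assert total == mask.source_count, "cluster sizes must sum to source count"
    return df


def source_mean_series(
    mat: VoxelTimeSeriesMatrix | np.ndarray, mask: SourceMask | np.ndarray
) -> np.ndarray:
    """Voxel-wise time series: unweighted mean over the source columns."""
    values = mat.values if isinstance(mat, VoxelTimeSeriesMatrix) else np.asarray(mat)
    sel = mask.values if isinstance(mask, SourceMask) else np.asarray(mask, dtype=bool)
    if sel.shape != (values.shape[1],):
        raise ValueError("mask length must equal the number of voxel columns")
    if not sel.any():
        raise ValueError(
            "source mask is empty; lower the intensity threshold theta"
        )
    return values[:, sel].mean(axis=1)
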