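"""Inter-regional voxel-pair correlations and per-link group tests.

For every pair of voxels (i in region A, j in region B) and every subject,
the Pearson correlation r_ij is Fisher r-to-z transformed, and a two-sample
t-test across subjects compares patients with controls link by link. No
multiple-testing correction is applied at the link level: single-link tests
are noisy by design, and robustness is recovered downstream by aggregating
links into a per-voxel dysfunction intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.05
_R_CLIP = 1.0 - 1e-7


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two series.

    Returns NaN (flagged undefined) for zero-variance input; such links are
    excluded downstream rather than propagated.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 time points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:  # exactly constant input
        return np.nan
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def interregional_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All cross correlations between columns of two T x V matrices.

    Entry (i, j) is ``pearson_r(a[:, i], b[:, j])``; zero-variance columns
    yield NaN entries.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape[0] != b.shape[0]:
        raise ValueError("matrices must share the time dimension")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    na = np.sqrt(np.einsum("tv,tv->v", ac, ac))
    nb = np.sqrt(np.einsum("tv,tv->v", bc, bc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac.T @ bc) / np.outer(na, nb)
    np.clip(r, -1.0, 1.0, out=r)
    # exactly constant columns are undefined links, not perfect correlations
    r[np.ptp(a, axis=0) == 0.0, :] = np.nan
    r[:, np.ptp(b, axis=0) == 0.0] = np.nan
    return r


def fisher_z(r: np.ndarray | float, warn_on_clip: bool = True):
    """Variance-stabilizing transform z = atanh(r) = 0.5*ln((1+r)/(1-r)).

    |r| >= 1 is clipped just inside the open interval with a warning so that
    perfectly correlated toy inputs stay finite.
    """
    r = np.asarray(r, dtype=np.float64)
    if r.size and np.any(np.isfinite(r)):
        if warn_on_clip and np.nanmax(np.abs(r)) >= 1.0:
            warnings.warn("|r| >= 1 clipped before Fisher transform", stacklevel=2)
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    return float(z) if z.ndim == 0 else z


def two_sample_t(
    a: np.ndarray, b: np.ndarray, axis: int = 0, welch: bool = False
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two-sample t-test of group means, pooled variance by default.

    Returns (t, p, df) with two-sided p. Degenerate links where both groups
    are constant and equal give t=0, p=1 rather than NaN.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.shape[axis], b.shape[axis]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = a.mean(axis=axis) - b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1)
    vb = b.var(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = va / na + vb / nb
            df = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se2 = sp2 * (1.0 / na + 1.0 / nb)
            df = np.float64(na + nb - 2)
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero pooled variance: identical constant groups mean "no difference",
    # constant groups with unequal means a certain one
    zero = np.asarray(se2 == 0.0)
    if np.any(zero):
        with np.errstate(invalid="ignore"):
            signed_inf = np.where(diff == 0, 0.0, np.sign(diff) * np.inf)
        t = np.where(zero, signed_inf, t)
        p = np.where(zero, np.where(diff == 0, 1.0, 0.0), p)
    if np.ndim(t) == 0:
        return float(t), float(p), float(df)
    return t, p, df if welch else float(df)


@dataclass
class CorrelationStack:
    """Per-subject inter-regional correlations for one ROI pair.

    ``r`` and ``z`` are S x Va x Vb; ``group_labels`` is the S-vector of
    {"patient", "control"}.
    """

    r: np.ndarray
    z: np.ndarray
    group_labels: np.ndarray
    roi_a: str = "A"
    roi_b: str = "B"

    def __post_init__(self) -> None:
        self.group_labels = np.asarray(self.group_labels)
        if self.r.shape != self.z.shape:
            raise ValueError("r and z must have the same shape")
        if self.r.shape[0] != self.group_labels.shape[0]:
            raise ValueError("one label per subject required")

    @property
    def n_subjects(self) -> int:
        return self.r.shape[0]


def correlation_stack(
    mats_a: list[np.ndarray],
    mats_b: list[np.ndarray],
    group_labels,
    roi_a: str = "A",
    roi_b: str = "B",
) -> CorrelationStack:
    """Build the S x Va x Vb correlation/z stack from per-subject matrices."""
    if len(mats_a) != len(mats_b):
        raise ValueError("need one matrix pair per subject")
    a = np.stack([np.asarray(m, dtype=np.float64) for m in mats_a])  # (S,T,Va)
    b = np.stack([np.asarray(m, dtype=np.float64) for m in mats_b])
    if a.shape[1] != b.shape[1]:
        raise ValueError("matrices must share the time dimension")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt(np.einsum("stv,stv->sv", ac, ac))
    nb = np.sqrt(np.einsum("stv,stv->sv", bc, bc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac.transpose(0, 2, 1) @ bc) / (na[:, :, None] * nb[:, None, :])
    np.clip(r, -1.0, 1.0, out=r)
    # exactly constant columns are undefined links, not perfect correlations
    s_idx, v_idx = np.nonzero(np.ptp(a, axis=1) == 0.0)
    r[s_idx, v_idx, :] = np.nan
    s_idx, v_idx = np.nonzero(np.ptp(b, axis=1) == 0.0)
    r[s_idx, :, v_idx] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = fisher_z(r, warn_on_clip=False)
    return CorrelationStack(
        r=r, z=z, group_labels=np.asarray(group_labels), roi_a=roi_a, roi_b=roi_b
    )


@dataclass
class LinkPValueMatrix:
    """Va x Vb group-difference p-values (and t statistics) for all links."""

    p: np.ndarray
    t: np.ndarray
    df: float
    alpha: float = DEFAULT_ALPHA
    excluded: np.ndarray | None = None
    roi_a: str = "A"
    roi_b: str = "B"

    def __post_init__(self) -> None:
        if self.excluded is None:
            self.excluded = np.zeros(self.p.shape, dtype=bool)
        if not (self.p.shape == self.t.shape == self.excluded.shape):
            raise ValueError("p, t and excluded must share a shape")


def pvalues_from_z(
    z: np.ndarray,
    group_labels,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
    roi_a: str = "A",
    roi_b: str = "B",
) -> LinkPValueMatrix:
    """Per-link two-sample t-test on an S x Va x Vb Fisher-z array.

    Links undefined for any subject (zero-variance voxel) are excluded:
    p is set to 1 so they can never contribute to a dysfunction intensity.
    """
    labels = np.asarray(group_labels)
    pat = labels == "patient"
    con = labels == "control"
    if pat.sum() < 2 or con.sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    excluded = ~np.all(np.isfinite(z), axis=0)
    if excluded.any():
        z = np.where(np.isfinite(z), z, 0.0)
    t, p, df = two_sample_t(z[pat], z[con], axis=0, welch=welch)
    if excluded.any():
        t = np.where(excluded, 0.0, t)
        p = np.where(excluded, 1.0, p)
    return LinkPValueMatrix(
        p=p, t=t, df=df, alpha=alpha, excluded=excluded,
        roi_a=roi_a, roi_b=roi_b,
    )


def link_pvalue_matrix(
    stack: CorrelationStack, alpha: float = DEFAULT_ALPHA, welch: bool = False
) -> LinkPValueMatrix:
    """Per-link group test for a full correlation stack (see pvalues_from_z)."""
    return pvalues_from_z(
        stack.z, stack.group_labels, alpha=alpha, welch=welch,
        roi_a=stack.roi_a, roi_b=stack.roi_b,
    )
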