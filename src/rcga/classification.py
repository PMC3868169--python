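"""Patients-vs-controls classification from the two link correlations.

Features are the per-subject correlation coefficients of the two analyzed
links, computed either from ROI-mean series ("roi" mode) or from source-mean
series ("voxel" mode). In voxel mode the source voxels are re-located on the
training subjects only (intensity > theta, default 0.1), and the test
subjects' features are computed with the training-derived masks — test data
never influence the localization.

The classifier follows the reference protocol: RBF-kernel SVM with C = 10,
kernel width at the conventional 1/n_features default, features standardized
per split with the training mean/SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .link_stats import correlation_stack, pearson_r, pvalues_from_z
from .source_localization import (
    CLASSIFY_THETA,
    combine_max,
    intensity_from_pvalues,
    source_mean_series,
    threshold_mask,
)

logger = logging.getLogger(__name__)

FRACTION_SCHEMES = (0.40, 0.50, 0.60, 0.70)


@dataclass
class ClassificationResult:
    """Mean test metrics (percent) over repeated splits or LOO folds."""

    scheme: str
    mode: str
    n_repeats: int
    accuracy: float
    specificity: float
    sensitivity: float
    seed: int | None
    n_fallback: int = 0  # splits where an empty source mask forced roi mode


@dataclass
class FeatureTable:
    """S x 2 link-correlation features with subject labels."""

    values: np.ndarray
    labels: np.ndarray
    mode: str
    theta: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("features must be S x n_links")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per subject required")


def roi_mean_features(
    pre_mats: dict[str, list[np.ndarray]], link_pairs: list[tuple[str, str]]
) -> np.ndarray:
    """Per-subject correlations of ROI-mean series for each link."""
    n_sub = len(next(iter(pre_mats.values())))
    feats = np.empty((n_sub, len(link_pairs)))
    for j, (ra, rb) in enumerate(link_pairs):
        for s in range(n_sub):
            feats[s, j] = pearson_r(
                pre_mats[ra][s].mean(axis=1), pre_mats[rb][s].mean(axis=1)
            )
    return feats


class VoxelFeatureBuilder:
    """Builds voxel-mode features with sources located on a training split.

    Correlation/z stacks for every link are computed once; each call then
    restricts the group test to the training subjects, derives the source
    masks (per-link intensities combined by elementwise max on shared ROIs,
    threshold strictly > theta) and returns the S x n_links correlations of
    source-mean series for ALL subjects under those masks.
    """

    def __init__(
        self,
        pre_mats: dict[str, list[np.ndarray]],
        labels,
        link_pairs: list[tuple[str, str]],
        alpha: float = 0.05,
        theta: float = CLASSIFY_THETA,
    ) -> None:
        self.pre_mats = pre_mats
        self.labels = np.asarray(labels)
        self.link_pairs = list(link_pairs)
        self.alpha = alpha
        self.theta = theta
        self.z_stacks: dict[tuple[str, str], np.ndarray] = {}
        for ra, rb in self.link_pairs:
            stack = correlation_stack(
                pre_mats[ra], pre_mats[rb], self.labels, roi_a=ra, roi_b=rb
            )
            self.z_stacks[(ra, rb)] = stack.z  # r not needed for localization
        self._roi_features = roi_mean_features(pre_mats, self.link_pairs)

    @property
    def roi_features(self) -> np.ndarray:
        return self._roi_features

    def masks_for(self, train_idx: np.ndarray) -> dict[str, np.ndarray]:
        """Source masks per ROI derived from the training subjects only."""
        train_idx = np.asarray(train_idx)
        per_roi: dict[str, list] = {}
        for (ra, rb), z in self.z_stacks.items():
            pmat = pvalues_from_z(
                z[train_idx], self.labels[train_idx], alpha=self.alpha,
                roi_a=ra, roi_b=rb,
            )
            per_roi.setdefault(ra, []).append(
                intensity_from_pvalues(pmat, side="rows")
            )
            per_roi.setdefault(rb, []).append(
                intensity_from_pvalues(pmat, side="cols")
            )
        masks = {}
        for roi, maps in per_roi.items():
            imap = combine_max(maps) if len(maps) > 1 else maps[0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                masks[roi] = threshold_mask(imap, theta=self.theta).values
        return masks

    def __call__(self, train_idx: np.ndarray) -> tuple[np.ndarray, bool]:
        """Features for all subjects; falls back to roi mode on empty masks."""
        masks = self.masks_for(train_idx)
        if any(not m.any() for m in masks.values()):
            logger.info("empty source mask in split; falling back to ROI mode")
            return self._roi_features, True
        n_sub = len(self.labels)
        feats = np.empty((n_sub, len(self.link_pairs)))
        means = {
            roi: np.stack(
                [source_mean_series(m, masks[roi]) for m in self.pre_mats[roi]]
            )
            for roi in masks
        }
        for j, (ra, rb) in enumerate(self.link_pairs):
            for s in range(n_sub):
                feats[s, j] = pearson_r(means[ra][s], means[rb][s])
        return feats, False


class FixedFeatureBuilder:
    """Wraps a precomputed feature matrix (roi mode: split-independent)."""

    def __init__(self, features: np.ndarray) -> None:
        self.features = np.asarray(features, dtype=np.float64)

    def __call__(self, train_idx) -> tuple[np.ndarray, bool]:
        return self.features, False


def _fit_predict(
    features: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    c: float,
) -> np.ndarray:
    x_train = features[train_idx]
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(C=c, kernel="rbf", gamma="auto")
    clf.fit((x_train - mu) / sd, y[train_idx])
    return clf.predict((features[test_idx] - mu) / sd)


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, specificity, sensitivity); patient coded 1 is positive."""
    acc = float((y_true == y_pred).mean())
    sens = float((y_pred[y_true == 1] == 1).mean()) if (y_true == 1).any() else np.nan
    spec = float((y_pred[y_true == 0] == 0).mean()) if (y_true == 0).any() else np.nan
    return acc, spec, sens


def evaluate_scheme(
    features_builder,
    labels,
    scheme: float | str,
    n_repeats: int = 5000,
    seed: int | None = 0,
    c: float = 10.0,
    mode: str = "unspecified",
    theta: float | None = None,
) -> ClassificationResult:
    """Mean accuracy/specificity/sensitivity under a split scheme.

    ``scheme`` is a training fraction in (0, 1) — stratified random splits
    repeated ``n_repeats`` times — or ``"loo"`` for deterministic
    leave-one-subject-out. Sensitivity is patient recall, specificity is
    control recall; all metrics are percentages of test subjects.
    """
    labels = np.asarray(labels)
    y = (labels == "patient").astype(int)
    n = len(y)
    idx_pat = np.flatnonzero(y == 1)
    idx_con = np.flatnonzero(y == 0)
    if len(idx_pat) < 2 or len(idx_con) < 2:
        raise ValueError("need at least 2 subjects per group")
    n_fallback = 0

    if scheme == "loo":
        preds = np.empty(n, dtype=int)
        for i in range(n):
            train = np.delete(np.arange(n), i)
            feats, fb = features_builder(train)
            n_fallback += int(fb)
            preds[i] = _fit_predict(feats, y, train, np.array([i]), c)[0]
        acc, spec, sens = _metrics(y, preds)
        return ClassificationResult(
            scheme="loo", mode=mode, n_repeats=n,
            accuracy=100 * acc, specificity=100 * spec, sensitivity=100 * sens,
            seed=seed, n_fallback=n_fallback,
        )

    frac = float(scheme)
    if not (0.0 < frac < 1.0):
        raise ValueError(f"training fraction must be in (0, 1), got {frac}")
    n_tr_pat = int(np.clip(round(frac * len(idx_pat)), 1, len(idx_pat) - 1))
    n_tr_con = int(np.clip(round(frac * len(idx_con)), 1, len(idx_con) - 1))
    rng = np.random.default_rng(seed)
    accs = np.empty(n_repeats)
    specs = np.empty(n_repeats)
    senss = np.empty(n_repeats)
    for rep in range(n_repeats):
        tr = np.concatenate([
            rng.choice(idx_pat, size=n_tr_pat, replace=False),
            rng.choice(idx_con, size=n_tr_con, replace=False),
        ])
        te = np.setdiff1d(np.arange(n), tr)
        feats, fb = features_builder(tr)
        n_fallback += int(fb)
        preds = _fit_predict(feats, y, tr, te, c)
        accs[rep], specs[rep], senss[rep] = _metrics(y[te], preds)
    return ClassificationResult(
        scheme=f"{frac:.2f}", mode=mode, n_repeats=n_repeats,
        accuracy=100 * float(np.mean(accs)),
        specificity=100 * float(np.mean(specs)),
        sensitivity=100 * float(np.mean(senss)),
        seed=seed, n_fallback=n_fallback,
    )
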