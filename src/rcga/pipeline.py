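"""End-to-end orchestration: simulate -> preprocess -> locate -> effects ->
ALFF -> classify.

Two layers live here. The in-memory helpers (`preprocess_matrices`,
`locate_sources`, `link_effects_table`, `alff_table`, `classify_cohort`)
operate on per-subject per-ROI time-series matrices and are what tests,
examples and the acceptance script drive. `run_pipeline` is the file-based
runner behind the CLI: it reads/writes NIfTI + TSV/JSON artifacts, records
a manifest with a config hash, and is idempotent for an unchanged config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alff import compute_alff
from .classification import (
    ClassificationResult,
    FixedFeatureBuilder,
    VoxelFeatureBuilder,
    evaluate_scheme,
    roi_mean_features,
)
from .data_io import (
    extract_roi_matrix,
    load_image_4d,
    load_roi_mask,
    read_subject_table,
)
from .effect_measures import EffectResult, link_effect
from .link_stats import correlation_stack, link_pvalue_matrix
from .preprocess import DEFAULT_BAND, DEFAULT_FILTER_ORDER, preprocess_series
from .source_localization import (
    IntensityMap,
    SourceMask,
    cluster_table,
    combine_max,
    intensity_from_pvalues,
    threshold_mask,
)
from .synthetic_data import CohortSpec, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "locate", "effects", "alff", "classify")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and context."""


# --------------------------------------------------------------------------
# in-memory analysis helpers


def preprocess_matrices(
    mats: dict[str, list[np.ndarray]],
    tr: float,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_FILTER_ORDER,
    nuisance=None,
) -> dict[str, list[np.ndarray]]:
    """Detrend + band-pass (+ optional nuisance regression) every matrix.

    Subjects of one ROI are filtered as a single wide matrix (the cleaning is
    columnwise) and split back, which keeps the per-series semantics while
    avoiding hundreds of small filter calls.
    """
    out: dict[str, list[np.ndarray]] = {}
    for roi, subject_mats in mats.items():
        widths = [m.shape[1] for m in subject_mats]
        stacked = np.concatenate(subject_mats, axis=1)
        cleaned = preprocess_series(
            stacked, tr, low=band[0], high=band[1], order=order,
            nuisance=nuisance,
        )
        out[roi] = list(np.split(cleaned, np.cumsum(widths)[:-1], axis=1))
    return out


@dataclass
class RoiSourceResult:
    """Localization output for one ROI."""

    roi: str
    intensity: IntensityMap
    mask: SourceMask
    clusters: pd.DataFrame
    min_link_p: np.ndarray  # per-voxel minimum link p over all probing links


def locate_sources(
    pre: dict[str, list[np.ndarray]],
    labels,
    link_pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    theta: float = 0.15,
    coords: dict[str, np.ndarray] | None = None,
    affine: np.ndarray | None = None,
) -> dict[str, RoiSourceResult]:
    """Run the reversal coarse-grained localization for every ROI.

    Per link: per-subject cross correlations, Fisher z, per-link two-sample
    t-tests; per ROI: dysfunction intensities (combined across links by
    elementwise max for shared ROIs), strict thresholding at ``theta``, and
    18-connected cluster summaries.
    """
    labels = np.asarray(labels)
    per_roi_maps: dict[str, list[IntensityMap]] = {}
    per_roi_minp: dict[str, np.ndarray] = {}
    for ra, rb in link_pairs:
        stack = correlation_stack(pre[ra], pre[rb], labels, roi_a=ra, roi_b=rb)
        pmat = link_pvalue_matrix(stack, alpha=alpha)
        for roi, side, axis in ((ra, "rows", 1), (rb, "cols", 0)):
            imap = intensity_from_pvalues(
                pmat, side=side, voxel_coords=None if coords is None else coords[roi]
            )
            per_roi_maps.setdefault(roi, []).append(imap)
            minp = pmat.p.min(axis=axis)
            if roi in per_roi_minp:
                per_roi_minp[roi] = np.minimum(per_roi_minp[roi], minp)
            else:
                per_roi_minp[roi] = minp
    results: dict[str, RoiSourceResult] = {}
    for roi, maps in per_roi_maps.items():
        imap = combine_max(maps) if len(maps) > 1 else maps[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = threshold_mask(imap, theta=theta)
        if imap.voxel_coords is not None:
            clusters = cluster_table(
                imap, mask, affine=affine, link_p=per_roi_minp[roi]
            )
        else:
            clusters = pd.DataFrame()
        results[roi] = RoiSourceResult(
            roi=roi, intensity=imap, mask=mask, clusters=clusters,
            min_link_p=per_roi_minp[roi],
        )
    return results


def _series_per_subject(
    pre: dict[str, list[np.ndarray]],
    roi: str,
    mask: np.ndarray | None,
) -> list[np.ndarray]:
    """ROI-mean series (mask=None) or source-mean series for every subject."""
    if mask is None:
        return [m.mean(axis=1) for m in pre[roi]]
    return [m[:, mask].mean(axis=1) for m in pre[roi]]


def link_effects_table(
    pre: dict[str, list[np.ndarray]],
    labels,
    link_pairs: list[tuple[str, str]],
    masks: dict[str, np.ndarray] | None = None,
    alpha: float = 0.05,
    rule: str = "significant-positive-r",
    n_perm: int = 10000,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict[str, EffectResult]]:
    """OR/CI, RD with permutation p, and DOC for every link.

    ``masks=None`` gives ROI-wise results; passing per-ROI source masks gives
    voxel-wise results.
    """
    mode = "roi" if masks is None else "voxel"
    rows = []
    results: dict[str, EffectResult] = {}
    for ra, rb in link_pairs:
        sa = _series_per_subject(pre, ra, None if masks is None else masks[ra])
        sb = _series_per_subject(pre, rb, None if masks is None else masks[rb])
        res = link_effect(
            sa, sb, labels, alpha=alpha, rule=rule, n_perm=n_perm, seed=seed
        )
        name = f"{ra}-{rb}"
        results[name] = res
        rows.append({
            "link": name, "mode": mode,
            "OR": res.odds_ratio, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "RD": res.risk_difference, "p_perm": res.p_perm, "DOC": res.doc,
            "rule": res.rule, "alpha": res.alpha,
        })
    return pd.DataFrame(rows), results


def alff_table(
    pre: dict[str, list[np.ndarray]],
    labels,
    subject_ids,
    tr: float,
    masks: dict[str, np.ndarray] | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> pd.DataFrame:
    """Per subject/ROI ALFF of ROI-mean and (optionally) source-mean series."""
    labels = np.asarray(labels)
    rows = []
    for roi in pre:
        modes: list[tuple[str, np.ndarray | None]] = [("roi", None)]
        if masks is not None:
            modes.append(("voxel", masks[roi]))
        for mode, mask in modes:
            series = _series_per_subject(pre, roi, mask)
            for sid, group, s in zip(subject_ids, labels, series):
                rows.append({
                    "subject_id": sid, "group": group, "roi": roi,
                    "mode": mode, "alff": compute_alff(s, tr, band=band),
                })
    return pd.DataFrame(rows)


def classify_cohort(
    pre: dict[str, list[np.ndarray]],
    labels,
    link_pairs: list[tuple[str, str]],
    scheme: float | str = 0.5,
    n_repeats: int = 5000,
    seed: int | None = 0,
    theta: float = 0.1,
    alpha: float = 0.05,
) -> dict[str, ClassificationResult]:
    """ROI-mode and voxel-mode classification under one split scheme."""
    labels = np.asarray(labels)
    roi_builder = FixedFeatureBuilder(roi_mean_features(pre, link_pairs))
    voxel_builder = VoxelFeatureBuilder(
        pre, labels, link_pairs, alpha=alpha, theta=theta
    )
    return {
        "roi": evaluate_scheme(
            roi_builder, labels, scheme, n_repeats=n_repeats, seed=seed,
            mode="roi",
        ),
        "voxel": evaluate_scheme(
            voxel_builder, labels, scheme, n_repeats=n_repeats, seed=seed,
            mode="voxel", theta=theta,
        ),
    }


# --------------------------------------------------------------------------
# file-based runner


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str = "rcga_run"
    seed: int = 0
    # cohort (simulate stage)
    n_patients: int = 39
    n_controls: int = 37
    n_timepoints: int = 170
    tr: float = 2.0
    # signal cleaning
    band_low: float = 0.01
    band_high: float = 0.08
    filter_order: int = 4
    # localization / effects
    alpha: float = 0.05
    theta_locate: float = 0.15
    theta_classify: float = 0.10
    presence_rule: str = "significant-positive-r"
    n_perm: int = 10000
    # classification
    scheme: str = "0.5"
    n_repeats: int = 200
    # synthetic couplings
    a_control: float = 0.8
    a_patient: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high < 0.5 / self.tr):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")
        for theta in (self.theta_locate, self.theta_classify):
            if not (0 < theta < 1):
                raise ValueError("intensity thresholds must be in (0, 1)")
        if self.scheme != "loo":
            float(self.scheme)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls(**tomllib.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _cohort_spec(config: RunConfig) -> CohortSpec:
    return CohortSpec(
        n_patients=config.n_patients,
        n_controls=config.n_controls,
        n_timepoints=config.n_timepoints,
        tr=config.tr,
        a_control=config.a_control,
        a_patient=config.a_patient,
        band=(config.band_low, config.band_high),
        filter_order=config.filter_order,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages into ``config.out_dir``; returns the run directory.

    Re-running with an identical config and an existing complete manifest is
    a no-op. Any stage error is re-raised as :class:`PipelineError` naming
    the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == config.hash() and old.get("stages") == list(STAGES):
            logger.info("existing run with identical config found; skipping")
            return out

    spec = _cohort_spec(config)
    state: dict = {}

    def _stage(name, fn):
        logger.info("stage %s", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    def do_simulate():
        cohort = generate_cohort(spec, seed=config.seed)
        cohort.write(out / "data")
        state["cohort"] = cohort

    def do_preprocess():
        data_dir = out / "data"
        table = read_subject_table(data_dir / "subjects.tsv")
        table.require_both_groups()
        roi_names = [r.name for r in spec.rois]
        masks = {
            name: load_roi_mask(data_dir / f"roi_{name}.nii.gz", name=name)
            for name in roi_names
        }
        mats: dict[str, list[np.ndarray]] = {name: [] for name in roi_names}
        coords = {}
        affine = None
        for _, row in table.table.iterrows():
            img = load_image_4d(row["image_path"], tr=config.tr)
            affine = img.affine
            for name in roi_names:
                m = extract_roi_matrix(img, masks[name])
                mats[name].append(m.values)
                coords[name] = m.voxel_coords
        state.update(
            pre=preprocess_matrices(
                mats, config.tr, band=(config.band_low, config.band_high),
                order=config.filter_order,
            ),
            labels=table.groups, subject_ids=table.subject_ids,
            coords=coords, affine=affine,
            link_pairs=[(l.roi_a, l.roi_b) for l in spec.links],
        )

    def do_locate():
        import nibabel as nib

        results = locate_sources(
            state["pre"], state["labels"], state["link_pairs"],
            alpha=config.alpha, theta=config.theta_locate,
            coords=state["coords"], affine=state["affine"],
        )
        state["locate"] = results
        loc_dir = out / "locate"
        loc_dir.mkdir(exist_ok=True)
        for roi, res in results.items():
            vol = np.zeros(spec.shape)
            vol[tuple(np.asarray(state["coords"][roi]).T)] = res.intensity.values
            nib.save(nib.Nifti1Image(vol.astype(np.float32), state["affine"]),
                     loc_dir / f"intensity_{roi}.nii.gz")
            mvol = np.zeros(spec.shape, dtype=np.uint8)
            mvol[tuple(np.asarray(state["coords"][roi]).T)] = res.mask.values
            nib.save(nib.Nifti1Image(mvol, state["affine"]),
                     loc_dir / f"source_{roi}.nii.gz")
            res.clusters.to_csv(loc_dir / f"clusters_{roi}.tsv", sep="\t",
                                index=False)

    def do_effects():
        masks = {r: res.mask.values for r, res in state["locate"].items()}
        frames = []
        for use in (None, masks):
            if use is not None and any(not m.any() for m in use.values()):
                logger.warning("empty source mask; voxel-wise effects skipped")
                continue
            df, _ = link_effects_table(
                state["pre"], state["labels"], state["link_pairs"], masks=use,
                alpha=config.alpha, rule=config.presence_rule,
                n_perm=config.n_perm, seed=config.seed,
            )
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        df["seed"] = config.seed
        df.to_csv(out / "effects.tsv", sep="\t", index=False)
        state["effects"] = df

    def do_alff():
        masks = {r: res.mask.values for r, res in state["locate"].items()}
        if any(not m.any() for m in masks.values()):
            masks = None
        df = alff_table(
            state["pre"], state["labels"], state["subject_ids"], config.tr,
            masks=masks, band=(config.band_low, config.band_high),
        )
        df.to_csv(out / "alff.tsv", sep="\t", index=False)
        state["alff"] = df

    def do_classify():
        scheme = "loo" if config.scheme == "loo" else float(config.scheme)
        results = classify_cohort(
            state["pre"], state["labels"], state["link_pairs"],
            scheme=scheme, n_repeats=config.n_repeats, seed=config.seed,
            theta=config.theta_classify, alpha=config.alpha,
        )
        payload = {m: dataclasses.asdict(r) for m, r in results.items()}
        (out / "classification.json").write_text(json.dumps(payload, indent=2))
        state["classify"] = results

    for name, fn in zip(
        STAGES, (do_simulate, do_preprocess, do_locate, do_effects, do_alff,
                 do_classify)
    ):
        _stage(name, fn)

    manifest = {
        "package": "rcga",
        "version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": list(STAGES),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return out


def cohort_matrices(cohort: SyntheticCohort) -> dict[str, list[np.ndarray]]:
    """Raw per-ROI per-subject matrices of an in-memory synthetic cohort."""
    return {roi: cohort.matrices(roi) for roi in cohort.roi_names()}
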