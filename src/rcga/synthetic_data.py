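"""Synthetic two-group BOLD cohorts with known source subregions.

The generator emulates the data structure the localization method assumes:
two groups of subjects, a few ROIs on a shared grid, and inside each linked
ROI pair a compact "source" blob whose cross-ROI coupling is weaker in
patients. The generative model for voxel i of region r at time t is

    x_i(t) = a_g * c_l(t) + w * s_r(t) + sigma * eps_i(t)   (source voxel of link l)
    x_i(t) = sigma_nonsource * eps_i(t)                      (non-source voxel)

where the latent drive c_l is shared by both ROIs of link l, the regional
signal s_r by all of region r's source voxels, both band-limited
(0.01-0.08 Hz) unit-variance Gaussian processes, and eps_i is independent
AR(1) noise per voxel. Patients get a weaker coupling a_patient < a_control.

Non-source voxels are independent of everything (so every null property of
the link tests is exact) but noisier than source voxels
(sigma_nonsource > sigma): the coarse ROI average is thereby dominated by
non-informative signal, which is the regime the source localization exists
for. The default 5x ratio makes the non-source contribution to the ROI-mean
variance comparable to the planted circuit signal, emulating at desk scale
the heterogeneity of anatomical ROIs an order of magnitude larger.
Everything is seeded deterministically per subject.

Default sizes mirror the study conditions the method targets: 39 patients,
37 controls, 170 volumes at TR = 2 s; the 24^3 grid with ROIs of 256-384
voxels and blobs of 48-64 voxels is a desk-scale stand-in for ROIs of
352-1184 voxels.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .data_io import Image4D, RoiMask, SubjectTable, VoxelTimeSeriesMatrix
from .preprocess import bandpass_sos

_BURN_IN = 60  # AR(1) warm-up samples discarded
_LATENT_PAD = 80  # extra samples around latents before center-cropping


@dataclass(frozen=True)
class RoiGeom:
    """Axis-aligned ROI box, half-open voxel index ranges."""

    name: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class SourceBlob:
    """A compact true-source box inside one ROI, coupled to one link."""

    roi: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    link: str


@dataclass(frozen=True)
class LinkGeom:
    name: str
    roi_a: str
    roi_b: str


def _default_rois() -> tuple[RoiGeom, ...]:
    return (
        RoiGeom("regionA", ((2, 10), (2, 10), (2, 8))),    # 384 voxels
        RoiGeom("regionB", ((14, 22), (2, 10), (2, 6))),   # 256 voxels (shared)
        RoiGeom("regionC", ((8, 16), (14, 22), (8, 14))),  # 384 voxels
    )


def _default_blobs() -> tuple[SourceBlob, ...]:
    return (
        SourceBlob("regionA", ((4, 8), (4, 8), (3, 7)), "link1"),     # 64
        SourceBlob("regionB", ((16, 20), (2, 6), (2, 5)), "link1"),   # 48
        SourceBlob("regionB", ((16, 20), (6, 10), (2, 5)), "link2"),  # 48
        SourceBlob("regionC", ((10, 14), (16, 20), (9, 13)), "link2"),  # 64
    )


def _default_links() -> tuple[LinkGeom, ...]:
    return (
        LinkGeom("link1", "regionA", "regionB"),
        LinkGeom("link2", "regionB", "regionC"),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort (deterministic given a seed)."""

    n_patients: int = 39
    n_controls: int = 37
    n_timepoints: int = 170
    tr: float = 2.0
    shape: tuple[int, int, int] = (24, 24, 24)
    rois: tuple[RoiGeom, ...] = field(default_factory=_default_rois)
    blobs: tuple[SourceBlob, ...] = field(default_factory=_default_blobs)
    links: tuple[LinkGeom, ...] = field(default_factory=_default_links)
    a_control: float = 0.8
    a_patient: float = 0.2
    w: float = 0.5  # within-region source coherence
    sigma: float = 1.0
    sigma_nonsource: float = 5.0  # noise sd of non-source voxels
    rho: float = 0.3  # AR(1) coefficient of the voxel noise
    band: tuple[float, float] = (0.01, 0.08)
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.sigma_nonsource > 0):
            raise ValueError("noise sds must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.a_patient < 0 or self.a_control < 0:
            raise ValueError("coupling weights must be non-negative")
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("duplicate ROI names")
        link_names = {l.name for l in self.links}
        for link in self.links:
            if link.roi_a not in names or link.roi_b not in names:
                raise ValueError(f"link {link.name} references unknown ROI")
        for blob in self.blobs:
            if blob.roi not in names:
                raise ValueError(f"blob references unknown ROI {blob.roi}")
            if blob.link not in link_names:
                raise ValueError(f"blob references unknown link {blob.link}")
            roi = next(r for r in self.rois if r.name == blob.roi)
            for (blo, bhi), (rlo, rhi) in zip(blob.box, roi.box):
                if blo < rlo or bhi > rhi:
                    raise ValueError(
                        f"source blob outside ROI {blob.roi}: {blob.box}"
                    )

    def roi(self, name: str) -> RoiGeom:
        return next(r for r in self.rois if r.name == name)

    def a(self, group: str) -> float:
        if group == "patient":
            return self.a_patient
        if group == "control":
            return self.a_control
        raise ValueError(f"unknown group {group!r}")


def small_spec(**overrides) -> CohortSpec:
    """A fast cohort for smoke tests: fewer subjects, shorter scans."""
    base = CohortSpec(n_patients=4, n_controls=4, n_timepoints=96)
    return replace(base, **overrides)


def null_spec(base: CohortSpec | None = None) -> CohortSpec:
    """The null-calibration cohort: voxels carry no shared signal at all.

    Removing the group difference alone (a_control = a_patient) leaves the
    per-link group tests exactly null but keeps voxels within a source blob
    correlated through the shared latents; per-voxel significant-link counts
    are then overdispersed relative to Binomial and can occasionally cross
    the source threshold even with no group effect. The calibration of the
    intensity statistic itself (false-positive rate, Binomial count
    behavior, empty source masks) is defined on the fully decoupled null:
    a_control = a_patient = 0 and w = 0, i.e. all voxels independent noise.
    """
    base = base or CohortSpec()
    return replace(base, a_control=0.0, a_patient=0.0, w=0.0)


def _box_mask(shape, box) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    m[x0:x1, y0:y1, z0:z1] = True
    return m


def _roi_coords(spec: CohortSpec, roi: RoiGeom) -> np.ndarray:
    """(V, 3) voxel coordinates of the ROI in canonical C order."""
    return np.argwhere(_box_mask(spec.shape, roi.box))


@functools.lru_cache(maxsize=32)
def _filter_gain_integrals(
    tr: float, low: float, high: float, order: int, rho: float
) -> tuple[float, float, float]:
    """Quadrature of the zero-phase band-pass power gain |H|^4.

    Returns (v_raw, v_twice, v_noise):
      v_raw   = variance of once-filtered unit white noise  (int |H|^4),
      v_twice = variance after filtering the normalized latent again
                (int |H|^8 / v_raw),
      v_noise = variance of unit-variance AR(1) noise after one zero-phase
                filtering (int |H|^4 * S_AR1).
    Integrals are (1/pi) int_0^pi ... dw against the discrete-time spectrum.
    """
    sos = bandpass_sos(tr, low, high, order)
    w, h = sp_signal.sosfreqz(sos, worN=16384)
    gain2 = np.abs(h) ** 2  # forward-backward amplitude gain is |H|^2
    g4 = gain2 ** 2
    ar1 = (1.0 - rho**2) / (1.0 - 2.0 * rho * np.cos(w) + rho**2)
    v_raw = np.trapezoid(g4, w) / np.pi
    v_twice = np.trapezoid(g4 * g4, w) / np.pi / v_raw
    v_noise = np.trapezoid(g4 * ar1, w) / np.pi
    return float(v_raw), float(v_twice), float(v_noise)


def expected_source_correlation(spec: CohortSpec, group: str) -> float:
    """Closed-form cross-ROI correlation of a source-voxel pair.

    For two voxels that share a link latent with weight a_g, after the
    standard preprocessing (band-pass identical to the latent band):

        r = a_g^2 / (a_g^2 + w^2 + sigma_eff^2),

    where sigma_eff^2 is the band-passed AR(1) noise variance expressed in
    units of the band-passed latent variance, computed by quadrature over
    the filter response.
    """
    a = spec.a(group)
    if a == 0.0:
        return 0.0
    _, v_twice, v_noise = _filter_gain_integrals(
        spec.tr, spec.band[0], spec.band[1], spec.filter_order, spec.rho
    )
    sigma_eff2 = spec.sigma**2 * v_noise / v_twice
    return a**2 / (a**2 + spec.w**2 + sigma_eff2)


def _band_limited_latent(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Unit-variance band-limited Gaussian latent of length T."""
    t = spec.n_timepoints
    white = rng.standard_normal(t + 2 * _LATENT_PAD)
    sos = bandpass_sos(spec.tr, spec.band[0], spec.band[1], spec.filter_order)
    filt = sp_signal.sosfiltfilt(sos, white)
    v_raw, _, _ = _filter_gain_integrals(
        spec.tr, spec.band[0], spec.band[1], spec.filter_order, spec.rho
    )
    return filt[_LATENT_PAD:_LATENT_PAD + t] / np.sqrt(v_raw)


def _ar1_noise(rng: np.random.Generator, spec: CohortSpec, n_voxels: int) -> np.ndarray:
    """(T, V) stationary unit-variance AR(1) noise."""
    t = spec.n_timepoints
    eta = rng.standard_normal((t + _BURN_IN, n_voxels))
    if spec.rho == 0.0:
        return eta[_BURN_IN:]
    eps = sp_signal.lfilter([np.sqrt(1.0 - spec.rho**2)], [1.0, -spec.rho], eta, axis=0)
    return eps[_BURN_IN:]


@dataclass
class SyntheticCohort:
    """Generated cohort: per-subject per-ROI matrices plus ground truth."""

    spec: CohortSpec
    seed: int
    subjects: pd.DataFrame  # subject_id, group
    data: dict  # subject_id -> {roi_name: VoxelTimeSeriesMatrix}
    truth: dict  # roi_name -> bool (V,) true source columns
    affine: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        return self.subjects["group"].to_numpy()

    @property
    def subject_ids(self) -> list[str]:
        return self.subjects["subject_id"].tolist()

    def roi_names(self) -> list[str]:
        return [r.name for r in self.spec.rois]

    def roi_mask(self, name: str) -> RoiMask:
        geom = self.spec.roi(name)
        return RoiMask(name=name, values=_box_mask(self.spec.shape, geom.box))

    def truth_mask_3d(self, name: str) -> np.ndarray:
        coords = _roi_coords(self.spec, self.spec.roi(name))
        m = np.zeros(self.spec.shape, dtype=bool)
        m[tuple(coords[self.truth[name]].T)] = True
        return m

    def matrices(self, roi: str) -> list[np.ndarray]:
        """Per-subject raw (T, V) arrays for one ROI, in subject order."""
        return [self.data[s][roi].values for s in self.subject_ids]

    def write(self, outdir) -> dict:
        """Materialize the cohort as NIfTI files + subjects.tsv + truth masks.

        ROI voxels carry exactly the in-memory signals; the rest of the grid
        is filled with independent noise from a separate, equally seeded
        stream, so written and in-memory analyses agree.
        """
        from pathlib import Path

        import nibabel as nib

        from .data_io import save_image_4d, save_roi_mask, write_subject_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spec = self.spec
        bg_seeds = np.random.SeedSequence(
            entropy=(self.seed, 0xB0))  # background stream, disjoint from signals
        children = bg_seeds.spawn(len(self.subject_ids))
        roi_masks = {r.name: _box_mask(spec.shape, r.box) for r in spec.rois}
        rows = []
        for sid, child in zip(self.subject_ids, children):
            rng = np.random.default_rng(child)
            vol = (
                spec.sigma
                * rng.standard_normal(spec.shape + (spec.n_timepoints,))
            ).astype(np.float32).astype(np.float64)
            for roi_name, mat in self.data[sid].items():
                vol[roi_masks[roi_name]] = mat.values.T
            img = Image4D(values=vol, affine=self.affine, tr=spec.tr)
            path = outdir / f"{sid}.nii.gz"
            save_image_4d(img, path)
            group = self.subjects.set_index("subject_id").loc[sid, "group"]
            rows.append({"subject_id": sid, "group": group,
                         "image_path": str(path)})
        table = SubjectTable(table=pd.DataFrame(rows))
        write_subject_table(table, outdir / "subjects.tsv")
        for name, m in roi_masks.items():
            save_roi_mask(RoiMask(name=name, values=m), self.affine,
                          outdir / f"roi_{name}.nii.gz")
            nib.save(
                nib.Nifti1Image(self.truth_mask_3d(name).astype(np.uint8),
                                self.affine),
                outdir / f"truth_{name}.nii.gz",
            )
        return {"dir": str(outdir), "subjects": len(rows)}


def generate_cohort(spec: CohortSpec, seed: int = 0) -> SyntheticCohort:
    """Draw a cohort from the generative model, byte-reproducible per seed."""
    roi_coords = {r.name: _roi_coords(spec, r) for r in spec.rois}
    # column-aligned truth and per-link source column indices
    truth: dict[str, np.ndarray] = {}
    blob_cols: list[tuple[str, str, np.ndarray]] = []  # (roi, link, cols)
    for roi in spec.rois:
        coords = roi_coords[roi.name]
        mask = np.zeros(coords.shape[0], dtype=bool)
        for blob in spec.blobs:
            if blob.roi != roi.name:
                continue
            inside = np.ones(coords.shape[0], dtype=bool)
            for ax, (lo, hi) in enumerate(blob.box):
                inside &= (coords[:, ax] >= lo) & (coords[:, ax] < hi)
            if mask[inside].any():
                raise ValueError(f"overlapping source blobs in ROI {roi.name}")
            mask |= inside
            blob_cols.append((roi.name, blob.link, np.flatnonzero(inside)))
        truth[roi.name] = mask

    sids = [f"sub-p{i + 1:02d}" for i in range(spec.n_patients)] + [
        f"sub-c{i + 1:02d}" for i in range(spec.n_controls)
    ]
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    subjects = pd.DataFrame({"subject_id": sids, "group": groups})

    children = np.random.SeedSequence(entropy=(seed, 0x51)).spawn(len(sids))
    data: dict[str, dict[str, VoxelTimeSeriesMatrix]] = {}
    for sid, group, child in zip(sids, groups, children):
        rng = np.random.default_rng(child)
        a_g = spec.a(group)
        latents = {l.name: _band_limited_latent(rng, spec) for l in spec.links}
        regional = {r.name: _band_limited_latent(rng, spec) for r in spec.rois}
        per_roi: dict[str, VoxelTimeSeriesMatrix] = {}
        for roi in spec.rois:
            coords = roi_coords[roi.name]
            sd = np.where(truth[roi.name], spec.sigma, spec.sigma_nonsource)
            x = sd[None, :] * _ar1_noise(rng, spec, coords.shape[0])
            for roi_name, link_name, cols in blob_cols:
                if roi_name != roi.name:
                    continue
                x[:, cols] += (
                    a_g * latents[link_name][:, None]
                    + spec.w * regional[roi.name][:, None]
                )
            per_roi[roi.name] = VoxelTimeSeriesMatrix(
                values=x, voxel_coords=coords, tr=spec.tr, roi_name=roi.name
            )
        data[sid] = per_roi

    affine = np.array(
        [[3.0, 0, 0, -36.0], [0, 3.0, 0, -36.0], [0, 0, 3.0, -36.0], [0, 0, 0, 1.0]]
    )
    return SyntheticCohort(
        spec=spec, seed=seed, subjects=subjects, data=data, truth=truth,
        affine=affine,
    )
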