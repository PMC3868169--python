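"""Amplitude of low-frequency fluctuation (ALFF).

ALFF of a (detrended, band-passed) series is the mean, over the DFT bins
whose frequency lies inside the band (inclusive edges), of the square root
of the one-sided periodogram |DFT|^2 / T. The frequency resolution is
1/(T*tr). The convention (normalization, one-sidedness, inclusive edges) is
fixed here so that reported numbers are reproducible bit for bit; no
across-voxel mean normalization (mALFF) is applied.
"""

from __future__ import annotations

import numpy as np

from .link_stats import two_sample_t

DEFAULT_BAND = (0.01, 0.08)


def periodogram(series: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram: frequencies and power |DFT|^2 / T."""
    series = np.asarray(series, dtype=np.float64)
    t = series.shape[0]
    spec = np.fft.rfft(series)
    power = np.abs(spec) ** 2 / t
    freqs = np.fft.rfftfreq(t, d=tr)
    return freqs, power


def compute_alff(
    series: np.ndarray,
    tr: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Band-averaged square-root power of a series.

    The series is expected to be detrended and band-pass filtered already
    (the pipeline enforces that order); ALFF itself only summarizes the
    spectrum. Scales linearly with the series amplitude.
    """
    low, high = band
    if not (0.0 <= low < high):
        raise ValueError("band must satisfy 0 <= low < high")
    freqs, power = periodogram(series, tr)
    in_band = (freqs >= low) & (freqs <= high)
    if not in_band.any():
        raise ValueError(
            f"band {band} Hz contains no DFT bins at resolution "
            f"{freqs[1] - freqs[0]:.6g} Hz; lengthen the series"
        )
    return float(np.sqrt(power[in_band]).mean())


def alff_group_compare(
    alff_patients: np.ndarray, alff_controls: np.ndarray
) -> tuple[float, float]:
    """Pooled two-sample t-test of per-subject ALFF between groups."""
    t, p, _ = two_sample_t(
        np.asarray(alff_patients, dtype=np.float64),
        np.asarray(alff_controls, dtype=np.float64),
    )
    return t, p
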