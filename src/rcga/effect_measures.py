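"""Group-level effect measures for a functional link.

A link (ROI pair or source pair) is dichotomized per subject into
present/absent, giving a 2x2 contingency table over patients and controls.
From it:

* odds ratio  OR = (P11 * P00) / (P01 * P10), with a Woolf (logit) confidence
  interval exp(ln OR +/- u_{1-alpha/2} * sqrt(1/P11 + 1/P10 + 1/P01 + 1/P00));
* risk difference  RD = L_p/N_p - L_N/N_N, the absolute difference of the
  occurrence proportions, with a label-permutation test for significance;
* DOC, the difference of mean correlation coefficients between controls and
  patients.

The per-subject presence rule is deliberately pluggable: "the link is present
in the individual network" is not a standardized criterion. The default rule
declares a link present when the subject's Pearson correlation is
significantly positive (two-sided t on r with df = T-2 at alpha, and r > 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .link_stats import pearson_r


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 link-presence counts: patients/controls x present/absent."""

    p11: int  # present in patients
    p10: int  # absent in patients
    p01: int  # present in controls
    p00: int  # absent in controls

    def __post_init__(self) -> None:
        if min(self.p11, self.p10, self.p01, self.p00) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_patients == 0 or self.n_controls == 0:
            raise ValueError("both groups must be non-empty")

    @property
    def n_patients(self) -> int:
        return self.p11 + self.p10

    @property
    def n_controls(self) -> int:
        return self.p01 + self.p00

    def swapped_groups(self) -> "ContingencyTable":
        return ContingencyTable(self.p01, self.p00, self.p11, self.p10)


@dataclass
class EffectResult:
    """Bundle of effect measures for one link."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    ci_level: float
    risk_difference: float
    p_perm: float
    doc: float
    table: ContingencyTable
    rule: str = "significant-positive-r"
    alpha: float = 0.05


def r_significance_p(r: float, n: int) -> float:
    """Two-sided p of a Pearson r under H0: rho=0 (t with df = n-2)."""
    df = n - 2
    if df <= 0:
        raise ValueError("need at least 3 time points")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def link_present(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    rule: str = "significant-positive-r",
    r_threshold: float = 0.3,
) -> bool:
    """Decide whether a link is present in one subject's network.

    Rules:
      * ``significant-positive-r`` (default): r significant at ``alpha``
        (two-sided, t with df=T-2) and positive.
      * ``significant-abs-r``: |r| significant at ``alpha``.
      * ``r-threshold``: r > ``r_threshold``.
    Zero-variance input makes the link absent.
    """
    r = pearson_r(x, y)
    if not np.isfinite(r):
        return False
    n = len(x)
    if rule == "significant-positive-r":
        return r > 0 and r_significance_p(r, n) < alpha
    if rule == "significant-abs-r":
        return r_significance_p(r, n) < alpha
    if rule == "r-threshold":
        return r > r_threshold
    raise ValueError(f"unknown presence rule: {rule!r}")


def contingency_from_presence(
    presence: np.ndarray, labels: np.ndarray
) -> ContingencyTable:
    """Count the 2x2 table from per-subject presence and group labels."""
    presence = np.asarray(presence, dtype=bool)
    labels = np.asarray(labels)
    if presence.shape != labels.shape:
        raise ValueError("presence and labels must align")
    pat = labels == "patient"
    con = labels == "control"
    if not (pat.any() and con.any()):
        raise ValueError("both groups must be represented")
    return ContingencyTable(
        p11=int((presence & pat).sum()),
        p10=int((~presence & pat).sum()),
        p01=int((presence & con).sum()),
        p00=int((~presence & con).sum()),
    )


def odds_ratio(tab: ContingencyTable) -> float:
    """OR = (P11 * P00) / (P01 * P10); infinity (flagged) on zero denominator."""
    num = tab.p11 * tab.p00
    den = tab.p01 * tab.p10
    if den == 0:
        if num == 0:
            return np.nan
        warnings.warn("odds ratio denominator is zero; returning inf", stacklevel=2)
        return np.inf
    return num / den


def or_confidence_interval(
    tab: ContingencyTable, level: float = 0.95
) -> tuple[float, float]:
    """Woolf logit confidence interval for the odds ratio.

    Zero cells get the Haldane–Anscombe +0.5 correction (all four cells),
    applied to the interval only — the point estimate stays raw.
    """
    cells = np.array([tab.p11, tab.p10, tab.p01, tab.p00], dtype=np.float64)
    if np.any(cells == 0):
        warnings.warn(
            "zero cell in 2x2 table; applying Haldane–Anscombe +0.5 for the CI",
            stacklevel=2,
        )
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log(a * d / (b * c))
    se = np.sqrt((1.0 / cells).sum())
    u = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(log_or - u * se)), float(np.exp(log_or + u * se))


def risk_difference(tab: ContingencyTable) -> float:
    """RD = L_p / N_p - L_N / N_N (occurrence proportion difference)."""
    return tab.p11 / tab.n_patients - tab.p01 / tab.n_controls


def permutation_test_rd(
    presence: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = 0,
    tie_break: str = "none",
) -> float:
    """Two-sided permutation p for the risk difference under label shuffling.

    The default reported p is the add-one estimator
    p = (1 + #{|RD_perm| >= |RD_obs|}) / (n_perm + 1), which is never zero and
    is (slightly conservatively) valid. With binary per-subject data the
    permutation distribution is discrete, so this p cannot be exactly uniform
    under the null; ``tie_break="randomized"`` returns the randomized
    p-value p = (#{>} + U*(1 + #{=})) / (n_perm + 1), U ~ U(0,1), which is
    exactly uniform under the null and is the estimator used to verify the
    test's calibration.
    """
    presence = np.asarray(presence, dtype=bool)
    labels = np.asarray(labels)
    pat = labels == "patient"
    n_p = int(pat.sum())
    n_n = presence.size - n_p
    if n_p < 2 or n_n < 2:
        raise ValueError("need at least 2 subjects per group")
    rd_obs = presence[pat].sum() / n_p - presence[~pat].sum() / n_n
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = int(presence.sum())
    # shuffling labels == drawing which n_p of the subjects are "patients";
    # only the count of present subjects among them matters
    perm_lp = rng.hypergeometric(total, presence.size - total, n_p, size=n_perm)
    rd_perm = np.abs(perm_lp / n_p - (total - perm_lp) / n_n)
    obs = abs(rd_obs)
    greater = int((rd_perm > obs + 1e-12).sum())
    equal = int((np.abs(rd_perm - obs) <= 1e-12).sum())
    if tie_break == "randomized":
        return (greater + rng.random() * (1 + equal)) / (n_perm + 1)
    if tie_break != "none":
        raise ValueError(f"unknown tie_break: {tie_break!r}")
    return (1 + greater + equal) / (n_perm + 1)


def difference_of_correlation(
    r_controls: np.ndarray, r_patients: np.ndarray
) -> float:
    """DOC: mean correlation in controls minus mean correlation in patients."""
    r_controls = np.asarray(r_controls, dtype=np.float64)
    r_patients = np.asarray(r_patients, dtype=np.float64)
    if r_controls.size == 0 or r_patients.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(r_controls.mean() - r_patients.mean())


def round_half_away(x: float, decimals: int = 4) -> float:
    """Round half away from zero at ``decimals`` (the table convention)."""
    scale = 10.0 ** decimals
    return np.sign(x) * np.floor(abs(x) * scale + 0.5) / scale


def recover_counts_from_rd(
    rd_printed: float, n_p: int = 39, n_n: int = 37
) -> tuple[int, int]:
    """Invert a printed risk difference back to the integer counts.

    Exhaustively searches (L_p, L_N) in {0..n_p} x {0..n_n} for pairs whose
    RD rounds (4 dp, half away from zero) to ``rd_printed``; errors unless
    exactly one pair matches.
    """
    hits = [
        (lp, ln)
        for lp in range(n_p + 1)
        for ln in range(n_n + 1)
        if round_half_away(lp / n_p - ln / n_n) == round_half_away(rd_printed)
    ]
    if len(hits) != 1:
        raise ValueError(
            f"risk difference {rd_printed} maps to {len(hits)} count pairs: {hits}"
        )
    return hits[0]


def recover_counts_from_or(
    or_printed: float, n_p: int = 39, n_n: int = 37
) -> tuple[int, int]:
    """Invert a printed odds ratio back to the integer counts (see above)."""
    hits = []
    for lp in range(n_p + 1):
        for ln in range(n_n + 1):
            den = (n_p - lp) * ln
            if den == 0:
                continue
            if round_half_away(lp * (n_n - ln) / den) == round_half_away(or_printed):
                hits.append((lp, ln))
    if len(hits) != 1:
        raise ValueError(
            f"odds ratio {or_printed} maps to {len(hits)} count pairs: {hits}"
        )
    return hits[0]


def link_effect(
    series_a: list[np.ndarray],
    series_b: list[np.ndarray],
    labels: np.ndarray,
    alpha: float = 0.05,
    rule: str = "significant-positive-r",
    n_perm: int = 10000,
    seed: int | None = 0,
    ci_level: float = 0.95,
) -> EffectResult:
    """All effect measures for one link from per-subject series pairs."""
    labels = np.asarray(labels)
    r = np.array([pearson_r(a, b) for a, b in zip(series_a, series_b)])
    presence = np.array([
        link_present(a, b, alpha=alpha, rule=rule)
        for a, b in zip(series_a, series_b)
    ])
    tab = contingency_from_presence(presence, labels)
    pat = labels == "patient"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        orr = odds_ratio(tab)
        lo, hi = or_confidence_interval(tab, level=ci_level)
    return EffectResult(
        odds_ratio=orr,
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        risk_difference=risk_difference(tab),
        p_perm=permutation_test_rd(presence, labels, n_perm=n_perm, seed=seed),
        doc=difference_of_correlation(r[~pat], r[pat]),
        table=tab,
        rule=rule,
        alpha=alpha,
    )
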