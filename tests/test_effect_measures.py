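import numpy as np
import pytest
from scipy import stats

from rcga import (
    ContingencyTable,
    contingency_from_presence,
    difference_of_correlation,
    link_present,
    odds_ratio,
    or_confidence_interval,
    permutation_test_rd,
    recover_counts_from_or,
    recover_counts_from_rd,
    risk_difference,
)
from rcga.effect_measures import round_half_away


class TestLinkPresent:
    def test_identical_series_present(self, rng):
        x = rng.standard_normal(50)
        assert link_present(x, x.copy())

    def test_strong_negative_correlation_absent_by_default(self, rng):
        x = rng.standard_normal(100)
        y = -x + 0.1 * rng.standard_normal(100)
        assert not link_present(x, y)
        assert link_present(x, y, rule="significant-abs-r")

    def test_zero_variance_absent(self, rng):
        assert not link_present(np.ones(50), rng.standard_normal(50))

    def test_null_presence_rate_is_half_alpha(self):
        # positive-tail rule: independent noise is "present" in ~2.5% of draws
        g = np.random.default_rng(5)
        t_len, reps = 170, 10000
        x = g.standard_normal((t_len, reps))
        y = g.standard_normal((t_len, reps))
        xc = x - x.mean(0)
        yc = y - y.mean(0)
        r = (xc * yc).sum(0) / np.sqrt((xc**2).sum(0) * (yc**2).sum(0))
        tcrit = stats.t.ppf(0.975, t_len - 2)
        rcrit = np.sqrt(tcrit**2 / (tcrit**2 + t_len - 2))
        rate = ((r > rcrit)).mean()
        assert rate == pytest.approx(0.025, abs=0.01)
        # spot-check agreement with the scalar rule
        k = int(np.argmax(r))
        assert link_present(x[:, k], y[:, k]) == (r[k] > rcrit)


class TestContingency:
    def test_all_present(self):
        labels = np.array(["patient", "patient", "control"])
        tab = contingency_from_presence(np.array([True] * 3), labels)
        assert (tab.p10, tab.p00) == (0, 0)
        assert (tab.p11, tab.p01) == (2, 1)

    def test_two_subject_example(self):
        tab = contingency_from_presence(
            np.array([True, False]), np.array(["patient", "control"])
        )
        assert (tab.p11, tab.p10, tab.p01, tab.p00) == (1, 0, 0, 1)

    def test_random_vector_matches_loop_count(self, rng):
        presence = rng.random(76) > 0.4
        labels = np.array(["patient"] * 39 + ["control"] * 37)
        tab = contingency_from_presence(presence, labels)
        assert tab.p11 == sum(
            p and g == "patient" for p, g in zip(presence, labels)
        )
        assert tab.p00 == sum(
            (not p) and g == "control" for p, g in zip(presence, labels)
        )


class TestOddsRatioAndRd:
    def test_roiwise_anchor_table(self):
        tab = ContingencyTable(32, 7, 36, 1)
        assert round_half_away(odds_ratio(tab)) == 0.1270
        assert round_half_away(risk_difference(tab)) == -0.1525

    def test_no_association(self):
        assert odds_ratio(ContingencyTable(1, 1, 1, 1)) == 1.0

    def test_voxelwise_anchor_table(self):
        tab = ContingencyTable(19, 20, 32, 5)
        assert round_half_away(odds_ratio(tab)) == 0.1484
        assert round_half_away(risk_difference(tab)) == -0.3777

    def test_second_link_anchor_table(self):
        tab = ContingencyTable(26, 13, 36, 1)
        assert round_half_away(risk_difference(tab)) == -0.3063
        assert round_half_away(odds_ratio(tab)) == 0.0556

    def test_zero_denominator_flagged_infinite(self):
        with pytest.warns(UserWarning, match="inf"):
            assert np.isinf(odds_ratio(ContingencyTable(5, 5, 0, 5)))

    def test_equal_proportions_give_zero_rd(self):
        assert risk_difference(ContingencyTable(10, 10, 10, 10)) == 0.0

    def test_group_swap_inverts_or_and_negates_rd(self):
        tab = ContingencyTable(19, 20, 32, 5)
        swapped = tab.swapped_groups()
        assert odds_ratio(swapped) == pytest.approx(1.0 / odds_ratio(tab))
        assert risk_difference(swapped) == pytest.approx(-risk_difference(tab))


class TestWoolfInterval:
    def test_balanced_table_symmetric_about_one(self):
        lo, hi = or_confidence_interval(ContingencyTable(10, 10, 10, 10))
        assert lo * hi == pytest.approx(1.0, abs=1e-9)

    def test_interval_shrinks_with_counts(self):
        lo1, hi1 = or_confidence_interval(ContingencyTable(10, 10, 10, 10))
        lo2, hi2 = or_confidence_interval(ContingencyTable(100, 100, 100, 100))
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_matches_direct_formula_oracle(self):
        tab = ContingencyTable(32, 7, 36, 1)
        lo, hi = or_confidence_interval(tab, level=0.95)
        log_or = np.log(32 * 1 / (36 * 7))
        se = np.sqrt(1 / 32 + 1 / 7 + 1 / 36 + 1 / 1)
        u = stats.norm.ppf(0.975)
        assert lo == pytest.approx(np.exp(log_or - u * se), rel=1e-9)
        assert hi == pytest.approx(np.exp(log_or + u * se), rel=1e-9)

    def test_zero_cell_gets_haldane_correction(self):
        with pytest.warns(UserWarning, match="0.5"):
            lo, hi = or_confidence_interval(ContingencyTable(5, 0, 3, 4))
        assert 0 < lo < hi < np.inf

    def test_point_estimate_inside_interval(self):
        tab = ContingencyTable(19, 20, 32, 5)
        lo, hi = or_confidence_interval(tab)
        assert lo <= odds_ratio(tab) <= hi


class TestPermutationTest:
    LABELS = np.array(["patient"] * 39 + ["control"] * 37)

    def test_all_present_gives_p_one(self):
        assert permutation_test_rd(np.ones(76, bool), self.LABELS, seed=0) == 1.0

    def test_perfect_separation_is_extreme(self):
        presence = np.array([False] * 39 + [True] * 37)
        p = permutation_test_rd(presence, self.LABELS, n_perm=10000, seed=0)
        assert p <= 0.001

    def test_p_and_rd_sign_consistency(self, rng):
        # p < 0.05 implies |RD| above the 95th percentile of permuted |RD|
        for _ in range(20):
            presence = rng.random(76) < rng.uniform(0.2, 0.8)
            p = permutation_test_rd(presence, self.LABELS, n_perm=2000, seed=1)
            g = np.random.default_rng(1)
            total = presence.sum()
            perm_lp = g.hypergeometric(total, 76 - total, 39, size=2000)
            perm_rd = np.abs(perm_lp / 39 - (total - perm_lp) / 37)
            rd_obs = abs(presence[:39].sum() / 39 - presence[39:].sum() / 37)
            if p < 0.05:
                assert rd_obs >= np.quantile(perm_rd, 0.95)


class TestCountRecovery:
    def test_roiwise_rd_recovers_unique_counts(self):
        assert recover_counts_from_rd(-0.1525) == (32, 36)

    def test_voxelwise_rd_recovers_unique_counts(self):
        assert recover_counts_from_rd(-0.3777) == (19, 32)

    def test_or_recovery(self):
        assert recover_counts_from_or(0.0556) == (26, 36)

    def test_ambiguous_rd_is_an_error(self):
        with pytest.raises(ValueError, match="count pairs"):
            recover_counts_from_rd(0.0, n_p=2, n_n=2)

    def test_round_half_away_from_zero(self):
        assert round_half_away(-0.30625) == -0.3063
        assert round_half_away(0.30625) == 0.3063
        assert round_half_away(0.12345) == 0.1235


class TestDoc:
    def test_identical_groups(self):
        r = np.array([0.2, 0.4])
        assert difference_of_correlation(r, r) == 0.0

    def test_simple_difference(self):
        assert difference_of_correlation(
            np.array([0.5, 0.5]), np.array([0.3, 0.3])
        ) == pytest.approx(0.2)

    def test_matches_loop_means(self, rng):
        rc, rp = rng.random(37), rng.random(39)
        assert difference_of_correlation(rc, rp) == pytest.approx(
            sum(rc) / 37 - sum(rp) / 39, abs=1e-12
        )
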