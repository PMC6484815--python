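"""Cohort statistics: 2x2 diagnostics, zone rates, ROC, OR, logistic fits."""

import numpy as np
import pytest

from icgquant import (
    ContingencyTable2x2,
    InvalidSpecificationError,
    UndefinedStatisticError,
    diagnostic_values,
    logistic_model,
    odds_ratio,
    roc_analysis,
    zone_rates,
)
from icgquant import reference
from icgquant.stats import round_half_up


def mann_whitney_auc(values, outcomes):
    """Brute-force pairwise AUC oracle: P(pos > neg) + 0.5 P(tie)."""
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    pos = values[outcomes == 1]
    neg = values[outcomes == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (pos.size * neg.size)


class TestDiagnosticValues:
    def test_published_tr_column(self):
        """tp=5, fn=1, fp=3, tn=77: the five published TR percentages."""
        d = diagnostic_values(ContingencyTable2x2(tp=5, fp=3, fn=1, tn=77))
        assert d.sensitivity.value == pytest.approx(5 / 6)
        assert d.sensitivity.percent == 83.3
        assert d.specificity.percent == 96.3
        assert d.ppv.percent == 62.5
        assert d.npv.percent == 98.7
        assert d.accuracy.percent == 95.3

    def test_published_t_half_column_perfect_margins(self):
        """tp=6, fn=0: sensitivity 100% (6/6) and NPV 100% (67/67)."""
        d = diagnostic_values(ContingencyTable2x2(tp=6, fp=13, fn=0, tn=67))
        assert d.sensitivity.percent == 100.0
        assert d.sensitivity.numerator == 6
        assert d.npv.percent == 100.0
        assert d.npv.denominator == 67

    def test_all_fifteen_published_cells(self):
        """Every diagnostic cell reproduces its published percentage from
        its printed counts, at printed (one-decimal) precision."""
        for factor, table in reference.CONTINGENCY.items():
            d = diagnostic_values(table)
            for metric, printed in reference.PUBLISHED_DIAGNOSTICS[factor].items():
                value = getattr(d, metric)
                assert value.defined
                assert abs(100.0 * value.value - printed) <= 0.05 + 1e-9, (
                    f"{factor}/{metric}: {100 * value.value} vs {printed}"
                )

    def test_empty_positive_class_flagged_not_zero(self):
        d = diagnostic_values(ContingencyTable2x2(tp=0, fp=0, fn=0, tn=10))
        assert not d.sensitivity.defined
        assert d.sensitivity.value is None
        assert d.specificity.percent == 100.0
        assert not d.ppv.defined

    def test_accuracy_is_prevalence_weighted_combination(self):
        """accuracy = prev * sensitivity + (1 - prev) * specificity."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 40, size=4)
            d = diagnostic_values(ContingencyTable2x2(int(tp), int(fp),
                                                      int(fn), int(tn)))
            prev = (tp + fn) / (tp + fp + fn + tn)
            assert d.accuracy.value == pytest.approx(
                prev * d.sensitivity.value + (1 - prev) * d.specificity.value
            )

    def test_invalid_tables_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            ContingencyTable2x2(tp=-1, fp=0, fn=0, tn=1)
        with pytest.raises(InvalidSpecificationError):
            ContingencyTable2x2(tp=0, fp=0, fn=0, tn=0)

    def test_round_half_up_matches_clinical_tables(self):
        assert round_half_up(62.45) == 62.5
        assert round_half_up(83.75) == 83.8
        assert round_half_up(95.34) == 95.3


class TestZoneRates:
    def test_published_tr_zone_rates(self):
        """Dangerous 5/8 = 62.5%, intermediate 1/31 = 3.2%, safe 0/47."""
        zones = ["dangerous"] * 8 + ["intermediate"] * 31 + ["safe"] * 47
        outcomes = [1] * 5 + [0] * 3 + [1] + [0] * 30 + [0] * 47
        rates = zone_rates(zones, outcomes)
        assert rates["dangerous"].percent == 62.5
        assert rates["intermediate"].percent == 3.2
        assert rates["safe"].percent == 0.0
        assert rates["dangerous"].numerator == 5
        assert rates["dangerous"].denominator == 8

    def test_single_zone_rate_equals_overall_incidence(self):
        outcomes = [1, 0, 0, 1, 0]
        rates = zone_rates(["safe"] * 5, outcomes)
        assert rates["safe"].value == pytest.approx(np.mean(outcomes))

    def test_perfectly_separated_cohort(self):
        zones = ["slow"] * 4 + ["safe"] * 6
        outcomes = [1] * 4 + [0] * 6
        rates = zone_rates(zones, outcomes)
        assert rates["slow"].value == 1.0
        assert rates["safe"].value == 0.0

    def test_risk_zone_labels_sorted_by_severity(self):
        from icgquant import RiskZone

        zones = [RiskZone.CRITICAL, RiskZone.SAFE, RiskZone.DANGEROUS]
        rates = zone_rates(zones, [1, 0, 0])
        assert list(rates) == [RiskZone.SAFE, RiskZone.DANGEROUS,
                               RiskZone.CRITICAL]

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            zone_rates(["a"], [1, 0])


class TestRocAnalysis:
    def test_auc_matches_pairwise_oracle_on_random_cohorts(self):
        """Tie-aware AUC equals the brute-force Mann-Whitney statistic on
        50 random cohorts (with ties injected) to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(20, 200))
            n_pos = int(rng.integers(3, n - 3))
            values = np.round(rng.normal(size=n), 1)  # rounding makes ties
            values[:n_pos] += rng.uniform(0, 2)
            outcomes = np.r_[np.ones(n_pos, int), np.zeros(n - n_pos, int)]
            res = roc_analysis(values, outcomes, direction="higher")
            assert res.auc == pytest.approx(
                mann_whitney_auc(values, outcomes), abs=1e-12
            )

    def test_perfect_separation_gives_unit_auc(self):
        res = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.youden_j == 1.0
        assert 2.0 < res.chosen_cutoff < 3.0

    def test_all_ties_give_half_auc(self):
        res = roc_analysis([1.0, 1.0, 1.0, 1.0], [0, 0, 1, 1])
        assert res.auc == 0.5

    def test_single_class_input_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_protective_direction_reports_raw_and_flipped(self):
        """Slope-like factor: raw orientation AUC below 0.5, the directed
        value above, and the Youden cutoff in the overlap region."""
        rng = np.random.default_rng(0)
        slope_neg = rng.normal(2.5, 0.6, size=60)  # no complication: steep
        slope_pos = rng.normal(0.7, 0.3, size=12)  # complication: shallow
        values = np.r_[slope_neg, slope_pos]
        outcomes = np.r_[np.zeros(60, int), np.ones(12, int)]
        res = roc_analysis(values, outcomes, direction="lower")
        assert res.auc < 0.5 < res.auc_directed
        assert res.auc == pytest.approx(1.0 - res.auc_directed)
        assert res.auc_flipped == pytest.approx(res.auc_directed)
        assert 0.5 < res.chosen_cutoff < 2.5

    def test_ci_brackets_auc_and_detects_separation_strength(self):
        rng = np.random.default_rng(3)
        values = np.r_[rng.normal(0.4, 0.05, 80), rng.normal(0.62, 0.05, 6)]
        outcomes = np.r_[np.zeros(80, int), np.ones(6, int)]
        res = roc_analysis(values, outcomes)
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.ci_high <= 1.0
        assert res.p_value < 0.01

    def test_bootstrap_ci_seeded_and_deterministic(self):
        rng = np.random.default_rng(5)
        values = np.r_[rng.normal(0, 1, 30), rng.normal(1, 1, 30)]
        outcomes = np.r_[np.zeros(30, int), np.ones(30, int)]
        a = roc_analysis(values, outcomes, ci_method="bootstrap",
                         n_boot=200, seed=9)
        b = roc_analysis(values, outcomes, ci_method="bootstrap",
                         n_boot=200, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.auc <= a.ci_high

    def test_youden_cutoff_recovery_between_group_centers(self):
        """On well-separated TR-like cohorts the chosen cut-off lands
        between the group centers (0.40 and 0.65) in every seeded run."""
        from scipy.stats import truncnorm

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            neg = truncnorm.rvs(-7, 6, loc=0.40, scale=0.05, size=1000,
                                random_state=rng)
            pos = truncnorm.rvs(-7, 6, loc=0.65, scale=0.05, size=1000,
                                random_state=rng)
            res = roc_analysis(np.r_[neg, pos],
                               np.r_[np.zeros(1000, int), np.ones(1000, int)])
            hits += 0.4 < res.chosen_cutoff < 0.65
        assert hits >= 19


class TestOddsRatio:
    def test_published_tr_counts(self):
        """(tp*tn)/(fp*fn) = (5*77)/(3*1) = 128.33."""
        res = odds_ratio(ContingencyTable2x2(tp=5, fp=3, fn=1, tn=77))
        assert res.odds_ratio == pytest.approx(385 / 3, rel=1e-12)
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert not res.corrected

    def test_symmetric_table_gives_unit_or(self):
        res = odds_ratio(ContingencyTable2x2(1, 1, 1, 1))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_cell_haldane_corrected_and_flagged(self):
        res = odds_ratio(ContingencyTable2x2(tp=6, fp=13, fn=0, tn=67))
        assert res.corrected
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1
        assert np.isfinite(res.ci_high)

    def test_empty_margin_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            odds_ratio(ContingencyTable2x2(tp=0, fp=5, fn=0, tn=7))


class TestLogisticModel:
    def test_single_binary_covariate_reproduces_contingency_or(self):
        """A one-covariate logistic fit on data realizing the published TR
        2x2 counts returns the contingency OR to 1e-6."""
        x = np.r_[np.ones(5), np.zeros(1), np.ones(3), np.zeros(77)]
        y = np.r_[np.ones(6), np.zeros(80)]
        res = logistic_model(x.reshape(-1, 1), y, names=["tr_slow"])
        assert res.table.loc["tr_slow", "odds_ratio"] == pytest.approx(
            385 / 3, abs=1e-6
        )
        assert res.converged and not res.separation

    def test_null_covariate_ci_covers_one(self):
        """Permuted labels: the Wald CI covers OR = 1 in >= 90% of runs."""
        rng = np.random.default_rng(17)
        covered = 0
        for _ in range(100):
            x = rng.integers(0, 2, size=200).astype(float)
            y = np.zeros(200)
            y[rng.choice(200, size=60, replace=False)] = 1.0
            res = logistic_model(x.reshape(-1, 1), y)
            lo = res.table.iloc[0]["ci_low"]
            hi = res.table.iloc[0]["ci_high"]
            covered += lo <= 1.0 <= hi
        assert covered >= 90

    def test_duplicated_covariate_is_rank_deficiency_error(self):
        x = np.c_[np.r_[np.ones(10), np.zeros(10)],
                  np.r_[np.ones(10), np.zeros(10)]]
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(InvalidSpecificationError):
            logistic_model(x, y)

    def test_perfect_separation_reported_diagnostically(self):
        x = np.r_[np.ones(10), np.zeros(10)]
        y = np.r_[np.ones(10), np.zeros(10)]
        res = logistic_model(x.reshape(-1, 1), y)
        assert res.separation

    def test_non_binary_outcomes_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            logistic_model(np.ones((10, 1)), np.arange(10))


class TestConveniences:
    def test_group_t_test_detects_separation(self):
        from icgquant.stats import t_test_groups

        rng = np.random.default_rng(2)
        values = np.r_[rng.normal(30, 5, 40), rng.normal(64, 10, 8)]
        outcomes = np.r_[np.zeros(40, int), np.ones(8, int)]
        _, p = t_test_groups(values, outcomes)
        assert p < 1e-6

    def test_chi2_and_spearman_run(self):
        from icgquant.stats import chi2_2x2, spearman

        chi2, p = chi2_2x2(ContingencyTable2x2(5, 3, 1, 77))
        assert chi2 > 0 and p < 0.05
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 4, 5, 8, 9])
        assert rho == pytest.approx(1.0)
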