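"""Tertile stratification, Cox hazard ratio, Wilcoxon and Spearman checks."""

import numpy as np
import pandas as pd
import pytest

import ckdsim as c
from conftest import breslow_grid_oracle, signed_rank_exact_p_less
from ckdsim.stats import _breslow_newton


def scores_series(values):
    return pd.Series(
        np.asarray(values, dtype=float),
        index=[f"pt{i:04d}" for i in range(len(values))],
    )


def outcome_frame(times, events, ids=None):
    n = len(times)
    ids = ids if ids is not None else [f"pt{i:04d}" for i in range(n)]
    return pd.DataFrame(
        {"followup_days": np.asarray(times, float),
         "event": np.asarray(events, bool)},
        index=pd.Index(ids, name="patient_id"),
    )


class TestTertiles:
    def test_three_distinct_scores_one_per_stratum(self):
        strata = c.tertile_stratify(scores_series([1.0, 2.0, 3.0]))
        assert sorted(strata.assignments) == ["high", "intermediate", "low"]

    def test_all_equal_scores_collapse_to_low(self):
        strata = c.tertile_stratify(scores_series([0.5] * 10))
        assert (strata.assignments == "low").all()

    def test_935_patients_split_312_312_311(self):
        rng = np.random.default_rng(0)
        strata = c.tertile_stratify(scores_series(rng.normal(size=935)))
        sizes = sorted(strata.assignments.value_counts())
        assert sizes == [311, 312, 312]

    def test_counts_sum_and_cut_points_are_quantiles(self):
        rng = np.random.default_rng(1)
        scores = scores_series(rng.normal(size=200))
        strata = c.tertile_stratify(scores)
        assert strata.assignments.value_counts().sum() == 200
        q1, q2 = np.quantile(scores.to_numpy(), [1 / 3, 2 / 3])
        assert strata.cut_points == (q1, q2)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            c.tertile_stratify(scores_series([1.0, 2.0]))


class TestCoxHazardRatio:
    def _strata(self, n_low, n_high):
        labels = ["low"] * n_low + ["high"] * n_high
        ids = [f"pt{i:04d}" for i in range(n_low + n_high)]
        return c.TertileStrata(
            assignments=pd.Series(labels, index=ids), cut_points=(0.0, 1.0)
        )

    def test_identical_event_patterns_give_null_hazard(self):
        strata = self._strata(4, 4)
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 0, 1, 1, 0, 0]
        cmp = c.hazard_ratio_high_vs_low(strata, outcome_frame(times, events))
        assert cmp.hazard_ratio == pytest.approx(1.0, abs=1e-9)
        assert cmp.ci_low < 1.0 < cmp.ci_high

    def test_matches_partial_likelihood_grid_oracle_on_toy_data(self):
        # events in both strata so the maximiser is finite
        strata = self._strata(2, 2)
        times = [2.0, 4.0, 1.0, 3.0]
        events = [1, 0, 1, 1]
        frame = outcome_frame(times, events)
        cmp = c.hazard_ratio_high_vs_low(strata, frame)
        x = np.array([0.0, 0.0, 1.0, 1.0])
        rows = list(zip(times, [bool(e) for e in events], x))
        beta_oracle = breslow_grid_oracle(rows)
        assert np.log(cmp.hazard_ratio) == pytest.approx(beta_oracle, abs=1e-4)

    def test_matches_grid_oracle_with_tied_event_times(self):
        strata = self._strata(3, 3)
        times = [1.0, 1.0, 5.0, 1.0, 2.0, 4.0]
        events = [1, 1, 0, 1, 1, 1]
        frame = outcome_frame(times, events)
        cmp = c.hazard_ratio_high_vs_low(strata, frame)
        rows = list(zip(times, [bool(e) for e in events],
                        [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]))
        assert np.log(cmp.hazard_ratio) == pytest.approx(
            breslow_grid_oracle(rows), abs=1e-4
        )

    def test_agrees_with_lifelines_on_tie_free_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        n = 80
        x = np.repeat([0.0, 1.0], n // 2)
        times = rng.exponential(np.where(x == 1, 50.0, 100.0))
        censor = rng.exponential(120.0, n)
        observed = times <= censor
        fu = np.minimum(times, censor)
        assert len(np.unique(fu)) == n  # tie-free: Efron == Breslow
        strata = self._strata(n // 2, n // 2)
        cmp = c.hazard_ratio_high_vs_low(strata, outcome_frame(fu, observed))
        cph = lifelines.CoxPHFitter()
        cph.fit(
            pd.DataFrame({"t": fu, "e": observed.astype(int), "x": x}),
            duration_col="t", event_col="e",
        )
        assert np.log(cmp.hazard_ratio) == pytest.approx(
            float(cph.params_["x"]), abs=1e-4
        )

    def test_eventless_stratum_rejected_by_name(self):
        strata = self._strata(3, 3)
        times = [5, 6, 7, 1, 2, 3]
        events = [0, 0, 0, 1, 1, 1]
        with pytest.raises(ValueError, match="low"):
            c.hazard_ratio_high_vs_low(strata, outcome_frame(times, events))

    def test_complete_separation_returns_bounded_estimate(self):
        # all events in the x=1 group: the partial likelihood is monotone
        # (infinite MLE); the solver must return a bounded finite estimate
        beta, se = _breslow_newton(
            np.array([3.0, 3.0, 1.0, 2.0]),
            np.array([False, False, True, True]),
            np.array([0.0, 0.0, 1.0, 1.0]),
        )
        assert np.isfinite(beta) and beta > 1.0
        assert se > 0

    def test_synthetic_cohort_high_tertile_at_elevated_risk(self, default_report):
        hz = default_report.hazard
        assert hz.hazard_ratio > 1.0
        assert hz.ci_low > 1.0
        assert hz.p_value < 0.05


class TestPairedWilcoxon:
    def test_no_change_is_degenerate(self):
        before = np.array([1.0, 2.0, 3.0])
        res = c.paired_wilcoxon(before, before)
        assert res.degenerate and res.n_nonzero == 0

    def test_five_negative_pairs_one_sided_exact(self):
        before = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        after = before - np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        res = c.paired_wilcoxon(before, after, alternative="less")
        assert res.p_value == pytest.approx(1.0 / 32.0)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exact_mode_agrees_with_sign_pattern_enumeration(self, n):
        rng = np.random.default_rng(n)
        diffs = rng.normal(0.0, 1.0, n)
        diffs += np.sign(diffs) * 1e-6  # keep magnitudes nonzero
        res = c.paired_wilcoxon(np.zeros(n), diffs, alternative="less")
        _, p_enum = signed_rank_exact_p_less(diffs)
        assert res.p_value == pytest.approx(p_enum, abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        before = rng.normal(size=200)
        after = before - np.abs(rng.normal(0.5, 0.1, 200))
        res = c.paired_wilcoxon(before, after)
        assert res.p_value < 1e-10

    def test_optimized_cohort_scores_drop_significantly(self, default_report):
        assert default_report.wilcoxon.p_value < 1e-4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            c.paired_wilcoxon([1.0, 2.0], [1.0])


class TestSpearman:
    def test_strictly_decreasing_function_gives_minus_one(self):
        x = np.linspace(0, 1, 20)
        res = c.spearman_association(x, -np.exp(x))
        assert res.rho == pytest.approx(-1.0)

    def test_reversed_ranks_on_three_points(self):
        res = c.spearman_association([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.rho == pytest.approx(-1.0)

    def test_independent_inputs_near_zero(self):
        rng = np.random.default_rng(5)
        res = c.spearman_association(rng.normal(size=2000), rng.normal(size=2000))
        assert abs(res.rho) < 0.08

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            c.spearman_association([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestNewtonInternals:
    def test_newton_maximises_the_likelihood_it_reports(self):
        rng = np.random.default_rng(11)
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(np.where(x == 1, 30, 80))
        e = rng.random(n) < 0.8
        beta, se = _breslow_newton(t, e, x)
        rows = list(zip(t, e, x))
        assert beta == pytest.approx(breslow_grid_oracle(rows), abs=1e-4)
        assert se > 0
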