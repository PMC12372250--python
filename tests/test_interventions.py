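"""Fold-change application, regimen enumeration and optimal selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ckdsim as c
from conftest import brute_force_best, make_profile


def table(name, calibrated=False, **fc):
    return c.FoldChangeTable(name, pd.Series(fc, dtype=float), calibrated)


def linear_model(weights, bias=0.0, transform="log1p"):
    return c.ClassifierModel(pd.Series(weights, dtype=float), bias, transform)


class TestApplyFoldChanges:
    def test_all_ones_table_is_identity(self):
        p = make_profile(p1=4.0, p2=7.5)
        out = c.apply_fold_changes(p, table("t", p1=1.0, p2=1.0))
        pd.testing.assert_series_equal(out.intensities, p.intensities)

    def test_zero_intensity_stays_zero(self):
        out = c.apply_fold_changes(make_profile(p1=0.0), table("t", p1=3.5))
        assert out.intensities["p1"] == 0.0

    def test_uncovered_peptides_unchanged(self):
        out = c.apply_fold_changes(
            make_profile(p1=4.0, p2=10.0), table("t", p1=0.5)
        )
        assert out.intensities["p1"] == 2.0
        assert out.intensities["p2"] == 10.0

    def test_missing_profile_refused(self):
        with pytest.raises(c.MissingIntensityError):
            c.apply_fold_changes(make_profile(p1=np.nan), table("t", p1=2.0))

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.inf, np.nan])
    def test_non_positive_fold_changes_rejected_at_load(self, bad):
        with pytest.raises(ValueError, match="positive"):
            table("t", p1=bad)


class TestCombineInterventions:
    def test_single_table_unchanged(self):
        t = table("a", p1=2.0, p2=0.5)
        combined = c.combine_interventions([t])
        pd.testing.assert_series_equal(combined.fold_changes, t.fold_changes)
        assert combined.intervention_name == "a"

    def test_reciprocal_fold_changes_cancel(self):
        combined = c.combine_interventions([table("a", p1=2.0), table("b", p1=0.5)])
        assert combined.fold_changes["p1"] == 1.0

    def test_disjoint_union_and_order_invariance(self):
        t1, t2 = table("a", p1=2.0), table("b", p2=3.0)
        fwd = c.combine_interventions([t1, t2])
        rev = c.combine_interventions([t2, t1])
        assert fwd.fold_changes.to_dict() == {"p1": 2.0, "p2": 3.0}
        pd.testing.assert_series_equal(
            fwd.fold_changes.sort_index(), rev.fold_changes.sort_index()
        )
        assert fwd.intervention_name == rev.intervention_name == "a+b"

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            c.combine_interventions([])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            c.combine_interventions([table("a", p1=2.0), table("a", p2=3.0)])

    def test_calibrated_only_when_all_members_calibrated(self):
        raw, cal = table("a", p1=2.0), table("b", p2=3.0, calibrated=True)
        assert not c.combine_interventions([raw, cal]).calibrated
        assert c.combine_interventions(
            [table("a", p1=2.0, calibrated=True), cal]
        ).calibrated

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_combined_equals_sequential_application(self, seed):
        rng = np.random.default_rng(seed)
        peptides = [f"p{i}" for i in range(8)]
        p = make_profile(**{pid: float(v) for pid, v in
                            zip(peptides, rng.exponential(5, 8))})
        tables = [
            table(name, **{
                pid: float(f)
                for pid, f in zip(rng.choice(peptides, 4, replace=False),
                                  rng.lognormal(0, 0.5, 4))
            })
            for name in ("a", "b", "c")
        ]
        combined = c.apply_fold_changes(p, c.combine_interventions(tables))
        sequential = p
        for t in tables:
            sequential = c.apply_fold_changes(sequential, t)
        pd.testing.assert_series_equal(
            combined.intensities, sequential.intensities, rtol=1e-12
        )


class TestEnumerateRegimens:
    def test_six_interventions_give_63_regimens(self):
        regs = c.enumerate_regimens(c.DEFAULT_INTERVENTIONS)
        assert len(regs) == 63
        assert len(set(regs)) == 63

    def test_single_intervention(self):
        regs = c.enumerate_regimens(["only"])
        assert [r.label for r in regs] == ["only"]

    def test_three_interventions_give_all_seven_nonempty_subsets(self):
        regs = c.enumerate_regimens(["c", "a", "b"])
        assert len(regs) == 7
        assert all(len(r) >= 1 for r in regs)
        assert len(set(regs)) == 7

    def test_canonical_order_by_size_then_lexicographic(self):
        labels = [r.label for r in c.enumerate_regimens(["b", "a", "c"])]
        assert labels == ["a", "b", "c", "a+b", "a+c", "b+c", "a+b+c"]

    def test_no_interventions_rejected(self):
        with pytest.raises(ValueError):
            c.enumerate_regimens([])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            c.enumerate_regimens(["a", "a"])


class TestSelectOptimal:
    def test_identity_tables_tie_break_to_first_single_intervention(self):
        p = make_profile(p1=3.0, p2=2.0)
        m = linear_model({"p1": 1.0, "p2": -0.5})
        tables = [table(n, p1=1.0) for n in ("zeta", "alpha", "midway")]
        res = c.select_optimal(p, tables, m)
        assert res.best_regimen.interventions == ("alpha",)
        assert res.best_score == res.baseline_score
        assert len(res.all_scores) == 7

    def test_halving_the_positive_weight_peptide_wins(self):
        p = make_profile(p1=10.0, p2=4.0)
        m = linear_model({"p1": 2.0})
        tables = [
            table("noop1", p2=1.0),
            table("halver", p1=0.5),
            table("noop2", p2=1.0),
        ]
        res = c.select_optimal(p, tables, m)
        assert res.best_regimen.interventions == ("halver",)
        assert res.best_score < res.baseline_score

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(12345)
        peptides = [f"p{i}" for i in range(15)]
        for _ in range(100):
            weights = {pid: float(w) for pid, w in
                       zip(rng.choice(peptides, 8, replace=False),
                           rng.normal(0, 1, 8))}
            m = linear_model(weights, bias=float(rng.normal()), transform="log1p")
            p = make_profile(**{pid: float(v) for pid, v in
                                zip(peptides, rng.exponential(20, 15))})
            tables = [
                c.FoldChangeTable(
                    f"i{j}",
                    pd.Series(
                        rng.lognormal(-0.05, 0.5, 5),
                        index=rng.choice(peptides, 5, replace=False),
                    ),
                )
                for j in range(6)
            ]
            res = c.select_optimal(p, tables, m)
            oracle_names, oracle_score = brute_force_best(p, tables, m)
            assert len(res.all_scores) == 63
            assert res.best_regimen.interventions == oracle_names
            assert res.best_score == pytest.approx(oracle_score, rel=1e-9)

    def test_cohort_optimizer_matches_per_profile_selection(self):
        rng = np.random.default_rng(9)
        peptides = [f"p{i}" for i in range(10)]
        m = linear_model({pid: float(w) for pid, w in
                          zip(peptides[:6], rng.normal(0, 1, 6))})
        profiles = [
            make_profile(f"pt{i}", **{pid: float(v) for pid, v in
                                      zip(peptides, rng.exponential(8, 10))})
            for i in range(12)
        ]
        tables = [
            c.FoldChangeTable(
                f"i{j}",
                pd.Series(rng.lognormal(0, 0.4, 4),
                          index=rng.choice(peptides, 4, replace=False)),
            )
            for j in range(4)
        ]
        matrix = c.profiles_to_matrix(profiles).fillna(0.0)
        cohort_res = c.optimize_cohort(matrix, tables, m)
        for got in cohort_res:
            profile = next(p for p in profiles if p.patient_id == got.patient_id)
            single = c.select_optimal(profile, tables, m)
            assert got.best_regimen == single.best_regimen
            assert got.best_score == pytest.approx(single.best_score, rel=1e-12)
            assert got.baseline_score == pytest.approx(
                single.baseline_score, rel=1e-12
            )


class TestTabulation:
    def test_empty_input_gives_empty_table(self):
        counts = c.tabulate_optimal_regimens([])
        assert len(counts) == 0

    def test_three_patients_same_regimen(self):
        reg = c.Regimen(interventions=("a", "b"))
        results = [
            c.OptimizationResult(f"pt{i}", 1.0, reg, 0.5, {reg: 0.5})
            for i in range(3)
        ]
        counts = c.tabulate_optimal_regimens(results)
        assert counts.to_dict() == {"a+b": 3}

    def test_counts_sorted_descending_and_conserved(self):
        r1 = c.Regimen(interventions=("a",))
        r2 = c.Regimen(interventions=("b",))
        results = [
            c.OptimizationResult(f"pt{i}", 1.0, reg, 0.5, {reg: 0.5})
            for i, reg in enumerate([r1, r2, r2, r2, r1])
        ]
        counts = c.tabulate_optimal_regimens(results)
        assert counts.iloc[0] == 3 and counts.index[0] == "b"
        assert counts.sum() == len(results)
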