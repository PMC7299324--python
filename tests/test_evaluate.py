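"""Concordance, pooling, risk groups, KM/logrank, Cox harnesses, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from slidesurv.cohort import SurvivalRecord
from slidesurv.evaluate import (CIndexResult, assign_risk_groups, auc_5yr,
                                bootstrap_ci, concordance_by_study,
                                concordance_index, fit_cox, km_curve,
                                logrank_test, loo_cox_added_value,
                                pooled_concordance)
from tests.conftest import make_survival_records
from tests.test_simulate import _brute_force_cindex


def _recs(times, events, study="S", **kw):
    return [SurvivalRecord(case_id=f"{study}{i}", study=study, time_days=t,
                           event=o, **kw) for i, (t, o) in enumerate(zip(times, events))]


class TestConcordance:
    def test_perfect_inverse_ordering_no_censoring(self):
        t = np.array([10.0, 20, 30, 40])
        res = concordance_index(-t, t, np.ones(4, int))
        assert res.c_index == 1.0 and res.informative == 6

    def test_all_tied_scores_give_half(self):
        t = np.arange(1.0, 11.0)
        res = concordance_index(np.zeros(10), t, np.ones(10, int))
        assert res.c_index == 0.5

    @pytest.mark.parametrize("n,seed", [(200, 0), (350, 1)])
    def test_matches_brute_force_with_censoring_and_ties(self, n, seed):
        rng = np.random.default_rng(seed)
        s = rng.integers(0, 40, size=n).astype(float)      # score ties
        t = rng.integers(1, 60, size=n).astype(float)      # time ties
        o = (rng.random(n) > 0.3).astype(int)
        res = concordance_index(s, t, o)
        assert res.c_index == pytest.approx(
            _brute_force_cindex(s, t, o), abs=1e-12)

    def test_reversal_maps_c_to_one_minus_c(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=100)                            # tie-free
        t = rng.integers(1, 50, size=100).astype(float)
        o = rng.integers(0, 2, size=100)
        a = concordance_index(s, t, o).c_index
        b = concordance_index(-s, t, o).c_index
        assert a + b == pytest.approx(1.0)

    def test_no_informative_pairs_rejected(self):
        with pytest.raises(ValueError, match="informative"):
            concordance_index([1.0, 2.0], [5.0, 9.0], [0, 0])


class TestPooledConcordance:
    def test_single_study_identity(self):
        r = CIndexResult(concordant=7, informative=10, study="A")
        assert pooled_concordance([r]).c_index == 0.7

    def test_printed_pooling_formula(self):
        a = CIndexResult(concordant=3, informative=4, study="A")
        b = CIndexResult(concordant=1, informative=2, study="B")
        pooled = pooled_concordance([a, b])
        assert pooled.concordant == 4 and pooled.informative == 6
        assert pooled.c_index == pytest.approx(4 / 6)
        assert pooled_concordance([b, a]).c_index == pooled.c_index

    def test_never_forms_cross_study_pairs(self):
        # two studies with disjoint time ranges: pooled c must equal the
        # within-study value, not the inflated all-pairs value
        rng = np.random.default_rng(3)
        sa = rng.normal(size=50)
        sb = rng.normal(size=50)
        ta = rng.integers(1, 20, 50).astype(float)
        tb = rng.integers(1000, 1020, 50).astype(float)
        per = concordance_by_study(np.r_[sa, sb], np.r_[ta, tb],
                                   np.ones(100, int), ["A"] * 50 + ["B"] * 50)
        pooled = pooled_concordance(per)
        assert pooled.informative == per[0].informative + per[1].informative
        assert pooled.informative < 100 * 99 / 2


class TestRiskGroups:
    def test_exact_quartiles_one_study(self):
        recs = _recs(np.full(8, 100.0), np.ones(8, int))
        df = pd.DataFrame({"case_id": [r.case_id for r in recs],
                           "risk_score": np.arange(1.0, 9.0)})
        groups = assign_risk_groups(df, recs)
        lows = {c for c, g in groups.mapping.items() if g == "low"}
        highs = {c for c, g in groups.mapping.items() if g == "high"}
        assert lows == {"S0", "S1"} and highs == {"S6", "S7"}

    def test_each_study_contributes_its_share_to_high_group(self):
        recs = (_recs(np.full(40, 50.0), np.ones(40, int), study="A")
                + _recs(np.full(40, 50.0), np.ones(40, int), study="B"))
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"case_id": [r.case_id for r in recs],
                           "risk_score": np.r_[rng.uniform(0, 1, 40),
                                               rng.uniform(100, 101, 40)]})
        groups = assign_risk_groups(df, recs)
        high = [c for c, g in groups.mapping.items() if g == "high"]
        assert sum(c.startswith("A") for c in high) == len(high) // 2

    def test_all_tied_cell_is_all_medium(self):
        recs = _recs(np.full(6, 9.0), np.ones(6, int))
        df = pd.DataFrame({"case_id": [r.case_id for r in recs],
                           "risk_score": np.full(6, 2.5)})
        groups = assign_risk_groups(df, recs)
        assert set(groups.mapping.values()) == {"medium"}

    def test_within_stage_grouping_cells(self):
        recs = _recs(np.full(16, 50.0), np.ones(16, int),
                     stage=1) + _recs(np.full(16, 50.0), np.ones(16, int),
                                      study="T", stage=3)
        df = pd.DataFrame({"case_id": [r.case_id for r in recs],
                           "risk_score": np.arange(32.0)})
        groups = assign_risk_groups(df, recs, group_by=("study", "stage"))
        assert len(groups.cuts) == 2


class TestKMAndLogrank:
    def test_no_events_flat_at_one(self):
        _, s = km_curve(_recs([100, 200, 300], [0, 0, 0]))
        assert np.all(s == 1.0)

    def test_two_events_closed_form(self):
        t, s = km_curve(_recs([31.0, 62.0], [1, 1]))
        np.testing.assert_allclose(s, [1.0, 0.5, 0.0])

    def test_mixed_example_matches_product_limit_hand_computation(self):
        # times (months): events at 1,2,4; censored at 2,3
        days = np.array([1, 2, 2, 3, 4]) * 30.44 + 1
        recs = _recs(days, [1, 1, 0, 0, 1])
        t, s = km_curve(recs)
        # hand computation: S(1)=4/5; S(2)=4/5*3/4=3/5; S(4)=3/5*0=0
        got = dict(zip(t, s))
        assert got[1.0] == pytest.approx(4 / 5)
        assert got[2.0] == pytest.approx(3 / 5)
        assert got[4.0] == pytest.approx(0.0)

    def test_identical_groups_give_p_one(self):
        g = _recs([10, 20, 30, 40], [1, 0, 1, 1])
        assert logrank_test(g, list(g)) == pytest.approx(1.0)

    def test_separated_exponential_groups_significant(self):
        rng = np.random.default_rng(5)
        a = _recs(np.ceil(rng.exponential(100, 200)), np.ones(200, int), study="A")
        b = _recs(np.ceil(rng.exponential(20, 200)), np.ones(200, int), study="B")
        assert logrank_test(a, b) < 0.001

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(6)
        a = _recs(np.ceil(rng.exponential(80, 30)), rng.integers(0, 2, 30), "A")
        b = _recs(np.ceil(rng.exponential(50, 30)), rng.integers(0, 2, 30), "B")
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_recs([10], [0]), _recs([20], [0]))


class TestCoxHarness:
    def test_binary_hr_recovery(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, size=2000)
        recs = make_survival_records(2000, rng, hazard=0.002, beta=np.log(2),
                                     covariate=x, censor_rate=0.001)
        feats = pd.DataFrame({"case_id": [r.case_id for r in recs], "x": x})
        fit = fit_cox(feats, recs)
        assert 1.8 <= fit.summary.loc["x", "HR"] <= 2.2

    def test_age_scaling_identity(self):
        rng = np.random.default_rng(8)
        base = make_survival_records(300, rng, hazard=0.01)
        ages = rng.uniform(40, 80, 300)
        recs = [SurvivalRecord(r.case_id, r.study, r.time_days, r.event,
                               stage=2, age=a, sex="F" if i % 2 else "M")
                for i, (r, a) in enumerate(zip(base, ages))]
        feats = pd.DataFrame({"case_id": [r.case_id for r in recs]})
        from slidesurv.evaluate import build_design
        d10 = build_design(feats, recs, age_scale=10.0)
        d1 = build_design(feats, recs, age_scale=1.0)
        np.testing.assert_allclose(d10["age_per10"] * 10, d1["age_per10"] * 1)

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(9)
        base = make_survival_records(80, rng, hazard=0.01)
        recs = [SurvivalRecord(r.case_id, r.study, r.time_days, r.event,
                               stage=2, age=60.0, sex="F") for r in base]
        feats = pd.DataFrame({"case_id": [r.case_id for r in recs],
                              "score": rng.normal(size=80)})
        with pytest.warns(UserWarning, match="sex_male"):
            fit = fit_cox(feats, recs)
        assert "sex_male" in fit.dropped
        assert "sex_male" not in fit.summary.index

    def test_truncation_censors_after_horizon(self):
        rng = np.random.default_rng(10)
        recs = make_survival_records(400, rng, hazard=0.0005, censor_rate=0.0)
        feats = pd.DataFrame({"case_id": [r.case_id for r in recs],
                              "x": rng.normal(size=400)})
        full = fit_cox(feats, recs)
        trunc = fit_cox(feats, recs, truncate_months=60)
        assert trunc.fitter.event_observed.sum() < full.fitter.event_observed.sum()

    def test_interactions_and_dummies_present(self):
        rng = np.random.default_rng(11)
        recs = []
        for study in ("A", "B"):
            for r in make_survival_records(60, rng, hazard=0.01, study=study):
                recs.append(SurvivalRecord(r.case_id, r.study, r.time_days,
                                           r.event, stage=int(rng.integers(1, 5)),
                                           age=float(rng.uniform(40, 80)),
                                           sex="F" if rng.random() < 0.5 else "M"))
        feats = pd.DataFrame({"case_id": [r.case_id for r in recs],
                              "score": rng.normal(size=len(recs))})
        fit = fit_cox(feats, recs, study_dummies=True, interactions=True)
        idx = set(fit.summary.index)
        assert {"study_B", "study_B_x_stage", "study_B_x_age"} <= idx


class TestBootstrap:
    def test_constant_statistic_degenerate_interval(self):
        lo, hi = bootstrap_ci(lambda idx: 3.14, np.arange(50), B=25, seed=0)
        assert lo == hi == 3.14

    def test_single_resample_collapses(self):
        data = np.arange(10.0)
        lo, hi = bootstrap_ci(lambda idx: data[idx].mean(), data, B=1, seed=1)
        assert lo == hi

    def test_stratified_resampling_preserves_group_sizes(self):
        strata = np.array(["A"] * 30 + ["B"] * 10)

        def stat(idx):
            assert (strata[idx] == "A").sum() == 30
            return 0.0

        bootstrap_ci(stat, np.arange(40), B=10, seed=2, strata=strata)


class TestAuc5yr:
    def test_outcome_indicator_scores_perfect(self):
        recs = _recs([30 * 30.44, 70 * 30.44, 40 * 30.44, 80 * 30.44],
                     [1, 0, 1, 1])
        y = np.array([1, 0, 1, 0])          # 80-month event is a 5yr survivor
        assert auc_5yr(y.astype(float), recs) == 1.0

    def test_all_tied_scores_half(self):
        recs = _recs([30 * 30.44, 70 * 30.44], [1, 0])
        assert auc_5yr(np.zeros(2), recs) == 0.5

    def test_censored_before_horizon_excluded(self):
        recs = _recs([30 * 30.44, 40 * 30.44, 70 * 30.44], [1, 0, 0])
        # middle case censored at 40 months: unknown 5-yr status, must not count
        assert auc_5yr(np.array([5.0, 99.0, 1.0]), recs) == 1.0

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(12)
        t = rng.integers(1, 4000, size=50).astype(float)
        o = rng.integers(0, 2, size=50)
        s = rng.integers(0, 10, size=50).astype(float)
        recs = _recs(t, o)
        tm = np.array([r.time_months for r in recs])
        pos = [i for i in range(50) if o[i] == 1 and tm[i] <= 60]
        neg = [i for i in range(50) if tm[i] >= 60 and not (o[i] == 1 and tm[i] <= 60)]
        wins = sum((s[i] > s[j]) + 0.5 * (s[i] == s[j]) for i in pos for j in neg)
        assert auc_5yr(s, recs) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        recs = _recs([10 * 30.44, 20 * 30.44], [1, 1])
        with pytest.raises(ValueError):
            auc_5yr(np.array([1.0, 2.0]), recs)


class TestLOOAddedValue:
    def test_duplicated_feature_column_collapses(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=80)
        recs = make_survival_records(80, rng, hazard=0.003, beta=0.7, covariate=x)
        ids = [r.case_id for r in recs]
        single = {"m": pd.DataFrame({"case_id": ids, "x": x})}
        doubled = {"m": pd.DataFrame({"case_id": ids, "x": x, "x2": x})}
        a = loo_cox_added_value(single, recs)
        b = loo_cox_added_value(doubled, recs)
        assert a.loc[0, "c_index"] == pytest.approx(b.loc[0, "c_index"])
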