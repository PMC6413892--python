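"""Goodness of fit, concordance, calibration, and comparator risk scores."""

import numpy as np
import pandas as pd
import pytest

from predictprostate import (
    PatientRecord,
    calibration_quintiles,
    capra_score,
    compare_discrimination,
    eau_group,
    expected_events,
    gof_test,
    harrell_c,
    nccn_group,
)
from predictprostate.predict import RiskPrediction
from predictprostate.validate import NCCN_ORDER, cohort_expected_events


class TestGOF:
    def test_perfect_agreement(self):
        chi2, df, p = gof_test([10, 20, 30, 25, 15], [10, 20, 30, 25, 15])
        assert chi2 == 0.0 and df == 4 and p == 1.0

    def test_two_group_hand_value(self):
        chi2, df, p = gof_test([10, 20], [15, 15])
        assert chi2 == pytest.approx(50 / 15, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(0.0679, abs=5e-4)

    def test_groups_df_mode(self):
        _, df, _ = gof_test([10, 20], [15, 15], df_mode="groups")
        assert df == 2

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError, match="regroup|merge"):
            gof_test([1, 2], [0.0, 3.0])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            gof_test([5], [5])


def _flat_curve(level):
    times = np.array([5.0, 10.0, 15.0])
    r = np.full(3, level)
    z = np.zeros(3)
    return RiskPrediction(times, r, z, r, r, z, 0.0, 0.0, "s")


def _linear_curve(slope):
    times = np.array([5.0, 10.0, 15.0])
    r = slope * times
    z = np.zeros(3)
    return RiskPrediction(times, r, z, r, r, z, 0.0, 0.0, "s")


class TestExpectedEvents:
    def test_full_followup_gives_horizon_risk(self):
        e = expected_events([_flat_curve(0.3)], [10.0], horizon=10.0)
        assert e[0] == pytest.approx(0.3)

    def test_zero_followup_contributes_nothing(self):
        e = expected_events([_flat_curve(0.3)], [0.0], horizon=10.0)
        assert e[0] == 0.0

    def test_three_subject_toy_group_total(self):
        """Risks 0.1 at full follow-up, 0.2-at-10y curve censored at 5y
        contributing 0.08, 0.3 at full follow-up: E = 0.48."""
        preds = [_flat_curve(0.1), _linear_curve(0.016), _flat_curve(0.3)]
        e = expected_events(preds, [10.0, 5.0, 10.0], horizon=10.0)
        assert e[1] == pytest.approx(0.08)
        assert e.sum() == pytest.approx(0.48)

    def test_missing_followup_flagged_nan(self):
        e = expected_events([_flat_curve(0.2)], [np.nan], horizon=10.0)
        assert np.isnan(e[0])

    def test_deaths_integrate_to_horizon(self):
        e = expected_events(
            [_linear_curve(0.016)], [5.0], horizon=10.0, events=[1]
        )
        assert e[0] == pytest.approx(0.16)

    def test_additive_over_disjoint_subgroups(self, default_model, cohort_factory):
        df = cohort_factory(n=400, seed=9)
        e_all = np.nansum(cohort_expected_events(default_model, df, 10.0, "pcsm"))
        half = len(df) // 2
        e_a = np.nansum(
            cohort_expected_events(default_model, df.iloc[:half], 10.0, "pcsm")
        )
        e_b = np.nansum(
            cohort_expected_events(default_model, df.iloc[half:], 10.0, "pcsm")
        )
        assert e_all == pytest.approx(e_a + e_b, rel=1e-12)


def _brute_force_c(scores, times, events):
    """Exhaustive pair enumeration oracle for the concordance index."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j or not events[i]:
                continue
            if times[i] < times[j] or (times[i] == times[j] and not events[j]):
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestHarrellC:
    def test_perfect_ranking(self):
        scores = [4.0, 3.0, 2.0, 1.0]
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        rep = harrell_c(scores, times, events, cause=1)
        assert rep.c_index == 1.0

    def test_matches_brute_force_oracle_with_censoring(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            n = 30
            scores = rng.normal(size=n)
            times = rng.exponential(5, size=n)
            events = rng.choice([0, 1, 2], size=n, p=[0.3, 0.4, 0.3])
            rep = harrell_c(scores, times, events, cause=1)
            oracle = _brute_force_c(scores, times, (events == 1).astype(int))
            assert rep.c_index == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_lifelines_on_untied_data(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(11)
        n = 400
        scores = rng.normal(size=n)
        times = rng.exponential(5, size=n)
        events = (rng.uniform(size=n) < 0.6).astype(int)
        rep = harrell_c(scores, times, events, cause=1)
        ll = concordance_index(times, -np.asarray(scores), events)
        assert rep.c_index == pytest.approx(ll, abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        n = 5000
        scores = rng.normal(size=n)
        times = rng.exponential(5, size=n)
        events = (rng.uniform(size=n) < 0.5).astype(int)
        rep = harrell_c(scores, times, events, cause=1)
        assert rep.c_index == pytest.approx(0.5, abs=0.02)
        assert rep.ci_low < 0.5 < rep.ci_high

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        n = 200
        scores = rng.uniform(0.01, 0.99, size=n)
        times = rng.exponential(5, size=n)
        events = (rng.uniform(size=n) < 0.7).astype(int)
        a = harrell_c(scores, times, events, cause=1).c_index
        b = harrell_c(np.log(scores / (1 - scores)), times, events, cause=1).c_index
        assert a == pytest.approx(b, abs=1e-12)

    def test_competing_cause_censored_at_death(self):
        # a cause-2 death must act as censoring for the cause-1 index
        scores = [3.0, 2.0, 1.0]
        times = [1.0, 2.0, 3.0]
        events = [1, 2, 0]
        rep = harrell_c(scores, times, events, cause=1)
        assert rep.n_pairs == 2  # only subject 1's pairs are usable

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            harrell_c([1.0, 2.0], [1.0, 2.0], [0, 0], cause=1)


class TestCompareDiscrimination:
    def test_model_against_itself_is_null(self):
        rng = np.random.default_rng(4)
        n = 300
        s = rng.normal(size=n)
        times = rng.exponential(5, size=n)
        events = (rng.uniform(size=n) < 0.6).astype(int)
        table = compare_discrimination(
            {"a": s, "b": s.copy()}, times, events, cause=1
        )
        row = table[table["model"] == "b"].iloc[0]
        assert row["diff_vs_a"] == 0.0
        assert row["p_vs_a"] == 1.0

    def test_informative_score_beats_noise(self, cohort_factory, default_model):
        from predictprostate import cohort_risk_at

        df = cohort_factory(n=1500, seed=91)
        _, r_pca, _ = cohort_risk_at(df, default_model, 15.0)
        rng = np.random.default_rng(0)
        table = compare_discrimination(
            {"model": r_pca, "noise": rng.normal(size=len(df))},
            df["time_years"],
            df["event"],
            cause=1,
        )
        c_model = table[table["model"] == "model"]["c_index"].iloc[0]
        c_noise = table[table["model"] == "noise"]["c_index"].iloc[0]
        assert c_model > 0.7 > c_noise
        assert table[table["model"] == "noise"]["p_vs_model"].iloc[0] < 1e-4

    def test_misaligned_sets_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            compare_discrimination(
                {"a": [1, 2, 3], "b": [1, 2]}, [1, 2, 3], [1, 1, 1]
            )


class TestCalibration:
    def test_percent_difference_sign_convention(self, cohort_factory, default_model):
        """Observed exceeding expected yields a positive percent difference."""
        df = cohort_factory(n=1200, seed=14)
        rep = calibration_quintiles(default_model, df, horizon=10.0, cause="om")
        for o, e, n, pct in zip(
            rep.observed, rep.expected, rep.group_n, rep.percent_difference
        ):
            assert pct == pytest.approx(100.0 * (o - e) / n, abs=1e-9)
        assert sum(rep.group_n) == len(df)
        assert sum(rep.observed) == ((df["event"] > 0) & (df["time_years"] <= 10)).sum()

    def test_risk_ordering_across_quintiles(self, cohort_factory, default_model):
        df = cohort_factory(n=2000, seed=15)
        rep = calibration_quintiles(default_model, df, horizon=10.0, cause="om")
        per_n = [e / n for e, n in zip(rep.expected, rep.group_n)]
        assert per_n == sorted(per_n)

    def test_degenerate_predictions_fall_back_to_one_group(self, cohort_factory):
        from predictprostate import build_published_model
        from predictprostate.model import FPBaseline

        df = cohort_factory(n=100, seed=16)
        # identical covariates => identical predictions
        for col, val in [
            ("age", 70.0),
            ("psa", 10.0),
            ("grade_group", 2),
            ("t_stage", 2),
            ("treatment", "conservative"),
            ("comorbidity", 0),
        ]:
            df[col] = val
        model = build_published_model()
        with pytest.warns(UserWarning, match="degenerate"):
            rep = calibration_quintiles(model, df, horizon=10.0, cause="om", n_groups=5)
        assert rep.grouping == ["all"]

    def test_stratified_mode(self, cohort_factory, default_model):
        df = cohort_factory(n=1000, seed=18)
        rep = calibration_quintiles(
            default_model, df, horizon=10.0, cause="pcsm", strata="treatment"
        )
        assert set(rep.grouping) == {"conservative", "radical", "hormone"}


def _patient(age=65, psa=5.0, gg=1, t=1, cp=None, ct=None):
    return PatientRecord(
        id="p",
        age=age,
        psa=psa,
        grade_group=gg,
        t_stage=t,
        treatment="conservative",
        cores_positive=cp,
        cores_total=ct,
    )


class TestComparatorScores:
    def test_capra_minimum(self):
        assert capra_score(_patient(age=49, psa=5, gg=1, t=1, cp=2, ct=10)) == 0

    def test_capra_high_risk_components(self):
        # age>=50 (1) + PSA 20.1-30 (3) + primary pattern >=4 (3) + T3 (1)
        # + >=34% cores (1)
        assert capra_score(_patient(age=65, psa=25, gg=5, t=3, cp=6, ct=10)) == 9

    def test_capra_gleason_mapping(self):
        # grade group 2 = 3+4: secondary pattern 4 scores 1 point
        assert capra_score(_patient(age=49, psa=5, gg=2, t=1, cp=1, ct=10)) == 1
        # grade group 3 = 4+3: primary pattern 4 scores 3 points
        assert capra_score(_patient(age=49, psa=5, gg=3, t=1, cp=1, ct=10)) == 3

    def test_capra_missing_cores_contribute_nothing(self):
        assert capra_score(_patient(age=49, psa=5, gg=1, t=1)) == 0

    def test_capra_missing_mandatory_component(self):
        rec = _patient()
        rec.psa = None
        with pytest.raises(ValueError, match="psa"):
            capra_score(rec)

    def test_eau_low(self):
        assert eau_group(_patient(psa=8, gg=1, t=1)) == "low"

    def test_eau_intermediate_with_collapsed_t2(self):
        # T2 is taken as T2a, so it does not force high risk
        assert eau_group(_patient(psa=15, gg=2, t=2)) == "intermediate"

    def test_eau_psa_alone_forces_high(self):
        assert eau_group(_patient(psa=25, gg=1, t=1)) == "high"

    def test_nccn_tiers(self):
        assert nccn_group(_patient(psa=5, gg=1, t=1)) == "low"
        # single intermediate risk factor (grade group 2), low core burden
        assert nccn_group(_patient(psa=5, gg=2, t=2, cp=2, ct=12)) == (
            "favourable_intermediate"
        )
        # >=50% positive cores is unfavourable under the pinned ruleset
        assert nccn_group(_patient(psa=5, gg=2, t=2, cp=6, ct=12)) == (
            "unfavourable_intermediate"
        )
        # two intermediate risk factors (PSA band + grade) are unfavourable
        assert nccn_group(_patient(psa=15, gg=2, t=2, cp=2, ct=12)) == (
            "unfavourable_intermediate"
        )
        assert nccn_group(_patient(psa=25, gg=1, t=1)) == "high"
        assert nccn_group(_patient(psa=5, gg=1, t=4)) == "very_high"

    def test_nccn_order_is_monotone_in_risk(self):
        tiers = [
            nccn_group(_patient(psa=5, gg=1, t=1)),
            nccn_group(_patient(psa=5, gg=2, t=1, cp=2, ct=12)),
            nccn_group(_patient(psa=15, gg=3, t=2)),
            nccn_group(_patient(psa=30, gg=4, t=3)),
            nccn_group(_patient(psa=30, gg=5, t=4)),
        ]
        idx = [NCCN_ORDER.index(t) for t in tiers]
        assert idx == sorted(idx)
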