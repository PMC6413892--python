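"""Prognostic indices, competing-risk combination, curves, treatment benefit."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predictprostate import (
    PatientRecord,
    combine_competing_risks,
    population_comorbidity_adjustment,
    ppc_multiplier,
    predict_curves,
    prognostic_index,
    treatment_benefit,
)
from predictprostate.predict import marginal_risk_from_cumhaz

# covariate values at which the published continuous transforms are zero
AGE_CENTER = 10.0 * 341.16 ** (1.0 / 3.0)  # ~69.94
PSA_CENTER = 100.0 * math.exp(-1.6364) - 1.0  # ~18.47
NPCM_AGE_CENTER = 69.87


def reference_patient(**kw):
    base = dict(
        id="ref",
        age=AGE_CENTER,
        psa=PSA_CENTER,
        grade_group=1,
        t_stage=1,
        treatment="conservative",
        comorbidity=0,
    )
    base.update(kw)
    return PatientRecord(**base)


class TestPrognosticIndex:
    def test_reference_patient_is_zero(self, default_model):
        assert prognostic_index(reference_patient(), default_model, "pcsm") == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_grade_group_five_shifts_by_log_hr(self, default_model):
        pi = prognostic_index(
            reference_patient(grade_group=5), default_model, "pcsm"
        )
        assert pi == pytest.approx(math.log(3.93), abs=1e-12)

    def test_radical_treatment_shifts_by_log_half(self, default_model):
        pi = prognostic_index(
            reference_patient(treatment="radical"), default_model, "pcsm"
        )
        assert pi == pytest.approx(math.log(0.50), abs=1e-12)

    def test_npcm_reference_zero_and_comorbidity_shift(self, default_model):
        rec = reference_patient(age=NPCM_AGE_CENTER)
        assert prognostic_index(rec, default_model, "npcm") == pytest.approx(0.0)
        rec1 = reference_patient(age=NPCM_AGE_CENTER, comorbidity=1)
        assert prognostic_index(rec1, default_model, "npcm") == pytest.approx(
            math.log(1.89)
        )

    def test_unknown_comorbidity_gets_population_average(self, default_model):
        rec = reference_patient(age=NPCM_AGE_CENTER, comorbidity=None)
        pi = prognostic_index(rec, default_model, "npcm")
        assert pi == pytest.approx(
            math.log(population_comorbidity_adjustment(0.1021, 1.89)), abs=1e-9
        )

    def test_unknown_cause_rejected(self, default_model):
        with pytest.raises(ValueError, match="cause"):
            prognostic_index(reference_patient(), default_model, "xyz")


class TestPPCMultiplier:
    def test_half_is_upper_class(self):
        assert ppc_multiplier(reference_patient(cores_positive=6, cores_total=12)) == 1.78

    def test_below_half_is_lower_class(self):
        assert ppc_multiplier(reference_patient(cores_positive=5, cores_total=12)) == 0.54

    def test_unknown_counts_are_neutral(self):
        assert ppc_multiplier(reference_patient()) == 1.0


class TestPopulationComorbidity:
    def test_published_prevalence_value(self):
        assert population_comorbidity_adjustment(0.1021, 1.89) == pytest.approx(
            1.0 + 0.1021 * 0.89, abs=1e-12
        )

    def test_zero_prevalence_neutral(self):
        assert population_comorbidity_adjustment(0.0, 1.89) == 1.0

    def test_null_hazard_ratio_neutral(self):
        assert population_comorbidity_adjustment(0.37, 1.0) == 1.0


class TestCombineCompetingRisks:
    def test_printed_worked_example(self):
        r_om, r_pca, r_npc = combine_competing_risks(0.2, 0.3)
        assert float(r_om) == pytest.approx(0.44, abs=1e-12)
        assert float(r_pca) == pytest.approx(0.176, abs=1e-12)
        assert float(r_npc) == pytest.approx(0.264, abs=1e-12)

    def test_single_cause_degenerates_to_marginal(self):
        for h in (0.0, 0.3, 0.99):
            r_om, r_pca, r_npc = combine_competing_risks(h, 0.0)
            assert float(r_om) == pytest.approx(h)
            assert float(r_pca) == pytest.approx(h)
            assert float(r_npc) == 0.0

    def test_double_zero_corner(self):
        assert combine_competing_risks(0.0, 0.0) == (0.0, 0.0, 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_competing_risks(1.2, 0.3)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=200, deadline=None)
    def test_partition_identity_and_bounds(self, h1, h2):
        r_om, r_pca, r_npc = combine_competing_risks(h1, h2)
        assert 0.0 <= r_om <= 1.0
        assert abs(float(r_pca + r_npc - r_om)) < 1e-12
        assert r_om >= max(r_pca, r_npc) - 1e-15


class TestMarginalRisk:
    def test_closed_form_value(self):
        assert marginal_risk_from_cumhaz(0.0, 0.1) == pytest.approx(
            1.0 - math.exp(-0.1), abs=1e-12
        )

    def test_zero_cumulative_hazard(self):
        assert marginal_risk_from_cumhaz(3.0, 0.0) == 0.0

    def test_vanishing_prognostic_index_limit(self):
        assert marginal_risk_from_cumhaz(-745.0, 5.0) == pytest.approx(0.0, abs=1e-300)


class TestPredictCurves:
    def test_monotone_and_conserved(self, default_model):
        pred = predict_curves(
            reference_patient(grade_group=3, treatment="hormone"), default_model
        )
        for curve in (pred.h_pca, pred.h_npc, pred.r_om, pred.r_pca, pred.r_npc):
            assert np.all(np.diff(curve) >= -1e-15)
            assert np.all((curve >= 0) & (curve <= 1))
        assert np.max(np.abs(pred.r_pca + pred.r_npc - pred.r_om)) < 1e-12

    def test_comorbidity_raises_other_cause_risk_and_lowers_cancer_share(
        self, default_model
    ):
        p0 = predict_curves(reference_patient(comorbidity=0), default_model)
        p1 = predict_curves(reference_patient(comorbidity=1), default_model)
        assert np.all(p1.r_npc > p0.r_npc)
        assert np.all(p1.r_pca < p0.r_pca)
        assert np.allclose(p1.h_pca, p0.h_pca)

    def test_radical_scenario_lowers_cancer_risk_everywhere(self, default_model):
        rec = reference_patient(grade_group=4)
        cons = predict_curves(rec, default_model, scenario="conservative")
        rad = predict_curves(rec, default_model, scenario="radical")
        assert np.all(rad.h_pca < cons.h_pca)
        assert np.all(rad.r_pca < cons.r_pca)

    def test_grid_domain_enforced(self, default_model):
        with pytest.raises(ValueError):
            predict_curves(reference_patient(), default_model, grid=[0.0, 5.0])
        with pytest.raises(ValueError):
            predict_curves(reference_patient(), default_model, grid=[16.0])

    def test_snapshots_on_grid(self, default_model):
        pred = predict_curves(reference_patient(), default_model)
        assert pred.at(10.0)["t"] == 10.0
        assert pred.at(15.0)["t"] == 15.0


class TestTreatmentBenefit:
    def test_null_efficacy_matches_conservative_curve(self, default_model):
        rec = reference_patient(grade_group=4)
        tb = treatment_benefit(rec, default_model, horizon=15)
        cons = predict_curves(rec, default_model, scenario="conservative")
        assert tb.band[0.0] == pytest.approx(1.0 - cons.at(15.0)["r_om"], abs=1e-12)

    def test_band_monotone_in_efficacy(self, default_model):
        tb = treatment_benefit(
            reference_patient(grade_group=5, t_stage=3), default_model, horizon=15
        )
        vals = [tb.band[f] for f in sorted(tb.band)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_gain_bounded_by_cancer_mortality_reduction(self, default_model):
        for gg, age, com in [(2, 62, 0), (4, 75, 1), (5, 80, 1), (3, 55, 0)]:
            tb = treatment_benefit(
                reference_patient(grade_group=gg, age=age, comorbidity=com),
                default_model,
                horizon=15,
            )
            assert tb.os_gain >= 0.0
            assert tb.os_gain <= tb.pcsm_reduction + 1e-12

    def test_competing_risk_attenuates_benefit_for_older_comorbid(
        self, default_model
    ):
        """Same tumour profile: an older comorbid man gains less overall
        survival from radical treatment than a younger healthy one."""
        young = treatment_benefit(
            reference_patient(age=58, comorbidity=0, grade_group=4),
            default_model,
            horizon=15,
        )
        old = treatment_benefit(
            reference_patient(age=80, comorbidity=1, grade_group=4),
            default_model,
            horizon=15,
        )
        assert old.os_gain < young.os_gain

    def test_hormone_record_warns_counterfactual(self, default_model):
        rec = reference_patient(treatment="hormone")
        with pytest.warns(UserWarning, match="hormone"):
            tb = treatment_benefit(rec, default_model, horizon=15)
        assert tb.note is not None

    def test_bad_horizon_rejected(self, default_model):
        with pytest.raises(ValueError):
            treatment_benefit(reference_patient(), default_model, horizon=12)
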