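"""Discounting, reading/episode costs, treatment cost streams, QALY streams."""

import numpy as np
import pytest

from mammosim import economics as econ
from mammosim.economics import (
    ArmConfiguration,
    CostSchedule,
    UtilitySchedule,
    age_band_qaly,
    ai_overhead_per_patient,
    annuity,
    discount,
    episode_cost,
    locum_rates_from_census,
    qaly_stream_components,
    reading_cost_per_study,
    treatment_costs,
)
from mammosim.natural_history import ADVANCED, DCIS, NPI_I, NPI_III
from mammosim.screening import ReaderProfile


def make_arm(uses_ai, **kw):
    r = ReaderProfile(0.76, 0.97)
    return ArmConfiguration(label="ai" if uses_ai else "sp", r1=r, r2=r,
                            arbitration=ReaderProfile(1.0, 0.95), uses_ai=uses_ai, **kw)


class TestDiscounting:
    def test_zero_rate_is_identity(self):
        assert discount(100.0, 73.0, 0.0) == 100.0

    def test_closed_form_example(self):
        assert discount(100.0, 53.0, 0.035) == pytest.approx(100 * 1.035**-3, rel=1e-12)
        assert discount(100.0, 53.0, 0.035) == pytest.approx(90.19, abs=0.005)

    def test_accrual_before_50_forbidden(self):
        with pytest.raises(ValueError):
            discount(100.0, 49.9, 0.035)

    def test_discounted_never_exceeds_undiscounted(self):
        ages = np.linspace(50, 100, 20)
        assert np.all(discount(100.0, ages, 0.035) <= 100.0)
        assert np.all(annuity(50.0, ages, 0.035) <= annuity(50.0, ages, 0.0))

    def test_annuity_zero_rate_is_duration(self):
        assert annuity(55.0, 60.0, 0.0) == 5.0
        assert annuity(45.0, 55.0, 0.0) == 5.0  # clipped at accrual start


class TestReadingCosts:
    def test_headline_per_study_costs(self):
        assert reading_cost_per_study(make_arm(True)) == pytest.approx(10.62)
        assert reading_cost_per_study(make_arm(False)) == pytest.approx(11.80)

    def test_locum_mix(self):
        arm = make_arm(False, locum_fraction=0.10, locum_read_cost=10.30)
        assert reading_cost_per_study(arm) == pytest.approx(2 * (0.9 * 5.90 + 0.1 * 10.30))
        assert reading_cost_per_study(arm) == pytest.approx(12.68)

    def test_locum_rates_from_census(self):
        rates = locum_rates_from_census()
        assert rates["premium_per_study"] == pytest.approx(8.80)
        assert rates["premium_per_reader"] == pytest.approx(4.40)
        assert rates["locum_cost_per_read"] == pytest.approx(10.30)

    def test_invalid_configuration(self):
        with pytest.raises(ValueError):
            make_arm(True, ai_price=-1.0)
        with pytest.raises(ValueError):
            make_arm(False, locum_fraction=1.5)


class TestEpisodeCosts:
    def test_true_negative_standard_practice(self):
        from mammosim.screening import EpisodeOutcome

        ep = EpisodeOutcome(attended=True, reads=(False, False), final_call="normal",
                            classification="TN")
        assert episode_cost(ep, make_arm(False), CostSchedule()) == pytest.approx(195.80)

    def test_false_positive_with_arbitration_ai_arm(self):
        from mammosim.screening import EpisodeOutcome

        ep = EpisodeOutcome(attended=True, reads=(True, False), discordant=True, arbitrated=True,
                            final_call="recall", recall_result="FP", classification="FP")
        assert episode_cost(ep, make_arm(True), CostSchedule()) == pytest.approx(514.52)

    def test_non_attendance_is_free(self):
        from mammosim.screening import EpisodeOutcome

        assert episode_cost(EpisodeOutcome(attended=False), make_arm(False), CostSchedule()) == 0.0


class TestOverhead:
    def test_setup_amortisation(self):
        assert ai_overhead_per_patient(35000.0, 0.0, 21.0, 100_000) == pytest.approx(0.35)
        assert ai_overhead_per_patient(35000.0, 0.0, 21.0, 100_000) < 0.50
        assert ai_overhead_per_patient(0.0, 0.0, 21.0, 1234) == 0.0

    def test_maintenance_stream(self):
        for years in (1.0, 10.0, 26.5):
            assert ai_overhead_per_patient(0.0, 17000.0, years, 100_000) == pytest.approx(0.17 * years)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            ai_overhead_per_patient(35000.0, 0.0, 21.0, 0)


class TestTreatmentCosts:
    def test_dcis_one_off(self):
        assert treatment_costs(DCIS, 50.0, 90.0, "natural", CostSchedule(), 0.0) == 8968.0

    def test_npi1_survivor_full_schedule(self):
        got = treatment_costs(NPI_I, 60.0, 95.0, "natural", CostSchedule(), 0.0)
        assert got == pytest.approx(10471 + 8 * 2819)
        assert got == pytest.approx(33023)

    def test_npi3_death_one_year_after_diagnosis(self):
        costs = CostSchedule()
        got = treatment_costs(NPI_III, 60.0, 61.0, "cancer", costs, 0.0)
        # final year of life replaces the first-year schedule entirely:
        # six months advanced care + six months pro-rata palliative care
        expected = 14984.0 + 14827.0 * 182.625 / 372.0
        assert got == pytest.approx(expected)

    def test_npi_death_in_year_five_hand_enumeration(self):
        costs = CostSchedule()
        got = treatment_costs(NPI_III, 60.0, 65.0, "cancer", costs, 0.0)
        # anniversaries at 60 (first year), 61, 62, 63 (< 64 = start of final year),
        # then advanced+palliative final year
        expected = 21951 + 3 * 3815 + 14984 + 14827 * 182.625 / 372.0
        assert got == pytest.approx(expected)

    def test_advanced_at_diagnosis_short_survival(self):
        costs = CostSchedule()
        got = treatment_costs(ADVANCED, 60.0, 60.4, "cancer", costs, 0.0)
        # under six months: palliative only, pro rata
        assert got == pytest.approx(costs.palliative_final_6m() * 0.4 / 0.5)

    def test_discounting_applied_at_event_ages(self):
        undisc = treatment_costs(NPI_I, 60.0, 95.0, "natural", CostSchedule(), 0.0)
        disc = treatment_costs(NPI_I, 60.0, 95.0, "natural", CostSchedule(), 0.035)
        assert disc < undisc
        assert disc == pytest.approx(
            10471 * 1.035**-10 + sum(2819 * 1.035 ** -(10 + y) for y in range(1, 9))
        )

    def test_pre50_cash_flows_dropped(self):
        # diagnosed at 45, survives: first-year cost and anniversaries at 46-49 drop
        got = treatment_costs(NPI_I, 45.0, 90.0, "natural", CostSchedule(), 0.0)
        assert got == pytest.approx(4 * 2819)  # years 6-9 anniversaries at ages 50-53


class TestQALYStreams:
    def test_all_one_utilities_give_survival_time(self):
        utils = UtilitySchedule(
            age_band_utils=np.ones(4), npi_at_12m=np.ones(3), npi_from_12m=np.ones(3),
            advanced=1.0, palliative=1.0,
        )
        assert qaly_stream_components(87.0, None, None, "natural", utils, 0.0) == pytest.approx(37.0)
        assert qaly_stream_components(87.0, NPI_I, 60.0, "cancer", utils, 0.0) == pytest.approx(37.0)

    def test_never_cancer_band_sum(self):
        utils = UtilitySchedule()
        expected = 5 * 0.846 + 10 * 0.804 + 10 * 0.760 + 12 * 0.692
        assert qaly_stream_components(87.0, None, None, "natural", utils, 0.0) == pytest.approx(expected)

    def test_npi1_cured_hand_enumeration(self):
        utils = UtilitySchedule()
        got = qaly_stream_components(95.0, NPI_I, 60.0, "natural", utils, 0.0)
        expected = (
            5 * 0.846 + 5 * 0.804  # 50-60 age band
            + 1 * 0.704  # first year post-diagnosis
            + 4 * 0.779 + 4 * 0.779  # years 2-9 at the from-12-months utility (60-69)
            + 6 * 0.760  # cured, back to age band to 75
            + 20 * 0.692
        )
        assert got == pytest.approx(expected)

    def test_cancer_death_final_year_utilities(self):
        utils = UtilitySchedule()
        got = qaly_stream_components(64.0, NPI_III, 60.0, "cancer", utils, 0.0)
        expected = 5 * 0.846 + 5 * 0.804 + 1 * 0.727 + 2 * 0.759 + 0.5 * 0.74 + 0.5 * 0.51
        assert got == pytest.approx(expected)

    def test_dcis_six_month_dip_then_healed(self):
        utils = UtilitySchedule()
        got = qaly_stream_components(87.0, DCIS, 60.0, "natural", utils, 0.0)
        base = 5 * 0.846 + 10 * 0.804 + 10 * 0.760 + 12 * 0.692
        assert got == pytest.approx(base - 0.5 * (0.804 - 0.704))

    def test_qalys_bounded_by_survival_from_50(self):
        utils = UtilitySchedule()
        for death, stage, diag, cause in [(87.0, None, None, "natural"), (70.0, NPI_III, 60.0, "cancer"),
                                          (51.0, ADVANCED, 50.0, "cancer")]:
            q = qaly_stream_components(death, stage, diag, cause, utils, 0.035)
            assert 0.0 <= q <= death - 50.0

    def test_vector_age_band_matches_scalar_stream(self, rng):
        """The engine's vectorised cancer-free path equals the scalar accounting."""
        utils = UtilitySchedule()
        deaths = rng.uniform(50.0, 105.0, 50)
        vec = age_band_qaly(50.0, deaths, utils, 0.035)
        scal = [qaly_stream_components(d, None, None, "natural", utils, 0.035) for d in deaths]
        assert np.allclose(vec, scal, rtol=0, atol=1e-12)

    def test_wrapper_over_woman_profile(self):
        from mammosim.economics import qaly_stream
        from mammosim.natural_history import TumourState, WomanProfile

        utils = UtilitySchedule()
        p = WomanProfile(id=0, density=0, death_age_natural=87.0, death_age=87.0)
        assert qaly_stream(p, utils, 0.0) == pytest.approx(
            qaly_stream_components(87.0, None, None, "natural", utils, 0.0)
        )
        t = TumourState(onset_age=55.0, growth_rate=1.07)
        t.set_stage(NPI_I, 60.0)
        p2 = WomanProfile(id=1, density=0, death_age_natural=87.0, death_age=64.0,
                          tumour=t, cause_of_death="cancer")
        assert qaly_stream(p2, utils, 0.0) == pytest.approx(
            qaly_stream_components(64.0, NPI_I, 60.0, "cancer", utils, 0.0)
        )
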