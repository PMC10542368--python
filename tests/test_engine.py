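"""Cohort driver: common random numbers, accounting identities, determinism."""

import dataclasses

import numpy as np
import pytest

from mammosim import demographics as dg
from mammosim import engine as E
from mammosim import params as P
from mammosim.economics import make_arms, reading_cost_per_study


@pytest.fixture(scope="module")
def cancer_free_registry():
    return P.default_registry(incidence=dg.build_incidence_table(lifetime_risk=0.0))


class TestAccountingIdentities:
    def test_cancer_free_cohort_cost_gap_is_reading_price_difference(self, cancer_free_registry):
        """With no cancer anywhere, the arms differ only in reading labour and
        AI overhead; QALYs are identical arrays."""
        ps = P.sample_parameter_set(cancer_free_registry, np.random.default_rng(0), psa=False)
        s, natural, oc = E.run_cohort(4000, ps, seed=11, return_outcomes=True)
        assert s.n_excluded == 0
        assert np.array_equal(oc["ai"].qalys, oc["sp"].qalys)
        assert s.arms["ai"].mean_qalys == s.arms["sp"].mean_qalys
        # every attended episode is a TN (possibly a FP) in both arms; the
        # discounted study counts coincide because attendance is shared
        assert np.array_equal(oc["ai"].disc_reads, oc["sp"].disc_reads)
        arms = make_arms(ps.screening, ps.economics)
        price_gap = reading_cost_per_study(arms["ai"]) - reading_cost_per_study(arms["sp"])
        expected = price_gap * s.arms["ai"].mean_disc_reads + s.arms["ai"].ai_overhead
        observed = s.arms["ai"].mean_cost - s.arms["sp"].mean_cost
        # residual: arbitration and false-positive recall costs, which differ
        # only through the independent reading streams
        fp_terms = abs(observed - expected)
        assert fp_terms < 1.5  # pounds per woman, small stream noise
        # with a shared reading stream and identical specificities the
        # identity is exact up to float addition order
        ps2 = P.apply_overrides(ps, {"screening.ai_reader.specificity": 0.97})
        s2 = E.run_cohort(4000, ps2, seed=11, share_reading_stream=True)
        arms2 = make_arms(ps2.screening, ps2.economics)
        gap2 = reading_cost_per_study(arms2["ai"]) - reading_cost_per_study(arms2["sp"])
        expected2 = gap2 * s2.arms["ai"].mean_disc_reads + s2.arms["ai"].ai_overhead
        assert s2.arms["ai"].mean_cost - s2.arms["sp"].mean_cost == pytest.approx(expected2, abs=1e-9)

    def test_identical_readers_shared_stream_bit_identical(self, base_params):
        ps = P.apply_overrides(
            base_params,
            {
                "screening.ai_human.sensitivity": 0.760,
                "screening.ai_reader.sensitivity": 0.760,
                "screening.ai_reader.specificity": 0.970,
            },
        )
        s, natural, oc = E.run_cohort(
            3000, ps, seed=21, share_reading_stream=True, return_outcomes=True
        )
        assert np.array_equal(oc["ai"].qalys, oc["sp"].qalys)
        assert np.array_equal(oc["ai"].stage, oc["sp"].stage)
        assert np.array_equal(oc["ai"].death_age, oc["sp"].death_age)
        assert s.arms["ai"].mean_qalys == s.arms["sp"].mean_qalys  # delta == 0 exactly


class TestCommonRandomNumbers:
    def test_natural_history_shared_across_arms(self, base_params):
        _, natural, oc = E.run_cohort(2000, base_params, seed=5, return_outcomes=True)
        # tumour trajectory inputs are one shared object; outcomes may differ
        # only through reading
        assert oc["ai"].diagnosed.shape == oc["sp"].diagnosed.shape
        same_dx = oc["ai"].diagnosed == oc["sp"].diagnosed
        both = oc["ai"].diagnosed & oc["sp"].diagnosed
        same_age = oc["ai"].diagnosis_age[both] == oc["sp"].diagnosis_age[both]
        # women diagnosed at the same age get identical stage and death draws
        agree = both & np.isclose(oc["ai"].diagnosis_age, oc["sp"].diagnosis_age)
        assert np.array_equal(oc["ai"].stage[agree], oc["sp"].stage[agree])
        assert np.array_equal(oc["ai"].death_age[agree], oc["sp"].death_age[agree])
        # and the vast majority of the cohort is identical across arms
        assert same_dx.mean() > 0.98

    def test_crn_variance_reduction(self, base_params):
        """Var of the paired cost delta is far below the independent-arms var."""
        paired, ai_costs, sp_costs = [], [], []
        for k in range(120):
            s = E.run_cohort(300, base_params, seed=(1000, k))
            paired.append(s.arms["ai"].mean_cost - s.arms["sp"].mean_cost)
            ai_costs.append(s.arms["ai"].mean_cost)
            sp_costs.append(s.arms["sp"].mean_cost)
        paired = np.array(paired)
        # independent pairing: offset the sp sequence by one run
        indep = np.array(ai_costs) - np.roll(np.array(sp_costs), 1)
        assert paired.var() < indep.var()

    def test_same_seed_reproduces_cohort_summary(self, base_params):
        a = E.run_cohort(500, base_params, seed=7)
        b = E.run_cohort(500, base_params, seed=7)
        assert dataclasses.asdict(a) == dataclasses.asdict(b)


class TestEventStructure:
    def test_death_dominates_all_events(self, base_params):
        _, natural, oc = E.run_cohort(5000, base_params, seed=13, return_outcomes=True)
        for o in oc.values():
            dx = o.diagnosed
            assert np.all(o.diagnosis_age[dx] <= o.death_age[dx])
            assert np.all(o.diagnosis_age[dx] < natural.nat_death_age[dx])
            # cause matches the minimum of natural and cancer death ages
            assert np.all(o.death_age[o.cause == 1] < natural.nat_death_age[o.cause == 1])
            assert np.array_equal(o.death_age[o.cause == 0], natural.nat_death_age[o.cause == 0])
            assert np.all(o.death_age > 0)
            # nobody undiagnosed dies of cancer
            assert not np.any((o.cause == 1) & ~dx)

    def test_diameter_monotone_along_every_trajectory(self, base_params):
        from mammosim.natural_history import tumour_diameter

        natural = E.draw_natural_history(base_params, 2000, np.random.default_rng(3))
        has = ~np.isnan(natural.onset_age)
        for t0, t1 in [(50.0, 53.0), (53.0, 56.0), (65.0, 68.0)]:
            m = has & (natural.onset_age <= t0)
            d0 = tumour_diameter(t0 - natural.onset_age[m], natural.growth_rate[m])
            d1 = tumour_diameter(t1 - natural.onset_age[m], natural.growth_rate[m])
            assert np.all(d1 >= d0)

    def test_standard_error_halves_when_n_quadruples(self, base_params):
        means_small, means_big = [], []
        for k in range(100):
            means_small.append(E.run_cohort(200, base_params, seed=(2000, k)).arms["sp"].mean_cost)
            means_big.append(E.run_cohort(800, base_params, seed=(3000, k)).arms["sp"].mean_cost)
        ratio = np.std(means_small) / np.std(means_big)
        assert 1.6 < ratio < 2.4  # i.i.d. scaling sqrt(800/200) = 2 within 20 %


class TestSingleTrace:
    def test_walkthrough_onset_at_47_perfect_readers(self):
        """A woman with carcinogenesis at 47 and perfect attendance/readers is
        screen-diagnosed at the age-50 invitation, staged from the diameter
        there."""
        rates = np.zeros(92)
        rates[47 - 19] = 1.0  # onset certainly in [47, 48)
        registry = P.default_registry(incidence=dg.AgeRateTable(np.arange(19, 111), rates))
        ps = P.apply_overrides(
            registry.base,
            {
                "screening.attendance": 1.0,
                "screening.sp_r1.sensitivity": 1.0,
                "screening.sp_r2.sensitivity": 1.0,
                "screening.ai_human.sensitivity": 1.0,
                "screening.ai_reader.sensitivity": 1.0,
                "natural_history.symptomatic_props": [0.0, 0.0, 0.0],
            },
        )
        rec = E.simulate_woman(3, ps)
        assert 47.0 <= rec.profile.carcinogenesis_age < 48.0
        for label in ("sp", "ai"):
            dx = rec.diagnosis[label]
            assert dx["diagnosed"] and dx["age"] == 50.0 and dx["route"] == "screen"
            first = rec.episodes[label][0]
            assert first["age"] == 50.0 and first["classification"] == "TP"
        # natural history identical across arms under CRN
        assert rec.diagnosis["sp"]["stage"] == rec.diagnosis["ai"]["stage"]
        assert rec.diagnosis["sp"]["death_age"] == rec.diagnosis["ai"]["death_age"]

    def test_single_woman_cohort_means_equal_her_totals(self, base_params):
        rec = E.simulate_woman(8, base_params)
        s = E.run_cohort(1, base_params, seed=8)
        if s.n_excluded == 0:
            assert s.arms["sp"].mean_qalys == pytest.approx(rec.qalys["sp"])
            assert s.arms["sp"].mean_cost == pytest.approx(rec.costs["sp"] + s.arms["sp"].ai_overhead)


class TestPSA:
    def test_bookkeeping_and_reproducibility(self, registry):
        a = E.run_psa(2, 300, registry, seed=17, psa=True)
        b = E.run_psa(2, 300, registry, seed=17, psa=True)
        assert len(a) == 2
        assert [r.provenance for r in a] == ["iter=0 psa-draw", "iter=1 psa-draw"]
        for ra, rb in zip(a, b):
            assert dataclasses.asdict(ra) == dataclasses.asdict(rb)

    def test_psa_off_uses_base_case_every_iteration(self, registry):
        res = E.run_psa(2, 300, registry, seed=17, psa=False)
        assert all("base-case" in r.provenance for r in res)

    def test_frame_layout(self, registry):
        res = E.run_psa(2, 200, registry, seed=1, psa=False)
        frame = E.psa_frame(res)
        assert set(frame.columns) >= {"iteration", "arm", "mean_cost", "mean_qalys", "mean_disc_reads"}
        assert len(frame) == 4
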