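"""The discrete-event driver.

Each woman is followed from age 19 to death under both strategy arms with
common random numbers: a single shared natural-history stream fixes her
breast density, natural death age, carcinogenesis age, tumour growth rate,
the uniforms behind every stage draw, the standardised survival draw,
attendance, and the symptomatic-presentation uniforms; each arm then has its
own independent reading stream.  Only reading outcomes (and everything
downstream of them: diagnosis age, stage, costs, QALYs) may differ between
arms.

Time advances on the triennial screening grid anchored at age 50, with
invitations at 50, 53, ..., 68 and symptomatic-presentation checks mid-way
through every 3-year cycle from age 19 until death — so cancers arising
before screening eligibility can present through the symptomatic service,
and cancers missed or arising after the last invitation can still surface.
Women whose cancer presents symptomatically before 50 are diagnosed and
treated outside the programme: the screened cohort conditions on reaching
age 50 undiagnosed, so these women are flagged in the shared natural
history (the check involves no reading and is identical across arms) and
excluded from the cohort denominator.  Costs and QALYs accrue from age 50
only.

The cohort simulation is vectorised across women; per-woman treatment-cost
and QALY streams reuse the scalar accounting in :mod:`mammosim.economics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import economics as econ
from . import natural_history as nh_mod
from .demographics import sample_event_ages
from .economics import ArmConfiguration, make_arms
from .natural_history import (
    ADVANCED,
    DCIS,
    NPI_III,
    classify_from_uniforms,
    sample_growth_rates,
    tumour_diameter,
)
from .params import ParameterSet, Registry, apply_overrides, sample_parameter_set
from .screening import episode_calls, invitation_ages

# stream identifiers for counter-based seeding: adding a new purpose never
# perturbs existing streams
_STREAM_PARAMS, _STREAM_NATURAL, _STREAM_READ_SP, _STREAM_READ_AI = 0, 1, 2, 3

CYCLE_FIRST, CYCLE_LAST = -10, 19  # midpoints 21.5 .. 108.5 on the 50-anchored grid
N_MIDPOINTS = CYCLE_LAST - CYCLE_FIRST + 1


def _stream(seed, key: int) -> np.random.Generator:
    entropy = seed if isinstance(seed, (tuple, list)) else (int(seed),)
    return np.random.default_rng(np.random.SeedSequence(tuple(entropy), spawn_key=(key,)))


@dataclass
class NaturalHistory:
    """Shared (arm-independent) per-woman draws for one cohort."""

    density: np.ndarray  # VDG group, 0-based
    nat_death_age: np.ndarray
    onset_age: np.ndarray  # nan if carcinogenesis never occurs
    growth_rate: np.ndarray
    u_dcis: np.ndarray
    u_npi: np.ndarray
    u_advanced: np.ndarray
    e_survival: np.ndarray  # standardised Exp(1) survival draw
    u_attend: np.ndarray  # (n, n_invitations)
    u_symptomatic: np.ndarray  # (n, N_MIDPOINTS)
    pre_screening_dx: np.ndarray = None  # presented symptomatically before 50

    @property
    def n(self) -> int:
        return len(self.density)


def _symptomatic_candidates(
    natural: "NaturalHistory", nh: nh_mod.NaturalHistoryParams, exclude: np.ndarray, t_mid: float
) -> np.ndarray:
    """Indices of women with an undetected invasive tumour alive at ``t_mid``."""
    mask = (
        ~exclude
        & (natural.nat_death_age > t_mid)
        & ~np.isnan(natural.onset_age)
        & (natural.onset_age <= t_mid)
        & (natural.u_dcis >= nh.p_dcis)  # provisional DCIS is asymptomatic
    )
    return np.flatnonzero(mask)


def _symptomatic_presenters(
    natural: "NaturalHistory", nh: nh_mod.NaturalHistoryParams, idx: np.ndarray, t_mid: float, col: int
) -> np.ndarray:
    """Subset of ``idx`` presenting symptomatically at this cycle midpoint."""
    if idx.size == 0:
        return idx
    diam = tumour_diameter(
        t_mid - natural.onset_age[idx], natural.growth_rate[idx], nh.vcell_mm, nh.vmax_mm
    )
    prov = classify_from_uniforms(
        diam, natural.u_dcis[idx], natural.u_npi[idx], natural.u_advanced[idx], nh
    )
    p_sym = np.asarray(nh.symptomatic_props, dtype=float)[np.minimum(prov, NPI_III) - 1]
    return idx[natural.u_symptomatic[idx, col] < p_sym]


def draw_natural_history(params: ParameterSet, n: int, rng: np.random.Generator) -> NaturalHistory:
    """All arm-independent randomness for a cohort of ``n`` women.

    Includes the pre-screening symptomatic pathway: an invasive tumour
    arising before 50 may present at any cycle midpoint from 21.5 to 48.5;
    such women enter care before the programme and are flagged for exclusion
    from the screened cohort.
    """
    nh = params.natural_history
    n_inv = len(invitation_ages(params.screening.policy))
    natural = NaturalHistory(
        density=nh_mod.assign_density(nh.density_props, rng, n),
        nat_death_age=sample_event_ages(params.mortality, 19.0, rng, n),
        onset_age=sample_event_ages(params.incidence, 19.0, rng, n),
        growth_rate=sample_growth_rates(nh, rng, n),
        u_dcis=rng.random(n),
        u_npi=rng.random(n),
        u_advanced=rng.random(n),
        e_survival=rng.exponential(size=n),
        u_attend=rng.random((n, n_inv)),
        u_symptomatic=rng.random((n, N_MIDPOINTS)),
    )
    excluded = np.zeros(n, dtype=bool)
    for cycle in range(CYCLE_FIRST, 0):
        t_mid = 50.0 + 3.0 * cycle + 1.5
        idx = _symptomatic_candidates(natural, nh, excluded, t_mid)
        excluded[_symptomatic_presenters(natural, nh, idx, t_mid, cycle - CYCLE_FIRST)] = True
    natural.pre_screening_dx = excluded
    return natural


@dataclass
class ArmOutcome:
    """Per-woman outcomes of one arm over one cohort."""

    label: str
    diagnosed: np.ndarray
    diagnosis_age: np.ndarray
    stage: np.ndarray  # -1 while undiagnosed
    route: np.ndarray  # 0 none, 1 screen-detected, 2 symptomatic
    death_age: np.ndarray
    cause: np.ndarray  # 0 natural, 1 cancer
    screen_cost: np.ndarray  # discounted screening-operation cost
    disc_reads: np.ndarray  # discounted count of attended studies
    treat_cost: np.ndarray = field(default=None)
    qalys: np.ndarray = field(default=None)
    n_episodes: int = 0
    n_recalls: int = 0
    n_false_positives: int = 0
    log: list = field(default_factory=list)

    @property
    def total_cost(self) -> np.ndarray:
        return self.screen_cost + self.treat_cost


def _survival_means_by_stage(
    stage: np.ndarray, age: np.ndarray, nh: nh_mod.NaturalHistoryParams
) -> np.ndarray:
    """Vectorised exponential survival means; inf for DCIS (background only)."""
    sm = nh.survival_means
    adv_mean = np.select(
        [age < 50.0, age <= 70.0], [sm["adv_lt50"], sm["adv_50_70"]], sm["adv_gt70"]
    )
    npi_means = np.array([sm["npi1"], sm["npi2"], sm["npi3"]])
    means = np.where(stage == ADVANCED, adv_mean, npi_means[np.clip(stage, 1, 3) - 1])
    return np.where(stage == DCIS, np.inf, means)


def simulate_arm(
    natural: NaturalHistory,
    params: ParameterSet,
    arm: ArmConfiguration,
    rng_read: np.random.Generator,
    collect_log: bool = False,
) -> ArmOutcome:
    """Run one arm over a cohort whose natural history is already drawn."""
    nh = params.natural_history
    sc = params.screening
    rate = params.economics.discount_rate
    costs = params.economics.costs
    n = natural.n

    out = ArmOutcome(
        label=arm.label,
        diagnosed=np.zeros(n, dtype=bool),
        diagnosis_age=np.full(n, np.nan),
        stage=np.full(n, -1, dtype=int),
        route=np.zeros(n, dtype=int),
        death_age=natural.nat_death_age.copy(),
        cause=np.zeros(n, dtype=int),
        screen_cost=np.zeros(n),
        disc_reads=np.zeros(n),
    )
    excluded = natural.pre_screening_dx
    has_onset = ~np.isnan(natural.onset_age)
    mult = np.asarray(nh.density_sens_mult, dtype=float)[natural.density]
    read_cost = econ.reading_cost_per_study(arm)
    inv_ages = invitation_ages(sc.policy)

    def diagnose(idx: np.ndarray, t: float, route: int) -> None:
        if idx.size == 0:
            return
        diam = tumour_diameter(t - natural.onset_age[idx], natural.growth_rate[idx], nh.vcell_mm, nh.vmax_mm)
        stage = classify_from_uniforms(
            diam, natural.u_dcis[idx], natural.u_npi[idx], natural.u_advanced[idx], nh
        )
        means = _survival_means_by_stage(stage, np.full(idx.size, t), nh)
        with np.errstate(invalid="ignore"):
            cancer_death = t + means * natural.e_survival[idx]
        nat_death = natural.nat_death_age[idx]
        dies_of_cancer = cancer_death < nat_death
        out.diagnosed[idx] = True
        out.diagnosis_age[idx] = t
        out.stage[idx] = stage
        out.route[idx] = route
        out.death_age[idx] = np.where(dies_of_cancer, cancer_death, nat_death)
        out.cause[idx] = np.where(dies_of_cancer, 1, 0)

    for cycle in range(0, CYCLE_LAST + 1):
        t_inv = 50.0 + 3.0 * cycle
        if cycle < len(inv_ages):
            # --- screening invitation -------------------------------------
            u1, u2, ua = rng_read.random((3, n))  # drawn unconditionally: stream stability
            active = (
                ~excluded
                & ~out.diagnosed
                & (natural.nat_death_age > t_inv)
                & (natural.u_attend[:, cycle] < sc.attendance)
            )
            present = active & has_onset & (natural.onset_age <= t_inv)
            calls = episode_calls(present, arm.r1, arm.r2, sc.arbitration, mult, u1, u2, ua)
            recall = calls["recall"] & active
            arb = calls["arbitrated"] & active
            tp = recall & present
            fp = recall & ~present
            v = (1.0 + rate) ** -(t_inv - econ.ACCRUAL_START)
            out.screen_cost += v * active * (
                costs.mammography
                + read_cost
                + arb * arm.human_read_cost
                + recall * costs.triple_assessment
                + tp * (costs.oncologist + costs.mri)
            )
            out.disc_reads += v * active
            out.n_episodes += int(active.sum())
            out.n_recalls += int(recall.sum())
            out.n_false_positives += int(fp.sum())
            diagnose(np.flatnonzero(tp), t_inv, route=1)
            if collect_log:
                for i in np.flatnonzero(active):
                    out.log.append(
                        {
                            "woman": int(i),
                            "age": t_inv,
                            "arm": arm.label,
                            "r1": bool(calls["pos1"][i]),
                            "r2": bool(calls["pos2"][i]),
                            "arbitrated": bool(arb[i]),
                            "final": "recall" if recall[i] else "normal",
                            "classification": "TP" if tp[i] else "FP" if fp[i] else "FN" if present[i] else "TN",
                        }
                    )
        # --- mid-cycle symptomatic presentation ---------------------------
        t_mid = t_inv + 1.5
        idx = _symptomatic_candidates(natural, nh, excluded | out.diagnosed, t_mid)
        presenting = _symptomatic_presenters(natural, nh, idx, t_mid, cycle - CYCLE_FIRST)
        if presenting.size:
            out.screen_cost[presenting] += econ.discount(
                econ.symptomatic_diagnosis_cost(costs), t_mid, rate
            )
            diagnose(presenting, t_mid, route=2)
            if collect_log:
                for i in presenting:
                    out.log.append(
                        {"woman": int(i), "age": t_mid, "arm": arm.label,
                         "final": "symptomatic", "classification": "TP"}
                    )

    # --- economics ------------------------------------------------------
    utils = params.economics.utilities
    out.treat_cost = np.zeros(n)
    out.qalys = np.asarray(
        econ.age_band_qaly(econ.ACCRUAL_START, out.death_age, utils, rate), dtype=float
    )
    for i in np.flatnonzero(out.diagnosed):
        cause = "cancer" if out.cause[i] == 1 else "natural"
        out.treat_cost[i] = econ.treatment_costs(
            int(out.stage[i]), float(out.diagnosis_age[i]), float(out.death_age[i]), cause, costs, rate
        )
        out.qalys[i] = econ.qaly_stream_components(
            float(out.death_age[i]), int(out.stage[i]), float(out.diagnosis_age[i]), cause, utils, rate
        )
    return out


@dataclass
class ArmSummary:
    mean_cost: float
    mean_qalys: float
    mean_disc_reads: float
    n_diagnosed: int
    n_recalls: int
    n_false_positives: int
    ai_overhead: float = 0.0


@dataclass
class CohortSummary:
    """Per-arm mean discounted costs and QALYs for one cohort run."""

    n: int
    seed: object
    provenance: str
    arms: dict[str, ArmSummary]
    n_excluded: int = 0  # pre-screening symptomatic diagnoses, outside the cohort

    def delta(self, intervention: str = "ai", comparator: str = "sp") -> tuple[float, float]:
        """(incremental cost, incremental QALYs), intervention minus comparator."""
        a, b = self.arms[intervention], self.arms[comparator]
        return a.mean_cost - b.mean_cost, a.mean_qalys - b.mean_qalys


def summarise_arm(outcome: ArmOutcome, arm: ArmConfiguration, included: np.ndarray) -> ArmSummary:
    """Cohort means over the screened cohort (pre-screening diagnoses excluded)."""
    overhead = (
        econ.ai_overhead_per_patient(
            arm.ai_setup, arm.ai_maintenance, arm.service_years, arm.reference_cohort
        )
        if arm.uses_ai
        else 0.0
    )
    return ArmSummary(
        mean_cost=float(outcome.total_cost[included].mean()) + overhead,
        mean_qalys=float(outcome.qalys[included].mean()),
        mean_disc_reads=float(outcome.disc_reads[included].mean()),
        n_diagnosed=int(outcome.diagnosed[included].sum()),
        n_recalls=outcome.n_recalls,
        n_false_positives=outcome.n_false_positives,
        ai_overhead=overhead,
    )


def run_cohort(
    n: int,
    params: ParameterSet,
    arms: dict[str, ArmConfiguration] | None = None,
    seed: int | tuple = 0,
    share_reading_stream: bool = False,
    collect_log: bool = False,
    return_outcomes: bool = False,
):
    """Simulate ``n`` women under both arms with common random numbers.

    ``share_reading_stream=True`` seeds both arms' reading streams
    identically (useful to verify that identical readers give bit-identical
    outcomes); the default gives each arm an independent stream.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    arms = arms or make_arms(params.screening, params.economics)
    natural = draw_natural_history(params, n, _stream(seed, _STREAM_NATURAL))
    outcomes = {}
    for label, arm in arms.items():
        key = _STREAM_READ_SP if (share_reading_stream or label == "sp") else _STREAM_READ_AI
        outcomes[label] = simulate_arm(natural, params, arm, _stream(seed, key), collect_log)
    included = ~natural.pre_screening_dx
    if not included.any():
        raise ValueError("entire cohort was diagnosed before screening age; nothing to summarise")
    summary = CohortSummary(
        n=n,
        seed=seed,
        provenance=params.provenance,
        arms={label: summarise_arm(outcomes[label], arms[label], included) for label in arms},
        n_excluded=int(natural.pre_screening_dx.sum()),
    )
    if return_outcomes:
        return summary, natural, outcomes
    return summary


@dataclass
class WomanRecord:
    """Full trajectory of one woman under both arms (common random numbers)."""

    profile: nh_mod.WomanProfile
    episodes: dict[str, list]
    diagnosis: dict[str, dict]
    costs: dict[str, float]
    qalys: dict[str, float]


def simulate_woman(
    woman_seed: int, params: ParameterSet, arms: dict[str, ArmConfiguration] | None = None
) -> WomanRecord:
    """Single-trace run of one woman (a size-1 cohort) for inspection."""
    summary, natural, outcomes = run_cohort(
        1, params, arms, seed=woman_seed, collect_log=True, return_outcomes=True
    )
    any_arm = next(iter(outcomes.values()))
    profile = nh_mod.WomanProfile(
        id=woman_seed,
        density=int(natural.density[0]),
        death_age_natural=float(natural.nat_death_age[0]),
        carcinogenesis_age=(None if np.isnan(natural.onset_age[0]) else float(natural.onset_age[0])),
    )
    diagnosis = {}
    for label, oc in outcomes.items():
        diagnosis[label] = {
            "diagnosed": bool(oc.diagnosed[0]),
            "age": float(oc.diagnosis_age[0]) if oc.diagnosed[0] else None,
            "stage": nh_mod.STAGE_NAMES.get(int(oc.stage[0])),
            "route": {0: None, 1: "screen", 2: "symptomatic"}[int(oc.route[0])],
            "death_age": float(oc.death_age[0]),
            "cause": "cancer" if oc.cause[0] == 1 else "natural",
        }
    return WomanRecord(
        profile=profile,
        episodes={label: oc.log for label, oc in outcomes.items()},
        diagnosis=diagnosis,
        costs={label: float(oc.total_cost[0]) for label, oc in outcomes.items()},
        qalys={label: float(oc.qalys[0]) for label, oc in outcomes.items()},
    )


def run_psa(
    iterations: int,
    n: int,
    registry: Registry,
    seed: int = 0,
    psa: bool = True,
    overrides: dict | None = None,
) -> list[CohortSummary]:
    """PSA over ``iterations`` parameter draws, each driving one cohort.

    Iteration ``k`` samples ParameterSet ``k`` from the registry (or the base
    case if ``psa`` is off) and runs an ``n``-woman cohort with an
    iteration-specific seed; results are reproducible from
    ``(seed, iterations, n)`` and order-independent across iterations.
    Dotted-key ``overrides`` (scenario settings) are applied to every
    sampled ParameterSet.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    results = []
    for k in range(iterations):
        rng_params = _stream((seed, k), _STREAM_PARAMS)
        ps = sample_parameter_set(registry, rng_params, psa=psa)
        if overrides:
            ps = apply_overrides(ps, overrides)
        summary = run_cohort(n, ps, seed=(seed, k))
        summary.provenance = f"iter={k} {ps.provenance}"
        results.append(summary)
    return results


def psa_frame(results: list[CohortSummary]):
    """Long-format DataFrame (iteration, arm, mean_cost, mean_qalys, ...)."""
    import pandas as pd

    rows = []
    for k, res in enumerate(results):
        for label, s in res.arms.items():
            rows.append(
                {
                    "iteration": k,
                    "arm": label,
                    "mean_cost": s.mean_cost,
                    "mean_qalys": s.mean_qalys,
                    "mean_disc_reads": s.mean_disc_reads,
                    "n_diagnosed": s.n_diagnosed,
                }
            )
    return pd.DataFrame(rows)
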