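"""Discounted cost and QALY accrual.

Costs and QALYs accrue only from age 50 (programme eligibility); everything
is discounted to age 50 at a common annual rate (NICE reference case 3.5 %).
Point cash flows use the discrete factor ``(1+r)^-(t-50)``; utility streams
are integrated continuously, i.e. a constant utility u over [t0, t1) is worth
``u * ((1+r)^-(t0-50) - (1+r)^-(t1-50)) / ln(1+r)`` QALYs.

The screening-operation cost of an arm is split into arm-independent image
acquisition (mammography, cancels in increments) and the reading labour that
drives the comparison: two human reads under standard practice versus one
human read plus the AI per-study price in the intervention arm, each human
read optionally outsourced to a locum at a premium rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .natural_history import ADVANCED, DCIS, NPI_I, WomanProfile
from .screening import ReaderProfile

ACCRUAL_START = 50.0
PALLIATIVE_REFERENCE_DAYS = 372.0  # the palliative figure averages 372 survival days
HALF_YEAR_DAYS = 182.625


@dataclass
class CostSchedule:
    """Unit costs in 2020 GBP."""

    mammography: float = 184.0  # both breasts, image acquisition
    biopsy: float = 452.0
    recall_mammography: float = 46.0
    ultrasound: float = 52.0
    triple_assessment: float = 314.0  # overall second-stage assessment cost
    oncologist: float = 52.90
    mri: float = 148.40
    dcis: float = 8968.0
    npi_first_year: np.ndarray = field(default_factory=lambda: np.array([10471.0, 15484.0, 21951.0]))
    npi_later_years: np.ndarray = field(default_factory=lambda: np.array([2819.0, 2819.0, 3815.0]))
    advanced_6m: float = 14984.0
    advanced_12m: float = 21951.0
    palliative: float = 14827.0  # average over 372 survival days; used pro rata

    def palliative_final_6m(self) -> float:
        return self.palliative * HALF_YEAR_DAYS / PALLIATIVE_REFERENCE_DAYS


@dataclass
class UtilitySchedule:
    """Health-state utilities (EQ-5D scale)."""

    age_band_edges: np.ndarray = field(default_factory=lambda: np.array([50.0, 55.0, 65.0, 75.0]))
    age_band_utils: np.ndarray = field(default_factory=lambda: np.array([0.846, 0.804, 0.760, 0.692]))
    npi_at_12m: np.ndarray = field(default_factory=lambda: np.array([0.704, 0.775, 0.727]))
    npi_from_12m: np.ndarray = field(default_factory=lambda: np.array([0.779, 0.794, 0.759]))
    advanced: float = 0.74
    palliative: float = 0.51


@dataclass
class ArmConfiguration:
    """Reader profiles and unit costs defining one strategy arm."""

    label: str
    r1: ReaderProfile
    r2: ReaderProfile
    arbitration: ReaderProfile
    uses_ai: bool
    human_read_cost: float = 5.90
    ai_price: float = 4.72
    ai_setup: float = 35000.0
    ai_maintenance: float = 0.0
    service_years: float = 21.0
    reference_cohort: int = 100_000
    locum_fraction: float = 0.0
    locum_read_cost: float = 10.30

    def __post_init__(self) -> None:
        for name in ("human_read_cost", "ai_price", "ai_setup", "ai_maintenance", "locum_read_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.locum_fraction <= 1.0:
            raise ValueError("locum_fraction must lie in [0, 1]")


def locum_rates_from_census(
    total_locum_spend: float = 88e6,
    breast_share: float = 0.20,
    studies: float = 2e6,
    base_read_cost: float = 5.90,
) -> dict[str, float]:
    """Locum premium derived from the radiology workforce-census figures.

    The census total locum spend times the breast-service share, spread over
    the double-read studies, gives a per-study premium; halving it gives the
    per-reader premium, which is added to the in-house cost per read.
    """
    per_study = total_locum_spend * breast_share / studies
    per_reader = per_study / 2.0
    return {
        "premium_per_study": per_study,
        "premium_per_reader": per_reader,
        "locum_cost_per_read": base_read_cost + per_reader,
    }


def discount(amount, event_age, rate: float):
    """Present value at age 50 of a point amount occurring at ``event_age``."""
    event_age = np.asarray(event_age, dtype=float)
    if np.any(event_age < ACCRUAL_START):
        raise ValueError("no accrual before age 50")
    out = np.asarray(amount, dtype=float) * (1.0 + rate) ** -(event_age - ACCRUAL_START)
    return out if out.ndim else float(out)


def annuity(t0, t1, rate: float):
    """Discounted duration of the interval [t0, t1) (both >= 50), in years."""
    t0 = np.maximum(np.asarray(t0, dtype=float), ACCRUAL_START)
    t1 = np.maximum(np.asarray(t1, dtype=float), t0)
    if rate == 0.0:
        out = t1 - t0
    else:
        lr = np.log1p(rate)
        v0 = (1.0 + rate) ** -(t0 - ACCRUAL_START)
        v1 = (1.0 + rate) ** -(t1 - ACCRUAL_START)
        out = (v0 - v1) / lr
    out = np.asarray(out)
    return out if out.ndim else float(out)


def reading_cost_per_study(arm: ArmConfiguration) -> float:
    """Reading labour cost of one double-read study under the arm.

    Each human read costs the in-house rate, with ``locum_fraction`` of reads
    outsourced at the locum rate; the AI arm replaces the second human read
    with the AI per-study price (never outsourced).
    """
    human = (
        arm.human_read_cost * (1.0 - arm.locum_fraction)
        + arm.locum_read_cost * arm.locum_fraction
    )
    return human + arm.ai_price if arm.uses_ai else 2.0 * human


def episode_cost(outcome, arm: ArmConfiguration, costs: CostSchedule) -> float:
    """Undiscounted cost of one screening episode (0 if not attended).

    Image acquisition + reading labour + one human arbitration read when the
    first reads disagree + triple assessment on recall + the oncology workup
    (consultant + staging MRI) when the recall confirms a cancer.
    """
    if not outcome.attended:
        return 0.0
    total = costs.mammography + reading_cost_per_study(arm)
    if outcome.arbitrated:
        total += arm.human_read_cost
    if outcome.final_call == "recall":
        total += costs.triple_assessment
        if outcome.recall_result == "TP":
            total += costs.oncologist + costs.mri
    return total


def symptomatic_diagnosis_cost(costs: CostSchedule) -> float:
    """Workup cost when a cancer presents via the symptomatic service."""
    return costs.triple_assessment + costs.oncologist + costs.mri


def ai_overhead_per_patient(
    setup: float, maintenance: float, service_years: float, cohort_n: int
) -> float:
    """One-off set-up plus maintenance stream spread over the service cohort."""
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    return (setup + maintenance * service_years) / cohort_n


def _npi_annual_flows(
    stage: int, diagnosis_age: float, stop_age: float, costs: CostSchedule
) -> list[tuple[float, float]]:
    """(age, amount) anniversaries of the NPI treatment schedule before stop_age.

    First-year cost at diagnosis, then the years-2-to-9 annual cost at each
    anniversary while the woman is alive (and before any final-year
    replacement at ``stop_age``).
    """
    flows = []
    if diagnosis_age < stop_age:
        flows.append((diagnosis_age, float(costs.npi_first_year[stage - 1])))
    for year in range(1, 9):
        t = diagnosis_age + year
        if t < stop_age:
            flows.append((t, float(costs.npi_later_years[stage - 1])))
    return flows


def treatment_costs(
    stage: int,
    diagnosis_age: float,
    death_age: float,
    cause: str,
    costs: CostSchedule,
    rate: float,
) -> float:
    """Discounted treatment cost stream for one diagnosed cancer.

    DCIS is a one-off treatment cost.  NPI cancers pay the first-year cost at
    diagnosis and the years-2-9 annual cost at each anniversary survived; a
    death from cancer replaces the final year of life with advanced-cancer
    costing (six months at the advanced 6-month cost) plus pro-rata monthly
    palliative care over the last six months.  Advanced-at-diagnosis cancers
    accrue advanced costing from diagnosis.  Cash flows before age 50 are
    outside the accrual window and are dropped.
    """
    if death_age < diagnosis_age:
        raise ValueError("death_age must not precede diagnosis_age")

    def disc(age: float, amount: float) -> float:
        return discount(amount, age, rate) if age >= ACCRUAL_START and amount else 0.0

    if stage == DCIS:
        return disc(diagnosis_age, costs.dcis)

    flows: list[tuple[float, float]] = []
    if cause == "cancer":
        final_start = max(death_age - 1.0, diagnosis_age)
        pall_start = max(death_age - 0.5, diagnosis_age)
        if stage == ADVANCED:
            # advanced costing from diagnosis up to the final year
            t = diagnosis_age
            while t < final_start:
                flows.append((t, costs.advanced_12m * min(1.0, final_start - t)))
                t += 1.0
        else:
            flows.extend(_npi_annual_flows(stage, diagnosis_age, final_start, costs))
        # final year of life: advanced care then palliative care
        adv_dur = max(pall_start - final_start, 0.0)
        if adv_dur > 0:
            flows.append((final_start, costs.advanced_6m * adv_dur / 0.5))
        pall_dur = max(death_age - pall_start, 0.0)
        if pall_dur > 0:
            flows.append((pall_start, costs.palliative_final_6m() * pall_dur / 0.5))
    else:  # survived the cancer (or died of natural causes during treatment)
        if stage == ADVANCED:
            t = diagnosis_age
            while t < death_age:
                flows.append((t, costs.advanced_12m * min(1.0, death_age - t)))
                t += 1.0
        else:
            flows.extend(_npi_annual_flows(stage, diagnosis_age, min(death_age, diagnosis_age + 9.0), costs))
    return float(sum(disc(t, a) for t, a in flows))


def age_band_qaly(t0, t1, utils: UtilitySchedule, rate: float):
    """Discounted QALYs of the age-band utility over [t0, t1) (vectorised).

    Ages below 50 contribute nothing; the last band is open-ended.
    """
    t0 = np.maximum(np.asarray(t0, dtype=float), ACCRUAL_START)
    t1 = np.maximum(np.asarray(t1, dtype=float), ACCRUAL_START)
    edges = np.append(utils.age_band_edges, np.inf)
    total = np.zeros(np.broadcast(t0, t1).shape)
    for lo, hi, u in zip(edges[:-1], edges[1:], utils.age_band_utils):
        a = np.clip(t0, lo, hi)
        b = np.clip(t1, lo, hi)
        total = total + u * annuity(a, np.maximum(b, a), rate)
    return total if total.ndim else float(total)


def _cancer_overrides(
    stage: int, diagnosis_age: float, death_age: float, cause: str, utils: UtilitySchedule
) -> list[tuple[float, float, float]]:
    """(t0, t1, utility) segments that replace the age-band utility."""
    d, D = diagnosis_age, death_age
    segs: list[tuple[float, float, float]] = []
    if stage == DCIS:
        # treated for six months at the mildest cancer-state utility, then healed
        segs.append((d, min(d + 0.5, D), utils.npi_at_12m[NPI_I - 1]))
        return segs
    if cause == "cancer":
        final_start = max(D - 1.0, d)
        pall_start = max(D - 0.5, d)
        if stage == ADVANCED:
            segs.append((d, pall_start, utils.advanced))
        else:
            segs.append((d, min(d + 1.0, final_start), utils.npi_at_12m[stage - 1]))
            segs.append((min(d + 1.0, final_start), min(d + 9.0, final_start), utils.npi_from_12m[stage - 1]))
            segs.append((final_start, pall_start, utils.advanced))
        segs.append((pall_start, D, utils.palliative))
    else:
        if stage == ADVANCED:
            segs.append((d, D, utils.advanced))
        else:
            segs.append((d, min(d + 1.0, D), utils.npi_at_12m[stage - 1]))
            segs.append((min(d + 1.0, D), min(d + 9.0, D), utils.npi_from_12m[stage - 1]))
    return [(a, b, u) for a, b, u in segs if b > a]


def qaly_stream_components(
    death_age: float,
    stage: int | None,
    diagnosis_age: float | None,
    cause: str,
    utils: UtilitySchedule,
    rate: float,
) -> float:
    """Discounted lifetime QALYs from age 50 for one woman.

    Age-band utility while cancer-free or cured; stage-specific utilities from
    diagnosis (first year at the "at 12 months" value, then the "from 12
    months onwards" value to year 9); cancer deaths spend their final year at
    the advanced-cancer utility with palliative utility over the last six
    months.
    """
    base = age_band_qaly(ACCRUAL_START, death_age, utils, rate)
    if stage is None or diagnosis_age is None:
        return float(base)
    total = float(base)
    for t0, t1, u in _cancer_overrides(stage, diagnosis_age, death_age, cause, utils):
        t0c, t1c = max(t0, ACCRUAL_START), max(t1, ACCRUAL_START)
        if t1c > t0c:
            total += u * float(annuity(t0c, t1c, rate)) - float(age_band_qaly(t0c, t1c, utils, rate))
    return total


def qaly_stream(profile: WomanProfile, utils: UtilitySchedule, rate: float) -> float:
    """Discounted QALYs for a woman's full trajectory (wrapper over components)."""
    if profile.death_age is None:
        raise ValueError("death age must be set")
    tumour = profile.tumour
    if tumour is None or tumour.stage_at_classification is None:
        return qaly_stream_components(profile.death_age, None, None, "natural", utils, rate)
    return qaly_stream_components(
        profile.death_age,
        tumour.stage_at_classification,
        tumour.classification_age,
        profile.cause_of_death,
        utils,
        rate,
    )


@dataclass
class EconomicsParams:
    """Economics block of a parameter set."""

    costs: CostSchedule = field(default_factory=CostSchedule)
    utilities: UtilitySchedule = field(default_factory=UtilitySchedule)
    discount_rate: float = 0.035
    wtp: float = 20000.0  # willingness-to-pay threshold, GBP per QALY
    human_read_cost: float = 5.90
    human_read_cost_alternate: float = 5.88  # 27 scans/hour of the hourly rate
    ai_price: float = 4.72
    ai_setup: float = 35000.0
    ai_maintenance: float = 0.0
    service_years: float = 21.0
    reference_cohort: int = 100_000
    locum_fraction: float = 0.0
    locum_read_cost: float = 10.30


def make_arms(screening_params, econ: EconomicsParams) -> dict[str, ArmConfiguration]:
    """Build the two comparator arms from a parameter set's blocks."""
    common = dict(
        human_read_cost=econ.human_read_cost,
        ai_price=econ.ai_price,
        ai_setup=econ.ai_setup,
        ai_maintenance=econ.ai_maintenance,
        service_years=econ.service_years,
        reference_cohort=econ.reference_cohort,
        locum_fraction=econ.locum_fraction,
        locum_read_cost=econ.locum_read_cost,
    )
    sp = ArmConfiguration(
        label="sp",
        r1=screening_params.sp_r1,
        r2=screening_params.sp_r2,
        arbitration=screening_params.arbitration,
        uses_ai=False,
        **common,
    )
    ai = ArmConfiguration(
        label="ai",
        r1=screening_params.ai_human,
        r2=screening_params.ai_reader,
        arbitration=screening_params.arbitration,
        uses_ai=True,
        **common,
    )
    return {"sp": sp, "ai": ai}


def with_ai_price(arm: ArmConfiguration, price: float) -> ArmConfiguration:
    return replace(arm, ai_price=price)
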