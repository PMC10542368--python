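"""Model parameters, their uncertainty distributions, and PSA sampling.

Every tabulated parameter carries a :class:`DistributionSpec`.  The base case
uses the means; a probabilistic sensitivity analysis (PSA) draw samples each
non-fixed parameter from its distribution — Beta from mean and standard
error, lognormal from mean and 95 % CI, Dirichlet blocks jointly — while
reader sensitivities/specificities and all fixed rows stay at their means.

Conventions (standard in health-economic modelling):

* Beta shapes by method of moments from (mean, SE);
* lognormal sigma from the 95 % CI width on the log scale,
  ``sigma = (ln hi - ln lo) / (2 * 1.96)``, with the location chosen so the
  distribution mean matches the tabulated mean;
* Dirichlet concentrations ``proportions * n_eff`` with a configurable
  effective sample size (default 100), since only proportions are published.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import demographics as dg
from . import natural_history as nh_mod
from .economics import CostSchedule, EconomicsParams, UtilitySchedule
from .natural_history import NaturalHistoryParams, SizeBandTable
from .screening import ReaderProfile, ScreeningPolicy

logger = logging.getLogger(__name__)

Z95 = 1.96  # conventional 95 % normal quantile used in published CI conversions

_warned_ci: set[tuple[float, float, float]] = set()


@dataclass(frozen=True)
class DistributionSpec:
    """One parameter's sampling law.

    kind:
        ``fixed`` (never varied), ``beta`` (mean + SE), ``lognormal``
        (mean + 95 % CI), ``dirichlet`` (category proportions + n_eff), or
        ``exponential-mean`` (a per-woman survival-time law, not PSA-varied).
    """

    kind: str
    mean: float | np.ndarray
    se: float | None = None
    ci: tuple[float, float] | None = None
    n_eff: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"fixed", "beta", "lognormal", "dirichlet", "exponential-mean"}:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "beta":
            if not 0.0 < self.mean < 1.0 or self.se is None or self.se <= 0:
                raise ValueError("beta requires 0 < mean < 1 and se > 0")
        if self.kind == "lognormal":
            if self.ci is None or self.ci[0] >= self.ci[1]:
                raise ValueError("lognormal requires lo < hi")
        if self.kind == "dirichlet":
            p = np.asarray(self.mean, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("dirichlet proportions must sum to 1 within 1e-9")

    def sample(self, rng: np.random.Generator):
        if self.kind in ("fixed", "exponential-mean"):
            return self.mean
        if self.kind == "beta":
            a, b = beta_from_moments(self.mean, self.se)
            return float(rng.beta(a, b))
        if self.kind == "lognormal":
            mu, sigma = lognormal_from_ci(self.mean, *self.ci)
            return float(rng.lognormal(mu, sigma))
        # dirichlet: joint draw, renormalised defensively against rounding
        conc = np.asarray(self.mean, dtype=float) * (self.n_eff or 100.0)
        draw = rng.dirichlet(conc)
        return draw / draw.sum()


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape pair reproducing the given mean and variance ``se**2``."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    var = se * se
    if var <= 0 or var >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible beta variance: se^2={var:.6g} must lie in (0, mean(1-mean)={mean * (1 - mean):.6g})"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def lognormal_from_ci(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) with sigma from the 95 % CI width on the log scale
    and mu chosen so the distribution mean equals ``mean``."""
    if not 0.0 < lo < hi:
        raise ValueError(f"require 0 < lo < hi, got ({lo}, {hi})")
    if not lo < mean < hi and (mean, lo, hi) not in _warned_ci:
        _warned_ci.add((mean, lo, hi))
        logger.warning("lognormal mean %s outside its CI (%s, %s); proceeding with printed values", mean, lo, hi)
    sigma = (np.log(hi) - np.log(lo)) / (2.0 * Z95)
    mu = np.log(mean) - sigma * sigma / 2.0
    return float(mu), float(sigma)


@dataclass
class ScreeningParams:
    """Reader operating points and programme policy."""

    sp_r1: ReaderProfile = field(default_factory=lambda: ReaderProfile(0.760, 0.970, "human-R1"))
    sp_r2: ReaderProfile = field(default_factory=lambda: ReaderProfile(0.760, 0.970, "human-R2"))
    ai_human: ReaderProfile = field(default_factory=lambda: ReaderProfile(0.761, 0.970, "human-R1"))
    ai_reader: ReaderProfile = field(default_factory=lambda: ReaderProfile(0.751, 0.973, "AI"))
    arbitration: ReaderProfile = field(default_factory=lambda: ReaderProfile(1.0, 0.95, "arbitration"))
    recall: ReaderProfile = field(default_factory=lambda: ReaderProfile(1.0, 1.0, "biopsy"))
    policy: ScreeningPolicy = field(default_factory=ScreeningPolicy)
    attendance: float = 0.60

    def __post_init__(self) -> None:
        if not 0.0 <= self.attendance <= 1.0:
            raise ValueError("attendance must lie in [0, 1]")


@dataclass
class ParameterSet:
    """One concrete realisation of every model parameter."""

    natural_history: NaturalHistoryParams = field(default_factory=NaturalHistoryParams)
    screening: ScreeningParams = field(default_factory=ScreeningParams)
    economics: EconomicsParams = field(default_factory=EconomicsParams)
    incidence: dg.AgeRateTable = field(default_factory=dg.build_incidence_table)
    mortality: dg.AgeRateTable = field(default_factory=dg.build_mortality_table)
    provenance: str = "base-case"

    def validate(self) -> None:
        nh = self.natural_history
        for name, vec in [
            ("density_props", nh.density_props),
            ("symptomatic_props", nh.symptomatic_props),
        ]:
            if np.any(np.asarray(vec) < 0) or np.any(np.asarray(vec) > 1):
                raise ValueError(f"{name} outside [0, 1]")
        if not 0.0 <= nh.p_dcis <= 1.0:
            raise ValueError("p_dcis outside [0, 1]")
        ut = self.economics.utilities
        for name, vec in [
            ("age_band_utils", ut.age_band_utils),
            ("npi_at_12m", ut.npi_at_12m),
            ("npi_from_12m", ut.npi_from_12m),
            ("advanced/palliative", np.array([ut.advanced, ut.palliative])),
        ]:
            if np.any(np.asarray(vec) < 0) or np.any(np.asarray(vec) > 1):
                raise ValueError(f"utility {name} outside [0, 1]")
        co = self.economics.costs
        cost_vals = np.concatenate(
            [
                np.asarray(co.npi_first_year, dtype=float),
                np.asarray(co.npi_later_years, dtype=float),
                np.array(
                    [co.mammography, co.biopsy, co.recall_mammography, co.ultrasound,
                     co.triple_assessment, co.oncologist, co.mri, co.dcis,
                     co.advanced_6m, co.advanced_12m, co.palliative]
                ),
            ]
        )
        if np.any(cost_vals < 0):
            raise ValueError("costs must be nonnegative")
        if self.screening.policy.interval <= 0:
            raise ValueError("screening interval must be positive")


class Registry:
    """All DistributionSpecs plus the fixed scaffolding needed to assemble a
    :class:`ParameterSet` (rate tables, reader profiles, unit costs)."""

    def __init__(self, base: ParameterSet, specs: dict[str, DistributionSpec]):
        self.base = base
        self.specs = specs

    def spec(self, name: str) -> DistributionSpec:
        try:
            return self.specs[name]
        except KeyError:
            raise KeyError(f"no distribution spec for parameter {name!r}") from None


def default_registry(
    incidence: dg.AgeRateTable | None = None,
    mortality: dg.AgeRateTable | None = None,
    npi_by_size: SizeBandTable | None = None,
    advanced_by_size: SizeBandTable | None = None,
    n_eff: float = 100.0,
    **overrides,
) -> Registry:
    """The bundled default registry reproducing the published parameter tables.

    ``n_eff`` scales every Dirichlet/Beta block built from bare proportions.
    Keyword overrides replace fields of the base ParameterSet blocks by dotted
    name (see :func:`apply_overrides`).
    """
    base = ParameterSet(
        natural_history=NaturalHistoryParams(
            npi_by_size=npi_by_size or nh_mod.default_npi_by_size(),
            advanced_by_size=advanced_by_size or nh_mod.default_advanced_by_size(),
        ),
        incidence=incidence or dg.build_incidence_table(),
        mortality=mortality or dg.build_mortality_table(),
    )
    nh = base.natural_history
    ut = base.economics.utilities
    co = base.economics.costs
    specs: dict[str, DistributionSpec] = {
        "p_dcis": DistributionSpec("beta", nh.p_dcis, se=0.03),
        "density_props": DistributionSpec("dirichlet", nh.density_props, n_eff=n_eff),
        "growth_rate": DistributionSpec("exponential-mean", nh.growth_rate_mean),
        "utility_advanced": DistributionSpec("beta", ut.advanced, se=0.26),
        "utility_palliative": DistributionSpec("beta", ut.palliative, se=0.29),
        "cost_dcis": DistributionSpec("lognormal", co.dcis, ci=(9692.0, 10471.0)),
        "cost_advanced_6m": DistributionSpec("lognormal", co.advanced_6m, ci=(13161.0, 16839.0)),
        "cost_advanced_12m": DistributionSpec("lognormal", co.advanced_12m, ci=(19044.0, 24882.0)),
        "cost_palliative": DistributionSpec("lognormal", co.palliative, ci=(1472.0, 45326.0)),
    }
    for i, (p, se) in enumerate(
        zip(ut.age_band_utils, [0.007, 0.008, 0.009, 0.01])
    ):
        specs[f"utility_age_band_{i}"] = DistributionSpec("beta", float(p), se=se)
    for i, (at12, from12) in enumerate(zip([0.034, 0.022, 0.027], [0.034, 0.023, 0.035])):
        specs[f"utility_npi{i + 1}_at_12m"] = DistributionSpec("beta", float(ut.npi_at_12m[i]), se=at12)
        specs[f"utility_npi{i + 1}_from_12m"] = DistributionSpec("beta", float(ut.npi_from_12m[i]), se=from12)
    for i, ci in enumerate([(8665.0, 12615.0), (13548.0, 17614.0), (19044.0, 24882.0)]):
        specs[f"cost_npi{i + 1}_first_year"] = DistributionSpec(
            "lognormal", float(co.npi_first_year[i]), ci=ci
        )
    # symptomatic proportions: two-category Dirichlet (symptomatic vs screen)
    for i, p in enumerate(nh.symptomatic_props):
        specs[f"symptomatic_npi{i + 1}"] = DistributionSpec(
            "dirichlet", np.array([float(p), 1.0 - float(p)]), n_eff=n_eff
        )
    for i, row in enumerate(np.atleast_2d(nh.npi_by_size.values)):
        specs[f"npi_by_size_row_{i}"] = DistributionSpec("dirichlet", row.copy(), n_eff=n_eff)
    for i, p in enumerate(np.asarray(nh.advanced_by_size.values)):
        specs[f"advanced_by_size_row_{i}"] = DistributionSpec(
            "dirichlet", np.array([float(p), 1.0 - float(p)]), n_eff=n_eff
        )
    if overrides:
        base = apply_overrides(base, overrides)
    return Registry(base, specs)


def sample_parameter_set(
    registry: Registry, rng: np.random.Generator, psa: bool = True
) -> ParameterSet:
    """Base-case (psa=False) or PSA-sampled (psa=True) ParameterSet.

    Reader sensitivities/specificities and every fixed row stay at their
    means in the PSA; Dirichlet blocks are sampled jointly and renormalised.
    """
    base = registry.base
    if not psa:
        out = _copy_parameter_set(base)
        out.provenance = "base-case"
        out.validate()
        return out

    def draw(name: str):
        return registry.spec(name).sample(rng)

    nh0 = base.natural_history
    nh = replace(
        nh0,
        p_dcis=draw("p_dcis"),
        density_props=np.asarray(draw("density_props")),
        symptomatic_props=np.array([draw(f"symptomatic_npi{i + 1}")[0] for i in range(3)]),
        npi_by_size=SizeBandTable(
            nh0.npi_by_size.edges.copy(),
            np.vstack(
                [draw(f"npi_by_size_row_{i}") for i in range(len(nh0.npi_by_size.values))]
            ),
        ),
        advanced_by_size=SizeBandTable(
            nh0.advanced_by_size.edges.copy(),
            np.array(
                [draw(f"advanced_by_size_row_{i}")[0] for i in range(len(nh0.advanced_by_size.values))]
            ),
        ),
        survival_means=dict(nh0.survival_means),
    )
    ut0 = base.economics.utilities
    utilities = UtilitySchedule(
        age_band_edges=ut0.age_band_edges.copy(),
        age_band_utils=np.array([draw(f"utility_age_band_{i}") for i in range(4)]),
        npi_at_12m=np.array([draw(f"utility_npi{i + 1}_at_12m") for i in range(3)]),
        npi_from_12m=np.array([draw(f"utility_npi{i + 1}_from_12m") for i in range(3)]),
        advanced=draw("utility_advanced"),
        palliative=draw("utility_palliative"),
    )
    co0 = base.economics.costs
    costs = replace(
        co0,
        npi_first_year=np.array([draw(f"cost_npi{i + 1}_first_year") for i in range(3)]),
        npi_later_years=np.asarray(co0.npi_later_years).copy(),
        dcis=draw("cost_dcis"),
        advanced_6m=draw("cost_advanced_6m"),
        advanced_12m=draw("cost_advanced_12m"),
        palliative=draw("cost_palliative"),
    )
    out = ParameterSet(
        natural_history=nh,
        screening=base.screening,
        economics=replace(base.economics, costs=costs, utilities=utilities),
        incidence=base.incidence,
        mortality=base.mortality,
        provenance="psa-draw",
    )
    out.validate()
    return out


def _copy_parameter_set(ps: ParameterSet) -> ParameterSet:
    nh = ps.natural_history
    return ParameterSet(
        natural_history=replace(
            nh,
            density_props=np.asarray(nh.density_props).copy(),
            density_sens_mult=np.asarray(nh.density_sens_mult).copy(),
            symptomatic_props=np.asarray(nh.symptomatic_props).copy(),
            survival_means=dict(nh.survival_means),
        ),
        screening=replace(ps.screening),
        economics=replace(
            ps.economics,
            costs=replace(ps.economics.costs),
            utilities=replace(ps.economics.utilities),
        ),
        incidence=ps.incidence,
        mortality=ps.mortality,
        provenance=ps.provenance,
    )


# ---------------------------------------------------------------------------
# overrides and serialisation

_READER_FIELDS = {"sp_r1", "sp_r2", "ai_human", "ai_reader", "arbitration", "recall"}


def valid_override_keys(ps: ParameterSet) -> list[str]:
    keys: list[str] = []
    for block in ("natural_history", "screening", "economics"):
        obj = getattr(ps, block)
        for name in vars(obj):
            if block == "screening" and name in _READER_FIELDS:
                keys.extend(f"{block}.{name}.{f}" for f in ("sensitivity", "specificity"))
            elif block == "economics" and name in ("costs", "utilities"):
                keys.extend(f"{block}.{name}.{f}" for f in vars(getattr(obj, name)))
            else:
                keys.append(f"{block}.{name}")
    return sorted(keys)


def apply_overrides(ps: ParameterSet, overrides: dict) -> ParameterSet:
    """Return a copy of ``ps`` with dotted-key overrides applied.

    Keys look like ``economics.ai_price`` or
    ``screening.ai_reader.sensitivity``; an unknown key raises with the full
    list of valid keys.
    """
    out = _copy_parameter_set(ps)
    valid = set(valid_override_keys(out))
    for key, value in overrides.items():
        if key not in valid:
            raise KeyError(
                f"unknown override {key!r}; valid keys are: {', '.join(sorted(valid))}"
            )
        parts = key.split(".")
        obj = out
        for part in parts[:-1]:
            obj = getattr(obj, part)
        leaf = parts[-1]
        if isinstance(obj, ReaderProfile):
            # frozen dataclass: rebuild the profile on its parent
            parent = getattr(out, parts[0])
            setattr(parent, parts[1], replace(obj, **{leaf: value}))
        else:
            current = getattr(obj, leaf)
            if isinstance(current, np.ndarray):
                value = np.asarray(value, dtype=float)
            setattr(obj, leaf, value)
    out.validate()
    return out


def parameter_set_to_dict(ps: ParameterSet) -> dict:
    """Plain-python representation (YAML-safe) of a ParameterSet."""
    nh = ps.natural_history
    sc = ps.screening
    ec = ps.economics

    def reader(r: ReaderProfile) -> dict:
        return {"sensitivity": r.sensitivity, "specificity": r.specificity, "label": r.label}

    return {
        "natural_history": {
            "growth_rate_mean": nh.growth_rate_mean,
            "growth_rate_se": nh.growth_rate_se,
            "vmax_mm": nh.vmax_mm,
            "vcell_mm": nh.vcell_mm,
            "density_props": np.asarray(nh.density_props).tolist(),
            "density_sens_mult": np.asarray(nh.density_sens_mult).tolist(),
            "p_dcis": float(nh.p_dcis),
            "npi_by_size": {
                "edges": nh.npi_by_size.edges.tolist(),
                "values": nh.npi_by_size.values.tolist(),
            },
            "advanced_by_size": {
                "edges": nh.advanced_by_size.edges.tolist(),
                "values": nh.advanced_by_size.values.tolist(),
            },
            "symptomatic_props": np.asarray(nh.symptomatic_props).tolist(),
            "survival_means": {k: float(v) for k, v in nh.survival_means.items()},
        },
        "screening": {
            **{name: reader(getattr(sc, name)) for name in sorted(_READER_FIELDS)},
            "policy": {
                "start_age": sc.policy.start_age,
                "end_age": sc.policy.end_age,
                "interval": sc.policy.interval,
            },
            "attendance": sc.attendance,
        },
        "economics": {
            "discount_rate": ec.discount_rate,
            "wtp": ec.wtp,
            "human_read_cost": ec.human_read_cost,
            "human_read_cost_alternate": ec.human_read_cost_alternate,
            "ai_price": ec.ai_price,
            "ai_setup": ec.ai_setup,
            "ai_maintenance": ec.ai_maintenance,
            "service_years": ec.service_years,
            "reference_cohort": ec.reference_cohort,
            "locum_fraction": ec.locum_fraction,
            "locum_read_cost": ec.locum_read_cost,
            "costs": {
                k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else float(v))
                for k, v in vars(ec.costs).items()
            },
            "utilities": {
                k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else float(v))
                for k, v in vars(ec.utilities).items()
            },
        },
        "tables": {
            "incidence": {"ages": ps.incidence.ages.tolist(), "rates": ps.incidence.rates.tolist()},
            "mortality": {"ages": ps.mortality.ages.tolist(), "rates": ps.mortality.rates.tolist()},
        },
    }


def parameter_set_from_dict(d: dict) -> ParameterSet:
    nhd, scd, ecd = d["natural_history"], d["screening"], d["economics"]

    def reader(rd: dict) -> ReaderProfile:
        return ReaderProfile(rd["sensitivity"], rd["specificity"], rd.get("label", "reader"))

    nh = NaturalHistoryParams(
        growth_rate_mean=nhd["growth_rate_mean"],
        growth_rate_se=nhd["growth_rate_se"],
        vmax_mm=nhd["vmax_mm"],
        vcell_mm=nhd["vcell_mm"],
        density_props=np.asarray(nhd["density_props"]),
        density_sens_mult=np.asarray(nhd["density_sens_mult"]),
        p_dcis=nhd["p_dcis"],
        npi_by_size=SizeBandTable(nhd["npi_by_size"]["edges"], nhd["npi_by_size"]["values"]),
        advanced_by_size=SizeBandTable(
            nhd["advanced_by_size"]["edges"], nhd["advanced_by_size"]["values"]
        ),
        symptomatic_props=np.asarray(nhd["symptomatic_props"]),
        survival_means=dict(nhd["survival_means"]),
    )
    sc = ScreeningParams(
        **{name: reader(scd[name]) for name in sorted(_READER_FIELDS)},
        policy=ScreeningPolicy(**scd["policy"]),
        attendance=scd["attendance"],
    )
    costs = CostSchedule(
        **{
            k: (np.asarray(v) if isinstance(v, list) else v)
            for k, v in ecd["costs"].items()
        }
    )
    utilities = UtilitySchedule(
        **{
            k: (np.asarray(v) if isinstance(v, list) else v)
            for k, v in ecd["utilities"].items()
        }
    )
    ec = EconomicsParams(
        costs=costs,
        utilities=utilities,
        **{
            k: ecd[k]
            for k in (
                "discount_rate", "wtp", "human_read_cost", "human_read_cost_alternate",
                "ai_price", "ai_setup", "ai_maintenance", "service_years",
                "reference_cohort", "locum_fraction", "locum_read_cost",
            )
        },
    )
    tables = d["tables"]
    return ParameterSet(
        natural_history=nh,
        screening=sc,
        economics=ec,
        incidence=dg.AgeRateTable(tables["incidence"]["ages"], tables["incidence"]["rates"]),
        mortality=dg.AgeRateTable(tables["mortality"]["ages"], tables["mortality"]["rates"]),
    )


def save_config(ps: ParameterSet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(parameter_set_to_dict(ps), sort_keys=False))


def load_config(path: str | Path) -> ParameterSet:
    ps = parameter_set_from_dict(yaml.safe_load(Path(path).read_text()))
    ps.validate()
    return ps
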