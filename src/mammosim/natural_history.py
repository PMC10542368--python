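"""Per-woman breast-cancer natural history.

Covers breast-density assignment (VDG 1-4), logistic tumour growth between
onset at 0.25 mm and the 128 mm asymptote, size-conditional staging (DCIS /
NPI I-III / Advanced), interim symptomatic presentation between screens, and
stage-specific exponential cancer survival.

Growth model
------------
Tumour volume follows logistic growth

    V(t) = Vmax / (1 + (Vmax/V0 - 1) * exp(-k t))

with spherical diameter-volume conversion (V proportional to d^3), anchored at
diameter 0.25 mm at onset and asymptote 128 mm.  The per-year volumetric rate
k (mean 1.07, lognormal across women) gives a diameter doubling time of
3 ln 2 / k = 1.9 years in the exponential regime, matching published
continuous-growth estimates of the time to grow from 10 mm to 20 mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# stage codes
DCIS, NPI_I, NPI_II, NPI_III, ADVANCED = 0, 1, 2, 3, 4
STAGE_NAMES = {DCIS: "DCIS", NPI_I: "NPI I", NPI_II: "NPI II", NPI_III: "NPI III", ADVANCED: "Advanced"}


@dataclass(frozen=True)
class SizeBandTable:
    """Probabilities tabulated by tumour-diameter band.

    ``edges`` are band boundaries in mm (length k+1, increasing); ``values``
    holds one row per band (NPI membership triples) or one probability per
    band (advanced-at-detection).
    """

    edges: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "values", values)
        if len(edges) != len(values) + 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be increasing with one more entry than rows")
        if values.ndim == 2 and not np.allclose(values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of a probability table must sum to 1")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    def band_index(self, diameter: np.ndarray) -> np.ndarray:
        """Band index per diameter, clamped (with a warning) outside support."""
        d = np.asarray(diameter, dtype=float)
        if np.any(d < self.edges[0]) or np.any(d > self.edges[-1]):
            logger.warning("diameter outside table support; clamping to nearest band")
        idx = np.searchsorted(self.edges, d, side="right") - 1
        return np.clip(idx, 0, len(self.values) - 1)

    def to_frame(self):
        import pandas as pd

        cols = (
            {"p_advanced": self.values}
            if self.values.ndim == 1
            else {f"p_npi{j + 1}": self.values[:, j] for j in range(self.values.shape[1])}
        )
        return pd.DataFrame({"size_lo_mm": self.edges[:-1], "size_hi_mm": self.edges[1:], **cols})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "SizeBandTable":
        import pandas as pd

        df = pd.read_csv(path)
        edges = np.append(df["size_lo_mm"].to_numpy(), df["size_hi_mm"].to_numpy()[-1])
        value_cols = [c for c in df.columns if c.startswith("p_")]
        values = df[value_cols].to_numpy()
        if values.shape[1] == 1:
            values = values[:, 0]
        return cls(edges, values)


# Synthetic stand-ins for the size-conditional staging tables.  Band edges and
# the monotone structure (NPI I falling, NPI III and advanced rising with
# size) follow the clinical literature's size bands; the exact probabilities
# are synthetic.
def default_npi_by_size() -> SizeBandTable:
    return SizeBandTable(
        edges=[0.0, 10.0, 15.0, 20.0, 30.0, 50.0, 128.0],
        values=[
            [0.72, 0.23, 0.05],
            [0.55, 0.33, 0.12],
            [0.40, 0.40, 0.20],
            [0.25, 0.45, 0.30],
            [0.12, 0.43, 0.45],
            [0.05, 0.35, 0.60],
        ],
    )


def default_advanced_by_size() -> SizeBandTable:
    return SizeBandTable(
        edges=[0.0, 10.0, 15.0, 20.0, 30.0, 50.0, 128.0],
        values=[0.01, 0.02, 0.04, 0.08, 0.18, 0.35],
    )


@dataclass
class NaturalHistoryParams:
    """Natural-history block of a parameter set (see params.default_registry)."""

    growth_rate_mean: float = 1.07
    growth_rate_se: float = 0.00208
    vmax_mm: float = 128.0
    vcell_mm: float = 0.25
    density_props: np.ndarray = field(default_factory=lambda: np.array([0.22, 0.41, 0.29, 0.08]))
    density_sens_mult: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.91, 0.81, 0.69]))
    p_dcis: float = 0.09
    npi_by_size: SizeBandTable = field(default_factory=default_npi_by_size)
    advanced_by_size: SizeBandTable = field(default_factory=default_advanced_by_size)
    symptomatic_props: np.ndarray = field(default_factory=lambda: np.array([0.53, 0.80, 0.87]))
    survival_means: dict = field(
        default_factory=lambda: {
            "npi1": 5.413,
            "npi2": 4.023,
            "npi3": 2.465,
            "adv_lt50": 0.527,
            "adv_50_70": 0.537,
            "adv_gt70": 0.849,
        }
    )


@dataclass
class TumourState:
    """One tumour: onset, per-woman growth rate, and stage once classified."""

    onset_age: float
    growth_rate: float
    invasive: bool | None = None
    stage_at_classification: int | None = None
    classification_age: float | None = None

    def set_stage(self, stage: int, age: float) -> None:
        if self.stage_at_classification is not None:
            raise ValueError("stage may be set only once, at the classification event")
        self.stage_at_classification = stage
        self.classification_age = age
        self.invasive = stage != DCIS


@dataclass
class WomanProfile:
    """One simulated woman's disease trajectory under a given arm."""

    id: int
    density: int  # VDG group, 0-based (0 == VDG1)
    death_age_natural: float
    carcinogenesis_age: float | None = None
    tumour: TumourState | None = None
    survival_after_cancer: float | None = None
    death_age: float | None = None
    cause_of_death: str = "natural"


def tumour_diameter(
    elapsed: np.ndarray | float,
    k: np.ndarray | float,
    vcell: float = 0.25,
    vmax: float = 128.0,
) -> np.ndarray | float:
    """Tumour diameter in mm after ``elapsed`` years of growth at rate ``k``.

    Logistic growth on volume with spherical conversion: strictly increasing
    in ``elapsed``, equals ``vcell`` at 0 and approaches ``vmax``
    asymptotically.  ``k`` is the per-year volumetric growth rate.
    """
    if not 0.0 < vcell < vmax:
        raise ValueError("require 0 < vcell < vmax")
    elapsed = np.asarray(elapsed, dtype=float)
    if np.any(elapsed < 0):
        raise ValueError("elapsed must be nonnegative")
    ratio = (vmax / vcell) ** 3  # volume ratio; the 4/3*pi factor cancels
    vol_rel = 1.0 / (1.0 + (ratio - 1.0) * np.exp(-np.asarray(k) * elapsed))  # / vmax volume
    d = vmax * np.cbrt(vol_rel)
    return d if d.ndim else float(d)


def sample_growth_rates(nh: NaturalHistoryParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """Per-woman volumetric growth rates, lognormal with the table's mean/SE."""
    m, s = nh.growth_rate_mean, nh.growth_rate_se
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def assign_density(
    proportions: np.ndarray, rng: np.random.Generator, n: int | None = None
) -> np.ndarray | int:
    """Categorical VDG draw(s) (0-based group index)."""
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("density proportions must sum to 1")
    draws = rng.choice(len(p), size=n if n is not None else 1, p=p)
    return draws if n is not None else int(draws[0])


def classify_from_uniforms(
    diameter: np.ndarray,
    u_dcis: np.ndarray,
    u_npi: np.ndarray,
    u_advanced: np.ndarray,
    nh: NaturalHistoryParams,
) -> np.ndarray:
    """Deterministic staging given pre-drawn uniforms (common random numbers).

    DCIS with probability ``p_dcis``; otherwise the NPI class is read off the
    size-conditional row, and Advanced supersedes with the size-conditional
    advanced probability.  Sharing the uniforms across arms makes a woman's
    stage a deterministic function of the diameter at classification.
    """
    d = np.atleast_1d(np.asarray(diameter, dtype=float))
    u_dcis = np.atleast_1d(u_dcis)
    u_npi = np.atleast_1d(u_npi)
    u_advanced = np.atleast_1d(u_advanced)
    bands = nh.npi_by_size.band_index(d)
    rows = np.atleast_2d(nh.npi_by_size.values)[bands]
    cum = np.cumsum(rows, axis=1)
    npi = 1 + np.minimum((u_npi[:, None] >= cum).sum(axis=1), 2)
    p_adv = np.asarray(nh.advanced_by_size.values)[nh.advanced_by_size.band_index(d)]
    stage = np.where(u_advanced < p_adv, ADVANCED, npi)
    return np.where(u_dcis < nh.p_dcis, DCIS, stage)


def classify_tumour(diameter: float, nh: NaturalHistoryParams, rng: np.random.Generator) -> int:
    """Stage at a classification event for a tumour of the given diameter."""
    u = rng.random(3)
    return int(classify_from_uniforms(np.asarray([diameter]), u[:1], u[1:2], u[2:3], nh)[0])


def underlying_npi_class(
    diameter: np.ndarray, u_npi: np.ndarray, nh: NaturalHistoryParams
) -> np.ndarray:
    """NPI class (1-3) ignoring the DCIS/advanced layers, for symptom rates."""
    d = np.atleast_1d(np.asarray(diameter, dtype=float))
    rows = np.atleast_2d(nh.npi_by_size.values)[nh.npi_by_size.band_index(d)]
    cum = np.cumsum(rows, axis=1)
    return 1 + np.minimum((np.atleast_1d(u_npi)[:, None] >= cum).sum(axis=1), 2)


def interim_symptomatic(stage: int, nh: NaturalHistoryParams, rng: np.random.Generator) -> bool:
    """Does an undetected invasive tumour present symptomatically this cycle?

    Bernoulli with the stage-specific proportion; evaluated mid-way through
    the 3-year cycle.  Advanced tumours use the NPI III proportion.  DCIS is
    asymptomatic in-model and is a caller error.
    """
    if stage == DCIS:
        raise ValueError("DCIS is asymptomatic in-model; interim_symptomatic is undefined")
    if stage not in (NPI_I, NPI_II, NPI_III, ADVANCED):
        raise ValueError(f"unknown stage {stage}")
    p = nh.symptomatic_props[min(stage, NPI_III) - 1]
    return bool(rng.random() < p)


def survival_mean(stage: int, age_at_diagnosis: float, nh: NaturalHistoryParams) -> float:
    """Mean exponential survival in years for the stage (and age band)."""
    if stage == DCIS:
        raise ValueError("DCIS survival follows background mortality")
    if stage == ADVANCED:
        if age_at_diagnosis < 50.0:
            return nh.survival_means["adv_lt50"]
        if age_at_diagnosis <= 70.0:
            return nh.survival_means["adv_50_70"]
        return nh.survival_means["adv_gt70"]
    return nh.survival_means[f"npi{stage}"]


def sample_cancer_survival(
    stage: int, age_at_diagnosis: float, nh: NaturalHistoryParams, rng: np.random.Generator
) -> float:
    """Exponential survival-time draw (years) from the classification event."""
    return float(rng.exponential(survival_mean(stage, age_at_diagnosis, nh)))
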