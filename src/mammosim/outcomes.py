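"""Cost-effectiveness analytics over PSA output.

Implements the decision statistics of the evaluation: incremental
cost-effectiveness ratio (with cost-effectiveness-plane quadrant), net
monetary benefit and its increment at a willingness-to-pay threshold, the
cost-effectiveness acceptability curve, a jackknife confidence interval for
the ICER over PSA iterations (ratio of mean incremental costs to mean
incremental QALYs, leave-one-out pseudo-values, normal-theory interval), a
maximum-reimbursable-price search, and a scenario runner with common random
numbers against the base case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CohortSummary, run_psa
from .params import Registry

DEFAULT_WTP = 20000.0
DEFAULT_CEAC_GRID = np.arange(0.0, 50001.0, 1000.0)


@dataclass
class CEResult:
    """Cost-effectiveness summary of one (possibly scenario) PSA run."""

    mean_cost: dict[str, float]
    mean_qalys: dict[str, float]
    nmb: dict[str, float]
    delta_cost: float  # intervention minus comparator
    delta_qalys: float
    icer: float | None
    icer_quadrant: str
    inmb: float
    prob_cost_effective: float
    jackknife_ci: tuple[float, float] | None
    ceac: list[tuple[float, float]]
    wtp: float = DEFAULT_WTP
    intervention: str = "ai"
    comparator: str = "sp"
    n_iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention,
            "comparator": self.comparator,
            "wtp": self.wtp,
            "mean_cost": self.mean_cost,
            "mean_qalys": self.mean_qalys,
            "nmb": self.nmb,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "icer": self.icer,
            "icer_quadrant": self.icer_quadrant,
            "inmb": self.inmb,
            "prob_cost_effective": self.prob_cost_effective,
            "jackknife_ci": list(self.jackknife_ci) if self.jackknife_ci else None,
            "ceac": [[float(l), float(p)] for l, p in self.ceac],
            "n_iterations": self.n_iterations,
        }


def icer(
    cost_intervention: float,
    qalys_intervention: float,
    cost_comparator: float,
    qalys_comparator: float,
) -> tuple[float | None, str]:
    """ICER (GBP/QALY) with its cost-effectiveness-plane quadrant.

    Quadrants (x = incremental QALYs, y = incremental cost): NE more costly /
    more effective, SE cheaper / more effective (``dominant``), NW more
    costly / less effective (``dominated``), SW cheaper / less effective —
    where a ratio *below* threshold favours the comparator.  A zero QALY
    difference is classified by the cost sign alone.
    """
    dc = cost_intervention - cost_comparator
    dq = qalys_intervention - qalys_comparator
    if dq == 0.0:
        if dc == 0.0:
            return 0.0, "equivalent"
        return None, "dominant" if dc < 0 else "dominated"
    quadrant = {(True, True): "NE", (True, False): "SE (dominant)",
                (False, True): "NW (dominated)", (False, False): "SW"}[(dq > 0, dc > 0)]
    return dc / dq, quadrant


def nmb(mean_qalys: float, mean_cost: float, wtp: float = DEFAULT_WTP) -> float:
    """Net monetary benefit: QALYs valued at the threshold, minus cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return mean_qalys * wtp - mean_cost


def inmb(
    qalys_intervention: float,
    cost_intervention: float,
    qalys_comparator: float,
    cost_comparator: float,
    wtp: float = DEFAULT_WTP,
) -> float:
    return nmb(qalys_intervention, cost_intervention, wtp) - nmb(qalys_comparator, cost_comparator, wtp)


def ceac(
    delta_costs: np.ndarray, delta_qalys: np.ndarray, wtp_grid: np.ndarray = DEFAULT_CEAC_GRID
) -> list[tuple[float, float]]:
    """Probability the intervention is cost-effective at each threshold.

    The probability at a threshold is the fraction of PSA draws with positive
    incremental NMB; exact ties with the comparator are split evenly.
    """
    dc = np.asarray(delta_costs, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    if len(dc) < 2:
        raise ValueError("ceac needs at least two PSA draws")
    out = []
    for lam in np.asarray(wtp_grid, dtype=float):
        b = lam * dq - dc
        out.append((float(lam), float(np.mean(b > 0) + 0.5 * np.mean(b == 0))))
    return out


def jackknife_ci_icer(
    delta_costs: np.ndarray, delta_qalys: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Jackknife 95 % interval for the ICER over PSA iterations.

    The estimator is the ratio of means (mean incremental cost over mean
    incremental QALYs); leave-one-out pseudo-values give the normal-theory
    interval.  Degenerate (all-equal) draws give a zero-width interval.
    """
    from scipy.stats import norm

    dc = np.asarray(delta_costs, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    m = len(dc)
    if m < 3:
        raise ValueError("jackknife needs at least three draws")
    theta = dc.mean() / dq.mean()
    loo = (dc.sum() - dc) / (dq.sum() - dq)  # leave-one-out ratios of means
    pseudo = m * theta - (m - 1) * loo
    se = pseudo.std(ddof=1) / np.sqrt(m)
    z = norm.ppf(1.0 - alpha / 2.0)
    centre = pseudo.mean()
    return float(centre - z * se), float(centre + z * se)


def analyse(
    results: list[CohortSummary],
    wtp: float = DEFAULT_WTP,
    wtp_grid: np.ndarray = DEFAULT_CEAC_GRID,
    intervention: str = "ai",
    comparator: str = "sp",
) -> CEResult:
    """Full cost-effectiveness summary of a PSA run."""
    costs = {label: np.array([r.arms[label].mean_cost for r in results]) for label in (intervention, comparator)}
    qalys = {label: np.array([r.arms[label].mean_qalys for r in results]) for label in (intervention, comparator)}
    dc = costs[intervention] - costs[comparator]
    dq = qalys[intervention] - qalys[comparator]
    mean_cost = {label: float(v.mean()) for label, v in costs.items()}
    mean_qalys = {label: float(v.mean()) for label, v in qalys.items()}
    ratio, quadrant = icer(
        mean_cost[intervention], mean_qalys[intervention], mean_cost[comparator], mean_qalys[comparator]
    )
    b = wtp * dq - dc
    prob = float(np.mean(b > 0) + 0.5 * np.mean(b == 0)) if len(b) else float("nan")
    ci = jackknife_ci_icer(dc, dq) if len(dc) >= 3 and not np.allclose(dq.mean(), 0) else None
    return CEResult(
        mean_cost=mean_cost,
        mean_qalys=mean_qalys,
        nmb={label: nmb(mean_qalys[label], mean_cost[label], wtp) for label in mean_cost},
        delta_cost=float(dc.mean()),
        delta_qalys=float(dq.mean()),
        icer=ratio,
        icer_quadrant=quadrant,
        inmb=float(b.mean()),
        prob_cost_effective=prob,
        jackknife_ci=ci,
        ceac=ceac(dc, dq, wtp_grid) if len(dc) >= 2 else [],
        wtp=wtp,
        intervention=intervention,
        comparator=comparator,
        n_iterations=len(results),
    )


def find_mrp(
    inmb_fn,
    bracket: tuple[float, float] = (0.0, 50.0),
    tolerance: float = 0.01,
    max_iter: int = 200,
) -> float:
    """Bisection for the price at which the mean INMB crosses zero.

    ``inmb_fn(price)`` must be evaluated under common random numbers across
    prices and be monotone decreasing in price.  Raises if the bracket shows
    no sign change (reporting the boundary INMBs).
    """
    lo, hi = bracket
    f_lo, f_hi = inmb_fn(lo), inmb_fn(hi)
    if f_lo < 0 or f_hi > 0:
        raise ValueError(
            f"no INMB sign change in bracket [{lo}, {hi}]: INMB({lo})={f_lo:.4f}, INMB({hi})={f_hi:.4f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = inmb_fn(mid)
        if abs(f_mid) < tolerance and (hi - lo) < max(tolerance, 1e-6):
            return mid
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def repriced_inmb_fn(results: list[CohortSummary], base_ai_price: float, wtp: float = DEFAULT_WTP):
    """Closure giving the mean INMB as a function of the AI per-study price.

    The AI price enters the AI arm's cost linearly through the number of
    discounted attended studies, and (under common random numbers) changes
    nothing else, so repricing one PSA run is exact:
    ``INMB(p) = INMB(p0) - (p - p0) * mean discounted AI-arm studies``.
    """
    base = analyse(results, wtp=wtp)
    s_ai = float(np.mean([r.arms["ai"].mean_disc_reads for r in results]))

    def fn(price: float) -> float:
        return base.inmb - (price - base_ai_price) * s_ai

    return fn


@dataclass
class ScenarioResult:
    name: str
    overrides: dict
    result: CEResult
    base: CEResult | None = None
    mrp: float | None = None

    def delta_vs_base(self) -> dict | None:
        if self.base is None:
            return None
        return {
            "delta_inmb": self.result.inmb - self.base.inmb,
            "delta_prob_cost_effective": self.result.prob_cost_effective - self.base.prob_cost_effective,
            "delta_delta_cost": self.result.delta_cost - self.base.delta_cost,
            "delta_delta_qalys": self.result.delta_qalys - self.base.delta_qalys,
        }


def run_scenario(
    name: str,
    overrides: dict,
    registry: Registry,
    n: int,
    iterations: int,
    seed: int = 0,
    psa: bool = True,
    wtp: float = DEFAULT_WTP,
    base_result: CEResult | None = None,
    compute_mrp: bool = False,
    mrp_bracket: tuple[float, float] = (0.0, 50.0),
    mrp_tolerance: float = 0.01,
) -> ScenarioResult:
    """Run one named scenario: overrides on a copy of the base configuration,
    re-run with the same master seed (common random numbers across scenarios).

    An empty override dict reproduces the base analysis bit-exactly.
    """
    results = run_psa(iterations, n, registry, seed=seed, psa=psa, overrides=overrides or None)
    ce = analyse(results, wtp=wtp)
    mrp = None
    if compute_mrp:
        price = overrides.get("economics.ai_price", registry.base.economics.ai_price)
        mrp = find_mrp(repriced_inmb_fn(results, price, wtp), mrp_bracket, mrp_tolerance)
    return ScenarioResult(name=name, overrides=dict(overrides), result=ce, base=base_result, mrp=mrp)
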