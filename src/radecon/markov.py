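"""Three-state lifetime cohort Markov model and cost-utility summaries.

States: "RAD (first year)" -> "RAD (following years)" -> death.  The whole
cohort starts in the first-year state at the model start age; after one cycle
every survivor is in the following-years state and stays there until death.
Mortality is the general female annual death probability from the life table
and is independent of strategy: the two strategies differ only in costs and
utilities, so the incremental effect is driven by the quality-of-life gain
after repair.

Accrual convention: costs and QALYs accrue on the occupancy alive at cycle
start (optionally half-cycle corrected); cycle t covers age start_age + t;
productivity losses are zeroed from the first cycle whose attained age
reaches retirement age; the discount weight is (1+r)^-t (exponential) or
1/(1+r t) (simple), with cycle 0 undiscounted unless requested otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional

import numpy as np

from .costing import CycleCostSet, derive_cycle_costs
from .parameters import LifeTable, ModelConfig, Payer, Strategy, annual_death_prob

__all__ = [
    "CohortTrace",
    "IcurOutcome",
    "CEAResult",
    "PERSPECTIVES",
    "discount_factors",
    "run_cohort",
    "discounted_totals",
    "icur",
    "inmb_trajectory",
    "run_cea",
    "calibrate_discounting",
    "REFERENCE_DETERMINISTIC_TOTALS",
]

PERSPECTIVES = ("nhs", "societal")

#: Published deterministic lifetime totals (societal costs in EUR, QALYs)
#: used only by :func:`calibrate_discounting` to score accrual/discount
#: convention candidates; never fed back into model computations.
REFERENCE_DETERMINISTIC_TOTALS = {
    "soc_societal_cost_eur": 64115.0,
    "repair_societal_cost_eur": 46541.0,
    "soc_qalys": 19.55,
    "repair_qalys": 25.75,
}


def discount_factors(
    n_cycles: int,
    rate: float,
    convention: str = "exponential",
    cycle0_discounted: bool = False,
) -> np.ndarray:
    """Per-cycle discount weights d(t), t = 0 .. n_cycles-1.

    ``exponential``: d(t) = (1+r)^-t; ``simple``: d(t) = 1/(1 + r t).  With
    ``cycle0_discounted`` the exponent/time index is shifted by one so the
    first cycle is already discounted.
    """
    t = np.arange(n_cycles, dtype=float)
    if cycle0_discounted:
        t = t + 1.0
    if convention == "exponential":
        return (1.0 + rate) ** (-t)
    if convention == "simple":
        return 1.0 / (1.0 + rate * t)
    raise ValueError(f"unknown discounting convention {convention!r}")


@dataclass
class CohortTrace:
    """Per-cycle occupancy and cost/QALY accruals for one strategy.

    ``occupancy`` has one row per cycle start (first-year, following-years,
    dead fractions); cycle t corresponds to age ``ages[t]``.  Cost arrays are
    euro accruals per cycle by payer, both undiscounted and discounted.
    """

    strategy: Strategy
    ages: np.ndarray
    occupancy: np.ndarray  # (n_cycles, 3): [first_year, following_years, dead]
    cost_undisc: dict[Payer, np.ndarray]
    cost_disc: dict[Payer, np.ndarray]
    qaly_undisc: np.ndarray
    qaly_disc: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.ages)

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, 0] + self.occupancy[:, 1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "age": self.ages,
                "occ_first_year": self.occupancy[:, 0],
                "occ_following_years": self.occupancy[:, 1],
                "occ_dead": self.occupancy[:, 2],
                "qaly_undiscounted": self.qaly_undisc,
                "qaly_discounted": self.qaly_disc,
            }
        )
        for p in Payer:
            df[f"cost_{p.value}_undiscounted"] = self.cost_undisc[p]
            df[f"cost_{p.value}_discounted"] = self.cost_disc[p]
        return df


def _utility_per_cycle(cfg: ModelConfig, strategy: Strategy, n_cycles: int) -> np.ndarray:
    u = np.full(n_cycles, cfg.utilities.soc)
    if strategy == Strategy.REPAIR:
        u[:] = cfg.utilities.repair_following_years
        if n_cycles:
            u[0] = cfg.utilities.repair_first_year
    return u


def run_cohort(
    strategy: Strategy,
    cfg: ModelConfig,
    costs: Optional[CycleCostSet] = None,
    lt: Optional[LifeTable] = None,
    horizon: Optional[int] = None,
) -> CohortTrace:
    """Run the cohort through the lifetime horizon for one strategy.

    ``horizon`` defaults to max_age - start_age cycles.  The life table must
    cover every attained age; ages beyond its end carry q = 1.
    """
    if lt is None:
        raise ValueError("a life table is required")
    if costs is None:
        costs = derive_cycle_costs(cfg)
    econ = cfg.econ
    n = econ.horizon_cycles if horizon is None else int(horizon)
    if n < 1:
        raise ValueError("horizon must be at least one cycle")
    ages = econ.start_age_years + np.arange(n)
    if econ.start_age_years < lt.min_age:
        raise ValueError(
            f"life table starts at age {lt.min_age}, after model start age {econ.start_age_years}"
        )
    q = np.array([annual_death_prob(lt, int(a)) for a in ages])

    # occupancy at cycle start, plus one extra row for half-cycle correction
    occ = np.zeros((n + 1, 3))
    occ[0, 0] = 1.0
    for t in range(n):
        y1, fo, dead = occ[t]
        died = (y1 + fo) * q[t]
        occ[t + 1] = (0.0, (y1 + fo) * (1.0 - q[t]), dead + died)

    alive_start = occ[:n, 0] + occ[:n, 1]
    if econ.half_cycle_correction:
        alive_end = occ[1 : n + 1, 0] + occ[1 : n + 1, 1]
        weight = 0.5 * (alive_start + alive_end)
    else:
        weight = alive_start

    d = discount_factors(n, econ.discount_rate, econ.discounting, econ.discount_cycle0)

    u = _utility_per_cycle(cfg, strategy, n)
    qaly_undisc = weight * u
    qaly_disc = qaly_undisc * d

    retired = ages >= econ.retirement_age_years
    cost_undisc: dict[Payer, np.ndarray] = {}
    cost_disc: dict[Payer, np.ndarray] = {}
    for p in Payer:
        per_cycle = np.where(
            np.arange(n) == 0,
            costs.cycle_cost(strategy, "first_year", p),
            costs.cycle_cost(strategy, "following_years", p),
        ).astype(float)
        if p == Payer.PRODUCTIVITY:
            per_cycle = np.where(retired, 0.0, per_cycle)
        stream = weight * per_cycle
        # one-offs are charged on the full cohort entering cycle 0
        if n:
            stream[0] += occ[0, :2].sum() * costs.one_off[strategy][p]
        cost_undisc[p] = stream
        cost_disc[p] = stream * d

    return CohortTrace(
        strategy=strategy,
        ages=ages,
        occupancy=occ[:n].copy(),
        cost_undisc=cost_undisc,
        cost_disc=cost_disc,
        qaly_undisc=qaly_undisc,
        qaly_disc=qaly_disc,
    )


def _perspective_payers(perspective: str) -> tuple[Payer, ...]:
    if perspective == "nhs":
        return (Payer.NHS,)
    if perspective == "societal":
        return tuple(Payer)
    raise ValueError(f"unknown perspective {perspective!r}; expected one of {PERSPECTIVES}")


def discounted_totals(trace: CohortTrace, perspective: str) -> tuple[float, float]:
    """Lifetime discounted (cost EUR, QALYs) under one payer perspective."""
    payers = _perspective_payers(perspective)
    cost = float(sum(trace.cost_disc[p].sum() for p in payers))
    return cost, float(trace.qaly_disc.sum())


@dataclass
class IcurOutcome:
    """Incremental comparison of REPAIR vs SOC under one perspective."""

    delta_cost_eur: float
    delta_qalys: float
    #: 'icur' (finite ratio), 'dominant', 'dominated', or 'undefined' (dE=0)
    flag: str
    icur_eur_per_qaly: Optional[float] = None


def icur(soc: tuple[float, float], repair: tuple[float, float]) -> IcurOutcome:
    """Incremental cost-utility ratio of repair vs no intervention.

    Dominance (cheaper and more effective) and its reverse are flagged
    instead of reporting a misleading negative ratio; a zero QALY difference
    yields an explicit undefined-ICUR outcome rather than a division.
    """
    d_cost = repair[0] - soc[0]
    d_qaly = repair[1] - soc[1]
    if d_qaly == 0.0:
        return IcurOutcome(d_cost, d_qaly, "undefined")
    if d_qaly > 0 and d_cost < 0:
        return IcurOutcome(d_cost, d_qaly, "dominant")
    if d_qaly < 0 and d_cost > 0:
        return IcurOutcome(d_cost, d_qaly, "dominated")
    return IcurOutcome(d_cost, d_qaly, "icur", d_cost / d_qaly)


def inmb_trajectory(
    trace_soc: CohortTrace,
    trace_repair: CohortTrace,
    wtp: float,
    perspective: str,
) -> np.ndarray:
    """Cumulative discounted incremental net monetary benefit by year.

    INMB(t) = wtp * sum_{s<=t} dQALY(s) - sum_{s<=t} dCost(s), all discounted;
    element t is the cumulative value through cycle t.
    """
    if trace_soc.n_cycles != trace_repair.n_cycles:
        raise ValueError("traces must share the same horizon")
    payers = _perspective_payers(perspective)
    d_cost = sum(trace_repair.cost_disc[p] - trace_soc.cost_disc[p] for p in payers)
    d_qaly = trace_repair.qaly_disc - trace_soc.qaly_disc
    return np.cumsum(wtp * d_qaly - d_cost)


@dataclass
class CEAResult:
    """Deterministic lifetime cost-utility results, both perspectives."""

    qalys: dict[str, float]  # strategy value -> lifetime discounted QALYs
    costs: dict[str, dict[str, float]]  # perspective -> strategy value -> EUR
    outcomes: dict[str, IcurOutcome]  # perspective -> incremental outcome
    inmb: dict[str, np.ndarray] = field(default_factory=dict)  # perspective -> cumulative series
    wtp_eur_per_qaly: float = 0.0
    traces: dict[str, CohortTrace] = field(default_factory=dict)

    def to_summary_dict(self) -> dict:
        out = {
            "qalys": self.qalys,
            "costs_eur": self.costs,
            "wtp_eur_per_qaly": self.wtp_eur_per_qaly,
            "incremental": {},
            "inmb_cumulative_eur": {p: list(map(float, s)) for p, s in self.inmb.items()},
        }
        for persp, o in self.outcomes.items():
            out["incremental"][persp] = {
                "delta_cost_eur": o.delta_cost_eur,
                "delta_qalys": o.delta_qalys,
                "flag": o.flag,
                "icur_eur_per_qaly": o.icur_eur_per_qaly,
            }
        return out


def run_cea(
    cfg: ModelConfig,
    lt: LifeTable,
    costs: Optional[CycleCostSet] = None,
    wtp: Optional[float] = None,
) -> CEAResult:
    """Full deterministic comparison of REPAIR vs SOC, both perspectives."""
    if costs is None:
        costs = derive_cycle_costs(cfg)
    wtp = cfg.econ.wtp_reference_eur_per_qaly if wtp is None else wtp
    traces = {s.value: run_cohort(s, cfg, costs, lt) for s in Strategy}
    qalys = {}
    costs_by_persp: dict[str, dict[str, float]] = {p: {} for p in PERSPECTIVES}
    for s in Strategy:
        tr = traces[s.value]
        for persp in PERSPECTIVES:
            c, e = discounted_totals(tr, persp)
            costs_by_persp[persp][s.value] = c
            qalys[s.value] = e
    outcomes = {
        persp: icur(
            (costs_by_persp[persp][Strategy.SOC.value], qalys[Strategy.SOC.value]),
            (costs_by_persp[persp][Strategy.REPAIR.value], qalys[Strategy.REPAIR.value]),
        )
        for persp in PERSPECTIVES
    }
    inmb = {
        persp: inmb_trajectory(traces[Strategy.SOC.value], traces[Strategy.REPAIR.value], wtp, persp)
        for persp in PERSPECTIVES
    }
    return CEAResult(
        qalys=qalys,
        costs=costs_by_persp,
        outcomes=outcomes,
        inmb=inmb,
        wtp_eur_per_qaly=wtp,
        traces=traces,
    )


def calibrate_discounting(
    cfg: ModelConfig,
    lt: LifeTable,
    targets: Optional[dict[str, float]] = None,
) -> list[dict]:
    """Score every accrual/discount convention against published lifetime totals.

    The published deterministic QALYs imply more discounted life-years than an
    exponentially discounted annuity from the start age can produce, so the
    convention that generated them is not recoverable from the text alone.
    This utility evaluates all combinations of {exponential, simple} x
    {cycle 0 discounted or not} x {half-cycle correction on/off} and returns
    one record per combination with the four totals and the maximum relative
    error versus the targets, sorted best first.  It reports; it does not
    silently change any default.
    """
    targets = dict(REFERENCE_DETERMINISTIC_TOTALS if targets is None else targets)
    results = []
    for conv, cycle0, hcc in product(("exponential", "simple"), (False, True), (False, True)):
        trial = cfg.model_copy(deep=True)
        trial.econ.discounting = conv
        trial.econ.discount_cycle0 = cycle0
        trial.econ.half_cycle_correction = hcc
        res = run_cea(trial, lt)
        achieved = {
            "soc_societal_cost_eur": res.costs["societal"][Strategy.SOC.value],
            "repair_societal_cost_eur": res.costs["societal"][Strategy.REPAIR.value],
            "soc_qalys": res.qalys[Strategy.SOC.value],
            "repair_qalys": res.qalys[Strategy.REPAIR.value],
        }
        rel_err = {
            k: abs(achieved[k] - targets[k]) / abs(targets[k]) for k in targets
        }
        results.append(
            {
                "discounting": conv,
                "discount_cycle0": cycle0,
                "half_cycle_correction": hcc,
                **{f"model_{k}": v for k, v in achieved.items()},
                **{f"rel_err_{k}": v for k, v in rel_err.items()},
                "max_rel_err": max(rel_err.values()),
            }
        )
    results.sort(key=lambda r: r["max_rel_err"])
    return results
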