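"""Probabilistic and one-way deterministic sensitivity analysis.

PSA: Monte Carlo over independent parameter distributions -- gamma for
costs (moment-matched shape/scale) and beta for utilities and percentages
(moment-matched alpha/beta).  Where a parameter carries a source-reported
standard deviation it is used directly; otherwise a +/-20% variation of the
baseline is translated to an SD (by default as the half-width of a 95%
interval, sd = 0.2 m / 1.96).  Each draw rebuilds the per-cycle cost set
(including the complication-cost expectation, recomputed from the sampled
rates and unit costs) and re-runs both strategies through the Markov engine.
Results feed the cost-effectiveness plane and the acceptability curves
CEAC(wtp) = P(wtp * dE - dC > 0).

OWSA: one parameter at a time to its low/high bound, tornado entries sorted
by outcome range.  Under societal dominance the incremental cost is reported
instead of the sign-unstable ICUR.

Draw order is fixed and documented (utilities, complication rates,
complication unit costs, tariffs, then cost items in configuration order;
``n`` variates per parameter, in that order, from one seeded generator), so
identical (config, n, seed) give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .costing import CycleCostSet, STATES, _zero_payers, uplift_cost
from .markov import discounted_totals, icur, run_cohort
from .parameters import (
    LifeTable,
    ModelConfig,
    Payer,
    Recurrence,
    Strategy,
)

__all__ = [
    "gamma_from_mean_sd",
    "beta_from_mean_sd",
    "SampledParameter",
    "parameter_registry",
    "PSAResult",
    "run_psa",
    "TornadoEntry",
    "run_owsa",
]

#: Cap on the beta "sample size" nu = alpha + beta when sd -> 0.
MAX_BETA_NU = 1e8


def gamma_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched gamma (shape, scale) for a cost parameter.

    shape = mean^2 / sd^2, scale = sd^2 / mean, so the distribution has
    exactly the requested first two moments.
    """
    if mean <= 0:
        raise ValueError(f"gamma mean must be positive, got {mean} (zero-mean costs are held fixed)")
    if sd <= 0:
        raise ValueError(f"gamma sd must be positive, got {sd}")
    return mean * mean / (sd * sd), sd * sd / mean


def beta_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched beta (alpha, beta) for a utility or percentage.

    nu = mean(1-mean)/sd^2 - 1; alpha = mean nu, beta = (1-mean) nu.  The
    variance bound sd^2 < mean(1-mean) must hold; as sd -> 0 nu is capped
    (with a warning) to keep the parameters finite.
    """
    if not 0 < mean < 1:
        raise ValueError(f"beta mean must be strictly inside (0, 1), got {mean}")
    if sd <= 0:
        raise ValueError(f"beta sd must be positive, got {sd}")
    if sd * sd >= mean * (1 - mean):
        raise ValueError(
            f"infeasible moments for beta: sd^2={sd*sd:.6g} >= mean(1-mean)={mean*(1-mean):.6g}"
        )
    nu = mean * (1 - mean) / (sd * sd) - 1
    if nu > MAX_BETA_NU:
        warnings.warn(
            f"beta concentration capped at {MAX_BETA_NU:g} (requested {nu:.3g})", stacklevel=2
        )
        nu = MAX_BETA_NU
    return mean * nu, (1 - mean) * nu


@dataclass(frozen=True)
class SampledParameter:
    """One scalar model parameter eligible for sampling / one-way variation.

    ``target`` addresses the parameter: ('utility', field), ('comp_rate', name),
    ('comp_cost', name), ('tariff', name) or ('item', index into cost_items).
    ``kind`` selects the PSA family: 'cost' -> gamma, 'fraction' -> beta.
    """

    name: str
    kind: str
    mean: float
    sd: Optional[float]
    target: tuple


def parameter_registry(cfg: ModelConfig) -> list[SampledParameter]:
    """Eligible parameters in the documented, deterministic order.

    Zero-mean costs are excluded (held fixed, not sampled).
    """
    params: list[SampledParameter] = []
    for fieldname in ("soc", "repair_first_year", "repair_following_years"):
        params.append(
            SampledParameter(
                name=f"utility_{fieldname}",
                kind="fraction",
                mean=getattr(cfg.utilities, fieldname),
                sd=None,
                target=("utility", fieldname),
            )
        )
    for name in sorted(cfg.complications):
        comp = cfg.complications[name]
        params.append(
            SampledParameter(
                name=f"complication_rate_{name}", kind="fraction",
                mean=comp.rate, sd=comp.rate_sd, target=("comp_rate", name),
            )
        )
    for name in sorted(cfg.complications):
        comp = cfg.complications[name]
        if comp.unit_cost_eur > 0:
            params.append(
                SampledParameter(
                    name=f"complication_cost_{name}", kind="cost",
                    mean=comp.unit_cost_eur, sd=comp.cost_sd_eur, target=("comp_cost", name),
                )
            )
    for name in sorted(cfg.nhs_tariffs):
        tariff = cfg.nhs_tariffs[name]
        if tariff.amount_eur > 0:
            params.append(
                SampledParameter(
                    name=f"tariff_{name}", kind="cost",
                    mean=tariff.amount_eur, sd=tariff.sd_eur, target=("tariff", name),
                )
            )
    for i, it in enumerate(cfg.cost_items):
        if it.amount_eur > 0:
            params.append(
                SampledParameter(
                    name=f"item_{it.strategy.value}_{it.state_scope.value}_{it.label}",
                    kind="cost", mean=it.amount_eur, sd=it.sd_eur, target=("item", i),
                )
            )
    return params


def resolve_sd(p: SampledParameter, pct_variation: float, pct_as_95ci: bool) -> float:
    """Source SD when reported, else the +/-pct rule translated to an SD."""
    if p.sd is not None:
        return p.sd
    sd = pct_variation * p.mean
    return sd / 1.96 if pct_as_95ci else sd


def _cycle_costs_from_values(
    cfg: ModelConfig,
    item_amounts: np.ndarray,
    tariff_amounts: dict[str, float],
    comp_rates: dict[str, float],
    comp_costs: dict[str, float],
) -> CycleCostSet:
    """Assemble a CycleCostSet from (possibly sampled) raw parameter values."""
    ccs = CycleCostSet()
    for i, it in enumerate(cfg.cost_items):
        amount = uplift_cost(float(item_amounts[i]), it.uplift_factor)
        if it.recurrence == Recurrence.MONTHLY_RECURRING:
            states = STATES if it.state_scope.value == "both" else (it.state_scope.value,)
            for st in states:
                ccs.recurring[(it.strategy, st)][it.payer] += 12.0 * amount
        else:
            ccs.one_off[it.strategy][it.payer] += amount
    expected_comp = sum(
        comp_rates[name] * uplift_cost(comp_costs[name], cfg.complications[name].uplift_factor)
        for name in cfg.complications
    )
    ccs.one_off[Strategy.REPAIR][Payer.NHS] += sum(tariff_amounts.values()) + expected_comp
    return ccs


def _baseline_values(cfg: ModelConfig):
    item_amounts = np.array([it.amount_eur for it in cfg.cost_items], dtype=float)
    tariffs = {k: t.amount_eur for k, t in cfg.nhs_tariffs.items()}
    rates = {k: c.rate for k, c in cfg.complications.items()}
    ccosts = {k: c.unit_cost_eur for k, c in cfg.complications.items()}
    utilities = {
        "soc": cfg.utilities.soc,
        "repair_first_year": cfg.utilities.repair_first_year,
        "repair_following_years": cfg.utilities.repair_following_years,
    }
    return utilities, item_amounts, tariffs, rates, ccosts


def _run_once(cfg: ModelConfig, lt: LifeTable, utilities, item_amounts, tariffs, rates, ccosts):
    """One deterministic engine pass with raw parameter values; returns
    (dC_nhs, dC_societal, dE)."""
    work = cfg.model_copy(deep=True)
    work.utilities.soc = utilities["soc"]
    work.utilities.repair_first_year = utilities["repair_first_year"]
    work.utilities.repair_following_years = utilities["repair_following_years"]
    ccs = _cycle_costs_from_values(cfg, item_amounts, tariffs, rates, ccosts)
    tr = {s: run_cohort(s, work, ccs, lt) for s in Strategy}
    c_nhs = {s: discounted_totals(tr[s], "nhs") for s in Strategy}
    c_soc = {s: discounted_totals(tr[s], "societal") for s in Strategy}
    d_e = c_nhs[Strategy.REPAIR][1] - c_nhs[Strategy.SOC][1]
    return (
        c_nhs[Strategy.REPAIR][0] - c_nhs[Strategy.SOC][0],
        c_soc[Strategy.REPAIR][0] - c_soc[Strategy.SOC][0],
        d_e,
    )


@dataclass
class PSAResult:
    """Draw-level incremental outcomes plus acceptability curves."""

    draws: pd.DataFrame  # columns: draw, delta_cost_nhs_eur, delta_cost_societal_eur, delta_qalys
    ceac: pd.DataFrame  # columns: wtp_eur_per_qaly, p_cost_effective_nhs, p_cost_effective_societal
    seed: int
    n: int

    def ceac_at(self, wtp: float, perspective: str) -> float:
        col = f"p_cost_effective_{perspective}"
        row = self.ceac.loc[self.ceac["wtp_eur_per_qaly"] == wtp, col]
        if row.empty:
            raise KeyError(f"wtp {wtp} not on the CEAC grid")
        return float(row.iloc[0])


def run_psa(
    cfg: ModelConfig,
    lt: LifeTable,
    n: int = 10_000,
    seed: int = 0,
    wtp_grid: Optional[list[float]] = None,
    pct_variation: float = 0.2,
    pct_as_95ci: bool = True,
) -> PSAResult:
    """Monte Carlo PSA: ``n`` independent joint parameter draws.

    Parameters are sampled independently; utilities and percentages from
    moment-matched betas, positive costs from moment-matched gammas.  Each
    draw re-runs both strategies through the Markov engine with the
    complication-cost expectation recomputed from the sampled rates and unit
    costs.  Fully reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    wtp_grid = list(cfg.econ.wtp_grid_eur_per_qaly) if wtp_grid is None else list(wtp_grid)
    params = parameter_registry(cfg)
    rng = np.random.default_rng(seed)
    variates: dict[str, np.ndarray] = {}
    for p in params:  # documented draw order; n variates per parameter
        sd = resolve_sd(p, pct_variation, pct_as_95ci)
        if sd == 0:
            variates[p.name] = np.full(n, p.mean)
        elif p.kind == "cost":
            shape, scale = gamma_from_mean_sd(p.mean, sd)
            variates[p.name] = rng.gamma(shape, scale, size=n)
        elif p.kind == "fraction":
            a, b = beta_from_mean_sd(p.mean, sd)
            variates[p.name] = rng.beta(a, b, size=n)
        else:  # pragma: no cover
            raise ValueError(f"unresolvable distribution for parameter {p.name}")

    base_utilities, base_items, base_tariffs, base_rates, base_ccosts = _baseline_values(cfg)
    rows = np.empty((n, 3))
    for i in range(n):
        utilities = dict(base_utilities)
        items = base_items.copy()
        tariffs = dict(base_tariffs)
        rates = dict(base_rates)
        ccosts = dict(base_ccosts)
        for p in params:
            v = float(variates[p.name][i])
            section, key = p.target
            if section == "utility":
                utilities[key] = v
            elif section == "comp_rate":
                rates[key] = v
            elif section == "comp_cost":
                ccosts[key] = v
            elif section == "tariff":
                tariffs[key] = v
            else:
                items[key] = v
        rows[i] = _run_once(cfg, lt, utilities, items, tariffs, rates, ccosts)

    draws = pd.DataFrame(
        {
            "draw": np.arange(n),
            "delta_cost_nhs_eur": rows[:, 0],
            "delta_cost_societal_eur": rows[:, 1],
            "delta_qalys": rows[:, 2],
        }
    )
    ceac_rows = []
    for wtp in wtp_grid:
        nb_nhs = wtp * rows[:, 2] - rows[:, 0]
        nb_soc = wtp * rows[:, 2] - rows[:, 1]
        ceac_rows.append(
            {
                "wtp_eur_per_qaly": wtp,
                "p_cost_effective_nhs": float(np.mean(nb_nhs > 0)),
                "p_cost_effective_societal": float(np.mean(nb_soc > 0)),
            }
        )
    return PSAResult(draws=draws, ceac=pd.DataFrame(ceac_rows), seed=seed, n=n)


@dataclass
class TornadoEntry:
    """One-way variation of a single parameter between its two bounds."""

    parameter: str
    low_value: float
    high_value: float
    outcome_low: float
    outcome_high: float
    #: 'icur_eur_per_qaly' or 'delta_cost_eur' (used when dominance makes
    #: the ICUR sign-unstable)
    outcome_metric: str
    dominant_throughout: bool

    @property
    def range_width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def run_owsa(
    cfg: ModelConfig,
    lt: LifeTable,
    perspective: str = "nhs",
    pct_variation: float = 0.2,
) -> list[TornadoEntry]:
    """Tornado analysis: each parameter to mean -/+ 20% (or -/+ SD).

    The outcome is the ICUR for the NHS perspective; for the societal
    perspective, where baseline dominance makes the ICUR undefined, the
    incremental cost is reported instead (flagged on each entry).  Entries
    are sorted by outcome range, widest first.
    """
    if perspective not in ("nhs", "societal"):
        raise ValueError(f"unknown perspective {perspective!r}")
    params = parameter_registry(cfg)
    base = _baseline_values(cfg)
    entries: list[TornadoEntry] = []
    for p in params:
        delta = p.sd if p.sd is not None else pct_variation * p.mean
        bounds = [p.mean - delta, p.mean + delta]
        if p.kind == "fraction":
            bounds = [min(max(b, 0.0), 1.0) for b in bounds]
        else:
            bounds = [max(b, 0.0) for b in bounds]
        outcomes = []
        flags = []
        for v in bounds:
            utilities, items, tariffs, rates, ccosts = (
                dict(base[0]), base[1].copy(), dict(base[2]), dict(base[3]), dict(base[4]),
            )
            section, key = p.target
            if section == "utility":
                utilities[key] = v
            elif section == "comp_rate":
                rates[key] = v
            elif section == "comp_cost":
                ccosts[key] = v
            elif section == "tariff":
                tariffs[key] = v
            else:
                items[key] = v
            dc_nhs, dc_soc, de = _run_once(cfg, lt, utilities, items, tariffs, rates, ccosts)
            dc = dc_nhs if perspective == "nhs" else dc_soc
            out = icur((0.0, 0.0), (dc, de))
            flags.append(out.flag == "dominant")
            if perspective == "nhs" and out.icur_eur_per_qaly is not None:
                outcomes.append(out.icur_eur_per_qaly)
            else:
                outcomes.append(dc)
        entries.append(
            TornadoEntry(
                parameter=p.name,
                low_value=bounds[0],
                high_value=bounds[1],
                outcome_low=outcomes[0],
                outcome_high=outcomes[1],
                outcome_metric="icur_eur_per_qaly" if perspective == "nhs" else "delta_cost_eur",
                dominant_throughout=all(flags),
            )
        )
    entries.sort(key=lambda e: e.range_width, reverse=True)
    return entries
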