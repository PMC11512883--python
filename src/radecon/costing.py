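"""Derivation of per-cycle, per-state, per-payer cost parameters.

Questionnaire summary statistics (monthly and one-off out-of-pocket expenses
and productivity losses), NHS tariffs and the post-surgical complication
profile are folded into a :class:`CycleCostSet`: for each strategy and health
state, the euro amount accrued per 1-year Markov cycle split by payer, plus
the one-off amounts charged in the first cycle only.

Productivity is valued with the human-capital approach: each lost working
hour at the average hourly wage of the respondent's professional category,
8 hours per whole day lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .parameters import (
    Complication,
    CostItem,
    ModelConfig,
    Payer,
    Recurrence,
    StateScope,
    Strategy,
    Tariff,
)

__all__ = [
    "STATES",
    "CycleCostSet",
    "WageTable",
    "expected_complication_cost",
    "nhs_repair_first_cycle_cost",
    "annualize_cost_items",
    "productivity_value",
    "uplift_cost",
    "derive_cycle_costs",
    "load_wage_table",
]

#: Alive health states of the Markov model, in pathway order.
STATES = ("first_year", "following_years")

#: Working hours in a full-time Italian year (8 h x 215 working days),
#: used to convert annual wages to hourly wages.
DEFAULT_WORKING_HOURS_PER_YEAR = 1720.0

MONTHS_PER_YEAR = 12


def _zero_payers() -> dict[Payer, float]:
    return {p: 0.0 for p in Payer}


@dataclass
class CycleCostSet:
    """Per-cycle recurring and first-cycle one-off costs by payer.

    ``recurring[(strategy, state)][payer]`` is EUR per cycle while the cohort
    occupies ``state``; ``one_off[strategy][payer]`` is charged once, in the
    first cycle.  Complication management and NHS tariffs for the repair
    pathway enter as REPAIR one-offs (they are sustained in the first year).
    """

    recurring: dict[tuple[Strategy, str], dict[Payer, float]] = field(default_factory=dict)
    one_off: dict[Strategy, dict[Payer, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in Strategy:
            self.one_off.setdefault(s, _zero_payers())
            for st in STATES:
                self.recurring.setdefault((s, st), _zero_payers())

    def cycle_cost(self, strategy: Strategy, state: str, payer: Payer) -> float:
        return self.recurring[(strategy, state)][payer]

    def societal_cycle_cost(self, strategy: Strategy, state: str) -> float:
        """Societal per-cycle cost = sum over all payers (exact additivity)."""
        return sum(self.recurring[(strategy, state)].values())

    def to_records(self) -> list[dict]:
        """Flat JSON-ready records, one per (strategy, state, payer, recurrence)."""
        recs = []
        for (s, st), by_payer in sorted(self.recurring.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
            for p, amount in by_payer.items():
                recs.append({"strategy": s.value, "state": st, "payer": p.value,
                             "recurrence": "per_cycle", "amount_eur": amount})
        for s, by_payer in sorted(self.one_off.items(), key=lambda kv: kv[0].value):
            for p, amount in by_payer.items():
                recs.append({"strategy": s.value, "state": "first_year", "payer": p.value,
                             "recurrence": "one_off_first_cycle", "amount_eur": amount})
        return recs


def uplift_cost(amount: float, factor: float) -> float:
    """Inflate a cost to the analysis price year by a multiplicative factor."""
    if factor <= 0:
        raise ValueError(f"uplift factor must be positive, got {factor}")
    return amount * factor


def expected_complication_cost(profile: Mapping[str, Complication]) -> float:
    """Mean per-patient cost of post-repair complications.

    The expectation sum(rate_i * unit_cost_i * uplift_i) over the profile;
    with the baseline registry rates and literature unit costs this is the
    ~174 EUR per repaired patient charged in the first model cycle.
    """
    return sum(
        c.rate * uplift_cost(c.unit_cost_eur, c.uplift_factor) for c in profile.values()
    )


def nhs_repair_first_cycle_cost(
    tariffs: Mapping[str, Tariff], profile: Mapping[str, Complication]
) -> float:
    """NHS cost of the repair pathway, all sustained in the first cycle.

    Pre- and post-intervention specialist visits, the intervention DRG
    reimbursement, and the expected complication-management cost.
    """
    required = ("pre_intervention_visit", "post_intervention_visit", "intervention_drg")
    missing = [k for k in required if k not in tariffs]
    if missing:
        raise KeyError(f"missing NHS tariff key(s): {', '.join(missing)}")
    visits_and_drg = sum(tariffs[k].amount_eur for k in required)
    return visits_and_drg + expected_complication_cost(profile)


def _scope_covers(scope: StateScope, state: str) -> bool:
    return scope == StateScope.BOTH or scope.value == state


def annualize_cost_items(
    items: Iterable[CostItem], strategy: Strategy, state: str
) -> tuple[dict[Payer, float], dict[Payer, float]]:
    """Per-cycle and one-off payer components for one (strategy, state).

    Monthly recurring items contribute 12x their monthly amount per cycle;
    one-off items contribute their full amount once (returned separately and
    only for the first-year state).  Uplift factors are applied here.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    recurring = _zero_payers()
    one_off = _zero_payers()
    for it in items:
        if it.strategy != strategy or not _scope_covers(it.state_scope, state):
            continue
        amount = uplift_cost(it.amount_eur, it.uplift_factor)
        if it.recurrence == Recurrence.MONTHLY_RECURRING:
            recurring[it.payer] += MONTHS_PER_YEAR * amount
        elif it.recurrence == Recurrence.ONE_OFF_FIRST_CYCLE:
            if state == "first_year":
                one_off[it.payer] += amount
        else:  # pragma: no cover - enum is closed
            raise ValueError(f"unknown recurrence {it.recurrence}")
    return recurring, one_off


def derive_cycle_costs(cfg: ModelConfig) -> CycleCostSet:
    """Build the full :class:`CycleCostSet` from a validated configuration.

    Survey-derived items populate the recurring and out-of-pocket /
    productivity one-off components; the NHS repair-pathway bundle (visits +
    DRG + expected complication cost) is added as a first-cycle NHS one-off
    for the REPAIR strategy.
    """
    ccs = CycleCostSet()
    for strategy in Strategy:
        for state in STATES:
            recurring, one_off = annualize_cost_items(cfg.cost_items, strategy, state)
            ccs.recurring[(strategy, state)] = recurring
            if state == "first_year":
                for payer, amount in one_off.items():
                    ccs.one_off[strategy][payer] += amount
    ccs.one_off[Strategy.REPAIR][Payer.NHS] += nhs_repair_first_cycle_cost(
        cfg.nhs_tariffs, cfg.complications
    )
    return ccs


# ---------------------------------------------------------------------------
# Productivity valuation (human-capital approach)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WageTable:
    """Annual and derived hourly wages per professional category."""

    annual_wage_eur: dict[str, float]
    working_hours_per_year: float = DEFAULT_WORKING_HOURS_PER_YEAR

    def __post_init__(self) -> None:
        bad = [k for k, w in self.annual_wage_eur.items() if w <= 0]
        if bad:
            raise ValueError(f"non-positive annual wage for occupation(s): {bad}")
        if self.working_hours_per_year <= 0:
            raise ValueError("working_hours_per_year must be positive")

    def hourly_wage(self, occupation: str) -> float:
        try:
            annual = self.annual_wage_eur[occupation]
        except KeyError:
            known = ", ".join(sorted(self.annual_wage_eur))
            raise KeyError(f"unknown occupation {occupation!r}; known: {known}") from None
        return annual / self.working_hours_per_year


def load_wage_table(path: str | Path, working_hours_per_year: float = DEFAULT_WORKING_HOURS_PER_YEAR) -> WageTable:
    """Read a delimited ``occupation,annual_wage_eur`` file."""
    import pandas as pd

    df = pd.read_csv(path)
    expected = {"occupation", "annual_wage_eur"}
    if set(df.columns) != expected:
        raise ValueError(f"wage table must have columns {sorted(expected)}, got {list(df.columns)}")
    return WageTable(
        annual_wage_eur=dict(zip(df["occupation"], df["annual_wage_eur"].astype(float))),
        working_hours_per_year=working_hours_per_year,
    )


#: Hours counted for one whole working day lost.
HOURS_PER_DAY_LOST = 8.0


def productivity_value(hours_lost: float, occupation: str, wages: WageTable) -> float:
    """Euro value of lost working time for one person (human capital).

    ``hours_lost`` is in hours; callers converting whole days lost should
    count :data:`HOURS_PER_DAY_LOST` hours per day.
    """
    if hours_lost < 0:
        raise ValueError(f"hours_lost must be >= 0, got {hours_lost}")
    return hours_lost * wages.hourly_wage(occupation)
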