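"""Dynamic five-year budget-impact model.

Each calendar year a fresh incident cohort of women with RAD enters and is
split between no intervention and surgical repair by that year's adoption
fraction.  Every cohort is then followed -- within the budget window only --
through the Markov engine's per-cycle *undiscounted* cost accruals
(age-advancing, mortality-thinned), and budget-year totals sum the in-window
costs of all active cohorts.  The current scenario keeps 100% of patients on
standard of care; the future scenario ramps repair adoption (2% -> 10% over
five years in the baseline).  QALY impact is computed the same way from
undiscounted QALY accruals; the NHS share isolates the nhs payer components.

User counts are displayed as the un-thinned cohort sizes (the convention of
published budget-impact tables); mortality thinning applies to cost and QALY
accrual and can be disabled with ``thin_mortality=False`` for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .costing import CycleCostSet, derive_cycle_costs
from .markov import run_cohort
from .parameters import LifeTable, ModelConfig, Payer, Strategy

__all__ = [
    "AdoptionScenario",
    "BIAResult",
    "estimate_incident_population",
    "run_bia",
    "payer_split",
    "soc_only_scenario",
    "default_ramp_scenario",
]


def estimate_incident_population(
    newborns: float, fecundity: float, rad_fraction: float
) -> tuple[int, int]:
    """Yearly (mothers, incident RAD cases) from the epidemiological chain.

    mothers = newborns / fecundity rate (births per woman), rounded to the
    unit; incident cases = mothers x the fraction of women showing RAD after
    pregnancy, rounded to the nearest 1,000 for planning purposes.
    """
    if newborns <= 0 or fecundity <= 0 or rad_fraction <= 0:
        raise ValueError("newborns, fecundity and rad_fraction must all be positive")
    mothers = round(newborns / fecundity)
    incident = round(mothers * rad_fraction / 1000.0) * 1000
    return int(mothers), int(incident)


@dataclass(frozen=True)
class AdoptionScenario:
    """Adoption path of surgical repair over the budget window."""

    horizon_years: int
    incident_cohort_size: int
    adoption_fraction: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.adoption_fraction) != self.horizon_years:
            raise ValueError(
                f"adoption_fraction needs {self.horizon_years} entries, got {len(self.adoption_fraction)}"
            )
        if any(not 0 <= f <= 1 for f in self.adoption_fraction):
            raise ValueError("adoption fractions must lie in [0, 1]")
        if self.incident_cohort_size <= 0:
            raise ValueError("incident_cohort_size must be positive")


def soc_only_scenario(horizon_years: int = 5, incident_cohort_size: int = 105_000) -> AdoptionScenario:
    """Current scenario: 100% standard of care."""
    return AdoptionScenario(horizon_years, incident_cohort_size, (0.0,) * horizon_years)


def default_ramp_scenario(horizon_years: int = 5, incident_cohort_size: int = 105_000) -> AdoptionScenario:
    """Future scenario: repair adoption ramping 2%, 4%, 6%, 8%, 10%."""
    ramp = tuple(0.02 * (y + 1) for y in range(horizon_years))
    return AdoptionScenario(horizon_years, incident_cohort_size, ramp)


@dataclass
class BIAResult:
    """Year-by-year scenario costs and the incremental summary."""

    years: np.ndarray
    table: pd.DataFrame  # one row per (scenario, year)
    incremental_cost_by_year_eur: np.ndarray
    total_incremental_cost_eur: float
    incremental_cost_per_patient_eur: float
    nhs_incremental_cost_eur: float
    nhs_share_fraction: Optional[float]
    incremental_qalys_total: float
    incremental_qalys_per_patient: float
    flags: dict = field(default_factory=dict)

    def to_summary_dict(self) -> dict:
        return {
            "total_incremental_cost_eur": self.total_incremental_cost_eur,
            "incremental_cost_by_year_eur": [float(x) for x in self.incremental_cost_by_year_eur],
            "incremental_cost_per_patient_eur": self.incremental_cost_per_patient_eur,
            "nhs_incremental_cost_eur": self.nhs_incremental_cost_eur,
            "nhs_share_fraction": self.nhs_share_fraction,
            "incremental_qalys_total": self.incremental_qalys_total,
            "incremental_qalys_per_patient": self.incremental_qalys_per_patient,
            "flags": self.flags,
        }


def _per_cycle_streams(
    strategy: Strategy,
    cfg: ModelConfig,
    costs: CycleCostSet,
    lt: LifeTable,
    horizon: int,
    thin_mortality: bool,
    first_year_utility: bool,
):
    """Undiscounted per-cycle (societal cost, NHS cost, QALY) streams of one
    entering cohort, taken from the Markov engine over the budget window."""
    work = cfg.model_copy(deep=True)
    work.econ.discounting = "exponential"
    work.econ.discount_cycle0 = False
    if not first_year_utility and strategy == Strategy.REPAIR:
        # steady-state utility-gain variant: following-years utility from entry
        work.utilities.repair_first_year = work.utilities.repair_following_years
    tr = run_cohort(strategy, work, costs, lt, horizon=horizon)
    societal = sum(tr.cost_undisc[p] for p in Payer)
    nhs = tr.cost_undisc[Payer.NHS]
    qaly = tr.qaly_undisc
    if not thin_mortality:
        alive = tr.alive
        societal, nhs, qaly = societal / alive, nhs / alive, qaly / alive
    return societal, nhs, qaly


def _scenario_totals(scn, streams):
    """Budget-year totals across all active cohorts of one scenario."""
    h = scn.horizon_years
    soc_cost = np.zeros(h)
    rep_cost = np.zeros(h)
    nhs_cost = np.zeros(h)
    qalys = np.zeros(h)
    soc_users = np.empty(h)
    rep_users = np.empty(h)
    for entry in range(h):  # cohort entering in budget year `entry`
        n_rep = scn.incident_cohort_size * scn.adoption_fraction[entry]
        n_soc = scn.incident_cohort_size - n_rep
        soc_users[entry] = n_soc
        rep_users[entry] = n_rep
        for year in range(entry, h):
            a = year - entry  # years since cohort entry
            soc_cost[year] += n_soc * streams[Strategy.SOC][0][a]
            rep_cost[year] += n_rep * streams[Strategy.REPAIR][0][a]
            nhs_cost[year] += n_soc * streams[Strategy.SOC][1][a] + n_rep * streams[Strategy.REPAIR][1][a]
            qalys[year] += n_soc * streams[Strategy.SOC][2][a] + n_rep * streams[Strategy.REPAIR][2][a]
    return soc_users, rep_users, soc_cost, rep_cost, nhs_cost, qalys


def run_bia(
    cfg: ModelConfig,
    costs: Optional[CycleCostSet],
    lt: LifeTable,
    current: AdoptionScenario,
    future: AdoptionScenario,
    thin_mortality: bool = True,
    first_year_utility: bool = True,
) -> BIAResult:
    """Compare two adoption scenarios over the budget window.

    Financial streams are undiscounted; so are the QALY accruals (mirroring
    them).  ``first_year_utility=False`` switches the repair QALY stream to
    the steady-state utility-gain variant used for calibration against
    published budget-impact QALY totals.
    """
    if (current.horizon_years, current.incident_cohort_size) != (
        future.horizon_years,
        future.incident_cohort_size,
    ):
        raise ValueError("scenarios must share horizon and incident cohort size")
    if costs is None:
        costs = derive_cycle_costs(cfg)
    h = current.horizon_years
    streams = {
        s: _per_cycle_streams(s, cfg, costs, lt, h, thin_mortality, first_year_utility)
        for s in Strategy
    }
    rows = []
    totals = {}
    for name, scn in (("current", current), ("future", future)):
        soc_users, rep_users, soc_cost, rep_cost, nhs_cost, qalys = _scenario_totals(scn, streams)
        totals[name] = {
            "total": soc_cost + rep_cost,
            "nhs": nhs_cost,
            "qalys": qalys,
        }
        for y in range(h):
            rows.append(
                {
                    "scenario": name,
                    "year": y + 1,
                    "soc_fraction": 1.0 - scn.adoption_fraction[y],
                    "soc_users": soc_users[y],
                    "repair_fraction": scn.adoption_fraction[y],
                    "repair_users": rep_users[y],
                    "soc_cost_eur": soc_cost[y],
                    "repair_cost_eur": rep_cost[y],
                    "total_cost_eur": soc_cost[y] + rep_cost[y],
                }
            )
    inc_cost = totals["future"]["total"] - totals["current"]["total"]
    total_inc = float(inc_cost.sum())
    nhs_inc = float((totals["future"]["nhs"] - totals["current"]["nhs"]).sum())
    inc_qalys = float((totals["future"]["qalys"] - totals["current"]["qalys"]).sum())
    n_patients = current.incident_cohort_size * h
    table = pd.DataFrame(rows)
    table["incremental_cost_eur"] = [
        (inc_cost[int(r.year) - 1] if r.scenario == "future" else 0.0) for r in table.itertuples()
    ]
    return BIAResult(
        years=np.arange(1, h + 1),
        table=table,
        incremental_cost_by_year_eur=inc_cost,
        total_incremental_cost_eur=total_inc,
        incremental_cost_per_patient_eur=total_inc / n_patients,
        nhs_incremental_cost_eur=nhs_inc,
        nhs_share_fraction=(nhs_inc / total_inc) if total_inc != 0 else None,
        incremental_qalys_total=inc_qalys,
        incremental_qalys_per_patient=inc_qalys / n_patients,
        flags={"thin_mortality": thin_mortality, "first_year_utility": first_year_utility},
    )


def payer_split(result: BIAResult) -> tuple[float, float, Optional[float]]:
    """(NHS EUR, non-NHS EUR, NHS fraction) of the total incremental cost.

    NHS + non-NHS equals the total exactly; a zero total yields an undefined
    (None) fraction rather than 0.
    """
    nhs = result.nhs_incremental_cost_eur
    non_nhs = result.total_incremental_cost_eur - nhs
    if result.total_incremental_cost_eur == 0:
        return nhs, non_nhs, None
    return nhs, non_nhs, nhs / result.total_incremental_cost_eur
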