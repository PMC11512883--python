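"""Parameter data model, configuration and life-table I/O.

The economic model is parameter dense: strategy-specific cost items split by
payer (NHS, patient out-of-pocket, productivity), health-state utilities,
complication rates and unit costs, NHS reimbursement tariffs and the general
economic settings (discount rate, ages, willingness-to-pay grid).  Everything
is carried by a single validated :class:`ModelConfig`, round-trippable through
a YAML file, with every parameter annotated by a citation key so the
provenance of each number can be audited.

Background mortality enters through a :class:`LifeTable` of annual death
probabilities for Italian females, indexed by integer age to match the 1-year
Markov cycle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "Strategy",
    "Payer",
    "Recurrence",
    "StateScope",
    "EconSettings",
    "UtilitySet",
    "CostItem",
    "Complication",
    "ModelConfig",
    "LifeTable",
    "Tariff",
    "load_config",
    "save_config",
    "default_config",
    "load_life_table",
    "annual_death_prob",
    "uncited_parameters",
    "DEFAULT_CONFIG_PATH",
    "DEFAULT_LIFE_TABLE_PATH",
]

_DATA_DIR = Path(__file__).parent / "data"
DEFAULT_CONFIG_PATH = _DATA_DIR / "default_config.yaml"
#: Synthetic stand-in for an Italian female period life table (see
#: :func:`radecon.synthetic.generate_life_table`).
DEFAULT_LIFE_TABLE_PATH = _DATA_DIR / "life_table_synthetic_italian_female.csv"


class Strategy(str, Enum):
    """Treatment strategy: no intervention (SOC) or mesh repair (REPAIR)."""

    SOC = "SOC"
    REPAIR = "REPAIR"


class Payer(str, Enum):
    NHS = "nhs"
    OUT_OF_POCKET = "out_of_pocket"
    PRODUCTIVITY = "productivity"


class Recurrence(str, Enum):
    ONE_OFF_FIRST_CYCLE = "one_off_first_cycle"
    MONTHLY_RECURRING = "monthly_recurring"


class StateScope(str, Enum):
    FIRST_YEAR = "first_year"
    FOLLOWING_YEARS = "following_years"
    BOTH = "both"


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class EconSettings(_StrictModel):
    """Global economic settings.

    ``discount_rate`` is an annual fraction applied to both costs and QALYs.
    ``discounting`` selects the per-cycle discount weight: ``exponential``
    for (1+r)^-t or ``simple`` for 1/(1+r*t); ``discount_cycle0`` shifts the
    exponent so that the first cycle is discounted too.  ``half_cycle_correction``
    averages start- and end-of-cycle occupancy when accruing.
    """

    discount_rate: float = Field(ge=0, lt=1)
    cycle_length_years: int = 1
    start_age_years: int = Field(gt=0)
    retirement_age_years: int
    max_age_years: int
    wtp_grid_eur_per_qaly: list[float]
    wtp_reference_eur_per_qaly: float = Field(gt=0)
    discounting: str = "exponential"
    discount_cycle0: bool = False
    half_cycle_correction: bool = False
    sources: dict[str, str] = Field(default_factory=dict)

    @field_validator("cycle_length_years")
    @classmethod
    def _cycle_is_one_year(cls, v: int) -> int:
        if v != 1:
            raise ValueError("cycle_length_years is fixed at 1 in this model")
        return v

    @field_validator("discounting")
    @classmethod
    def _known_discounting(cls, v: str) -> str:
        if v not in ("exponential", "simple"):
            raise ValueError(f"discounting must be 'exponential' or 'simple', got {v!r}")
        return v

    @field_validator("wtp_grid_eur_per_qaly")
    @classmethod
    def _wtp_nonneg(cls, v: list[float]) -> list[float]:
        if any(w < 0 for w in v):
            raise ValueError("wtp grid values must be >= 0")
        return v

    @model_validator(mode="after")
    def _age_ordering(self) -> "EconSettings":
        if not (self.start_age_years < self.retirement_age_years <= self.max_age_years):
            raise ValueError(
                "require start_age_years < retirement_age_years <= max_age_years, got "
                f"{self.start_age_years} / {self.retirement_age_years} / {self.max_age_years}"
            )
        return self

    @property
    def horizon_cycles(self) -> int:
        """Lifetime horizon in 1-year cycles (ages start_age .. max_age-1)."""
        return self.max_age_years - self.start_age_years


class UtilitySet(_StrictModel):
    """EuroQol-derived utility weights per health state, in [0, 1]/year."""

    soc: float = Field(ge=0, le=1)
    repair_first_year: float = Field(ge=0, le=1)
    repair_following_years: float = Field(ge=0, le=1)
    sources: dict[str, str] = Field(default_factory=dict)


class CostItem(_StrictModel):
    """One cost item from the socio-economic questionnaire or tariff list.

    ``amount_eur`` is per month for ``monthly_recurring`` items and per event
    for ``one_off_first_cycle`` items.  The productivity payer is zeroed by
    the Markov engine once the cohort reaches retirement age -- never here.
    """

    label: str
    strategy: Strategy
    payer: Payer
    recurrence: Recurrence
    state_scope: StateScope
    amount_eur: float = Field(ge=0)
    sd_eur: Optional[float] = Field(default=None, ge=0)
    uplift_factor: float = Field(default=1.0, gt=0)
    source: str = ""


class Complication(_StrictModel):
    """Post-repair complication: frequency and NHS management cost."""

    rate: float = Field(ge=0, le=1)
    unit_cost_eur: float = Field(ge=0)
    rate_sd: Optional[float] = Field(default=None, ge=0)
    cost_sd_eur: Optional[float] = Field(default=None, ge=0)
    uplift_factor: float = Field(default=1.0, gt=0)
    source: str = ""


class Tariff(_StrictModel):
    """An NHS reimbursement tariff (outpatient code or DRG)."""

    amount_eur: float = Field(ge=0)
    sd_eur: Optional[float] = Field(default=None, ge=0)
    source: str = ""


class ModelConfig(_StrictModel):
    """Complete, validated parameter set for the CEA/BIA models."""

    econ: EconSettings
    utilities: UtilitySet
    cost_items: list[CostItem]
    complications: dict[str, Complication]
    nhs_tariffs: dict[str, Tariff]

    @model_validator(mode="after")
    def _has_both_strategies(self) -> "ModelConfig":
        covered = {it.strategy for it in self.cost_items}
        if self.nhs_tariffs:
            covered.add(Strategy.REPAIR)
        missing = set(Strategy) - covered
        if missing:
            raise ValueError(
                "every strategy needs at least one cost item or tariff; missing: "
                + ", ".join(s.value for s in sorted(missing, key=lambda s: s.value))
            )
        return self

    def to_plain_dict(self) -> dict:
        """JSON/YAML-safe dict with enums rendered as their string values."""
        return self.model_dump(mode="json", exclude_none=True)


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from a YAML file.

    Raises ``pydantic.ValidationError`` naming the offending field for any
    missing required key, unknown key, or out-of-range value.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return ModelConfig.model_validate(raw)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    """Serialize a configuration back to YAML (lossless round-trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_plain_dict(), fh, sort_keys=False)


def default_config() -> ModelConfig:
    """The bundled baseline parameter set (Italian setting, euro 2022)."""
    return load_config(DEFAULT_CONFIG_PATH)


def uncited_parameters(cfg: ModelConfig) -> list[str]:
    """Dotted names of numeric parameters lacking a citation key.

    Citations live in ``econ.sources`` / ``utilities.sources`` (keyed by field
    name) and in the ``source`` field of cost items, complications and tariffs.
    An audit-complete config returns an empty list.
    """
    missing: list[str] = []
    for field in ("discount_rate", "start_age_years", "retirement_age_years",
                  "max_age_years", "wtp_reference_eur_per_qaly"):
        if not cfg.econ.sources.get(field):
            missing.append(f"econ.{field}")
    for field in ("soc", "repair_first_year", "repair_following_years"):
        if not cfg.utilities.sources.get(field):
            missing.append(f"utilities.{field}")
    for it in cfg.cost_items:
        if not it.source:
            missing.append(f"cost_items[{it.strategy.value}:{it.label}]")
    for name, comp in cfg.complications.items():
        if not comp.source:
            missing.append(f"complications.{name}")
    for name, tariff in cfg.nhs_tariffs.items():
        if not tariff.source:
            missing.append(f"nhs_tariffs.{name}")
    return missing


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(age) on contiguous integer ages.

    ``q`` at the final tabulated age is 1, so no cohort member survives past
    it.  Lookups beyond the table return 1.
    """

    ages: np.ndarray  # int, contiguous ascending
    q: np.ndarray     # float in [0, 1]

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        if ages.size == 0 or ages.size != q.size:
            raise ValueError("life table needs equal, non-empty age and q columns")
        gaps = np.flatnonzero(np.diff(ages) != 1)
        if gaps.size:
            missing = [int(ages[i]) + 1 for i in gaps]
            raise ValueError(f"life table ages must be contiguous; missing ages after {missing}")
        bad = np.flatnonzero((q < 0) | (q > 1))
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"death probability out of [0, 1] in row for age {int(ages[i])}: q={q[i]}"
            )
        if q[-1] != 1.0:
            raise ValueError(
                f"life table must close with q=1 at its final age (got q={q[-1]} at {int(ages[-1])})"
            )

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"age": self.ages, "q": self.q})


def load_life_table(path: str | Path, max_age: int = 110) -> LifeTable:
    """Read a two-column ``age,q`` delimited file into a :class:`LifeTable`.

    If the file ends before ``max_age`` the remaining ages are filled with
    q=1 and a warning is emitted, so the table always closes the cohort.
    """
    import pandas as pd

    df = pd.read_csv(path)
    expected = {"age", "q"}
    if set(df.columns) != expected:
        raise ValueError(f"life table must have exactly columns {sorted(expected)}, got {list(df.columns)}")
    ages = df["age"].to_numpy(dtype=int)
    q = df["q"].to_numpy(dtype=float)
    if not np.all(np.diff(ages) > 0):
        raise ValueError("life table ages must be sorted strictly ascending")
    bad = np.flatnonzero((q < 0) | (q > 1))
    if bad.size:
        raise ValueError(f"death probability out of [0, 1] in row for age {int(ages[bad[0]])}")
    if ages[-1] < max_age:
        pad_ages = np.arange(ages[-1] + 1, max_age + 1)
        msg = (f"life table {path} ends at age {int(ages[-1])}; "
               f"padding ages {int(pad_ages[0])}-{max_age} with q=1")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        ages = np.concatenate([ages, pad_ages])
        q = np.concatenate([q, np.ones(pad_ages.size)])
    q = q.copy()
    q[-1] = 1.0  # closure at the terminal age
    return LifeTable(ages=ages, q=q)


def annual_death_prob(lt: LifeTable, age: int) -> float:
    """Tabulated annual death probability at integer ``age``.

    Ages beyond the table return 1 (the cohort is closed); ages below the
    table start are a domain error.
    """
    if age < lt.min_age:
        raise ValueError(f"age {age} below life-table start {lt.min_age}")
    if age > lt.max_age:
        return 1.0
    return float(lt.q[age - lt.min_age])
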