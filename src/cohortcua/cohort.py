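"""Four-state cohort trace built by partitioned survival.

States: progression-free without adverse events, progression-free with
adverse events, progressed disease, and death.  Occupancy is read directly
from the progression-free and overall survival curves (progressed = overall
- progression-free, clamped at zero), with all-cause background mortality
from a life table layered multiplicatively on both curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import ParametricSurvival

__all__ = [
    "DAYS_PER_CYCLE",
    "DAYS_PER_YEAR",
    "CYCLES_PER_YEAR",
    "CYCLE_YEARS",
    "STATES",
    "LifeTable",
    "EngineSettings",
    "StateTrace",
    "other_cause_prob",
    "combine_mortality",
    "discount_factor",
    "half_cycle_person_time",
    "run_cohort",
]

logger = logging.getLogger(__name__)

DAYS_PER_CYCLE = 21.0
DAYS_PER_YEAR = 365.25
CYCLES_PER_YEAR = DAYS_PER_YEAR / DAYS_PER_CYCLE  # ~17.393 cycles
CYCLE_YEARS = DAYS_PER_CYCLE / DAYS_PER_YEAR

STATES = ("pfs_no_ae", "pfs_ae", "pd", "death")


class LifeTable:
    """Age-indexed annual all-cause death probabilities.

    Ages must be contiguous integers; the terminal age must carry qx = 1 so
    the table closes out.
    """

    def __init__(self, ages, qx) -> None:
        ages = np.asarray(ages, dtype=int)
        qx = np.asarray(qx, dtype=float)
        if ages.size == 0 or ages.size != qx.size:
            raise ValueError("ages and qx must be non-empty and equal length")
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + ages.size)):
            raise ValueError("ages must be contiguous integers")
        if np.any(qx < 0) or np.any(qx > 1):
            raise ValueError("qx must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise ValueError("qx at the maximum age must equal 1")
        self.ages = ages
        self.qx = qx
        self._warned_clamp = False

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_qx(self, age: float) -> float:
        """qx for the whole year of age containing ``age``; ages above the
        table maximum are clamped (logged once)."""
        year = int(np.floor(age))
        if year < self.min_age:
            raise ValueError(f"age {age} below life-table minimum {self.min_age}")
        if year > self.max_age:
            if not self._warned_clamp:
                logger.warning(
                    "age %.1f above life-table maximum %d; clamping", age, self.max_age
                )
                self._warned_clamp = True
            year = self.max_age
        return float(self.qx[year - self.min_age])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)


@dataclass(frozen=True)
class EngineSettings:
    """Cycle length, discounting, cohort age and horizon controls."""

    annual_discount_rate: float = 0.03
    start_age: float = 45.0
    horizon_cycles: int = 1000
    half_cycle_correction: bool = True
    cycle_length_days: float = DAYS_PER_CYCLE

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_discount_rate <= 0.08:
            raise ValueError("annual discount rate must lie in [0, 0.08]")
        if self.horizon_cycles < 1:
            raise ValueError("horizon must be at least one cycle")

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR


@dataclass
class StateTrace:
    """Per-cycle occupancy of the four states plus discount factors.

    ``occupancy`` has shape (n_cycles + 1, 4) with columns ordered as
    :data:`STATES`; row 0 is model entry.
    """

    occupancy: np.ndarray
    discount_factors: np.ndarray
    settings: EngineSettings
    crossing_cycles: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != len(STATES):
            raise ValueError("occupancy must be (cycles+1, 4)")
        self.occupancy = occ

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def column(self, state: str) -> np.ndarray:
        return self.occupancy[:, STATES.index(state)]

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.column("death")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(len(df)))
        df["discount_factor"] = self.discount_factors
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def other_cause_prob(table: LifeTable | None, current_age: float) -> float:
    """Per-cycle background death probability at ``current_age``.

    Converts the annual qx via 1 - (1-qx)**(21/365.25).  A missing table
    means no background mortality.
    """
    if table is None:
        return 0.0
    qx = table.annual_qx(current_age)
    if qx >= 1.0:
        return 1.0
    return 1.0 - (1.0 - qx) ** (DAYS_PER_CYCLE / DAYS_PER_YEAR)


def combine_mortality(p_disease: float, p_other: float) -> float:
    """Combine two independent per-cycle death probabilities:
    1 - (1-p_disease)(1-p_other)."""
    for p in (p_disease, p_other):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    return 1.0 - (1.0 - p_disease) * (1.0 - p_other)


def discount_factor(cycle_index: float, annual_rate: float) -> float:
    """Continuous-age discount factor (1+r)^(-cycle*21/365.25)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    return float((1.0 + annual_rate) ** (-cycle_index * CYCLE_YEARS))


def half_cycle_person_time(occupancy) -> float:
    """Trapezoidal person-time (in cycles) of one occupancy column."""
    col = np.asarray(occupancy, dtype=float)
    if col.ndim != 1 or col.size < 2:
        raise ValueError("occupancy column must have length >= 2")
    return float(np.trapezoid(col))


def _background_survival(
    table: LifeTable | None, settings: EngineSettings, n_cycles: int
) -> np.ndarray:
    """Cumulative other-cause survival at cycles 0..n_cycles."""
    b = np.ones(n_cycles + 1)
    if table is None:
        return b
    ages = settings.start_age + np.arange(n_cycles) * settings.cycle_years
    years = np.floor(ages).astype(int)
    if years[0] < table.min_age:
        raise ValueError(
            f"start age {settings.start_age} below life-table minimum {table.min_age}"
        )
    if years[-1] > table.max_age and not table._warned_clamp:
        logger.warning(
            "ages above life-table maximum %d; clamping", table.max_age
        )
        table._warned_clamp = True
    qx = table.qx[np.clip(years - table.min_age, 0, table.qx.size - 1)]
    p = np.where(qx >= 1.0, 1.0, 1.0 - (1.0 - qx) ** (DAYS_PER_CYCLE / DAYS_PER_YEAR))
    b[1:] = np.cumprod(1.0 - p)
    return b


def run_cohort(
    pfs: ParametricSurvival,
    os_model: ParametricSurvival,
    table: LifeTable | None,
    settings: EngineSettings,
    ae_split: float = 0.0,
) -> StateTrace:
    """Build the partitioned-survival state trace.

    Alive occupancy is the overall-survival curve times cumulative background
    survival; the progression-free compartment tracks the progression-free
    curve under the same adjustment, split into with/without-adverse-event
    sub-states by ``ae_split``.  Progressed occupancy is the difference,
    clamped at zero where the disease curves cross (logged).  The trace stops
    at the horizon, once the cohort is effectively extinct, or at the
    life-table maximum age.
    """
    if not 0.0 <= ae_split <= 1.0:
        raise ValueError("ae_split must lie in [0, 1]")

    horizon = settings.horizon_cycles
    if table is not None:
        max_cycles_by_age = int(
            np.ceil((table.max_age + 1 - settings.start_age) / settings.cycle_years)
        )
        horizon = min(horizon, max(max_cycles_by_age, 1))

    t_grid = np.arange(horizon + 1, dtype=float)
    s_pfs = np.atleast_1d(pfs.survival(t_grid))
    s_os = np.atleast_1d(os_model.survival(t_grid))
    b = _background_survival(table, settings, horizon)

    alive = s_os * b
    pfs_occ = np.minimum(s_pfs * b, alive)
    pd_occ = alive - pfs_occ

    crossings = [int(c) for c in np.flatnonzero(s_pfs > s_os + 1e-15)]
    if crossings:
        logger.info(
            "progression-free curve exceeds overall survival from cycle %d; "
            "progressed occupancy clamped at 0",
            crossings[0],
        )

    # truncate once the cohort is effectively dead
    dead = 1.0 - alive
    done = np.flatnonzero(dead > 1.0 - 1e-6)
    last = int(done[0]) if done.size else horizon
    last = max(last, 1)

    occ = np.column_stack(
        [
            pfs_occ[: last + 1] * (1.0 - ae_split),
            pfs_occ[: last + 1] * ae_split,
            pd_occ[: last + 1],
            dead[: last + 1],
        ]
    )
    dfs = (1.0 + settings.annual_discount_rate) ** (
        -np.arange(last + 1) * CYCLE_YEARS
    )
    return StateTrace(occ, dfs, settings, crossing_cycles=crossings[:1])
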