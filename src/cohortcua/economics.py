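"""Cost, QALY and life-year accrual over a cohort trace, and incremental
cost-effectiveness indices.

All monetary arithmetic is carried out unrounded in US dollars; rounding to
whole dollars happens only in the reporting layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import STATES, EngineSettings, StateTrace

__all__ = [
    "DrugRegimen",
    "Patient",
    "UtilitySet",
    "StrategyConfig",
    "StrategyResult",
    "ComparisonResult",
    "regimen_cycle_quantity",
    "regimen_cycle_cost",
    "expected_ae_cost",
    "accrue",
    "accrue_strategy",
    "incremental_measures",
]

logger = logging.getLogger(__name__)

_ALIVE = ("pfs_no_ae", "pfs_ae", "pd")
_PFS = ("pfs_no_ae", "pfs_ae")


@dataclass(frozen=True)
class DrugRegimen:
    """One drug's dosing rule within a cycle.

    ``dose`` is per square metre (basis="bsa"), per kilogram (basis="weight")
    or absolute (basis="flat"), per administration.  ``unit_size`` is the
    smallest dispensed unit (tablet or vial) in the same dose units;
    ``unit_cost`` is dollars per dispensed unit.  ``round_per`` controls
    wastage: "admin" rounds dispensed units up per administration (tablets),
    "cycle" rounds once per cycle (shared vials).
    """

    drug: str
    dose: float
    admins_per_cycle: int
    unit_cost: float
    unit_size: float
    basis: str = "bsa"
    round_per: str = "admin"

    def __post_init__(self) -> None:
        if self.basis not in ("bsa", "weight", "flat"):
            raise ValueError(f"unknown dosing basis {self.basis!r}")
        if self.round_per not in ("admin", "cycle"):
            raise ValueError(f"unknown rounding rule {self.round_per!r}")
        if self.dose < 0 or self.unit_cost < 0:
            raise ValueError("dose and unit cost must be non-negative")
        if self.unit_size <= 0 or self.admins_per_cycle < 0:
            raise ValueError("unit size must be > 0 and admins >= 0")


@dataclass(frozen=True)
class Patient:
    body_weight_kg: float = 65.0
    body_surface_area_m2: float = 1.72

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0 or self.body_surface_area_m2 <= 0:
            raise ValueError("patient measurements must be positive")


@dataclass(frozen=True)
class UtilitySet:
    u_pfs: float = 0.760
    u_pd: float = 0.350
    u_death: float = 0.0
    ae_disutility: float = 0.0

    def __post_init__(self) -> None:
        for u in (self.u_pfs, self.u_pd, self.u_death):
            if not 0.0 <= u <= 1.0:
                raise ValueError("utilities must lie in [0, 1]")
        if self.ae_disutility < 0:
            raise ValueError("ae_disutility must be >= 0")


@dataclass(frozen=True)
class StrategyConfig:
    """Everything needed to cost one treatment arm.

    ``maintenance`` is the on-treatment regimen billed while progression-free
    (None for supportive care alone), capped at ``maintenance_max_cycles``.
    Subsequent-therapy regimens are billed per progressed-state entrant for
    at most ``pd_therapy_cap_cycles``, weighted by uptake proportions;
    subsequent radiotherapy is a one-off course per entrant.
    """

    name: str
    maintenance: DrugRegimen | None = None
    maintenance_max_cycles: int = 35
    concomitant_radiotherapy_prop: float = 0.0
    bisphosphonate_prop: float = 0.0
    bisphosphonate_regimen: DrugRegimen | None = None
    subsequent_props: dict = field(default_factory=dict)
    subsequent_regimens: dict = field(default_factory=dict)
    ae_incidence: dict = field(default_factory=dict)
    ae_cost: dict = field(default_factory=dict)
    bsc_cost_per_cycle: float = 0.0
    lab_cost_per_cycle: float = 0.0
    imaging_cost: float = 0.0
    imaging_interval_cycles: int = 3
    radiotherapy_course_cost: float = 0.0
    pd_therapy_cap_cycles: int = 6

    def __post_init__(self) -> None:
        for p in (
            self.concomitant_radiotherapy_prop,
            self.bisphosphonate_prop,
            *self.subsequent_props.values(),
            *self.ae_incidence.values(),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions and incidences must lie in [0, 1]")
        for c in (
            self.bsc_cost_per_cycle,
            self.lab_cost_per_cycle,
            self.imaging_cost,
            self.radiotherapy_course_cost,
            *self.ae_cost.values(),
        ):
            if c < 0:
                raise ValueError("costs must be non-negative")

    @property
    def ae_any_prob(self) -> float:
        """1 - prod(1 - incidence): chance of at least one grade 3-4 event."""
        prod = 1.0
        for inc in self.ae_incidence.values():
            prod *= 1.0 - inc
        return 1.0 - prod


@dataclass(frozen=True)
class StrategyResult:
    name: str
    cost: float
    qalys: float
    lys: float
    cost_pfs: float = 0.0
    cost_pd: float = 0.0
    qalys_pfs: float = 0.0
    qalys_pd: float = 0.0
    cost_components: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental economics of treated vs control at one WTP threshold."""

    delta_cost: float
    delta_qalys: float
    delta_lys: float
    wtp: float
    icur: float | None
    icer: float | None
    inmb: float
    inhb: float
    dominant: bool = False
    dominated: bool = False


# ---------------------------------------------------------------------------
# Drug and adverse-event arithmetic
# ---------------------------------------------------------------------------


def regimen_cycle_quantity(regimen: DrugRegimen, patient: Patient) -> int:
    """Dispensed units consumed per cycle, with ceiling-based wastage."""
    if regimen.basis == "bsa":
        scale = patient.body_surface_area_m2
    elif regimen.basis == "weight":
        scale = patient.body_weight_kg
    else:
        scale = 1.0
    amount_per_admin = regimen.dose * scale
    if amount_per_admin == 0 or regimen.admins_per_cycle == 0:
        return 0
    if regimen.round_per == "admin":
        units = math.ceil(amount_per_admin / regimen.unit_size - 1e-9)
        return units * regimen.admins_per_cycle
    total = amount_per_admin * regimen.admins_per_cycle
    return math.ceil(total / regimen.unit_size - 1e-9)


def regimen_cycle_cost(regimen: DrugRegimen, patient: Patient) -> float:
    return regimen_cycle_quantity(regimen, patient) * regimen.unit_cost


def expected_ae_cost(incidences: dict, costs: dict) -> float:
    """One-off expected adverse-event management cost: sum incidence*cost."""
    total = 0.0
    for name, inc in incidences.items():
        if inc == 0:
            continue
        if name not in costs:
            raise KeyError(f"no management cost configured for adverse event {name!r}")
        total += inc * costs[name]
    return total


# ---------------------------------------------------------------------------
# Accrual
# ---------------------------------------------------------------------------


def accrue(
    trace: StateTrace,
    per_state_values,
    settings: EngineSettings | None = None,
) -> float:
    """Discounted total of per-cycle state values over a trace.

    ``per_state_values`` maps state name -> scalar per-cycle value, or is an
    array of shape (n_cycles+1, 4) for time-varying values.  Each cycle
    interval (t-1, t] contributes mean occupancy (half-cycle corrected) times
    value times the discount factor at t; without the correction the
    occupancy at t is used, matching end-of-cycle accrual.
    """
    settings = settings or trace.settings
    occ = trace.occupancy
    n = trace.n_cycles
    if isinstance(per_state_values, dict):
        vals = np.zeros_like(occ)
        for state, v in per_state_values.items():
            vals[:, STATES.index(state)] = v
    else:
        vals = np.asarray(per_state_values, dtype=float)
        if vals.shape != occ.shape:
            raise ValueError(
                f"value array shape {vals.shape} does not match trace {occ.shape}"
            )
    if settings.half_cycle_correction:
        occ_eff = 0.5 * (occ[:-1] + occ[1:])
    else:
        occ_eff = occ[1:]
    d = trace.discount_factors[1 : n + 1]
    return float(np.sum(occ_eff * vals[1:] * d[:, None]))


def _pd_on_treatment(trace: StateTrace, cap_cycles: int) -> np.ndarray:
    """Occupancy receiving subsequent therapy: progressed-state entrants are
    billed for at most ``cap_cycles`` cycles after leaving progression-free.

    Entrants at cycle t are approximated by the drop in progression-free
    occupancy; within-cap mortality is ignored (conservative on cost)."""
    pfs = trace.column("pfs_no_ae") + trace.column("pfs_ae")
    entrants = np.maximum(-np.diff(pfs), 0.0)
    treated = np.zeros(trace.n_cycles + 1)
    for t in range(1, trace.n_cycles + 1):
        lo = max(t - cap_cycles, 0)
        treated[t] = entrants[lo:t].sum()
    return np.minimum(treated, trace.column("pd"))


def accrue_strategy(
    trace: StateTrace,
    strategy: StrategyConfig,
    patient: Patient,
    utilities: UtilitySet,
    settings: EngineSettings | None = None,
) -> StrategyResult:
    """Total discounted cost, QALYs and LYs of one arm over its trace."""
    settings = settings or trace.settings
    cyl = settings.cycle_years
    n = trace.n_cycles
    d1 = trace.discount_factors[1] if n >= 1 else 1.0

    # --- QALYs and LYs ------------------------------------------------
    qaly_vals = {
        "pfs_no_ae": utilities.u_pfs * cyl,
        "pfs_ae": max(utilities.u_pfs - utilities.ae_disutility, 0.0) * cyl,
        "pd": utilities.u_pd * cyl,
    }
    qalys_pfs = accrue(
        trace,
        {k: v for k, v in qaly_vals.items() if k in _PFS},
        settings,
    )
    qalys_pd = accrue(trace, {"pd": qaly_vals["pd"]}, settings)
    lys = accrue(trace, {s: cyl for s in _ALIVE}, settings)

    components: dict[str, float] = {}

    # --- recurring per-cycle costs ------------------------------------
    care = strategy.bsc_cost_per_cycle + strategy.lab_cost_per_cycle
    components["supportive_care"] = accrue(trace, {s: care for s in _ALIVE}, settings)

    if strategy.bisphosphonate_regimen is not None and strategy.bisphosphonate_prop:
        bis = regimen_cycle_cost(strategy.bisphosphonate_regimen, patient)
        components["bisphosphonates"] = accrue(
            trace,
            {s: bis * strategy.bisphosphonate_prop for s in _ALIVE},
            settings,
        )

    if strategy.imaging_cost:
        vals = np.zeros_like(trace.occupancy)
        interval = max(strategy.imaging_interval_cycles, 1)
        for t in range(interval, n + 1, interval):
            for s in _ALIVE:
                vals[t, STATES.index(s)] = strategy.imaging_cost
        # imaging is a point cost at scheduled cycles: bill survivors at t,
        # so no half-cycle correction applies
        occ = trace.occupancy
        total = float(
            np.sum(occ[1:] * vals[1:] * trace.discount_factors[1:, None])
        )
        components["imaging"] = total

    # --- maintenance drug while progression-free ----------------------
    if strategy.maintenance is not None:
        per_cycle = regimen_cycle_cost(strategy.maintenance, patient)
        vals = np.zeros_like(trace.occupancy)
        cap = min(strategy.maintenance_max_cycles, n)
        for s in _PFS:
            vals[1 : cap + 1, STATES.index(s)] = per_cycle
        components["maintenance_drug"] = accrue(trace, vals, settings)

    # --- one-off costs at model entry / cycle 1 -----------------------
    components["concomitant_radiotherapy"] = (
        strategy.concomitant_radiotherapy_prop * strategy.radiotherapy_course_cost
    )
    components["adverse_events"] = (
        expected_ae_cost(strategy.ae_incidence, strategy.ae_cost) * d1
    )

    # --- subsequent therapy in the progressed state -------------------
    sub_cost = 0.0
    if strategy.subsequent_props:
        per_cycle_drug = 0.0
        for therapy, prop in strategy.subsequent_props.items():
            if therapy == "radiotherapy":
                continue
            reg = strategy.subsequent_regimens.get(therapy)
            if reg is None:
                if prop > 0:
                    raise KeyError(f"no regimen configured for {therapy!r}")
                continue
            per_cycle_drug += prop * regimen_cycle_cost(reg, patient)
        treated = _pd_on_treatment(trace, strategy.pd_therapy_cap_cycles)
        if per_cycle_drug:
            sub_cost += float(
                np.sum(treated[1:] * per_cycle_drug * trace.discount_factors[1:])
            )
        rt_prop = strategy.subsequent_props.get("radiotherapy", 0.0)
        if rt_prop and strategy.radiotherapy_course_cost:
            pfs = trace.column("pfs_no_ae") + trace.column("pfs_ae")
            entrants = np.maximum(-np.diff(pfs), 0.0)
            sub_cost += float(
                np.sum(
                    entrants
                    * rt_prop
                    * strategy.radiotherapy_course_cost
                    * trace.discount_factors[1:]
                )
            )
    components["subsequent_therapy"] = sub_cost

    cost = float(sum(components.values()))
    cost_pd = components["subsequent_therapy"]
    return StrategyResult(
        name=strategy.name,
        cost=cost,
        qalys=qalys_pfs + qalys_pd,
        lys=lys,
        cost_pfs=cost - cost_pd,
        cost_pd=cost_pd,
        qalys_pfs=qalys_pfs,
        qalys_pd=qalys_pd,
        cost_components=components,
    )


def cycle_ledger(
    trace: StateTrace,
    strategy: StrategyConfig,
    utilities: UtilitySet,
    settings: EngineSettings | None = None,
):
    """Per-cycle discounted accrual table: recurring care cost, QALYs and
    LYs per cycle interval (half-cycle corrected when enabled)."""
    import pandas as pd

    settings = settings or trace.settings
    cyl = settings.cycle_years
    occ = trace.occupancy
    occ_eff = 0.5 * (occ[:-1] + occ[1:]) if settings.half_cycle_correction else occ[1:]
    d = trace.discount_factors[1:]
    pfs = occ_eff[:, 0] + occ_eff[:, 1]
    pd_occ = occ_eff[:, 2]
    alive = pfs + pd_occ
    care = strategy.bsc_cost_per_cycle + strategy.lab_cost_per_cycle
    return pd.DataFrame(
        {
            "cycle": np.arange(1, trace.n_cycles + 1),
            "discount_factor": d,
            "care_cost": alive * care * d,
            "qalys": (pfs * utilities.u_pfs + pd_occ * utilities.u_pd) * cyl * d,
            "lys": alive * cyl * d,
        }
    )


# ---------------------------------------------------------------------------
# Incremental indices
# ---------------------------------------------------------------------------


def incremental_measures(
    treated: StrategyResult, control: StrategyResult, wtp: float
) -> ComparisonResult:
    """ICUR, ICER, INMB and INHB of ``treated`` relative to ``control``.

    Ratios are None when their denominator is zero; net-benefit measures are
    always defined.  Dominance flags mark quadrant membership.
    """
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    dc = treated.cost - control.cost
    du = treated.qalys - control.qalys
    de = treated.lys - control.lys
    icur = dc / du if du != 0 else None
    icer = dc / de if de != 0 else None
    inmb = du * wtp - dc
    return ComparisonResult(
        delta_cost=dc,
        delta_qalys=du,
        delta_lys=de,
        wtp=wtp,
        icur=icur,
        icer=icer,
        inmb=inmb,
        inhb=inmb / wtp,
        dominant=dc < 0 and du > 0,
        dominated=dc > 0 and du < 0,
    )
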