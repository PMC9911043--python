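"""Assemble domain objects from a configuration mapping and evaluate the
full two-strategy comparison (trace -> accrual -> incremental indices)."""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import EngineSettings, LifeTable, StateTrace, run_cohort
from .config import ConfigError
from .economics import (
    ComparisonResult,
    DrugRegimen,
    Patient,
    StrategyConfig,
    StrategyResult,
    UtilitySet,
    accrue_strategy,
    incremental_measures,
)
from .survival import ParametricSurvival

__all__ = ["ModelOutput", "build_settings", "build_patient", "build_utilities",
           "build_survival", "build_strategy", "run_comparison"]

ARMS = ("cbsc", "bsc")
TREATED_ARM, CONTROL_ARM = "cbsc", "bsc"


@dataclass(frozen=True)
class ModelOutput:
    """One full evaluation: per-arm traces and results plus the comparison."""

    treated: StrategyResult
    control: StrategyResult
    comparison: ComparisonResult
    traces: dict[str, StateTrace]


def build_settings(cfg: dict, relax_discount_bound: bool = False) -> EngineSettings:
    s = cfg["settings"]
    rate = float(s["annual_discount_rate"])
    if relax_discount_bound:
        # probabilistic draws from Beta(0.03, 0.97) can leave the
        # deterministic [0, 0.08] range; clamp them back into it
        rate = min(max(rate, 0.0), 0.08)
    return EngineSettings(
        annual_discount_rate=rate,
        start_age=float(s.get("start_age", 45)),
        horizon_cycles=int(s.get("horizon_cycles", 1000)),
        half_cycle_correction=bool(s.get("half_cycle_correction", True)),
    )


def build_patient(cfg: dict) -> Patient:
    p = cfg["patient"]
    return Patient(
        body_weight_kg=float(p["body_weight_kg"]),
        body_surface_area_m2=float(p["body_surface_area_m2"]),
    )


def build_utilities(cfg: dict) -> UtilitySet:
    u = cfg["utilities"]
    return UtilitySet(
        u_pfs=float(u["pfs"]),
        u_pd=float(u["pd"]),
        u_death=float(u.get("death", 0.0)),
        ae_disutility=float(u.get("ae_disutility", 0.0)),
    )


def build_survival(cfg: dict, arm: str, endpoint: str) -> ParametricSurvival:
    spec = cfg["survival"][arm][endpoint]
    return ParametricSurvival(spec["family"], tuple(spec["params"]))


def _build_regimen(cfg: dict, spec: dict | None) -> DrugRegimen | None:
    if spec is None:
        return None
    drug = spec["drug"]
    try:
        unit_cost = float(cfg["drug_costs"][drug])
        unit_size = float(cfg["assumptions"]["unit_sizes"][drug])
    except KeyError as exc:
        raise ConfigError(f"no unit cost/size for drug {drug!r}") from exc
    return DrugRegimen(
        drug=drug,
        dose=float(spec["dose"]),
        admins_per_cycle=int(spec["admins_per_cycle"]),
        unit_cost=unit_cost,
        unit_size=unit_size,
        basis=spec.get("basis", "bsa"),
        round_per=spec.get("round_per", "admin"),
    )


def build_strategy(cfg: dict, arm: str) -> StrategyConfig:
    s = cfg["strategies"][arm]
    assumptions = cfg.get("assumptions", {})
    costs = cfg["costs"]
    sub_regimens = {
        therapy: _build_regimen(cfg, spec)
        for therapy, spec in assumptions.get("subsequent_regimens", {}).items()
    }
    return StrategyConfig(
        name=arm,
        maintenance=_build_regimen(cfg, s.get("maintenance")),
        maintenance_max_cycles=int(s.get("maintenance_max_cycles", 35)),
        concomitant_radiotherapy_prop=float(s["concomitant"]["radiotherapy"]),
        bisphosphonate_prop=float(s["concomitant"]["bisphosphonates"]),
        bisphosphonate_regimen=_build_regimen(
            cfg, assumptions.get("bisphosphonate_regimen")
        ),
        subsequent_props={k: float(v) for k, v in s["subsequent"].items()},
        subsequent_regimens=sub_regimens,
        ae_incidence={k: float(v) for k, v in s["ae_incidence"].items()},
        ae_cost={k: float(v) for k, v in costs["ae"].items()},
        bsc_cost_per_cycle=float(costs["bsc_per_cycle"]),
        lab_cost_per_cycle=float(costs["lab_per_cycle"]),
        imaging_cost=float(costs["imaging"]),
        imaging_interval_cycles=int(assumptions.get("imaging_interval_cycles", 3)),
        radiotherapy_course_cost=float(costs["radiotherapy_course"]),
        pd_therapy_cap_cycles=int(assumptions.get("pd_therapy_cap_cycles", 6)),
    )


def run_comparison(
    cfg: dict,
    table: LifeTable | None = None,
    survival_overrides: dict | None = None,
    relax_discount_bound: bool = False,
) -> ModelOutput:
    """Run both strategies under one configuration and compare them.

    ``survival_overrides`` maps (arm, endpoint) to a survival object exposing
    ``survival(t)``; used by the subgroup analysis to swap in hazard-ratio
    adjusted progression curves.
    """
    settings = build_settings(cfg, relax_discount_bound=relax_discount_bound)
    patient = build_patient(cfg)
    utilities = build_utilities(cfg)
    overrides = survival_overrides or {}

    results: dict[str, StrategyResult] = {}
    traces: dict[str, StateTrace] = {}
    for arm in ARMS:
        pfs = overrides.get((arm, "pfs")) or build_survival(cfg, arm, "pfs")
        os_model = overrides.get((arm, "os")) or build_survival(cfg, arm, "os")
        strategy = build_strategy(cfg, arm)
        trace = run_cohort(
            pfs, os_model, table, settings, ae_split=strategy.ae_any_prob
        )
        traces[arm] = trace
        results[arm] = accrue_strategy(trace, strategy, patient, utilities, settings)

    comparison = incremental_measures(
        results[TREATED_ARM], results[CONTROL_ARM], float(cfg["settings"]["wtp"])
    )
    return ModelOutput(
        treated=results[TREATED_ARM],
        control=results[CONTROL_ARM],
        comparison=comparison,
        traces=traces,
    )
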