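"""Configuration loading, validation and the sampling-distribution audit.

The configuration is a nested mapping (YAML or JSON on disk).  Uncertain
parameters are addressed by dot-separated paths into that mapping, e.g.
``drug_costs.capecitabine`` or ``strategies.cbsc.ae_incidence.anemia``; the
``distributions`` list attaches a probabilistic-sensitivity sampling law to
a path, and ``owsa`` ranges attach deterministic low/high bounds.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import yaml

__all__ = [
    "get_by_path",
    "set_by_path",
    "load_config",
    "save_config",
    "validate_config",
    "audit_distributions",
    "ConfigError",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for schema violations or failed distribution audits."""


def get_by_path(cfg: dict, path: str):
    node = cfg
    for key in path.split("."):
        try:
            node = node[key]
        except (KeyError, TypeError) as exc:
            raise KeyError(f"config path {path!r} not found (at {key!r})") from exc
    return node


def set_by_path(cfg: dict, path: str, value) -> None:
    keys = path.split(".")
    node = cfg
    for key in keys[:-1]:
        node = node[key]
    if keys[-1] not in node:
        raise KeyError(f"config path {path!r} not found")
    node[keys[-1]] = value


# ---------------------------------------------------------------------------
# Schema validation
# ---------------------------------------------------------------------------

_UNIT_INTERVAL_PREFIXES = (
    "utilities.",
    "strategies.cbsc.concomitant.",
    "strategies.bsc.concomitant.",
    "strategies.cbsc.subsequent.",
    "strategies.bsc.subsequent.",
    "strategies.cbsc.ae_incidence.",
    "strategies.bsc.ae_incidence.",
)

_REQUIRED_PATHS = (
    "settings.annual_discount_rate",
    "settings.start_age",
    "settings.horizon_cycles",
    "settings.wtp",
    "patient.body_weight_kg",
    "patient.body_surface_area_m2",
    "survival.cbsc.pfs",
    "survival.cbsc.os",
    "survival.bsc.pfs",
    "survival.bsc.os",
    "utilities.pfs",
    "utilities.pd",
    "costs.bsc_per_cycle",
    "costs.lab_per_cycle",
    "costs.imaging",
    "costs.radiotherapy_course",
    "drug_costs.capecitabine",
    "assumptions.unit_sizes.capecitabine",
)


def _iter_leaves(node, prefix=""):
    if isinstance(node, dict):
        for key, val in node.items():
            yield from _iter_leaves(val, f"{prefix}{key}.")
    else:
        yield prefix.rstrip("."), node


def validate_config(cfg: dict) -> list[str]:
    """Check the schema; returns warnings, raises :class:`ConfigError` with
    every offending key listed on hard violations."""
    problems: list[str] = []
    warnings: list[str] = []

    for path in _REQUIRED_PATHS:
        try:
            get_by_path(cfg, path)
        except KeyError:
            problems.append(f"missing required key {path}")

    for path, value in _iter_leaves(cfg):
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            continue
        if any(path.startswith(p) for p in _UNIT_INTERVAL_PREFIXES):
            if not 0.0 <= value <= 1.0:
                problems.append(f"{path} = {value} outside [0, 1]")
        if path.startswith(("costs.", "drug_costs.")) and value < 0:
            problems.append(f"{path} = {value} is negative")

    rate = cfg.get("settings", {}).get("annual_discount_rate")
    if rate is not None and not 0.0 <= rate <= 0.08:
        problems.append(f"settings.annual_discount_rate = {rate} outside [0, 0.08]")

    if problems:
        raise ConfigError("; ".join(problems))
    return warnings


# ---------------------------------------------------------------------------
# Distribution audit
# ---------------------------------------------------------------------------


def _analytic_mean(kind: str, params) -> float:
    if kind == "beta":
        a, b = params
        return a / (a + b)
    if kind == "gamma":
        shape, rate = params
        return shape / rate
    if kind == "fixed":
        return float(params[0])
    raise ConfigError(f"unknown distribution kind {kind!r}")


def audit_distributions(
    cfg: dict,
    tol: float = 0.01,
    hard_tol: float = 0.05,
    recalibrate: bool | None = None,
) -> list[dict]:
    """Check that every sampling distribution's analytic mean matches the
    baseline value at its path.

    Gamma rows whose printed (rounded) rate leaves the mean off baseline by
    more than ``tol`` are recalibrated in place (rate = shape / baseline)
    when ``recalibrate`` is enabled — the default, controlled by
    ``assumptions.recalibrate_distribution_rates``.  Any residual deviation
    beyond ``hard_tol`` raises :class:`ConfigError`.
    """
    if recalibrate is None:
        recalibrate = bool(
            cfg.get("assumptions", {}).get("recalibrate_distribution_rates", True)
        )
    rows = []
    offenders = []
    for entry in cfg.get("distributions", []):
        path, kind = entry["path"], entry["kind"]
        params = list(entry["params"])
        baseline = float(get_by_path(cfg, path))
        mean = _analytic_mean(kind, params)
        rel = abs(mean - baseline) / abs(baseline) if baseline else abs(mean)
        recal = False
        if rel > tol and kind == "gamma" and recalibrate and baseline > 0:
            entry["params"] = [params[0], params[0] / baseline]
            mean = baseline
            rel = 0.0
            recal = True
            logger.info(
                "recalibrated gamma rate for %s: printed mean %.4g vs baseline %.4g",
                path,
                _analytic_mean(kind, params),
                baseline,
            )
        if rel > hard_tol:
            offenders.append(f"{path}: mean {mean:.4g} vs baseline {baseline:.4g}")
        rows.append(
            {
                "path": path,
                "kind": kind,
                "mean": mean,
                "baseline": baseline,
                "rel_error": rel,
                "recalibrated": recal,
            }
        )
    if offenders:
        raise ConfigError(
            "distribution means deviate from baselines: " + "; ".join(offenders)
        )
    return rows


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def load_config(path, audit: bool = True) -> dict:
    """Read, validate and (optionally) audit a YAML/JSON configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path} did not parse to a mapping")
    validate_config(cfg)
    if audit:
        audit_distributions(cfg)
    return cfg


def save_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def clone(cfg: dict) -> dict:
    return copy.deepcopy(cfg)
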