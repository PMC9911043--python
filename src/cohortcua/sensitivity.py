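"""Deterministic (tornado) and probabilistic sensitivity analyses, and
cost-effectiveness acceptability curves.

All draws flow through one ``numpy.random.Generator`` seeded per run, and
parameters are sampled in the order they appear in the configuration's
``distributions`` list, so identical seeds give identical sample sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import LifeTable
from .config import clone, get_by_path, set_by_path
from .model import run_comparison

__all__ = [
    "DEFAULT_SEED",
    "PsaDistribution",
    "OwsaRange",
    "TornadoEntry",
    "PsaSampleSet",
    "owsa_range",
    "run_owsa",
    "sample_parameter",
    "run_psa",
    "ceac",
]

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20220801


@dataclass(frozen=True)
class PsaDistribution:
    """Sampling law for one parameter: beta(a, b), gamma(shape, rate) with
    mean shape/rate, or a degenerate fixed value."""

    kind: str
    params: tuple[float, ...]
    path: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "gamma", "fixed"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind in ("beta", "gamma") and (
            len(self.params) != 2 or any(p <= 0 for p in self.params)
        ):
            raise ValueError(f"{self.kind} needs two positive parameters")

    def mean(self) -> float:
        if self.kind == "beta":
            a, b = self.params
            return a / (a + b)
        if self.kind == "gamma":
            shape, rate = self.params
            return shape / rate
        return float(self.params[0])

    @classmethod
    def from_entry(cls, entry: dict) -> "PsaDistribution":
        return cls(entry["kind"], tuple(entry["params"]), entry.get("path", ""))


@dataclass(frozen=True)
class OwsaRange:
    path: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low bound exceeds high bound")


@dataclass(frozen=True)
class TornadoEntry:
    path: str
    icur_low: float
    icur_high: float
    failed: bool = False

    @property
    def spread(self) -> float:
        if self.failed:
            return float("nan")
        return abs(self.icur_high - self.icur_low)


@dataclass
class PsaSampleSet:
    """Monte Carlo (delta-cost, delta-QALY) pairs plus the sampled vectors."""

    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    samples: pd.DataFrame
    seed: int
    n_requested: int
    n_failed: int = 0

    @property
    def n(self) -> int:
        return len(self.delta_cost)


# ---------------------------------------------------------------------------
# One-way (tornado) analysis
# ---------------------------------------------------------------------------


def owsa_range(baseline: float, low: float | None = None, high: float | None = None):
    """Default +/-20% band around a baseline, unless explicit bounds given."""
    if not math.isfinite(baseline):
        raise ValueError("baseline must be finite")
    lo = 0.8 * baseline if low is None else float(low)
    hi = 1.2 * baseline if high is None else float(high)
    return (lo, hi)


def _ranges_from_config(cfg: dict) -> list[OwsaRange]:
    out = []
    for entry in cfg.get("owsa", []):
        baseline = float(get_by_path(cfg, entry["path"]))
        lo, hi = owsa_range(baseline, entry.get("low"), entry.get("high"))
        out.append(OwsaRange(entry["path"], lo, hi))
    return out


def _icur_at(cfg: dict, table, path: str, value: float) -> float:
    trial = clone(cfg)
    set_by_path(trial, path, value)
    out = run_comparison(trial, table, relax_discount_bound=True)
    c = out.comparison
    return float("nan") if c.icur is None else c.icur


def run_owsa(
    cfg: dict,
    table: LifeTable | None = None,
    ranges: list[OwsaRange] | None = None,
) -> list[TornadoEntry]:
    """Re-run the full two-strategy model at each parameter's low and high
    bound (all else at baseline); entries sorted by spread, descending.
    Failures are flagged, never silently dropped."""
    ranges = ranges if ranges is not None else _ranges_from_config(cfg)
    entries = []
    for rng_ in ranges:
        try:
            lo = _icur_at(cfg, table, rng_.path, rng_.low)
            hi = _icur_at(cfg, table, rng_.path, rng_.high)
            entries.append(TornadoEntry(rng_.path, lo, hi))
        except Exception as exc:
            logger.warning("one-way analysis failed for %s: %s", rng_.path, exc)
            entries.append(
                TornadoEntry(rng_.path, float("nan"), float("nan"), failed=True)
            )
    entries.sort(key=lambda e: (-(e.spread if not math.isnan(e.spread) else -1.0)))
    return entries


def tornado_frame(entries: list[TornadoEntry], top: int | None = None) -> pd.DataFrame:
    rows = entries[:top] if top else entries
    return pd.DataFrame(
        {
            "parameter": [e.path for e in rows],
            "icur_low": [e.icur_low for e in rows],
            "icur_high": [e.icur_high for e in rows],
            "spread": [e.spread for e in rows],
        }
    )


# ---------------------------------------------------------------------------
# Probabilistic analysis
# ---------------------------------------------------------------------------


def sample_parameter(dist: PsaDistribution, rng: np.random.Generator) -> float:
    if dist.kind == "beta":
        return float(rng.beta(*dist.params))
    if dist.kind == "gamma":
        shape, rate = dist.params
        return float(rng.gamma(shape, 1.0 / rate))
    return float(dist.params[0])


def run_psa(
    cfg: dict,
    table: LifeTable | None = None,
    n: int = 10_000,
    seed: int = DEFAULT_SEED,
    survival_overrides: dict | None = None,
) -> PsaSampleSet:
    """Monte Carlo over the configuration's sampling distributions.

    Each draw samples every distribution independently, rebuilds the model
    and records (delta cost, delta QALYs).  Draws on which the model fails
    are excluded and counted."""
    if n < 1:
        raise ValueError("need at least one draw")
    dists = [PsaDistribution.from_entry(e) for e in cfg.get("distributions", [])]
    rng = np.random.default_rng(seed)
    rows, dcs, dus = [], [], []
    n_failed = 0
    for i in range(n):
        values = {d.path: sample_parameter(d, rng) for d in dists}
        trial = clone(cfg)
        for path, value in values.items():
            set_by_path(trial, path, value)
        try:
            out = run_comparison(
                trial,
                table,
                survival_overrides=survival_overrides,
                relax_discount_bound=True,
            )
        except Exception as exc:
            n_failed += 1
            logger.warning("draw %d excluded: %s", i, exc)
            continue
        rows.append(values)
        dcs.append(out.comparison.delta_cost)
        dus.append(out.comparison.delta_qalys)
    if n_failed:
        logger.warning("%d of %d draws excluded", n_failed, n)
    return PsaSampleSet(
        delta_cost=np.asarray(dcs),
        delta_qalys=np.asarray(dus),
        samples=pd.DataFrame(rows),
        seed=seed,
        n_requested=n,
        n_failed=n_failed,
    )


def ceac(samples: PsaSampleSet, wtp_grid) -> pd.DataFrame:
    """Probability of positive net monetary benefit at each threshold."""
    if samples.n == 0:
        raise ValueError("empty sample set")
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    probs = [
        float(np.mean(samples.delta_qalys * w - samples.delta_cost > 0))
        for w in grid
    ]
    return pd.DataFrame(
        {"wtp": grid, "prob_cbsc": probs, "prob_bsc": [1.0 - p for p in probs]}
    )
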