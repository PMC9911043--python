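"""Synthetic inputs: pseudo individual-patient data with known ground truth,
a Gompertz-Makeham life-table fixture, and the complete baseline model
configuration.

The life-table parameters approximate modern East-Asian adult all-cause
mortality; they are a stand-in, not published values.  Subgroup hazard
ratios other than the trial-level one are illustrative placeholders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import LifeTable
from .survival import KMCurve, ParametricSurvival

__all__ = [
    "SimulationSpec",
    "simulate_ipd",
    "km_estimate",
    "synthetic_life_table",
    "baseline_fixture",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth plus censoring scheme for pseudo-IPD simulation."""

    model: ParametricSurvival
    n: int
    admin_censor_time: float = math.inf
    random_censor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one subject")
        if self.admin_censor_time < 0 or self.random_censor_rate < 0:
            raise ValueError("censoring parameters must be >= 0")


def _inverse_survival(model: ParametricSurvival, u: np.ndarray) -> np.ndarray:
    """Solve S(t) = u for each u in (0, 1); closed form per family."""
    p = model.params
    if model.family == "exponential":
        return -np.log(u) / p[0]
    if model.family == "weibull":
        return (-np.log(u) / p[0]) ** (1.0 / p[1])
    if model.family == "loglogistic":
        lam, gam = p
        return ((1.0 - u) / (lam * u)) ** (1.0 / gam)
    if model.family == "lognormal":
        mu, sigma = p
        return np.exp(mu + sigma * stats.norm.ppf(1.0 - u))
    rate, shape = p  # gompertz
    return np.log1p(shape * (-np.log(u)) / rate) / shape


def simulate_ipd(spec: SimulationSpec) -> list[tuple[float, int]]:
    """Draw (time, event) pairs from the true model under administrative and
    independent exponential censoring; reproducible under the seed."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(1e-12, 1.0 - 1e-12, size=spec.n)
    event_times = _inverse_survival(spec.model, u)
    censor = np.full(spec.n, spec.admin_censor_time)
    if spec.random_censor_rate > 0:
        censor = np.minimum(
            censor, rng.exponential(1.0 / spec.random_censor_rate, size=spec.n)
        )
    times = np.minimum(event_times, censor)
    events = (event_times <= censor).astype(int)
    return list(zip(times.tolist(), events.tolist()))


def km_estimate(ipd) -> KMCurve:
    """Product-limit estimate of the survival curve from (time, event) pairs."""
    arr = np.asarray(list(ipd), dtype=float)
    if arr.size == 0 or arr[:, 1].sum() < 1:
        raise ValueError("need at least one observed event")
    kmf = KaplanMeierFitter()
    kmf.fit(arr[:, 0], event_observed=arr[:, 1])
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = None
    try:
        at_risk = tuple(
            int(kmf.event_table["at_risk"].reindex(times, method="ffill").iloc[i])
            for i in range(len(times))
        )
    except Exception:  # pragma: no cover - cosmetic only
        at_risk = None
    return KMCurve(tuple(times), tuple(surv), at_risk)


def synthetic_life_table(
    makeham_a: float = 5e-4,
    gompertz_b: float = 3e-5,
    gompertz_c: float = 0.09,
    max_age: int = 100,
    min_age: int = 0,
) -> LifeTable:
    """Gompertz-Makeham annual death probabilities:
    qx = 1 - exp(-(a + b*exp(c*age))), closed at ``max_age`` with qx = 1."""
    ages = np.arange(min_age, max_age + 1)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_c * ages)
    qx = 1.0 - np.exp(-hazard)
    if np.any(qx < 0) or np.any(qx > 1):
        raise ValueError("parameters produce qx outside [0, 1]")
    qx[-1] = 1.0
    return LifeTable(ages, qx)


# ---------------------------------------------------------------------------
# Baseline configuration fixture
# ---------------------------------------------------------------------------


def baseline_fixture() -> dict:
    """The complete baseline configuration: survival parameters, therapy
    proportions, adverse-event incidences, unit costs, utilities, sampling
    distributions and one-way ranges, plus clearly namespaced modelling
    assumptions (unit sizes, recurrence intervals, start age defaults)."""
    cfg: dict = {
        "settings": {
            "annual_discount_rate": 0.03,
            "start_age": 45,
            "horizon_cycles": 1000,
            "half_cycle_correction": True,
            "wtp": 36007.0,
        },
        "patient": {"body_weight_kg": 65.0, "body_surface_area_m2": 1.72},
        "survival": {
            "cbsc": {
                "os": {"family": "loglogistic", "params": [0.006220, 1.070002]},
                "pfs": {"family": "loglogistic", "params": [0.034595, 0.840056]},
            },
            "bsc": {
                "os": {"family": "loglogistic", "params": [0.0051219, 1.3690167]},
                "pfs": {"family": "loglogistic", "params": [0.11712, 0.80840]},
            },
        },
        "strategies": {
            "cbsc": {
                "maintenance": {
                    "drug": "capecitabine",
                    "dose": 1000.0,
                    "basis": "bsa",
                    "admins_per_cycle": 28,  # twice daily, days 1-14
                    "round_per": "admin",
                },
                "maintenance_max_cycles": 35,  # 2-year cap at 21-day cycles
                "concomitant": {"radiotherapy": 0.528, "bisphosphonates": 0.512},
                "subsequent": {
                    "chemotherapy": 0.608,
                    "radiotherapy": 0.087,
                    "immunotherapy": 0.087,
                },
                "ae_incidence": {
                    "anemia": 0.120,
                    "neutropenia": 0.020,
                    "thrombocytopenia": 0.020,
                    "hand_foot_syndrome": 0.100,
                    "nausea_vomiting": 0.060,
                    "mucositis": 0.040,
                    "fatigue": 0.040,
                },
            },
            "bsc": {
                "maintenance": None,
                "concomitant": {"radiotherapy": 0.476, "bisphosphonates": 0.488},
                "subsequent": {
                    "chemotherapy": 0.467,
                    "radiotherapy": 0.054,
                    "immunotherapy": 0.162,
                },
                "ae_incidence": {
                    "anemia": 0.021,
                    "neutropenia": 0.0,
                    "thrombocytopenia": 0.0,
                    "hand_foot_syndrome": 0.0,
                    "nausea_vomiting": 0.0,
                    "mucositis": 0.0,
                    "fatigue": 0.0,
                },
            },
        },
        "drug_costs": {
            "capecitabine": 1.91,
            "paclitaxel": 27.94,
            "cisplatin": 3.00,
            "bisphosphonates": 250.47,
            "docetaxel": 75.56,
            "gemcitabine": 26.05,
            "irinotecan": 159.20,
            "camrelizumab": 458.93,
            "toripalimab": 142.01,
            "nivolumab": 1451.41,
            "pembrolizumab": 2808.46,
        },
        "costs": {
            "bsc_per_cycle": 274.00,
            "lab_per_cycle": 82.59,
            "imaging": 176.49,
            "radiotherapy_course": 3690.64,
            "ae": {
                "anemia": 6434.00,
                "neutropenia": 466.00,
                "thrombocytopenia": 3551.70,
                "hand_foot_syndrome": 773.64,
                "nausea_vomiting": 44.30,
                "mucositis": 3719.0,
                "fatigue": 107.01,
            },
        },
        "utilities": {"pfs": 0.760, "pd": 0.350, "death": 0.0, "ae_disutility": 0.0},
        "assumptions": {
            # everything below is a modelling default, not a published value
            "recalibrate_distribution_rates": True,
            "imaging_interval_cycles": 3,
            "pd_therapy_cap_cycles": 6,
            "unit_sizes": {  # mg per tablet/vial
                "capecitabine": 500,
                "paclitaxel": 30,
                "cisplatin": 10,
                "bisphosphonates": 4,
                "docetaxel": 20,
                "gemcitabine": 200,
                "irinotecan": 40,
                "camrelizumab": 200,
                "toripalimab": 80,
                "nivolumab": 100,
                "pembrolizumab": 100,
            },
            "subsequent_regimens": {
                "chemotherapy": {
                    "drug": "gemcitabine",
                    "dose": 1250.0,
                    "basis": "bsa",
                    "admins_per_cycle": 2,
                    "round_per": "cycle",
                },
                "immunotherapy": {
                    "drug": "camrelizumab",
                    "dose": 200.0,
                    "basis": "flat",
                    "admins_per_cycle": 1,
                    "round_per": "cycle",
                },
            },
            "bisphosphonate_regimen": {
                "drug": "bisphosphonates",
                "dose": 4.0,
                "basis": "flat",
                "admins_per_cycle": 1,
                "round_per": "cycle",
            },
            "life_table": {
                "makeham_a": 5e-4,
                "gompertz_b": 3e-5,
                "gompertz_c": 0.09,
                "max_age": 100,
            },
        },
        # trial-level hazard ratio is published; the named subgroup rows are
        # placeholders (the source presents them only graphically)
        "subgroups": [
            {"name": "overall", "hr": 0.44, "hr_low": 0.26, "hr_high": 0.74},
            {"name": "placeholder_strong_benefit", "hr": 0.35, "hr_low": 0.20, "hr_high": 0.60},
            {"name": "placeholder_moderate_benefit", "hr": 0.55, "hr_low": 0.35, "hr_high": 0.85},
            {"name": "placeholder_weak_benefit", "hr": 0.75, "hr_low": 0.50, "hr_high": 1.00},
        ],
        "distributions": _baseline_distributions(),
        "owsa": _baseline_owsa_ranges(),
    }
    return cfg


def _baseline_distributions() -> list[dict]:
    beta = lambda path, a, b: {"path": path, "kind": "beta", "params": [a, b]}
    gamma = lambda path, s, r: {"path": path, "kind": "gamma", "params": [s, r]}
    return [
        beta("strategies.cbsc.concomitant.radiotherapy", 0.528, 0.472),
        beta("strategies.cbsc.concomitant.bisphosphonates", 0.512, 0.488),
        beta("strategies.bsc.concomitant.radiotherapy", 0.476, 0.524),
        beta("strategies.bsc.concomitant.bisphosphonates", 0.488, 0.512),
        beta("strategies.cbsc.subsequent.chemotherapy", 0.608, 0.392),
        beta("strategies.cbsc.subsequent.radiotherapy", 0.087, 0.913),
        beta("strategies.cbsc.subsequent.immunotherapy", 0.087, 0.913),
        beta("strategies.bsc.subsequent.chemotherapy", 0.467, 0.533),
        beta("strategies.bsc.subsequent.radiotherapy", 0.054, 0.946),
        beta("strategies.bsc.subsequent.immunotherapy", 0.162, 0.838),
        beta("strategies.cbsc.ae_incidence.anemia", 6, 44),
        beta("strategies.cbsc.ae_incidence.neutropenia", 1, 49),
        beta("strategies.cbsc.ae_incidence.thrombocytopenia", 1, 49),
        beta("strategies.cbsc.ae_incidence.hand_foot_syndrome", 5, 45),
        beta("strategies.cbsc.ae_incidence.nausea_vomiting", 3, 47),
        beta("strategies.cbsc.ae_incidence.mucositis", 2, 48),
        beta("strategies.cbsc.ae_incidence.fatigue", 2, 48),
        beta("strategies.bsc.ae_incidence.anemia", 1, 47),
        gamma("drug_costs.capecitabine", 96.04, 50.28),
        gamma("drug_costs.paclitaxel", 96.04, 3.44),
        gamma("drug_costs.cisplatin", 96.04, 32.01),
        gamma("drug_costs.bisphosphonates", 96.04, 0.383),
        gamma("drug_costs.docetaxel", 96.04, 1.27),
        gamma("drug_costs.gemcitabine", 96.04, 3.69),
        gamma("drug_costs.irinotecan", 96.04, 0.60),
        gamma("drug_costs.camrelizumab", 96.04, 0.21),
        gamma("drug_costs.toripalimab", 96.04, 0.68),
        gamma("drug_costs.nivolumab", 96.04, 0.07),
        gamma("drug_costs.pembrolizumab", 96.04, 0.03),
        gamma("costs.radiotherapy_course", 96.04, 0.03),
        gamma("patient.body_weight_kg", 15.37, 0.24),
        gamma("patient.body_surface_area_m2", 96.04, 55.84),
        gamma("costs.bsc_per_cycle", 96.04, 0.35),
        gamma("costs.imaging", 96.03, 0.54),
        gamma("costs.lab_per_cycle", 96.02, 1.16),
        beta("settings.annual_discount_rate", 0.03, 0.97),
        gamma("costs.ae.anemia", 96.04, 0.01),
        gamma("costs.ae.neutropenia", 96.04, 0.21),
        gamma("costs.ae.thrombocytopenia", 96.04, 0.03),
        gamma("costs.ae.hand_foot_syndrome", 86.37, 0.12),
        gamma("costs.ae.nausea_vomiting", 96.04, 2.17),
        gamma("costs.ae.mucositis", 96.04, 0.03),
        gamma("costs.ae.fatigue", 96.04, 0.98),
        beta("utilities.pfs", 0.76, 0.24),
        beta("utilities.pd", 0.35, 0.65),
    ]


def _baseline_owsa_ranges() -> list[dict]:
    """One-way ranges: +/-20% of baseline except where an explicit printed
    range deviates (discount rate 0-8%, body weight +/-50%)."""
    paths = [d["path"] for d in _baseline_distributions()]
    ranges = []
    for path in paths:
        entry: dict = {"path": path}
        if path == "settings.annual_discount_rate":
            entry.update(low=0.0, high=0.08)
        elif path == "patient.body_weight_kg":
            entry.update(low=32.5, high=97.5)
        ranges.append(entry)
    return ranges
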