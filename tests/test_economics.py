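import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cohortcua.cohort import EngineSettings, run_cohort
from cohortcua.economics import (
    DrugRegimen,
    Patient,
    StrategyConfig,
    StrategyResult,
    UtilitySet,
    accrue,
    accrue_strategy,
    expected_ae_cost,
    incremental_measures,
    regimen_cycle_cost,
    regimen_cycle_quantity,
)
from cohortcua.survival import ParametricSurvival

from conftest import WTP

PATIENT = Patient(body_weight_kg=65.0, body_surface_area_m2=1.72)

CAPE = DrugRegimen(
    drug="capecitabine",
    dose=1000.0,
    admins_per_cycle=28,
    unit_cost=1.91,
    unit_size=500.0,
    basis="bsa",
    round_per="admin",
)

CBSC_AE_INCIDENCE = {
    "anemia": 0.12,
    "neutropenia": 0.02,
    "thrombocytopenia": 0.02,
    "hand_foot_syndrome": 0.10,
    "nausea_vomiting": 0.06,
    "mucositis": 0.04,
    "fatigue": 0.04,
}
AE_COSTS = {
    "anemia": 6434.00,
    "neutropenia": 466.00,
    "thrombocytopenia": 3551.70,
    "hand_foot_syndrome": 773.64,
    "nausea_vomiting": 44.30,
    "mucositis": 3719.0,
    "fatigue": 107.01,
}


# ---------------------------------------------------------------------------
# regimen arithmetic
# ---------------------------------------------------------------------------


def test_capecitabine_cycle_amount_and_units():
    # 1000 mg/m2 x 1.72 m2 x 2/day x 14 days = 48,160 mg per cycle
    amount = CAPE.dose * PATIENT.body_surface_area_m2 * CAPE.admins_per_cycle
    assert amount == pytest.approx(48160.0)
    # 1720 mg/administration -> 4 x 500 mg tablets, 28 administrations
    assert regimen_cycle_quantity(CAPE, PATIENT) == 112
    assert regimen_cycle_cost(CAPE, PATIENT) == pytest.approx(112 * 1.91)


def test_flat_dose_single_unit():
    reg = DrugRegimen("x", 200.0, 1, 10.0, 200.0, basis="flat")
    assert regimen_cycle_quantity(reg, PATIENT) == 1


def test_zero_dose_zero_units():
    reg = DrugRegimen("x", 0.0, 3, 10.0, 200.0, basis="flat")
    assert regimen_cycle_quantity(reg, PATIENT) == 0


def test_vial_rounding_per_cycle_vs_admin():
    reg_admin = DrugRegimen("x", 150.0, 2, 5.0, 100.0, basis="flat", round_per="admin")
    reg_cycle = DrugRegimen("x", 150.0, 2, 5.0, 100.0, basis="flat", round_per="cycle")
    assert regimen_cycle_quantity(reg_admin, PATIENT) == 4  # ceil(1.5)*2
    assert regimen_cycle_quantity(reg_cycle, PATIENT) == 3  # ceil(3.0)


def test_weight_basis():
    reg = DrugRegimen("x", 2.0, 1, 1.0, 10.0, basis="weight", round_per="cycle")
    assert regimen_cycle_quantity(reg, PATIENT) == 13  # 130 mg / 10


def test_unknown_basis_rejected():
    with pytest.raises(ValueError):
        DrugRegimen("x", 1.0, 1, 1.0, 1.0, basis="imperial")


# ---------------------------------------------------------------------------
# adverse-event expectation
# ---------------------------------------------------------------------------


def test_expected_ae_cost_cbsc():
    assert expected_ae_cost(CBSC_AE_INCIDENCE, AE_COSTS) == pytest.approx(
        1085.50, abs=0.01
    )


def test_expected_ae_cost_bsc():
    assert expected_ae_cost({"anemia": 0.021}, AE_COSTS) == pytest.approx(
        135.11, abs=0.01
    )


def test_expected_ae_cost_zero_and_missing():
    assert expected_ae_cost({k: 0.0 for k in CBSC_AE_INCIDENCE}, AE_COSTS) == 0.0
    with pytest.raises(KeyError):
        expected_ae_cost({"sepsis": 0.1}, AE_COSTS)


# ---------------------------------------------------------------------------
# accrue
# ---------------------------------------------------------------------------


def _exp_trace(r_pfs=0.2, r_os=0.1, horizon=300, rate=0.0, hcc=True):
    settings = EngineSettings(
        annual_discount_rate=rate, horizon_cycles=horizon, half_cycle_correction=hcc
    )
    return run_cohort(
        ParametricSurvival("exponential", (r_pfs,)),
        ParametricSurvival("exponential", (r_os,)),
        None,
        settings,
    )


def test_unit_utilities_give_lys():
    trace = _exp_trace(rate=0.0)
    cyl = trace.settings.cycle_years
    qalys = accrue(trace, {"pfs_no_ae": cyl, "pfs_ae": cyl, "pd": cyl})
    lys = accrue(trace, {s: cyl for s in ("pfs_no_ae", "pfs_ae", "pd")})
    assert qalys == pytest.approx(lys, rel=1e-12)


def test_constant_occupancy_one_year_utility():
    trace = _exp_trace()
    # constant full occupancy of a single state, zero discount:
    # accrual per cycle is u * cycle_years regardless of the trace shape
    occ = np.zeros_like(trace.occupancy)
    occ[:, 0] = 1.0
    trace.occupancy = occ
    trace.discount_factors = np.ones_like(trace.discount_factors)
    u = 0.76
    total = accrue(trace, {"pfs_no_ae": u * trace.settings.cycle_years})
    years = trace.n_cycles * trace.settings.cycle_years
    assert total / years == pytest.approx(u, rel=1e-12)


def test_geometric_value_accrual_oracle():
    r, rate, v = 0.15, 0.03, 123.0
    trace = _exp_trace(r_pfs=r, r_os=r, horizon=1000, rate=rate, hcc=False)
    q = math.exp(-r)
    d = (1 + rate) ** (-21.0 / 365.25)
    total = accrue(trace, {"pfs_no_ae": v, "pfs_ae": v, "pd": v})
    T = trace.n_cycles
    assert total == pytest.approx(v * q * d * (1 - (q * d) ** T) / (1 - q * d), abs=1e-8)


def test_accrue_dimension_mismatch_rejected():
    trace = _exp_trace()
    with pytest.raises(ValueError):
        accrue(trace, np.zeros((3, 4)))


# ---------------------------------------------------------------------------
# accrue_strategy
# ---------------------------------------------------------------------------


def _strategy(**kw):
    base = dict(
        name="test",
        maintenance=CAPE,
        maintenance_max_cycles=35,
        concomitant_radiotherapy_prop=0.5,
        bisphosphonate_prop=0.5,
        bisphosphonate_regimen=DrugRegimen(
            "bis", 4.0, 1, 250.47, 4.0, basis="flat", round_per="cycle"
        ),
        subsequent_props={"chemotherapy": 0.6, "radiotherapy": 0.1},
        subsequent_regimens={
            "chemotherapy": DrugRegimen(
                "gem", 1250.0, 2, 26.05, 200.0, basis="bsa", round_per="cycle"
            )
        },
        ae_incidence=CBSC_AE_INCIDENCE,
        ae_cost=AE_COSTS,
        bsc_cost_per_cycle=274.0,
        lab_cost_per_cycle=82.59,
        imaging_cost=176.49,
        radiotherapy_course_cost=3690.64,
    )
    base.update(kw)
    return StrategyConfig(**base)


def test_qalys_bounded_by_lys():
    trace = _exp_trace()
    res = accrue_strategy(trace, _strategy(), PATIENT, UtilitySet())
    assert 0 < res.qalys <= res.lys
    assert res.cost > 0
    assert res.qalys == pytest.approx(res.qalys_pfs + res.qalys_pd, rel=1e-12)


def test_cost_monotone_in_unit_cost():
    trace = _exp_trace()
    lo = accrue_strategy(trace, _strategy(bsc_cost_per_cycle=100.0), PATIENT, UtilitySet())
    hi = accrue_strategy(trace, _strategy(bsc_cost_per_cycle=200.0), PATIENT, UtilitySet())
    assert hi.cost > lo.cost
    assert hi.qalys == pytest.approx(lo.qalys, rel=1e-12)


def test_qalys_monotone_in_utility():
    trace = _exp_trace()
    lo = accrue_strategy(trace, _strategy(), PATIENT, UtilitySet(u_pfs=0.6))
    hi = accrue_strategy(trace, _strategy(), PATIENT, UtilitySet(u_pfs=0.9))
    assert hi.qalys > lo.qalys
    assert hi.cost == pytest.approx(lo.cost, rel=1e-12)


def test_maintenance_cap_limits_drug_cost():
    trace = _exp_trace(r_pfs=0.001, r_os=0.0005, horizon=200)  # long PFS
    short = accrue_strategy(
        trace, _strategy(maintenance_max_cycles=10), PATIENT, UtilitySet()
    )
    long = accrue_strategy(
        trace, _strategy(maintenance_max_cycles=100), PATIENT, UtilitySet()
    )
    assert short.cost_components["maintenance_drug"] < long.cost_components[
        "maintenance_drug"
    ]


def test_zero_discount_lys_equal_person_time():
    trace = _exp_trace(rate=0.0)
    res = accrue_strategy(trace, _strategy(), PATIENT, UtilitySet())
    alive_pt = float(np.trapezoid(trace.alive))
    assert res.lys == pytest.approx(alive_pt * trace.settings.cycle_years, rel=1e-10)


# ---------------------------------------------------------------------------
# incremental_measures
# ---------------------------------------------------------------------------


def _result(cost, qalys, lys, name="arm"):
    return StrategyResult(name=name, cost=cost, qalys=qalys, lys=lys)


def test_published_increments_reproduce_indices():
    treated = _result(9734.0, 1.16, 1.56)
    control = _result(0.0, 0.0, 0.0)
    cmp = incremental_measures(treated, control, WTP)
    assert round(cmp.icur) == 8391
    assert round(cmp.icer) == 6240
    assert round(cmp.inmb) == 32034
    assert round(cmp.inhb, 2) == 0.89


def test_zero_deltas_degenerate():
    cmp = incremental_measures(_result(5.0, 1.0, 2.0), _result(5.0, 1.0, 2.0), WTP)
    assert cmp.icur is None and cmp.icer is None
    assert cmp.inmb == 0.0 and cmp.inhb == 0.0


def test_dominance_flags():
    assert incremental_measures(_result(10, 2, 2), _result(20, 1, 1), WTP).dominant
    assert incremental_measures(_result(20, 1, 1), _result(10, 2, 2), WTP).dominated


def test_wtp_must_be_positive():
    with pytest.raises(ValueError):
        incremental_measures(_result(1, 1, 1), _result(0, 0, 0), 0.0)


@given(
    st.floats(-1e5, 1e5),
    st.floats(-10, 10),
    st.floats(1e3, 1e6),
)
def test_inhb_wtp_identity(dc, du, wtp):
    cmp = incremental_measures(_result(dc, du, du), _result(0, 0, 0), wtp)
    assert cmp.inhb * wtp == pytest.approx(cmp.inmb, rel=1e-12, abs=1e-9)
    if abs(du) > 1e-9:
        assert cmp.icur * du == pytest.approx(dc, rel=1e-9, abs=1e-9)


def test_icur_invariant_under_shared_cost():
    a = incremental_measures(_result(1000, 2, 3), _result(400, 1, 2), WTP)
    b = incremental_measures(_result(1500, 2, 3), _result(900, 1, 2), WTP)
    assert a.icur == pytest.approx(b.icur, rel=1e-12)


def test_utility_bounds_enforced():
    with pytest.raises(ValueError):
        UtilitySet(u_pfs=1.3)
    with pytest.raises(ValueError):
        StrategyConfig(name="x", ae_incidence={"anemia": 1.5})
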