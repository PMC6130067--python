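"""Combined two-compartment model: fixed point, split identities, inversion,
and brute-force oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acidbase import (
    BloodSpec,
    ConvergenceError,
    DomainError,
    be_from_ph,
    nsid,
    sid_composition,
    solve_combined,
)
from helpers import oracle_combined_ph


@pytest.mark.parametrize(
    ("alb", "pi", "expected"),
    [(44.0, 1.15, 38.797), (0.0, 0.0, 24.422), (22.0, 1.15, 32.655)],
)
def test_nsid_examples(alb, pi, expected):
    assert nsid(alb, pi) == pytest.approx(expected, abs=1e-3)


@pytest.mark.parametrize("hct", [0.0, 0.2, 0.45, 0.7])
@pytest.mark.parametrize(("alb", "pi"), [(44.0, 1.15), (0.0, 0.0), (70.0, 2.5)])
def test_standard_state_fixed_point(hct, alb, pi):
    """BE=0 at pCO2 40 gives pH 7.400 and zero ion transfer for any
    hematocrit/albumin/phosphate: both submodels share the anchor."""
    sol = solve_combined(BloodSpec(be=0.0, pco2=40.0, hct=hct, alb=alb, pi=pi))
    assert sol.ph == pytest.approx(7.400, abs=1e-6)
    assert sol.z_ti == pytest.approx(0.0, abs=1e-6)


def test_split_identities_hold_exactly():
    for be in (-18.0, -5.0, 3.0, 20.0):
        sol = solve_combined(BloodSpec(be=be, pco2=57.0, hct=0.38))
        assert sol.be_hct1 - sol.be_hct0 == pytest.approx(sol.z_ti, abs=1e-12)
        assert sol.sid == pytest.approx(sol.nsid + sol.be_hct0, abs=1e-12)
        assert abs(sol.residual) < 1e-9


@pytest.mark.parametrize(
    ("spec", "expected_ph"),
    [
        (BloodSpec(be=0.0, pco2=80.0, hct=0.45), 7.185501),   # frozen from oracle
        (BloodSpec(be=-10.0, pco2=40.0, hct=0.45), 7.208015),
    ],
)
def test_regression_fixtures_from_grid_oracle(spec, expected_ph):
    sol = solve_combined(spec)
    assert sol.ph == pytest.approx(expected_ph, abs=1e-6)
    oracle = oracle_combined_ph(spec.be, spec.pco2, spec.hct, spec.alb, spec.pi)
    assert sol.ph == pytest.approx(oracle, abs=1e-6)


def test_acidosis_direction():
    assert solve_combined(BloodSpec(be=-10.0)).ph < 7.40


def test_be_from_ph_is_exact_inverse():
    for be in np.arange(-25.0, 26.0, 5.0):
        for pco2 in (15.0, 40.0, 95.0):
            for hct in (0.2, 0.45, 0.6):
                sol = solve_combined(BloodSpec(be=be, pco2=pco2, hct=hct))
                assert be_from_ph(sol.ph, pco2, hct) == pytest.approx(be, abs=1e-6)


def test_be_from_ph_standard_state():
    assert be_from_ph(7.400, 40.0, 0.45) == pytest.approx(0.0, abs=1e-9)


def test_be_from_ph_agrees_with_bisection_on_be():
    """Independent check of the algebraic inverse: bisect solve_combined on BE."""
    target_ph = 7.20
    lo, hi = -30.0, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if solve_combined(BloodSpec(be=mid)).ph < target_ph:
            lo = mid
        else:
            hi = mid
    assert be_from_ph(target_ph, 40.0, 0.45) == pytest.approx(
        0.5 * (lo + hi), abs=1e-6)


def test_ph_monotone_in_be_and_pco2():
    for hct in (0.2, 0.45, 0.6):
        phs = [solve_combined(BloodSpec(be=b, hct=hct)).ph
               for b in np.arange(-25, 26, 5)]
        assert all(np.diff(phs) > 0)
        phs = [solve_combined(BloodSpec(be=0.0, pco2=p, hct=hct)).ph
               for p in (10, 20, 40, 80, 150)]
        assert all(np.diff(phs) < 0)


def test_erythrocytes_buffer_co2_titration():
    """Full blood deviates less from 7.40 under a pCO2 swing than
    erythrocyte-free plasma at the same base excess."""
    from acidbase import plasma_ph

    for pco2 in (20.0, 80.0):
        full = solve_combined(BloodSpec(be=0.0, pco2=pco2, hct=0.45)).ph
        plasma = plasma_ph(nsid(44.0, 1.15), pco2, 44.0, 1.15)
        assert abs(full - 7.40) < abs(plasma - 7.40)


def test_sid_is_not_independent_of_pco2_in_full_blood():
    sids = [solve_combined(BloodSpec(be=0.0, pco2=p, hct=0.45)).sid
            for p in np.arange(20.0, 80.1, 10.0)]
    assert all(np.diff(sids) > 0)  # strictly monotone, hence non-constant


def test_sid_composition_sums_and_standard_values():
    sol = solve_combined(BloodSpec(be=0.0))
    comp = sid_composition(sol)
    assert comp["hco3"] == pytest.approx(24.422, abs=1e-3)
    assert comp["alb_charge"] == pytest.approx(12.285, abs=1e-3)
    assert comp["pi_charge"] == pytest.approx(2.090, abs=1e-3)
    sol2 = solve_combined(BloodSpec(be=0.0, pco2=80.0))
    comp2 = sid_composition(sol2)
    assert sum(comp2.values()) == pytest.approx(sol2.sid, abs=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    be=st.floats(-25.0, 25.0),
    pco2=st.floats(12.0, 140.0),
    hct=st.floats(0.0, 0.7),
)
def test_solution_invariants_property(be, pco2, hct):
    sol = solve_combined(BloodSpec(be=be, pco2=pco2, hct=hct))
    assert sol.be_hct1 - sol.be_hct0 == pytest.approx(sol.z_ti, abs=1e-9)
    assert sol.sid == pytest.approx(sol.nsid + sol.be_hct0, abs=1e-9)
    assert be_from_ph(sol.ph, pco2, hct) == pytest.approx(be, abs=1e-6)


def test_degenerate_hematocrit_rejected():
    with pytest.raises(DomainError, match="hematocrit"):
        BloodSpec(be=0.0, hct=1.0)
    with pytest.raises(DomainError):
        BloodSpec(be=0.0, hct=-0.1)


def test_unsolvable_spec_reports_residuals():
    with pytest.raises(ConvergenceError, match="residual"):
        solve_combined(BloodSpec(be=2000.0))
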