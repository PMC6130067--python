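"""Plasma compartment: charge model, electroneutrality, and pH inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acidbase import (
    DomainError,
    ConvergenceError,
    albumin_charge,
    hco3_conc,
    phosphate_charge,
    plasma_ph,
    plasma_sid,
    plasma_state,
)

PH_GRID = np.arange(6.8, 7.8001, 0.05)
PCO2_GRID = [20.0, 40.0, 80.0]
ALB_GRID = [0.0, 22.0, 44.0, 88.0]
PI_GRID = [0.0, 1.15, 2.3]


@pytest.mark.parametrize(
    ("ph", "pco2", "expected"),
    [
        (7.40, 40.0, 24.422),   # standard state: 0.0306*40*10^1.3
        (6.10, 40.0, 1.224),    # pH = pK makes the power term unity
        (7.40, 0.0, 0.0),       # no gas, no bicarbonate
    ],
)
def test_hco3_conc_examples(ph, pco2, expected):
    assert hco3_conc(ph, pco2) == pytest.approx(expected, abs=1e-3)


@pytest.mark.parametrize(
    ("func", "ph", "conc", "expected"),
    [
        (albumin_charge, 7.40, 44.0, 12.2848),
        (albumin_charge, 7.40, 0.0, 0.0),
        (albumin_charge, 0.631 / 0.123, 44.0, 0.0),  # root of the linear form
        (phosphate_charge, 7.40, 1.15, 2.09024),
        (phosphate_charge, 7.40, 0.0, 0.0),
        (phosphate_charge, 0.469 / 0.309, 1.15, 0.0),
    ],
)
def test_weak_buffer_charge_examples(func, ph, conc, expected):
    assert func(ph, conc) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    ("ph", "pco2", "alb", "pi", "expected"),
    [
        (7.40, 40.0, 44.0, 1.15, 38.797),  # 24.422 + 12.285 + 2.090
        (7.40, 40.0, 0.0, 0.0, 24.422),
        (6.10, 40.0, 0.0, 0.0, 1.224),
    ],
)
def test_plasma_sid_examples(ph, pco2, alb, pi, expected):
    assert plasma_sid(ph, pco2, alb, pi) == pytest.approx(expected, abs=1e-3)


def test_plasma_ph_inverts_standard_state():
    sid = plasma_sid(7.40, 40.0, 44.0, 1.15)
    assert plasma_ph(sid, 40.0, 44.0, 1.15) == pytest.approx(7.400, abs=1e-9)
    assert plasma_ph(24.422, 40.0, 0.0, 0.0) == pytest.approx(7.400, abs=1e-4)


def test_roundtrip_and_monotonicity_over_validated_grid():
    """plasma_ph inverts plasma_sid to 1e-7 and the SID is strictly increasing
    in pH at every grid combination."""
    for pco2 in PCO2_GRID:
        for alb in ALB_GRID:
            for pi in PI_GRID:
                sids = [plasma_sid(ph, pco2, alb, pi) for ph in PH_GRID]
                assert all(np.diff(sids) > 0), (pco2, alb, pi)
                for ph, sid in zip(PH_GRID[::4], sids[::4]):
                    assert plasma_ph(sid, pco2, alb, pi) == pytest.approx(
                        ph, abs=1e-7)


def test_electroneutrality_decomposition_is_exact():
    st_ = plasma_state(7.21, 63.0, 31.0, 1.8)
    assert st_.sid == st_.hco3 + st_.alb_charge + st_.pi_charge


@pytest.mark.parametrize(
    ("func", "args"),
    [
        (hco3_conc, (7.4, -1.0)),
        (albumin_charge, (7.4, -5.0)),
        (phosphate_charge, (7.4, -0.1)),
        (plasma_sid, (7.4, -1.0, 44.0, 1.15)),
    ],
)
def test_negative_inputs_rejected(func, args):
    with pytest.raises(DomainError):
        func(*args)


def test_plasma_ph_reports_unreachable_sid():
    with pytest.raises(ConvergenceError, match="SID=1000"):
        plasma_ph(1000.0, 40.0, 44.0, 1.15)
    with pytest.raises(ConvergenceError):
        plasma_ph(-50.0, 40.0, 44.0, 1.15)


@settings(derandomize=True, max_examples=60)
@given(
    ph=st.floats(6.5, 8.0),
    pco2=st.floats(15.0, 120.0),
    alb=st.floats(0.0, 90.0),
    pi=st.floats(0.0, 3.0),
)
def test_inverse_function_property(ph, pco2, alb, pi):
    sid = plasma_sid(ph, pco2, alb, pi)
    assert plasma_ph(sid, pco2, alb, pi) == pytest.approx(ph, abs=1e-7)
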