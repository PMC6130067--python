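"""Physicochemical plasma compartment (the HCT0 limit of blood).

Plasma pH is determined by the strong ion difference (SID), pCO2 and the weak
non-carbonate buffers (albumin, phosphate) following the Stewart approach in
its simple-Fencl form.  Electroneutrality ties the effective SID to the sum of
the bicarbonate, albumin and phosphate charges:

    SID = [HCO3-] + Q_alb(pH) + Q_pi(pH)

with Henderson-Hasselbalch bicarbonate [HCO3-] = sCO2 * pCO2 * 10^(pH - pK)
and linear-in-pH albumin/phosphate charge models.  Every term is strictly
increasing in pH, so the SID <-> pH relation is a monotone bijection; the
inverse is computed by bracketed Brent root-finding.

A richer albumin description (e.g. the detailed Figge-Fencl residue model)
could replace these charge functions behind the same interface; only the
simple model ships.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .config import DEFAULT_CONFIG, PlasmaConstants, SolverSettings
from .errors import ConvergenceError, DomainError

__all__ = [
    "PlasmaState",
    "hco3_conc",
    "albumin_charge",
    "phosphate_charge",
    "plasma_sid",
    "plasma_ph",
    "plasma_state",
]

_PC = DEFAULT_CONFIG.plasma
_SOLVER = DEFAULT_CONFIG.solver


@dataclass(frozen=True)
class PlasmaState:
    """Fully resolved plasma-side quantities at one equilibrium point.

    ``sid == hco3 + alb_charge + pi_charge`` holds exactly as computed.
    """

    ph: float          # dimensionless
    pco2: float        # mmHg
    sid: float         # mEq/l
    hco3: float        # mmol/l
    alb_charge: float  # mEq/l
    pi_charge: float   # mEq/l
    alb: float         # g/l
    pi: float          # mmol/l


def hco3_conc(ph: float, pco2: float, constants: PlasmaConstants = _PC) -> float:
    """Bicarbonate concentration (mmol/l) from Henderson-Hasselbalch.

    ``sCO2 * pCO2 * 10**(pH - pK)``; linear in pCO2 and strictly increasing
    in pH.
    """
    if pco2 < 0:
        raise DomainError(f"pCO2 must be non-negative, got {pco2}")
    return constants.s_co2 * pco2 * 10.0 ** (ph - constants.pk)


def albumin_charge(ph: float, alb: float, constants: PlasmaConstants = _PC) -> float:
    """Negative charge carried by albumin (mEq/l), linear in concentration and pH."""
    if alb < 0:
        raise DomainError(f"albumin must be non-negative, got {alb}")
    return alb * (constants.alb_slope * ph - constants.alb_intercept)


def phosphate_charge(ph: float, pi: float, constants: PlasmaConstants = _PC) -> float:
    """Negative charge carried by inorganic phosphate (mEq/l)."""
    if pi < 0:
        raise DomainError(f"phosphate must be non-negative, got {pi}")
    return pi * (constants.pi_slope * ph - constants.pi_intercept)


def plasma_sid(
    ph: float,
    pco2: float,
    alb: float,
    pi: float,
    constants: PlasmaConstants = _PC,
) -> float:
    """Effective SID (mEq/l) of plasma at the given pH: the electroneutrality sum."""
    return (
        hco3_conc(ph, pco2, constants)
        + albumin_charge(ph, alb, constants)
        + phosphate_charge(ph, pi, constants)
    )


def plasma_ph(
    sid: float,
    pco2: float,
    alb: float,
    pi: float,
    constants: PlasmaConstants = _PC,
    solver: SolverSettings = _SOLVER,
) -> float:
    """Invert :func:`plasma_sid`: the unique pH at which plasma carries ``sid``.

    Monotonicity of the charge sum guarantees uniqueness; the root is found by
    Brent's method on the sub-model bracket (default pH 5..9).

    Raises
    ------
    ConvergenceError
        If ``sid`` is unreachable within the bracket (no sign change).
    """
    if pco2 <= 0:
        raise DomainError(f"pCO2 must be strictly positive to invert, got {pco2}")
    lo, hi = solver.submodel_bracket

    def f(ph: float) -> float:
        return plasma_sid(ph, pco2, alb, pi, constants) - sid

    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ConvergenceError(
            f"plasma_ph: no pH in [{lo}, {hi}] yields SID={sid} mEq/l "
            f"(pCO2={pco2} mmHg, alb={alb} g/l, pi={pi} mmol/l; "
            f"SID range [{sid + flo:.4g}, {sid + fhi:.4g}])"
        )
    return float(brentq(f, lo, hi, xtol=solver.xtol))


def plasma_state(
    ph: float,
    pco2: float,
    alb: float,
    pi: float,
    constants: PlasmaConstants = _PC,
) -> PlasmaState:
    """Resolve all plasma quantities at a given pH (the charge decomposition)."""
    hco3 = hco3_conc(ph, pco2, constants)
    qa = albumin_charge(ph, alb, constants)
    qp = phosphate_charge(ph, pi, constants)
    return PlasmaState(
        ph=ph, pco2=pco2, sid=hco3 + qa + qp,
        hco3=hco3, alb_charge=qa, pi_charge=qp, alb=alb, pi=pi,
    )
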