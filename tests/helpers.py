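"""Independent brute-force oracles used to cross-check the solvers.

These deliberately avoid the package's root-finding paths: equilibria are
located by dense grid scan plus interval bisection on the model's primitive
(forward) functions only.
"""

from __future__ import annotations

import numpy as np

from acidbase import nsid, plasma_sid, van_slyke_be
from acidbase.config import DEFAULT_CONFIG


def implied_whole_blood_be(ph: float, pco2: float, hct: float, alb: float,
                           pi: float) -> float:
    """Whole-blood BE consistent with a shared pH, from the split equations
    written out directly (no inversion anywhere)."""
    cfg = DEFAULT_CONFIG
    be_hct0 = plasma_sid(ph, pco2, alb, pi) - nsid(alb, pi)
    be_hct1 = van_slyke_be(ph, pco2, cfg.sa.mchc_mmol)
    z_ti = be_hct1 - be_hct0
    return be_hct0 + z_ti * (1.0 - hct)


def oracle_combined_ph(be: float, pco2: float, hct: float, alb: float, pi: float,
                       lo: float = 6.0, hi: float = 8.5, step: float = 1e-3,
                       tol: float = 1e-10) -> float:
    """Equilibrium pH by grid scan + bisection on the implied-BE mismatch."""
    grid = np.arange(lo, hi + step, step)
    vals = np.array([implied_whole_blood_be(p, pco2, hct, alb, pi) - be
                     for p in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise AssertionError(f"oracle: no sign change for be={be}, pco2={pco2}")
    a, b = grid[sign_change[0]], grid[sign_change[0] + 1]
    fa = implied_whole_blood_be(a, pco2, hct, alb, pi) - be
    while b - a > tol:
        m = 0.5 * (a + b)
        fm = implied_whole_blood_be(m, pco2, hct, alb, pi) - be
        if (fa < 0) == (fm < 0):
            a, fa = m, fm
        else:
            b = m
    return 0.5 * (a + b)


def oracle_plasma_closed_dilution(factor: float, alb: float = 44.0,
                                  pi: float = 1.15) -> tuple[float, float]:
    """Brute-force (pH, pCO2) of pure plasma after closed-system dilution.

    Scans pCO2 for the value at which the diluted-SID plasma carries exactly
    ``factor`` times the pre-dilution total CO2 content; plasma pH at each
    trial pCO2 is itself found by scan + bisection on electroneutrality.
    """
    from acidbase import hco3_conc
    from acidbase.config import DEFAULT_CONFIG

    s = DEFAULT_CONFIG.plasma.s_co2
    sid_pre = plasma_sid(7.40, 40.0, alb, pi)
    tot_pre = s * 40.0 + hco3_conc(7.40, 40.0)

    def plasma_ph_scan(sid: float, pco2: float, alb_: float, pi_: float) -> float:
        a, b = 5.0, 9.0
        f = lambda p: plasma_sid(p, pco2, alb_, pi_) - sid
        fa = f(a)
        for _ in range(80):
            m = 0.5 * (a + b)
            fm = f(m)
            if (fa < 0) == (fm < 0):
                a, fa = m, fm
            else:
                b = m
        return 0.5 * (a + b)

    def content_gap(pco2: float) -> float:
        ph = plasma_ph_scan(sid_pre * factor, pco2, alb * factor, pi * factor)
        return s * pco2 + hco3_conc(ph, pco2) - factor * tot_pre

    a, b = 1.0, 120.0
    fa = content_gap(a)
    for _ in range(60):
        m = 0.5 * (a + b)
        fm = content_gap(m)
        if (fa < 0) == (fm < 0):
            a, fa = m, fm
        else:
            b = m
    pco2 = 0.5 * (a + b)
    ph = plasma_ph_scan(sid_pre * factor, pco2, alb * factor, pi * factor)
    return ph, pco2
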