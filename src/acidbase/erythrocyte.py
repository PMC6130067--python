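"""Behavioral erythrocyte compartment (the HCT1 limit of blood).

Blood extrapolated to hematocrit 1, fully oxygenated, is described by the
Siggaard-Andersen relation between base excess, pH, pCO2 and hemoglobin in
its Van Slyke closed form:

    BE = (1 - 0.023*ctHb) * [([HCO3-] - [HCO3-]_ref) + (2.3*ctHb + 7.7)*(pH - 7.40)]

with ctHb in mmol/l of monomer and the reference bicarbonate taken from the
plasma constants at pH 7.40 / pCO2 40 mmHg, which anchors BE(7.40, 40) = 0
exactly.  The compartment's hemoglobin is the mean corpuscular hemoglobin
concentration (MCHC), not the whole-blood value: whole blood carries
Hct * MCHC.

The simpler single-formula model of Zander is available as an alternative
submodel (``zander_be``); its oxygen-saturation term is evaluated at sO2 = 1.
Neither submodel carries DPG, fetal-hemoglobin or CO corrections.
"""

from __future__ import annotations

from scipy.optimize import brentq

from .config import DEFAULT_CONFIG, ModelConfig
from .errors import ConvergenceError, DomainError
from .plasma import hco3_conc
from .units import hb_mmol_to_gdl

__all__ = ["van_slyke_be", "zander_be", "erythro_be", "sa_ph", "hco3_ref"]

_CFG = DEFAULT_CONFIG

# Zander's 1995 single-equation coefficients (hemoglobin in g/dl).
_ZANDER_HB_FACTOR = 0.0143
_ZANDER_HCO3_REF = 24.26
_ZANDER_SCO2 = 0.0304
_ZANDER_PK = 6.1
_ZANDER_BUF_INTERCEPT = 9.5
_ZANDER_BUF_SLOPE = 1.63


def hco3_ref(config: ModelConfig = _CFG) -> float:
    """Reference bicarbonate at the standard state, from the plasma constants."""
    return hco3_conc(7.40, 40.0, config.plasma)


def van_slyke_be(
    ph: float, pco2: float, cthb: float, config: ModelConfig = _CFG
) -> float:
    """Base excess (mEq/l) by the Van Slyke equation.

    ``cthb`` is hemoglobin in mmol/l of monomer.  Strictly increasing in pH at
    fixed pCO2 and hemoglobin; zero at (pH 7.40, pCO2 40) for any hemoglobin.
    """
    if cthb < 0:
        raise DomainError(f"hemoglobin must be non-negative, got {cthb}")
    if pco2 <= 0:
        raise DomainError(f"pCO2 must be strictly positive, got {pco2}")
    sa = config.sa
    hco3 = hco3_conc(ph, pco2, config.plasma)
    return (1.0 - sa.hb_factor * cthb) * (
        (hco3 - hco3_ref(config))
        + (sa.buf_slope * cthb + sa.buf_intercept) * (ph - 7.40)
    )


def zander_be(
    ph: float, pco2: float, cthb: float, config: ModelConfig = _CFG
) -> float:
    """Base excess (mEq/l) by Zander's single formula, for fully oxygenated blood.

    Zander's coefficients are fixed by his publication (hemoglobin enters in
    g/dl); the sO2-dependent term vanishes at full saturation.  Not exactly
    zero at the standard state — the residual is below 0.1 mEq/l.
    """
    if cthb < 0:
        raise DomainError(f"hemoglobin must be non-negative, got {cthb}")
    if pco2 <= 0:
        raise DomainError(f"pCO2 must be strictly positive, got {pco2}")
    hb_gdl = hb_mmol_to_gdl(cthb)
    hco3 = _ZANDER_SCO2 * pco2 * 10.0 ** (ph - _ZANDER_PK)
    return (1.0 - _ZANDER_HB_FACTOR * hb_gdl) * (
        (hco3 - _ZANDER_HCO3_REF)
        + (_ZANDER_BUF_INTERCEPT + _ZANDER_BUF_SLOPE * hb_gdl) * (ph - 7.40)
    )


def erythro_be(ph: float, pco2: float, cthb: float, config: ModelConfig = _CFG) -> float:
    """Dispatch to the configured erythrocyte submodel."""
    if config.erythrocyte_model == "zander":
        return zander_be(ph, pco2, cthb, config)
    return van_slyke_be(ph, pco2, cthb, config)


def sa_ph(be: float, pco2: float, cthb: float, config: ModelConfig = _CFG) -> float:
    """Invert the erythrocyte submodel: the unique pH at which BE equals ``be``.

    Raises :class:`ConvergenceError` when ``be`` lies outside the range the
    bracket (default pH 5..9) can produce.
    """
    lo, hi = config.solver.submodel_bracket
    be_lo = erythro_be(lo, pco2, cthb, config)
    be_hi = erythro_be(hi, pco2, cthb, config)
    if be < be_lo or be > be_hi:
        raise ConvergenceError(
            f"sa_ph: no pH in [{lo}, {hi}] yields BE={be} mEq/l "
            f"(reachable BE range [{be_lo:.4g}, {be_hi:.4g}]; "
            f"pCO2={pco2} mmHg, ctHb={cthb} mmol/l, "
            f"model={config.erythrocyte_model})"
        )
    return _sa_ph_clamped(be, pco2, cthb, config)


def _sa_ph_clamped(
    be: float, pco2: float, cthb: float, config: ModelConfig = _CFG
) -> float:
    """Like :func:`sa_ph` but clamps to the bracket endpoint when ``be`` is
    unreachable — a monotone total extension of the inverse, used by the
    combined solver so its own bracket-endpoint evaluations cannot raise."""
    lo, hi = config.solver.submodel_bracket

    def f(ph: float) -> float:
        return erythro_be(ph, pco2, cthb, config) - be

    if f(lo) > 0:
        return lo
    if f(hi) < 0:
        return hi
    return float(brentq(f, lo, hi, xtol=config.solver.xtol))
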