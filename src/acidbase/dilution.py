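"""Hemodilution and hemoconcentration with saline.

Saline carries neither strong-ion difference nor buffers, so dilution by a
factor f multiplies the plasma SID, albumin, phosphate and hemoglobin (hence
hematocrit) by f.  The post-dilution whole-blood base excess follows from the
NSID bridge:

    BE' = SID_pre * f - NSID(Alb*f, Pi*f)

(f < 1 dilutes — dilutional acidosis; f > 1 concentrates.)  Two gas regimes:

* **open** — pCO2 is held at its pre-dilution value, as in vivo where
  ventilation regulates it;
* **closed** — no gas exchange: the plasma total CO2 content (dissolved CO2
  plus bicarbonate) is diluted by the same factor, and the post-dilution pCO2
  is solved for by an outer bracketed root search.

The CO2 accounting of the closed system is plasma-side only: the behavioral
erythrocyte compartment has no explicit CO2 state, so carbamino and
intracellular CO2 stores are not conserved.  Erythrocyte volume changes
(shrinkage/swelling) are ignored: hct' = hct * f.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .config import DEFAULT_CONFIG, ModelConfig, PlasmaConstants
from .errors import ConvergenceError, DomainError
from .combined import BloodSpec, CombinedSolution, nsid, solve_combined

__all__ = ["DilutionResult", "dilute_open", "dilute_closed", "plasma_total_co2"]

_CFG = DEFAULT_CONFIG


@dataclass(frozen=True)
class DilutionResult:
    """Pre/post equilibria for one dilution factor."""

    factor: float             # > 0; < 1 = dilution, > 1 = concentration
    mode: str                 # "open" | "closed"
    pre: CombinedSolution
    post: CombinedSolution
    be_post: float            # mEq/l, from the NSID bridge
    pco2_post: float          # mmHg


def plasma_total_co2(ph: float, pco2: float, constants: PlasmaConstants) -> float:
    """Plasma total CO2 content (mmol/l): dissolved CO2 + bicarbonate."""
    from .plasma import hco3_conc

    return constants.s_co2 * pco2 + hco3_conc(ph, pco2, constants)


def _diluted_spec(
    pre: CombinedSolution, factor: float, pco2_post: float, config: ModelConfig
) -> tuple[BloodSpec, float]:
    spec = pre.spec
    alb_post = spec.alb * factor
    pi_post = spec.pi * factor
    hct_post = spec.hct * factor
    be_post = pre.sid * factor - nsid(alb_post, pi_post, config)
    return BloodSpec(be=be_post, pco2=pco2_post, hct=hct_post,
                     alb=alb_post, pi=pi_post), be_post


def dilute_open(spec: BloodSpec, factor: float, config: ModelConfig = _CFG) -> DilutionResult:
    """Dilute/concentrate at constant pCO2 (the in-vivo, gas-exchanging regime)."""
    if factor <= 0:
        raise DomainError(f"dilution factor must be strictly positive, got {factor}")
    if spec.hct * factor >= 1.0:
        raise DomainError(
            f"concentration factor {factor} drives hematocrit to "
            f"{spec.hct * factor:.3f} >= 1"
        )
    pre = solve_combined(spec, config)
    post_spec, be_post = _diluted_spec(pre, factor, spec.pco2, config)
    post = solve_combined(post_spec, config)
    return DilutionResult(factor=factor, mode="open", pre=pre, post=post,
                          be_post=be_post, pco2_post=spec.pco2)


def dilute_closed(spec: BloodSpec, factor: float, config: ModelConfig = _CFG) -> DilutionResult:
    """Dilute/concentrate with no gas exchange: plasma total CO2 is diluted
    by the same factor and the post pCO2 is solved for."""
    if factor <= 0:
        raise DomainError(f"dilution factor must be strictly positive, got {factor}")
    if spec.hct * factor >= 1.0:
        raise DomainError(
            f"concentration factor {factor} drives hematocrit to "
            f"{spec.hct * factor:.3f} >= 1"
        )
    pre = solve_combined(spec, config)
    target = factor * plasma_total_co2(pre.ph, spec.pco2, config.plasma)

    def content_gap(pco2: float) -> float:
        post_spec, _ = _diluted_spec(pre, factor, pco2, config)
        sol = solve_combined(post_spec, config)
        return plasma_total_co2(sol.ph, pco2, config.plasma) - target

    # Total CO2 content is strictly increasing in pCO2, so bracket around the
    # pre value, expanding geometrically if needed.
    lo, hi = spec.pco2 * min(factor, 1.0) * 0.25, spec.pco2 * max(factor, 1.0) * 2.0
    for _ in range(4):
        try:
            glo, ghi = content_gap(lo), content_gap(hi)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"dilute_closed: inner solve failed while bracketing pCO2 "
                f"(factor={factor}, spec={spec}): {exc}"
            ) from exc
        if glo < 0 < ghi:
            break
        lo, hi = lo * 0.5, hi * 2.0
    else:
        raise ConvergenceError(
            f"dilute_closed: could not bracket post-dilution pCO2 "
            f"(factor={factor}, spec={spec})"
        )
    pco2_post = float(brentq(content_gap, lo, hi, xtol=1e-10))
    post_spec, be_post = _diluted_spec(pre, factor, pco2_post, config)
    post = solve_combined(post_spec, config)
    return DilutionResult(factor=factor, mode="closed", pre=pre, post=post,
                          be_post=be_post, pco2_post=pco2_post)
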