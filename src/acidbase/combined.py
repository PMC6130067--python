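"""The combined full-blood model: plasma and erythrocyte compartments coupled
by passive ion exchange.

Whole blood is treated as a mixture of two theoretical limit compartments —
pure plasma (HCT0, mechanistic physicochemical model) and pure erythrocytes
(HCT1, behavioral Van Slyke/Siggaard-Andersen model) — that must share one pH
at equilibrium.  The coupling currency is the total charge of passively
exchanged ions Z_TI (the chloride shift: Cl- for HCO3-, 1:1), which splits
the whole-blood base excess between the compartments:

    BE_HCT0 = BE - Z_TI * (1 - Hct)
    BE_HCT1 = BE + Z_TI * Hct

On the plasma side, base excess is the SID displacement from the normal SID
(NSID), the SID the same plasma would have at pH 7.40 / pCO2 40 mmHg:

    BE_HCT0 = SID - NSID(Alb, Pi)

Eliminating Z_TI reduces the equilibrium to a single monotone scalar equation
in pH, solved by bracketed Brent iteration; the model is therefore invertible
in both directions (pH from BE, BE from pH) without any iterative guesswork
in the inverse direction, which is closed-form.

Both submodels are anchored at the standard state, so BE = 0 at pCO2 40 mmHg
yields pH 7.400 and Z_TI = 0 for every hematocrit, albumin and phosphate —
the model's defining fixed point.

The split equations are implemented literally; their (1-Hct)/Hct weighting
does not volume-conserve charge (the weighted compartment sum equals
BE + Z_TI*(2*Hct - 1)).  No correction is applied: the asymmetry is part of
the coupling's definition, documented rather than silently altered.
At Hct -> 0 the second equation leaves BE_HCT1 = BE, so the limit does not
degenerate to the plasma-only model; physiological claims are validated for
Hct in [0.2, 0.6].
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .config import DEFAULT_CONFIG, ModelConfig
from .errors import ConvergenceError, DomainError
from .erythrocyte import _sa_ph_clamped, erythro_be
from .plasma import PlasmaState, plasma_sid, plasma_state

__all__ = [
    "BloodSpec",
    "CombinedSolution",
    "nsid",
    "solve_combined",
    "be_from_ph",
    "sid_composition",
]

_CFG = DEFAULT_CONFIG

#: Validated input domain (physiological claims are only made inside it).
BE_RANGE = (-25.0, 25.0)
PCO2_RANGE = (10.0, 150.0)
HCT_RANGE = (0.0, 0.7)


@dataclass(frozen=True)
class BloodSpec:
    """The independent clinical state of a whole-blood solve."""

    be: float           # whole-blood base excess, mEq/l
    pco2: float = 40.0  # mmHg
    hct: float = 0.45   # fraction of blood volume that is erythrocytes
    alb: float = 44.0   # plasma albumin, g/l
    pi: float = 1.15    # plasma inorganic phosphate, mmol/l

    def __post_init__(self) -> None:
        if not 0.0 <= self.hct < 1.0:
            raise DomainError(
                f"hematocrit must lie in [0, 1); got {self.hct} "
                "(hct = 1 leaves no plasma to carry the ion exchange)"
            )
        if self.pco2 <= 0:
            raise DomainError(f"pCO2 must be strictly positive, got {self.pco2}")
        if self.alb < 0 or self.pi < 0:
            raise DomainError("albumin and phosphate must be non-negative")


@dataclass(frozen=True)
class CombinedSolution:
    """Equilibrium of the coupled two-compartment model.

    Invariants (exact up to floating point): ``be_hct1 - be_hct0 == z_ti``
    and ``sid == nsid + be_hct0``.
    """

    ph: float        # shared blood pH
    z_ti: float      # transferred-ion charge, mEq/l
    be_hct0: float   # plasma-compartment base excess, mEq/l
    be_hct1: float   # erythrocyte-compartment base excess, mEq/l
    sid: float       # plasma SID at equilibrium, mEq/l
    nsid: float      # normal SID for the actual Alb/Pi, mEq/l
    plasma: PlasmaState
    residual: float  # final solver residual, pH units
    spec: BloodSpec


def nsid(alb: float, pi: float, config: ModelConfig = _CFG) -> float:
    """Normal SID (mEq/l): the SID of plasma with this albumin and phosphate
    at the standard state pH 7.40, pCO2 40 mmHg.

    NSID is the bridge between the Stewart and base-excess views of plasma:
    BE_plasma = SID - NSID.
    """
    return plasma_sid(7.40, 40.0, alb, pi, config.plasma)


def _split(spec: BloodSpec, ph: float, config: ModelConfig) -> tuple[float, float, float, float]:
    """At a trial pH, the plasma-side compartment split (nsid, be_hct0, z_ti, be_hct1)."""
    n = nsid(spec.alb, spec.pi, config)
    be_hct0 = plasma_sid(ph, spec.pco2, spec.alb, spec.pi, config.plasma) - n
    z_ti = (spec.be - be_hct0) / (1.0 - spec.hct)
    be_hct1 = spec.be + z_ti * spec.hct
    return n, be_hct0, z_ti, be_hct1


def solve_combined(spec: BloodSpec, config: ModelConfig = _CFG) -> CombinedSolution:
    """Solve the coupled model for the equilibrium pH and compartment split.

    For a trial pH the plasma side fixes BE_HCT0 = SID(pH) - NSID, hence
    Z_TI and BE_HCT1 by the split equations; the residual is the gap between
    the trial pH and the erythrocyte-side pH at that BE_HCT1.  The residual is
    strictly monotone in pH, so the bracketed root is unique.  Deterministic;
    no random state.

    Raises :class:`ConvergenceError` when no sign change exists even on the
    widened bracket, reporting the residual at both ends.
    """
    mchc = config.sa.mchc_mmol

    def residual(ph: float) -> float:
        *_, be_hct1 = _split(spec, ph, config)
        return ph - _sa_ph_clamped(be_hct1, spec.pco2, mchc, config)

    lo, hi = config.solver.bracket
    rlo, rhi = residual(lo), residual(hi)
    if not rlo < 0 < rhi:
        lo, hi = config.solver.wide_bracket
        rlo, rhi = residual(lo), residual(hi)
        if not rlo < 0 < rhi:
            raise ConvergenceError(
                f"solve_combined: no root bracketed on pH [{lo}, {hi}] for {spec} "
                f"(residual {rlo:.4g} at pH {lo}, {rhi:.4g} at pH {hi})"
            )
    ph = float(brentq(residual, lo, hi, xtol=config.solver.xtol))
    res = residual(ph)
    if abs(res) > config.solver.ph_tol:
        raise ConvergenceError(
            f"solve_combined: residual {res:.3g} above tolerance "
            f"{config.solver.ph_tol} for {spec}"
        )
    n, be_hct0, z_ti, be_hct1 = _split(spec, ph, config)
    st = plasma_state(ph, spec.pco2, spec.alb, spec.pi, config.plasma)
    return CombinedSolution(
        ph=ph, z_ti=z_ti, be_hct0=be_hct0, be_hct1=be_hct1,
        sid=st.sid, nsid=n, plasma=st, residual=res, spec=spec,
    )


def be_from_ph(
    ph: float,
    pco2: float,
    hct: float = 0.45,
    alb: float = 44.0,
    pi: float = 1.15,
    config: ModelConfig = _CFG,
) -> float:
    """Whole-blood base excess (mEq/l) at a known pH — the closed-form inverse.

    At a shared pH both compartment base excesses are direct function
    evaluations: BE_HCT0 from the plasma SID displacement, BE_HCT1 from the
    erythrocyte submodel at MCHC hemoglobin.  Z_TI = BE_HCT1 - BE_HCT0 and
    BE = BE_HCT0 + Z_TI*(1 - Hct) then follow from the split equations —
    no root-finding, exact inverse of :func:`solve_combined`.
    """
    if not 0.0 <= hct < 1.0:
        raise DomainError(f"hematocrit must lie in [0, 1); got {hct}")
    n = nsid(alb, pi, config)
    be_hct0 = plasma_sid(ph, pco2, alb, pi, config.plasma) - n
    be_hct1 = erythro_be(ph, pco2, config.sa.mchc_mmol, config)
    z_ti = be_hct1 - be_hct0
    return be_hct0 + z_ti * (1.0 - hct)


def sid_composition(solution: CombinedSolution) -> dict[str, float]:
    """Decompose the equilibrium plasma SID into its electroneutrality terms.

    The three components sum to ``solution.sid`` exactly as computed.
    """
    p = solution.plasma
    return {"hco3": p.hco3, "alb_charge": p.alb_charge, "pi_charge": p.pi_charge}
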