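"""Computational experiments over the combined model, emitted as tables.

Every sweep returns a :class:`pandas.DataFrame` with one row per grid point
and a fixed column schema (pH, SID and its decomposition, compartment base
excesses, transferred-ion charge, solver residual, convergence flag).  Rows
that fail to converge are flagged, never dropped, and never abort a sweep.
Everything is deterministic, so re-running any sweep is bit-identical.

Default grids: pCO2 10..150 step 5 mmHg, BE -25..25 step 1 mEq/l,
Hct 0.2..0.6 step 0.05.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ModelConfig
from .errors import AcidBaseError
from .combined import BloodSpec, CombinedSolution, nsid, solve_combined
from .plasma import plasma_ph

__all__ = [
    "default_pco2_grid",
    "default_be_grid",
    "default_hct_grid",
    "titrate_pco2",
    "albumin_sensitivity",
    "titrate_be",
    "convergence_grid",
    "stable_be_halfwidth",
]

_CFG = DEFAULT_CONFIG

COLUMNS = [
    "ph", "sid", "hco3", "alb_charge", "pi_charge",
    "z_ti", "be_hct0", "be_hct1", "residual", "converged",
]


def default_pco2_grid() -> np.ndarray:
    return np.arange(10.0, 151.0, 5.0)


def default_be_grid() -> np.ndarray:
    return np.arange(-25.0, 26.0, 1.0)


def default_hct_grid() -> np.ndarray:
    return np.arange(0.20, 0.601, 0.05)


def _solution_row(sol: CombinedSolution | None) -> dict[str, float | bool]:
    if sol is None:
        return {c: (False if c == "converged" else math.nan) for c in COLUMNS}
    return {
        "ph": sol.ph, "sid": sol.sid, "hco3": sol.plasma.hco3,
        "alb_charge": sol.plasma.alb_charge, "pi_charge": sol.plasma.pi_charge,
        "z_ti": sol.z_ti, "be_hct0": sol.be_hct0, "be_hct1": sol.be_hct1,
        "residual": sol.residual, "converged": True,
    }


def _try_solve(spec: BloodSpec, config: ModelConfig) -> CombinedSolution | None:
    try:
        return solve_combined(spec, config)
    except AcidBaseError:
        return None


def _plasma_only_ph(be: float, pco2: float, alb: float, pi: float,
                    config: ModelConfig) -> float:
    """Reference pH of erythrocyte-free plasma at the same base excess
    (SID = NSID + BE, the plasma-side bridge)."""
    try:
        return plasma_ph(nsid(alb, pi, config) + be, pco2, alb, pi,
                         config.plasma, config.solver)
    except AcidBaseError:
        return math.nan


def titrate_pco2(
    be: float,
    hct: float,
    pco2_grid: Sequence[float] | None = None,
    alb: float = 44.0,
    pi: float = 1.15,
    config: ModelConfig = _CFG,
) -> pd.DataFrame:
    """CO2 titration at fixed base excess: the pH-pCO2 diagram of full blood,
    with an erythrocyte-free plasma reference column (``ph_plasma``)."""
    grid = np.sort(np.asarray(default_pco2_grid() if pco2_grid is None else pco2_grid,
                              dtype=float))
    rows = []
    for pco2 in grid:
        sol = _try_solve(BloodSpec(be=be, pco2=pco2, hct=hct, alb=alb, pi=pi), config)
        row: dict[str, float | bool] = {"pco2": pco2}
        row.update(_solution_row(sol))
        row["ph_plasma"] = _plasma_only_ph(be, pco2, alb, pi, config)
        rows.append(row)
    return pd.DataFrame(rows)


def albumin_sensitivity(
    be: float,
    pco2: float,
    hct: float,
    pi: float = 1.15,
    fraction_grid: Sequence[float] | None = None,
    nominal_alb: float = 44.0,
    config: ModelConfig = _CFG,
) -> pd.DataFrame:
    """pH response to albumin varied as a fraction of nominal, at constant BE.

    Holding BE constant means the plasma SID co-varies with the albumin charge
    (SID = NSID(Alb, Pi) + BE_HCT0); the sweep reports full blood alongside
    the plasma-only reference.
    """
    if fraction_grid is None:
        fraction_grid = np.arange(0.5, 2.01, 0.1)
    fracs = np.sort(np.asarray(fraction_grid, dtype=float))
    rows = []
    for f in fracs:
        alb = f * nominal_alb
        sol = _try_solve(BloodSpec(be=be, pco2=pco2, hct=hct, alb=alb, pi=pi), config)
        row: dict[str, float | bool] = {"fraction": f, "alb": alb}
        row.update(_solution_row(sol))
        row["ph_plasma"] = _plasma_only_ph(be, pco2, alb, pi, config)
        rows.append(row)
    return pd.DataFrame(rows)


def titrate_be(
    pco2: float,
    hct: float,
    alb: float = 44.0,
    pi: float = 1.15,
    be_grid: Sequence[float] | None = None,
    config: ModelConfig = _CFG,
) -> pd.DataFrame:
    """Strong acid/base titration: SID and its decomposition across BE."""
    grid = np.sort(np.asarray(default_be_grid() if be_grid is None else be_grid,
                              dtype=float))
    rows = []
    for be in grid:
        sol = _try_solve(BloodSpec(be=be, pco2=pco2, hct=hct, alb=alb, pi=pi), config)
        row: dict[str, float | bool] = {"be": be}
        row.update(_solution_row(sol))
        rows.append(row)
    return pd.DataFrame(rows)


def convergence_grid(
    be_values: Sequence[float] | None = None,
    pco2_values: Sequence[float] | None = None,
    hct_values: Sequence[float] | None = None,
    alb: float = 44.0,
    pi: float = 1.15,
    config: ModelConfig = _CFG,
) -> tuple[pd.DataFrame, dict]:
    """Deterministic solver-stability sweep over a (BE, pCO2, Hct) grid.

    Returns the per-cell table (converged flag and residual; failures are
    data, not exceptions) and a summary dict with the count of non-converged
    cells, the maximum residual, and the largest symmetric BE half-width
    ``b`` such that every BE in [-b, b] converges at pCO2 40 mmHg, Hct 0.45
    (computed on a dedicated step-1 BE sweep).
    """
    be_values = np.asarray(
        np.arange(-30.0, 31.0, 1.0) if be_values is None else be_values, dtype=float)
    pco2_values = np.asarray([40.0] if pco2_values is None else pco2_values, dtype=float)
    hct_values = np.asarray([0.45] if hct_values is None else hct_values, dtype=float)
    rows = []
    for hct in hct_values:
        for pco2 in pco2_values:
            for be in be_values:
                sol = _try_solve(
                    BloodSpec(be=be, pco2=pco2, hct=hct, alb=alb, pi=pi), config)
                rows.append({
                    "be": be, "pco2": pco2, "hct": hct,
                    "converged": sol is not None,
                    "residual": math.nan if sol is None else abs(sol.residual),
                    "ph": math.nan if sol is None else sol.ph,
                })
    table = pd.DataFrame(rows)
    failed = table.loc[~table["converged"], ["be", "pco2", "hct"]]
    summary = {
        "n_cells": len(table),
        "n_converged": int(table["converged"].sum()),
        "max_abs_residual": float(table["residual"].max()),
        "non_converged": failed.to_dict("records"),
        "stable_be_halfwidth": stable_be_halfwidth(
            be_max=float(np.max(np.abs(be_values))), alb=alb, pi=pi, config=config),
    }
    return table, summary


def stable_be_halfwidth(
    be_max: float = 30.0,
    pco2: float = 40.0,
    hct: float = 0.45,
    alb: float = 44.0,
    pi: float = 1.15,
    config: ModelConfig = _CFG,
) -> float:
    """Largest b (step 1 mEq/l) such that all BE in [-b, b] converge at the
    given conditions; 0 if even BE = 0 fails."""
    b = -1.0
    for step in np.arange(0.0, be_max + 0.5, 1.0):
        ok = all(
            _try_solve(BloodSpec(be=s * step, pco2=pco2, hct=hct, alb=alb, pi=pi),
                       config) is not None
            for s in ((1.0,) if step == 0 else (-1.0, 1.0))
        )
        if not ok:
            break
        b = step
    return max(b, 0.0)
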