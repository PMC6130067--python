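"""Unit conversion at the I/O boundary.

Canonical internal units: pCO2 mmHg, albumin g/l, phosphate mmol/l,
hemoglobin mmol/l (monomer).  Clinical literature mixes kPa with mmHg and
g/dl with g/l, so CLI inputs may carry a unit suffix (``5.32kPa``,
``4.4g/dl``); these helpers normalise them.
"""

from __future__ import annotations

import re

from .config import HB_MONOMER_KG_MOL
from .errors import DomainError

#: 1 mmHg in kPa (exact definition via the standard atmosphere).
KPA_PER_MMHG = 0.133322

_PRESSURE_UNITS = ("mmHg", "kPa")


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between mmHg and kPa.

    Roundtrips are exact to 1e-12 relative since both directions use the same
    single factor.
    """
    units = {u.lower(): u for u in _PRESSURE_UNITS}
    try:
        src, dst = units[from_unit.lower()], units[to_unit.lower()]
    except KeyError as exc:
        raise DomainError(
            f"unknown pressure unit {exc.args[0]!r}; accepted units: {_PRESSURE_UNITS}"
        ) from None
    if src == dst:
        return value
    if src == "kPa":   # -> mmHg
        return value / KPA_PER_MMHG
    return value * KPA_PER_MMHG


def hb_gdl_to_mmol(hb_gdl: float) -> float:
    """Hemoglobin g/dl -> mmol/l of monomer (molar mass 16.114 kg/mol)."""
    return hb_gdl * 10.0 / HB_MONOMER_KG_MOL


def hb_mmol_to_gdl(hb_mmol: float) -> float:
    return hb_mmol * HB_MONOMER_KG_MOL / 10.0


_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Z/%]*)\s*$")

# kind -> {unit(lower) -> factor to canonical}
_KINDS: dict[str, dict[str, float]] = {
    "pressure": {"": 1.0, "mmhg": 1.0, "kpa": 1.0 / KPA_PER_MMHG},   # canonical mmHg
    "albumin": {"": 1.0, "g/l": 1.0, "g/dl": 10.0},                  # canonical g/l
    "phosphate": {"": 1.0, "mmol/l": 1.0},                           # canonical mmol/l
    "hemoglobin": {"": 1.0, "mmol/l": 1.0, "g/dl": 10.0 / HB_MONOMER_KG_MOL},
    "plain": {"": 1.0},
}


def parse_quantity(text: str, kind: str = "plain") -> float:
    """Parse ``"40"``, ``"5.32kPa"`` or ``"4.4 g/dl"`` into the canonical unit."""
    try:
        factors = _KINDS[kind]
    except KeyError:
        raise DomainError(f"unknown quantity kind {kind!r}") from None
    m = _QUANTITY_RE.match(str(text))
    if not m:
        raise DomainError(f"cannot parse quantity {text!r}")
    number, unit = m.groups()
    try:
        value = float(number)
    except ValueError:
        raise DomainError(f"cannot parse number in {text!r}") from None
    try:
        factor = factors[unit.lower()]
    except KeyError:
        accepted = sorted(u for u in factors if u)
        raise DomainError(
            f"unknown unit {unit!r} for {kind}; accepted units: {accepted}"
        ) from None
    return value * factor
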