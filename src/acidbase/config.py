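"""Model constants and configuration.

All constants live in small frozen dataclasses so a calibration study can swap
them without touching the model code.  Canonical internal units are fixed:
pCO2 in mmHg, albumin in g/l, phosphate in mmol/l, hemoglobin in mmol/l of
monomer.  Unit conversion happens only at the I/O boundary (:mod:`.units`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import DomainError

#: Molar mass of the hemoglobin monomer, kg/mol; g/dl -> mmol/l is x10/16.114.
HB_MONOMER_KG_MOL = 16.114

ERYTHROCYTE_MODELS = ("van_slyke", "zander")


@dataclass(frozen=True)
class PlasmaConstants:
    """Coefficients of the simple physicochemical plasma description.

    The albumin and phosphate charges are linear in pH:
    ``alb * (alb_slope * pH - alb_intercept)`` mEq/l per g/l of albumin and
    ``pi * (pi_slope * pH - pi_intercept)`` mEq/l per mmol/l of phosphate.
    """

    pk: float = 6.1            # apparent carbonic-acid pK
    s_co2: float = 0.0306      # CO2 solubility, mmol/(l*mmHg)
    alb_slope: float = 0.123   # per g/l per pH unit
    alb_intercept: float = 0.631
    pi_slope: float = 0.309    # per mmol/l per pH unit
    pi_intercept: float = 0.469

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise DomainError(f"PlasmaConstants.{f.name} must be strictly positive")


@dataclass(frozen=True)
class SaConstants:
    """Coefficients of the Van Slyke closed form for the erythrocyte compartment.

    ``mchc`` is the hemoglobin concentration of the pure-erythrocyte (HCT1)
    compartment in g/dl; whole blood carries ``hct * mchc``.
    """

    hb_factor: float = 0.023   # per mmol/l Hb, plasma-dilution factor
    buf_slope: float = 2.3     # non-bicarbonate buffer slope per mmol/l Hb
    buf_intercept: float = 7.7  # hemoglobin-free buffer value, mEq/l per pH
    mchc: float = 33.34        # g/dl

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise DomainError(f"SaConstants.{f.name} must be strictly positive")

    @property
    def mchc_mmol(self) -> float:
        """MCHC as mmol/l of hemoglobin monomer (~20.7)."""
        return self.mchc * 10.0 / HB_MONOMER_KG_MOL


@dataclass(frozen=True)
class SolverSettings:
    """Brackets and tolerances for the scalar root searches (all pH units)."""

    ph_tol: float = 1e-9                 # accepted |residual| of the combined solve
    xtol: float = 1e-12                  # brentq absolute tolerance on pH
    bracket: tuple[float, float] = (6.5, 8.0)        # combined solve, first try
    wide_bracket: tuple[float, float] = (5.5, 9.0)   # combined solve, one expansion
    submodel_bracket: tuple[float, float] = (5.0, 9.0)  # plasma_ph / sa_ph inversions

    def __post_init__(self) -> None:
        for name in ("bracket", "wide_bracket", "submodel_bracket"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise DomainError(f"SolverSettings.{name} must satisfy lo < hi")
        if self.ph_tol <= 0 or self.xtol <= 0:
            raise DomainError("solver tolerances must be strictly positive")


@dataclass(frozen=True)
class Nominal:
    """Nominal clinical values used as CLI/workbench defaults."""

    alb: float = 44.0    # g/l
    pi: float = 1.15     # mmol/l
    hct: float = 0.45    # fraction
    pco2: float = 40.0   # mmHg


@dataclass(frozen=True)
class ModelConfig:
    plasma: PlasmaConstants = field(default_factory=PlasmaConstants)
    sa: SaConstants = field(default_factory=SaConstants)
    solver: SolverSettings = field(default_factory=SolverSettings)
    nominal: Nominal = field(default_factory=Nominal)
    erythrocyte_model: str = "van_slyke"

    def __post_init__(self) -> None:
        if self.erythrocyte_model not in ERYTHROCYTE_MODELS:
            raise DomainError(
                f"erythrocyte_model must be one of {ERYTHROCYTE_MODELS}, "
                f"got {self.erythrocyte_model!r}"
            )


DEFAULT_CONFIG = ModelConfig()

_SECTIONS = {
    "plasma": PlasmaConstants,
    "sa": SaConstants,
    "solver": SolverSettings,
    "nominal": Nominal,
}


def _build_section(cls: type, data: dict[str, Any], section: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise DomainError(f"unknown key(s) in config section {section!r}: {sorted(unknown)}")
    coerced: dict[str, Any] = {}
    for key, value in data.items():
        if isinstance(value, (list, tuple)):
            coerced[key] = tuple(float(v) for v in value)
        else:
            coerced[key] = float(value)
    return cls(**coerced)


def config_from_dict(data: dict[str, Any]) -> ModelConfig:
    """Build a validated :class:`ModelConfig` from a plain dict; unknown keys rejected."""
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        if section in data:
            raw = data.pop(section)
            if not isinstance(raw, dict):
                raise DomainError(f"config section {section!r} must be a mapping")
            kwargs[section] = _build_section(cls, raw, section)
    if "erythrocyte_model" in data:
        kwargs["erythrocyte_model"] = str(data.pop("erythrocyte_model"))
    if data:
        raise DomainError(f"unknown key(s) in config: {sorted(data)}")
    return ModelConfig(**kwargs)


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        obj = getattr(config, section)
        out[section] = {
            f.name: (list(v) if isinstance(v := getattr(obj, f.name), tuple) else v)
            for f in dataclasses.fields(cls)
        }
    out["erythrocyte_model"] = config.erythrocyte_model
    return out


def load_config(path: str | Path) -> ModelConfig:
    """Load a YAML config file; every key is validated, unknown keys are errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return ModelConfig()
    if not isinstance(data, dict):
        raise DomainError(f"config file {path} must contain a mapping at top level")
    return config_from_dict(data)


def dump_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
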