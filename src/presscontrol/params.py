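"""Parameter containers for the rotary tablet-press compaction model.

All boundary units follow plant convention: lengths in mm, masses in mg,
forces in kN, pressures in MPa, densities in g/cm^3, speeds in rev/min,
mass flows in kg/h, glidant concentration in % w/w, mixing time in min.
These units are mutually consistent for the compaction equations
(1 g/cm^3 == 1 mg/mm^3, 1 MPa * 1 mm^2 == 1 N), so no internal conversion
layer is needed beyond the explicit factors in :mod:`presscontrol.compaction`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ModelParameters",
    "ToolingGeometry",
    "ProcessInputs",
    "ProcessOutputs",
    "PARAMETER_SETS",
    "get_parameters",
    "load_parameters",
    "packaged_parameter_path",
    "dump_parameters",
    "CompactionModelError",
    "ModelValidityError",
]


class CompactionModelError(ValueError):
    """An input falls outside the physical domain of the compaction model."""


class ModelValidityError(CompactionModelError):
    """A quantity left the validity region of one of the model equations."""


@dataclass(frozen=True)
class ModelParameters:
    """Fitted constants of the tablet-press mechanistic model.

    Die-filling constants ``xi1``/``xi2`` correct tablet weight for turret
    and feed-frame speed and for dosing depth.  ``kaw_a`` and ``kaw_inv_b``
    are the Kawakita maximum degree of compression and its pressure scale
    (1/b, MPa).  ``rho_c`` is the critical relative density below which the
    powder bed transmits no punch force.  The tensile-strength law is
    anchored by ``sigma0`` (strength at zero porosity, MPa) and the critical
    density ``rho_c0``/``rho_cinf`` pair that shifts with glidant shear.
    ``b1..b3`` and ``r1..r3`` parameterise the lumped glidant-mixing factors
    for tensile strength and bulk density respectively; the bulk-density
    asymptotes ``rho_b_0``/``rho_b_inf`` apply only when the glidant
    bulk-density model is active (otherwise ``rho_b`` is used directly).
    """

    xi1: float = 0.036
    xi2: float = 0.030
    rho_b: float = 0.365        # g/cm^3, direct bulk density (glidant model off)
    rho_c: float = 0.265        # critical relative density (Kawakita)
    kaw_a: float = 0.80         # Kawakita a
    kaw_inv_b: float = 10.26    # Kawakita 1/b, MPa
    rho_t: float = 1.53         # true density, g/cm^3
    eps0: float = 0.08          # in-die elastic recovery at full compaction
    rho_c_eps: float = 0.57     # density below which no elastic recovery
    sigma0: float = 11.67       # MPa, zero-porosity tensile strength (sigma_0,phi)
    rho_c0: float = 0.57        # tensile critical density, zero glidant shear
    rho_cinf: float = 0.61      # tensile critical density, infinite glidant shear
    b1: float = 0.31
    b2: float = 0.38
    b3: float = 8.40
    rho_b_inf: Optional[float] = None   # g/cm^3, bulk density asymptote
    rho_b_0: Optional[float] = None     # g/cm^3, bulk density at zero shear
    r1: Optional[float] = None
    r2: Optional[float] = None
    r3: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.rho_b > 0 and self.rho_t > 0):
            raise CompactionModelError("densities must be positive")
        if not (0.0 < self.rho_c < 1.0):
            raise CompactionModelError(f"rho_c out of (0, 1): {self.rho_c}")
        if not (0.0 < self.kaw_a < 1.1):
            raise CompactionModelError(f"Kawakita a out of range: {self.kaw_a}")
        if self.kaw_inv_b <= 0:
            raise CompactionModelError("Kawakita 1/b must be positive")
        if not (0.0 <= self.rho_c_eps < 1.0):
            raise CompactionModelError(f"rho_c_eps out of [0, 1): {self.rho_c_eps}")
        if not (self.rho_c0 < self.rho_cinf < 1.0):
            raise CompactionModelError("require rho_c0 < rho_cinf < 1")
        if self.has_glidant_bulk_model:
            if not (0.0 < self.rho_b_0 < self.rho_b_inf):
                raise CompactionModelError("require 0 < rho_b_0 < rho_b_inf")

    @property
    def has_glidant_bulk_model(self) -> bool:
        return None not in (self.rho_b_inf, self.rho_b_0, self.r1, self.r2, self.r3)

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


# Nominal turret speed: the speed at which a 210 mg tablet on a 10-station
# turret yields exactly 6.9 kg/h.  The feed frame is geared to run at this
# speed, making the weight correction factor unity at the nominal point.
NOMINAL_TURRET_SPEED_RPM = 6.9 / (210e-6 * 10 * 60)  # = 54.7619... rev/min


@dataclass(frozen=True)
class ToolingGeometry:
    """Die/turret constants of the press (Natoli D-type, shallow cup)."""

    die_diameter_D: float = 10.0        # mm
    cup_depth_h: float = 1.0            # mm
    n_stations: int = 10
    feed_frame_speed_nF: float = NOMINAL_TURRET_SPEED_RPM  # rev/min, held constant
    holdup_mfh: float = 1.0             # kg, feed-frame + hopper holdup
    gamma0: float = 10.0                # min, blender shear baseline

    def __post_init__(self) -> None:
        vals = (self.die_diameter_D, self.cup_depth_h, self.n_stations,
                self.feed_frame_speed_nF, self.holdup_mfh, self.gamma0)
        if any(v <= 0 for v in vals[:4]) or self.holdup_mfh < 0 or self.gamma0 < 0:
            raise CompactionModelError("geometry constants must be positive")
        if self.cup_depth_h >= self.die_diameter_D:
            raise CompactionModelError("cup depth must be smaller than die diameter")


@dataclass(frozen=True)
class ProcessInputs:
    """Manipulated variables of the press (plus glidant concentration)."""

    dosing_position_Hfill: float        # mm
    precomp_thickness_Hpc: float        # mm
    maincomp_thickness_Hindie: float    # mm
    turret_speed_nT: float              # rev/min
    glidant_conc_cl: float = 0.2        # % w/w

    _ORDER_TOL = 1e-9

    def __post_init__(self) -> None:
        if min(self.dosing_position_Hfill, self.precomp_thickness_Hpc,
               self.maincomp_thickness_Hindie, self.turret_speed_nT) <= 0:
            raise CompactionModelError("process inputs must be positive")
        if self.glidant_conc_cl < 0:
            raise CompactionModelError("glidant concentration must be >= 0")
        if (self.maincomp_thickness_Hindie > self.precomp_thickness_Hpc + self._ORDER_TOL
                or self.precomp_thickness_Hpc > self.dosing_position_Hfill + self._ORDER_TOL):
            raise CompactionModelError(
                "compression ordering violated: require "
                "H_in-die <= H_pc <= H_fill, got "
                f"{self.maincomp_thickness_Hindie} / {self.precomp_thickness_Hpc} "
                f"/ {self.dosing_position_Hfill}")

    def replace(self, **kwargs) -> "ProcessInputs":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ProcessOutputs:
    """Noise-free outputs of one evaluation of the compaction model."""

    tablet_weight_W: float              # mg
    precompression_force_Fpc: float     # kN
    main_compression_force_Fpunch: float  # kN
    production_rate: float              # kg/h
    tensile_strength_sigmat: float      # MPa
    tablet_relative_density: float
    in_die_relative_density: float
    bulk_density: float                 # g/cm^3, effective value used
    mixing_time_gamma: float            # min, equivalent shear mixing time
    flags: tuple = ()                   # names of clamped/zeroed equations

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = list(self.flags)
        return d


# --- Case-study parameter columns -----------------------------------------

_BASE = dict(xi1=0.036, xi2=0.030, rho_b=0.365, rho_c=0.265, kaw_a=0.80,
             kaw_inv_b=10.26, rho_t=1.53, eps0=0.08, rho_c_eps=0.57,
             sigma0=11.67, rho_c0=0.57, rho_cinf=0.61,
             b1=0.31, b2=0.38, b3=8.40)

_GLIDANT_BULK = dict(rho_b_inf=0.450, rho_b_0=0.330, r1=0.361, r2=1.394, r3=23.326)

PARAMETER_SETS: dict[str, ModelParameters] = {
    "no_pmm": ModelParameters(**_BASE),
    "mild_pmm": ModelParameters(**{**_BASE, "rho_b": 0.390, "rho_c": 0.290,
                                   "kaw_a": 0.77}),
    "high_pmm": ModelParameters(**{**_BASE, "xi2": 0.050, "rho_b": 0.410,
                                   "rho_c": 0.230, "kaw_a": 0.84,
                                   "kaw_inv_b": 8.55, "rho_t": 1.51}),
    "cs2_nominal": ModelParameters(**{**_BASE, **_GLIDANT_BULK}),
}


def get_parameters(name: str) -> ModelParameters:
    """Return one of the packaged parameter columns by name."""
    try:
        return PARAMETER_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown parameter set {name!r}; valid names: "
            f"{sorted(PARAMETER_SETS)}") from None


def packaged_parameter_path(name: str) -> Path:
    """Path to the shipped YAML fixture for a named parameter column."""
    if name not in PARAMETER_SETS:
        raise KeyError(
            f"unknown parameter set {name!r}; valid names: "
            f"{sorted(PARAMETER_SETS)}")
    from importlib import resources
    return Path(str(resources.files("presscontrol").joinpath(f"data/{name}.yaml")))


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a parameter set from a YAML file (one key per model symbol)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    known = {f.name for f in fields(ModelParameters)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    return ModelParameters(**data)


def dump_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set to YAML, dropping unset optional fields."""
    data = {k: v for k, v in params.to_dict().items() if v is not None}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
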