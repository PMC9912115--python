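"""Mechanistic rotary tablet-press model with glidant effects.

The model is a static nonlinear output map: given the manipulated inputs
(dosing position, pre/main compression thickness, turret speed, glidant
concentration) and a parameter set, it returns tablet weight, compression
forces, production rate and tensile strength.  The chain is

    bulk density -> tablet weight -> production rate -> pre-compression
    force -> main compression force -> elastic recovery -> out-of-die
    density -> tensile strength,

with the die-fill weight law, the Kawakita force law, a linear elastic
recovery law, and an exponential porosity-strength law.  Glidant (colloidal
silica) shifts both bulk density and tensile strength through lumped
mixing factors that combine concentration and an equivalent mixing time.

Two evaluation modes are provided.  ``evaluate_outputs`` is strict: inputs
outside the validity region of an equation raise ``ModelValidityError``
naming the offending quantity.  ``evaluate_outputs_soft`` clamps invalid
intermediates and returns a smooth quadratic penalty alongside the outputs,
so gradient-based optimizers (the estimator and the controller) can
traverse infeasible iterates without crashing.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import optimize

from .params import (
    CompactionModelError,
    ModelParameters,
    ModelValidityError,
    ProcessInputs,
    ProcessOutputs,
    ToolingGeometry,
)

__all__ = [
    "fill_volume",
    "compression_volume",
    "tablet_weight",
    "production_rate",
    "relative_density",
    "kawakita_force",
    "elastic_recovery",
    "glidant_shear",
    "lumped_sigma_factor",
    "lumped_rho_factor",
    "bulk_density_from_factor",
    "glidant_bulk_density",
    "tensile_critical_density",
    "tensile_strength",
    "evaluate_outputs",
    "evaluate_outputs_soft",
    "calibrate_nominal_inputs",
    "invert_outputs",
    "NOMINAL_SETPOINTS",
]

# Nominal pre-step operating targets: weight mg, PCF kN, rate kg/h, tensile MPa.
NOMINAL_SETPOINTS = {"weight": 210.0, "pcf": 0.3, "rate": 6.9, "tensile": 4.2}

# kg/h per (mg * rev/min * station)
_RATE_FACTOR = 60e-6


def fill_volume(geometry: ToolingGeometry, H_fill: float) -> float:
    """Die cavity volume at fill, mm^3 (cylinder plus one shallow cup)."""
    if H_fill <= 0:
        raise CompactionModelError(f"H_fill must be positive, got {H_fill}")
    D, h = geometry.die_diameter_D, geometry.cup_depth_h
    return math.pi * D * D * H_fill / 4.0 + math.pi * h * (3 * D * D / 4.0 + h * h) / 6.0


def compression_volume(geometry: ToolingGeometry, H: float) -> float:
    """Volume between punches at thickness ``H``, mm^3 (two punch cups)."""
    if H <= 0:
        raise CompactionModelError(f"compression thickness must be positive, got {H}")
    D, h = geometry.die_diameter_D, geometry.cup_depth_h
    return math.pi * D * D * H / 4.0 + math.pi * h * (3 * D * D / 4.0 + h * h) / 3.0


def tablet_weight(params: ModelParameters, geometry: ToolingGeometry,
                  u: ProcessInputs, rho_b_effective: float) -> float:
    """Tablet weight in mg from the die-fill law.

    ``W = rho_b * V_fill * (1 - xi1 * nT/nF + xi2 * Hfill/D)``; the bulk
    density is passed explicitly so the caller decides whether it is the
    direct parameter or the glidant-dependent value.
    """
    if rho_b_effective <= 0:
        raise CompactionModelError("bulk density must be positive")
    corr = (1.0 - params.xi1 * u.turret_speed_nT / geometry.feed_frame_speed_nF
            + params.xi2 * u.dosing_position_Hfill / geometry.die_diameter_D)
    if corr <= 0:
        raise ModelValidityError(
            f"die-fill correction factor non-positive ({corr:.4f}) at "
            f"nT={u.turret_speed_nT}, Hfill={u.dosing_position_Hfill}")
    return rho_b_effective * fill_volume(geometry, u.dosing_position_Hfill) * corr


def production_rate(W: float, nT: float, n_stations: int) -> float:
    """Tablet production rate in kg/h from weight (mg) and turret speed (rpm)."""
    if W < 0 or nT <= 0 or n_stations <= 0:
        raise CompactionModelError("production rate arguments must be positive")
    return W * nT * n_stations * _RATE_FACTOR


def relative_density(W: float, V: float, rho_t: float) -> float:
    """Relative density of a W mg compact in a V mm^3 volume (rho_t g/cm^3)."""
    if V <= 0 or rho_t <= 0:
        raise CompactionModelError("volume and true density must be positive")
    return W / (V * rho_t)


def _kawakita_upper_limit(params: ModelParameters) -> float:
    """Density at which the Kawakita denominator vanishes (inf if a >= 1)."""
    if params.kaw_a >= 1.0:
        return math.inf
    return params.rho_c / (1.0 - params.kaw_a)


def kawakita_force(rho_rel: float, params: ModelParameters, D: float) -> float:
    """Punch force in kN from the Kawakita compression isotherm.

    Below the critical density the powder bed transmits no force and 0 is
    returned (degenerate but physical); at or beyond the denominator zero
    the equation loses validity and a ``ModelValidityError`` is raised.
    """
    if rho_rel <= params.rho_c:
        return 0.0
    limit = _kawakita_upper_limit(params)
    if rho_rel >= limit:
        raise ModelValidityError(
            f"relative density {rho_rel:.4f} outside Kawakita validity "
            f"interval [{params.rho_c:.4f}, {limit:.4f})")
    area = math.pi * D * D / 4.0  # mm^2
    ratio = (rho_rel - params.rho_c) / (rho_rel * (params.kaw_a - 1.0) + params.rho_c)
    return area * params.kaw_inv_b * ratio / 1000.0  # MPa*mm^2 = N -> kN


def elastic_recovery(rho_in_die: float, params: ModelParameters) -> float:
    """In-die elastic recovery; clamps to 0 below the critical density."""
    if rho_in_die < params.rho_c_eps:
        return 0.0
    return params.eps0 * (rho_in_die - params.rho_c_eps) / (1.0 - params.rho_c_eps)


def glidant_shear(geometry: ToolingGeometry, production_rate_kg_h: float) -> float:
    """Equivalent mixing time in minutes: blender baseline plus feed-frame
    residence time (holdup over throughput)."""
    if production_rate_kg_h <= 0:
        raise CompactionModelError(
            "production rate must be positive (infinite residence time)")
    return geometry.gamma0 + 60.0 * geometry.holdup_mfh / production_rate_kg_h


def lumped_sigma_factor(cl: float, gamma: float, params: ModelParameters) -> float:
    """Lumped glidant-mixing factor for the tensile-strength law.

    ``C_sigma = cl**b1 * gamma**b2 / b3`` with cl in % w/w and gamma in min.
    The division by b3 is the only reading consistent with the fitted
    constants: a multiplicative b3 would depress the zero-porosity strength
    below 1 MPa at the nominal 0.2% silica, contradicting the nominal
    4.2 MPa operating point.  Kept in one function so an alternate reading
    is a one-line change.
    """
    if cl < 0:
        raise CompactionModelError("glidant concentration must be >= 0")
    if cl == 0.0:
        return 0.0
    return cl ** params.b1 * gamma ** params.b2 / params.b3


def lumped_rho_factor(cl: float, gamma: float, gamma0: float,
                      params: ModelParameters) -> float:
    """Lumped glidant-mixing factor for the bulk-density law.

    ``C_rho = cl**r1 * (gamma + gamma0)**r2 / r3``; same division reading as
    :func:`lumped_sigma_factor` (a multiplicative r3 saturates the bulk
    density at its asymptote for any realistic concentration, which would
    make the silica level unobservable from the plant outputs).
    """
    if cl < 0:
        raise CompactionModelError("glidant concentration must be >= 0")
    if cl == 0.0:
        return 0.0
    return cl ** params.r1 * (gamma + gamma0) ** params.r2 / params.r3


def bulk_density_from_factor(C_rho: float, params: ModelParameters) -> float:
    """Bulk density g/cm^3 interpolated between its zero- and infinite-shear
    asymptotes by the lumped factor: ``rho_b_inf - (rho_b_inf - rho_b_0)/(1 + C)``."""
    if not params.has_glidant_bulk_model:
        raise CompactionModelError("parameter set has no glidant bulk-density model")
    if C_rho < 0:
        raise CompactionModelError("lumped factor must be >= 0")
    return params.rho_b_inf - (params.rho_b_inf - params.rho_b_0) / (1.0 + C_rho)


def glidant_bulk_density(cl: float, gamma: float, params: ModelParameters,
                         gamma0: float) -> float:
    """Bulk density under the glidant model at concentration ``cl`` (% w/w)
    and equivalent mixing time ``gamma`` (min)."""
    return bulk_density_from_factor(lumped_rho_factor(cl, gamma, gamma0, params), params)


def tensile_critical_density(C_sigma: float, params: ModelParameters) -> float:
    """Relative density at which a tablet starts forming, shifted by glidant."""
    return (params.rho_c0 - params.rho_cinf) / (1.0 + C_sigma) + params.rho_cinf


def tensile_strength(rho_tablet: float, cl: float, gamma: float,
                     params: ModelParameters) -> float:
    """Tablet tensile strength in MPa from the exponential porosity law.

    Returns 0 below the (glidant-shifted) critical density — no coherent
    tablet forms there.  With ``cl = 0`` the glidant correction vanishes and
    the law reduces to its base form with ``sigma0`` and ``rho_c0``.
    """
    C = lumped_sigma_factor(cl, gamma, params)
    rho_crit = tensile_critical_density(C, params)
    sigma0_eff = params.sigma0 / (1.0 + C)
    if rho_tablet < rho_crit:
        return 0.0
    if rho_tablet > 1.0:
        raise ModelValidityError(f"tablet relative density {rho_tablet:.4f} > 1")
    bracket = 1.0 - ((1.0 - rho_tablet) / (1.0 - rho_crit)) * math.exp(rho_tablet - rho_crit)
    return sigma0_eff * bracket


# --------------------------------------------------------------------------
# Composite output map
# --------------------------------------------------------------------------

_GAMMA_FP_TOL = 1e-12
_GAMMA_FP_MAXITER = 200


@lru_cache(maxsize=32)
def _geom_constants(g: ToolingGeometry):
    """Hoisted geometry constants: punch area (mm^2), fill cup term (/6)
    and compression cup term (/3)."""
    D, h = g.die_diameter_D, g.cup_depth_h
    area = math.pi * D * D / 4.0
    cup6 = math.pi * h * (3.0 * D * D / 4.0 + h * h) / 6.0
    return area, cup6, 2.0 * cup6


def _evaluate_core(H_fill: float, H_pc: float, H_indie: float, nT: float,
                   cl: float, params: ModelParameters, geometry: ToolingGeometry,
                   glidant_active: bool, soft: bool):
    """Float-only evaluation kernel (no dataclass construction, equation
    math inlined); the hot path for the estimator and controller
    objectives.  Semantics match the public per-equation functions."""
    g, p = geometry, params
    area, cup6, cup3 = _geom_constants(g)
    pen = 0.0
    flags: list[str] = []

    if cl < 0:
        if not soft:
            raise CompactionModelError(f"glidant concentration negative: {cl}")
        pen += (50.0 * cl) ** 2
        cl = 0.0
    if H_fill <= 0 or H_pc <= 0 or H_indie <= 0 or nT <= 0:
        raise CompactionModelError("process inputs must be positive")

    corr = (1.0 - p.xi1 * nT / g.feed_frame_speed_nF
            + p.xi2 * H_fill / g.die_diameter_D)
    if corr <= 1e-3:
        if not soft:
            raise ModelValidityError(
                f"die-fill correction factor non-positive ({corr:.4f})")
        pen += (100.0 * (1e-3 - corr)) ** 2
        corr = 1e-3

    WV = (area * H_fill + cup6) * corr          # weight per unit bulk density
    rate_const = nT * g.n_stations * _RATE_FACTOR
    residence_const = 60.0 * g.holdup_mfh
    gamma0 = g.gamma0

    if glidant_active:
        if not p.has_glidant_bulk_model:
            raise CompactionModelError(
                "glidant bulk-density model requested but rho_b_inf/rho_b_0/"
                "r1..r3 are unset in this parameter set")
        rb_inf, drb = p.rho_b_inf, p.rho_b_inf - p.rho_b_0
        if cl == 0.0:
            rho_b = rb_inf - drb            # C_rho = 0
            W = rho_b * WV
            mdot = W * rate_const
            gamma = gamma0 + residence_const / mdot
        else:
            # gamma depends on throughput which depends on bulk density
            # which depends on gamma: resolve the scalar fixed point by
            # iteration (contraction: d(rho_b)/d(gamma) is small at
            # operating conditions).
            cl_r1 = cl ** p.r1 / p.r3
            gamma = gamma0 + residence_const / NOMINAL_SETPOINTS["rate"]
            for _ in range(_GAMMA_FP_MAXITER):
                C_rho = cl_r1 * (gamma + gamma0) ** p.r2
                rho_b = rb_inf - drb / (1.0 + C_rho)
                W = rho_b * WV
                mdot = W * rate_const
                gamma_new = gamma0 + residence_const / mdot
                if abs(gamma_new - gamma) < _GAMMA_FP_TOL:
                    gamma = gamma_new
                    break
                gamma = gamma_new
            C_rho = cl_r1 * (gamma + gamma0) ** p.r2
            rho_b = rb_inf - drb / (1.0 + C_rho)
            W = rho_b * WV
            mdot = W * rate_const
            gamma = gamma0 + residence_const / mdot
    else:
        rho_b = p.rho_b
        W = rho_b * WV
        mdot = W * rate_const
        gamma = gamma0 + residence_const / mdot

    inv_rho_t = 1.0 / p.rho_t
    rho_pc = W * inv_rho_t / (area * H_pc + cup3)
    rho_id = W * inv_rho_t / (area * H_indie + cup3)

    # Kawakita forces (inline); upper validity bound clamped with a smooth
    # penalty in soft mode, raised in strict mode
    rho_c, a1 = p.rho_c, p.kaw_a - 1.0
    force_const = area * p.kaw_inv_b / 1000.0
    limit = rho_c / (1.0 - p.kaw_a) if p.kaw_a < 1.0 else math.inf
    cap = rho_c + 0.98 * (limit - rho_c) if math.isfinite(limit) else math.inf

    def punch_force(rho):
        nonlocal pen
        if not soft:
            if rho >= limit:
                raise ModelValidityError(
                    f"relative density {rho:.4f} outside Kawakita validity "
                    f"interval [{rho_c:.4f}, {limit:.4f})")
        elif rho > cap:
            pen += (100.0 * (rho - cap) / limit) ** 2
            rho = cap
        if rho <= rho_c:
            return 0.0, rho
        return force_const * (rho - rho_c) / (rho * a1 + rho_c), rho

    F_pc, rho_pc = punch_force(rho_pc)
    F_mc, rho_id = punch_force(rho_id)
    if rho_pc <= rho_c:
        flags.append("pcf_below_critical")
    if rho_id <= rho_c:
        flags.append("mcf_below_critical")

    if rho_id < p.rho_c_eps:
        eps = 0.0
        flags.append("elastic_recovery_clamped")
    else:
        eps = p.eps0 * (rho_id - p.rho_c_eps) / (1.0 - p.rho_c_eps)
    rho_tab = (1.0 - eps) * rho_id
    if rho_tab >= 1.0:
        if not soft:
            raise ModelValidityError(
                f"out-of-die relative density {rho_tab:.4f} >= 1")
        pen += (100.0 * (rho_tab - 0.9999)) ** 2
        rho_tab = 0.9999

    # tensile strength (inline glidant-lumped law)
    C = cl ** p.b1 * gamma ** p.b2 / p.b3 if cl > 0.0 else 0.0
    inv1C = 1.0 / (1.0 + C)
    rho_crit = (p.rho_c0 - p.rho_cinf) * inv1C + p.rho_cinf
    if rho_tab < rho_crit:
        sigma_t = 0.0
        flags.append("tensile_below_critical")
    else:
        sigma_t = (p.sigma0 * inv1C
                   * (1.0 - ((1.0 - rho_tab) / (1.0 - rho_crit))
                      * math.exp(rho_tab - rho_crit)))

    return (W, F_pc, F_mc, mdot, sigma_t, rho_tab, rho_id, rho_b, gamma,
            tuple(flags), pen)


def _core_from_inputs(u: ProcessInputs, params, geometry, glidant_active,
                      cl_override, soft):
    cl = u.glidant_conc_cl if cl_override is None else cl_override
    return _evaluate_core(u.dosing_position_Hfill, u.precomp_thickness_Hpc,
                          u.maincomp_thickness_Hindie, u.turret_speed_nT,
                          cl, params, geometry, glidant_active, soft)


def _evaluate(u: ProcessInputs, params: ModelParameters, geometry: ToolingGeometry,
              glidant_active: bool, cl_override: Optional[float], soft: bool):
    (W, F_pc, F_mc, mdot, sigma_t, rho_tab, rho_id, rho_b, gamma, flags,
     penalty) = _core_from_inputs(u, params, geometry, glidant_active,
                                  cl_override, soft)
    out = ProcessOutputs(
        tablet_weight_W=W,
        precompression_force_Fpc=F_pc,
        main_compression_force_Fpunch=F_mc,
        production_rate=mdot,
        tensile_strength_sigmat=sigma_t,
        tablet_relative_density=rho_tab,
        in_die_relative_density=rho_id,
        bulk_density=rho_b,
        mixing_time_gamma=gamma,
        flags=flags,
    )
    return out, penalty


def evaluate_outputs(u: ProcessInputs, params: ModelParameters,
                     geometry: ToolingGeometry, glidant_active: bool = False,
                     cl_override: Optional[float] = None) -> ProcessOutputs:
    """Evaluate the full output map; strict validity checking.

    With ``glidant_active`` the bulk density comes from the glidant model
    (concentration and mixing time), otherwise the direct ``rho_b``
    parameter is used.  ``cl_override`` substitutes the glidant
    concentration without touching the input record (used when the
    concentration is an uncertain parameter rather than a manipulated
    input).
    """
    out, _ = _evaluate(u, params, geometry, glidant_active, cl_override, soft=False)
    return out


def evaluate_outputs_soft(u: ProcessInputs, params: ModelParameters,
                          geometry: ToolingGeometry, glidant_active: bool = False,
                          cl_override: Optional[float] = None):
    """Like :func:`evaluate_outputs` but clamps invalid intermediates and
    returns ``(outputs, penalty)`` where penalty is a smooth nonnegative
    measure of constraint violation (0 inside the validity region)."""
    return _evaluate(u, params, geometry, glidant_active, cl_override, soft=True)


# --------------------------------------------------------------------------
# Calibration / inversion
# --------------------------------------------------------------------------

_INPUT_FIELDS = ("dosing_position_Hfill", "precomp_thickness_Hpc",
                 "maincomp_thickness_Hindie", "turret_speed_nT")

# mm / mm / mm / rpm bounds used for calibration root-finding; identical to
# the controller's input box.
_CAL_BOUNDS = ([2.0, 2.0, 1.0, 10.0], [16.0, 8.0, 6.0, 100.0])


def _outputs_vector(u, params, geometry, glidant_active, cl_override):
    out, pen = evaluate_outputs_soft(u, params, geometry, glidant_active, cl_override)
    return np.array([out.tablet_weight_W, out.precompression_force_Fpc,
                     out.production_rate, out.tensile_strength_sigmat]), pen


def invert_outputs(targets: dict, params: ModelParameters,
                   geometry: ToolingGeometry, glidant_active: bool = False,
                   cl: float = 0.2, x0=None, n_starts: int = 8,
                   seed: int = 0) -> ProcessInputs:
    """Find inputs that reproduce a target output vector by multi-start
    bounded least squares on the forward model.

    ``targets`` maps ``weight``/``pcf``/``rate``/``tensile`` to desired
    values (plant units).  The glidant concentration is held at ``cl``.
    Raises if no start converges to a residual below 1e-6 relative.
    """
    tvec = np.array([targets["weight"], targets["pcf"],
                     targets["rate"], targets["tensile"]])

    def resid(x):
        u = ProcessInputs(dosing_position_Hfill=x[0],
                          precomp_thickness_Hpc=min(x[1], x[0]),
                          maincomp_thickness_Hindie=min(x[2], x[1], x[0]),
                          turret_speed_nT=x[3], glidant_conc_cl=cl)
        y, pen = _outputs_vector(u, params, geometry, glidant_active, None)
        return np.concatenate([(y - tvec) / tvec, [math.sqrt(pen)]])

    rng = np.random.default_rng(seed)
    lo, hi = (np.array(b) for b in _CAL_BOUNDS)
    starts = [np.array(x0)] if x0 is not None else []
    starts.append(np.array([7.0, 4.0, 1.2, 55.0]))
    while len(starts) < n_starts:
        starts.append(lo + rng.random(4) * (hi - lo))

    best = None
    for s in starts:
        try:
            res = optimize.least_squares(resid, np.clip(s, lo, hi),
                                         bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
                                         gtol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-16:
            break
    if best is None or np.linalg.norm(best.fun[:4]) > 1e-6:
        raise CompactionModelError(
            f"inversion failed: best relative residual "
            f"{np.linalg.norm(best.fun[:4]) if best is not None else math.inf:.2e}")
    x = best.x
    return ProcessInputs(dosing_position_Hfill=x[0],
                         precomp_thickness_Hpc=min(x[1], x[0]),
                         maincomp_thickness_Hindie=min(x[2], x[1], x[0]),
                         turret_speed_nT=x[3], glidant_conc_cl=cl)


def calibrate_nominal_inputs(params: ModelParameters, geometry: ToolingGeometry,
                             targets: Optional[dict] = None,
                             glidant_active: bool = False,
                             cl: float = 0.2) -> ProcessInputs:
    """Root-find the nominal operating point: the inputs at which the
    noise-free model outputs equal the nominal setpoints (210 mg, 0.3 kN,
    6.9 kg/h, 4.2 MPa by default)."""
    return invert_outputs(targets or NOMINAL_SETPOINTS, params, geometry,
                          glidant_active=glidant_active, cl=cl)
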