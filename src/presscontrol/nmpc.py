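"""Receding-horizon nonlinear MPC with move blocking.

At each step the controller minimises

    sum_{t=k}^{k+Np} (y_hat_t - y_sp)' W_y (y_hat_t - y_sp)
        + sum_{t=k}^{k+Nc-1} du_t' W_du du_t

over the move sequence, where ``y_hat = h(u, theta_hat) + zeta`` adds the
current output-disturbance median to every measured controlled output over
the whole prediction horizon (held at its time-k value), while the
soft-sensed tensile strength carries no disturbance term.  Moves beyond the
control window are zero, so the input is constant over the tail of the
prediction horizon; because the process model is a static map, the tail
reduces to a terminal weight on the last blocked input, but the objective
is assembled over the full horizon so the code remains valid if dynamics
are added.  Only the first move is ever applied (receding horizon).

Outputs are normalised by their setpoints and moves by their actuator
ranges, so the default weights are dimensionless.  Input-box, move-size and
compression-ordering constraints (H_in-die <= H_pc <= H_fill) are linear in
the move sequence and passed to SLSQP with their exact constant Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .compaction import _evaluate_core, evaluate_outputs_soft
from .params import ModelParameters, ProcessInputs, ToolingGeometry

__all__ = [
    "ControllerConfig",
    "ControlMove",
    "nmpc_solve",
    "predict_horizon",
    "default_controller_config",
    "INPUT_FIELDS",
    "CONTROLLED_OUTPUT_ATTRS",
]

INPUT_FIELDS = ("dosing_position_Hfill", "precomp_thickness_Hpc",
                "maincomp_thickness_Hindie", "turret_speed_nT",
                "glidant_conc_cl")

CONTROLLED_OUTPUT_ATTRS = {
    "weight": "tablet_weight_W",
    "pcf": "precompression_force_Fpc",
    "rate": "production_rate",
    "tensile": "tensile_strength_sigmat",
}

DEFAULT_U_BOUNDS = {
    "dosing_position_Hfill": (2.0, 16.0),     # mm
    "precomp_thickness_Hpc": (2.0, 8.0),      # mm
    "maincomp_thickness_Hindie": (1.0, 6.0),  # mm
    "turret_speed_nT": (10.0, 100.0),         # rev/min
    "glidant_conc_cl": (0.0, 1.0),            # % w/w
}

# Thickness ordering pairs enforced at every horizon step.
_ORDERING = (("dosing_position_Hfill", "precomp_thickness_Hpc"),
             ("precomp_thickness_Hpc", "maincomp_thickness_Hindie"))


@dataclass(frozen=True)
class ControllerConfig:
    """Tuning of the receding-horizon controller."""

    manipulated_inputs: tuple
    controlled_outputs: tuple = ("weight", "pcf", "rate", "tensile")
    n_pred: int = 60
    n_ctrl: int = 10
    w_y: dict = field(default_factory=lambda: {
        "weight": 1.0, "pcf": 1.0, "rate": 1.0, "tensile": 1.0})
    w_du: float = 0.01
    u_bounds: dict = field(default_factory=lambda: dict(DEFAULT_U_BOUNDS))
    du_frac: float = 0.02       # per-step move limit, fraction of range
    maxiter: int = 60
    ftol: float = 1e-10

    def __post_init__(self) -> None:
        if not (1 <= self.n_ctrl <= self.n_pred):
            raise ValueError("require 1 <= n_ctrl <= n_pred")
        if any(w < 0 for w in self.w_y.values()) or self.w_du < 0:
            raise ValueError("weights must be >= 0")
        for name in self.manipulated_inputs:
            lo, hi = self.u_bounds[name]
            if not lo < hi:
                raise ValueError(f"empty input bound interval for {name}")


def default_controller_config(case: str) -> ControllerConfig:
    """4x5 system for case 1 (glidant concentration manipulated), 4x4 for
    case 2 (glidant concentration is an uncertain parameter)."""
    if case == "case1":
        return ControllerConfig(manipulated_inputs=INPUT_FIELDS)
    if case == "case2":
        return ControllerConfig(manipulated_inputs=INPUT_FIELDS[:4])
    raise ValueError(f"unknown case {case!r}")


@dataclass(frozen=True)
class ControlMove:
    """First move of the optimised sequence, plus solver diagnostics."""

    du_first: dict                  # input name -> applied delta
    u_applied: ProcessInputs
    predicted_outputs: list         # per blocked step: dict of outputs (with zeta)
    objective_value: float
    converged: bool
    du_plan: np.ndarray = None      # (n_ctrl, n_u) solution, for warm starting


def _substitute_theta(theta_hat: dict, model_params: ModelParameters,
                      manipulated: tuple):
    """Apply the estimate to the model; the glidant concentration becomes a
    cl-override only when it is not itself a manipulated input."""
    updates, cl_override = {}, None
    for name, value in (theta_hat or {}).items():
        if name == "glidant_conc_cl":
            if name not in manipulated:
                cl_override = float(value)
        else:
            updates[name] = float(value)
    params = model_params.replace(**updates) if updates else model_params
    return params, cl_override


def _make_inputs(u_prev: ProcessInputs, manipulated, values) -> ProcessInputs:
    d = u_prev.to_dict()
    d.update(dict(zip(manipulated, map(float, values))))
    # tiny numerical violations from optimizer iterates are snapped
    d["glidant_conc_cl"] = max(d["glidant_conc_cl"], 0.0)
    d["maincomp_thickness_Hindie"] = min(d["maincomp_thickness_Hindie"],
                                         d["precomp_thickness_Hpc"],
                                         d["dosing_position_Hfill"])
    d["precomp_thickness_Hpc"] = min(d["precomp_thickness_Hpc"],
                                     d["dosing_position_Hfill"])
    return ProcessInputs(**d)


def predict_horizon(theta_hat: dict, zeta: dict, u_trajectory,
                    model_params: ModelParameters, geometry: ToolingGeometry,
                    cfg: ControllerConfig, u_prev: ProcessInputs,
                    glidant_active: bool = False):
    """Predicted controlled outputs along a blocked input trajectory.

    ``u_trajectory`` is an (n_steps, n_u) array of manipulated-input values
    (already cumulated).  The static map is evaluated at each step; the
    disturbance median is added to every measured controlled output (all
    but the soft-sensed tensile strength).  Returns (list of per-step
    output dicts, accumulated validity penalty).
    """
    params, cl_override = _substitute_theta(theta_hat, model_params,
                                            cfg.manipulated_inputs)
    zeta = zeta or {}
    traj, penalty = [], 0.0
    for row in np.atleast_2d(u_trajectory):
        u = _make_inputs(u_prev, cfg.manipulated_inputs, row)
        out, pen = evaluate_outputs_soft(u, params, geometry,
                                         glidant_active=glidant_active,
                                         cl_override=cl_override)
        penalty += pen
        y = {k: getattr(out, attr) for k, attr in CONTROLLED_OUTPUT_ATTRS.items()}
        for k in y:
            if k != "tensile":
                y[k] += zeta.get(k, 0.0)
        traj.append(y)
    return traj, penalty


def _linear_constraints(u_prev_vec, lo, hi, cfg):
    """Box and ordering constraints as A x + b >= 0 over the flattened move
    sequence (cumulative-sum map is linear with a constant Jacobian)."""
    nc, nu = cfg.n_ctrl, len(cfg.manipulated_inputs)
    idx = {name: i for i, name in enumerate(cfg.manipulated_inputs)}
    cum = np.tril(np.ones((nc, nc)))
    rows, offs = [], []
    for i in range(nu):
        sel = np.zeros((nc, nc * nu))
        sel[:, i::nu] = cum
        rows.append(sel)                      # u_j >= lo
        offs.append(np.full(nc, u_prev_vec[i] - lo[i]))
        rows.append(-sel)                     # u_j <= hi
        offs.append(np.full(nc, hi[i] - u_prev_vec[i]))
    for hi_name, lo_name in _ORDERING:
        if hi_name in idx and lo_name in idx:
            a, b_ = idx[hi_name], idx[lo_name]
            sel = np.zeros((nc, nc * nu))
            sel[:, a::nu] = cum
            sel[:, b_::nu] -= cum
            rows.append(sel)                  # u_hi_j - u_lo_j >= gap
            offs.append(np.full(nc, u_prev_vec[a] - u_prev_vec[b_]))
    A = np.vstack(rows)
    b = np.concatenate(offs)
    return A, b


def nmpc_solve(theta_hat: dict, zeta: dict, y_sp: dict, u_prev: ProcessInputs,
               model_params: ModelParameters, geometry: ToolingGeometry,
               cfg: ControllerConfig, glidant_active: bool = False,
               warm_start: Optional[np.ndarray] = None) -> ControlMove:
    """Solve the receding-horizon problem and return the first move.

    On solver failure, or if the solution is worse than holding the input,
    the move is zero and ``converged`` is False only for genuine solver
    failure.  The applied input always satisfies the input box and the
    per-step move limit.
    """
    nc, nu = cfg.n_ctrl, len(cfg.manipulated_inputs)
    u_prev_vec = np.array([getattr(u_prev, n) for n in cfg.manipulated_inputs])
    lo = np.array([cfg.u_bounds[n][0] for n in cfg.manipulated_inputs])
    hi = np.array([cfg.u_bounds[n][1] for n in cfg.manipulated_inputs])
    ranges = hi - lo
    du_max = cfg.du_frac * ranges
    sp = np.array([y_sp[k] for k in cfg.controlled_outputs])
    wy = np.array([cfg.w_y[k] for k in cfg.controlled_outputs])
    # terminal block weight: steps k+Nc .. k+Np share the last blocked input
    step_w = np.ones(nc)
    step_w[-1] += cfg.n_pred - cfg.n_ctrl

    params, cl_override = _substitute_theta(theta_hat, model_params,
                                            cfg.manipulated_inputs)
    zeta_vec = np.array([0.0 if k == "tensile" else (zeta or {}).get(k, 0.0)
                         for k in cfg.controlled_outputs])

    # core result indices for the controlled outputs (W, F_pc, F_mc, rate, sigma_t)
    _CORE_IDX = {"weight": 0, "pcf": 1, "rate": 3, "tensile": 4}
    out_idx = [_CORE_IDX[k] for k in cfg.controlled_outputs]
    base = [getattr(u_prev, n) for n in INPUT_FIELDS]
    pos = {n: i for i, n in enumerate(INPUT_FIELDS)}
    man_pos = [pos[n] for n in cfg.manipulated_inputs]
    sp_l, wy_l, zeta_l = sp.tolist(), wy.tolist(), zeta_vec.tolist()
    w_du_n = cfg.w_du / ranges ** 2

    def stage_cost(u_vals):
        """Weighted tracking error plus validity penalty at one input point."""
        hf, hp, hi_, nt, cl = u_vals
        # snap tiny ordering violations so the kernel stays evaluable
        hp = hp if hp <= hf else hf
        hi_ = hi_ if hi_ <= hp else hp
        res = _evaluate_core(hf, hp, hi_, nt,
                             cl if cl_override is None else cl_override,
                             params, geometry, glidant_active, soft=True)
        track = 0.0
        for i, oi in enumerate(out_idx):
            e = (res[oi] + zeta_l[i] - sp_l[i]) / sp_l[i]
            track += wy_l[i] * e * e
        return track + res[10]

    def _stage_points(x):
        du = x.reshape(nc, nu)
        U = u_prev_vec + np.cumsum(du, axis=0)
        pts = []
        for j in range(nc):
            vals = base.copy()
            for p_, v in zip(man_pos, U[j]):
                vals[p_] = v
            pts.append(vals)
        return du, pts

    def objective(x):
        du, pts = _stage_points(x)
        J = sum(step_w[j] * stage_cost(pts[j]) for j in range(nc))
        return J + float(np.sum(w_du_n * du * du))

    # Because the model is static, the stage cost at horizon step m depends
    # only on the cumulated input U_m, and dJ/d(du_j) is the suffix sum over
    # m >= j of the stage gradients: one forward-difference gradient per
    # blocked step instead of one full objective per decision variable.
    fd_h = 1e-7 * ranges

    def gradient(x):
        du, pts = _stage_points(x)
        g_stage = np.empty((nc, nu))
        for j in range(nc):
            f0 = stage_cost(pts[j])
            for i in range(nu):
                pert = list(pts[j])
                pert[man_pos[i]] += fd_h[i]
                g_stage[j, i] = step_w[j] * (stage_cost(pert) - f0) / fd_h[i]
        suffix = np.cumsum(g_stage[::-1], axis=0)[::-1]
        return (suffix + 2.0 * w_du_n * du).ravel()

    A, b = _linear_constraints(u_prev_vec, lo, hi, cfg)
    cons = {"type": "ineq", "fun": lambda x: A @ x + b, "jac": lambda x: A}
    bounds = [(-du_max[i], du_max[i]) for _ in range(nc) for i in range(nu)]

    x0 = np.zeros(nc * nu)
    if warm_start is not None and warm_start.shape == (nc, nu):
        x0 = np.vstack([warm_start[1:], np.zeros((1, nu))]).ravel()
        x0 = np.clip(x0, [bd[0] for bd in bounds], [bd[1] for bd in bounds])
        if np.any(A @ x0 + b < 0):
            x0 = np.zeros(nc * nu)

    J_hold = objective(np.zeros(nc * nu))
    converged = True
    best_x, best_J = np.zeros(nc * nu), J_hold
    try:
        res = optimize.minimize(objective, x0, jac=gradient, method="SLSQP",
                                bounds=bounds, constraints=[cons],
                                options={"maxiter": cfg.maxiter,
                                         "ftol": cfg.ftol})
        # micro-violations from SLSQP's active-set iterates are harmless:
        # the applied first move is clipped into the box and move limits
        feasible = np.all(A @ res.x + b >= -1e-6)
        if feasible and res.fun <= best_J:
            best_x, best_J = res.x, float(res.fun)
        converged = bool(res.success)
    except Exception:
        converged = False

    du = best_x.reshape(nc, nu)
    du0 = np.clip(du[0], -du_max, du_max)
    u_new_vec = np.clip(u_prev_vec + du0, lo, hi)
    du0 = u_new_vec - u_prev_vec
    u_applied = _make_inputs(u_prev, cfg.manipulated_inputs, u_new_vec)
    U = u_prev_vec + np.cumsum(du, axis=0)
    predicted, _ = predict_horizon(theta_hat, zeta, U, model_params, geometry,
                                   cfg, u_prev, glidant_active=glidant_active)
    return ControlMove(
        du_first=dict(zip(cfg.manipulated_inputs, map(float, du0))),
        u_applied=u_applied, predicted_outputs=predicted,
        objective_value=best_J, converged=converged, du_plan=du)
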