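"""Moving-horizon estimation of uncertain model parameters and the
output-disturbance median.

At each control interval the estimator solves a bounded least-squares
problem over the past measurement window

    min_theta  sum_t  eps_t' W_E eps_t  +  (theta - theta_prev)' W_theta (theta - theta_prev)

where ``eps_t = y_t - y_hat_t(u_t, theta)`` and the model prediction is the
static compaction output map with ``theta`` substituted.  The compaction
model has no differential states, so the state-propagation constraint of
the generic moving-horizon formulation collapses to the algebraic output
map and the decision vector is the parameter vector alone; the information
carried from one interval to the next is the incumbent estimate and the
sliding window itself.

The per-output median of the residuals at the optimum is the output
disturbance ``zeta`` used by the controller for offset-free tracking: the
median is robust to outliers in the window, unlike the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .compaction import _evaluate_core
from .params import ModelParameters, ToolingGeometry
from .plant import DEFAULT_NOISE_SD, MEASURED_OUTPUTS, MeasurementRecord

__all__ = [
    "EstimatorConfig",
    "EstimateBundle",
    "MovingHorizonEstimator",
    "mhe_update",
    "median_disturbance",
    "default_estimator_config",
]


def median_disturbance(residuals) -> np.ndarray:
    """Componentwise median of a per-output residual series.

    ``residuals`` is array-like of shape (n_samples, n_outputs) or
    (n_samples,).  Even-length series give the midpoint of the two central
    order statistics.
    """
    arr = np.asarray(residuals, dtype=float)
    if arr.size == 0:
        raise ValueError("residual series is empty")
    return np.median(arr, axis=0)


@dataclass(frozen=True)
class EstimatorConfig:
    """Tuning of the moving-horizon estimator.

    ``theta_names`` are fields of :class:`ModelParameters`, or the special
    name ``"glidant_conc_cl"`` for the uncertain silica concentration.
    ``w_e`` are per-output residual weights applied on top of the
    inverse-noise-variance normalisation; ``w_theta`` penalises relative
    deviation from the incumbent estimate (soft trust region).
    """

    theta_names: tuple
    theta_bounds: dict              # name -> (lo, hi)
    theta_ref: dict                 # name -> normalisation scale (> 0)
    n_past: int = 30
    w_e: dict = field(default_factory=lambda: {k: 1.0 for k in MEASURED_OUTPUTS})
    w_theta: float = 1e-2
    residual_scale: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    residual_outputs: tuple = ("weight", "pcf", "mcf", "rate")
    solver_tol: float = 1e-8
    maxiter: int = 100

    def __post_init__(self) -> None:
        if self.n_past < 1:
            raise ValueError("n_past must be >= 1")
        if any(w < 0 for w in self.w_e.values()) or self.w_theta < 0:
            raise ValueError("weights must be >= 0")
        for name in self.theta_names:
            lo, hi = self.theta_bounds[name]
            if not lo < hi:
                raise ValueError(f"empty bound interval for {name}")
            if self.theta_ref[name] <= 0:
                raise ValueError(f"theta_ref must be positive for {name}")


def default_estimator_config(case: str,
                             model_params: Optional[ModelParameters] = None,
                             cl_nominal: float = 0.2) -> EstimatorConfig:
    """Default estimator tuning for the two case studies.

    Case 1 tracks bulk density, critical density and the Kawakita ``a``
    within +/-30% of nominal (brackets every plant column); case 2 tracks
    the silica concentration on [0, 1] % w/w.
    """
    from .params import get_parameters
    if case == "case1":
        p = model_params or get_parameters("no_pmm")
        names = ("rho_b", "rho_c", "kaw_a")
        nominal = {n: getattr(p, n) for n in names}
        return EstimatorConfig(
            theta_names=names,
            theta_bounds={n: (0.7 * v, 1.3 * v) for n, v in nominal.items()},
            theta_ref=dict(nominal))
    if case == "case2":
        return EstimatorConfig(
            theta_names=("glidant_conc_cl",),
            theta_bounds={"glidant_conc_cl": (1e-4, 1.0)},
            theta_ref={"glidant_conc_cl": cl_nominal})
    raise ValueError(f"unknown case {case!r}")


@dataclass(frozen=True)
class EstimateBundle:
    """Result of one moving-horizon update."""

    theta_hat: dict                 # name -> estimate
    zeta: dict                      # output -> residual median (raw units)
    y_hat_window: list              # per-record dict of reconstructed outputs
    objective_value: float
    converged: bool

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.zeta.values()):
            raise ValueError("zeta must be finite")
        if self.objective_value < 0:
            raise ValueError("objective must be >= 0")


class MovingHorizonEstimator:
    """Windowed nonlinear least-squares model of the past measurements.

    Statsmodels-style: construct from the data window and configuration,
    call :meth:`fit` (with the incumbent estimate as the warm start /
    regularisation anchor) to obtain an :class:`EstimateBundle`.
    """

    def __init__(self, window: Sequence[MeasurementRecord],
                 model_params: ModelParameters, geometry: ToolingGeometry,
                 config: EstimatorConfig, glidant_active: bool = False):
        if not window:
            raise ValueError("measurement window is empty")
        self.window = list(window)[-(config.n_past + 1):]
        self.model_params = model_params
        self.geometry = geometry
        self.config = config
        self.glidant_active = glidant_active
        self._names = list(config.theta_names)
        self._ref = np.array([config.theta_ref[n] for n in self._names])
        self._lo = np.array([config.theta_bounds[n][0] for n in self._names])
        self._hi = np.array([config.theta_bounds[n][1] for n in self._names])
        # unpack window once for the float-only model kernel
        self._u_rows = [(r.applied_inputs.dosing_position_Hfill,
                         r.applied_inputs.precomp_thickness_Hpc,
                         r.applied_inputs.maincomp_thickness_Hindie,
                         r.applied_inputs.turret_speed_nT,
                         r.applied_inputs.glidant_conc_cl)
                        for r in self.window]

    # -- model plumbing ----------------------------------------------------

    def _substitute(self, theta: np.ndarray):
        """Split the decision vector into a parameter replacement and an
        optional glidant-concentration override."""
        updates, cl_override = {}, None
        for name, value in zip(self._names, theta):
            if name == "glidant_conc_cl":
                cl_override = float(value)
            else:
                updates[name] = float(value)
        params = self.model_params.replace(**updates) if updates else self.model_params
        return params, cl_override

    def _predict_window(self, theta: np.ndarray):
        """Model outputs for every record in the window at ``theta``.

        Returns (list of per-record output dicts, accumulated penalty).
        """
        params, cl_override = self._substitute(theta)
        y_hat, penalty = [], 0.0
        for (hf, hp, hi_, nt, cl) in self._u_rows:
            res = _evaluate_core(hf, hp, hi_, nt,
                                 cl if cl_override is None else cl_override,
                                 params, self.geometry, self.glidant_active,
                                 soft=True)
            penalty += res[10]
            # core order: W, F_pc, F_mc, rate
            y_hat.append({"weight": res[0], "pcf": res[1],
                          "mcf": res[2], "rate": res[3]})
        return y_hat, penalty

    def _residual_matrix(self, y_hat):
        keys = self.config.residual_outputs
        return np.array([[rec.measured()[k] - yh[k] for k in keys]
                         for rec, yh in zip(self.window, y_hat)])

    def _objective(self, theta_scaled: np.ndarray, theta_prev_scaled: np.ndarray):
        theta = theta_scaled * self._ref
        y_hat, penalty = self._predict_window(theta)
        eps = self._residual_matrix(y_hat)
        keys = self.config.residual_outputs
        scale = np.array([self.config.residual_scale[k] for k in keys])
        w = np.array([self.config.w_e[k] for k in keys])
        J = float(np.sum(w * (eps / scale) ** 2))
        J += self.config.w_theta * float(
            np.sum((theta_scaled - theta_prev_scaled) ** 2))
        return J + penalty

    # -- public surface ----------------------------------------------------

    def evaluate(self, theta: dict) -> EstimateBundle:
        """Residuals, median disturbance and objective at a fixed ``theta``
        (no optimisation); used when parameter updating is disabled."""
        vec = np.array([theta[n] for n in self._names])
        y_hat, _ = self._predict_window(vec)
        eps = self._residual_matrix(y_hat)
        zeta = median_disturbance(eps)
        J = self._objective(vec / self._ref, vec / self._ref)
        return EstimateBundle(
            theta_hat={n: float(v) for n, v in zip(self._names, vec)},
            zeta=dict(zip(self.config.residual_outputs, map(float, zeta))),
            y_hat_window=y_hat, objective_value=J, converged=True)

    def fit(self, theta_prev: dict) -> EstimateBundle:
        """Solve the windowed estimation problem warm-started at the
        incumbent estimate.

        The returned estimate never degrades the incumbent: if the solver
        fails, or ends at a worse objective than ``theta_prev``, the
        incumbent is kept (with ``converged=False`` on solver failure).
        """
        x_prev = np.clip(np.array([theta_prev[n] for n in self._names]),
                         self._lo, self._hi) / self._ref
        bounds = list(zip(self._lo / self._ref, self._hi / self._ref))
        J_prev = self._objective(x_prev, x_prev)
        converged = True
        x_best, J_best = x_prev, J_prev
        try:
            res = optimize.minimize(
                self._objective, x_prev, args=(x_prev,), method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.config.maxiter, "ftol": 1e-15,
                         "gtol": self.config.solver_tol})
            if res.fun <= J_prev:
                x_best, J_best = res.x, float(res.fun)
            converged = bool(res.success) or res.fun <= J_prev
        except Exception:
            converged = False

        theta = np.clip(x_best * self._ref, self._lo, self._hi)
        y_hat, _ = self._predict_window(theta)
        zeta = median_disturbance(self._residual_matrix(y_hat))
        return EstimateBundle(
            theta_hat={n: float(v) for n, v in zip(self._names, theta)},
            zeta=dict(zip(self.config.residual_outputs, map(float, zeta))),
            y_hat_window=y_hat, objective_value=J_best, converged=converged)


def mhe_update(window: Sequence[MeasurementRecord], theta_prev: dict,
               model_params: ModelParameters, geometry: ToolingGeometry,
               cfg: EstimatorConfig, glidant_active: bool = False) -> EstimateBundle:
    """One moving-horizon update: fit the window starting from ``theta_prev``."""
    return MovingHorizonEstimator(window, model_params, geometry, cfg,
                                  glidant_active=glidant_active).fit(theta_prev)
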