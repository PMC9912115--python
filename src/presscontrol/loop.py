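"""Closed-loop orchestration of the virtual plant, the moving-horizon
estimator and the receding-horizon controller.

The case-study timeline is: open-loop operation over [0, 100) s, estimation
with open-loop inputs over [100, 200) s, and closed-loop control from
200 s.  In ``nmpc_only`` mode parameter updating is disabled (the estimate
stays at nominal) but the output-disturbance median is still maintained
from the residual window; in ``open`` mode neither runs and the inputs are
held at the calibrated nominal point.

Every run is fully determined by the scenario (which carries the seed);
two runs with identical configuration produce byte-identical CSV output.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .metrics import compute_metrics
from .mhe import (
    EstimatorConfig,
    MovingHorizonEstimator,
    default_estimator_config,
)
from .nmpc import (
    ControllerConfig,
    default_controller_config,
    nmpc_solve,
)
from .compaction import evaluate_outputs_soft
from .plant import ScenarioConfig, VirtualPlant

__all__ = ["RunResult", "run_closed_loop", "MODES"]

MODES = ("open", "nmpc_only", "mhe_nmpc")

_TRUTH_ATTRS = {
    "weight": "tablet_weight_W",
    "pcf": "precompression_force_Fpc",
    "mcf": "main_compression_force_Fpunch",
    "rate": "production_rate",
    "tensile": "tensile_strength_sigmat",
}


@dataclass
class RunResult:
    """All series of one closed-loop run on the shared 1 s time grid."""

    scenario: ScenarioConfig
    mode: str
    measurements: pd.DataFrame
    truth: pd.DataFrame
    estimates: pd.DataFrame
    moves: pd.DataFrame
    setpoints: pd.DataFrame
    soft_tensile: pd.DataFrame
    est_cfg: EstimatorConfig
    ctl_cfg: ControllerConfig
    wall_time_s: float = 0.0

    def event_times(self) -> list:
        evs = [e[0] for e in self.scenario.setpoint_schedule]
        evs += [e[0] for e in self.scenario.disturbance_schedule]
        return sorted(set(evs))

    def metrics(self, band: float = 1.0, window=(300, 1000)) -> dict:
        return compute_metrics(self, band=band, window=window)

    def save(self, out_dir: str | Path, band: float = 1.0,
             window=(300, 1000)) -> Path:
        """Write measurements/truth/estimates/moves/setpoints CSVs plus
        metrics.json and a config echo into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(out / "measurements.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.estimates.to_csv(out / "estimates.csv", index=False)
        self.moves.to_csv(out / "moves.csv", index=False)
        self.setpoints.to_csv(out / "setpoints.csv", index=False)
        self.soft_tensile.to_csv(out / "soft_tensile.csv", index=False)
        with open(out / "metrics.json", "w") as fh:
            json.dump(self.metrics(band=band, window=window), fh, indent=2)
        echo = {
            "scenario": self.scenario.name,
            "mode": self.mode,
            "seed": self.scenario.seed,
            "horizon_end": self.scenario.horizon_end,
            "noise_sd": self.scenario.noise_sd,
            "estimator": {
                "n_past": self.est_cfg.n_past,
                "theta_names": list(self.est_cfg.theta_names),
                "w_theta": self.est_cfg.w_theta,
            },
            "controller": {
                "n_pred": self.ctl_cfg.n_pred,
                "n_ctrl": self.ctl_cfg.n_ctrl,
                "w_du": self.ctl_cfg.w_du,
                "du_frac": self.ctl_cfg.du_frac,
                "manipulated_inputs": list(self.ctl_cfg.manipulated_inputs),
            },
        }
        with open(out / "config.json", "w") as fh:
            json.dump(echo, fh, indent=2)
        return out


def run_closed_loop(scenario: ScenarioConfig,
                    est_cfg: Optional[EstimatorConfig] = None,
                    ctl_cfg: Optional[ControllerConfig] = None,
                    mode: str = "mhe_nmpc") -> RunResult:
    """Run one case study end to end and return all series.

    Per 1 s step: sample the plant, update the estimate (moving-horizon fit
    in ``mhe_nmpc``; residual median only in ``nmpc_only``), evaluate the
    tensile soft sensor, then solve the receding-horizon problem and apply
    the first move.  Any estimator or controller failure is recorded in the
    trace and the loop continues with held inputs.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; valid: {MODES}")
    est_cfg = est_cfg or default_estimator_config(
        scenario.case, scenario.model_params, cl_nominal=scenario.cl_nominal)
    ctl_cfg = ctl_cfg or default_controller_config(scenario.case)
    # sensor noise levels feed the estimator's inverse-variance residual
    # scaling (zero-noise scenarios keep the default scales)
    scales = {k: (scenario.noise_sd[k] if scenario.noise_sd[k] > 0
                  else est_cfg.residual_scale[k])
              for k in est_cfg.residual_scale}
    est_cfg = EstimatorConfig(
        theta_names=est_cfg.theta_names, theta_bounds=est_cfg.theta_bounds,
        theta_ref=est_cfg.theta_ref, n_past=est_cfg.n_past, w_e=est_cfg.w_e,
        w_theta=est_cfg.w_theta, residual_scale=scales,
        residual_outputs=est_cfg.residual_outputs,
        solver_tol=est_cfg.solver_tol, maxiter=est_cfg.maxiter)

    plant = VirtualPlant(scenario)
    u = scenario.u0
    theta_nominal = {}
    for name in est_cfg.theta_names:
        if name == "glidant_conc_cl":
            theta_nominal[name] = scenario.cl_nominal
        else:
            theta_nominal[name] = getattr(scenario.model_params, name)
    theta = dict(theta_nominal)
    zeta = {k: 0.0 for k in est_cfg.residual_outputs}
    setpoints = dict(scenario.setpoints0)
    sp_schedule = list(scenario.setpoint_schedule)
    sp_idx = 0
    warm = None

    records = []
    m_rows, t_rows, e_rows, mv_rows, sp_rows, soft_rows = [], [], [], [], [], []
    t_start = _time.perf_counter()

    for t in range(scenario.horizon_end + 1):
        while sp_idx < len(sp_schedule) and sp_schedule[sp_idx][0] <= t:
            _, out_name, value = sp_schedule[sp_idx]
            setpoints[out_name] = value
            sp_idx += 1

        record, truth = plant.step(t, u)
        records.append(record)

        estimate_active = (mode != "open" and t >= scenario.t_estimation_start)
        bundle = None
        if estimate_active:
            window = records[-(est_cfg.n_past + 1):]
            est = MovingHorizonEstimator(window, scenario.model_params,
                                         scenario.geometry, est_cfg,
                                         glidant_active=scenario.glidant_active)
            try:
                if mode == "mhe_nmpc":
                    bundle = est.fit(theta)
                else:
                    bundle = est.evaluate(theta_nominal)
                theta = bundle.theta_hat
                zeta = bundle.zeta
            except Exception:
                bundle = None  # hold previous estimate

        # tensile soft sensor: controller-side model at the current inputs
        params_model, cl_override = _model_view(theta, scenario,
                                                ctl_cfg.manipulated_inputs)
        soft_out, _ = evaluate_outputs_soft(
            u, params_model, scenario.geometry,
            glidant_active=scenario.glidant_active, cl_override=cl_override)

        move = None
        if mode != "open" and t >= scenario.t_control_start:
            move = nmpc_solve(theta, zeta, setpoints, u, scenario.model_params,
                              scenario.geometry, ctl_cfg,
                              glidant_active=scenario.glidant_active,
                              warm_start=warm)
            warm = move.du_plan
            u = move.u_applied

        # -- trace rows ----------------------------------------------------
        m_rows.append({"time_s": t, "weight_mg": record.weight,
                       "pcf_kN": record.pcf, "mcf_kN": record.mcf,
                       "rate_kg_h": record.rate,
                       **{f"u_{k}": v for k, v in
                          record.applied_inputs.to_dict().items()}})
        t_rows.append({"time_s": t,
                       **{f"true_{k}": getattr(truth, a)
                          for k, a in _TRUTH_ATTRS.items()},
                       "true_bulk_density": truth.bulk_density,
                       "true_glidant_conc": plant.true_glidant_conc})
        sp_rows.append({"time_s": t,
                        **{f"sp_{k}": setpoints[k] for k in
                           ("weight", "pcf", "rate", "tensile")}})
        soft_rows.append({"time_s": t,
                          "sigma_t_soft_MPa": soft_out.tensile_strength_sigmat})
        if estimate_active:
            row = {"time_s": t, "converged": bundle is not None and bundle.converged,
                   "objective": bundle.objective_value if bundle else np.nan}
            for n in est_cfg.theta_names:
                row[f"theta_{n}"] = theta[n]
            for k in est_cfg.residual_outputs:
                row[f"zeta_{k}"] = zeta[k]
            e_rows.append(row)
        if move is not None:
            mv_rows.append({"time_s": t, "objective": move.objective_value,
                            "converged": move.converged,
                            **{f"du_{k}": v for k, v in move.du_first.items()},
                            **{f"u_{k}": getattr(move.u_applied, k)
                               for k in ctl_cfg.manipulated_inputs}})

    return RunResult(
        scenario=scenario, mode=mode,
        measurements=pd.DataFrame(m_rows), truth=pd.DataFrame(t_rows),
        estimates=pd.DataFrame(e_rows), moves=pd.DataFrame(mv_rows),
        setpoints=pd.DataFrame(sp_rows), soft_tensile=pd.DataFrame(soft_rows),
        est_cfg=est_cfg, ctl_cfg=ctl_cfg,
        wall_time_s=_time.perf_counter() - t_start)


def _model_view(theta: dict, scenario: ScenarioConfig, manipulated: tuple):
    """Controller-side parameter view: estimate substituted into the model
    copy; silica becomes a concentration override when not manipulated."""
    updates, cl_override = {}, None
    for name, value in theta.items():
        if name == "glidant_conc_cl":
            if name not in manipulated:
                cl_override = float(value)
        else:
            updates[name] = float(value)
    params = (scenario.model_params.replace(**updates)
              if updates else scenario.model_params)
    return params, cl_override
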