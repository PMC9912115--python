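"""Virtual plant: the compaction model with scenario-specific (mismatched)
parameters, sensor noise, and timed disturbance / setpoint schedules.

The plant is the source of truth in every simulation and the generator of
all synthetic measurement streams used by the tests.  The controller-facing
surface is the stream of :class:`MeasurementRecord`; the plant's own
parameters are deliberately not part of any estimator or controller call
signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .compaction import calibrate_nominal_inputs, evaluate_outputs
from .params import (
    ModelParameters,
    ProcessInputs,
    ProcessOutputs,
    ToolingGeometry,
    get_parameters,
)

__all__ = [
    "ScenarioConfig",
    "MeasurementRecord",
    "VirtualPlant",
    "make_scenario",
    "SCENARIO_NAMES",
    "DEFAULT_NOISE_SD",
    "MEASURED_OUTPUTS",
]

# Measured channels and the ProcessOutputs attribute each one samples.
MEASURED_OUTPUTS = {
    "weight": "tablet_weight_W",
    "pcf": "precompression_force_Fpc",
    "mcf": "main_compression_force_Fpunch",
    "rate": "production_rate",
}

# 1-sigma sensor noise, chosen at roughly 0.5-5% of the nominal signal:
# weight mg, PCF kN, MCF kN, rate kg/h.
DEFAULT_NOISE_SD = {"weight": 1.0, "pcf": 0.02, "mcf": 0.2, "rate": 0.05}

SCENARIO_NAMES = ("cs1_no_pmm", "cs1_mild_pmm", "cs1_high_pmm", "cs2_silica_steps")

# Case-study timeline: open loop, then estimation only, then closed loop.
T_ESTIMATION_START = 100
T_CONTROL_START = 200


@dataclass(frozen=True)
class MeasurementRecord:
    """One second of noisy plant outputs with the inputs that produced it."""

    time: int
    weight: float   # mg
    pcf: float      # kN
    mcf: float      # kN
    rate: float     # kg/h
    applied_inputs: ProcessInputs

    def measured(self) -> dict:
        return {"weight": self.weight, "pcf": self.pcf,
                "mcf": self.mcf, "rate": self.rate}


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one reproducible case-study run."""

    name: str
    case: str                         # "case1" (4x5) or "case2" (4x4)
    plant_params: ModelParameters
    model_params: ModelParameters     # the controller/estimator copy
    geometry: ToolingGeometry
    glidant_active: bool              # bulk density from the glidant model?
    u0: ProcessInputs                 # calibrated nominal operating point
    setpoints0: dict
    noise_sd: dict
    disturbance_schedule: tuple       # ((time s, name, value), ...)
    setpoint_schedule: tuple          # ((time s, output, value), ...)
    horizon_end: int                  # s
    seed: int
    cl_nominal: float = 0.2           # % w/w
    t_estimation_start: int = T_ESTIMATION_START
    t_control_start: int = T_CONTROL_START

    def __post_init__(self) -> None:
        for sched in (self.disturbance_schedule, self.setpoint_schedule):
            times = [e[0] for e in sched]
            if times != sorted(times):
                raise ValueError("schedules must be sorted by time")
            if any(t < 0 or t > self.horizon_end for t in times):
                raise ValueError("schedule times must lie within [0, horizon_end]")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise standard deviations must be >= 0")


def make_scenario(name: str, seed: int = 0, horizon_end: Optional[int] = None,
                  noise_scale: float = 1.0,
                  geometry: Optional[ToolingGeometry] = None) -> ScenarioConfig:
    """Build one of the packaged case-study scenarios.

    Case-study 1 scenarios pair a plant parameter column (no/mild/high
    mismatch) with the nominal model column and the stepped setpoint
    schedule; case-study 2 pairs the nominal glidant model with a plant
    whose silica concentration steps 0.2 -> 0.35 % over [300, 700) s and
    0.2 -> 0.05 % over [1100, 1500) s.  ``noise_scale`` scales all sensor
    noise (0 gives a noise-free plant); ``horizon_end`` truncates or
    extends the default timeline.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; valid names: {SCENARIO_NAMES}")
    geometry = geometry or ToolingGeometry()
    noise = {k: v * noise_scale for k, v in DEFAULT_NOISE_SD.items()}
    setpoints0 = {"weight": 210.0, "pcf": 0.3, "rate": 6.9, "tensile": 4.2}

    if name.startswith("cs1"):
        column = {"cs1_no_pmm": "no_pmm", "cs1_mild_pmm": "mild_pmm",
                  "cs1_high_pmm": "high_pmm"}[name]
        plant = get_parameters(column)
        model = get_parameters("no_pmm")
        horizon = 1000 if horizon_end is None else horizon_end
        sp_schedule = tuple(e for e in (
            (400, "weight", 240.0),
            (600, "pcf", 0.6),
            (600, "tensile", 6.0),
            (800, "rate", 8.0),
        ) if e[0] <= horizon)
        u0 = calibrate_nominal_inputs(model, geometry, glidant_active=False, cl=0.2)
        return ScenarioConfig(
            name=name, case="case1", plant_params=plant, model_params=model,
            geometry=geometry, glidant_active=False, u0=u0,
            setpoints0=setpoints0, noise_sd=noise,
            disturbance_schedule=(), setpoint_schedule=sp_schedule,
            horizon_end=horizon, seed=seed)

    # cs2_silica_steps
    plant = get_parameters("cs2_nominal")
    model = get_parameters("cs2_nominal")
    horizon = 1500 if horizon_end is None else horizon_end
    dist_schedule = tuple(e for e in (
        (300, "glidant_conc_cl", 0.35),
        (700, "glidant_conc_cl", 0.2),
        (1100, "glidant_conc_cl", 0.05),
        (1500, "glidant_conc_cl", 0.2),
    ) if e[0] <= horizon)
    u0 = calibrate_nominal_inputs(model, geometry, glidant_active=True, cl=0.2)
    return ScenarioConfig(
        name=name, case="case2", plant_params=plant, model_params=model,
        geometry=geometry, glidant_active=True, u0=u0,
        setpoints0=setpoints0, noise_sd=noise,
        disturbance_schedule=dist_schedule, setpoint_schedule=(),
        horizon_end=horizon, seed=seed)


class VirtualPlant:
    """The 'true' process: evaluates the plant-side model at each 1 s step,
    applies the disturbance schedule, and adds seeded Gaussian sensor noise.

    A scenario plus its seed fully determines the measurement stream.
    """

    def __init__(self, scenario: ScenarioConfig,
                 rng: Optional[np.random.Generator] = None):
        self.scenario = scenario
        self.rng = np.random.default_rng(scenario.seed) if rng is None else rng
        self._params = scenario.plant_params
        self._cl_true = scenario.cl_nominal
        self._applied = 0  # schedule entries consumed so far

    @property
    def true_glidant_conc(self) -> float:
        return self._cl_true

    @property
    def current_params(self) -> ModelParameters:
        return self._params

    def _apply_schedule(self, t: int) -> None:
        sched = self.scenario.disturbance_schedule
        while self._applied < len(sched) and sched[self._applied][0] <= t:
            _, pname, value = sched[self._applied]
            if pname == "glidant_conc_cl":
                self._cl_true = value
            else:
                self._params = self._params.replace(**{pname: value})
            self._applied += 1

    def true_outputs(self, u: ProcessInputs) -> ProcessOutputs:
        """Noise-free plant outputs at the current (post-schedule) state."""
        s = self.scenario
        cl_override = self._cl_true if s.case == "case2" else None
        return evaluate_outputs(u, self._params, s.geometry,
                                glidant_active=s.glidant_active,
                                cl_override=cl_override)

    def step(self, t: int, u: ProcessInputs):
        """Advance the schedule to ``t`` and sample one measurement record.

        Returns ``(record, truth)`` where ``truth`` is the noise-free
        :class:`ProcessOutputs`; truth is for analysis and test oracles
        only and is never passed to the estimator or controller.
        """
        if t < 0 or t != int(t):
            raise ValueError(f"time must be a nonnegative integer second, got {t}")
        self._apply_schedule(t)
        truth = self.true_outputs(u)
        sd = self.scenario.noise_sd
        noise = {k: self.rng.normal(0.0, sd[k]) if sd[k] > 0 else 0.0
                 for k in MEASURED_OUTPUTS}
        record = MeasurementRecord(
            time=t,
            weight=getattr(truth, MEASURED_OUTPUTS["weight"]) + noise["weight"],
            pcf=getattr(truth, MEASURED_OUTPUTS["pcf"]) + noise["pcf"],
            mcf=getattr(truth, MEASURED_OUTPUTS["mcf"]) + noise["mcf"],
            rate=getattr(truth, MEASURED_OUTPUTS["rate"]) + noise["rate"],
            applied_inputs=u,
        )
        return record, truth
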