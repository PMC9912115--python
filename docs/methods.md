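# Methods

## Process model

The rotary tablet press is modelled as a purely algebraic (static)
nonlinear output map from the manipulated inputs — dosing position
`H_fill` (mm), pre-compression thickness `H_pc` (mm), main compression
thickness `H_in-die` (mm), turret speed `n_T` (rpm) and, where applicable,
glidant concentration `c_l` (% w/w) — to tablet weight (mg),
pre/main-compression forces (kN), production rate (kg/h) and tensile
strength (MPa). The evaluation chain is: bulk density → tablet weight →
production rate → pre-compression force → main compression force →
elastic recovery → out-of-die density → tensile strength. There are no
differential states: punch kinematics are orders of magnitude faster than
the 1 s control interval, so each interval sees a quasi-steady press.

Unit conventions are the plant's: mm, mg, kN, MPa, g/cm³, rpm, kg/h,
% w/w, minutes of mixing time. These are mutually consistent
(1 g/cm³ = 1 mg/mm³, 1 MPa·mm² = 1 N), so a single unit system is used
throughout with explicit factors only for kN and kg/h.

### Parameters

All fitted constants ship as four named columns (`no_pmm`, `mild_pmm`,
`high_pmm`, `cs2_nominal`), one YAML fixture each under
`presscontrol/data/`. The mismatch columns differ from nominal in
(ρ_b, ρ_c, a) for the mild case and additionally in (ξ₂, 1/b, ρ_t) for
the high case; the case-2 column adds the glidant bulk-density constants
(ρ_b,0 = 0.330, ρ_b,∞ = 0.450 g/cm³, r₁–r₃).

### Glidant lumped factors — reading of the fitted form

The glidant corrections enter through two lumped mixing factors combining
concentration and equivalent mixing time,

    C_σ = c_l^b1 · γ^b2 / b3          (tensile strength)
    C_ρ = c_l^r1 · (γ+γ0)^r2 / r3     (bulk density)

with `σ0 = σ0,φ/(1+C_σ)`, a critical-density shift between ρ_c,0 and
ρ_c,∞, and `ρ_b = ρ_b,∞ − (ρ_b,∞ − ρ_b,0)/(1+C_ρ)`. The placement of the
third constant (b₃ = 8.40, r₃ = 23.326) is a genuine reading choice; this
package divides by it. The alternative (multiplying) is inconsistent with
the fitted values: at the nominal operating point (0.2 % silica, γ ≈ 19
min) a multiplicative b₃ gives C_σ ≈ 15 and caps the attainable tensile
strength below 1 MPa — incompatible with the 4.2 MPa nominal target — and
a multiplicative r₃ saturates the bulk density at its asymptote for every
realistic concentration, destroying the observability of silica that the
second case study depends on. Each reading is isolated in one function
(`lumped_sigma_factor`, `lumped_rho_factor`) so an alternate convention is
a one-line change.

The mixing time `γ = γ0 + m_f,h / ṁ` depends on throughput, which depends
on the weight, which (when the glidant bulk-density model is active)
depends on `γ` again; this scalar fixed point is resolved by direct
iteration to 1e-12 (it is a strong contraction at operating conditions,
converging in under ten iterations).

### Geometry and calibration

Die/turret constants are not part of the fitted columns and are fixed by a
documented calibration: D = 10 mm, cup depth h = 1 mm, 10 stations,
feed-frame holdup 1 kg, blender shear baseline γ0 = 10 min, and a
feed-frame speed equal to the nominal turret speed (so n_T/n_F = 1
nominally). The nominal turret speed follows from the nominal weight/rate
pair: 6.9 kg/h at 210 mg on 10 stations gives 54.76 rpm. The remaining
nominal inputs are then root-found (`calibrate_nominal_inputs`, bounded
multi-start least squares) so that the noise-free outputs equal the
nominal targets (210 mg, 0.3 kN, 6.9 kg/h, 4.2 MPa); every run starts at
that operating point. All geometry is configurable; tests pin the
defaults.

### Validity handling

Degenerate regions are handled so optimizers can traverse them: densities
below the critical value yield zero force / zero strength with a validity
flag (physically meaningful), while genuinely invalid regions (Kawakita
denominator zero, out-of-die density ≥ 1, non-positive die-fill
correction) raise in strict mode and are clamped with a smooth quadratic
penalty in the soft mode used inside the estimator and controller
objectives.

## Virtual plant

The plant is the same model evaluated with its own (possibly mismatched)
parameter column, plus independent zero-mean Gaussian sensor noise added
to the four measured outputs each second. Noise magnitudes are sensor-like
fractions of the nominal signals — 1 mg (weight), 0.02 kN (PCF), 0.2 kN
(MCF), 0.05 kg/h (rate) — and configurable; one seeded generator per run
makes the stream fully reproducible. Disturbance schedules switch plant
parameters (or the true silica concentration) instantaneously at their
event times; step changes are square. The generator emulates stationary
sensor noise and abrupt parameter shifts only: it has no autocorrelated or
non-Gaussian noise, no multi-rate sensors, and no upstream
feeder/blender dynamics, so passing tests demonstrate estimator/controller
behaviour under those idealised conditions, not under real plant data.

## Moving-horizon estimator

Because the model is static, the generic moving-horizon formulation
collapses: the state-propagation constraint disappears and the decision
vector is the uncertain-parameter vector alone. At each step the estimator
minimises, over the past window of up to N_past = 30 records (plus the
current one; start-up uses whatever is available),

    Σ_t ‖(y_t − h(u_t, θ))/s‖²_{W_E} + ‖(θ − θ_prev)/θ_ref‖²_{W_θ}

subject to box bounds Ω_θ. Residuals are scaled by the configured sensor
noise levels (inverse-variance weighting, W_E = I on the scaled
residuals); the regularizer uses relative parameter deviation with
W_θ = 10⁻², small enough to track fast parameter shifts but pinning the
minimiser exactly at the incumbent when the window carries no information.
The solver is L-BFGS-B in scaled variables (θ/θ_ref), warm-started at the
incumbent; the returned estimate never degrades the incumbent objective
(the better of the two points is kept), and bound feasibility is enforced
by the solver and re-clipped on return. Case 1 estimates (ρ_b, ρ_c, a)
within ±30 % of nominal — a box that brackets all shipped plant columns;
case 2 estimates the silica concentration on [10⁻⁴, 1] % w/w. Main
compression force is included in the residual (it carries information
about ρ_c and a) although it is never a controlled output.

The output disturbance ζ is the per-output median of the window residuals
at the optimum — robust to occasional outliers, unlike the mean — and is
what gives the controller zero steady-state offset on the measured
outputs.

## NMPC

The controller minimises setpoint-normalised tracking error over a
N_p = 60 s prediction horizon plus range-normalised move suppression
(W_y = I, W_Δu = 0.01) over a N_c = 10 s control window, with moves
blocked to zero beyond N_c. Predictions add ζ (held at its time-k value)
to every measured controlled output; the soft-sensed tensile strength
carries no disturbance term, exactly as a model-based soft sensor would
behave. Constraints are the input box (H_fill ∈ [2,16] mm, H_pc ∈ [2,8]
mm, H_in-die ∈ [1,6] mm, n_T ∈ [10,100] rpm, c_l ∈ [0,1] %), a per-step
move limit of 2 % of each range, and the physical thickness ordering
H_in-die ≤ H_pc ≤ H_fill at every horizon step; all are linear in the
move sequence and passed to SLSQP with their exact constant Jacobian.
Because the model is static, the stage cost at horizon step m depends only
on the cumulated input there, so the objective gradient is assembled from
one forward-difference stage gradient per blocked step and suffix-summed —
roughly an order of magnitude cheaper than differencing the full
objective per decision variable. Only the first move is applied; the next
measurement re-triggers the whole chain. A failed or degrading solve falls
back to holding the input (flagged in the trace); validity violations
inside the optimizer act as smooth penalties rather than hard failures so
line searches can cross invalid regions.

With bounds inactive, none of the tuning above is printed to more than
order of magnitude by the source material for the original study; the
weights, bounds and move limits here are the package's own documented
defaults, pinned by the tests. Quantitative metric values therefore are
not expected to coincide with any externally tabulated values, and the
acceptance checks assert structure (ratios, orderings, settling) rather
than exact metric numbers.

## Closed-loop timeline and metrics

Runs follow the case-study timeline: open loop over [0, 100) s,
estimation with held inputs over [100, 200) s, closed loop from 200 s
(the fixed-parameter `nmpc_only` mode maintains ζ from the same residual
window but never updates θ; `open` does neither). Case 1 runs 1000 s with
the stepped setpoint schedule; case 2 runs 1500 s with constant setpoints
and the silica disturbance schedule.

IAE, M2P and D2R are computed on percent-of-setpoint error over the 1 s
grid (window [300, 1000] s by default) so outputs with different units
are comparable. They are evaluated on the plant's noise-free output
trajectories — the honest quality-attribute paths — rather than on noisy
measurements or on the controller's own soft sensor: with a static model
the controller can place its soft sensor exactly at the setpoint even
when the true tensile strength is off, so soft-sensor metrics would hide
precisely the mismatch effect the metrics exist to expose. The soft-sensor
trace is stored alongside for comparison. D2R uses a ±1 % settling band
(configurable) and requires the output to stay inside the band until the
window end; a later event that re-disturbs the output therefore extends
D2R for earlier events, and an output that never re-enters the band is
flagged unsettled (`None`). The pre-compression force regularly fails the
1 % band under default noise: its sensor noise (0.02 kN) is nearly 7 % of
the 0.3 kN signal, so the disturbance median wanders by more than the
band — a faithful consequence of the study conditions, not a controller
defect.

All metrics are pure functions of the stored series; recomputing them
from the written CSVs (`presscontrol metrics`) reproduces the in-memory
report exactly.

## Numerical and design choices

* NLP backend: scipy's SLSQP (controller) and L-BFGS-B (estimator); both
  problems are smooth, small (≤ 50 variables) and warm-started, keeping a
  full MHE + NMPC iteration well under the 1 s real-time budget on one
  CPU core (typically 30–80 ms).
* Determinism: a single seeded generator per run; identical scenario +
  seed gives byte-identical CSV output.
* Problem sizes: the shipped case studies run their full timelines
  (1000 s and 1500 s); the test suite reuses one session-level run per
  scenario and otherwise works on 230–350 s truncations, which contain
  the full phase timeline and one transient.

## Known limitations

* The static-map reading means settling is governed by the move limits
  and the estimation window, not by process dynamics; settling times are
  therefore shorter than on a press with material-transport lags.
* With six mismatched parameters and three estimated (high-mismatch
  scenario), the estimator deliberately converges to a biased compromise;
  the tensile strength then carries a persistent offset. This is the
  expected identifiability limit, asserted as such in the tests.
* No arrival-cost/covariance propagation in the estimator, no terminal
  cost or stability constraint in the controller, no economic objective,
  and no lubricant (as opposed to glidant) modelling.
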