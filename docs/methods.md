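# Methods

## The model

`mitohfpn` simulates the functional activity of isolated rat myometrial
mitochondria — simultaneous NADH oxidation, electric-potential (EP)
generation on the inner membrane, electrophoretic Ca²⁺ accumulation,
Ca²⁺-dependent NO synthesis, and ROS formation — and the inhibition of
these processes by the thiacalix[4]arene C-1193, a macrocyclic compound
carrying hydroxymethylphosphonic groups that acts as a high-affinity
blocker of mitochondrial NO generation.

The formalism is a hybrid functional Petri net (HFPN): a bipartite graph of
places (resources) and transitions (processes). Places are *discrete*
(integer tokens), *continuous* (real amounts) or *generic* (opaque
structural elements); transitions are *discrete* (fire atomically after a
delay) or *continuous* (move marking at a real-valued speed). *Normal* arcs
carry flux; *test* arcs read a marking without consuming it (enabled when
marking ≥ threshold); *inhibitory* arcs disable their transition once the
source marking reaches the threshold (strict `<` to enable).

Two restrictions define this package's semantics, both deliberate:

1. **Transition speeds are polynomials of simulation time t (minutes),
   not of markings.** The biology enters through fluorescence dynamics
   F(t) fitted to experimental time courses (degree 1–4 polynomials,
   valid on 0–15 min); each observable's transition fires at the analytic
   derivative dF/dt. Marking-dependent kinetics are out of scope.
2. **The validity window [0, 15] min is hard-capped.** `simulate` refuses
   `t_end > 15` unless explicitly overridden (with a logged warning),
   because the fitted polynomials mean nothing outside their window.

### Observables and their dynamics

All fluorescence values are relative units scaled ×1000; EP is in mV. The
fitted dynamics encoded in `mitohfpn.model` are (control / 10 μM C-1193):

| observable | form | control | C-1193 |
|---|---|---|---|
| NADH change | cubic | −0.38 t³ + 7.44 t² − 49.20 t | −0.16 t³ + 3.81 t² − 30.80 t |
| EP (mV) | cubic | NADH − 40.00 | NADH − 40.00 |
| DCF* (ROS) | line | 13.9 t + 1000 | 1.3 t + 1000 |
| DAF-FM-T (NO) | line | 17.39 t + 16.91 | 13.12 t − 8.23 |
| Fluo-4 (Ca²⁺) | quartic | −0.20 t⁴ + 4.06 t³ − 28.68 t² + 106.15 t + 1.57 | −0.14 t⁴ + 2.80 t³ − 19.58 t² + 61.15 t + 3.26 |

The Fluo-4 dynamics additionally carry a two-component linearization
around a 2.5-min breakpoint: 27.68 t − 11.41 and 20.44 t + 116.03
(control), 12.86 t + 1.01 and 4.17 t + 66.43 (C-1193). The quartic and the
piecewise lines were fitted to data independently and disagree numerically
(at t = 15 the control quartic is negative while the late line gives
422.6); both are implemented as selectable parameterizations and neither is
"corrected".

EP is numerically identified with the NADH fluorescence change shifted by
the constant −40.00 mV. The implied unit equivalence (1 fluorescence
unit ≙ 1 mV) is adopted as the model states it, without physical
interpretation; in the net, the EP place simply shares the NADH rate law
and starts at −40.00, which makes EP(t) = NADH(t) − 40.00 hold at every
sample by construction.

### Inhibitor gating

C-1193 action is encoded structurally, not as a rate multiplier, because
two complete rate laws per observable are available rather than a scaling
factor. Each observable has a *pair* of continuous transitions: the
control-rate transition carries an inhibitory arc from the `C1193` place
and the inhibited-rate transition a test arc from the same place, both at a
1 nM threshold (well below the 10 μM experimental dose). Exactly one
member of each pair is enabled at any concentration — a property the test
suite sweeps from 0 to 100 μM.

Electron-transport-chain complexes I–IV, NO synthase and the Ca²⁺
uniporter are generic catalytic places gated through test arcs; succinate
and pyruvate are substrate places whose removal disables every chain
transition. None of these has quantitative dynamics of its own. The
permeability transition pore (MPTP) is a discrete transition blocked by an
inhibitory arc from the cyclosporin-A place (0.005 mM in the release
medium); it never fires in any shipped configuration, and the tests assert
an empty event log.

### Signed observables and clamping

NADH change and EP are signed quantities and carry `allow_negative`;
Ca²⁺, NO and ROS fluorescence amounts are clamped at 0, and every clamp is
recorded in the simulation result (the first clamp of a place is logged at
warning level, repeats at debug). Two fitted curves collide with the
non-negativity of fluorescence:

* the C-1193 DAF-FM intercept is −8.23; the NO place starts at
  max(intercept, 0) = 0, the analytic model is retained for fitting
  comparisons, and only the slope is recoverable from the simulated
  trajectory;
* the control Fluo-4 quartic crosses zero near t ≈ 12.1 min, so the Ca
  place clamps from there on; coefficient round-trips for the quartic are
  therefore checked on the subinterval where it is positive.

## Numerics

The engine advances with a fixed-step explicit trapezoid (Heun) update:
per step the flux of an enabled continuous transition is
dt·(r(t) + r(t+dt))/2. Because rates depend only on time, this is plain
trapezoid quadrature — exact for linear rates, with global error
O(dt²)·max|r′′| otherwise; halving dt quarters the error, comfortably
satisfying the at-least-halving contract the tests check. A first-order
Euler update was considered and rejected: its accumulated error,
≈ (dt/2)(r(t) − r(0)), perturbs refitted cubic coefficients at relative
~10⁻⁴ at the default dt, i.e. at the edge of the four-significant-figure
round-trip contract, whereas the trapezoid scheme leaves ~10⁻⁷ headroom.
Default dt = 0.001 min; with sampling every 0.5 min a full 15-min run of
the mitochondrial net takes on the order of a second.

Discrete transitions are examined at the start of each step, in
lexicographic id order (a reproducibility tie-break only — the model has no
competing discrete transitions); a transition fires once it has been
continuously enabled for its delay.

Least squares uses `numpy.polynomial` fits in the ordinary power basis;
degrees are user-specified per observable (3 for NADH/EP, 1 for DCF/DAF,
4 for Fluo-4), never auto-selected, and no weighting is applied. In the
two-component fit the t = 2.5 sample belongs to the early interval
(closed [0, 2.5], open (2.5, 15]) — a deterministic convention — and no
continuity is imposed at the breakpoint. R² = 1 − SS_res/SS_tot, with
residuals at round-off scale counted as a perfect fit (otherwise constant
noiseless data would report R² = 0 through a 10⁻²⁸/10⁻²⁸ ratio).

## Hill analysis

Dose–response data follow F(C) = Fmax / (1 + (C/Ki)ⁿ). The transform
y = −log₁₀((Fmax − F)/F), x = −log₁₀(C) maps the ideal law onto the line
y = n·x + n·log₁₀(Ki), so the slope estimates the Hill coefficient and
the x-intercept is −log₁₀(Ki); Ki is read off as 10^(−x-intercept), the
standard Hill-plot convention, exact in the noiseless limit (the tests
require recovery to ≥ 6 significant figures across Ki ∈ [1 nM, 100 μM]
and n ∈ {0.5, 1, 2}). Fmax is taken per replicate from that replicate's
zero-inhibitor row, not fitted. Rows with F outside (0, Fmax) — possible
under noise — are dropped with a logged count rather than truncated, since
the transform is undefined there and truncation would bias the fit.
Replicates with R² ≤ 0.9 are excluded; the aggregate is the mean ± SE of
the surviving replicate Ki values, reported in nM.

## Synthetic data

The generators emulate the study's data shapes, not its instruments:

* **Time series**: model value (polynomial or piecewise-linear) on a grid
  within [0, 15] min plus additive Gaussian noise, default σ = 5 relative
  units and n = 4 replicates. σ is a convention chosen to resemble the
  scatter of typical-experiment panels; the true replicate noise of the
  fluorometry is not recoverable and no fidelity is claimed.
* **Dose–response**: the Hill law above at 0.001–100 μM (decade steps)
  with multiplicative Gaussian noise, default CV 5% and n = 7 replicates.
  The zero-inhibitor Fmax row is the normalization reference of the
  transform and is recorded noise-free; measurement noise applies to the
  responses at the inhibitor concentrations.

One integer seed governs all randomness; per-replicate substreams are
spawned from it through `numpy.random.SeedSequence`, so output is
bit-reproducible and replicates are statistically independent.

Clamping at zero in the time-series generator is an explicit flag, off by
default: noiseless samples follow the generating model exactly — including
fitted intercepts below zero such as the control early Ca component
(27.68 t − 11.41) — which is what the round-trip checks require. Callers
modeling physically non-negative fluorescence can enable the clamp (each
clamped sample is logged).

What passing tests show, and what they do not: recovery of every fitted
coefficient from noiseless synthetic or simulated data demonstrates that
the simulator, generators and estimators are mutually consistent and
numerically sound. It does not validate the underlying polynomials against
new biology — those coefficients are inputs to this package, not outputs.

## Initial velocities

The V₀ report collects, per condition: V₀(NO) = slope of the DAF-FM line,
V₀(Ca) = slope of the early (0–2.5 min) Fluo-4 component, V₀(EP) = the EP
polynomial's derivative at t = 0. The quantities are presented side by
side for comparison across conditions; no arithmetic identity among them
is asserted, because the fitted slopes do not satisfy one (control:
17.39 vs 27.68 + (−49.20)).

## Problem sizes and defaults

Simulations run at dt = 0.001 min over 0–15 min, sampled every 0.5 min
(31 points — dense enough that discretization does not perturb refitted
coefficients at four significant figures). Ki recovery is exercised at
n = 7 replicates × 6 concentrations; the calibration property uses 100
seeded repetitions. The noise-statistics check uses 1000 replicates.

## Known limitations

* Rates cannot depend on markings; feedback (e.g. Ca²⁺-dependent NOS
  kinetics) is represented structurally, not kinetically.
* FAD/FADH₂ dynamics, mitochondrial swelling/MPTP kinetics, the H⁺/Ca²⁺
  exchanger and dose–response interpolation between the two encoded
  conditions are not modeled.
* Generic places are pass-through flags; no payload computation.
* The two Fluo-4 parameterizations are mutually inconsistent by
  construction of their source fits; downstream users must choose one
  (`--ca-model quartic|piecewise`).
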