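# mitohfpn

Hybrid functional Petri net (HFPN) simulation of myometrial mitochondrial
function under the thiacalix[4]arene inhibitor C-1193, with trajectory
fitting and Hill-plot estimation of the apparent inhibition constant.

## The problem

Isolated rat myometrial mitochondria, energized with succinate and
pyruvate, simultaneously oxidize NADH, build an electric potential (EP) on
the inner membrane, accumulate Ca²⁺ electrophoretically, synthesize nitric
oxide in a Ca²⁺-dependent way, and form reactive oxygen species. Each
process is observed through a fluorescent reporter (NADH autofluorescence,
Fluo-4, DAF-FM, DCF; relative units ×1000, EP in mV), and each is
suppressed by the macrocyclic compound C-1193. This package is for
modelers who want to reproduce and probe that system on a desk: it encodes
the network as an HFPN, simulates the fluorescence time courses under
control and 10 μM C-1193 conditions, refits the model forms to (simulated
or synthetic) trajectories, and estimates the inhibitor's Ki from
dose–response data.

## The model in brief

An HFPN is a bipartite graph of places and transitions with discrete,
continuous and generic elements plus test and inhibitory arcs. Here each
observable's dynamics is a fitted polynomial F(t) on 0–15 min (e.g. NADH
change −0.38 t³ + 7.44 t² − 49.20 t in the control; DCF 13.9 t + 1000),
and the corresponding continuous transition fires at the analytic speed
dF/dt (for the control NADH transition: −1.14 t² + 14.88 t − 49.20). EP is
the NADH dynamics shifted by −40.00 mV. C-1193 gates each observable
between its control and inhibited rate law through an inhibitory/test arc
pair at a 1 nM threshold.

For NO inhibition, dose–response data F(C) = Fmax/(1 + (C/Ki)ⁿ) is
linearized in Hill coordinates {−lg[(Fmax − F)/F]; −lg C}: the slope
estimates the Hill coefficient n and the x-intercept gives −lg Ki.
Replicates with R² ≤ 0.9 are excluded and the surviving Ki values are
aggregated as mean ± SE.

See `docs/methods.md` for the full account: semantics, numerics, noise
model, and the design choices where the source fits are internally
inconsistent.

## Worked example

Simulate the control net, refit the ROS trajectory, then generate a
synthetic NO dose–response experiment and estimate Ki:

```console
$ mitohfpn simulate --condition control --out traj.csv
wrote traj.csv (31 samples, 0 discrete firings, 2935 clamp events)

$ mitohfpn fit traj.csv --degree 1 --observable ROS_DCF --out fit.yaml
coefficients (ascending): [1000.0, 13.9] R2=1.000000
wrote fit.yaml

$ mitohfpn synth doseresponse --seed 1 --out dose.csv
wrote dose.csv (7 replicates x 7 rows)

$ mitohfpn hill dose.csv
Ki = 5.75 ± 0.645 nM (n = 7, mean R2 = 0.9982)
```

Reading the numbers: the degree-1 refit of the simulated DCF trajectory
returns exactly the encoded dynamics 13.9 t + 1000 (slope in relative
units/min, intercept the initial fluorescence), confirming the
simulate→fit round trip. The clamp events come from the Fluo-4 place,
whose fitted quartic crosses zero near t ≈ 12 min and is floored at 0 from
there on. The synthetic dose–response was generated from the default NO
inhibition law (Ki = 5.5 nM, n = 1, CV 5% noise, 7 replicates); the
Hill-coordinate estimate 5.75 ± 0.645 nM recovers the generating constant
within one standard error. The `0 discrete firings` line reports that the
cyclosporin-A-blocked permeability transition pore never opened.

The same pipeline is available as a library:

```python
from mitohfpn import Condition, Trajectory, build_model, fit_polynomial, simulate

net, obs = build_model(Condition.c1193())
res = simulate(net, t_end=15.0, dt=0.001, sample_every=0.5)
fit = fit_polynomial(Trajectory("ROS_DCF", "c1193", res.times, res["ROS_DCF"]), 1)
print(fit.coefficients)   # (1000.0..., 1.2999...) — the inhibited DCF dynamics
```

Other commands: `validate` (net YAML schema check), `velocities` (initial
velocities V₀ of NO synthesis, Ca²⁺ accumulation and energization),
`synth timeseries`, and `report` (combined per-condition tables). The two
nets ship as YAML under `src/mitohfpn/models/`.

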