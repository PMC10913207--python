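# adaptivepi

Stability and parameter-invariance analysis of a two-state adaptive
proportional–integral (PI) feedback circuit.

## The problem

Biological control circuits — the canonical example being blood-glucose
regulation, where insulin secreted by a slowly adapting tissue mass steers
glucose — often keep their *output* response unchanged even when an internal
parameter (say, per-cell hormone secretion) varies over orders of magnitude.
This robustness is called **dynamical compensation (DC)**: after an
adaptation phase, the input–output behaviour does not depend on the
compensated parameter, even though the hidden state does.  DC is equivalent
to a **parameter invariance** property: the existence of a parameter-indexed
state transformation (an *equivariance*) that fixes the output coordinate
and intertwines the vector fields.

`adaptivepi` studies the minimal system exhibiting this, an exponentially
unstable plant under adaptive PI feedback:

```
dy/dt = b·y + d(t) + s·z·(l·r(t) − y)
dz/dt = −c·z·(r(t) − y)
```

Here `y` is the output tracking the reference `r(t)` against the disturbance
`d(t)`; `z` is an adapting state whose product `s·z(t)` acts as a
time-varying PI gain; `b` is the open-loop growth rate, `c` the adaptation
rate, and `0 < l < 1` scales the reference inside the proportional error.
With constant inputs the system has two equilibria,

```
E1 = (−d/b, 0)                      always a saddle,
E2 = (r, (d + b·r)/(s·r·(1 − l)))   locally stable for 0 < l < 1,
```

with the E2 spectrum given by the roots of `λ² − τλ + δ`,
`τ = (d + b·l·r)/(r·(l − 1))`, `δ = c·(d + b·r)` — note that neither `τ`
nor `δ` contains `s`.

The package answers, symbolically and by simulation, *which parameters are
compensated*: the gain scale `s` is (the equivariance `α_s = x₁/s` works
exactly, equivalently the rescaling `v₁ = s·x₁` removes `s` from the
equations), while the growth rate `b` and adaptation rate `c` are not.  It
is written for control theorists and systems biologists who want a worked,
testable example of DC/invariance analysis on a concrete circuit.

## What's inside

- `adaptivepi.models` — right-hand sides and parameter sets of the adaptive
  PI system, its two-state simplification, and the three-state hormonal
  circuit it descends from; YAML (de)serialization.
- `adaptivepi.signals` — seeded step-like reference/disturbance schedules
  with held Gaussian noise (`make_step_schedule`), the input protocol of all
  paired experiments.
- `adaptivepi.equilibria` — closed-form equilibria, Jacobian, eigenvalues,
  stability classification.
- `adaptivepi.simulate` — trajectory integration with restarts at signal
  discontinuities, equilibration (`settle`), phase portraits.
- `adaptivepi.invariance` — the symbolic equivariance consistency check, the
  numeric intertwining residual, the compensating state rescalings, and the
  paired-simulation output-invariance experiment.
- `adaptivepi.experiments` / CLI `adaptivepi` — reproducible experiment
  driver with hashed manifests.

## Worked example

Equilibria and spectra at the canonical operating point
(`b=0.3, s=0.25, l=0.7, c=2`, constant `r=11, d=0.01`):

```
$ adaptivepi equilibria
equilibrium      y     z     tau  delta  lambda1_re  lambda1_im  lambda2_re  lambda2_im    stability
         E1 -0.033 0.000 -21.767 -6.620       0.300       0.000     -22.067       0.000       saddle
         E2 11.000 4.012  -0.703  6.620      -0.352       2.549      -0.352      -2.549 stable_focus
```

E1 is the biologically infeasible off state (negative output, zero gain), a
saddle with eigenvalues `{0.300, −22.067}`.  E2 is the tracking state
`y = r = 11` with gain state `z ≈ 4.012` and a stable focus
(`λ ≈ −0.35 ± 2.55i`): trajectories spiral into perfect reference tracking.

Paired invariance experiment — two runs differing only in `s` (0.25 vs 1.5,
a 6× change), driven by the same noisy step schedule, the second run started
from the equivariance image of the first initial state:

```
$ adaptivepi invariance --param s --p1 0.25 --p2 1.5 --protocol strict --seed 1
{
  "max_abs_output_diff": 2.114890449433915e-07,
  "parameter_name": "s",
  "protocol": "strict",
  "value_pair": [0.25, 1.5],
  "verdict": "invariant",
  ...
}
```

The outputs agree to solver precision over the whole 400-time-unit schedule
— `s` is compensated.  Running the same experiment with `--param b --p1 0.3
--p2 0.6` or `--param c --p1 2 --p2 4` yields `"verdict": "not_invariant"`
with a maximal output difference of order 1: `b` and `c` are not.

The symbolic side of the same verdicts:

```python
>>> from adaptivepi import equivariance_consistency, dc_rescaling
>>> equivariance_consistency("s").alpha
x1/s
>>> equivariance_consistency("b").violated_conditions
['ratio_dx1', 'zero_dx2']
>>> dc_rescaling("s").parameter_eliminated
True
```

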