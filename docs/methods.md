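# Methods

## Model

The core system is a two-state adaptive proportional–integral loop around an
exponentially unstable scalar plant:

    dy/dt = b·y + d(t) + s·z·(l·r(t) − y)
    dz/dt = −c·z·(r(t) − y)

* `y(t)` — output, driven to track the reference `r(t)`;
* `z(t)` — adapting state; `s·z(t)` is the time-varying PI gain;
* `b > 0` — open-loop growth rate (the uncontrolled plant diverges);
* `s > 0` — gain scale; `c > 0` — adaptation rate (both dimensionless rates
  in the model's arbitrary time unit);
* `0 < l < 1` — reference scaling inside the proportional error
  `l·r(t) − y`.  At `l = 1` the tracking equilibrium's gain state diverges,
  and beyond it stability is lost; constructing parameters with `l ≥ 1`
  warns rather than errors so the degenerate regime can still be probed.

All parameters and states are read as positive in the biological
interpretation.  The right-hand side is globally defined, so integration
never clips negative excursions; `Trajectory.positivity_violations()`
reports them post hoc instead.

Two ancestors of this system are included for context and cross-checks: the
three-state hormonal circuit (regulated variable, hormone, functional
tissue mass) and its two-state simplification, whose substitution
`z̃ = s·z` exhibits the gain-invariance mechanism in its purest form.

State ordering is fixed everywhere as `(y, z)` (three-state model:
`(y, x, z)`); the output is always the first component.

## Equilibria and stability

Closed forms (constant `r, d`): `E1 = (−d/b, 0)` and
`E2 = (r, (d + b·r)/(s·r·(1 − l)))`.  The Jacobian

    J(y, z) = [[b − s·z, s·(l·r − y)], [c·z, −c·(r − y)]]

is triangular at E1 (eigenvalues `b > 0` and `−c·(d + b·r)/b < 0`: always a
saddle).  At E2 the eigenvalues are the roots of `λ² − τλ + δ` with
`τ = (d + b·l·r)/(r·(l − 1)) < 0` and `δ = c·(d + b·r) > 0` throughout the
admissible regime, so E2 is locally stable — a focus, node, or (on the
measure-zero discriminant boundary, detected with absolute tolerance 1e-12)
a degenerate node.  `τ` and `δ` contain no `s`: the gain scale relocates
the equilibrium gain state but leaves the local output dynamics untouched.
Only local stability is certified; the global claim is supported empirically
by phase-portrait trajectories converging to E2, not by a Lyapunov argument.

Eigenvalues are returned with the non-negative imaginary part first (ties
broken by descending real part) so tests and tables are deterministic.
Comparisons against the published reference values use exact 3-decimal
rounding, except the E2 eigenvalue real parts: those are `τ/2 =
−0.35151…`/`−0.70151…`, which the reference prints truncated (−0.351,
−0.701) rather than rounded, so they are compared to within one unit in the
last printed digit.

## Input signals

`PiecewiseSignal` is a piecewise-constant schedule plus optional Gaussian
noise, refreshed every `sample_step = 1` time unit and held in between
(zero-order hold), keeping the ODE right-hand side piecewise constant.  All
draws are frozen at construction from the seed, so evaluation is a pure
function: paired runs handed the same signal objects share one noise
realization exactly.  Draws that would push a signal to zero or below are
truncated at 1e-6, preserving the positivity assumption on `r(t)`.

The canonical schedule (`make_step_schedule`) spans `[0, 400]`:
constant `(11, 0.01)` on `[0, 50)`; `r` steps to 16 with unit noise on
`[50, 150)`; both flat on `[150, 200)`; `d` steps to 5 with noise on
`[200, 300)`; both noisy on `[300, 350)` with `r` stepping to 13.75; both
flat at `(13.75, 5)` on `[350, 400]`.  The endpoints `(11, 0.01)` and
`(13.75, 5)` are the published operating levels; the intermediate plateau
at `r = 16` and the unit noise sd are this package's conventions for the
"varying" phases, chosen to give excursions comparable to the step sizes.
What the generator does *not* emulate: continuous-time stochastic forcing
(no Brownian/SDE inputs), multiplicative or state-dependent noise, and any
measurement noise on `y` — passing tests therefore demonstrate invariance
of the deterministic flow under shared exogenous inputs, not robustness to
sensor noise or to noise realizations differing between the paired runs
(the latter would trivially break any invariance).

## Integration

Adaptive explicit Runge–Kutta 5(4) (`scipy.integrate.solve_ivp`, RK45) with
rtol 1e-8 / atol 1e-10.  These are deliberately far below the invariance
thresholds so that solver error never decides a verdict.  The integrator is
restarted at every signal breakpoint and noise-refresh time, with the
signals frozen to their segment value in between — adaptive error control
degrades across discontinuities, and restarting makes every jump a grid
point of the output (default output step 0.01, resolving the fastest
eigenfrequency |Im λ| ≈ 3.6 with ~170 samples per period).  Equilibration
(`settle`) integrates under constant inputs until the RHS norm falls below
a tolerance (default 1e-6; accumulated solver error leaves a residual floor
near 1e-7, so much tighter settle tolerances are unreachable at the default
solver settings) and flags non-convergence and divergence explicitly.
Phase portraits use a 15×15 grid on y ∈ [0, 20], z ∈ [0, 10] (contains both
equilibria for all canonical parameter sets) and horizon 60.

## Invariance analysis

For a parameter `p`, the system is invariance-compensated when some
`η_p = (α_p(x₁,x₂), x₂)` (the output coordinate must be fixed) satisfies
`f(η_p(x), u, p) = Dη_p(x)·f(x, u, 1)`, the reference being the system with
the varied parameter set to 1 and all others kept.  For `s` and `b` the
analysis is posed with the gain state hidden (`x₁ = z`, output `x₂ = y`);
for `c`, which only enters the gain-state equation, with the roles swapped.

Because `α` enters the output row of the identity linearly, that row is
solved for `α` outright (sympy); the hidden row then splits — the
disturbance `d` appears there only through the reference field multiplied
by `∂α/∂x₂` — into two conditions: `∂α/∂x₂ = 0` and `∂α/∂x₁` equal to a
forced coefficient ratio.  The candidate either satisfies both identically
(`s`: `α_s = x₁/s`) or violates at least one (`b`: both, `c`: the ratio
condition), which is the returned verdict together with the violated
condition ids.  The procedure is specific to this affine-in-α structure; it
is not a general equivariance search, and non-invariance verdicts mean "no
consistent α within this ansatz".  The solved candidates are undefined on
`l·r − x₂ = 0` (for `s`, `b`) or `c·x₂ = 0` (for `c`); these exclusion sets
are recorded on the candidate and avoided when sampling numeric residuals.

The complementary dynamical-compensation view applies diagonal state
rescalings: `v₁ = s·x₁` eliminates `s` from the transformed equations
(so `s = 1` may be assumed — DC holds), while `v₂ = b·x₂` and `v₁ = c·x₁`
leave `b` and `c` in place.

### Paired simulation experiments

Two runs differ only in the tested parameter and share the seeded schedule.
Protocols:

* **strict** — the second run starts from the equivariance image of the
  first run's initial state (for `s`: `z(0)` scaled by `p₁/p₂`, since
  `s·z` is the invariant gain); outputs are compared over the full span.
  Decision threshold 1e-5 on max |y₁ − y₂| (solver-limited; measured values
  sit near 2e-7).
* **dc_after_adaptation** — identical initial states `(y, z)(0) = (8, 2)`
  (a documented convention: a state at a moderate distance from E2, inside
  its basin); comparison starts at t = 40, after each run has settled onto
  its own equilibrium but before the first input change at t = 50.
  Threshold 1e-3.

Non-invariance (for `b`, `c`) produces max |Δy| of order 1, four orders of
magnitude above the thresholds, so verdicts are not threshold-sensitive.
For `c` the difference is transient: both runs settle onto `y = r` at every
plateau, and the terminal output difference is back below 1e-3 — the
adaptation rate shapes transients, not set points.

## Numerical and design choices

* Reference-system convention: the varied parameter is set to 1, the others
  keep their values (this is what makes the `b` derivation's reference row
  read `x₂ + d + s·x₁(l·r − x₂)`).
* Signal intervals are right-open; the value at a breakpoint is the new
  level, so each integration segment sees exactly one signal value.
* Eigenvalue pair ordering and the 1e-12 discriminant tolerance are pure
  determinism devices; no scientific content.
* Random draws in property tests sample b ∈ [0.1, 1], s ∈ [0.1, 2],
  l ∈ [0.1, 0.9], c ∈ [0.5, 5], r ∈ [1, 20], d ∈ [0.01, 5] — comfortably
  inside the admissible regime, away from the `l → 1` degeneracy.
* Problem sizes: paired experiments integrate the full `[0, 400]` schedule
  (two runs each, ~1–2 s); test-suite phase portraits use reduced grids
  (the CLI default remains 15×15).

## Known limitations

* Stability certification is local; the "global" attractivity of E2 is an
  empirical observation on sampled boxes.
* The equivariance check covers the single-output, fixed-output-coordinate
  ansatz only; it cannot exclude exotic transformations outside it.
* The noise model is an exogenous zero-order-hold process, not a diffusion;
  no claims are made about stochastic (in the SDE sense) invariance.
* `settle` detects divergence by state-norm blow-up (> 1e12) or solver
  failure; slow non-exponential escape within the horizon is reported as
  plain non-convergence.
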