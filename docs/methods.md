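# Methods

## Model and assumptions

The microscopic system is a globally coupled network of `N` theta neurons.
Each neuron is a phase `θ_j` on the circle obeying
`dθ_j/dt = (1 − cos θ_j) + [η_j + I_syn,j](1 + cos θ_j)`; a spike is an
upward crossing of `θ = π`. The synaptic current is pulse-coupled and shared,
`I_syn,j = k_j S(t)` with `S(t) = (1/N) Σ_i P_n(θ_i)` and
`P_n(θ) = a_n(1 − cos θ)^n`: every neuron sees the same population drive
`S(t)`, scaled by its own synaptic gain `k_j`. Excitabilities and gains are
quenched random parameters drawn from independent Cauchy–Lorentz
distributions with centers `η₀, k₀` and half-widths at half-maximum
`Δ_η, Δ_k ≥ 0` (all dimensionless; time is in units of the theta-neuron's
intrinsic scale).

The reduced model is the exact `N → ∞` closure of the Kuramoto order
parameter on the Ott–Antonsen manifold:

```
dz/dt = −i(z−1)²/2 + (z+1)²/2 [ −(Δ_η + Δ_k H(z,n)) + i(η₀ + k₀ H(z,n)) ].
```

Assumptions inherited from this closure:

* **Cauchy heterogeneity.** The residue evaluation that collapses the
  continuum density to one complex ODE requires distributions with simple
  pole structure; other distributions are out of scope.
* **Independence** of `η` and `k` per neuron, and both marginals static.
* **Global coupling** through a single scalar field; no synaptic kinetics
  (the pulse acts instantaneously) and no network topology.
* **Attractivity of the OA manifold** holds for heterogeneous populations
  (`Δ_η > 0`). On the boundary plane `Δ_η = 0` the reduced flow is
  non-hyperbolic (marginal), which is why surface cross-validation and the
  test-suite round trips restrict themselves to the physical interior
  `Δ_η > 0`.
* Only order-parameter states with `|z| ≤ 1` are meaningful; all solvers
  enforce the closed unit disk with an absolute domain tolerance of 1e−9
  (continuation steps may graze the boundary).

`H(z, n)` is evaluated from the finite Fourier expansion of the pulse. The
coefficients `A_0..A_n` are computed in exact rational arithmetic (integer
factorials, late division) and the normalization is taken from them
(`a_n = 1/A_0`, which equals the closed form `2^n / C(2n, n)`); numerical
quadrature of the pulse is reserved for the test oracles. The Jacobian of
the planar flow and the derivative of the field with respect to each
distribution parameter are closed-form; no differencing enters the
production code paths (finite differences appear only as test oracles and
inside the codimension-2 defining system, where the smooth polynomial test
function is differenced centrally at step 1e−7).

## Finite-network simulator

* **Integrator:** fixed-step classical RK4 with the shared drive `S(t)`
  recomputed at every stage, so each step is O(N). Default `dt = 2e−3`;
  halving `dt` moves the post-burn-in mean `|z|` by less than 1e−3 (checked
  in the suite). A numba kernel (cached, exact match to the numpy reference
  path, asserted in tests) makes `N = 10⁴` runs tractable on one core.
* **Sampling schemes:** `quantile` places parameters at the deterministic
  equispaced quantiles `u_j = (j − 1/2)/N` of the inverse CDF and shuffles
  the two vectors independently (seeded), which suppresses sampling noise in
  the comparison with the reduction and automatically bounds the extreme
  draws by the `1/(2N)` quantile; `random` draws i.i.d., with optional
  clipping at the 1e−4 quantiles (recorded in the realization and manifest,
  never silent) to keep the fastest rotators resolvable at the default
  `dt`.
* **Initial phases:** equispaced (`z(0) ≈ 0`) by default, fully
  synchronized (`z(0) = 1`), or *on the mean-field manifold* at an arbitrary
  centroid `z₀` (phases are the Möbius image of equispaced unit phasors
  under the disk automorphism centred at `z₀`, whose density is the
  wrapped-Cauchy/Poisson kernel). The network is multistable in parts of
  parameter space, so all basins must be reachable. Validation against the
  reduction integrates the reduced ODE *from the same initial `z`* and
  compares like with like (same burn-in, same sampling window).
* **Spike detection** uses per-step unwrapped increments; a wrap from just
  below `2π` to just above 0 is not a crossing. Crossing times are linearly
  interpolated.
* Validation problem sizes: the suite compares an `N = 10,000`
  quantile-sampled network against the reduction on 10 parameter sets
  spanning both regimes. The 8 equilibrium sets start at `z(0) ≈ 0` and
  compare window means over 50 time units with a 30-unit burn-in
  (agreement 0.03 on the mean order parameter). The 2 oscillating sets sit
  close to the Hopf point, where relaxation onto the cycle is slow (Floquet
  multiplier near 1), so the network is dropped onto the manifold at a
  point of the shooting-polished reduced cycle and its `|z|` extremes over
  a 25-unit window are compared with that cycle's extremes (agreement
  0.05). What passing shows: the reduction predicts this network's
  collective states at these sizes and horizons. It does not probe
  non-Cauchy heterogeneity, sparse topology, synaptic kinetics, or
  finite-size fluctuation effects beyond `N = 10⁴`.

## Equilibria and one-parameter continuation

Equilibria are roots of the planar field found by damped Newton (backtracking
halving, iterates pulled back to the disk) from a 21×21 polar seed grid plus
the origin, deduplicated at 1e−7 in the plane; accepted roots satisfy
`|dz/dt| < 1e−10`. Classification follows the Jacobian scalars: saddle for
`det J < 0`, node/focus by the sign of the discriminant `tr²J − 4 det J`,
with `|disc| < 1e−10` labelled as the node-focus boundary.

Branches are continued by pseudo-arclength (secant predictor, Newton
corrector on the arclength-extended system; initial step 1e−2, adaptive in
[1e−5, 0.1]), which follows folds. Three test functions are monitored:
`det J` (saddle-node), `tr J` with the admissibility filter `det J > 0`
(Hopf; a trace zero with `det J < 0` is a neutral saddle and is discarded),
and the discriminant (node-focus). Sign changes are localized by bisection
along the branch chord until the sweep-parameter bracket is below 1e−6 *and*
the test function is below 1e−9 at the emitted point. Node-focus events that
coincide with a Hopf (`|tr J| < 1e−7`) are suppressed as duplicates.
Near a cusp two saddle-nodes can sit closer together than any reasonable
continuation step (separations below 1e−7 in the sweep parameter occur),
in which case the test function dips through zero and back *between*
consecutive branch points with no sign change; deep local minima (below
1e−3 relative to their neighbors) are therefore refined by golden-section
search along the branch and, when the minimum is negative, both crossings
are emitted.

## Limit cycles

Cycles are located by single shooting on a horizontal Poincaré section
through the cycle mean: unknowns `(x_start, period)`, residual
`Φ_T(x, y_sec) − (x, y_sec)`, flows computed with DOP853 at rtol 1e−11.
Seeds come from direct integration near a Hopf point — forward in time on
the supercritical side, backward for the unstable cycle of a subcritical
Hopf (time reversal swaps cycle stability) — in chunks until the orbit's
amplitude stabilizes, with the offset from the Hopf shrunk automatically
when the cycle window is narrow. The nontrivial Floquet multiplier is exact
for a planar flow: `exp(∮ div f dt)` along the orbit.

Branch continuation is pseudo-arclength in `(x_start, period, parameter)`
with the period coordinate scaled by 25 so that period growth near a
homoclinic drives the steps. Saddle equilibria are tracked alongside by
warm-started Newton. Events:

* **SNPO** (fold of the cycle branch): a turning point in the sweep
  parameter at which the multiplier crosses 1 with finite amplitude. The
  multiplier-crossing requirement distinguishes a genuine fold from a branch
  shrinking into its Hopf terminus (where the multiplier also approaches 1
  but from one side).
* **Homoclinic termination.** Near a homoclinic connection the period grows
  only logarithmically in the parameter distance (the saddle's unstable
  eigenvalue here is ≈ 3.5–5), so a pure period threshold of several
  hundred time units is unreachable in double precision. The branch is
  declared homoclinic when the converged cycle's minimum distance to a
  tracked saddle falls below 1e−3 while the period grows; a configurable
  period threshold (default 500) and a stall-with-saddle-approach rule
  (distance < 1e−2) act as fallbacks. The sweep value at termination then
  approximates the homoclinic parameter to ~1e−4.
* **Hopf terminus:** amplitude shrinking below min(0.05, 60% of the seed
  amplitude) ends the branch; returning to the seed state within the step
  tolerance ends a closed branch (as on the two-Hopf loop).

## First Lyapunov coefficient and codimension-2 tracking

At a Hopf point the field is transformed to the real eigenbasis in which the
linearization is `[[0, −ω], [ω, 0]]` (`ω = √det J`) and the cubic radial
coefficient is evaluated with the standard planar normal-form formula from
second and third partials. Those partials are exact: the reduced field is
polynomial in `(x, y)` of degree `n + 2`, and its derivatives are generated
symbolically once per pulse sharpness (sympy, rational coefficients) and
compiled to numeric functions. `l1 > 0` is subcritical, `l1 < 0`
supercritical, `|l1| < 1e−6` flags a Bautin candidate. The sign convention
is validated against direct simulation (a small stable cycle appears just
past the Hopf iff supercritical).

The Hopf curve in the `(k₀, Δ_k)` plane is the solution set of the three
defining equations (equilibrium pair, `tr J = 0`) in four unknowns
`(x, y, k₀, Δ_k)`, continued by pseudo-arclength from the `Δ_k = 0` Hopf.
Along the curve `l1` is recorded; its sign change is bisected on the curve
chord to a `Δ_k` bracket below 1e−3 (**Bautin point**). The fold of the
curve in `Δ_k` — the largest diversity at which any Hopf survives on the
sweep line — is refined by golden-section search on the chord
(**hopf-fold**). The continuation stops where `det J` reaches zero: there
`ω → 0` and the curve ends in a Bogdanov–Takens point, beyond which the
trace zero is a neutral saddle, not a Hopf. Between that BT end and the fold
the one-parameter sweep shows two genuine Hopf points; below it, one.

## Parametric bifurcation surfaces

At fixed `(Δ_k, n)` and a prescribed equilibrium location `z_e` inside the
open unit disk, the equilibrium conditions are affine in
`(η₀, Δ_η, k₀)` (because `H` depends only on `z`), with the coefficient
matrix degenerate exactly at `z_e = ±1` (excluded along with radius-1e−3
neighborhoods). Solving the pair for `(η₀, Δ_η)` as affine functions of `k₀`
and substituting into the closing condition leaves:

* `tr J = 0` (Hopf): affine in `k₀` — a single root, filtered by
  `det J > 0`;
* `det J = 0` (saddle-node) and `tr²J − 4 det J = 0` (node-focus): exactly
  quadratic in `k₀` — 0, 1, or 2 real roots.

The quadratic's coefficients are recovered from three exact evaluations
(the function *is* a quadratic, so this is interpolation, not fitting) and
each root is Newton-polished on the exact test function; roots whose
polished residual still exceeds 1e−9 (hyper-ill-conditioned far roots of a
nearly linear quadratic) are dropped. Every emitted solution satisfies both
the equilibrium residual and the test-function residual to 1e−9. Solutions
with `Δ_η < 0` are retained internally and flagged unphysical — the surfaces
migrate *into* that region as `Δ_k` grows, and following them is the point —
but dropped (and counted) by the default mesh filter. The default mesh is a
60×120 polar grid over radii (0.01, 0.995).

Two independent consistency routes guard the construction: a direct
three-equation Newton solve in `(x, y, free-parameter)` for line–surface
intersections (compared with continuation events to 1e−3), and a round-trip
re-detection of each surface solution by one-parameter continuation through
it (the validator sweeps from both window ends and, for fold "bubbles" whose
arms never reach the window ends, re-seeds next to the prescribed
equilibrium).

## Design choices made where the design was open

* The closed form of the pulse normalization is derived, not assumed:
  `a_n = 1/A_0` with `A_0` from the exact coefficient sum, cross-checked by
  quadrature in the tests.
* The discrete-network integrator, step, burn-in, and initial conditions
  are this package's choices (stated above); the mean-field structure makes
  RK4 with per-stage drive recomputation the natural O(N) scheme.
* Coefficient summation ranges for `A_q` run over `0 ≤ m ≤ j ≤ n` with
  `j − 2m = q`, the range on which the factorial expression is defined.
* Homoclinic detection is the proxy described above; rigorous homoclinic
  continuation is out of scope.
* Surface multivaluedness (≤ 2 roots per mesh point) is reported per point;
  sheet assembly is left to grid adjacency.
* A two-parameter scan whose starting `Δ_k` carries no Hopf point returns an
  empty event list (with the curve's termination recording why) rather than
  raising: "nothing to continue" is a result, not an error.

## Known limitations

* Everything is specific to Cauchy–Lorentz heterogeneity and global
  pulse coupling; no synaptic time constants, delays, or topology.
* The `Δ_η = 0` plane (and the delta-pulse limit `n → ∞`) are outside the
  validated domain.
* Bogdanov–Takens points are detected only as curve termini; their
  normal-form unfolding is not computed.
* Homoclinic parameters are proxy-accurate (~1e−4 here), not
  rigorously enclosed.
* The surface mesh reports solutions point-wise; it does not triangulate
  across the quadratic's branch switches, so rendering near creases needs
  care.
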