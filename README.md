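# thetanet

Collective dynamics of large theta-neuron networks with **joint heterogeneity
in excitability and synaptic coupling strength**, analyzed through an exact
mean-field reduction and numerical bifurcation analysis.

## The scientific problem

A network of `N` theta neurons (the canonical phase model of Type I
excitability) evolves as

```
dθ_j/dt = (1 − cos θ_j) + [η_j + I_syn,j](1 + cos θ_j),
I_syn,j = (k_j / N) Σ_i P_n(θ_i),      P_n(θ) = a_n (1 − cos θ)^n,
```

where `η_j` is the excitability (η < 0: resting but excitable; η > 0:
tonically spiking), `k_j` the synaptic coupling strength (k < 0 inhibitory,
k > 0 excitatory), and `n` the sharpness of the synaptic pulse, normalized by
`a_n` so that `∫ P_n dθ = 2π`. Real circuits are heterogeneous in **both**
`η` and `k`, so the package draws them from two independent Cauchy–Lorentz
distributions with centers `η₀, k₀` and half-widths `Δ_η, Δ_k`.

In the thermodynamic limit the Ott–Antonsen ansatz closes the dynamics of the
Kuramoto order parameter `z = ⟨e^{iθ}⟩` exactly:

```
dz/dt = −i(z−1)²/2 + (z+1)²/2 · [ −(Δ_η + Δ_k H(z,n)) + i(η₀ + k₀ H(z,n)) ],
H(z,n) = a_n ( A₀ + Σ_{q=1..n} A_q (z^q + z̄^q) ),
```

with `H` the population-averaged synaptic drive. The synaptic-diversity
parameter `Δ_k` enters as one additional damping-like term — and that term is
the whole story: **increasing Δ_k sweeps the network's bifurcation structure
(saddle-nodes, Hopf points, limit cycles, multistability) out of the
physiologically relevant region of parameter space**, leaving only simple
equilibria and the node↔focus character of their relaxation.

## What the package provides

| Module | Content |
| --- | --- |
| `thetanet.model` | pulse coefficients (exact rational arithmetic), `H(z,n)`, the reduced vector field and its closed-form Jacobian |
| `thetanet.network` | finite-`N` simulator (RK4, numba-accelerated, O(N) per step), Cauchy sampling (deterministic quantiles or i.i.d.), spike detection |
| `thetanet.equilibria` | damped-Newton equilibrium finding with stability / node-focus classification |
| `thetanet.continuation` | pseudo-arclength continuation with saddle-node, Hopf, and node-focus event localization |
| `thetanet.cycles` | limit-cycle shooting, branch continuation with Floquet multipliers, SNPO and homoclinic termination |
| `thetanet.lyapunov` | exact (symbolic third partials) planar first Lyapunov coefficient: sub/supercritical Hopf classification |
| `thetanet.codim2` | Hopf-curve continuation in `Δ_k`: Bautin point and Hopf-disappearance fold |
| `thetanet.surfaces` | parametric saddle-node / Hopf / node-focus surfaces in `(η₀, Δ_η, k₀)` space at fixed `Δ_k` |
| `thetanet.io`, `thetanet.cli` | YAML-configured runs, CSV tables + JSON manifests, `thetanet` command-line tool |

## A worked example

Continuing the equilibria of a predominantly excitable, excitatory-coupled
population (`η₀ = −0.3, Δ_η = 0.08, n = 2`) along the mean coupling `k₀`
(`examples/03_bifurcation_diagram.py`):

```
delta_k = 0.0:
  node-focus   at k0 = 0.1024   z = 0.4960-0.7376j
  saddle-node  at k0 = 0.9067   z = 0.3810-0.0865j
  node-focus   at k0 = 0.9075   z = 0.3634-0.0808j
  saddle-node  at k0 = 1.1230   z = 0.6471-0.3518j
delta_k = 0.2:
  node-focus   at k0 = 0.0740   z = 0.4358-0.6865j
  node-focus   at k0 = 0.8087   z = 0.3626-0.2067j
  (no saddle-nodes: the multistable interval is gone)
```

Between the two saddle-nodes (`k₀ ∈ (0.907, 1.123)`) a strongly and a weakly
synchronized equilibrium coexist — the network's state depends on its
history. A modest synaptic diversity (`Δ_k = 0.2`) annihilates the fold pair
and with it the multistability, while the node-focus transitions (which set
whether relaxation to equilibrium rings) survive.

The same machinery reproduces the full repertoire: the supercritical Hopf at
`η₀ = 10.907` of the spiking/inhibitory regime and its limit cycle's
homoclinic death at `η₀ = 10.578` (`examples/04`), the Bautin point at
`Δ_k = 0.115` and the disappearance of the last Hopf at `Δ_k = 0.864`
(`examples/05`), and the surface migration in `(η₀, Δ_η, k₀)` space
(`examples/06`). An `N = 10,000` quantile-sampled network matches the
reduction to a few parts in 10³ (`examples/02`).

## Command line

```bash
thetanet continue --eta0 -0.3 --delta-eta 0.08 --n 2 \
    --sweep-param k0 --sweep-range 0 3 --out runs/case1
thetanet surface --kind hopf --delta-k 1.0 --n 2 --out runs/hopf1
```

Each run writes CSV tables plus a `manifest.json` recording the full
configuration, seed, and derived pulse coefficients; identical configurations
reproduce identical outputs.

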