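"""How synaptic diversity reorganizes and then destroys the Hopf bifurcation.

Continues the subcritical Hopf point of a weakly active inhibitory network
in the diversity parameter delta_k.  Along the way the first Lyapunov
coefficient crosses zero (a Bautin point: the bifurcation turns
supercritical) and the curve folds back (beyond that delta_k no Hopf
bifurcation exists on the sweep line at all).
"""

from thetanet import ModelParams, continue_hopf_curve

params = ModelParams(eta0=6.0, delta_eta=0.4, k0=0.0, delta_k=0.0, n=2)
curve = continue_hopf_curve(params, "k0", (-25.0, 0.0), (0.0, 2.0))

print(f"Hopf curve: {len(curve.points)} points, termination: "
      f"{curve.termination}")
print(f"start: k0 = {curve.points[0][2]:.4f}, delta_k = 0, "
      f"l1 = {curve.l1[0]:+.3f} (subcritical)")
for e in curve.events:
    extra = f", l1 = {e.auxiliary['l1']:+.2e}" if "l1" in e.auxiliary else ""
    print(f"{e.kind:10s} at delta_k = {e.value:.4f} "
          f"(k0 = {e.auxiliary.get('k0', float('nan')):.3f}{extra})")
print("\nBelow the Bautin point the Hopf is subcritical (hysteresis with an")
print("unstable cycle); past the fold the oscillation instability is gone.")
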