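"""A collective oscillation born at a Hopf point and its homoclinic death.

In the spiking/inhibitory regime an eta0 sweep crosses a supercritical Hopf
bifurcation; the stable limit cycle of the order parameter grows as eta0
decreases until it collides with a saddle equilibrium.
"""

from thetanet import ModelParams, continue_equilibria, limit_cycle_branch

params = ModelParams(eta0=0.0, delta_eta=0.5, k0=-9.0, delta_k=0.0, n=2)
branches = continue_equilibria(params, "eta0", (0.0, 15.0))
hopf = [e for b in branches for e in b.events_of("hopf")][0]
print(f"Hopf at eta0 = {hopf.value:.4f}, z = {hopf.z:.4f}")

lcb = limit_cycle_branch(params, "eta0", (0.0, 15.0), init=hopf)
first, last = lcb.cycles[0], lcb.cycles[-1]
print(f"cycle branch: {len(lcb)} points, termination: {lcb.termination}")
print(f"  near Hopf : eta0 = {first.param_value:.4f}, period = "
      f"{first.period:.3f}, x in [{first.x_min:.3f}, {first.x_max:.3f}]")
print(f"  at the end: eta0 = {last.param_value:.4f}, period = "
      f"{last.period:.3f}, x in [{last.x_min:.3f}, {last.x_max:.3f}]")
for e in lcb.events:
    print(f"  event: {e.kind} at eta0 = {e.value:.5f} "
          f"(period {e.auxiliary.get('period', float('nan')):.2f})")
print("\nThe period grows and the orbit's closest approach to the saddle")
print("shrinks: the cycle dies in a homoclinic collision.")
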