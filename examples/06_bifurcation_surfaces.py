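"""Bifurcation surfaces in (eta0, delta_eta, k0) space and their migration.

At a prescribed equilibrium location the equilibrium conditions are affine
in (eta0, delta_eta, k0), so scanning locations over the unit disk sweeps
out entire surfaces of saddle-node, Hopf, and node-focus points.  Increasing
delta_k pushes them out of the physically relevant region.
"""

import numpy as np

from thetanet import build_surface_mesh

CLIP = {"eta0": (-30, 30), "k0": (-40, 40), "delta_eta": (0, 3)}

for kind in ("saddle-node", "hopf"):
    print(f"{kind} surface, solutions inside the viewing box:")
    for delta_k in (0.0, 1.0, 3.0):
        mesh = build_surface_mesh(kind, delta_k, n=2, clip=CLIP)
        arr = mesh.solutions_array()
        msg = f"  delta_k = {delta_k}: {len(arr):5d} solutions"
        if len(arr):
            c1 = np.sum((arr[:, 2] < 0) & (arr[:, 4] > 0))
            c2 = np.sum((arr[:, 2] > 0) & (arr[:, 4] < 0))
            msg += (f"  (excitable/excitatory: {c1}, "
                    f"spiking/inhibitory: {c2})")
        print(msg)
print("\nSaddle-node sheets live in the two competition quadrants; the Hopf")
print("sheet exists only for spiking/inhibitory networks. Diversity sweeps")
print("both toward extreme or unphysical (delta_eta < 0) parameters.")
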