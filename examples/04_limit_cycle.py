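"""Probing an unstable limit cycle in the reduced normal-form system.

The planar normal form dy1/dt = b*y1 - y2 + y1*(y1^2+y2^2), ... with b < 0
has an unstable limit cycle of radius sqrt(-b): trajectories started inside
spiral into the origin, trajectories outside escape. The probe launches
trajectories at chosen radii and the bisection recovers the cycle radius.
"""

import numpy as np

from kinecrit import (
    estimate_cycle_radius,
    make_normal_form_oscillator,
    orbit_structure,
    probe_limit_cycle,
)
from kinecrit.stability import NormalFormSignature

beta = -1.0
model = make_normal_form_oscillator(beta, sigma=+1, n_stable=2, n_unstable=1)
eq = np.zeros(model.n_dynamic)

outcomes = probe_limit_cycle(model, eq, plane=(0, 1), radii=[0.5, 1.0, 1.5], t_end=5.0)
print("probe outcomes by start radius:", outcomes)

radius = estimate_cycle_radius(model, eq, plane=(0, 1), r_lo=0.3, r_hi=1.4)
print(f"bisected cycle radius: {radius:.4f} (analytic sqrt(-beta) = {np.sqrt(-beta):.4f})")

orb = orbit_structure(NormalFormSignature(N_s=2, N_u=1, center_pairs=1,
                                          sigma=+1, beta=beta))
print("\nqualitative orbit structure:", orb.description)
for eq_line in orb.reduced_system:
    print("   ", eq_line)
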