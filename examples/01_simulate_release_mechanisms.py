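"""Simulate the three-pool model under each release mechanism.

Integrates the 10-day protocol (6 axenic days, then co-culture) for the
passive-diffusion base model and for each single active mechanism, and
prints the phytoplankton endometabolite pool P and bacterial uptake U at
the nine experimental sampling times (final two days, every 6 h).
"""

import numpy as np

from dielflux import ExperimentDesign, ModelParameters, sample_trajectory, simulate

design = ExperimentDesign()
params = ModelParameters(t_frac=0.1, r_diff=0.2, u_vmax=2.0, u_km=1.0,
                         o_decay=0.25, h_coef=1.0, b_factor=2.0)

print("clock hours:", design.clocks.astype(int))
for variant in ("base", "o", "h", "b"):
    traj = simulate(params, variant)
    P, U = sample_trajectory(traj, design)
    print(f"\nvariant {variant!r} ({len(traj.clamp_events)} clamp events)")
    print("  P:", np.round(P, 3))
    print("  U:", np.round(U, 3))

# Interpretation: P peaks shortly after noon in the base model (production
# tracks irradiance with a lag).  The o term suppresses afternoon
# production, h couples release directly to production, and b raises
# production after inoculation, shifting P toward an increasing trend.
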