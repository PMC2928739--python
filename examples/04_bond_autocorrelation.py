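"""Time-delayed autocorrelation of virtual backbone bond vectors.

Bond directions evolving by isotropic rotational diffusion with coefficient
D have the first-rank orientational autocorrelation exp(-2 D tau).  A slowly
diffusing chain (restricted orientational freedom) keeps its correlations at
long delays; a fast one loses them — the signature used to compare a
complex's orientational freedom with and without a bound effector.
"""

import numpy as np

import ensembledyn as ed

delays = [0.0, 0.2, 0.5, 1.0, 2.0]
print(f"{'tau (ns)':>8} {'slow D=0.1':>12} {'fast D=1.0':>12} {'exp(-2*0.1*tau)':>16} {'exp(-2*1.0*tau)':>16}")
profiles = {}
for d_coeff in (0.1, 1.0):
    spec = ed.SyntheticSpec(chains=[("A", 21)], n_frames=5000,
                            frame_interval_ns=0.01, seed=8)
    traj = ed.generate_rotational_diffusion_bonds(spec, d_coeff)
    profiles[d_coeff] = ed.bond_autocorrelation(traj, delays).values.mean(axis=0)

for k, tau in enumerate(delays):
    print(f"{tau:>8.1f} {profiles[0.1][k]:>12.3f} {profiles[1.0][k]:>12.3f} "
          f"{np.exp(-0.2 * tau):>16.3f} {np.exp(-2.0 * tau):>16.3f}")
print("-> tau = 0 is exactly 1 for every bond; the decay rate reads off the")
print("   orientational freedom (2D), matching the closed form.")
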