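"""Per-residue mean-square fluctuations and inter-residue distances.

Plants an isotropic per-axis variance of 0.25 Å² (msf = 3 x 0.25 = 0.75 Å²)
on a 60-residue chain and recovers it, then measures a Cα–Cα distance
series between two residues.
"""

import numpy as np

import ensembledyn as ed

spec = ed.SyntheticSpec(chains=[("A", 60)], n_frames=3000, seed=21, variance=0.25)
traj = ed.generate_gaussian_trajectory(spec)

profile = ed.mean_square_fluctuations(traj)
interior = profile.values[10:-10]
print(f"planted msf 0.75 A^2; recovered (interior mean) {interior.mean():.3f} A^2")
print(f"frames used: {profile.frames_used}")

res_a = ed.SelectionMask.from_residues(traj.topology, [("A", 5)])
res_b = ed.SelectionMask.from_residues(traj.topology, [("A", 40)])
series, mean = ed.distance_timeseries(traj, res_a, res_b, mode="calpha")
print(f"Calpha distance A:5 - A:40: mean {mean:.2f} A, sd {np.std(series):.2f} A")
print("-> the mean tracks the reference geometry; the sd reflects the")
print("   planted positional fluctuations of the two residues.")
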