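"""Dynamic cross-correlation maps, whole-trajectory and time-windowed.

Plants a correlation of rho = 0.8 between two residue groups for the first
half of a run and removes it for the second half, then shows that the
whole-trajectory map averages the two regimes while half-run windows
resolve the switch — the logic behind comparing correlation maps over the
time windows of a clustering timeline.
"""

import numpy as np

import ensembledyn as ed

group_a, group_b = [2, 3, 4], [10, 11, 12]
base = dict(chains=[("A", 16)], n_frames=2500, frame_interval_ns=0.01, variance=0.25)
first = ed.generate_gaussian_trajectory(
    ed.SyntheticSpec(**base, seed=5, correlation_blocks=[(group_a, group_b, 0.8)])
)
second = ed.generate_gaussian_trajectory(ed.SyntheticSpec(**base, seed=6))
traj = ed.join_trajectories(first, second)

whole = ed.cross_correlation_matrix(traj, prealigned=True)
half = first.frame_times[-1]
windows = [(0.0, half), (half, traj.frame_times[-1])]
mats, contrasts = ed.windowed_correlations(
    traj, windows, block_rows=np.array(group_a), block_cols=np.array(group_b),
    prealigned=True,
)

inter = lambda m: m.values[np.ix_(group_a, group_b)].mean()  # noqa: E731
print(f"planted inter-group rho: 0.8 (first half), 0.0 (second half)")
print(f"whole-trajectory inter-group mean: {inter(whole):.3f}")
print(f"window 1 (0-{half:.0f} ns):  {inter(mats[0]):.3f}")
print(f"window 2 ({half:.0f}-{traj.frame_times[-1]:.0f} ns): {inter(mats[1]):.3f}")
print(f"window-pair block contrast (mean |diff|): {contrasts[(0, 1)]:.3f}")
print("-> windowed maps resolve a correlation regime the whole-run map blurs.")
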