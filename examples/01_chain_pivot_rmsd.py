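"""Chain-pivot RMSD: detecting a quaternary reorientation.

Builds a two-chain trajectory in which chain B is rigidly reoriented by 30
degrees (plus a 2 Å shift) at t = 10 ns, then compares the self-aligned RMSD
of chain B with the cross-pivot RMSD (complex fitted on chain A, RMSD
measured on chain B).  Only the cross-pivot series sees the event, and its
post-event level matches the analytic RMSD of the planted transform.
"""

import ensembledyn as ed

spec = ed.SyntheticSpec(
    chains=[("A", 15), ("B", 15)],
    n_frames=400,
    frame_interval_ns=0.05,
    seed=13,
    variance=0.01,
    events=[ed.RotationEvent(time_ns=10.0, chain_id="B", angle_deg=30.0,
                             translation=(2.0, 0.0, 0.0))],
)
traj = ed.generate_rotation_event(spec)
ref = ed.helix_reference(spec.chains)
chain_a = ed.SelectionMask.from_chain(traj.topology, "A")
chain_b = ed.SelectionMask.from_chain(traj.topology, "B")

cross = ed.rmsd_timeseries(traj, ref, fit_mask=chain_a, measure_mask=chain_b)
self_b = ed.rmsd_timeseries(traj, ref, fit_mask=chain_b, measure_mask=chain_b)
pre = traj.frame_times <= 10.0

print(f"analytic RMSD of the planted transform: {ed.event_chain_rmsd(spec):.3f} A")
print(f"cross-pivot RMSD  pre-event {cross[pre].mean():.3f} A   "
      f"post-event {cross[~pre].mean():.3f} A")
print(f"self-aligned RMSD pre-event {self_b[pre].mean():.3f} A   "
      f"post-event {self_b[~pre].mean():.3f} A")
print("-> the step appears only under the cross pivot: the chains' internal")
print("   structure is unchanged, their relative orientation is not.")
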