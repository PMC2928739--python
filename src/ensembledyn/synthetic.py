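"""Synthetic Cα trajectories with planted, analytically known structure.

Every analysis stage in this package is validated against trajectories whose
statistical structure is planted by construction, so the expected outcome of
each statistic is known in closed form:

* stationary Gaussian fluctuations about an idealized helical reference with
  a planted residue-residue correlation structure (recovered by the
  cross-correlation map);
* Ornstein-Uhlenbeck temporal relaxation with known decay time, via the
  exact autoregressive update ``d_{t+1} = a d_t + sqrt(1-a^2) e_t`` with
  ``a = exp(-dt/theta)``, so the displacement autocorrelation is exactly
  ``exp(-tau/theta)`` on the frame grid;
* bond directions evolving by isotropic rotational diffusion with
  coefficient D, for which the first-rank orientational autocorrelation is
  ``exp(-2 D tau)`` (recovered by the bond-vector autocorrelation);
* a rigid-body reorientation of one chain partway through the run, whose
  analytic RMSD signature appears in cross-pivot RMSD series but not in
  self-aligned ones;
* multi-basin ensembles with planted cluster occupancies (recovered by the
  radius-seeded clustering).

The reference geometry is an idealized helical Cα trace with 3.8 Å
successive-Cα spacing, not a real protein: closed-form expectations and no
external files.  All randomness flows from one seeded generator per
trajectory; identical (spec, seed) gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Residue, Topology, Trajectory

__all__ = [
    "RotationEvent",
    "Basin",
    "SyntheticSpec",
    "helix_reference",
    "make_topology",
    "generate_gaussian_trajectory",
    "generate_rotational_diffusion_bonds",
    "generate_rotation_event",
    "generate_multibasin_ensemble",
    "basin_centers",
    "event_chain_rmsd",
]

_BOND_LENGTH = 3.8  # Å between successive Cα
_CHAIN_GAP = 30.0  # Å offset between chains of the reference


@dataclass(frozen=True)
class RotationEvent:
    """Rigid reorientation of one chain at a given time.

    After ``time_ns`` the chain's reference is rotated by ``angle_deg``
    about ``axis`` through the chain centroid and shifted by
    ``translation``.
    """

    time_ns: float
    chain_id: str
    angle_deg: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class Basin:
    """One conformational basin: center RMSD offset (Å), spread, weight."""

    offset: float  # RMSD of the basin center from the reference, Å
    spread: float  # per-axis Gaussian s.d. within the basin, Å
    weight: float


@dataclass
class SyntheticSpec:
    """Blueprint for a synthetic trajectory.

    ``variance`` is the planted per-residue, per-axis displacement variance
    (Å²); ``correlation_blocks`` lists residue groups whose displacements
    are mutually correlated at ρ (all off-diagonal pairs within the union of
    a block's groups get ρ — a compound-symmetric structure, which is a
    valid correlation matrix for ρ in (-1/(k-1), 1]).  The temporal model is
    white noise or an OU process with relaxation time ``theta_ns``.
    """

    chains: list[tuple[str, int]] = field(default_factory=lambda: [("A", 20)])
    n_frames: int = 1000
    frame_interval_ns: float = 0.01
    seed: int = 0
    variance: float = 0.25  # Å² per axis
    correlation_blocks: list[tuple[list[int], list[int], float]] = field(
        default_factory=list
    )
    temporal: str = "white"  # "white" | "ou"
    theta_ns: float = 0.1
    events: list[RotationEvent] = field(default_factory=list)
    basins: list[Basin] = field(default_factory=list)
    equilibration_end: float = 0.0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")
        if self.temporal not in {"white", "ou"}:
            raise ValueError(f"unknown temporal model {self.temporal!r}")
        if self.temporal == "ou" and self.theta_ns <= 0:
            raise ValueError("theta_ns must be positive for the OU model")
        if self.basins:
            w = sum(b.weight for b in self.basins)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"basin weights sum to {w}, not 1")
            if any(b.spread <= 0 for b in self.basins):
                raise ValueError("basin spreads must be positive")
        n = self.n_residues
        corr = self.correlation_matrix()
        if np.linalg.eigvalsh(corr)[0] < -1e-10:
            raise ValueError("planted correlation structure is not positive semidefinite")
        for a, b, _ in self.correlation_blocks:
            for i in list(a) + list(b):
                if not 0 <= i < n:
                    raise IndexError(f"correlation block index {i} out of range")

    @property
    def n_residues(self) -> int:
        return sum(n for _, n in self.chains)

    def correlation_matrix(self) -> np.ndarray:
        """The planted residue-residue correlation matrix."""
        n = self.n_residues
        corr = np.eye(n)
        for group_a, group_b, rho in self.correlation_blocks:
            members = sorted(set(group_a) | set(group_b))
            for i in members:
                for j in members:
                    if i != j:
                        corr[i, j] = rho
        return corr

    def times(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 1) * self.frame_interval_ns


def make_topology(chains: list[tuple[str, int]]) -> Topology:
    """Topology of poly-alanine chains with 1-based residue numbers."""
    residues = [
        Residue(cid, i + 1, "ALA") for cid, n in chains for i in range(n)
    ]
    return Topology(residues)


def helix_reference(chains: list[tuple[str, int]]) -> np.ndarray:
    """Idealized helical Cα trace, 3.8 Å successive-Cα spacing.

    Standard α-helix geometry: ~2.3 Å radius, 100° twist per residue and a
    rise chosen so that successive Cα atoms sit 3.8 Å apart.  Chains are
    laid side by side along x.
    """
    radius = 2.3
    twist = np.deg2rad(100.0)
    chord = 2 * radius * np.sin(twist / 2)
    rise = np.sqrt(_BOND_LENGTH**2 - chord**2)
    coords = []
    x0 = 0.0
    for _, n in chains:
        t = np.arange(n)
        xyz = np.stack(
            [
                x0 + radius * np.cos(twist * t),
                radius * np.sin(twist * t),
                rise * t,
            ],
            axis=1,
        )
        coords.append(xyz)
        x0 += _CHAIN_GAP
    return np.concatenate(coords)


def _correlated_displacements(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """(frames, residues, 3) displacements with the planted covariance.

    The three Cartesian axes are independent and share the residue-residue
    correlation structure, so the planted structure equals the normalized
    cross-correlation map in expectation.
    """
    n = spec.n_residues
    corr = spec.correlation_matrix()
    w, v = np.linalg.eigh(corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))  # corr = factor @ factor.T
    sigma = np.sqrt(spec.variance)

    def draw(frames: int) -> np.ndarray:
        z = rng.standard_normal((frames, 3, n))
        return np.einsum("ftk,nk->ftn", z, factor).transpose(0, 2, 1) * sigma

    if spec.temporal == "white" or spec.n_frames == 1:
        return draw(spec.n_frames)
    a = np.exp(-spec.frame_interval_ns / spec.theta_ns)
    out = np.empty((spec.n_frames, n, 3))
    innovations = draw(spec.n_frames)
    out[0] = innovations[0]
    c = np.sqrt(1.0 - a * a)
    for t in range(1, spec.n_frames):
        out[t] = a * out[t - 1] + c * innovations[t]
    return out


def generate_gaussian_trajectory(spec: SyntheticSpec) -> Trajectory:
    """Stationary Gaussian fluctuations about the helical reference.

    White or OU temporal structure; no events or basins.  The displacement
    lag-τ autocorrelation in OU mode is exactly ``exp(-tau/theta)`` at the
    frame grid.
    """
    spec.validate()
    if spec.events or spec.basins:
        raise ValueError("gaussian generator takes no events or basins")
    rng = np.random.default_rng(spec.seed)
    ref = helix_reference(spec.chains)
    coords = ref + _correlated_displacements(spec, rng)
    return Trajectory(
        make_topology(spec.chains), coords, spec.times(), spec.equilibration_end
    )


def generate_rotational_diffusion_bonds(spec: SyntheticSpec, D: float) -> Trajectory:
    """Single chain whose bond directions undergo rotational diffusion.

    Each virtual-bond direction is rotated every step by a random rotation
    with rotation-vector variance ``2 D dt`` per axis (isotropic diffusion
    with coefficient D, rad²/ns); coordinates are rebuilt by chaining 3.8 Å
    bonds.  The first-rank orientational autocorrelation of every bond is
    ``exp(-2 D tau)``.
    """
    spec.validate()
    if len(spec.chains) != 1:
        raise ValueError("rotational-diffusion generator takes a single chain")
    if D < 0:
        raise ValueError("diffusion coefficient must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    ref = helix_reference(spec.chains)
    directions = np.diff(ref, axis=0)
    directions /= np.linalg.norm(directions, axis=1)[:, None]
    n_bonds = n - 1
    sd = np.sqrt(2.0 * D * spec.frame_interval_ns)
    coords = np.empty((spec.n_frames, n, 3))
    for t in range(spec.n_frames):
        if t > 0 and sd > 0:
            rotvecs = rng.normal(scale=sd, size=(n_bonds, 3))
            directions = Rotation.from_rotvec(rotvecs).apply(directions)
        coords[t, 0] = 0.0
        coords[t, 1:] = np.cumsum(_BOND_LENGTH * directions, axis=0)
    return Trajectory(
        make_topology(spec.chains), coords, spec.times(), spec.equilibration_end
    )


def _event_transform(event: RotationEvent, chain_ref: np.ndarray):
    rot = Rotation.from_rotvec(
        np.deg2rad(event.angle_deg) * np.asarray(event.axis, dtype=float)
        / np.linalg.norm(event.axis)
    ).as_matrix()
    center = chain_ref.mean(axis=0)
    moved = (chain_ref - center) @ rot.T + center + np.asarray(event.translation)
    return moved


def event_chain_rmsd(spec: SyntheticSpec) -> float:
    """Analytic RMSD between the moving chain's pre- and post-event references."""
    (event,) = spec.events
    topo = make_topology(spec.chains)
    idx = topo.chain_indices(event.chain_id)
    chain_ref = helix_reference(spec.chains)[idx]
    moved = _event_transform(event, chain_ref)
    return float(np.sqrt(np.mean(np.sum((moved - chain_ref) ** 2, axis=1))))


def generate_rotation_event(spec: SyntheticSpec) -> Trajectory:
    """Two-chain trajectory with a planted mid-run rigid reorientation.

    Before the event both chains fluctuate (white Gaussian) about the
    reference; after it the target chain fluctuates about its rigidly
    transformed reference.  Per-chain internal geometry is statistically
    unchanged across the event, so only cross-pivot RMSD sees the step.
    """
    spec.validate()
    if len(spec.chains) < 2:
        raise ValueError("rotation-event generator needs at least 2 chains")
    if len(spec.events) != 1:
        raise ValueError("exactly one rotation event is required")
    (event,) = spec.events
    times = spec.times()
    if not times[0] <= event.time_ns < times[-1]:
        raise ValueError("event time outside trajectory span")
    topo = make_topology(spec.chains)
    idx = topo.chain_indices(event.chain_id)
    ref = helix_reference(spec.chains)
    post_ref = ref.copy()
    post_ref[idx] = _event_transform(event, ref[idx])
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(scale=np.sqrt(spec.variance), size=(spec.n_frames, len(topo), 3))
    coords = np.where(
        (times > event.time_ns)[:, None, None], post_ref[None], ref[None]
    ) + noise
    return Trajectory(topo, coords, times, spec.equilibration_end)


def basin_centers(spec: SyntheticSpec) -> np.ndarray:
    """Planted basin center conformations, (n_basins, residues, 3).

    Basin offsets are mutually orthogonal, per-residue displacement patterns
    scaled so each center's RMSD from the reference equals the basin's
    ``offset``.  The patterns have the rigid-body modes projected out (net
    translation and the linearized rotations about the reference centroid),
    so they are internal-shape changes that a rigid-body superposition
    cannot (to first order) remove.  Center-to-center RMSD is therefore
    ``sqrt(o_i^2 + o_j^2)``.
    """
    ref = helix_reference(spec.chains)
    n = spec.n_residues
    rng = np.random.default_rng(spec.seed + 7919)  # geometry stream, fixed offset
    rigid = _rigid_body_modes(ref)
    patterns: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    for b in spec.basins:
        if b.offset == 0:
            centers.append(ref.copy())
            continue
        p = rng.standard_normal((n, 3))
        for q in list(rigid) + patterns:
            p -= (np.sum(p * q) / np.sum(q * q)) * q
        p *= b.offset / np.sqrt(np.mean(np.sum(p * p, axis=1)))
        patterns.append(p)
        centers.append(ref + p)
    return np.asarray(centers)


def _rigid_body_modes(ref: np.ndarray) -> np.ndarray:
    """Translation and linearized-rotation displacement modes of a structure."""
    n = ref.shape[0]
    centered = ref - ref.mean(axis=0)
    modes = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        modes.append(t)
        axis = np.zeros(3)
        axis[k] = 1.0
        modes.append(np.cross(axis, centered))
    return np.asarray(modes)


def generate_multibasin_ensemble(
    spec: SyntheticSpec,
    weights_per_trajectory: list[list[float]] | None = None,
) -> list[Trajectory]:
    """One or more trajectories hopping between planted conformational basins.

    Each frame's basin is drawn independently from the planted weights
    (``weights_per_trajectory`` overrides the basin weights per output
    trajectory); within-basin spread is isotropic Gaussian.  Returns one
    trajectory per weight vector.
    """
    spec.validate()
    if not spec.basins:
        raise ValueError("basin spec required")
    weight_sets = weights_per_trajectory or [[b.weight for b in spec.basins]]
    for w in weight_sets:
        if len(w) != len(spec.basins):
            raise ValueError("weight vector length must match basin count")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {sum(w)}, not 1")
    centers = basin_centers(spec)
    topo = make_topology(spec.chains)
    seeds = np.random.SeedSequence(spec.seed).spawn(len(weight_sets))
    out = []
    for w, ss in zip(weight_sets, seeds):
        rng = np.random.default_rng(ss)
        which = rng.choice(len(spec.basins), size=spec.n_frames, p=w)
        spreads = np.array([b.spread for b in spec.basins])
        noise = rng.standard_normal((spec.n_frames, len(topo), 3))
        coords = centers[which] + noise * spreads[which, None, None]
        out.append(Trajectory(topo, coords, spec.times(), spec.equilibration_end))
    return out
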