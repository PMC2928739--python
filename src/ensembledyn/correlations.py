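"""Normalized fluctuation cross-correlations and bond-vector autocorrelations.

Two statistics quantify how binding reshapes a complex's dynamics:

* the dynamic cross-correlation map

      C_ij = <dR_i . dR_j> / sqrt(<dR_i^2> <dR_j^2>),

  with dR_i(t) the deviation of residue i's Cα from its mean position over
  the analysed frames, computed after per-frame superposition to remove
  rigid-body motion.  C_ij lies in [-1, 1]; +1 is fully correlated motion,
  -1 fully anti-correlated.  Maps can be computed over the whole trajectory
  or over time windows (each window self-contained: its own mean).

* the time-delayed autocorrelation of virtual backbone bond vectors

      A_i(tau) = <M_i(t) . M_i(t + tau)>,

  where M_i is the unit vector from the Cα of residue i-1 to the Cα of
  residue i.  A_i(0) = 1 for every bond; the decay with tau measures the
  bond's orientational freedom.  Bond vectors are internal directions, so
  this is computed on raw (unaligned) coordinates — per-frame realignment
  would alter it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SelectionMask, Topology, Trajectory
from .superpose import align_trajectory

__all__ = [
    "CorrelationMatrix",
    "AutocorrelationProfile",
    "cross_correlation_matrix",
    "windowed_correlations",
    "block_difference",
    "bond_vectors",
    "bond_autocorrelation",
]


@dataclass
class CorrelationMatrix:
    """Symmetric residue×residue matrix of normalized correlations.

    Residues with zero fluctuation have undefined correlations; their rows
    and columns are NaN, never silently zero, and are excluded from summary
    statistics.
    """

    values: np.ndarray
    labels: list[str]
    residue_indices: np.ndarray
    window: tuple[float, float] | None  # (start, end] in ns; None = whole
    n_frames: int

    def block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Sub-matrix addressed by topology indices (of the measured set)."""
        pos = {int(t): k for k, t in enumerate(self.residue_indices)}
        r = [pos[int(i)] for i in rows]
        c = [pos[int(j)] for j in cols]
        return self.values[np.ix_(r, c)]


@dataclass
class AutocorrelationProfile:
    """A_i(tau) per virtual bond over a grid of time delays (ns).

    Bond i points from the Cα of residue i-1 to the Cα of residue i; bonds
    never span a chain boundary.
    """

    values: np.ndarray  # (n_bonds, n_delays)
    delays: np.ndarray  # ns
    bond_indices: np.ndarray  # (n_bonds, 2) topology indices (i-1, i)
    bond_labels: list[str]


def _window_frames(
    traj: Trajectory,
    window: tuple[float, float] | None,
    exclude_equilibration: bool,
) -> np.ndarray:
    use = traj.usable(exclude_equilibration)
    if window is not None:
        lo, hi = window
        if hi <= lo:
            raise ValueError(f"empty window ({lo}, {hi}]")
        use = use & (traj.frame_times > lo) & (traj.frame_times <= hi)
    if use.sum() < 2:
        raise ValueError("window contains fewer than 2 usable frames")
    return use


def cross_correlation_matrix(
    traj: Trajectory,
    fit_mask: SelectionMask | None = None,
    measure_mask: SelectionMask | None = None,
    window: tuple[float, float] | None = None,
    exclude_equilibration: bool = True,
    use_global_mean: bool = False,
    prealigned: bool = False,
) -> CorrelationMatrix:
    """Normalized cross-correlation matrix over a time window.

    Each usable frame is superposed on ``fit_mask`` onto the first usable
    frame of the whole trajectory (so that windows share a frame of
    reference), unless ``prealigned`` is set.  Deviations are taken from the
    window-local mean by default; ``use_global_mean`` switches to the mean
    over all usable frames.
    """
    topo = traj.topology
    meas = measure_mask if measure_mask is not None else SelectionMask.all(topo)
    use_all = traj.usable(exclude_equilibration)
    use = _window_frames(traj, window, exclude_equilibration)
    if prealigned:
        aligned_all = traj.coordinates
    else:
        ref = traj.coordinates[np.flatnonzero(use_all)[0]]
        aligned_all = align_trajectory(traj, ref, fit_mask).coordinates
    sel = aligned_all[:, meas.indices]
    frames = sel[use]
    mean = sel[use_all].mean(axis=0) if use_global_mean else frames.mean(axis=0)
    delta = frames - mean  # (F, m, 3)
    inner = np.einsum("fik,fjk->ij", delta, delta) / delta.shape[0]
    var = np.einsum("fik,fik->i", delta, delta) / delta.shape[0]
    zero = var <= 0
    denom = np.sqrt(np.where(zero, 1.0, var))
    values = inner / np.outer(denom, denom)
    values[zero, :] = np.nan
    values[:, zero] = np.nan
    # enforce exact symmetry; einsum is symmetric up to rounding
    values = 0.5 * (values + values.T)
    return CorrelationMatrix(
        values=values,
        labels=meas.labels,
        residue_indices=meas.indices.copy(),
        window=window,
        n_frames=int(use.sum()),
    )


def block_difference(
    a: CorrelationMatrix,
    b: CorrelationMatrix,
    block_rows: np.ndarray | None = None,
    block_cols: np.ndarray | None = None,
) -> float:
    """Mean absolute difference between two maps over a residue block.

    Reduces a pair of (windowed) maps to one number for a chosen
    region-pair — e.g. catalytic-site rows against target-recognition
    columns.  Defaults to the full matrix; NaN entries are ignored.
    """
    if block_rows is None or block_cols is None:
        diff = a.values - b.values
    else:
        diff = a.block(block_rows, block_cols) - b.block(block_rows, block_cols)
    return float(np.nanmean(np.abs(diff)))


def windowed_correlations(
    traj: Trajectory,
    windows: list[tuple[float, float]],
    fit_mask: SelectionMask | None = None,
    measure_mask: SelectionMask | None = None,
    block_rows: np.ndarray | None = None,
    block_cols: np.ndarray | None = None,
    **kwargs,
) -> tuple[list[CorrelationMatrix], dict[tuple[int, int], float]]:
    """One correlation matrix per time window, plus pairwise block contrasts.

    Windows may come from a clustering timeline (each cluster's residence
    interval) and may overlap.  The second return value maps each window
    pair (i, j) to the mean absolute difference of their maps over the
    caller's residue block (whole matrix if no block given).
    """
    if not windows:
        raise ValueError("no windows given")
    mats = [
        cross_correlation_matrix(
            traj, fit_mask, measure_mask, window=w, **kwargs
        )
        for w in windows
    ]
    diffs: dict[tuple[int, int], float] = {}
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            diffs[(i, j)] = block_difference(mats[i], mats[j], block_rows, block_cols)
    return mats, diffs


def bond_vectors(
    coords: np.ndarray, topology: Topology
) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors between successive intra-chain Cα pairs of one frame.

    Returns ``(vectors, pairs)`` where ``pairs[k] = (i-1, i)`` are topology
    indices; chain-boundary pairs are omitted.  A zero-length bond
    (coincident successive Cα) is a hard error.
    """
    coords = np.asarray(coords, dtype=np.float64)
    pairs = bond_index_pairs(topology)
    vec = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    norms = np.linalg.norm(vec, axis=1)
    bad = np.flatnonzero(norms < 1e-12)
    if bad.size:
        i, j = pairs[bad[0]]
        ri, rj = topology.residues[i], topology.residues[j]
        raise ValueError(f"zero-length bond between {ri.label} and {rj.label}")
    return vec / norms[:, None], pairs


def bond_index_pairs(topology: Topology) -> np.ndarray:
    pairs = []
    for chain, (lo, hi) in topology.chain_offsets.items():
        if hi - lo < 2:
            raise ValueError(f"chain {chain!r} has fewer than 2 residues")
        for i in range(lo + 1, hi):
            pairs.append((i - 1, i))
    return np.asarray(pairs, dtype=np.intp)


def bond_autocorrelation(
    traj: Trajectory,
    delays_ns: list[float] | np.ndarray,
    exclude_equilibration: bool = True,
) -> AutocorrelationProfile:
    """Time-delayed autocorrelation of every virtual backbone bond vector.

    Computed on raw coordinates (no per-frame alignment; see module notes).
    Every delay must be a nonnegative multiple of the frame interval and
    must leave at least 2 frame pairs; averaging runs over all usable
    (t, t + tau) snapshot pairs.
    """
    delays = np.asarray(delays_ns, dtype=np.float64)
    if delays.size == 0:
        raise ValueError("no delays given")
    if np.any(delays < 0):
        raise ValueError("delays must be nonnegative")
    dt = traj.frame_interval()
    use = traj.usable(exclude_equilibration)
    coords = traj.coordinates[use]
    n_frames = coords.shape[0]
    if n_frames < 2:
        raise ValueError("need at least 2 usable frames")
    pairs = bond_index_pairs(traj.topology)
    # unit bond vectors for every usable frame at once
    vec = coords[:, pairs[:, 1]] - coords[:, pairs[:, 0]]  # (F, B, 3)
    norms = np.linalg.norm(vec, axis=2)
    if np.any(norms < 1e-12):
        f, b = np.argwhere(norms < 1e-12)[0]
        i, j = pairs[b]
        raise ValueError(
            f"zero-length bond between {traj.topology.residues[i].label} and "
            f"{traj.topology.residues[j].label} in frame {f}"
        )
    unit = vec / norms[:, :, None]
    values = np.empty((pairs.shape[0], delays.size))
    for k, tau in enumerate(delays):
        steps = tau / dt
        lag = int(round(steps))
        if abs(steps - lag) > 1e-6:
            raise ValueError(
                f"delay {tau} ns is not a multiple of the frame interval {dt} ns"
            )
        if n_frames - lag < 2:
            raise ValueError(f"delay {tau} ns leaves fewer than 2 frame pairs")
        if lag == 0:
            values[:, k] = np.einsum("fbk,fbk->b", unit, unit) / n_frames
        else:
            head, tail = unit[:-lag], unit[lag:]
            values[:, k] = np.einsum("fbk,fbk->b", head, tail) / head.shape[0]
    labels = [
        f"{traj.topology.residues[i].label}->{traj.topology.residues[j].label}"
        for i, j in pairs
    ]
    return AutocorrelationProfile(
        values=values, delays=delays, bond_indices=pairs, bond_labels=labels
    )
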