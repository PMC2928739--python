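"""Optimal rigid-body superposition and chain-pivot RMSD analyses.

The chain-pivot trick: superpose the complex on one chain (the fit mask)
and measure the RMSD of another chain (the measure mask).  A self-aligned
chain reports its internal deformation; a chain measured after fitting on
its partner additionally reports quaternary (relative-orientation) change,
which is how a rigid reorientation of one chain shows up as a step in the
cross-pivot RMSD series while each chain's self-aligned series stays flat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import SelectionMask, Trajectory

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "coordinate_rmsd",
    "rmsd_timeseries",
    "align_trajectory",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid transform: ``aligned = coords @ rotation.T + translation``."""

    rotation: np.ndarray  # 3x3 proper orthogonal
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float  # RMSD over the fit mask after superposition, Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def coordinate_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (non-superposing) RMSD between two congruent coordinate sets."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have identical shapes")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_mask: SelectionMask | np.ndarray | None = None,
) -> SuperpositionResult:
    """Mass-unweighted least-squares superposition of ``mobile`` onto ``reference``.

    Solved by singular value decomposition with the reflection branch
    forbidden (the returned rotation is proper, determinant +1).  Requires
    at least three non-collinear fit residues.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    idx = _mask_indices(fit_mask, mobile.shape[0])
    mob = mobile[idx]
    ref = reference[idx]
    if mob.shape[0] < 3:
        raise ValueError("superposition needs at least 3 fit residues")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if (
        np.linalg.matrix_rank(mob_c, tol=1e-8) < 2
        or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2
    ):
        raise ValueError("degenerate (collinear) fit selection")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    rotation = rot.as_matrix()
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    # recompute the residual from the transformed coordinates: the solver's
    # rssd is only sqrt(eps)-accurate near a perfect fit
    rmsd = coordinate_rmsd(mob @ rotation.T + translation, ref)
    return SuperpositionResult(rotation, translation, rmsd)


def _mask_indices(mask, n: int) -> np.ndarray:
    if mask is None:
        return np.arange(n)
    if isinstance(mask, SelectionMask):
        return mask.indices
    return np.asarray(mask, dtype=np.intp)


def rmsd_timeseries(
    traj: Trajectory,
    reference: np.ndarray,
    fit_mask: SelectionMask | None = None,
    measure_mask: SelectionMask | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference after superposing each frame on ``fit_mask``.

    With ``fit_mask == measure_mask`` this is the ordinary self-aligned RMSD;
    with distinct masks it is the chain-pivot RMSD (fit on one chain, measure
    the other).  Covers all frames; pair with ``traj.frame_times`` to plot.
    """
    fit_idx = _mask_indices(fit_mask, traj.n_residues)
    meas_idx = _mask_indices(measure_mask, traj.n_residues)
    if meas_idx.size == 0:
        raise ValueError("empty measure selection")
    out = np.empty(traj.n_frames)
    ref_meas = reference[meas_idx]
    for f in range(traj.n_frames):
        res = kabsch_superpose(traj.coordinates[f], reference, fit_idx)
        out[f] = coordinate_rmsd(res.apply(traj.coordinates[f])[meas_idx], ref_meas)
    return out


def align_trajectory(
    traj: Trajectory,
    reference: np.ndarray,
    fit_mask: SelectionMask | None = None,
) -> Trajectory:
    """Superpose every frame onto ``reference`` over ``fit_mask``.

    Topology, times and the equilibration marker are unchanged; alignment is
    idempotent.
    """
    fit_idx = _mask_indices(fit_mask, traj.n_residues)
    aligned = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        res = kabsch_superpose(traj.coordinates[f], reference, fit_idx)
        aligned[f] = res.apply(traj.coordinates[f])
    return traj.with_coordinates(aligned)
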