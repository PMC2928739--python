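"""Per-residue mean-square fluctuations and inter-residue distance series.

The mean-square fluctuation (msf) of residue *i* is the time average of
|R_i(t) - <R_i>|^2 after rigid-body motion has been removed by superposing
every frame on a chosen selection.  For chains in a complex the fit is done
per chain, so quaternary rearrangements do not inflate the per-chain
internal fluctuations; flexible segments (e.g. a disordered terminal tail)
can be excluded from the fit for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SelectionMask, Trajectory
from .superpose import align_trajectory

__all__ = ["FluctuationProfile", "mean_square_fluctuations", "distance_timeseries"]


@dataclass
class FluctuationProfile:
    """Per-residue msf in Å², keyed by topology index of the measured selection."""

    values: np.ndarray
    residue_indices: np.ndarray
    labels: list[str]
    frames_used: int
    alignment_indices: np.ndarray


def mean_square_fluctuations(
    traj: Trajectory,
    fit_mask: SelectionMask | None = None,
    measure_mask: SelectionMask | None = None,
    exclude_equilibration: bool = True,
    exclude_mask: SelectionMask | None = None,
) -> FluctuationProfile:
    """msf_i = <|R_i(t) - <R_i>|^2> over usable frames, Å².

    Frames are first superposed on ``fit_mask`` minus ``exclude_mask`` onto
    the first usable frame; the mean position is taken over the same frames.
    Equals the trace of the per-residue positional covariance.
    """
    topo = traj.topology
    fit = fit_mask if fit_mask is not None else SelectionMask.all(topo)
    fit = fit.minus(exclude_mask)
    if len(fit) == 0:
        raise ValueError("exclusions emptied the fit selection")
    meas = measure_mask if measure_mask is not None else SelectionMask.all(topo)
    use = traj.usable(exclude_equilibration)
    if use.sum() < 2:
        raise ValueError("need at least 2 usable frames for fluctuations")
    sub = Trajectory(
        topo, traj.coordinates[use], traj.frame_times[use], 0.0
    )
    ref = sub.coordinates[0]
    aligned = align_trajectory(sub, ref, fit).coordinates[:, meas.indices]
    mean = aligned.mean(axis=0)
    msf = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)
    return FluctuationProfile(
        values=msf,
        residue_indices=meas.indices.copy(),
        labels=meas.labels,
        frames_used=int(use.sum()),
        alignment_indices=fit.indices.copy(),
    )


def distance_timeseries(
    traj: Trajectory,
    selection_a: SelectionMask,
    selection_b: SelectionMask,
    mode: str = "calpha",
    exclude_equilibration: bool = True,
) -> tuple[np.ndarray, float]:
    """Per-frame distance (Å) between two selections, plus its mean.

    ``calpha`` mode measures between two single residues' Cα atoms;
    ``centroid`` mode measures between the unweighted Cα centroids of the
    two selections (a Cα-level stand-in for a center-of-mass distance).
    Distances are frame-internal, so no alignment is applied.
    """
    if len(selection_a) == 0 or len(selection_b) == 0:
        raise ValueError("empty selection")
    if mode == "calpha":
        if len(selection_a) != 1 or len(selection_b) != 1:
            raise ValueError("calpha mode requires single-residue selections")
    elif mode != "centroid":
        raise ValueError(f"unknown mode {mode!r}")
    coords = traj.usable_coordinates(exclude_equilibration)
    if coords.shape[0] == 0:
        raise ValueError("no usable frames")
    a = coords[:, selection_a.indices].mean(axis=1)
    b = coords[:, selection_b.indices].mean(axis=1)
    dist = np.linalg.norm(a - b, axis=1)
    return dist, float(dist.mean())
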