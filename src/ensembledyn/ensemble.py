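"""Conformational clustering and joined-ensemble principal component analysis.

Clustering uses a radius-seeded k-means: frames are scanned in order and a
frame farther than the radius (in coordinate RMSD) from every existing
centroid founds a new one; Lloyd iterations then alternate nearest-centroid
assignment (ties to the lowest cluster index) with coordinate-mean centroid
updates until assignments are stable.  The radius therefore controls the
number of clusters — larger radii merge basins — and, because seeding is
deterministic in frame order, results are exactly reproducible.

Joined-ensemble analysis fits one model on the union of frames from two
trajectories after aligning everything to a single fixed reference, so the
two ensembles' occupancies of the shared clusters (and their projections on
shared principal components) are directly comparable.  An ensemble confined
to one cluster while its partner spreads over several is the signature of a
restricted conformational space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import SelectionMask, Trajectory
from .superpose import align_trajectory

__all__ = [
    "ClusterModel",
    "PCAModel",
    "cluster_conformations",
    "joined_ensemble_analysis",
    "representative_structures",
    "pca_fit",
    "pca_project",
]


@dataclass
class ClusterModel:
    """Fitted radius-seeded k-means over one or more aligned ensembles."""

    centroids: np.ndarray  # (K, n_sel, 3)
    assignments: list[np.ndarray]  # per source trajectory, per usable frame
    frame_times: list[np.ndarray]  # times of the usable frames, per source
    radius: float
    occupancy: pd.DataFrame  # rows = sources, columns = clusters, percent
    selection_indices: np.ndarray
    n_iter: int
    objective_path: list[float] = field(default_factory=list)
    _frames: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.centroids.shape[0])

    def timelines(self) -> list[pd.DataFrame]:
        """(time, cluster) membership timeline per source trajectory."""
        return [
            pd.DataFrame({"time_ns": t, "cluster": a})
            for t, a in zip(self.frame_times, self.assignments)
        ]


@dataclass
class PCAModel:
    """Principal components of the joined, aligned coordinate ensemble."""

    mean: np.ndarray  # (n_sel, 3)
    components: np.ndarray  # (K, 3 * n_sel) orthonormal rows
    eigenvalues: np.ndarray  # Å², nonincreasing
    proportions: np.ndarray
    cumulative: np.ndarray
    fit_reference: np.ndarray
    fit_indices: np.ndarray
    selection_indices: np.ndarray


def _frame_rmsd(frames: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Coordinate RMSD of each frame to a centroid (no re-superposition)."""
    d = frames - centroid
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))


def _collect_frames(
    trajs: list[Trajectory],
    fit_reference: np.ndarray,
    fit_mask: SelectionMask | None,
    selection: SelectionMask | None,
    exclude_equilibration: bool,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Align every usable frame to the fixed reference; return selected coords."""
    frames, times = [], []
    n_res = trajs[0].n_residues
    sel_idx = (
        selection.indices if selection is not None else np.arange(n_res)
    )
    for traj in trajs:
        use = traj.usable(exclude_equilibration)
        if use.sum() == 0:
            raise ValueError("a trajectory has no usable frames")
        sub = Trajectory(
            traj.topology, traj.coordinates[use], traj.frame_times[use], 0.0
        )
        aligned = align_trajectory(sub, fit_reference, fit_mask)
        frames.append(aligned.coordinates[:, sel_idx])
        times.append(sub.frame_times)
    return frames, times, sel_idx


def cluster_conformations(
    trajs: Trajectory | list[Trajectory],
    fit_reference: np.ndarray,
    fit_mask: SelectionMask | None = None,
    radius: float = 1.7,
    seed: int = 0,
    max_iter: int = 100,
    selection: SelectionMask | None = None,
    exclude_equilibration: bool = True,
    shuffle_seeding: bool = False,
    source_labels: list[str] | None = None,
) -> ClusterModel:
    """Radius-seeded k-means on coordinate RMSD to the cluster centroid.

    Frames from every trajectory are aligned once to ``fit_reference`` over
    ``fit_mask`` (never re-aligned to moving centroids).  ``seed`` only
    matters with ``shuffle_seeding`` — by default seeding scans frames in
    their natural order and the fit is fully deterministic.  Empty clusters
    are dropped; the occupancy table has one row per source trajectory over
    its post-equilibration frames, each summing to 100%.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    frames, times, sel_idx = _collect_frames(
        trajs, fit_reference, fit_mask, selection, exclude_equilibration
    )
    data = np.concatenate(frames)  # (F, n_sel, 3)
    n_total = data.shape[0]

    order = np.arange(n_total)
    if shuffle_seeding:
        order = np.random.default_rng(seed).permutation(n_total)

    # Stage 1: greedy radius seeding
    centroids: list[np.ndarray] = []
    for f in order:
        if not centroids or min(
            _frame_rmsd(data[f][None], c)[0] for c in centroids
        ) > radius:
            centroids.append(data[f].copy())
    cent = np.asarray(centroids)

    # Stage 2: Lloyd iterations on plain coordinate RMSD
    assign = np.full(n_total, -1, dtype=np.intp)
    objective: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dists = np.stack([_frame_rmsd(data, c) for c in cent])  # (K, F)
        new_assign = np.argmin(dists, axis=0)  # argmin ties -> lowest index
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        keep = []
        for k in range(cent.shape[0]):
            members = assign == k
            if members.any():
                keep.append(data[members].mean(axis=0))
        cent = np.asarray(keep)
        # re-map assignments after dropping empty clusters
        dists = np.stack([_frame_rmsd(data, c) for c in cent])
        assign = np.argmin(dists, axis=0)
        objective.append(float(np.sum(dists[assign, np.arange(n_total)] ** 2)))

    # split per source and build occupancy table
    bounds = np.cumsum([f.shape[0] for f in frames])[:-1]
    per_source = np.split(assign, bounds)
    labels = source_labels or [f"trajectory_{i}" for i in range(len(trajs))]
    k = cent.shape[0]
    occ = pd.DataFrame(
        [
            [100.0 * np.mean(a == c) for c in range(k)]
            for a in per_source
        ],
        index=labels,
        columns=[f"cluster_{c}" for c in range(k)],
    )
    return ClusterModel(
        centroids=cent,
        assignments=per_source,
        frame_times=times,
        radius=float(radius),
        occupancy=occ,
        selection_indices=sel_idx,
        n_iter=n_iter,
        objective_path=objective,
        _frames=frames,
    )


def joined_ensemble_analysis(
    traj_a: Trajectory,
    traj_b: Trajectory,
    fit_reference: np.ndarray,
    fit_mask: SelectionMask | None = None,
    radius: float = 1.7,
    seed: int = 0,
    selection: SelectionMask | None = None,
    exclude_equilibration: bool = True,
    source_labels: tuple[str, str] = ("ensemble_a", "ensemble_b"),
) -> tuple[ClusterModel, list[pd.DataFrame]]:
    """Cluster the union of two ensembles; return the model and timelines.

    The occupancy table has one row per source ensemble over the shared
    clusters; the timelines give each frame's cluster membership against
    simulation time.
    """
    model = cluster_conformations(
        [traj_a, traj_b],
        fit_reference,
        fit_mask,
        radius=radius,
        seed=seed,
        selection=selection,
        exclude_equilibration=exclude_equilibration,
        source_labels=list(source_labels),
    )
    return model, model.timelines()


def representative_structures(model: ClusterModel) -> dict[int, dict]:
    """Per-cluster medoid: the member frame closest to its centroid.

    Ties break to the earliest frame (first source, then first in time).
    Returns ``{cluster: {"source", "frame", "coordinates", "rmsd"}}``.
    """
    reps: dict[int, dict] = {}
    for k in range(model.n_clusters):
        best = None
        for s, (frames, assign) in enumerate(zip(model._frames, model.assignments)):
            members = np.flatnonzero(assign == k)
            if members.size == 0:
                continue
            d = _frame_rmsd(frames[members], model.centroids[k])
            j = int(np.argmin(d))  # argmin ties -> earliest
            cand = (float(d[j]), s, int(members[j]))
            if best is None or cand[0] < best[0]:
                best = cand
        if best is None:
            import logging

            logging.getLogger(__name__).warning("cluster %d is empty; skipped", k)
            continue
        rmsd, s, f = best
        reps[k] = {
            "source": s,
            "frame": f,
            "coordinates": model._frames[s][f],
            "rmsd": rmsd,
        }
    return reps


def pca_fit(
    trajs: Trajectory | list[Trajectory],
    fit_reference: np.ndarray,
    fit_mask: SelectionMask | None = None,
    selection: SelectionMask | None = None,
    exclude_equilibration: bool = True,
) -> PCAModel:
    """PCA of the 3N coordinate covariance over the joined usable frames.

    Alignment follows the clustering convention (one fixed reference).  The
    model stores each component's variance proportion and the cumulative
    proportions (the numbers quoted on projection-plot axes).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    frames, _, sel_idx = _collect_frames(
        trajs, fit_reference, fit_mask, selection, exclude_equilibration
    )
    data = np.concatenate(frames)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 usable frames for PCA")
    flat = data.reshape(data.shape[0], -1)
    pca = PCA(svd_solver="full")
    pca.fit(flat)
    eigenvalues = pca.explained_variance_
    proportions = pca.explained_variance_ratio_
    return PCAModel(
        mean=pca.mean_.reshape(-1, 3),
        components=pca.components_,
        eigenvalues=eigenvalues,
        proportions=proportions,
        cumulative=np.cumsum(proportions),
        fit_reference=np.asarray(fit_reference, dtype=np.float64),
        fit_indices=(
            fit_mask.indices.copy()
            if fit_mask is not None
            else np.arange(fit_reference.shape[0])
        ),
        selection_indices=sel_idx,
    )


def pca_project(
    traj: Trajectory,
    model: PCAModel,
    components: list[int] | None = None,
    exclude_equilibration: bool = True,
) -> np.ndarray:
    """Project a trajectory's frames onto the model's principal components (Å).

    Frames are aligned with the model's stored convention, mean-centered on
    the model mean and dotted with the requested eigenvectors; component 0
    is the largest-variance mode.
    """
    if components is None:
        components = list(range(model.components.shape[0]))
    for c in components:
        if not 0 <= c < model.components.shape[0]:
            raise IndexError(f"component {c} out of range")
    use = traj.usable(exclude_equilibration)
    sub = Trajectory(traj.topology, traj.coordinates[use], traj.frame_times[use], 0.0)
    aligned = align_trajectory(sub, model.fit_reference, model.fit_indices)
    flat = aligned.coordinates[:, model.selection_indices].reshape(use.sum(), -1)
    centered = flat - model.mean.ravel()
    return centered @ model.components[components].T
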