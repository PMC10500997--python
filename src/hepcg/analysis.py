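"""Trajectory observables: end-to-end distance, radius of gyration, anchor
RMSD and density-based conformational clustering.

Conventions: the end-to-end distance (EED) is measured between the terminal
anchor oxygens (the experimental EED refers to chain termini); the radius of
gyration (Rg) is the mass-uniform RMS distance of the site centers from
their centroid (one site per residue).  Means and standard deviations are
taken over post-equilibration frames (the first 10% of each trajectory is
discarded by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import svd
from sklearn.cluster import DBSCAN

from .errors import AlignmentError, ParameterError
from .dynamics import Trajectory

__all__ = [
    "ObservableSeries",
    "ClusterReport",
    "PercentageError",
    "end_to_end_distance",
    "radius_of_gyration",
    "rmsd_anchors",
    "cluster_frames",
    "percentage_error",
    "compute_observables",
    "sites_from_anchors",
]


def sites_from_anchors(anchors: np.ndarray) -> np.ndarray:
    """Site centers (midpoints of consecutive anchors) for one frame."""
    anchors = np.asarray(anchors, float)
    return 0.5 * (anchors[:-1] + anchors[1:])


def end_to_end_distance(frame: np.ndarray) -> float:
    """Euclidean distance between the first and last anchor of a frame, Å."""
    frame = np.asarray(frame, float)
    if frame.shape[0] < 2:
        raise ParameterError("need at least 2 anchors for an end-to-end distance")
    return float(np.linalg.norm(frame[-1] - frame[0]))


def radius_of_gyration(points: np.ndarray) -> float:
    """Mass-uniform radius of gyration of a point set, Å.

    sqrt(<|x - <x>|²>); for trajectory frames pass the site centers
    (:func:`sites_from_anchors`).
    """
    points = np.atleast_2d(np.asarray(points, float))
    centered = points - points.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def rmsd_anchors(frame: np.ndarray, reference: np.ndarray) -> float:
    """Minimal RMSD between two anchor frames after optimal rigid superposition.

    Kabsch algorithm (SVD of the covariance, proper rotation enforced).
    """
    x = np.asarray(frame, float)
    y = np.asarray(reference, float)
    if x.shape != y.shape:
        raise AlignmentError(f"anchor count mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    U, _, Vt = svd(xc.T @ yc)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, sign])
    R = U @ D @ Vt
    diff = xc @ R - yc
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


@dataclass
class PercentageError:
    """Unsigned percentage error plus the direction of the deviation."""

    percent: float
    direction: str  # "above" | "below" | "exact"

    def __float__(self) -> float:
        return self.percent


def percentage_error(simulated: float, reference: float) -> PercentageError:
    """100·|simulated − reference|/reference, direction reported separately."""
    if reference <= 0:
        raise ParameterError(f"reference must be > 0, got {reference}")
    pe = 100.0 * abs(simulated - reference) / reference
    if simulated > reference:
        direction = "above"
    elif simulated < reference:
        direction = "below"
    else:
        direction = "exact"
    return PercentageError(percent=pe, direction=direction)


@dataclass
class ObservableSeries:
    """Per-frame EED and Rg with post-equilibration summary statistics."""

    eed: np.ndarray
    rg: np.ndarray
    eed_mean: float
    eed_std: float
    rg_mean: float
    rg_std: float
    equilibration: float  # fraction of initial frames excluded from the stats


def compute_observables(traj: Trajectory | np.ndarray, equilibration: float = 0.1) -> ObservableSeries:
    """EED/Rg series of a trajectory (or raw (F, n_anchors, 3) frame stack)."""
    frames = traj.frames if isinstance(traj, Trajectory) else np.asarray(traj, float)
    if not 0 <= equilibration < 1:
        raise ParameterError("equilibration fraction must lie in [0, 1)")
    eed = np.linalg.norm(frames[:, -1] - frames[:, 0], axis=1)
    sites = 0.5 * (frames[:, :-1] + frames[:, 1:])
    centered = sites - sites.mean(axis=1, keepdims=True)
    rg = np.sqrt((centered**2).sum(axis=2).mean(axis=1))
    n0 = int(equilibration * len(eed))
    return ObservableSeries(
        eed=eed,
        rg=rg,
        eed_mean=float(eed[n0:].mean()),
        eed_std=float(eed[n0:].std()),
        rg_mean=float(rg[n0:].mean()),
        rg_std=float(rg[n0:].std()),
        equilibration=equilibration,
    )


@dataclass
class ClusterReport:
    """Density-based clustering of trajectory frames by pairwise anchor RMSD."""

    labels: np.ndarray           # per-frame cluster label, -1 = noise
    n_clusters: int
    representatives: dict        # label -> frame index minimizing intra-cluster RMSD sum
    noise_count: int


def cluster_frames(
    traj: Trajectory | np.ndarray, eps: float = 4.0, min_size: int = 2
) -> ClusterReport:
    """DBSCAN clustering of frames with RMSD distance.

    Defaults follow the production analysis protocol: distance cutoff 4 Å and
    minimum cluster size 2.  The representative of each cluster is the frame
    minimizing the total RMSD to its cluster mates.
    """
    frames = traj.frames if isinstance(traj, Trajectory) else np.asarray(traj, float)
    n = frames.shape[0]
    if n == 0:
        return ClusterReport(labels=np.empty(0, int), n_clusters=0, representatives={}, noise_count=0)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = rmsd_anchors(frames[i], frames[j])
    labels = DBSCAN(eps=eps, min_samples=min_size, metric="precomputed").fit_predict(dist)
    uniq = sorted(set(labels) - {-1})
    reps = {}
    for lab in uniq:
        members = np.flatnonzero(labels == lab)
        reps[int(lab)] = int(members[np.argmin(dist[np.ix_(members, members)].sum(axis=1))])
    return ClusterReport(
        labels=labels,
        n_clusters=len(uniq),
        representatives=reps,
        noise_count=int((labels == -1).sum()),
    )
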