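"""Radius-based K-means clustering of conformers by mutual C-alpha RMSD.

The greedy radius seeding works like kclust: the first frame seeds
cluster 1 and each subsequent frame farther than the radius from every
existing centroid seeds a new cluster.  Assignments then iterate to a
fixed point, recomputing each centroid as the coordinate mean of its
members after superposing them onto the current centroid.  Clusters are
reported ordered by population.  A radius of 3.0 A is the conventional
choice for disordered protein ensembles.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ValidationError
from .helix_geometry import superpose

MAX_ITERATIONS = 100


def pairwise_rmsd_matrix(frames: np.ndarray,
                         selection: np.ndarray | None = None) -> np.ndarray:
    """Symmetric matrix of minimal RMSD after optimal superposition."""
    x = np.asarray(frames, dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 frames")
    if selection is not None:
        x = x[:, np.asarray(selection), :]
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = superpose(x[i], x[j])[2]
    return out


@dataclasses.dataclass
class ClusterResult:
    assignments: np.ndarray  # frame -> cluster id (0-based, by population)
    populations: np.ndarray  # fractions, sum to 1
    centroids: list[np.ndarray]  # mean coordinates of superposed members
    radius: float
    converged: bool
    n_iterations: int
    selection: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def member_rmsds(self, frames: np.ndarray) -> np.ndarray:
        """RMSD of each frame to its assigned centroid."""
        x = np.asarray(frames, dtype=float)
        if self.selection is not None:
            x = x[:, np.asarray(self.selection), :]
        return np.array([
            superpose(x[f], self.centroids[c])[2]
            for f, c in enumerate(self.assignments)])


def _centroid_of(members: np.ndarray) -> np.ndarray:
    """Coordinate mean after superposing every member onto the first."""
    ref = members[0]
    acc = np.zeros_like(ref)
    for frame in members:
        rot, t, _ = superpose(frame, ref)
        acc += frame @ rot.T + t
    return acc / members.shape[0]


def kmeans_radius_cluster(frames: np.ndarray,
                          selection: np.ndarray | None = None,
                          radius: float = 3.0,
                          max_iterations: int = MAX_ITERATIONS
                          ) -> ClusterResult:
    """Cluster frames so members lie within ``radius`` of their centroid.

    Equidistant frames break ties toward the lower-indexed cluster, so
    the result is deterministic for a given frame order.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    x = np.asarray(frames, dtype=float)
    if selection is not None:
        x = x[:, np.asarray(selection), :]
    n = x.shape[0]
    centroids: list[np.ndarray] = [x[0].copy()]
    assignments = np.zeros(n, dtype=int)
    converged = False
    iteration = 0
    for iteration in range(1, max_iterations + 1):
        changed = False
        for f in range(n):
            d = np.array([superpose(x[f], c)[2] for c in centroids])
            best = int(np.argmin(d))
            if d[best] > radius:
                centroids.append(x[f].copy())
                best = len(centroids) - 1
            if assignments[f] != best:
                assignments[f] = best
                changed = True
        # recompute centroids; drop clusters that lost all members
        new_centroids = []
        remap = {}
        for c in range(len(centroids)):
            members = x[assignments == c]
            if members.shape[0] == 0:
                continue
            remap[c] = len(new_centroids)
            new_centroids.append(_centroid_of(members))
        centroids = new_centroids
        assignments = np.array([remap[c] for c in assignments])
        if not changed and iteration > 1:
            converged = True
            break
    # order clusters by population (descending), stable on ties
    counts = np.bincount(assignments, minlength=len(centroids))
    order = np.argsort(-counts, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    assignments = rank[assignments]
    centroids = [centroids[i] for i in order]
    populations = counts[order] / n
    return ClusterResult(assignments=assignments, populations=populations,
                         centroids=centroids, radius=radius,
                         converged=converged, n_iterations=iteration,
                         selection=(None if selection is None
                                    else np.asarray(selection)))


def write_cluster_table(result: ClusterResult, frames: np.ndarray,
                        path: str) -> None:
    rmsds = result.member_rmsds(np.asarray(frames, dtype=float))
    with open(path, "w") as fh:
        fh.write(f"# radius_angstrom={result.radius} "
                 f"converged={result.converged}\n")
        fh.write("frame\tcluster\trmsd_to_centroid\n")
        for f, (c, r) in enumerate(zip(result.assignments, rmsds)):
            fh.write(f"{f}\t{c}\t{r:.4f}\n")
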