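"""k-means clustering of fragment embeddings (Lloyd's algorithm).

Fragments embedded in the 16-dimensional Euclidean latent space are
grouped into k classes; ideally each class collects the fragments of one
precursor. k is not a fixed constant: the caller typically sets it to the
number of candidate precursors detected in the slider. After high-scoring
precursor-fragment pairs are removed, the remaining fragments are
clustered again (second pass) to improve fragment usage.

Implementation notes: k-means++ seeding from a seeded generator; ties go
to the lowest-index centroid (argmin semantics); an emptied cluster is
re-seeded at the point farthest from its assigned centroid; Lloyd
iterations run until the max centroid shift is below `tol` or `max_iter`
is reached, and inertia is non-increasing across iterations by
construction (asserted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Set

import numpy as np

__all__ = ["ClusterAssignment", "kmeans_cluster", "second_pass_cluster"]


@dataclass
class ClusterAssignment:
    labels: np.ndarray      # cluster id per point
    centroids: np.ndarray   # (k, d)
    inertia: float
    point_ids: Optional[np.ndarray] = None  # original ids (second pass)

    def members(self, c: int):
        ids = self.point_ids if self.point_ids is not None \
            else np.arange(self.labels.size)
        return ids[self.labels == c]


def _plusplus_init(x: np.ndarray, k: int, rng: np.random.Generator):
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    d2 = np.sum((x - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = x[rng.integers(n)]
        else:
            centroids[j] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((x - centroids[j]) ** 2, axis=1))
    return centroids


def kmeans_cluster(embeddings, k: int, seed: int = 0,
                   max_iter: int = 100, tol: float = 1e-6) -> ClusterAssignment:
    """Cluster points into k classes with seeded Lloyd iterations."""
    x = np.atleast_2d(np.asarray(embeddings, dtype=float))
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    centroids = _plusplus_init(x, k, rng)
    prev_inertia = np.inf
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)  # ties -> lowest centroid index
        inertia = float(d2[np.arange(n), labels].sum())
        assert inertia <= prev_inertia + 1e-9, "Lloyd iteration raised inertia"
        prev_inertia = inertia
        new_centroids = centroids.copy()
        for c in range(k):
            mask = labels == c
            if mask.any():
                new_centroids[c] = x[mask].mean(axis=0)
            else:  # re-seed an emptied cluster at the farthest point
                far = int(d2[np.arange(n), labels].argmax())
                new_centroids[c] = x[far]
        shift = float(np.abs(new_centroids - centroids).max())
        centroids = new_centroids
        if shift < tol:
            break
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    return ClusterAssignment(labels=labels, centroids=centroids,
                             inertia=inertia)


def second_pass_cluster(embeddings, first_assignment: ClusterAssignment,
                        accepted: Set[int], k2: int,
                        seed: int = 0) -> ClusterAssignment:
    """Re-cluster the fragments not yet assigned to an accepted group.

    `accepted` holds fragment ids removed after the first matching round;
    k2 is clamped to [1, n_remaining]. An empty remainder yields an empty
    assignment.
    """
    x = np.atleast_2d(np.asarray(embeddings, dtype=float))
    keep = np.array([i for i in range(x.shape[0]) if i not in accepted],
                    dtype=int)
    if keep.size == 0:
        return ClusterAssignment(labels=np.empty(0, dtype=int),
                                 centroids=np.empty((0, x.shape[1])),
                                 inertia=0.0, point_ids=keep)
    k2 = int(min(max(k2, 1), keep.size))
    sub = kmeans_cluster(x[keep], k2, seed=seed)
    return ClusterAssignment(labels=sub.labels, centroids=sub.centroids,
                             inertia=sub.inertia, point_ids=keep)
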