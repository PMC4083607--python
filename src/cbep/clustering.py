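"""Group predicted antigenic-determinant residues into candidate epitopes.

Conformational epitopes are sequence-discontinuous but spatially compact,
so predicted residues are partitioned by divisive spatial clustering:
start with all residues in one cluster and repeatedly bisect (2-means on
Cα coordinates) any cluster whose diameter — the maximum pairwise member
distance — exceeds a threshold T. The threshold derives from the observed
geometry of real epitopes: with R_avg the mean distance of annotated
epitope residues to their epitope centroid (about 19 Å in both bound and
unbound benchmark sets), T = α·(2·R_avg); α = 1.1 gives T = 41.8 Å.

A complete-linkage agglomerative cut at the same T is available as an
alternative backend for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_array

from .io import AntigenRecord

__all__ = [
    "ClusteringConfig",
    "EpitopeCluster",
    "compute_r_avg",
    "derive_threshold",
    "EpitopeClusterer",
    "cluster_epitopes",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Threshold configuration: T = α·(2·r_avg) unless overridden."""

    alpha: float = 1.1
    r_avg: float = 19.0
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.r_avg <= 0:
            raise ValueError("alpha and r_avg must be positive")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class EpitopeCluster:
    """A candidate epitope: member residue indices and their Cα centroid."""

    members: np.ndarray  # sorted 0-based residue indices
    centroid: np.ndarray  # (3,) Å

    def __len__(self) -> int:
        return self.members.size


def derive_threshold(cfg: ClusteringConfig) -> float:
    """Clustering threshold in Å: the explicit override, else α·(2·r_avg)."""
    if cfg.threshold is not None:
        return float(cfg.threshold)
    return cfg.alpha * 2.0 * cfg.r_avg


def compute_r_avg(records: list[AntigenRecord]) -> float:
    """Mean distance of annotated epitope residues to their epitope centroid.

    Pools all annotated antigenic-determinant residues (with coordinates)
    over all records; each residue contributes its distance to the
    centroid of its own epitope. Raises if no annotated epitope exists.
    """
    dists: list[float] = []
    for rec in records:
        if rec.epitope_ids is None or rec.coords is None:
            continue
        for eid in np.unique(rec.epitope_ids):
            if eid == 0:
                continue
            pts = rec.coords[rec.epitope_ids == eid]
            pts = pts[~np.isnan(pts).any(axis=1)]
            if len(pts) == 0:
                continue
            centroid = pts.mean(axis=0)
            dists.extend(np.linalg.norm(pts - centroid, axis=1))
    if not dists:
        raise ValueError("no annotated epitopes with coordinates")
    return float(np.mean(dists))


def _diameter(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(pdist(points).max())


def _bisect(points: np.ndarray, idx: np.ndarray, n_restarts: int, seed: int):
    """Split one cluster in two by 2-means (best of ``n_restarts`` by WCSS)."""
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    lab = km.fit_predict(points)
    if np.unique(lab).size < 2:
        # degenerate split: assign each point to the nearer end of the
        # farthest pair, guaranteeing both sides are non-empty
        dm = squareform(pdist(points))
        i, j = np.unravel_index(np.argmax(dm), dm.shape)
        lab = (dm[:, j] < dm[:, i]).astype(int)
    return idx[lab == 0], idx[lab == 1]


class EpitopeClusterer(ClusterMixin, BaseEstimator):
    """Partition 3D points into clusters whose diameters do not exceed T.

    Parameters
    ----------
    alpha, r_avg, threshold :
        See :class:`ClusteringConfig`; ``threshold`` overrides the derived
        α·(2·r_avg).
    backend : {"divisive", "complete-linkage"}
        Divisive 2-means bisection (default) or an agglomerative
        complete-linkage cut at T.
    n_restarts : int
        2-means restarts per bisection.
    random_state : int or None
        Seeds the bisection k-means.

    Attributes
    ----------
    labels_ : ndarray
        Cluster label per input point; clusters are numbered 0, 1, … in
        descending size, ties broken by smallest member index.
    clusters_ : list of EpitopeCluster
    threshold_ : float
        The T actually used (Å).
    """

    def __init__(
        self,
        alpha: float = 1.1,
        r_avg: float = 19.0,
        threshold: float | None = None,
        backend: str = "divisive",
        n_restarts: int = 10,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.r_avg = r_avg
        self.threshold = threshold
        self.backend = backend
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite=False)
        if X.shape[1] != 3:
            raise ValueError("expected (n, 3) Cα coordinates")
        if np.isnan(X).any():
            bad = np.unique(np.nonzero(np.isnan(X))[0])
            raise ValueError(
                f"points without finite coordinates at rows {bad.tolist()}; "
                "drop coordinate-less residues before clustering"
            )
        cfg = ClusteringConfig(self.alpha, self.r_avg, self.threshold)
        T = derive_threshold(cfg)
        if self.backend == "divisive":
            groups = self._divisive(X, T)
        elif self.backend == "complete-linkage":
            lab = fcluster(linkage(X, method="complete"), t=T, criterion="distance") \
                if len(X) > 1 else np.ones(1, dtype=int)
            groups = [np.nonzero(lab == k)[0] for k in np.unique(lab)]
        else:
            raise ValueError(f"unknown backend {self.backend!r}")

        # descending size, ties by smallest member index
        groups.sort(key=lambda g: (-g.size, g.min()))
        self.labels_ = np.empty(len(X), dtype=int)
        self.clusters_ = []
        for k, g in enumerate(groups):
            self.labels_[g] = k
            self.clusters_.append(
                EpitopeCluster(members=np.sort(g), centroid=X[g].mean(axis=0))
            )
        self.threshold_ = T
        return self

    def _divisive(self, X: np.ndarray, T: float) -> list[np.ndarray]:
        rng = check_random_state(self.random_state)
        pending = [np.arange(len(X))]
        done: list[np.ndarray] = []
        while pending:
            idx = pending.pop()
            if _diameter(X[idx]) <= T:
                done.append(idx)
                continue
            seed = int(rng.randint(0, 2**31 - 1))
            left, right = _bisect(X[idx], idx, self.n_restarts, seed)
            pending.extend([left, right])
        return done

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_epitopes(
    residue_indices: np.ndarray,
    coords: np.ndarray,
    cfg: ClusteringConfig | None = None,
    seed: int | None = None,
    backend: str = "divisive",
) -> list[EpitopeCluster]:
    """Cluster predicted residues (given whole-chain coords) into epitopes.

    ``residue_indices`` are 0-based indices into ``coords``; every indexed
    residue must have finite coordinates. Returns clusters whose members
    are chain residue indices, ordered by descending size.
    """
    cfg = cfg or ClusteringConfig()
    residue_indices = np.asarray(residue_indices, dtype=int)
    if residue_indices.size == 0:
        return []
    pts = np.asarray(coords, dtype=float)[residue_indices]
    if np.isnan(pts).any():
        bad = residue_indices[np.isnan(pts).any(axis=1)]
        raise ValueError(f"residues without coordinates: {bad.tolist()}")
    clusterer = EpitopeClusterer(
        alpha=cfg.alpha,
        r_avg=cfg.r_avg,
        threshold=cfg.threshold,
        backend=backend,
        random_state=seed,
    )
    clusterer.fit(pts)
    return [
        EpitopeCluster(
            members=np.sort(residue_indices[c.members]), centroid=c.centroid
        )
        for c in clusterer.clusters_
    ]
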