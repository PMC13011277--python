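"""Compound structural similarity: fingerprints, Tanimoto, per-herb K-means
(k = 3) and cluster-validity scoring (Dunn index, silhouette).

Each herb's compounds are fingerprinted (hashed path fingerprints, 1024 bits
by default), clustered into three groups, and the herb is retained for
downstream synergy modelling only when its mean silhouette clears the
acceptance threshold — i.e. when its chemistry falls into well-separated
structural groups rather than an undifferentiated blur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "Fingerprint",
    "ClusterSolution",
    "fingerprint",
    "tanimoto",
    "tanimoto_distance_matrix",
    "TanimotoKMeans",
    "cluster_compounds",
    "dunn_index",
    "silhouette_scores",
    "retain_herbs",
]


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary molecular fingerprint."""

    compound_id: str
    bits: tuple
    generator: str = "rdkit-path-1024"

    def __len__(self):
        return len(self.bits)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.uint8)


def fingerprint(structure: str, length: int = 1024, compound_id: str = "") -> Fingerprint:
    """Hashed path-based binary fingerprint of a SMILES string.

    Structures are parsed (and thereby canonicalised) with RDKit, so
    alternative SMILES spellings of one molecule give identical bits.
    Unparsable input raises ``ValueError`` naming the compound.
    """
    from rdkit import Chem  # heavy import kept local

    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparsable SMILES for compound {compound_id or structure!r}")
    fp = Chem.RDKFingerprint(mol, fpSize=length)
    bits = np.zeros(length, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return Fingerprint(compound_id=compound_id, bits=tuple(int(b) for b in bits),
                       generator=f"rdkit-path-{length}")


def _bits(a) -> np.ndarray:
    if isinstance(a, Fingerprint):
        return a.as_array()
    return np.asarray(a, dtype=np.uint8)


def tanimoto(a, b) -> float:
    """|a ∧ b| / |a ∨ b|; defined as 1 when both fingerprints are all-zero."""
    av, bv = _bits(a), _bits(b)
    if av.shape != bv.shape:
        raise ValueError(f"fingerprint length mismatch: {av.shape} vs {bv.shape}")
    union = int(np.logical_or(av, bv).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(av, bv).sum()) / union


def tanimoto_distance_matrix(fps) -> np.ndarray:
    """Pairwise 1 − Tanimoto distances, vectorised over a bit matrix."""
    X = np.vstack([_bits(f) for f in fps]).astype(float)
    inter = X @ X.T
    pop = X.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union == 0, 1, union), 1.0)
    return 1.0 - sim


@dataclass
class ClusterSolution:
    """Per-herb clustering result with validity metrics.

    ``labels`` maps compound id → cluster label in 1..k.  ``dunn`` may be
    ``inf`` (all-singleton sentinel); such herbs are excluded from Dunn
    means downstream.
    """

    labels: dict
    k: int
    avg_silhouette: float
    dunn: float
    seed: int
    inertia: float = float("nan")

    def __post_init__(self):
        used = set(self.labels.values())
        if not used <= set(range(1, self.k + 1)):
            raise ValueError("cluster labels outside 1..k")


class TanimotoKMeans(BaseEstimator, ClusterMixin):
    """K-means over molecular fingerprints with Tanimoto-based validity.

    ``mode="bits"`` (default) runs k-means++ on the raw binary vectors —
    squared Euclidean distance on bits is monotone in 1 − Tanimoto at fixed
    popcount.  ``mode="medoid"`` runs a PAM-style k-medoid loop on the exact
    Tanimoto distance matrix.  Validity metrics (silhouette, Dunn) are
    always computed on the Tanimoto distance by default.

    Attributes after ``fit``: ``labels_`` (0-based, sklearn convention),
    ``inertia_``, ``silhouette_mean_``, ``dunn_``, ``distance_matrix_``.
    """

    def __init__(self, n_clusters: int = 3, restarts: int = 10, random_state: int = 0,
                 mode: str = "bits", validity_metric: str = "tanimoto"):
        self.n_clusters = n_clusters
        self.restarts = restarts
        self.random_state = random_state
        self.mode = mode
        self.validity_metric = validity_metric

    def fit(self, X, y=None):
        X = np.vstack([_bits(f) for f in X]).astype(float)
        n = X.shape[0]
        if n < self.n_clusters:
            raise ValueError(f"{n} compounds < k={self.n_clusters}")
        D = tanimoto_distance_matrix(X.astype(np.uint8))
        if self.mode == "bits":
            km = KMeans(n_clusters=self.n_clusters, n_init=self.restarts,
                        random_state=self.random_state)
            labels = km.fit_predict(X)
            self.inertia_ = float(km.inertia_)
            self.cluster_centers_ = km.cluster_centers_
        elif self.mode == "medoid":
            labels, cost = _kmedoids(D, self.n_clusters, self.restarts, self.random_state)
            self.inertia_ = float(cost)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        labels = _canonical_labels(labels)
        self.labels_ = labels
        Dv = D if self.validity_metric == "tanimoto" else _euclidean_matrix(X)
        self.distance_matrix_ = Dv
        if len(set(labels)) >= 2:
            scores, mean = silhouette_scores(labels, Dv)
            self.silhouette_mean_ = mean
            self.silhouette_samples_ = scores
            self.dunn_ = dunn_index(labels, Dv)
        else:  # degenerate k=1 fit
            self.silhouette_mean_ = 0.0
            self.silhouette_samples_ = np.zeros(n)
            self.dunn_ = float("inf")
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance so the labelling is
    invariant to the backend's arbitrary numbering."""
    mapping, out = {}, np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _euclidean_matrix(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _kmedoids(D: np.ndarray, k: int, restarts: int, seed: int):
    """Small PAM-style alternating k-medoid on a distance matrix."""
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    best_labels, best_cost = None, np.inf
    for _ in range(max(restarts, 1)):
        medoids = list(rng.choice(n, size=k, replace=False))
        for _ in range(100):
            labels = np.argmin(D[:, medoids], axis=1)
            new_medoids = []
            for c in range(k):
                members = np.flatnonzero(labels == c)
                if len(members) == 0:  # re-seed an emptied cluster
                    members = np.array([int(rng.integers(n))])
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids.append(int(members[int(np.argmin(within))]))
            if new_medoids == medoids:
                break
            medoids = new_medoids
        labels = np.argmin(D[:, medoids], axis=1)
        cost = float(D[np.arange(n), np.array(medoids)[labels]].sum())
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels, best_cost


def cluster_compounds(fps, k: int = 3, seed: int = 0, restarts: int = 10,
                      mode: str = "bits", validity_metric: str = "tanimoto") -> ClusterSolution:
    """Cluster one herb's compound fingerprints into ``k`` groups.

    Herbs with fewer than ``k`` compounds cannot be partitioned and raise;
    the caller is expected to skip them (mirroring the ≥ 3-compound rule).
    """
    fps = list(fps)
    ids = [f.compound_id if isinstance(f, Fingerprint) else str(i)
           for i, f in enumerate(fps)]
    order = sorted(range(len(fps)), key=lambda i: ids[i])  # order-invariant fit
    est = TanimotoKMeans(n_clusters=k, restarts=restarts, random_state=seed,
                         mode=mode, validity_metric=validity_metric).fit(
                             [fps[i] for i in order])
    labels = {ids[i]: int(lab) + 1 for i, lab in zip(order, est.labels_)}
    return ClusterSolution(labels=labels, k=k, avg_silhouette=float(est.silhouette_mean_),
                           dunn=float(est.dunn_), seed=seed, inertia=est.inertia_)


# -- cluster validity ----------------------------------------------------------


def dunn_index(labels, dist: np.ndarray) -> float:
    """Min inter-cluster pair distance over max intra-cluster pair distance.

    Returns ``inf`` when every cluster is a singleton (no intra-cluster
    pair exists); such sentinel values are excluded from herd means.
    """
    labels = np.asarray(labels)
    dist = np.asarray(dist, dtype=float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    inter = np.inf
    intra = 0.0
    any_intra = False
    for i, ci in enumerate(uniq):
        mi = labels == ci
        if mi.sum() > 1:
            sub = dist[np.ix_(mi, mi)]
            iu = np.triu_indices(int(mi.sum()), k=1)
            intra = max(intra, float(sub[iu].max()))
            any_intra = True
        for cj in uniq[i + 1:]:
            mj = labels == cj
            inter = min(inter, float(dist[np.ix_(mi, mj)].min()))
    if not any_intra or intra == 0.0:
        return float("inf")
    return inter / intra


def silhouette_scores(labels, dist: np.ndarray):
    """Per-point silhouette s(i) = (b − a)/max(a, b) on a distance matrix.

    a(i) is the mean dissimilarity to the other members of i's cluster,
    b(i) the minimum over other clusters of the mean dissimilarity to that
    cluster.  Points in singleton clusters score 0 by convention.  Returns
    ``(scores, mean)``.
    """
    labels = np.asarray(labels)
    dist = np.asarray(dist, dtype=float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = len(labels)
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = int(own.sum())
        if n_own == 1:
            scores[i] = 0.0
            continue
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return scores, float(scores.mean())


def retain_herbs(solutions: dict, threshold: float = 0.45) -> list:
    """Herbs whose mean silhouette is ≥ threshold, input order preserved."""
    if not (-1.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [-1, 1]")
    return [h for h, sol in solutions.items() if sol.avg_silhouette >= threshold]
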