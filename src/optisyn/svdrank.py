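"""SVD-based herb association, GCN-degree ranking, formula assembly and
core/auxiliary deconstruction.

The normalised node-feature matrix is reduced by truncated SVD; herb vectors
(U_k Σ_k) are compared by cosine-normalised inner products to give a
symmetric association matrix.  A herb's *GCN degree* counts its predicted
synergy partners (edge probability above threshold) and its *average drug
association* is the mean association over exactly those partners.  The final
formula keeps herbs passing both cutoffs (degree > 10 and association > 0.5
by default), and the ranked list splits into core (top quarter) and
auxiliary components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "svd_reduce",
    "herb_associations",
    "gcn_degree_and_association",
    "assemble_formula",
    "deconstruct_formula",
]


@dataclass
class AssociationMatrix:
    """Symmetric herb × herb association coefficients with unit diagonal."""

    values: np.ndarray
    herbs: list
    k: int
    provenance: str = "feature-svd"

    def __post_init__(self):
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.herbs):
            raise ValueError("association matrix shape does not match herb list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("association matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.herbs, columns=self.herbs)


def svd_reduce(X: np.ndarray, k: int):
    """Rank-k truncated SVD: returns (herb_vectors, singular_values, Vt_k).

    Herb vectors are U_k Σ_k.  Sign convention: each right singular vector's
    largest-|entry| component is made positive, so the decomposition is
    deterministic across platforms.
    """
    X = np.asarray(X, dtype=float)
    n, f = X.shape
    if not (1 <= k <= min(n, f)):
        raise ValueError(f"k must be in [1, {min(n, f)}] (got {k})")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    return U[:, :k] * S[:k][None, :], S[:k], Vt[:k]


def herb_associations(vectors: np.ndarray, herbs=None, k: int | None = None,
                      provenance: str = "feature-svd",
                      normalize: bool = True) -> AssociationMatrix:
    """Cosine-normalised inner products of reduced herb vectors.

    Zero vectors yield association 0 with a warning; the diagonal is set to
    1.  ``normalize=False`` returns raw inner products (diagonal untouched).
    """
    V = np.asarray(vectors, dtype=float)
    if V.shape[0] < 2:
        raise ValueError("need at least 2 herb vectors")
    herbs = list(herbs) if herbs is not None else [f"h{i}" for i in range(V.shape[0])]
    norms = np.linalg.norm(V, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero herb vectors; their associations are 0", int(zero.sum()))
    raw = V @ V.T
    if normalize:
        denom = np.outer(np.where(zero, 1.0, norms), np.where(zero, 1.0, norms))
        raw = raw / denom
        raw[zero, :] = 0.0
        raw[:, zero] = 0.0
        np.fill_diagonal(raw, 1.0)
    return AssociationMatrix(values=raw, herbs=herbs,
                             k=k if k is not None else V.shape[1], provenance=provenance)


def gcn_degree_and_association(probs: np.ndarray, assoc: AssociationMatrix,
                               prob_threshold: float = 0.5) -> pd.DataFrame:
    """Per-herb partner count and mean partner association.

    ``probs`` is the symmetric pairwise edge-probability matrix (diagonal
    ignored).  Herbs with no partner above the threshold get association 0
    and are flagged in the ``no_partner`` column.
    """
    P = np.asarray(probs, dtype=float)
    n = len(assoc.herbs)
    if P.shape != (n, n):
        raise ValueError("probability and association matrices are indexed differently")
    rows = []
    for i, h in enumerate(assoc.herbs):
        partners = [j for j in range(n) if j != i and P[i, j] > prob_threshold]
        deg = len(partners)
        avg = float(np.mean([assoc.values[i, j] for j in partners])) if deg else 0.0
        rows.append({"herb": h, "gcn_degree": deg, "avg_drug_association": avg,
                     "no_partner": deg == 0})
    out = pd.DataFrame(rows)
    if out["no_partner"].any():
        logger.warning("herbs with no predicted partner: %s",
                       out.loc[out["no_partner"], "herb"].tolist())
    return out


def assemble_formula(scores: pd.DataFrame, degree_min: float = 10,
                     assoc_min: float = 0.5) -> pd.DataFrame:
    """Herbs with gcn_degree > degree_min AND avg_drug_association > assoc_min,
    ranked by (degree desc, association desc, herb id asc)."""
    required = {"herb", "gcn_degree", "avg_drug_association"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    keep = scores[(scores["gcn_degree"].astype(float) > degree_min)
                  & (scores["avg_drug_association"].astype(float) > assoc_min)].copy()
    keep = keep.sort_values(
        by=["gcn_degree", "avg_drug_association", "herb"],
        ascending=[False, False, True], kind="mergesort").reset_index(drop=True)
    return keep


def deconstruct_formula(ranked, core_fraction: float = 0.25):
    """Split a ranked herb list into (core, auxiliary) components.

    Core is the top ⌈fraction·n⌉ herbs; the remainder is auxiliary.
    """
    if isinstance(ranked, pd.DataFrame):
        ranked = list(ranked["herb"])
    ranked = list(ranked)
    if not ranked:
        raise ValueError("empty ranking")
    if not (0 < core_fraction < 1):
        raise ValueError("core_fraction must lie in (0, 1)")
    n_core = math.ceil(core_fraction * len(ranked))
    return ranked[:n_core], ranked[n_core:]
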