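"""Clinical co-usage scoring: pair-level and herb-level Pscore, Mscore, and
factor-analysis loadings over the herb co-occurrence structure.

Pscore quantifies how strongly a herb participates in empirically
co-prescribed pairs: each pair's score is its frequency normalised by the
table's maximum pair frequency, and a herb's score is the mean over its
pairs, weighted by ε — the herb's maximum absolute factor loading from a
factor analysis of the co-occurrence matrix.  Mscore is the plain mean
co-occurrence frequency of a herb across its regularly used (high-frequency)
pairs, so it lives on a count scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import CoPrescriptionTable

logger = logging.getLogger(__name__)

__all__ = ["FactorModel", "factor_loadings", "herb_pscore", "herb_mscore", "pair_pscores"]


@dataclass
class FactorModel:
    """Herb × factor loading matrix with per-herb ε = max |loading|."""

    loadings: pd.DataFrame  # index: herb ids, columns: factor_1..factor_k
    n_factors: int
    method: str = "principal-axis"

    @property
    def epsilon(self) -> dict:
        return {h: float(np.max(np.abs(self.loadings.loc[h]))) for h in self.loadings.index}

    def epsilon_of(self, herb: str, default: float = 1.0) -> float:
        if herb not in self.loadings.index:
            logger.warning("herb %r absent from factor model; using epsilon=%s", herb, default)
            return default
        return float(np.max(np.abs(self.loadings.loc[herb])))

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "n_factors": self.n_factors,
            "herbs": list(self.loadings.index),
            "loadings": self.loadings.to_numpy().tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "FactorModel":
        payload = json.loads(Path(path).read_text())
        loadings = pd.DataFrame(
            payload["loadings"], index=payload["herbs"],
            columns=[f"factor_{i + 1}" for i in range(payload["n_factors"])],
        )
        return cls(loadings=loadings, n_factors=payload["n_factors"], method=payload["method"])


def cooccurrence_matrix(pairs: CoPrescriptionTable) -> pd.DataFrame:
    """Symmetric herb co-occurrence frequency matrix with zero diagonal."""
    herbs = pairs.herbs()
    m = pd.DataFrame(0.0, index=herbs, columns=herbs)
    for _, r in pairs.rows.iterrows():
        m.loc[r["herb_a"], r["herb_b"]] += r["frequency"]
        m.loc[r["herb_b"], r["herb_a"]] += r["frequency"]
    np.fill_diagonal(m.values, 0.0)
    return m


def factor_loadings(pairs: CoPrescriptionTable, n_factors: int, seed: int = 0) -> FactorModel:
    """Principal-axis factor loadings of the herb co-occurrence correlation.

    Loadings are eigenvector · sqrt(eigenvalue) of the correlation matrix of
    herb co-occurrence profiles, truncated to ``n_factors`` and rescaled so
    |loading| ≤ 1.  The procedure is deterministic; ``seed`` is accepted for
    interface uniformity only.  Sign convention: the largest-magnitude entry
    of each factor is made positive, so ε is platform-reproducible.
    """
    m = cooccurrence_matrix(pairs)
    n_herbs = len(m)
    if n_herbs < 2:
        raise ValueError("factor analysis needs at least 2 herbs")
    if not (1 <= n_factors < n_herbs):
        raise ValueError(f"n_factors must be in [1, {n_herbs - 1}]")
    X = m.to_numpy()
    if not X.any():
        raise ValueError("degenerate all-zero co-occurrence matrix")
    sd = X.std(axis=1)
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
    C = (Z @ Z.T) / X.shape[1]
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    np.fill_diagonal(C, 1.0)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:n_factors]
    w_top = np.clip(w[order], 0.0, None)
    L = V[:, order] * np.sqrt(w_top)
    for j in range(L.shape[1]):  # deterministic sign convention
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    peak = np.max(np.abs(L))
    if peak > 1.0:  # numerical guard; loadings of a correlation matrix are ≤ 1
        L = L / peak
    loadings = pd.DataFrame(L, index=m.index, columns=[f"factor_{i+1}" for i in range(n_factors)])
    return FactorModel(loadings=loadings, n_factors=n_factors)


def pair_pscores(pairs: CoPrescriptionTable) -> pd.DataFrame:
    """Pair-level Pscore: frequency normalised by the table maximum."""
    rows = pairs.rows.copy()
    fmax = rows["frequency"].max()
    rows["pscore"] = rows["frequency"] / fmax
    return rows


def herb_pscore(pairs: CoPrescriptionTable, factors: FactorModel, herb: str) -> float:
    """ε_herb · mean pair-level Pscore over pairs containing the herb.

    A herb absent from the pair table scores 0 (with a warning) rather than
    raising, so the cascade can proceed over partially covered herb sets.
    """
    sub = pairs.pairs_containing(herb)
    if len(sub) == 0:
        logger.warning("herb %r absent from co-prescription table; Pscore = 0", herb)
        return 0.0
    fmax = pairs.rows["frequency"].max()
    eps = factors.epsilon_of(herb)
    return float(eps * (sub["frequency"] / fmax).mean())


def herb_mscore(corpus_pairs: CoPrescriptionTable, herb: str, high_freq_cutoff: float = 5) -> float:
    """Mean raw co-occurrence frequency over the herb's pairs with
    frequency ≥ cutoff; 0 when no pair qualifies."""
    if high_freq_cutoff < 1:
        raise ValueError("high_freq_cutoff must be >= 1")
    sub = corpus_pairs.pairs_containing(herb)
    sub = sub[sub["frequency"] >= high_freq_cutoff]
    if len(sub) == 0:
        return 0.0
    return float(sub["frequency"].mean())
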