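"""Graph-convolutional herb-pair synergy classifier.

Herbs are nodes of a graph whose edges are known co-prescriptions; each node
carries a 12-dimensional feature vector assembled from network proximity,
docking, clustering-validity and clinical-usage scores.  A two-layer GCN

    H^(l+1) = act( Â H^(l) G^(l) ),      Â = D^{-1/2} (A + I) D^{-1/2}

produces node embeddings, and a diagonal inner-product decoder scores a
candidate pair:

    score(i, j) = h_iᵀ diag(w) h_j,      p = σ(score),   ŷ = 1[p > 0.5].

Training minimises binary cross-entropy with Adam, dropout on the hidden
activations, global gradient-norm clipping, and early stopping on a held-out
validation slice.  Â is built from *positive training edges only*, so test
edges never leak into message passing.

The model is implemented directly in numpy with hand-derived gradients: the
graphs involved are tens of nodes, so full-batch dense linear algebra is
ample, and the closed-form backward pass keeps the forward pass available to
exact oracle checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureMatrix",
    "build_feature_matrix",
    "normalize_adjacency",
    "gcn_forward",
    "edge_probability",
    "sample_negatives",
    "GCNSynergyClassifier",
    "train_model",
    "evaluate_model",
    "cross_validate",
    "train_test_split_edges",
]

FEATURE_COLUMNS = [
    "d_ab", "s_ab", "max_diameter", "ec", "overlap_rate", "hscore", "mscore",
    "avg_silhouette", "drug_drug_assoc", "drug_disease_assoc",
    "docking_capability", "compound_efficacy",
]


@dataclass
class FeatureMatrix:
    """Standardised N × F node-attribute matrix with its normalisation record."""

    X: np.ndarray
    herbs: list
    columns: list
    means: np.ndarray
    sds: np.ndarray
    variant: str = "full"

    @property
    def index(self) -> dict:
        return {h: i for i, h in enumerate(self.herbs)}


def build_feature_matrix(raw: pd.DataFrame, columns=None, max_missing_fraction: float = 0.5,
                         variant: str = "full") -> FeatureMatrix:
    """Assemble, impute and z-score the node-feature matrix.

    ``raw`` must have a ``herb`` column plus the feature columns.  Missing
    entries are imputed with the column median; a herb missing more than
    half its features is rejected.  Constant columns standardise to all
    zeros with a warning.  Rows are aligned by sorted herb id, so the result
    is invariant to input row order.
    """
    columns = list(columns or FEATURE_COLUMNS)
    missing_cols = set(columns) - set(raw.columns)
    if missing_cols:
        raise ValueError(f"feature table missing columns: {sorted(missing_cols)}")
    raw = raw.sort_values("herb").reset_index(drop=True)
    vals = raw[columns].astype(float)
    frac_missing = vals.isna().mean(axis=1)
    bad = raw.loc[frac_missing > max_missing_fraction, "herb"].tolist()
    if bad:
        raise ValueError(f"herbs missing more than half their features: {bad}")
    vals = vals.fillna(vals.median())
    vals = vals.fillna(0.0)  # columns that are entirely NaN
    X = vals.to_numpy()
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    const = sds == 0
    if const.any():
        logger.warning("constant feature columns standardised to zero: %s",
                       [c for c, f in zip(columns, const) if f])
    Xz = (X - means) / np.where(const, 1.0, sds)
    Xz[:, const] = 0.0
    return FeatureMatrix(X=Xz, herbs=list(raw["herb"]), columns=columns,
                         means=means, sds=sds, variant=variant)


def normalize_adjacency(edges, n: int) -> np.ndarray:
    """Â = D^{-1/2} (A + I) D^{-1/2} from undirected index-pair edges."""
    A = np.eye(n)
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i},{j}) outside node range 0..{n - 1}")
        A[i, j] = 1.0
        A[j, i] = 1.0
    d = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def _act(Z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(Z, 0.0)
    if activation == "linear":
        return Z
    raise ValueError(f"unknown activation {activation!r}")


def gcn_forward(X: np.ndarray, adj: np.ndarray, weights, activation: str = "relu",
                dropout: float = 0.0, rng: np.random.Generator | None = None,
                return_cache: bool = False):
    """Propagate node features through the GCN layers.

    In evaluation mode (``dropout=0`` or ``rng is None``) the pass is fully
    deterministic.  With ``return_cache`` the per-layer pre-activations and
    dropout masks are returned for the backward pass.
    """
    H = X
    cache = {"inputs": [], "pre": [], "masks": []}
    n_layers = len(weights)
    for l, G in enumerate(weights):
        P = adj @ H
        Z = P @ G
        H = _act(Z, activation)
        cache["inputs"].append(P)
        cache["pre"].append(Z)
        if dropout > 0 and rng is not None and l < n_layers - 1:
            mask = (rng.random(H.shape) >= dropout).astype(float)
            H = H * mask / (1.0 - dropout)
            cache["masks"].append(mask)
        else:
            cache["masks"].append(None)
    return (H, cache) if return_cache else H


def edge_probability(h_i: np.ndarray, h_j: np.ndarray, w: np.ndarray):
    """Diagonal inner-product decoder: returns (score, probability, label)."""
    h_i, h_j, w = map(np.asarray, (h_i, h_j, w))
    if not (h_i.shape == h_j.shape == w.shape):
        raise ValueError("embedding / decoder dimension mismatch")
    score = float(np.sum(w * (h_i * h_j)))  # h_i*h_j first: exactly symmetric
    prob = 1.0 / (1.0 + np.exp(-score))
    return score, prob, int(prob > 0.5)


def sample_negatives(herbs, positives, ratio: float = 1.0, seed: int = 0) -> list:
    """Uniform negative pairs from the complement of the positive pair set.

    Returns ``(i, j, label)`` triples for the negatives only.  Sampling is
    without replacement; requesting more negatives than the complement holds
    raises.
    """
    herbs = sorted(herbs)
    pos = {frozenset(p) for p in positives}
    pool = [(a, b) for k, a in enumerate(herbs) for b in herbs[k + 1:]
            if frozenset((a, b)) not in pos]
    n_request = int(round(ratio * len(pos)))
    if n_request > len(pool):
        raise ValueError(f"requested {n_request} negatives but only {len(pool)} "
                         "non-positive pairs exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_request, replace=False)
    return [(pool[k][0], pool[k][1], 0) for k in sorted(chosen)]


class GCNSynergyClassifier(BaseEstimator, ClassifierMixin):
    """Edge-level synergy classifier over a fixed herb node set.

    Samples are edges: ``fit(pairs, y)`` takes an (m, 2) integer array of
    node indices and binary labels.  The node-feature matrix is supplied at
    construction (it is global, computed before any split), which lets the
    estimator slot into sklearn model selection over edge samples.

    Defaults follow the reported final configuration: hidden dimension 32,
    learning rate 1e-4, dropout 0.5, Adam, binary cross-entropy, at most 100
    epochs, gradient clipping at max norm 1.0, early stopping.  The decoder
    weights start at 1 (plain inner product) and are refined by training.
    """

    def __init__(self, node_features=None, hidden_dim: int = 32, n_layers: int = 2,
                 learning_rate: float = 1e-4, dropout: float = 0.5,
                 max_epochs: int = 100, clip_norm: float = 1.0,
                 activation: str = "relu", val_fraction: float = 0.15,
                 patience: int = 10, init_scale: float = 0.01, random_state: int = 0):
        self.node_features = node_features
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.max_epochs = max_epochs
        self.clip_norm = clip_norm
        self.activation = activation
        self.val_fraction = val_fraction
        self.patience = patience
        self.init_scale = init_scale
        self.random_state = random_state

    # -- internals -------------------------------------------------------------

    def _X(self) -> np.ndarray:
        if self.node_features is None:
            raise ValueError("node_features must be provided")
        if isinstance(self.node_features, FeatureMatrix):
            return self.node_features.X
        return np.asarray(self.node_features, dtype=float)

    @staticmethod
    def _bce(probs: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(probs, 1e-12, 1 - 1e-12)
        return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())

    def _edge_scores(self, H: np.ndarray, pairs: np.ndarray) -> np.ndarray:
        return (H[pairs[:, 0]] * H[pairs[:, 1]] * self.w_[None, :]).sum(axis=1)

    def _forward_probs(self, pairs: np.ndarray, H: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self._edge_scores(H, pairs)))

    # -- sklearn API -----------------------------------------------------------

    def fit(self, pairs, y):
        pairs = np.asarray(pairs, dtype=int)
        y = np.asarray(y, dtype=float).ravel()
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("pairs must be an (m, 2) array of node indices")
        if len(set(y.tolist())) < 2:
            raise ValueError("training samples must contain both classes")
        X = self._X()
        n, F = X.shape
        rng = np.random.default_rng(self.random_state)

        # validation slice for early stopping (stratified)
        if self.val_fraction > 0 and len(y) >= 10:
            idx_tr, idx_val = train_test_split(
                np.arange(len(y)), test_size=self.val_fraction, stratify=y,
                random_state=int(rng.integers(2**31)))
        else:
            idx_tr, idx_val = np.arange(len(y)), np.array([], dtype=int)
        tr_pairs, tr_y = pairs[idx_tr], y[idx_tr]
        val_pairs, val_y = pairs[idx_val], y[idx_val]

        # message-passing graph from positive *training* edges only
        pos_edges = [tuple(p) for p, lab in zip(tr_pairs.tolist(), tr_y) if lab == 1]
        adj = normalize_adjacency(pos_edges, n)

        # Small-scale weight init; decoder starts as the identity inner product.
        # The init scale is deliberately far below Glorot: with Adam the total
        # per-parameter displacement over training is roughly lr × epochs, so
        # starting near zero lets the optimiser, not the random draw, set the
        # learned metric.  init_scale="glorot" restores the classical scheme.
        dims = [F] + [self.hidden_dim] * self.n_layers
        weights = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            if self.init_scale == "glorot":
                lim = np.sqrt(6.0 / (fan_in + fan_out))
                weights.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
            elif isinstance(self.init_scale, str) and self.init_scale.startswith("identity"):
                alpha = float(self.init_scale.split(":")[1]) if ":" in self.init_scale else 1.0
                W = np.zeros((fan_in, fan_out))
                k = min(fan_in, fan_out)
                W[np.arange(k), np.arange(k)] = alpha
                W += rng.normal(0, 0.01, size=W.shape)
                weights.append(W)
            else:
                weights.append(rng.normal(0.0, float(self.init_scale),
                                          size=(fan_in, fan_out)))
        w = np.ones(dims[-1])

        adam_m = [np.zeros_like(g) for g in weights] + [np.zeros_like(w)]
        adam_v = [np.zeros_like(g) for g in weights] + [np.zeros_like(w)]
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        self.loss_history_, self.val_loss_history_ = [], []
        best_val, best_params, wait = np.inf, None, 0
        m = len(tr_y)

        for epoch in range(1, self.max_epochs + 1):
            self.w_ = w
            H, cache = gcn_forward(X, adj, weights, self.activation,
                                   dropout=self.dropout, rng=rng, return_cache=True)
            scores = self._edge_scores(H, tr_pairs)
            probs = 1.0 / (1.0 + np.exp(-scores))
            loss = self._bce(probs, tr_y)
            self.loss_history_.append(loss)

            # backward pass
            g_score = (probs - tr_y) / m
            dH = np.zeros_like(H)
            hi, hj = H[tr_pairs[:, 0]], H[tr_pairs[:, 1]]
            np.add.at(dH, tr_pairs[:, 0], g_score[:, None] * w[None, :] * hj)
            np.add.at(dH, tr_pairs[:, 1], g_score[:, None] * w[None, :] * hi)
            dw = (g_score[:, None] * hi * hj).sum(axis=0)

            grads = [None] * len(weights)
            for l in range(len(weights) - 1, -1, -1):
                mask = cache["masks"][l]
                if mask is not None:
                    dH = dH * mask / (1.0 - self.dropout)
                Z = cache["pre"][l]
                dZ = dH * (Z > 0) if self.activation == "relu" else dH
                grads[l] = cache["inputs"][l].T @ dZ
                if l > 0:
                    dH = adj.T @ (dZ @ weights[l].T)

            # global gradient-norm clipping
            all_grads = grads + [dw]
            gnorm = np.sqrt(sum(float((g**2).sum()) for g in all_grads))
            if self.clip_norm and gnorm > self.clip_norm:
                all_grads = [g * (self.clip_norm / gnorm) for g in all_grads]

            # Adam update
            params = weights + [w]
            for k, (p, g) in enumerate(zip(params, all_grads)):
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g**2
                m_hat = adam_m[k] / (1 - beta1**epoch)
                v_hat = adam_v[k] / (1 - beta2**epoch)
                p -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            w = params[-1]

            # validation / early stopping (evaluation-mode forward)
            if len(val_y):
                self.w_ = w
                H_eval = gcn_forward(X, adj, weights, self.activation)
                val_loss = self._bce(self._forward_probs(val_pairs, H_eval), val_y)
                self.val_loss_history_.append(val_loss)
                if val_loss < best_val - 1e-9:
                    best_val, wait = val_loss, 0
                    best_params = ([g.copy() for g in weights], w.copy())
                else:
                    wait += 1
                    if wait >= self.patience:
                        logger.info("early stopping at epoch %d", epoch)
                        break

        if best_params is not None:
            weights, w = best_params
        self.weights_ = weights
        self.w_ = w
        self.adjacency_ = adj
        self.train_positive_edges_ = pos_edges
        self.embeddings_ = gcn_forward(X, adj, weights, self.activation)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = pairs.shape[1]
        return self

    def decision_function(self, pairs):
        pairs = np.asarray(pairs, dtype=int)
        return self._edge_scores(self.embeddings_, pairs)

    def predict_proba(self, pairs):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(pairs)))
        return np.column_stack([1 - p, p])

    def predict(self, pairs):
        return (self.predict_proba(pairs)[:, 1] > 0.5).astype(int)

    def pairwise_probability_matrix(self) -> np.ndarray:
        """Symmetric matrix of edge probabilities over all node pairs."""
        H = self.embeddings_
        S = (H * self.w_[None, :]) @ H.T
        P = 1.0 / (1.0 + np.exp(-S))
        np.fill_diagonal(P, 0.0)
        return P

    # -- checkpointing ---------------------------------------------------------

    def save(self, path, feature_matrix: FeatureMatrix | None = None) -> None:
        fm = feature_matrix if feature_matrix is not None else (
            self.node_features if isinstance(self.node_features, FeatureMatrix) else None)
        payload = {
            "hyperparameters": {k: getattr(self, k) for k in
                                ("hidden_dim", "n_layers", "learning_rate", "dropout",
                                 "max_epochs", "clip_norm", "activation", "val_fraction",
                                 "patience", "random_state")},
            "weights": [g.tolist() for g in self.weights_],
            "decoder_w": self.w_.tolist(),
            "train_positive_edges": [list(e) for e in self.train_positive_edges_],
        }
        if fm is not None:
            payload["feature_columns"] = fm.columns
            payload["herbs"] = fm.herbs
            payload["normalization"] = {"means": fm.means.tolist(), "sds": fm.sds.tolist()}
        Path(path).write_text(json.dumps(payload))


# -- training / evaluation harness ---------------------------------------------


def train_test_split_edges(pairs, y, test_size: float = 0.3, seed: int = 0):
    """Stratified 70:30 split over edge samples."""
    pairs = np.asarray(pairs, dtype=int)
    y = np.asarray(y, dtype=int)
    i_tr, i_te = train_test_split(np.arange(len(y)), test_size=test_size,
                                  stratify=y, random_state=int(seed) % (2**31))
    return pairs[i_tr], y[i_tr], pairs[i_te], y[i_te]


def train_model(feature_matrix: FeatureMatrix, pairs, y, seed: int = 0, **hyper):
    """Fit a classifier on a 70:30 stratified split; returns
    ``(model, test_metrics, (test_pairs, test_y))``."""
    tr_p, tr_y, te_p, te_y = train_test_split_edges(pairs, y, seed=seed)
    model = GCNSynergyClassifier(node_features=feature_matrix, random_state=seed,
                                 **hyper).fit(tr_p, tr_y)
    return model, evaluate_model(model, te_p, te_y), (te_p, te_y)


def evaluate_model(model, pairs, y) -> dict:
    """Classification metrics at the 0.5 threshold plus AUC, RMSE and MAE.

    RMSE/MAE compare predicted probabilities against the binary labels —
    the natural regression reading of a probabilistic binary task.
    """
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("evaluation set must contain both classes")
    probs = model.predict_proba(pairs)[:, 1]
    pred = (probs > 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": (tp + tn) / len(y),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": float(roc_auc_score(y, probs)),
        "rmse": float(np.sqrt(((probs - y) ** 2).mean())),
        "mae": float(np.abs(probs - y).mean()),
        "n": int(len(y)),
    }


def cross_validate(feature_matrix: FeatureMatrix, pairs, y, n_splits: int = 3,
                   seed: int = 0, **hyper) -> dict:
    """Stratified k-fold (default threefold) cross-validation; returns
    per-fold metrics and their means."""
    pairs = np.asarray(pairs, dtype=int)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(seed) % (2**31))
    folds = []
    for k, (i_tr, i_te) in enumerate(skf.split(pairs, y)):
        model = GCNSynergyClassifier(node_features=feature_matrix,
                                     random_state=seed + k, **hyper).fit(pairs[i_tr], y[i_tr])
        folds.append(evaluate_model(model, pairs[i_te], y[i_te]))
    means = {k: float(np.mean([f[k] for f in folds])) for k in folds[0] if k != "n"}
    return {"folds": folds, "mean": means}
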