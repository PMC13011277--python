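"""Ablation variants of the feature set and the baseline-model benchmark.

Variant ``S`` removes the compound-clustering feature (mean silhouette);
variant ``E`` removes the clinical-experience features (Mscore and the
Pscore-derived drug–drug association).  Dropping features lowers predicted
drug connectivity, so the ``E`` variant's degree cutoff is adapted to the
75th percentile of observed degrees downstream.

The benchmark harness evaluates any fit/predict-probability classifier on
symmetric edge feature vectors (elementwise product ‖ absolute difference of
the two node feature vectors) under the same 70:30 split and threefold CV as
the graph model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gcn import (FeatureMatrix, GCNSynergyClassifier, evaluate_model,
                  train_test_split_edges)

__all__ = ["AblationSpec", "make_variant", "edge_features", "default_baselines",
           "run_benchmark"]

_VARIANT_DROPS = {
    "full": [],
    "S": ["avg_silhouette"],
    "E": ["mscore", "drug_drug_assoc"],
}


@dataclass
class AblationSpec:
    """Which feature columns a model variant drops, plus adjusted cutoffs."""

    variant: str = "full"
    degree_min: float | None = None  # None -> pipeline default / percentile rule
    assoc_min: float = 0.5
    dropped: list = field(init=False)

    def __post_init__(self):
        if self.variant not in _VARIANT_DROPS:
            raise ValueError(f"unknown variant {self.variant!r}; expected full/S/E")
        self.dropped = list(_VARIANT_DROPS[self.variant])


def make_variant(spec: AblationSpec, fm: FeatureMatrix) -> FeatureMatrix:
    """Drop the variant's columns and re-standardise the remaining ones."""
    unknown = [c for c in spec.dropped if c not in fm.columns]
    if unknown:
        raise ValueError(f"variant drops unknown columns: {unknown}")
    keep = [c for c in fm.columns if c not in spec.dropped]
    idx = [fm.columns.index(c) for c in keep]
    X = fm.X[:, idx]
    sd = X.std(axis=0)
    Xz = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    Xz[:, sd == 0] = 0.0
    return FeatureMatrix(X=Xz, herbs=list(fm.herbs), columns=keep,
                         means=fm.means[idx], sds=fm.sds[idx], variant=spec.variant)


def edge_features(X: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Symmetric pair featurisation: [x_i ⊙ x_j, |x_i − x_j|]."""
    pairs = np.asarray(pairs, dtype=int)
    xi, xj = X[pairs[:, 0]], X[pairs[:, 1]]
    return np.hstack([xi * xj, np.abs(xi - xj)])


def default_baselines(seed: int = 0) -> dict:
    """The standard tabular classifiers, each exposing predict_proba."""
    from sklearn.dummy import DummyClassifier
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    models = {
        "Dummy": DummyClassifier(strategy="prior"),
        "DT": DecisionTreeClassifier(random_state=seed),
        "RF": RandomForestClassifier(n_estimators=100, random_state=seed),
        "GBDT": GradientBoostingClassifier(random_state=seed),
        "SVM": SVC(probability=True, random_state=seed),
        "KNN": KNeighborsClassifier(),
    }
    try:
        from xgboost import XGBClassifier
        models["XGBoost"] = XGBClassifier(eval_metric="logloss", random_state=seed)
    except ImportError:  # pragma: no cover
        pass
    try:
        from lightgbm import LGBMClassifier
        models["LightGBM"] = LGBMClassifier(random_state=seed, verbosity=-1)
    except ImportError:  # pragma: no cover
        pass
    return models


def run_benchmark(fm: FeatureMatrix, pairs, y, baselines: dict | None = None,
                  seed: int = 0, include_gcn: bool = True,
                  gcn_params: dict | None = None) -> pd.DataFrame:
    """Compare the graph model against tabular baselines on one split.

    Every model sees the identical stratified 70:30 edge split; baselines
    consume edge feature vectors, the graph model consumes the edge indices.
    Returns a table of metrics sorted by AUC (descending).
    """
    pairs = np.asarray(pairs, dtype=int)
    y = np.asarray(y, dtype=int)
    tr_p, tr_y, te_p, te_y = train_test_split_edges(pairs, y, seed=seed)
    rows = []

    if include_gcn:
        model = GCNSynergyClassifier(node_features=fm, random_state=seed,
                                     **(gcn_params or {})).fit(tr_p, tr_y)
        rows.append({"model": "OptiSyn-GCN", **evaluate_model(model, te_p, te_y)})

    Etr, Ete = edge_features(fm.X, tr_p), edge_features(fm.X, te_p)
    for name, clf in (baselines or default_baselines(seed)).items():
        if not hasattr(clf, "predict_proba"):
            raise TypeError(f"baseline {name!r} lacks predict_proba")
        clf.fit(Etr, tr_y)

        class _Wrap:
            def __init__(self, c):
                self.c = c

            def predict_proba(self, E):
                return self.c.predict_proba(E)

        rows.append({"model": name, **evaluate_model(_Wrap(clf), Ete, te_y)})

    out = pd.DataFrame(rows).sort_values("auc", ascending=False).reset_index(drop=True)
    out["seed"] = seed
    return out
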