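"""End-to-end pipeline: score → filter → cluster → train → rank.

Mirrors the full screening cascade: per-herb network/docking/usage scoring,
threshold triage, per-herb compound clustering with silhouette retention,
GCN synergy training on the surviving candidate set, and SVD-based formula
assembly with core/auxiliary deconstruction.  All node features are computed
before any train/test split so no split-dependent information leaks into
them; the GCN's message-passing graph additionally uses positive training
edges only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemsim, compounds, empirical, gcn, netscore, scoretable, svdrank
from ._rng import substream_seed
from .ablation import AblationSpec, make_variant
from .network import (read_coprescription_table, read_docking_table,
                      read_network_tables, read_smiles_file)
from .synthetic import SyntheticSpec, generate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "PipelineStageError", "run_pipeline",
           "compute_score_table", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = {
    "overlap_min": 0.0,        # strict >
    "hscore_min": 0.001,       # strict >
    "mscore_min": 5.0,         # strict >
    "mscore_cutoff": 5.0,      # high-frequency pair cutoff inside Mscore
    "silhouette_min": 0.45,    # inclusive >=
    "degree_min": 10.0,        # strict >
    "assoc_min": 0.5,          # strict >
    "affinity_cutoff": -5.0,   # strict <
    "representative_min_freq": 5,
}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full run specification.

    Either ``synthetic`` or ``inputs`` (role → path mapping with keys
    herb_compound, compound_target, ppi, disease_genes, docking,
    coprescription, smiles) must be given.
    """

    seed: int = 0
    synthetic: SyntheticSpec | None = None
    inputs: dict | None = None
    thresholds: dict = field(default_factory=dict)
    gcn_params: dict = field(default_factory=dict)
    svd_k: int = 3
    n_perm: int = 200
    n_factors: int = 4
    negative_ratio: float = 1.0
    ablation: str = "full"
    cluster_k: int = 3
    cluster_restarts: int = 10
    outdir: str | None = None

    def resolved_thresholds(self) -> dict:
        t = dict(DEFAULT_THRESHOLDS)
        unknown = set(self.thresholds) - set(t)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        t.update(self.thresholds)
        return t

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        missing = []
        if "synthetic" not in d and "inputs" not in d:
            missing.append("synthetic or inputs")
        if "seed" not in d:
            missing.append("seed")
        if missing:
            raise ValueError(f"missing config keys: {missing}")
        if d.get("synthetic") is not None and not isinstance(d["synthetic"], SyntheticSpec):
            d["synthetic"] = SyntheticSpec(**d["synthetic"])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResult:
    config: PipelineConfig
    score_table: pd.DataFrame
    filter_log: dict
    cluster_solutions: dict
    retained_herbs: list
    feature_matrix: object
    model: object
    metrics: dict
    ranking: pd.DataFrame
    core: list
    auxiliary: list

    @property
    def ranked_herbs(self) -> list:
        return list(self.ranking["herb"])


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        bundle = generate(config.synthetic)
        return (bundle.network, bundle.docking, bundle.coprescription, bundle.smiles)
    paths = config.inputs or {}
    required = {"herb_compound", "compound_target", "ppi", "disease_genes",
                "docking", "coprescription", "smiles"}
    missing = sorted(required - set(paths))
    if missing:
        raise ValueError(f"missing input roles: {missing}")
    network = read_network_tables(paths)
    docking = read_docking_table(paths["docking"], network=network)
    cop = read_coprescription_table(paths["coprescription"])
    smiles = read_smiles_file(paths["smiles"])
    return network, docking, cop, smiles


def compute_score_table(network, docking, coprescription, config: PipelineConfig,
                        dist: netscore.PPIDistances | None = None) -> pd.DataFrame:
    """Stage 1: every per-herb indicator except the post-training columns."""
    th = config.resolved_thresholds()
    herbs = sorted(network.herbs)
    if dist is None:
        dist = netscore.PPIDistances(network.ppi_graph())
    table = scoretable.new_score_table(herbs)

    n_factors = min(config.n_factors, max(len(coprescription.herbs()) - 1, 1))
    factors = empirical.factor_loadings(coprescription, n_factors=n_factors,
                                        seed=substream_seed(config.seed, "factors"))
    eff_pairs = compounds.effective_set(docking, th["affinity_cutoff"])
    eff_comp = {c for c, _ in eff_pairs}
    ec_in = compounds.build_ec_input(network, docking, th["affinity_cutoff"])
    aff = docking.rows.set_index(["compound_id", "target_id"])["affinity_kcal_mol"]

    disease = set(network.disease_genes)
    for i, h in enumerate(herbs):
        tgts = network.herb_targets(h)
        comps = network.compounds_of(h)
        row = {"herb": h}
        if tgts:
            row["overlap_rate"] = netscore.overlap_rate(tgts, disease)
            row["d_ab"] = netscore.closest_distance(dist, tgts, disease)
            row["max_diameter"] = netscore.max_module_diameter(dist, tgts)
            if len(tgts) >= 2 and len(disease) >= 2:
                row["s_ab"] = netscore.separation_score(dist, tgts, disease)
            z, _, _ = netscore.proximity_z(
                dist, tgts, disease, n_perm=config.n_perm,
                seed=substream_seed(config.seed, f"zperm:{h}"))
            row["z"] = z
        row["hscore"] = netscore.hscore(network, h) if comps else np.nan
        row["pscore"] = empirical.herb_pscore(coprescription, factors, h)
        row["mscore"] = empirical.herb_mscore(coprescription, h, th["mscore_cutoff"])
        if comps:
            row["ec"] = compounds.ec_score(ec_in, h)
            row["docking_capability"] = len(comps & eff_comp) / len(comps)
            h_eff = [(c, t) for (c, t) in eff_pairs if c in comps]
            row["compound_efficacy"] = (float(np.mean([abs(aff.loc[p]) for p in h_eff]))
                                        if h_eff else 0.0)
        for k, v in row.items():
            table.loc[i, k] = v
    # docking_capability / compound_efficacy feed the feature matrix only
    return table


def feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Map a score table onto the raw 12-column node-feature table."""
    return pd.DataFrame({
        "herb": table["herb"], "d_ab": table["d_ab"], "s_ab": table["s_ab"],
        "max_diameter": table["max_diameter"], "ec": table["ec"],
        "overlap_rate": table["overlap_rate"], "hscore": table["hscore"],
        "mscore": table["mscore"], "avg_silhouette": table["avg_silhouette"],
        "drug_drug_assoc": table["pscore"], "drug_disease_assoc": -table["z"],
        "docking_capability": table.get("docking_capability", np.nan),
        "compound_efficacy": table.get("compound_efficacy", np.nan),
    })


def prepare_edge_dataset(bundle, config: PipelineConfig):
    """Score every herb, cluster its compounds, and build the edge-sample
    dataset over the full herb set.

    Returns ``(feature_matrix, pairs, y, score_table)``.  This is the
    unfiltered training surface used for model evaluation and ablation; the
    filtered screening cascade lives in :func:`run_pipeline`.
    """
    table = compute_score_table(bundle.network, bundle.docking,
                                bundle.coprescription, config)
    for i, h in enumerate(table["herb"]):
        comps = sorted(bundle.network.compounds_of(h))
        fps = [chemsim.fingerprint(bundle.smiles[c], compound_id=c)
               for c in comps if c in bundle.smiles]
        if len(fps) >= config.cluster_k:
            sol = chemsim.cluster_compounds(
                fps, k=config.cluster_k,
                seed=substream_seed(config.seed, f"cluster:{h}"),
                restarts=config.cluster_restarts)
            table.loc[i, "avg_silhouette"] = sol.avg_silhouette
            table.loc[i, "dunn"] = sol.dunn
    fm = gcn.build_feature_matrix(feature_table(table))
    index = fm.index
    pos = [(index[a], index[b]) for a, b in zip(
        bundle.coprescription.rows["herb_a"], bundle.coprescription.rows["herb_b"])
        if a in index and b in index]
    negs = gcn.sample_negatives(range(len(fm.herbs)), pos,
                                ratio=config.negative_ratio,
                                seed=substream_seed(config.seed, "negatives"))
    pairs = np.array([list(p) for p in pos] + [[i, j] for i, j, _ in negs])
    y = np.array([1] * len(pos) + [0] * len(negs))
    return fm, pairs, y, table


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full cascade; any stage error aborts naming the stage."""
    th = config.resolved_thresholds()

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, e) from e

    network, docking, cop, smiles = _stage("load", lambda: _load_inputs(config))
    dist = netscore.PPIDistances(network.ppi_graph())

    table = _stage("score", lambda: compute_score_table(network, docking, cop, config, dist))

    fr = _stage("filter", lambda: netscore.apply_score_filters(table, [
        ("overlap_rate", ">", th["overlap_min"]),
        ("hscore", ">", th["hscore_min"]),
        ("mscore", ">", th["mscore_min"]),
    ]))
    filter_log = {"rules": fr.per_rule_survivors, "retained_after_filters": len(fr.retained)}

    def _cluster():
        sols = {}
        for h in fr.retained:
            comps = sorted(network.compounds_of(h))
            if len(comps) < config.cluster_k:
                continue  # herbs with too few active compounds are skipped
            fps = [chemsim.fingerprint(smiles[c], compound_id=c) for c in comps
                   if c in smiles]
            if len(fps) < config.cluster_k:
                continue
            sols[h] = chemsim.cluster_compounds(
                fps, k=config.cluster_k,
                seed=substream_seed(config.seed, f"cluster:{h}"),
                restarts=config.cluster_restarts)
        return sols

    solutions = _stage("cluster", _cluster)
    retained = chemsim.retain_herbs(solutions, th["silhouette_min"])
    filter_log["clustered"] = len(solutions)
    filter_log["retained_after_silhouette"] = len(retained)
    for h, sol in solutions.items():
        i = table.index[table["herb"] == h][0]
        table.loc[i, "avg_silhouette"] = sol.avg_silhouette
        table.loc[i, "dunn"] = sol.dunn

    if len(retained) < 4:
        raise PipelineStageError("cluster", ValueError(
            f"only {len(retained)} herbs survive the silhouette filter; "
            "cannot train a pair classifier"))

    def _train():
        sub = table[table["herb"].isin(retained)].copy()
        fm = gcn.build_feature_matrix(feature_table(sub))
        if config.ablation != "full":
            fm = make_variant(AblationSpec(variant=config.ablation), fm)
        index = fm.index
        pos_pairs = [(index[a], index[b]) for a, b in zip(
            cop.rows["herb_a"], cop.rows["herb_b"])
            if a in index and b in index]
        if len(pos_pairs) < 4:
            raise ValueError("too few positive pairs among retained herbs")
        n_all = len(fm.herbs) * (len(fm.herbs) - 1) // 2
        avail = n_all - len(pos_pairs)
        ratio = min(config.negative_ratio, avail / len(pos_pairs))
        if ratio < config.negative_ratio:
            logger.warning("negative pool smaller than requested ratio; using %.2f", ratio)
        negs = gcn.sample_negatives(range(len(fm.herbs)), pos_pairs, ratio=ratio,
                                    seed=substream_seed(config.seed, "negatives"))
        pairs = np.array([list(p) for p in pos_pairs] + [[i, j] for i, j, _ in negs])
        y = np.array([1] * len(pos_pairs) + [0] * len(negs))
        model, holdout, _ = gcn.train_model(
            fm, pairs, y, seed=substream_seed(config.seed, "train"), **config.gcn_params)
        cv = gcn.cross_validate(fm, pairs, y, n_splits=3,
                                seed=substream_seed(config.seed, "cv"), **config.gcn_params)
        return fm, model, {"holdout": holdout, "cv_mean": cv["mean"], "cv_folds": cv["folds"]}

    fm, model, metrics = _stage("train", _train)

    def _rank():
        # associations use min-max normalised features (positive orthant), so
        # cosines land in [0, 1] and the > 0.5 cutoff separates above- from
        # below-median partner similarity; the z-scored matrix stays with the GCN
        raw = fm.X * fm.sds[None, :] + 0.0  # standardised back to per-column scale
        span = raw.max(axis=0) - raw.min(axis=0)
        Xmm = (raw - raw.min(axis=0)) / np.where(span == 0, 1.0, span)
        vectors, svals, _ = svdrank.svd_reduce(Xmm, min(config.svd_k, min(Xmm.shape)))
        assoc = svdrank.herb_associations(vectors, herbs=fm.herbs, k=config.svd_k)
        probs = model.pairwise_probability_matrix()
        da = svdrank.gcn_degree_and_association(probs, assoc)
        degree_min = th["degree_min"]
        if config.ablation == "E":
            # reduced connectivity under the E variant: adapt the cutoff
            degree_min = float(np.percentile(da["gcn_degree"], 75))
        for _, r in da.iterrows():
            i = table.index[table["herb"] == r["herb"]][0]
            table.loc[i, "gcn_degree"] = r["gcn_degree"]
            table.loc[i, "avg_drug_association"] = r["avg_drug_association"]
        merged = da.merge(table[["herb"]], on="herb")
        ranking = svdrank.assemble_formula(merged, degree_min=degree_min,
                                           assoc_min=th["assoc_min"])
        core, aux = (svdrank.deconstruct_formula(ranking) if len(ranking)
                     else ([], []))
        return ranking, core, aux

    ranking, core, aux = _stage("rank", _rank)

    result = PipelineResult(config=config, score_table=table, filter_log=filter_log,
                            cluster_solutions=solutions, retained_herbs=retained,
                            feature_matrix=fm, model=model, metrics=metrics,
                            ranking=ranking, core=core, auxiliary=aux)
    if config.outdir:
        _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult) -> None:
    out = Path(result.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    scoretable.write_score_table(result.score_table, out / "score_table.csv")
    result.ranking.assign(
        role=["CORE" if h in result.core else "AUXILIARY" for h in result.ranking["herb"]]
    ).to_csv(out / "ranking.csv", index=False)
    (out / "metrics.json").write_text(json.dumps(result.metrics, indent=1))
    result.model.save(out / "model.json", feature_matrix=result.feature_matrix)
    cfg = asdict(result.config)
    (out / "config.json").write_text(json.dumps(cfg, indent=1, default=str))
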