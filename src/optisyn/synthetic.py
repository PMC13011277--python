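"""Synthetic input generator with a known ground-truth synergy rule.

Emulates the complete input bundle the pipeline consumes — a scale-free PPI
with a planted (densified) disease module, herbs as compound sets over a
shared compound pool, compound→target memberships biased toward the disease
module, docking affinities with a controllable effective fraction, compound
SMILES, and a co-prescription pair table generated from latent herb factors
— so every stage is testable without any external database, and recovery of
the planted synergy signal can be measured against the generator's truth.

Each herb carries three latent traits:

* ``disease_affinity`` a_h ∈ [0,1] — biases the herb toward compounds whose
  targets fall in the disease module (drives overlap/Hscore/proximity);
* ``chem_coherence`` c_h ∈ [0,1] — high-coherence herbs draw compounds from
  three tight structural families (high clustering silhouette), low-coherence
  herbs draw structurally diverse singletons (low silhouette);
* a latent factor vector u_h — pairwise affinity in prescriptions.

The true synergy score of a pair is

    s(i,j) = w_latent·(u_i·u_j) + w_disease·(a_i + a_j) + w_chem·(c_i + c_j) + ε,

and pairs above the ``positive_quantile`` of s become co-prescriptions with
frequency proportional to the score.  Both network-derived and
clustering/clinical features therefore carry real signal, which is what the
ablation ordering tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import substream
from .network import (CoPrescriptionTable, DockingTable, HeteroNetwork,
                      write_network_tables, write_smiles_file)

__all__ = ["SyntheticSpec", "SyntheticBundle", "generate_network", "generate_labels",
           "generate", "SMILES_FAMILIES", "SMILES_DIVERSE"]

# three tight structural families (within-family path fingerprints are
# similar, across-family dissimilar) plus a diverse pool of unrelated
# structures; placeholders for fingerprint plumbing, not real herb chemistry.
SMILES_FAMILIES = [
    ["CCCCCCO", "CCCCCCCO", "CC(C)CCCCO", "CCCCCCCCO", "CC(C)CCCCCO", "CCC(C)CCCO"],
    ["OCCOCCO", "OCCOCCOCCO", "OCCOCCOCCOCCO", "OCCOCCOCCOCCOCCO",
     "COCCOCCO", "COCCOCCOCCO"],
    ["C1CCC2(CCCCC2)CC1", "CC1CCC2(CCCCC2)CC1", "OC1CCC2(CCCCC2)CC1",
     "CC1(C)CCC2(CCCCC2)CC1", "OCC1CCC2(CCCCC2)CC1", "CC1CCC2(CCCC2)CC1"],
]
SMILES_DIVERSE = [
    "CC(=O)Oc1ccccc1C(=O)O", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C", "NC(=O)N",
    "CC(C)=O", "ClCCl", "CSC", "CC(C)CC(N)C(=O)O", "OCC(O)C(O)C(O)C(O)CO",
    "OC(=O)CCC(=O)O", "N#Cc1ccccc1", "C=CC=C", "c1ccncc1", "c1ccoc1",
    "OCC(O)CO", "CC(=O)O", "C[N+](=O)[O-]",
]


@dataclass
class SyntheticSpec:
    """Parameters of the generator; the defaults are the study conditions."""

    n_herbs: int = 60
    compounds_per_herb: tuple = (4, 10)
    n_compound_pool: int = 120
    tight_pool_fraction: float = 0.6
    n_targets: int = 300
    ppi_attachment: int = 3
    disease_module_size: int = 8
    disease_module_density: float = 0.8
    targets_per_compound: tuple = (2, 6)
    docking_effective_fraction: float = 0.95
    latent_dim: int = 4
    n_archetypes: int = 4
    archetype_scale: float = 1.0
    latent_jitter: float = 0.35
    w_latent: float = 0.3
    w_disease: float = 1.25
    w_chem: float = 1.25
    synergy_noise_sd: float = 0.25
    positive_quantile: float = 0.8
    max_pair_frequency: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.disease_module_size > self.n_targets:
            raise ValueError("disease module larger than the target layer")
        for name in ("tight_pool_fraction", "disease_module_density",
                     "docking_effective_fraction", "positive_quantile"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_herbs < 2 or self.n_compound_pool < 1:
            raise ValueError("counts must be >= 1 (and >= 2 herbs)")


@dataclass
class SyntheticBundle:
    """Everything one generation run produces, including the ground truth."""

    spec: SyntheticSpec
    network: HeteroNetwork
    docking: DockingTable
    smiles: dict
    coprescription: CoPrescriptionTable = None
    pair_truth: pd.DataFrame = None  # herb_a, herb_b, true_score, label
    herb_truth: pd.DataFrame = None  # herb, disease_affinity, chem_coherence, u_*
    compound_meta: pd.DataFrame = None

    def positive_pairs(self) -> list:
        t = self.pair_truth
        return [(a, b) for a, b, lab in zip(t["herb_a"], t["herb_b"], t["label"]) if lab == 1]

    def write(self, outdir) -> dict:
        """Write the bundle in exactly the formats the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = write_network_tables(self.network, outdir)
        p = outdir / "docking.csv"
        self.docking.rows.to_csv(p, index=False)
        paths["docking"] = str(p)
        p = outdir / "coprescription.csv"
        rows = self.coprescription.rows.copy()
        rows["source"] = self.coprescription.source
        rows.to_csv(p, index=False)
        paths["coprescription"] = str(p)
        p = outdir / "compounds.smi"
        write_smiles_file(self.smiles, p)
        paths["smiles"] = str(p)
        return paths


def _herb_ids(n):
    return [f"H{i + 1:03d}" for i in range(n)]


def generate_network(spec: SyntheticSpec):
    """Build the network, docking table, SMILES map and herb/compound truth.

    Returns a :class:`SyntheticBundle` whose label fields are not yet
    filled; :func:`generate_labels` completes it.
    """
    rng = substream(spec.seed, "network")

    # --- PPI: preferential attachment + planted densified disease module
    g_int = nx.barabasi_albert_graph(spec.n_targets, spec.ppi_attachment,
                                     seed=int(rng.integers(2**31)))
    targets = [f"T{i + 1:04d}" for i in range(spec.n_targets)]
    module_idx = rng.choice(spec.n_targets, size=spec.disease_module_size, replace=False)
    for p in range(len(module_idx)):
        for q in range(p + 1, len(module_idx)):
            if rng.random() < spec.disease_module_density:
                g_int.add_edge(int(module_idx[p]), int(module_idx[q]))
    ppi_edges = frozenset(frozenset((targets[a], targets[b])) for a, b in g_int.edges())
    disease_genes = frozenset(targets[i] for i in module_idx)

    # --- shared compound pool: structural family, popularity, disease propensity
    n_tight = int(round(spec.tight_pool_fraction * spec.n_compound_pool))
    compounds = [f"C{i + 1:04d}" for i in range(spec.n_compound_pool)]
    family = np.full(spec.n_compound_pool, -1)
    smiles = {}
    for i in range(spec.n_compound_pool):
        if i < n_tight:
            fam = i % 3
            family[i] = fam
            pool = SMILES_FAMILIES[fam]
            smiles[compounds[i]] = pool[(i // 3) % len(pool)]
        else:
            smiles[compounds[i]] = SMILES_DIVERSE[(i - n_tight) % len(SMILES_DIVERSE)]
    popularity = 1.0 / (1.0 + np.arange(spec.n_compound_pool)) ** 0.8
    popularity = popularity[rng.permutation(spec.n_compound_pool)]
    disease_prop = rng.random(spec.n_compound_pool)

    # --- compound -> target edges, biased toward the module by propensity
    lo_t, hi_t = spec.targets_per_compound
    ct_edges = set()
    module_list = [targets[i] for i in module_idx]
    for i, c in enumerate(compounds):
        n_t = int(rng.integers(lo_t, hi_t + 1))
        p_dis = 0.05 + 0.5 * disease_prop[i]
        tset = set()
        while len(tset) < n_t:
            if rng.random() < p_dis:
                tset.add(module_list[int(rng.integers(len(module_list)))])
            else:
                tset.add(targets[int(rng.integers(spec.n_targets))])
        ct_edges.update((c, t) for t in tset)

    # --- herbs: latent traits and compound membership
    herbs = _herb_ids(spec.n_herbs)
    affinity = rng.random(spec.n_herbs)
    coherence = rng.random(spec.n_herbs)
    # latent factors: archetype directions plus jitter, so co-prescription
    # communities (the real-data structure prescriptions exhibit) are planted
    # and recoverable from the pair graph
    n_arch = min(spec.n_archetypes, spec.latent_dim)
    arch = np.zeros((n_arch, spec.latent_dim))
    arch[np.arange(n_arch), np.arange(n_arch)] = spec.archetype_scale
    membership = rng.integers(n_arch, size=spec.n_herbs)
    U = (arch[membership]
         + spec.latent_jitter * rng.normal(size=(spec.n_herbs, spec.latent_dim))
         / np.sqrt(spec.latent_dim))

    tight_idx = np.flatnonzero(family >= 0)
    diverse_idx = np.flatnonzero(family < 0)
    lo_c, hi_c = spec.compounds_per_herb
    hc_edges = set()
    for h_i, h in enumerate(herbs):
        n_c = int(rng.integers(lo_c, hi_c + 1))
        # saturating map: clearly coherent herbs are purely family-structured,
        # clearly incoherent ones purely diverse, with a graded band between
        n_tight_h = int(round(n_c * min(1.0, 1.8 * coherence[h_i])))
        chosen: set = set()
        slot = 0
        while len(chosen) < min(n_c, spec.n_compound_pool):
            if slot < n_tight_h and len(tight_idx):
                fam = slot % 3  # cycle families so coherent herbs cover all three
                pool = tight_idx[family[tight_idx] == fam]
            else:
                pool = diverse_idx if len(diverse_idx) else tight_idx
            pool = np.array([k for k in pool if k not in chosen])
            if len(pool) == 0:  # requested pool exhausted: fall back to the rest
                pool = np.array([k for k in range(spec.n_compound_pool)
                                 if k not in chosen])
            w = popularity[pool] * np.exp(2.0 * affinity[h_i] * disease_prop[pool])
            chosen.add(int(rng.choice(pool, p=w / w.sum())))
            slot += 1
        hc_edges.update((h, compounds[k]) for k in chosen)

    used = {c for _, c in hc_edges}
    ct_edges = {(c, t) for c, t in ct_edges if c in used}
    smiles = {c: s for c, s in smiles.items() if c in used}

    network = HeteroNetwork(
        herbs=frozenset(herbs),
        compounds=frozenset(used),
        targets=frozenset(targets),
        disease_genes=disease_genes,
        herb_compound_edges=frozenset(hc_edges),
        compound_target_edges=frozenset(ct_edges),
        ppi_edges=ppi_edges,
    )

    # --- docking affinities: N(-4, 1.5), a controlled fraction shifted by -2
    drng = substream(spec.seed, "docking")
    rows = []
    for c in sorted(used):
        for t in sorted(disease_genes):
            aff = drng.normal(-4.0, 1.5)
            if drng.random() < spec.docking_effective_fraction:
                aff -= 2.0
            rows.append((c, t, round(float(aff), 3)))
    docking = DockingTable.from_rows(
        pd.DataFrame(rows, columns=["compound_id", "target_id", "affinity_kcal_mol"]),
        network=network, frequency_mode="cross_herb")

    herb_truth = pd.DataFrame({
        "herb": herbs, "disease_affinity": affinity, "chem_coherence": coherence,
        "archetype": membership,
        **{f"u_{k}": U[:, k] for k in range(spec.latent_dim)},
    })
    compound_meta = pd.DataFrame({
        "compound": compounds, "family": family,
        "popularity": popularity, "disease_propensity": disease_prop,
    })
    return SyntheticBundle(spec=spec, network=network, docking=docking, smiles=smiles,
                           herb_truth=herb_truth, compound_meta=compound_meta)


def generate_labels(spec: SyntheticSpec, bundle: SyntheticBundle) -> SyntheticBundle:
    """Fill in the ground-truth synergy scores, labels and co-prescriptions."""
    if bundle.spec != spec:
        raise ValueError("bundle was generated from a different spec")
    rng = substream(spec.seed, "labels")
    t = bundle.herb_truth
    herbs = list(t["herb"])
    U = t[[f"u_{k}" for k in range(spec.latent_dim)]].to_numpy()
    a = t["disease_affinity"].to_numpy()
    c = t["chem_coherence"].to_numpy()

    rows = []
    for i in range(len(herbs)):
        for j in range(i + 1, len(herbs)):
            s = (spec.w_latent * (U[i] @ U[j])
                 + spec.w_disease * (a[i] + a[j])
                 + spec.w_chem * (c[i] + c[j])
                 + (rng.normal(0.0, spec.synergy_noise_sd) if spec.synergy_noise_sd else 0.0))
            rows.append((herbs[i], herbs[j], float(s)))
    truth = pd.DataFrame(rows, columns=["herb_a", "herb_b", "true_score"])
    thresh = truth["true_score"].quantile(spec.positive_quantile)
    truth["label"] = (truth["true_score"] > thresh).astype(int)

    pos = truth[truth["label"] == 1].copy()
    smin, smax = pos["true_score"].min(), pos["true_score"].max()
    span = (smax - smin) or 1.0
    pos["frequency"] = (1 + np.round((spec.max_pair_frequency - 1)
                                     * (pos["true_score"] - smin) / span)).astype(int)
    cop = CoPrescriptionTable(
        rows=pos[["herb_a", "herb_b", "frequency"]].reset_index(drop=True),
        source="synthetic-prescriptions")
    bundle.pair_truth = truth
    bundle.coprescription = cop
    return bundle


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Full generation: network + docking + SMILES + labels."""
    return generate_labels(spec, generate_network(spec))
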