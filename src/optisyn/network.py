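"""Typed multilayer network container and validated tabular readers/writers.

The heterogeneous network has four node layers — herbs, compounds, targets
and a disease (hub) gene set — connected by layer-constrained edge sets:
herb→compound membership, compound→target interactions, and an undirected
target–target PPI.  All ids are opaque strings; no nomenclature
normalisation is attempted.

File formats are plain delimited tables with a mandatory header row.  TSV is
the default; CSV is inferred from a ``.csv`` extension or forced with
``delimiter=","``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HeteroNetwork",
    "DockingTable",
    "CoPrescriptionTable",
    "read_network_tables",
    "read_docking_table",
    "read_coprescription_table",
    "read_smiles_file",
    "write_smiles_file",
]


class NetworkValidationError(ValueError):
    """Raised when an edge references an undeclared node or a table is malformed."""


@dataclass(frozen=True)
class HeteroNetwork:
    """Immutable multilayer disease–herb–compound–target network.

    Invariants (enforced in ``__post_init__``): every edge endpoint exists in
    its declared node layer, the PPI is undirected with no self-loops,
    ``disease_genes`` is a subset of ``targets`` and edge sets hold no
    duplicates (guaranteed by the ``set``/``frozenset`` representation).
    """

    herbs: frozenset
    compounds: frozenset
    targets: frozenset
    disease_genes: frozenset
    herb_compound_edges: frozenset  # of (herb, compound) tuples
    compound_target_edges: frozenset  # of (compound, target) tuples
    ppi_edges: frozenset  # of frozenset({target, target})

    def __post_init__(self):
        for h, c in self.herb_compound_edges:
            if h not in self.herbs:
                raise NetworkValidationError(f"herb_compound edge references unknown herb {h!r}")
            if c not in self.compounds:
                raise NetworkValidationError(f"herb_compound edge references unknown compound {c!r}")
        for c, t in self.compound_target_edges:
            if c not in self.compounds:
                raise NetworkValidationError(f"compound_target edge references unknown compound {c!r}")
            if t not in self.targets:
                raise NetworkValidationError(f"compound_target edge references unknown target {t!r}")
        for e in self.ppi_edges:
            if len(e) != 2:
                raise NetworkValidationError(f"PPI self-loop or malformed edge: {set(e)!r}")
            for t in e:
                if t not in self.targets:
                    raise NetworkValidationError(f"PPI edge references unknown target {t!r}")
        missing = self.disease_genes - self.targets
        if missing:
            raise NetworkValidationError(
                f"disease genes not present in the target layer: {sorted(missing)!r}"
            )

    # -- convenience accessors -------------------------------------------------

    def compounds_of(self, herb: str) -> frozenset:
        return frozenset(c for h, c in self.herb_compound_edges if h == herb)

    def targets_of_compound(self, compound: str) -> frozenset:
        return frozenset(t for c, t in self.compound_target_edges if c == compound)

    def herb_targets(self, herb: str) -> frozenset:
        """Union of targets over the herb's compounds."""
        comps = self.compounds_of(herb)
        return frozenset(t for c, t in self.compound_target_edges if c in comps)

    def ppi_graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.targets)
        g.add_edges_from(tuple(e) for e in self.ppi_edges)
        return g


@dataclass
class DockingTable:
    """Ligand–receptor binding affinities plus compound occurrence counts.

    Affinities are signed kcal/mol — more negative means stronger binding.
    ``frequencies`` is the per-compound occurrence count used by the
    representative-compound filter; by default it counts the number of herbs
    containing the compound (cross-herb occurrence).
    """

    rows: pd.DataFrame  # columns: compound_id, target_id, affinity_kcal_mol
    frequencies: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"compound_id", "target_id", "affinity_kcal_mol"}
        missing = required - set(self.rows.columns)
        if missing:
            raise NetworkValidationError(f"docking table missing columns: {sorted(missing)}")
        aff = self.rows["affinity_kcal_mol"].to_numpy(dtype=float)
        import numpy as np

        if not np.all(np.isfinite(aff)):
            raise NetworkValidationError("docking affinities must be finite")
        for c, f in self.frequencies.items():
            if f < 1:
                raise NetworkValidationError(f"compound {c!r} has frequency {f} < 1")

    @classmethod
    def from_rows(cls, rows: pd.DataFrame, network: HeteroNetwork | None = None,
                  frequency_mode: str = "cross_herb") -> "DockingTable":
        """Build a table, deriving frequencies either from herb membership
        (``cross_herb``, default) or from raw docking row counts (``rows``)."""
        rows = rows.drop_duplicates(ignore_index=True)
        if frequency_mode == "cross_herb":
            if network is None:
                raise ValueError("cross_herb frequency mode requires a network")
            freq: dict = {}
            for _, c in network.herb_compound_edges:
                freq[c] = freq.get(c, 0) + 1
            freq = {c: f for c, f in freq.items() if c in set(rows["compound_id"])}
        elif frequency_mode == "rows":
            freq = rows["compound_id"].value_counts().to_dict()
        else:
            raise ValueError(f"unknown frequency_mode {frequency_mode!r}")
        return cls(rows=rows, frequencies=freq)


@dataclass
class CoPrescriptionTable:
    """Unordered, deduplicated herb-pair co-occurrence counts.

    ``source`` labels the provenance (e.g. patent-medicine database vs
    literature corpus); the scoring functions accept either.
    """

    rows: pd.DataFrame  # columns: herb_a, herb_b, frequency
    source: str = "unknown"

    def __post_init__(self):
        required = {"herb_a", "herb_b", "frequency"}
        missing = required - set(self.rows.columns)
        if missing:
            raise NetworkValidationError(f"co-prescription table missing columns: {sorted(missing)}")
        self.rows = _dedupe_pairs(self.rows)
        if (self.rows["frequency"] < 1).any():
            raise NetworkValidationError("co-prescription frequencies must be >= 1")

    def pairs_containing(self, herb: str) -> pd.DataFrame:
        r = self.rows
        return r[(r["herb_a"] == herb) | (r["herb_b"] == herb)]

    def herbs(self) -> list:
        return sorted(set(self.rows["herb_a"]) | set(self.rows["herb_b"]))


def _dedupe_pairs(rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse (a,b)/(b,a) and exact duplicates; duplicate pair frequencies
    are summed.  Self-pairs are dropped with a warning."""
    rows = rows.copy()
    selfp = rows["herb_a"] == rows["herb_b"]
    if selfp.any():
        logger.warning("dropping %d self-pair rows from co-prescription table", int(selfp.sum()))
        rows = rows[~selfp]
    key = rows.apply(lambda r: tuple(sorted((str(r["herb_a"]), str(r["herb_b"])))), axis=1)
    rows = rows.assign(_a=[k[0] for k in key], _b=[k[1] for k in key])
    n_before = len(rows)
    agg = rows.groupby(["_a", "_b"], as_index=False)["frequency"].sum()
    if len(agg) < n_before:
        logger.warning("collapsed %d duplicate co-prescription rows", n_before - len(agg))
    return agg.rename(columns={"_a": "herb_a", "_b": "herb_b"})[
        ["herb_a", "herb_b", "frequency"]
    ].reset_index(drop=True)


# -- delimited-table IO --------------------------------------------------------


def _infer_delim(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _read_table(path, columns: Iterable[str], delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep=_infer_delim(path, delimiter), dtype=str)
    missing = set(columns) - set(df.columns)
    if missing:
        raise NetworkValidationError(f"{path.name}: missing columns {sorted(missing)}")
    if df[list(columns)].isna().any().any():
        raise NetworkValidationError(f"{path.name}: malformed row (missing field)")
    n = len(df)
    df = df.drop_duplicates(subset=list(columns), ignore_index=True)
    if len(df) < n:
        logger.warning("%s: collapsed %d duplicate rows", path.name, n - len(df))
    return df


def read_network_tables(paths: Mapping[str, str], delimiter: str | None = None) -> HeteroNetwork:
    """Read and cross-validate the herb_compound / compound_target /
    ppi / disease_genes tables into a :class:`HeteroNetwork`.

    Node layers are declared implicitly: herbs by the herb_compound table,
    compounds by the compound_target table, targets by the union of
    compound_target and PPI endpoints.  An edge referencing an undeclared
    node raises :class:`NetworkValidationError` naming the offender.
    """
    required = {"herb_compound", "compound_target", "ppi", "disease_genes"}
    missing = required - set(paths)
    if missing:
        raise ValueError(f"missing input table roles: {sorted(missing)}")

    hc = _read_table(paths["herb_compound"], ["herb", "compound"], delimiter)
    ct = _read_table(paths["compound_target"], ["compound", "target"], delimiter)
    ppi = _read_table(paths["ppi"], ["target_a", "target_b"], delimiter)
    dg = _read_table(paths["disease_genes"], ["target"], delimiter)

    compounds = frozenset(ct["compound"])
    unknown = sorted(set(hc["compound"]) - compounds)
    if unknown:
        raise NetworkValidationError(
            f"herb_compound references compounds absent from compound_target: {unknown}"
        )
    targets = frozenset(ct["target"]) | frozenset(ppi["target_a"]) | frozenset(ppi["target_b"])

    # undirected PPI: self-loops dropped on read, reversed duplicates collapsed
    edges = set()
    n_loops = 0
    for a, b in zip(ppi["target_a"], ppi["target_b"]):
        if a == b:
            n_loops += 1
            continue
        edges.add(frozenset((a, b)))
    if n_loops:
        logger.warning("dropped %d PPI self-loops", n_loops)

    return HeteroNetwork(
        herbs=frozenset(hc["herb"]),
        compounds=compounds,
        targets=targets,
        disease_genes=frozenset(dg["target"]),
        herb_compound_edges=frozenset(zip(hc["herb"], hc["compound"])),
        compound_target_edges=frozenset(zip(ct["compound"], ct["target"])),
        ppi_edges=frozenset(edges),
    )


def write_network_tables(network: HeteroNetwork, outdir, delimiter: str = "\t") -> dict:
    """Write the four layer tables; returns the role → path mapping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".csv" if delimiter == "," else ".tsv"
    paths = {}

    def _w(name, df):
        p = outdir / f"{name}{ext}"
        df.to_csv(p, sep=delimiter, index=False)
        paths[name] = str(p)

    _w("herb_compound", pd.DataFrame(sorted(network.herb_compound_edges),
                                     columns=["herb", "compound"]))
    _w("compound_target", pd.DataFrame(sorted(network.compound_target_edges),
                                       columns=["compound", "target"]))
    _w("ppi", pd.DataFrame(sorted(tuple(sorted(e)) for e in network.ppi_edges),
                           columns=["target_a", "target_b"]))
    _w("disease_genes", pd.DataFrame(sorted(network.disease_genes), columns=["target"]))
    return paths


def read_docking_table(path, network: HeteroNetwork | None = None,
                       frequency_mode: str = "cross_herb",
                       delimiter: str | None = None) -> DockingTable:
    df = _read_table(path, ["compound_id", "target_id", "affinity_kcal_mol"], delimiter)
    df["affinity_kcal_mol"] = df["affinity_kcal_mol"].astype(float)
    if network is None and frequency_mode == "cross_herb":
        frequency_mode = "rows"
    return DockingTable.from_rows(df, network=network, frequency_mode=frequency_mode)


def read_coprescription_table(path, source: str | None = None,
                              delimiter: str | None = None) -> CoPrescriptionTable:
    df = _read_table(path, ["herb_a", "herb_b", "frequency"], delimiter)
    df["frequency"] = df["frequency"].astype(float)
    if source is None:
        source = df["source"].iloc[0] if "source" in df.columns and len(df) else "unknown"
    return CoPrescriptionTable(rows=df[["herb_a", "herb_b", "frequency"]], source=source)


def read_smiles_file(path) -> dict:
    """One ``SMILES<tab>compound_id`` per line → {compound_id: smiles}."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NetworkValidationError(f"{path}: malformed SMILES line {lineno}: {line!r}")
        smiles, cid = parts
        out[cid] = smiles
    return out


def write_smiles_file(smiles: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(smiles):
            fh.write(f"{smiles[cid]}\t{cid}\n")
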