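"""Representative-compound selection from docking results and the
compound-effectiveness score Ec.

A compound is *representative* when it occurs in at least ``min_freq`` herbs
(default 5), and *effective* when at least one of its docking poses binds
below the affinity cutoff (default −5 kcal/mol, strict).  The herb-level
effectiveness score is

    Ec(j) = (1 / N_eff) · (n_jRc / n_j)

where n_j is the herb's compound count, n_jRc its effective-compound count
and N_eff the total effective-compound count summed over herbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import DockingTable, HeteroNetwork

__all__ = ["EcInput", "representative_compounds", "effective_set", "effective_compounds",
           "ec_score", "build_ec_input"]


@dataclass
class EcInput:
    """Counts feeding the Ec formula."""

    n_total_effective: int
    n_compounds: dict = field(default_factory=dict)  # herb -> n_j
    n_effective: dict = field(default_factory=dict)  # herb -> n_jRc
    n_core_herbs: int | None = None  # reported as metadata only; not in the formula

    def __post_init__(self):
        for h, nj in self.n_compounds.items():
            njr = self.n_effective.get(h, 0)
            if not (0 <= njr <= nj):
                raise ValueError(f"herb {h!r}: effective count {njr} outside [0, {nj}]")


def representative_compounds(table: DockingTable, min_freq: int = 5) -> set:
    """Compounds whose occurrence frequency is ≥ min_freq."""
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    return {c for c, f in table.frequencies.items() if f >= min_freq}


def effective_set(table: DockingTable, affinity_cutoff: float = -5.0) -> set:
    """(compound, target) pairs binding strictly below the cutoff."""
    r = table.rows
    hits = r[r["affinity_kcal_mol"] < float(affinity_cutoff)]
    return set(zip(hits["compound_id"], hits["target_id"]))


def effective_compounds(table: DockingTable, affinity_cutoff: float = -5.0) -> set:
    """Compounds with at least one effective docking pair."""
    return {c for c, _ in effective_set(table, affinity_cutoff)}


def build_ec_input(network: HeteroNetwork, table: DockingTable,
                   affinity_cutoff: float = -5.0) -> EcInput:
    """Assemble per-herb compound/effective counts from one docking table.

    N_eff is the sum over herbs of per-herb effective counts, so a compound
    shared by several herbs contributes once per herb.
    """
    eff = effective_compounds(table, affinity_cutoff)
    n_compounds, n_effective = {}, {}
    for h in sorted(network.herbs):
        comps = network.compounds_of(h)
        n_compounds[h] = len(comps)
        n_effective[h] = len(comps & eff)
    total = sum(n_effective.values())
    return EcInput(n_total_effective=total, n_compounds=n_compounds,
                   n_effective=n_effective, n_core_herbs=len(network.herbs))


def ec_score(inp: EcInput, herb: str) -> float:
    """Ec(j) = (1/N_eff) · (n_jRc / n_j)."""
    if herb not in inp.n_compounds:
        raise KeyError(f"unknown herb {herb!r}")
    n_j = inp.n_compounds[herb]
    if n_j < 1:
        raise ValueError(f"herb {herb!r} has zero compounds")
    if inp.n_total_effective < 1:
        raise ValueError("no effective compounds in the input")
    return (1.0 / inp.n_total_effective) * (inp.n_effective.get(herb, 0) / n_j)
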