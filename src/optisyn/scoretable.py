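"""Per-herb score table with a fixed, Table-4-compatible CSV schema.

The table carries every per-herb indicator the pipeline computes: proximity
(Z, dab, s_ab, max diameter), association (Overlap rate, Hscore), empirical
usage (Pscore, Mscore), docking effectiveness (Ec score), clustering
validity (Dunn, Ave silhouette score) and the final ranking quantities (GCN
Degree, Average drug association).  Published-style headers are used on
disk; snake_case aliases are accepted on input and available in memory.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

# on-disk header -> internal snake_case alias, in the fixed on-disk order;
# the first block mirrors the published ranking-table column order.
COLUMN_ALIASES = {
    "herb": "herb",
    "Z": "z",
    "dab": "d_ab",
    "Overlap rate": "overlap_rate",
    "Hscore": "hscore",
    "Mscore": "mscore",
    "Ec score": "ec",
    "Ave silhouette score": "avg_silhouette",
    "GCN Degree": "gcn_degree",
    "Average drug association": "avg_drug_association",
    "s_ab": "s_ab",
    "max_diameter": "max_diameter",
    "Pscore": "pscore",
    "Dunn": "dunn",
}
DISK_COLUMNS = list(COLUMN_ALIASES)
INTERNAL_COLUMNS = list(COLUMN_ALIASES.values())
_TO_DISK = {v: k for k, v in COLUMN_ALIASES.items()}


def new_score_table(herbs) -> pd.DataFrame:
    """Empty score table (internal column names) indexed by row, one per herb."""
    df = pd.DataFrame({"herb": list(herbs)})
    for c in INTERNAL_COLUMNS[1:]:
        df[c] = float("nan")
    return df


def validate_score_table(table: pd.DataFrame) -> None:
    missing = set(INTERNAL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    sil = table["avg_silhouette"].dropna()
    if ((sil < -1) | (sil > 1)).any():
        raise ValueError("avg_silhouette outside [-1, 1]")
    ov = table["overlap_rate"].dropna()
    if ((ov < 0) | (ov > 1)).any():
        raise ValueError("overlap_rate outside [0, 1]")
    deg = table["gcn_degree"].dropna()
    if (deg > max(len(table) - 1, 0)).any():
        raise ValueError("gcn_degree exceeds n_herbs - 1")


def write_score_table(table: pd.DataFrame, path) -> None:
    """Write the table as CSV in the fixed disk schema.

    Floats are written with ``repr`` precision so values round-trip to 1e-9;
    missing values become empty cells.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty score table")
    validate_score_table(table)
    out = table[INTERNAL_COLUMNS].rename(columns=_TO_DISK)
    out.to_csv(Path(path), index=False)


def read_score_table(path) -> pd.DataFrame:
    """Read a score table written by :func:`write_score_table` (or a
    hand-built CSV using either disk headers or snake_case aliases)."""
    df = pd.read_csv(Path(path))
    df = df.rename(columns={k: v for k, v in COLUMN_ALIASES.items() if k in df.columns})
    missing = set(INTERNAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    df = df[INTERNAL_COLUMNS]
    validate_score_table(df)
    return df
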