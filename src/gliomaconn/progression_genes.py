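"""Sequential-upregulation filtering of stage-wise differential expression.

Operates on gene tables carrying log2 fold changes for two progression
transitions (mid vs. early and endpoint vs. mid stage of a glioma model)
plus per-transition p-values.  After Benjamini-Hochberg adjustment, a gene
is called sequentially upregulated when its log2FC clears the threshold
(default 0.25, positive — the call is about *up*regulation, though a
signed-absolute mode is available) and its adjusted p stays below 0.05 in
BOTH transitions.

A 42-gene reference table of sequentially upregulated genes ships with the
package (``load_progression_table``), carrying the two transition log2FC
columns plus p = 0.001 placeholders (no per-gene p-values accompany the
reference fold changes), so the worked example isolates the fold-change
logic.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

TRANSITIONS = ("mid_vs_early", "end_vs_mid")
LFC_COLUMNS = tuple(f"lfc_{t}" for t in TRANSITIONS)
P_COLUMNS = tuple(f"p_{t}" for t in TRANSITIONS)
Q_COLUMNS = tuple(f"q_{t}" for t in TRANSITIONS)


def load_progression_table() -> pd.DataFrame:
    """The packaged 42-gene sequential-upregulation reference table."""
    with resources.files("gliomaconn.data").joinpath("progression_genes.tsv").open() as fh:
        return load_de_table(fh)


def load_de_table(path_or_buf) -> pd.DataFrame:
    """Read a DE table (TSV) and BH-adjust its per-transition p-values."""
    df = pd.read_csv(path_or_buf, sep="\t")
    missing = [c for c in ("gene", *LFC_COLUMNS, *P_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns {missing}")
    if df["gene"].duplicated().any():
        raise ValueError("gene ids must be unique")
    return adjust_table(df)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add q columns (BH within each transition)."""
    out = df.copy()
    for p_col, q_col in zip(P_COLUMNS, Q_COLUMNS):
        out[q_col] = bh_adjust(out[p_col].to_numpy()) if len(out) else []
    return out


def sequential_upregulated(table: pd.DataFrame, lfc_min: float = 0.25,
                           q_max: float = 0.05, signed: bool = True) -> list[str]:
    """Genes significantly upregulated across BOTH progression transitions.

    ``signed=True`` (default) requires log2FC >= lfc_min in each transition;
    ``signed=False`` applies the threshold to |log2FC| instead.  Returns the
    selected gene ids sorted lexicographically.
    """
    missing = [c for c in (*LFC_COLUMNS, *Q_COLUMNS) if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns {missing} (run adjust_table first?)")
    if table.empty:
        return []
    keep = pd.Series(True, index=table.index)
    for lfc_col, q_col in zip(LFC_COLUMNS, Q_COLUMNS):
        lfc = table[lfc_col] if signed else table[lfc_col].abs()
        keep &= (lfc >= lfc_min) & (table[q_col] < q_max)
    return sorted(table.loc[keep, "gene"].tolist())


def max_transition_lfc(table: pd.DataFrame, which_transition: str = "end_vs_mid") -> tuple[str, float]:
    """Arg-max gene and value of one transition's log2FC (lexicographic ties)."""
    if which_transition not in TRANSITIONS:
        raise ValueError(f"which_transition must be one of {TRANSITIONS}")
    if table.empty:
        raise ValueError("empty table")
    col = f"lfc_{which_transition}"
    best = table[col].max()
    genes = sorted(table.loc[table[col] == best, "gene"])
    return genes[0], float(best)


def write_selection(table: pd.DataFrame, path, lfc_min: float = 0.25,
                    q_max: float = 0.05, signed: bool = True) -> pd.DataFrame:
    """Write the table with a ``selected`` flag column; returns the frame."""
    selected = set(sequential_upregulated(table, lfc_min, q_max, signed))
    out = table.assign(selected=table["gene"].isin(selected))
    out.to_csv(path, sep="\t", index=False)
    return out
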