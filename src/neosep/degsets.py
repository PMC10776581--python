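"""Post-processing of per-gene differential-expression tables.

Consumes externally produced tables (gene, log2FC, raw p, BH-adjusted p,
condition), applies the fixed haemoglobin filter, thresholds significant
DEGs (BH-adjusted p < 0.05 and |log2FC| > 0.95, both strict), selects
top-N genes by adjusted p, and partitions DEG sets from multiple
conditions into Venn regions with direction-concordance flags.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "HEMOGLOBIN_GENES",
    "filter_hemoglobin",
    "threshold_degs",
    "top_n_by_adjp",
    "set_partition",
]

#: The ten haemoglobin genes removed before any DEG graph or set analysis
#: (erythroid transcripts dominate whole-blood-contaminated PBMC libraries).
HEMOGLOBIN_GENES = ("HBB", "HBA1", "HBA2", "HBG1", "HBG2", "HBD", "HBE1", "HBM", "HBQ1", "HBZ")


def filter_hemoglobin(table: pd.DataFrame) -> pd.DataFrame:
    """Remove exactly the ten haemoglobin genes (case-insensitive symbols)."""
    keep = ~table["gene"].astype(str).str.upper().isin(HEMOGLOBIN_GENES)
    return table.loc[keep].copy()


def threshold_degs(table: pd.DataFrame, alpha: float = 0.05, lfc: float = 0.95) -> pd.DataFrame:
    """Significant DEGs: adjusted p strictly below ``alpha`` and |log2FC|
    strictly above ``lfc``; a ``direction`` column carries sign(log2FC)."""
    sel = (table["p_adj"] < alpha) & (table["log2fc"].abs() > lfc)
    out = table.loc[sel].copy()
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out


def top_n_by_adjp(table: pd.DataFrame, n: int = 50) -> list[str]:
    """The ``n`` genes with the smallest adjusted p-values.

    Ties are broken by smaller raw p, then lexicographic gene symbol, so
    the selection is deterministic; a table shorter than ``n`` is returned
    whole.
    """
    ordered = table.sort_values(
        ["p_adj", "p_raw", "gene"], kind="mergesort"
    )
    return ordered["gene"].astype(str).head(n).tolist()


def set_partition(deg_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Venn-region partition of DEG sets from several conditions.

    ``deg_sets`` maps condition name to a thresholded DEG table (with
    ``gene`` and ``direction`` columns). Every gene in the union is
    assigned to exactly one of the 2^k - 1 non-empty membership regions;
    each region row reports its genes, count, and whether every member
    gene's direction agrees across all the conditions containing it
    (the up/down concordance annotation of DiVenn-style diagrams).
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least two conditions to partition")
    conditions = list(deg_sets)
    membership: dict[str, dict[str, int]] = {}
    for cond in conditions:
        tab = deg_sets[cond]
        dirs = (
            tab.set_index(tab["gene"].astype(str))["direction"]
            if "direction" in tab.columns
            else pd.Series(1, index=tab["gene"].astype(str))
        )
        for gene, d in dirs.items():
            membership.setdefault(gene, {})[cond] = int(d)

    rows = []
    for r in range(1, len(conditions) + 1):
        for combo in combinations(conditions, r):
            combo_set = set(combo)
            genes = sorted(g for g, m in membership.items() if set(m) == combo_set)
            concordant = [g for g in genes if len({membership[g][c] for c in combo}) == 1]
            rows.append(
                {
                    "region": "&".join(combo),
                    "n_conditions": r,
                    "genes": genes,
                    "count": len(genes),
                    "n_direction_concordant": len(concordant),
                }
            )
    return pd.DataFrame(rows)
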