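"""Integrating translation, abundance, and protein-production changes.

Translation and transcript-abundance changes act multiplicatively on protein
output, so on the log2 scale their product predictor is simply the sum.
Correlation reports compare each predictor (and their product) against the
pSILAC protein-production changes with both Spearman and Pearson
coefficients, optionally after excluding translation-apparatus genes
(ribosomal proteins, initiation and elongation factors), whose coordinated
regulation otherwise dominates the comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "product_predictor",
    "correlation_report",
    "zscore_normalize",
    "merge_gene_changes",
]


def product_predictor(dt, da):
    """log2 of the product of translation and abundance changes: dt + da."""
    dt = np.asarray(dt, dtype=float)
    da = np.asarray(da, dtype=float)
    out = dt + da
    return out if out.ndim else float(out)


def merge_gene_changes(translation: pd.Series, abundance: pd.Series,
                       protein: pd.Series,
                       apparatus: pd.Series | None = None) -> pd.DataFrame:
    """Merge per-gene log2 changes into one record table.

    Rows are the union of gene ids; the product predictor is defined only
    where both translation and abundance are present.  ``apparatus`` is a
    boolean Series flagging translation-apparatus genes (defaults to False).
    """
    genes = translation.index.union(abundance.index).union(protein.index)
    out = pd.DataFrame(index=genes)
    out["delta_translation"] = translation.reindex(genes)
    out["delta_abundance"] = abundance.reindex(genes)
    out["delta_protein"] = protein.reindex(genes)
    out["product"] = out["delta_translation"] + out["delta_abundance"]
    out["apparatus"] = (apparatus.reindex(genes).fillna(False).astype(bool)
                        if apparatus is not None else False)
    return out


def correlation_report(records: pd.DataFrame, exclude_apparatus: bool = False) -> pd.DataFrame:
    """Spearman and Pearson correlations of each predictor with Δprotein.

    ``records`` as produced by :func:`merge_gene_changes`.  Pairwise-complete
    handling: each comparison uses the rows where both members are present.
    With ``exclude_apparatus``, translation-apparatus rows are removed first
    and the removed count is reported on every row of the output.
    """
    needed = {"delta_translation", "delta_abundance", "delta_protein", "product"}
    if not needed <= set(records.columns):
        raise ValueError(f"records missing columns: {sorted(needed - set(records.columns))}")
    n_all = len(records)
    removed = 0
    if exclude_apparatus:
        mask = records.get("apparatus", pd.Series(False, index=records.index)).astype(bool)
        removed = int(mask.sum())
        records = records.loc[~mask]
    assert n_all == len(records) + removed
    rows = []
    for name, col in [("translation", "delta_translation"),
                      ("abundance", "delta_abundance"),
                      ("product", "product")]:
        pair = records[[col, "delta_protein"]].dropna()
        if len(pair) < 3:
            raise ValueError(f"fewer than 3 complete records for comparison '{name}'")
        x = pair[col].to_numpy()
        y = pair["delta_protein"].to_numpy()
        rows.append({
            "comparison": name,
            "spearman_r": float(stats.spearmanr(x, y).statistic),
            "pearson_r": float(stats.pearsonr(x, y).statistic),
            "n": len(pair),
            "n_excluded_apparatus": removed,
        })
    return pd.DataFrame(rows)


def zscore_normalize(values) -> np.ndarray:
    """Median-zero, unit-SD normalization used for heatmap display scales."""
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("need >= 2 distinct values (zero SD otherwise)")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    out = (v - np.median(v)) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out
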