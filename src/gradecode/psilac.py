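"""Aggregating pulsed-SILAC peptide ratios into protein production changes.

During drug (or mock) treatment, cells grow in medium- or heavy-arginine
media so that only proteins synthesized during the treatment window carry
the label; the medium/heavy ratio of each confidently identified tryptic
peptide therefore reports the change in production of its protein.  The
forward experiment mixes medium-labeled treated with heavy-labeled untreated
lysate; the reverse experiment swaps the labels and serves as a biological
replicate, so its ratios must be flipped to the treated:untreated
orientation before combining.

Filters applied, in order: identification probability >= 0.95, the
quantitation-quality flag, median-centering of the log ratios within each
direction (to remove sample-loading bias), a geometric mean over all
assigned peptide ratios per protein, and the requirement of at least two
unique peptide sequences per reported protein.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PEPTIDE_COLUMNS",
    "MIN_IDENTIFICATION_PROBABILITY",
    "filter_peptide_table",
    "protein_log_ratios",
    "combine_forward_reverse",
]

#: Required columns of a peptide ratio table (tab-delimited on disk).
PEPTIDE_COLUMNS = ["peptide", "protein", "gene", "unique", "prob",
                   "ratio_mh", "quality_ok", "direction"]

MIN_IDENTIFICATION_PROBABILITY = 0.95
MIN_UNIQUE_PEPTIDES = 2
#: Optional protein-level probability threshold (proteins below are rejected).
MIN_PROTEIN_PROBABILITY = 0.05


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in PEPTIDE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    if (table["ratio_mh"] <= 0).any():
        raise ValueError("peptide ratios must be strictly positive")


def filter_peptide_table(table: pd.DataFrame,
                         protein_probability: pd.Series | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the identification and quality filters, then median-center.

    Keeps peptides with identification probability >= 0.95 whose quantitative
    ratio passed quality curation; log2 ratios are then median-centered to
    zero within each direction and stored in a ``log2_ratio`` column.  When
    ``protein_probability`` is given (a Series indexed by protein id),
    proteins with probability < 0.05 are rejected outright.  Returns
    ``(kept, rejected)``; the rejected frame carries a ``reason`` column.
    """
    _validate(table)
    reasons = pd.Series("", index=table.index, dtype=object)
    bad_prob = table["prob"] < MIN_IDENTIFICATION_PROBABILITY
    bad_qual = ~table["quality_ok"].astype(bool)
    reasons[bad_qual] = "low-quality quantitative ratio"
    reasons[bad_prob] = f"identification probability < {MIN_IDENTIFICATION_PROBABILITY}"
    drop = bad_prob | bad_qual
    if protein_probability is not None:
        bad_protein = table["protein"].map(protein_probability).lt(MIN_PROTEIN_PROBABILITY)
        bad_protein = bad_protein.fillna(False)
        reasons[bad_protein & ~drop] = f"protein probability < {MIN_PROTEIN_PROBABILITY}"
        drop = drop | bad_protein
    kept = table.loc[~drop].copy()
    rejected = table.loc[drop].copy()
    rejected["reason"] = reasons[drop]
    if kept.empty:
        raise ValueError("no peptides survive filtering")
    kept["log2_ratio"] = np.log2(kept["ratio_mh"].to_numpy(dtype=float))
    kept["log2_ratio"] -= kept.groupby("direction")["log2_ratio"].transform("median")
    return kept, rejected


def protein_log_ratios(filtered: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Per-protein log2 ratio for one direction: geometric mean of peptide ratios.

    The geometric mean over all assigned peptide ratios equals the arithmetic
    mean of their log2 ratios.  Proteins backed by fewer than two distinct
    unique peptide sequences are dropped.  Output columns: protein, gene,
    log2_ratio, n_peptides, n_unique_peptides.
    """
    sub = filtered.loc[filtered["direction"] == direction]
    if sub.empty:
        return pd.DataFrame(columns=["protein", "gene", "log2_ratio",
                                     "n_peptides", "n_unique_peptides"])
    grouped = sub.groupby("protein")
    out = grouped.agg(
        gene=("gene", "first"),
        log2_ratio=("log2_ratio", "mean"),
        n_peptides=("peptide", "size"),
    )
    uniq = sub.loc[sub["unique"].astype(bool)].groupby("protein")["peptide"].nunique()
    out["n_unique_peptides"] = uniq.reindex(out.index).fillna(0).astype(int)
    out = out.loc[out["n_unique_peptides"] >= MIN_UNIQUE_PEPTIDES]
    return out.reset_index()


def combine_forward_reverse(forward: pd.DataFrame, reverse: pd.DataFrame) -> pd.DataFrame:
    """Combine forward and reverse experiments on the treated:untreated scale.

    Reverse ratios are stored as untreated:treated, so their log2 values are
    negated before combining; per protein the combined value is the mean of
    the available log2 values (the geometric mean on the ratio scale).
    Proteins measured in only one direction keep that value and are flagged
    ``single_direction``.
    """
    fwd = forward.set_index("protein")
    rev = reverse.set_index("protein")
    proteins = fwd.index.union(rev.index)
    f = fwd["log2_ratio"].reindex(proteins)
    r = -rev["log2_ratio"].reindex(proteins)  # flip to treated:untreated
    combined = pd.concat([f, r], axis=1).mean(axis=1, skipna=True)
    gene = fwd["gene"].reindex(proteins).fillna(rev["gene"].reindex(proteins))
    n_unique = pd.concat([fwd["n_unique_peptides"].reindex(proteins),
                          rev["n_unique_peptides"].reindex(proteins)], axis=1).max(axis=1)
    out = pd.DataFrame({
        "protein": proteins,
        "gene": gene.to_numpy(),
        "log2_ratio": combined.to_numpy(),
        "log2_forward": f.to_numpy(),
        "log2_reverse_flipped": r.to_numpy(),
        "n_unique_peptides": n_unique.astype(int).to_numpy(),
        "single_direction": (f.isna() | r.isna()).to_numpy(),
    })
    return out.reset_index(drop=True)
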