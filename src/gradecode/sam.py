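"""SAM-style two-class differential statistics with permutation FDR.

The moderated two-class statistic is

    d_i = (mean_treated_i - mean_untreated_i) / (s_i + s0)

with ``s_i`` the unpaired pooled standard error of row i and ``s0`` a fudge
factor damping rows with tiny variance (``s0="auto"`` uses the median of the
``s_i``).  Sample columns are mean-centered before testing.  Significance is
assessed by permuting the class labels: at three replicates per class all 20
distinct assignments are enumerated deterministically, so no sampling seed
enters.  For each candidate |d| threshold,

    FDR(threshold) = pi0 * median_perm #{|d*| >= threshold} / #{|d| >= threshold}

with pi0 estimated from the share of observed d values inside the
interquartile range of the permuted d.  Per-row q-values are the minimum FDR
over thresholds that call the row, reported in percent and clipped to
[0, 100].  Tail-area q-values are the primary output; a kernel-density local
FDR is exposed separately and labeled approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mean_center_columns",
    "sam_statistic",
    "sam_fdr",
    "collapse_oligos",
    "classify_translation_only",
    "TranslationDifferential",
    "DifferentialResults",
]


def _as_matrix(matrix) -> tuple[np.ndarray, pd.Index]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), matrix.index
    x = np.asarray(matrix, dtype=float)
    return x, pd.RangeIndex(x.shape[0])


def _class_masks(labels, n_cols: int) -> tuple[np.ndarray, np.ndarray]:
    lab = np.asarray(labels)
    if lab.size != n_cols:
        raise ValueError("labels length must match the number of sample columns")
    classes = pd.unique(lab)
    if classes.size != 2:
        raise ValueError("exactly two classes are required")
    # untreated is the reference when present; otherwise first label seen
    if "untreated" in classes:
        ref = "untreated"
    else:
        ref = classes[0]
    mask_ref = lab == ref
    if mask_ref.sum() < 2 or (~mask_ref).sum() < 2:
        raise ValueError("each class needs at least two samples")
    return ~mask_ref, mask_ref  # (treated, untreated)


def mean_center_columns(x: np.ndarray) -> np.ndarray:
    """Subtract each sample column's mean (idempotent)."""
    x = np.asarray(x, dtype=float)
    return x - x.mean(axis=0, keepdims=True)


def _d_and_s(x: np.ndarray, treated: np.ndarray, untreated: np.ndarray):
    n1, n2 = treated.sum(), untreated.sum()
    xt, xu = x[:, treated], x[:, untreated]
    diff = xt.mean(axis=1) - xu.mean(axis=1)
    ss = ((xt - xt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((xu - xu.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return diff, s


def sam_statistic(matrix, labels, s0="auto", center: bool = True):
    """Moderated d statistic per row.  Returns ``(d, s, s0)``."""
    x, _ = _as_matrix(matrix)
    treated, untreated = _class_masks(labels, x.shape[1])
    if center:
        x = mean_center_columns(x)
    diff, s = _d_and_s(x, treated, untreated)
    if isinstance(s0, str):
        if s0 != "auto":
            raise ValueError("s0 must be a number or 'auto'")
        s0_val = float(np.median(s))
    else:
        s0_val = float(s0)
    if s0_val < 0:
        raise ValueError("s0 must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / (s + s0_val)
    d = np.where(np.isfinite(d), d, 0.0)
    return d, s, s0_val


def _label_permutations(labels, n_permutations, rng: np.random.Generator | None):
    lab = np.asarray(labels)
    n = lab.size
    n_ref = int((lab == lab[0]).sum())  # size of the first class
    all_assignments = list(combinations(range(n), n_ref))
    if n_permutations == "all":
        return all_assignments
    k = int(n_permutations)
    if k < 2:
        raise ValueError("n_permutations must be >= 2 (or 'all')")
    if k >= len(all_assignments):
        return all_assignments
    if rng is None:
        raise ValueError("a seed is required when sampling permutations")
    idx = rng.choice(len(all_assignments), size=k, replace=False)
    return [all_assignments[i] for i in idx]


def sam_fdr(matrix, labels, n_permutations="all", seed: int | None = None,
            s0="auto", center: bool = True):
    """Permutation q-values (percent) per row.

    Returns ``(d, q_percent, pi0)``.  With ``n_permutations="all"`` the
    distinct label assignments are enumerated (20 at 3 vs 3), which removes
    any seed dependence at the design's replicate count.
    """
    x, _ = _as_matrix(matrix)
    lab = np.asarray(labels)
    treated, untreated = _class_masks(lab, x.shape[1])
    if center:
        x = mean_center_columns(x)
    d, s, s0_val = sam_statistic(x, lab, s0=s0, center=False)

    rng = np.random.default_rng(seed) if seed is not None else None
    perms = _label_permutations(lab, n_permutations, rng)
    n_rows = x.shape[0]
    perm_d = np.empty((len(perms), n_rows))
    cols = np.arange(x.shape[1])
    for p, ref_cols in enumerate(perms):
        mask_ref = np.isin(cols, ref_cols)
        diff, sp = _d_and_s(x, ~mask_ref, mask_ref)
        perm_d[p] = diff / (sp + s0_val)
    perm_d = np.where(np.isfinite(perm_d), perm_d, 0.0)

    q1, q3 = np.percentile(perm_d, [25, 75])
    pi0 = min(1.0, float(((d >= q1) & (d <= q3)).sum()) / max(1, int(0.5 * n_rows)))

    abs_d = np.abs(d)
    order = np.argsort(-abs_d, kind="stable")
    thresholds = abs_d[order]
    # observed calls at each threshold (ties counted fully)
    obs_calls = np.searchsorted(-thresholds, -thresholds, side="right")
    sorted_perm = np.sort(np.abs(perm_d), axis=1)
    false_calls = np.empty((len(perms), n_rows))
    for p in range(len(perms)):
        false_calls[p] = n_rows - np.searchsorted(sorted_perm[p], thresholds, side="left")
    med_false = np.median(false_calls, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = 100.0 * pi0 * med_false / obs_calls
    fdr = np.clip(fdr, 0.0, 100.0)
    # q for the row ranked j = min FDR over thresholds <= its |d| (ranks >= j)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n_rows)
    q[order] = q_sorted
    return d, q, pi0


def collapse_oligos(values, oligo_to_gene, mode: str = "mean",
                    change_for_max=None) -> pd.Series:
    """Collapse per-oligo values to per-gene values.

    ``mode="mean"``: arithmetic mean of the (log2) values per gene.
    ``mode="max_change"``: value of the oligo with the largest absolute
    change; ``change_for_max`` supplies the change used for the argmax (it
    defaults to the values themselves).
    """
    vals = pd.Series(values, dtype=float)
    mapping = pd.Series(oligo_to_gene)
    unmapped = vals.index.difference(mapping.index)
    if len(unmapped):
        raise ValueError(f"unmapped oligos: {sorted(map(str, unmapped))}")
    genes = mapping.reindex(vals.index)
    if mode == "mean":
        return vals.groupby(genes).mean()
    if mode == "max_change":
        change = pd.Series(change_for_max, dtype=float).reindex(vals.index) \
            if change_for_max is not None else vals
        picked = change.abs().groupby(genes).idxmax()
        out = vals.reindex(picked.to_numpy())
        out.index = picked.index
        return out
    raise ValueError("mode must be 'mean' or 'max_change'")


def classify_translation_only(diff_translation: pd.DataFrame,
                              abundance_changes: pd.Series,
                              fdr_cutoff: float = 10.0) -> pd.Series:
    """Classify genes by translation significance vs. abundance shift.

    ``diff_translation`` needs columns ``q`` (percent) indexed by gene;
    ``abundance_changes`` gives per-gene log2 abundance changes for the same
    genes.  A gene is ``translation_only`` when it passes the translation FDR
    cutoff and its abundance change lies within one standard deviation of the
    mean over *all* detectable genes; significant genes outside that band are
    ``both``; non-significant genes split into ``abundance_only`` / ``neither``
    by the same one-SD band.
    """
    if set(diff_translation.index) != set(abundance_changes.index):
        raise ValueError("translation and abundance tables cover different gene sets")
    da = abundance_changes.reindex(diff_translation.index).astype(float)
    mu, sd = float(da.mean()), float(da.std(ddof=1))
    within = (da - mu).abs() <= sd
    sig = diff_translation["q"] <= fdr_cutoff
    out = pd.Series("neither", index=diff_translation.index, dtype=object)
    out[sig & within] = "translation_only"
    out[sig & ~within] = "both"
    out[~sig & ~within] = "abundance_only"
    return out


class TranslationDifferential:
    """Two-class differential model for a genes-by-samples log2 matrix.

    Parameters
    ----------
    matrix : DataFrame or array, rows = genes/oligos, columns = samples.
        Log2 average ribosome numbers (translation mode) or log2 normalized
        abundance ratios (abundance mode); every retained row must have a
        value in all samples.
    labels : sequence of "untreated"/"treated" (or any two labels) per column.
    """

    def __init__(self, matrix, labels, s0="auto"):
        x, index = _as_matrix(matrix)
        if np.isnan(x).any():
            raise ValueError("matrix must be complete: only rows measured in "
                             "all replicates are admissible")
        self.matrix = x
        self.index = index
        self.labels = np.asarray(labels)
        self.s0 = s0
        _class_masks(self.labels, x.shape[1])

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, s0="auto") -> "TranslationDifferential":
        """Build from a DataFrame whose columns are (condition, replicate) tuples."""
        labels = [c[0] if isinstance(c, tuple) else str(c).split("_")[0]
                  for c in frame.columns]
        return cls(frame, labels, s0=s0)

    def fit(self, n_permutations="all", seed: int | None = None,
            fdr_cutoff: float = 10.0) -> "DifferentialResults":
        d, q, pi0 = sam_fdr(self.matrix, self.labels, n_permutations=n_permutations,
                            seed=seed, s0=self.s0)
        _, s, s0_val = sam_statistic(self.matrix, self.labels, s0=self.s0)
        treated, untreated = _class_masks(self.labels, self.matrix.shape[1])
        centered = mean_center_columns(self.matrix)
        change = centered[:, treated].mean(axis=1) - centered[:, untreated].mean(axis=1)
        table = pd.DataFrame({"log2_change": change, "d": d, "q": q,
                              "significant": q <= fdr_cutoff,
                              "direction": np.where(change >= 0, "up", "down")},
                             index=self.index)
        return DifferentialResults(table=table, s0=s0_val, pi0=pi0,
                                   fdr_cutoff=fdr_cutoff, n_permutations=len(
                                       _label_permutations(self.labels, n_permutations,
                                                           np.random.default_rng(seed or 0))))


@dataclass
class DifferentialResults:
    """Fitted differential table plus the nuisance estimates behind it."""

    table: pd.DataFrame
    s0: float
    pi0: float
    fdr_cutoff: float
    n_permutations: int
    _local_fdr: pd.Series | None = field(default=None, repr=False)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def local_fdr(self) -> pd.Series:
        """Approximate local FDR via Gaussian-kernel density ratio.

        A kernel estimate of the null (permuted-scale) density over the d
        axis divided by the observed density, scaled by pi0.  Approximate and
        for ranking only; the tail-area q-values are the primary statistic.
        """
        if self._local_fdr is None:
            d = self.table["d"].to_numpy()
            obs = stats.gaussian_kde(d)
            null = stats.norm(loc=0.0, scale=max(1e-6, np.std(d[np.abs(d) < np.percentile(np.abs(d), 50)])))
            lf = np.clip(100.0 * self.pi0 * null.pdf(d) / np.maximum(obs(d), 1e-12), 0, 100)
            self._local_fdr = pd.Series(lf, index=self.table.index)
        return self._local_fdr

    def summary(self) -> str:
        t = self.table
        lines = [
            "Two-class SAM-style differential analysis",
            f"  rows tested:        {len(t)}",
            f"  permutations:       {self.n_permutations}",
            f"  s0 (fudge factor):  {self.s0:.4g}",
            f"  pi0 estimate:       {self.pi0:.3f}",
            f"  FDR cutoff:         {self.fdr_cutoff:.1f}%",
            f"  significant rows:   {self.n_significant} "
            f"({(t['significant'] & (t['log2_change'] > 0)).sum()} up, "
            f"{(t['significant'] & (t['log2_change'] < 0)).sum()} down)",
        ]
        top = t.loc[t["significant"]].reindex(
            t.loc[t["significant"], "d"].abs().sort_values(ascending=False).index).head(10)
        if len(top):
            lines.append("  top rows by |d|:")
            for idx, row in top.iterrows():
                lines.append(f"    {idx!s:<20} log2_change={row['log2_change']:+.3f} "
                             f"d={row['d']:+.3f} q={row['q']:.2f}%")
        return "\n".join(lines)
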