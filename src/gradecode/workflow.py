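"""End-to-end pipeline: simulate or ingest arrays, decode, test, integrate.

``run_experiment`` drives a complete synthetic study at the configured
conditions: three replicate gradients per condition are encoded and decoded,
abundance arrays are normalized against their spike-ins, oligos are
collapsed to genes, SAM-style statistics call differential translation and
abundance at the configured FDR, genes are classified by their mode of
regulation, and the pSILAC protein table is folded in for the correlation
report.  Only features passing quality filtering in every replicate enter
the matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decode import decode_experiment, normalize_abundance, quality_filter
from .encoding import assign_doping_controls
from .integrate import correlation_report, merge_gene_changes
from .psilac import combine_forward_reverse, filter_peptide_table, protein_log_ratios
from .sam import DifferentialResults, TranslationDifferential, classify_translation_only
from .simulate import (GradientRun, SimConfig, SimTruth, simulate_abundance_run,
                       simulate_gradient_run, simulate_psilac, simulate_truth)

__all__ = ["ExperimentResult", "run_experiment", "decode_runs",
           "validation_panel_compare", "RIBOSOME_LOG_FLOOR"]

#: Decoded average ribosome numbers are floored here before taking log2;
#: only heavily sub-monosomal decodes (top-of-gradient noise) are affected.
RIBOSOME_LOG_FLOOR = 0.1

CONDITIONS = ("untreated", "treated")


@dataclass
class ExperimentResult:
    """Everything a synthetic study produces, truth included."""

    truth: SimTruth
    runs: list
    translation_matrix: pd.DataFrame   # genes x samples, log2 avg ribosome number
    abundance_matrix: pd.DataFrame     # genes x samples, log2 sample/reference
    diff_translation: DifferentialResults
    diff_abundance: DifferentialResults
    delta_translation: pd.Series
    delta_abundance: pd.Series
    classification: pd.Series
    protein_table: pd.DataFrame
    records: pd.DataFrame
    correlations: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Gradient Encoding synthetic experiment",
            f"  genes simulated:   {len(self.truth.genes)}",
            f"  genes analyzable:  {len(self.translation_matrix)} (in all replicates)",
            "", "Differential translation:",
            self.diff_translation.summary(), "",
            "Classification of significant translation calls:",
        ]
        counts = self.classification.value_counts()
        for name in ("translation_only", "both", "abundance_only", "neither"):
            lines.append(f"  {name:<17} {int(counts.get(name, 0))}")
        lines += ["", "Correlations with protein production (pSILAC):"]
        for _, row in self.correlations.iterrows():
            lines.append(f"  {row['comparison']:<12} Spearman r = {row['spearman_r']:+.3f}  "
                         f"Pearson r = {row['pearson_r']:+.3f}  (n = {int(row['n'])})")
        return "\n".join(lines)


def _log2_ribosomes(k: np.ndarray) -> np.ndarray:
    return np.log2(np.maximum(k, RIBOSOME_LOG_FLOOR))


def decode_runs(runs: list[GradientRun], config: SimConfig,
                collapse: str = "mean") -> pd.DataFrame:
    """Decode a set of gradient runs into a gene-level log2 ribosome matrix.

    Features must pass quality filtering in every run to be retained; oligos
    of the same gene are collapsed by ``collapse`` ("mean" averages their
    log2 values).  Columns are (condition, replicate) tuples.
    """
    scheme = config.scheme()
    dope = assign_doping_controls(scheme, config.controls_per_fraction,
                                  config.control_mass_pg)
    decoded = {}
    kept_sets = []
    for run in runs:
        kept, _ = quality_filter(run.feature_table)
        est = decode_experiment(kept, scheme, dope, run.geometry, run.calibration)
        decoded[(run.condition, run.replicate)] = est.set_index("feature_id")
        kept_sets.append(set(est["feature_id"]))
    common = set.intersection(*kept_sets)
    cols = {}
    gene_of = None
    for key, est in decoded.items():
        est = est.loc[sorted(common)]
        cols[key] = _log2_ribosomes(est["avg_ribosomes"].to_numpy())
        gene_of = est["gene_id"]
    matrix = pd.DataFrame(cols, index=pd.Index(sorted(common), name="feature_id"))
    if collapse == "none":
        return matrix
    return matrix.groupby(gene_of).mean()


def validation_panel_compare(config: SimConfig, truth: SimTruth | None = None) -> pd.DataFrame:
    """Array decode vs. the explicit qPCR oracle on a small gene panel.

    Mirrors the targeted validation design: a panel of genes spanning
    translational repression to activation is measured both by encoded
    arrays (decoded, replicate-averaged) and by per-fraction qPCR on
    dedicated gradients (explicitly encoded through the oracle).  Returns a
    frame with ``decode`` and ``oracle`` log2 treated/untreated columns per
    gene.  With all noise at zero the two columns agree exactly.
    """
    from dataclasses import replace

    from .qpcr import normalize_qpcr_profile, oracle_translation_change
    from .simulate import make_validation_truth, simulate_qpcr_run

    # panel genes are picked for being well measured: no quality dropouts
    config = replace(config, quality_fail_rate=0.0)
    if truth is None:
        truth = make_validation_truth(config)
    runs = [simulate_gradient_run(truth, config, rep, cond)
            for cond in CONDITIONS for rep in range(1, config.n_replicates + 1)]
    mat = decode_runs(runs, config)
    t_cols = [c for c in mat.columns if c[0] == "treated"]
    u_cols = [c for c in mat.columns if c[0] == "untreated"]
    decode_delta = mat[t_cols].mean(axis=1) - mat[u_cols].mean(axis=1)

    qp = {cond: simulate_qpcr_run(truth, config, cond, truth.gene_ids)
          for cond in CONDITIONS}
    scheme = config.scheme()
    oracle = {}
    for gid in truth.gene_ids:
        profiles = {}
        for cond in CONDITIONS:
            sub = qp[cond].table
            sub = sub.loc[sub["gene"] == gid].sort_values("fraction")
            profiles[cond] = normalize_qpcr_profile(
                sub["mean"], sub["se"], sub["control_mean"], sub["control_se"],
                gene_id=gid, condition=cond)
        oracle[gid] = oracle_translation_change(
            profiles["treated"], profiles["untreated"], scheme,
            qp["treated"].geometry, qp["treated"].calibration,
            qp["untreated"].geometry, qp["untreated"].calibration)
    out = pd.concat([decode_delta.rename("decode"),
                     pd.Series(oracle).rename("oracle")], axis=1).dropna()
    out.index.name = "gene_id"
    return out


def _abundance_matrix(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    cols = {}
    gene_of = None
    for condition in CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            table, spikes = simulate_abundance_run(truth, config, rep, condition)
            genes, _ = normalize_abundance(table, spikes)
            genes = genes.set_index("feature_id")
            cols[(condition, rep)] = genes["log2_abundance_ratio"]
            gene_of = genes["gene_id"]
    matrix = pd.DataFrame(cols)
    return matrix.groupby(gene_of).mean()


def run_experiment(config: SimConfig, truth: SimTruth | None = None,
                   fdr_cutoff: float = 10.0) -> ExperimentResult:
    """Run the full synthetic study and analysis at the given conditions."""
    if truth is None:
        truth = simulate_truth(config)
    runs = [simulate_gradient_run(truth, config, rep, cond)
            for cond in CONDITIONS for rep in range(1, config.n_replicates + 1)]
    translation = decode_runs(runs, config)
    abundance = _abundance_matrix(truth, config)

    genes = translation.index.intersection(abundance.index)
    translation = translation.loc[genes]
    abundance = abundance.loc[genes]
    labels = [c[0] for c in translation.columns]

    diff_t = TranslationDifferential(translation, labels).fit(fdr_cutoff=fdr_cutoff)
    diff_a = TranslationDifferential(abundance, [c[0] for c in abundance.columns]).fit(
        fdr_cutoff=fdr_cutoff)

    treated_cols = [c for c in translation.columns if c[0] == "treated"]
    untreated_cols = [c for c in translation.columns if c[0] == "untreated"]
    delta_t = (translation[treated_cols].mean(axis=1)
               - translation[untreated_cols].mean(axis=1))
    delta_a = (abundance[[c for c in abundance.columns if c[0] == "treated"]].mean(axis=1)
               - abundance[[c for c in abundance.columns if c[0] == "untreated"]].mean(axis=1))

    classification = classify_translation_only(diff_t.table, delta_a,
                                               fdr_cutoff=fdr_cutoff)

    fwd, rev = simulate_psilac(truth, config)
    kept_f, _ = filter_peptide_table(fwd)
    kept_r, _ = filter_peptide_table(rev)
    prot = combine_forward_reverse(protein_log_ratios(kept_f, "forward"),
                                   protein_log_ratios(kept_r, "reverse"))
    protein_by_gene = prot.set_index("gene")["log2_ratio"]
    protein_by_gene = protein_by_gene[protein_by_gene.index.isin(genes)]

    records = merge_gene_changes(delta_t, delta_a, protein_by_gene,
                                 apparatus=truth.genes["apparatus"])
    try:
        correlations = correlation_report(records)
    except ValueError:
        correlations = pd.DataFrame(columns=["comparison", "spearman_r", "pearson_r",
                                             "n", "n_excluded_apparatus"])
    return ExperimentResult(truth=truth, runs=runs,
                            translation_matrix=translation,
                            abundance_matrix=abundance,
                            diff_translation=diff_t, diff_abundance=diff_a,
                            delta_translation=delta_t, delta_abundance=delta_a,
                            classification=classification,
                            protein_table=prot, records=records,
                            correlations=correlations)
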