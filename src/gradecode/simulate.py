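"""Seeded synthetic gradient-encoding experiments with known ground truth.

The generator realizes the assumptions behind the encoding readout: each
transcript's sedimentation is set by its ribosome load, initiation is
rate-limiting with uniform elongation, and ORF length is constant across
conditions.  A gene's latent state is its mean ribosome load and mRNA
abundance per condition; per gradient, the transcript spreads as a Gaussian
in fractional-position space around the position its load implies, the
profile is pooled into the two dye channels, and array features acquire
Gaussian log2-ratio noise plus simulated quality metrics.  A260 traces carry
per-replicate peak-time jitter, so each gradient has its own ribosome
calibration — gradients are never perfectly superimposable.

All randomness flows from ``SimConfig.seed`` through named child streams
(:func:`stream`), so any table can be regenerated in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoding import EncodingScheme, assign_doping_controls, make_encoding_scheme
from .gradient import (A260Trace, GradientGeometry, RibosomeCalibration,
                       fit_ribosome_calibration, time_to_ribosomes)

__all__ = [
    "SimConfig",
    "SimTruth",
    "GradientRun",
    "QpcrRun",
    "stream",
    "simulate_truth",
    "make_validation_truth",
    "simulate_gradient_run",
    "simulate_qpcr_run",
    "simulate_abundance_run",
    "simulate_psilac",
]

#: Regulation classes a gene can belong to.
CLASSES = ("null", "translation_up", "translation_down",
           "abundance_up", "abundance_down", "coupled")

#: Directionally balanced by default: per-array mean centering assumes the
#: bulk of the cohort is unchanged or symmetrically regulated.
DEFAULT_PROPORTIONS = {
    "null": 0.40,
    "translation_up": 0.14,
    "translation_down": 0.14,
    "abundance_up": 0.05,
    "abundance_down": 0.05,
    "coupled": 0.22,
}


def stream(seed: int, *keys) -> np.random.Generator:
    """Named child RNG: deterministic function of the master seed and keys."""
    ints = [zlib.crc32(str(k).encode("utf8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31)] + ints))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic gradient-encoding experiment.

    Defaults mirror the experimental design: 15 fractions, three biological
    replicates per condition, a monosome peak near 150 s with six resolvable
    ribosome peaks, four 100-pg doping controls per fraction, and noise
    scales tuned so replicate agreement of log ribosome numbers sits near
    the >0.95 regime reported for this kind of assay.
    """

    n_genes: int = 2000
    n_fractions: int = 15
    n_replicates: int = 3
    seed: int = 0

    # encoding scheme
    a_min: float = 0.03
    a_max: float = 0.97
    ramp: str = "log-ratio"
    controls_per_fraction: int = 4
    control_mass_pg: float = 100.0

    # gradient geometry and ribosome calibration (k = alpha + beta ln t)
    fraction_time_s: float = 60.0
    monosome_time_s: float = 150.0
    last_peak_time_s: float = 600.0
    n_peaks: int = 6
    peak_jitter_sigma: float = 0.01   # lognormal sigma on peak times, per gradient

    # transcript behaviour
    dispersion_pos: tuple[float, float] = (0.8, 1.3)  # per-gene Gaussian SD, position units
    load_bounds: tuple[float, float] = (1.8, 7.0)     # admissible mean ribosome loads
    abundance_sigma_ln: float = 0.6                   # lognormal spread of base abundance

    # effect sizes (log2 magnitudes, uniform)
    translation_effect: tuple[float, float] = (0.8, 1.8)
    abundance_effect: tuple[float, float] = (0.8, 1.6)

    # noise scales
    sigma_fraction: float = 0.10      # lognormal sigma on per-fraction abundance
    sigma_array: float = 0.20         # Gaussian sigma on array log2 ratios
    sigma_abundance_array: float = 0.15
    qpcr_cv: float = 0.05             # CV of qPCR means
    quality_fail_rate: float = 0.05   # features drawn to fail the 0.6/2.5 filters

    # pSILAC
    n_psilac_proteins: int = 258
    protein_coupling: tuple[float, float] = (1.0, 1.0)  # (c_translation, c_abundance)
    sigma_protein: float = 0.30
    sigma_peptide: float = 0.20
    peptide_lowprob_rate: float = 0.10
    peptide_lowquality_rate: float = 0.03
    max_peptides: int = 8

    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown regulation classes: {sorted(unknown)}")
        for name in ("sigma_fraction", "sigma_array", "sigma_abundance_array",
                     "qpcr_cv", "sigma_protein", "sigma_peptide", "peak_jitter_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def noiseless(self) -> "SimConfig":
        """Copy with every stochastic scale set to zero (round-trip oracle)."""
        return replace(self, sigma_fraction=0.0, sigma_array=0.0,
                       sigma_abundance_array=0.0, qpcr_cv=0.0,
                       peak_jitter_sigma=0.0, quality_fail_rate=0.0,
                       sigma_protein=0.0, sigma_peptide=0.0,
                       peptide_lowprob_rate=0.0, peptide_lowquality_rate=0.0)

    # -- derived study objects ------------------------------------------------
    def scheme(self) -> EncodingScheme:
        return make_encoding_scheme(self.n_fractions, self.a_min, self.a_max, self.ramp)

    def geometry(self) -> GradientGeometry:
        return GradientGeometry.equal_fractions(self.n_fractions,
                                                self.n_fractions * self.fraction_time_s)

    def reference_calibration(self) -> RibosomeCalibration:
        """The jitter-free peak-time model shared by all gradients."""
        return fit_ribosome_calibration(self.reference_peak_times(), first_count=1)

    def reference_peak_times(self) -> np.ndarray:
        k = np.arange(1, self.n_peaks + 1, dtype=float)
        beta = (self.n_peaks - 1) / np.log(self.last_peak_time_s / self.monosome_time_s)
        alpha = 1.0 - beta * np.log(self.monosome_time_s)
        return np.exp((k - alpha) / beta)


@dataclass(frozen=True)
class SimTruth:
    """Per-gene latent state; ``genes`` is indexed by gene_id."""

    genes: pd.DataFrame
    config: SimConfig

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def delta_translation(self) -> pd.Series:
        return np.log2(self.genes["load_treated"] / self.genes["load_untreated"])

    def delta_abundance(self) -> pd.Series:
        return np.log2(self.genes["abundance_treated"] / self.genes["abundance_untreated"])

    def oligo_map(self) -> pd.Series:
        """Series oligo_id -> gene_id for every simulated array feature."""
        ids, genes = [], []
        for gid, n in self.genes["n_oligos"].items():
            for o in range(int(n)):
                ids.append(f"{gid}_oligo{o + 1}")
                genes.append(gid)
        return pd.Series(genes, index=pd.Index(ids, name="feature_id"), name="gene_id")


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw the latent cohort: classes, effects, loads, abundances, oligos."""
    rng = stream(config.seed, "truth")
    n = config.n_genes
    names = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in names])
    classes = rng.choice(names, size=n, p=probs)

    t_mag = rng.uniform(*config.translation_effect, size=n)
    a_mag = rng.uniform(*config.abundance_effect, size=n)
    coupled_sign = rng.choice([-1.0, 1.0], size=n)

    dt = np.zeros(n)
    da = np.zeros(n)
    dt[classes == "translation_up"] = t_mag[classes == "translation_up"]
    dt[classes == "translation_down"] = -t_mag[classes == "translation_down"]
    da[classes == "abundance_up"] = a_mag[classes == "abundance_up"]
    da[classes == "abundance_down"] = -a_mag[classes == "abundance_down"]
    coup = classes == "coupled"
    dt[coup] = coupled_sign[coup] * t_mag[coup]
    da[coup] = coupled_sign[coup] * a_mag[coup]

    # base load drawn log-uniform inside the window keeping both conditions
    # within load_bounds, so no transcript sediments off the gradient
    lo_b, hi_b = config.load_bounds
    lo = np.log2(lo_b * np.exp2(np.maximum(0.0, -dt)))
    hi = np.log2(hi_b * np.exp2(-np.maximum(0.0, dt)))
    if np.any(hi <= lo):
        raise ValueError("load_bounds window too narrow for the configured "
                         "translation effect sizes (needs hi/lo > 2^max_effect)")
    load_u = np.exp2(rng.uniform(lo, hi))
    load_t = load_u * np.exp2(dt)

    abund_u = np.exp(rng.normal(0.0, config.abundance_sigma_ln, size=n))
    abund_t = abund_u * np.exp2(da)

    genes = pd.DataFrame({
        "class_label": classes,
        "load_untreated": load_u,
        "load_treated": load_t,
        "abundance_untreated": abund_u,
        "abundance_treated": abund_t,
        "dispersion": rng.uniform(*config.dispersion_pos, size=n),
        "apparatus": rng.random(n) < 0.05,
        "n_oligos": rng.choice([1, 2, 3], size=n, p=[0.5, 0.35, 0.15]),
    }, index=pd.Index([f"G{i:05d}" for i in range(1, n + 1)], name="gene_id"))
    return SimTruth(genes=genes, config=config)


def make_validation_truth(config: SimConfig, deltas=None) -> SimTruth:
    """Small hand-specified panel with a spread of translation effects.

    Mirrors a targeted qPCR validation design: nine genes spanning repression
    to activation, abundance held constant, some genes carried by two oligos.
    """
    if deltas is None:
        deltas = np.linspace(-1.5, 1.5, 9)
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.size
    rng = stream(config.seed, "validation-truth")
    lo_b, hi_b = config.load_bounds
    lo = np.log2(lo_b * np.exp2(np.maximum(0.0, -deltas)))
    hi = np.log2(hi_b * np.exp2(-np.maximum(0.0, deltas)))
    load_u = np.exp2(rng.uniform(lo, hi))
    genes = pd.DataFrame({
        "class_label": np.where(deltas > 0, "translation_up",
                                np.where(deltas < 0, "translation_down", "null")),
        "load_untreated": load_u,
        "load_treated": load_u * np.exp2(deltas),
        "abundance_untreated": np.ones(n),
        "abundance_treated": np.ones(n),
        "dispersion": np.full(n, float(np.mean(config.dispersion_pos))),
        "apparatus": np.zeros(n, dtype=bool),
        "n_oligos": (np.arange(n) % 2) + 1,
    }, index=pd.Index([f"V{i:02d}" for i in range(1, n + 1)], name="gene_id"))
    return SimTruth(genes=genes, config=config)


# ---------------------------------------------------------------------------
# gradient runs


@dataclass(frozen=True)
class GradientRun:
    """One simulated gradient + encoded array for a (replicate, condition)."""

    replicate: int
    condition: str
    trace: A260Trace
    geometry: GradientGeometry
    peak_times: np.ndarray            # exact jittered peak times
    calibration: RibosomeCalibration  # fit on the exact peak times
    profiles: pd.DataFrame            # genes x fractions, noisy
    feature_table: pd.DataFrame       # encoded two-color array
    truth_table: pd.DataFrame         # per-oligo noiseless encoded truth


def _position_of_load(load, calib: RibosomeCalibration, geom: GradientGeometry):
    """Fractional gradient position implied by a mean ribosome load."""
    t = calib.time_at(load)
    mids = geom.midpoints()
    fracs = np.arange(1, geom.n_fractions + 1, dtype=float)
    return np.interp(t, mids, fracs)


def _profiles_for(truth: SimTruth, condition: str, calib: RibosomeCalibration,
                  geom: GradientGeometry, rng: np.random.Generator,
                  sigma_fraction: float) -> pd.DataFrame:
    g = truth.genes
    load = g[f"load_{condition}"].to_numpy()
    abundance = g[f"abundance_{condition}"].to_numpy()
    center = _position_of_load(load, calib, geom)
    disp = g["dispersion"].to_numpy()
    fracs = np.arange(1, geom.n_fractions + 1, dtype=float)
    w = np.exp(-0.5 * ((fracs[None, :] - center[:, None]) / disp[:, None]) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    profile = w * abundance[:, None]
    if sigma_fraction > 0:
        profile = profile * rng.lognormal(0.0, sigma_fraction, size=profile.shape)
    return pd.DataFrame(profile, index=g.index, columns=fracs.astype(int))


def _jittered_calibration(config: SimConfig, rng: np.random.Generator):
    times = config.reference_peak_times()
    if config.peak_jitter_sigma > 0:
        times = np.sort(times * rng.lognormal(0.0, config.peak_jitter_sigma,
                                              size=times.size))
    return times, fit_ribosome_calibration(times, first_count=1)


def _trace_for(config: SimConfig, peak_times: np.ndarray) -> A260Trace:
    total = config.n_fractions * config.fraction_time_s
    t = np.arange(0.0, total + 1.0, 1.0)
    y = 0.30 * np.exp(-t / 120.0) + 0.02  # UV-absorbing material at the top
    widths = 8.0 + 1.5 * np.arange(peak_times.size)
    heights = 0.9 * 0.70 ** np.arange(peak_times.size)
    for tc, h, w in zip(peak_times, heights, widths):
        y = y + h * np.exp(-0.5 * ((t - tc) / w) ** 2)
    return A260Trace(times=t, absorbance=y)


def simulate_gradient_run(truth: SimTruth, config: SimConfig, replicate: int,
                          condition: str) -> GradientRun:
    """Simulate one gradient, its A260 trace, and its encoded array.

    The per-oligo ``truth_table`` records the noiseless encoded chain
    (pooled log2 ratio -> position -> time -> average ribosome number) under
    this gradient's own calibration; with all noise at zero the decode must
    reproduce it exactly.
    """
    if condition not in ("untreated", "treated"):
        raise ValueError("condition must be 'untreated' or 'treated'")
    if not 1 <= replicate <= config.n_replicates:
        raise ValueError("replicate out of range for this config")
    scheme = config.scheme()
    geom = config.geometry()
    rng = stream(config.seed, "gradient", replicate, condition)
    peak_times, calib = _jittered_calibration(config, rng)
    trace = _trace_for(config, peak_times)
    profiles = _profiles_for(truth, condition, calib, geom, rng, config.sigma_fraction)

    a = scheme.a
    p = profiles.to_numpy()
    amount_a = p @ a
    amount_b = p @ (1.0 - a)
    true_ratio = np.log2(amount_a / amount_b)

    # noiseless truth chain, per gene then expanded per oligo
    from .decode import position_to_time, ratio_to_position
    pos, _, _ = ratio_to_position(true_ratio, scheme)
    t_mid = position_to_time(pos, geom)
    true_k = time_to_ribosomes(calib, t_mid)

    oligo_map = truth.oligo_map()
    gene_row = pd.Series(np.arange(len(profiles)), index=profiles.index)
    rows = gene_row.reindex(oligo_map.to_numpy()).to_numpy()
    n_feat = rows.size

    measured = true_ratio[rows] + (
        rng.normal(0.0, config.sigma_array, size=n_feat) if config.sigma_array > 0
        else 0.0)
    total_mass = amount_a[rows] + amount_b[rows]
    intensity = 2000.0 * total_mass
    cy5 = intensity * np.exp2(measured) / (1.0 + np.exp2(measured))
    cy3 = intensity - cy5

    fail = rng.random(n_feat) < config.quality_fail_rate
    pixel_r = np.where(fail, rng.uniform(0.20, 0.59, n_feat),
                       rng.uniform(0.75, 0.995, n_feat))
    ib5 = np.where(fail, rng.uniform(0.5, 2.4, n_feat),
                   rng.lognormal(np.log(12.0), 0.4, n_feat))
    ib3 = np.where(fail, rng.uniform(0.5, 2.4, n_feat),
                   rng.lognormal(np.log(12.0), 0.4, n_feat))

    features = pd.DataFrame({
        "feature_id": oligo_map.index,
        "gene_id": oligo_map.to_numpy(),
        "transcript_id": [f"{g}_tx" for g in oligo_map.to_numpy()],
        "cy5": cy5, "cy3": cy3,
        "log2_ratio": measured,
        "pixel_r": pixel_r, "ib_cy5": ib5, "ib_cy3": ib3,
        "is_control": False, "control_fraction": np.nan,
    })

    dope = assign_doping_controls(scheme, config.controls_per_fraction,
                                  config.control_mass_pg)
    nc = len(dope.controls)
    ctl_true = dope.controls["expected_log2_ratio"].to_numpy()
    ctl_meas = ctl_true + (rng.normal(0.0, config.sigma_array, size=nc)
                           if config.sigma_array > 0 else 0.0)
    ctl_int = np.full(nc, 2000.0 * config.control_mass_pg / 100.0)
    ctl5 = ctl_int * np.exp2(ctl_meas) / (1.0 + np.exp2(ctl_meas))
    controls = pd.DataFrame({
        "feature_id": dope.controls["control_id"],
        "gene_id": dope.controls["control_id"],
        "transcript_id": dope.controls["control_id"],
        "cy5": ctl5, "cy3": ctl_int - ctl5,
        "log2_ratio": ctl_meas,
        "pixel_r": rng.uniform(0.9, 0.999, nc),
        "ib_cy5": rng.lognormal(np.log(20.0), 0.3, nc),
        "ib_cy3": rng.lognormal(np.log(20.0), 0.3, nc),
        "is_control": True,
        "control_fraction": dope.controls["fraction"].astype(float),
    })
    table = pd.concat([features, controls], ignore_index=True)

    truth_table = pd.DataFrame({
        "feature_id": oligo_map.index,
        "gene_id": oligo_map.to_numpy(),
        "true_log2_ratio": true_ratio[rows],
        "true_position": pos[rows],
        "true_midpoint_time_s": np.asarray(t_mid)[rows],
        "true_avg_ribosomes": np.asarray(true_k)[rows],
    })
    return GradientRun(replicate=replicate, condition=condition, trace=trace,
                       geometry=geom, peak_times=peak_times, calibration=calib,
                       profiles=profiles, feature_table=table, truth_table=truth_table)


@dataclass(frozen=True)
class QpcrRun:
    """Per-fraction qPCR measurements on a dedicated gradient for one condition."""

    condition: str
    geometry: GradientGeometry
    peak_times: np.ndarray
    calibration: RibosomeCalibration
    table: pd.DataFrame  # gene, condition, fraction, mean, se, control_mean, control_se


def simulate_qpcr_run(truth: SimTruth, config: SimConfig, condition: str,
                      gene_ids=None) -> QpcrRun:
    """qPCR the fractions of an independent gradient for a gene panel.

    Triplicate-reaction means per fraction with configured CV, plus a
    doping-control reaction per fraction; the gradient carries its own peak
    jitter, so the oracle must use this run's calibration.
    """
    geom = config.geometry()
    rng = stream(config.seed, "qpcr", condition)
    peak_times, calib = _jittered_calibration(config, rng)
    if gene_ids is None:
        gene_ids = truth.gene_ids[: min(9, len(truth.gene_ids))]
    sub = SimTruth(genes=truth.genes.loc[gene_ids], config=truth.config)
    profiles = _profiles_for(sub, condition, calib, geom, rng, 0.0)
    rows = []
    cv = config.qpcr_cv
    for gid in gene_ids:
        base = profiles.loc[gid].to_numpy()
        raw = 50.0 * base
        ctl = np.full(base.size, 5.0)
        if cv > 0:
            raw = raw * rng.lognormal(0.0, cv, base.size)
            ctl = ctl * rng.lognormal(0.0, cv, base.size)
        raw_se = raw * cv / np.sqrt(3.0)
        ctl_se = ctl * cv / np.sqrt(3.0)
        for f in range(base.size):
            rows.append({"gene": gid, "condition": condition, "fraction": f + 1,
                         "mean": raw[f], "se": raw_se[f],
                         "control_mean": ctl[f], "control_se": ctl_se[f]})
    return QpcrRun(condition=condition, geometry=geom, peak_times=peak_times,
                   calibration=calib, table=pd.DataFrame(rows))


#: Known log2 concentration ratios of the abundance-array spike-in set.
ABUNDANCE_SPIKE_LEVELS = (-2.0, -1.0, 0.0, 1.0, 2.0)


def simulate_abundance_run(truth: SimTruth, config: SimConfig, replicate: int,
                           condition: str):
    """Simulate one abundance array (sample vs universal reference).

    The reference channel is the per-gene geometric mean of the two
    conditions; each array applies its own affine distortion (dye offset and
    slope compression) which the spike-in regression must undo.  Returns
    ``(table, spike_expected)``.
    """
    rng = stream(config.seed, "abundance", replicate, condition)
    g = truth.genes
    ref = np.sqrt(g["abundance_untreated"] * g["abundance_treated"])
    true = np.log2(g[f"abundance_{condition}"] / ref)
    offset = rng.uniform(-0.4, 0.4)
    slope = rng.uniform(0.85, 1.1) if config.sigma_abundance_array > 0 else 1.0
    oligo_map = truth.oligo_map()
    gene_row = pd.Series(np.arange(len(g)), index=g.index)
    rows = gene_row.reindex(oligo_map.to_numpy()).to_numpy()
    noise = (rng.normal(0.0, config.sigma_abundance_array, rows.size)
             if config.sigma_abundance_array > 0 else 0.0)
    measured = slope * true.to_numpy()[rows] + offset + noise
    gene_rows = pd.DataFrame({
        "feature_id": oligo_map.index,
        "gene_id": oligo_map.to_numpy(),
        "log2_ratio": measured,
    })
    spike_expected = {}
    spike_rows = []
    for level in ABUNDANCE_SPIKE_LEVELS:
        for i in range(3):
            fid = f"SPIKE_{level:+.0f}_{i + 1}"
            spike_expected[fid] = level
            noise_s = (rng.normal(0.0, 0.05) if config.sigma_abundance_array > 0 else 0.0)
            spike_rows.append({"feature_id": fid, "gene_id": fid,
                               "log2_ratio": slope * level + offset + noise_s})
    table = pd.concat([gene_rows, pd.DataFrame(spike_rows)], ignore_index=True)
    return table, spike_expected


def simulate_psilac(truth: SimTruth, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward and reverse peptide ratio tables for a protein subset.

    Protein-level log2 truth is ``c_t * dTranslation + c_a * dAbundance``
    plus Gaussian noise; each protein yields 1..max_peptides peptides with
    per-peptide noise and seeded identification-probability / quality fields.
    The reverse table stores ratios in untreated:treated orientation and each
    direction carries its own loading bias, removed later by median
    centering.  Returns ``(forward, reverse)``.
    """
    rng = stream(config.seed, "psilac")
    n_prot = min(config.n_psilac_proteins, len(truth.gene_ids))
    gene_ids = pd.Index(rng.choice(truth.gene_ids.to_numpy(), size=n_prot, replace=False))
    dt = truth.delta_translation().reindex(gene_ids).to_numpy()
    da = truth.delta_abundance().reindex(gene_ids).to_numpy()
    c_t, c_a = config.protein_coupling
    prot_truth = c_t * dt + c_a * da + (
        rng.normal(0.0, config.sigma_protein, n_prot) if config.sigma_protein > 0 else 0.0)

    tables = []
    for direction, sign, bias in (("forward", 1.0, 0.15), ("reverse", -1.0, -0.10)):
        rows = []
        n_peps = rng.integers(1, config.max_peptides + 1, size=n_prot)
        for gid, pt, k in zip(gene_ids, prot_truth, n_peps):
            pep_noise = (rng.normal(0.0, config.sigma_peptide, k)
                         if config.sigma_peptide > 0 else np.zeros(k))
            log2r = sign * pt + pep_noise + bias
            prob = np.where(rng.random(k) < config.peptide_lowprob_rate,
                            rng.uniform(0.5, 0.949, k), rng.uniform(0.95, 1.0, k))
            quality = rng.random(k) >= config.peptide_lowquality_rate
            unique = rng.random(k) >= 0.05
            for j in range(k):
                rows.append({"peptide": f"{gid}_{direction[0]}pep{j + 1}",
                             "protein": f"P_{gid}", "gene": gid,
                             "unique": bool(unique[j]), "prob": float(prob[j]),
                             "ratio_mh": float(np.exp2(log2r[j])),
                             "quality_ok": bool(quality[j]),
                             "direction": direction})
        tables.append(pd.DataFrame(rows))
    return tables[0], tables[1]
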