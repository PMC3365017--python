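"""Decoding measured two-color array ratios into average ribosome numbers.

One encoded array corresponds to one (replicate, condition) gradient.  The
decode chain per non-control feature is

    measured log2 ratio
      -> dye calibration (regression against the doping controls)
      -> fractional gradient position (inversion of the per-fraction
         expected log2 ratios)
      -> elution time (linear interpolation between fraction midpoints)
      -> average ribosome number (time calibration from the A260 peaks).

Abundance arrays (sample vs. universal reference) are normalized the same
way against spike-ins doped at known concentration ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import DopingControlSet, EncodingScheme
from .gradient import GradientGeometry, RibosomeCalibration, time_to_ribosomes

__all__ = [
    "ARRAY_COLUMNS",
    "DyeCalibration",
    "validate_feature_table",
    "quality_filter",
    "fit_dye_calibration",
    "ratio_to_position",
    "position_to_time",
    "decode_experiment",
    "normalize_abundance",
]

#: Required columns of an array feature table (tab-delimited on disk).
ARRAY_COLUMNS = ["feature_id", "gene_id", "transcript_id", "cy5", "cy3",
                 "log2_ratio", "pixel_r", "ib_cy5", "ib_cy3", "is_control",
                 "control_fraction"]

#: Feature-quality thresholds: pixel-level Cy5~Cy3 regression correlation,
#: and intensity/background ratio required in at least one channel.
MIN_PIXEL_REGRESSION_R = 0.6
MIN_INTENSITY_OVER_BACKGROUND = 2.5


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ARRAY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if table["feature_id"].duplicated().any():
        raise ValueError("feature_id must be unique within an array")
    return table


@dataclass(frozen=True)
class DyeCalibration:
    """Affine fit of measured control log2 ratios on their expected values.

    ``calibrate`` applies the inverse map (measured - intercept) / slope so
    that calibrated control ratios land on the per-fraction expected scale.
    """

    slope: float
    intercept: float
    r_squared: float
    n_controls: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("dye calibration slope must be positive")

    def calibrate(self, measured_log2_ratio):
        return (np.asarray(measured_log2_ratio, dtype=float) - self.intercept) / self.slope


def quality_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop features failing both quality criteria; log a reason per dropped row.

    A feature is kept when its pixel regression correlation is >= 0.6 OR its
    intensity/background ratio is >= 2.5 in at least one channel (both
    thresholds inclusive).  Returns ``(kept, rejected)``; the rejected frame
    carries a ``reason`` column and the two frames partition the input.
    """
    validate_feature_table(table)
    for col in ("pixel_r", "ib_cy5", "ib_cy3"):
        if table[col].isna().any():
            raise ValueError(f"quality field '{col}' has missing values")
    r_ok = table["pixel_r"] >= MIN_PIXEL_REGRESSION_R
    ib_ok = (table[["ib_cy5", "ib_cy3"]].max(axis=1) >= MIN_INTENSITY_OVER_BACKGROUND)
    keep = r_ok | ib_ok
    kept = table.loc[keep].copy()
    rejected = table.loc[~keep].copy()
    rejected["reason"] = (
        f"pixel_r < {MIN_PIXEL_REGRESSION_R} and max(I/B) < {MIN_INTENSITY_OVER_BACKGROUND}"
    )
    return kept, rejected


def fit_dye_calibration(controls: pd.DataFrame, dope_set: DopingControlSet) -> DyeCalibration:
    """Regress measured control log2 ratios on the expected per-fraction ratios."""
    if controls.empty:
        raise ValueError("no control rows supplied")
    fractions = controls["control_fraction"].astype(int)
    if fractions.nunique() < 2:
        raise ValueError("controls from >= 2 distinct fractions are required")
    expected = dope_set.scheme.expected_log2_ratio(fractions.to_numpy())
    measured = controls["log2_ratio"].to_numpy(dtype=float)
    res = stats.linregress(expected, measured)
    return DyeCalibration(slope=float(res.slope), intercept=float(res.intercept),
                          r_squared=float(res.rvalue ** 2), n_controls=len(controls))


def ratio_to_position(calibrated_log2_ratio, scheme: EncodingScheme):
    """Invert the per-fraction expected ratios into a fractional position.

    Piecewise-linear inversion of f -> log2(a[f]/(1-a[f])) evaluated at the
    integer fractions.  Ratios outside the scheme's range clamp to 1 or
    n_fractions; the returned ``clamped`` mask flags them and the unclamped
    linear extrapolation is returned alongside.
    Returns ``(position, clamped, position_unclamped)``.
    """
    r = np.atleast_1d(np.asarray(calibrated_log2_ratio, dtype=float))
    grid = scheme.expected_log2_ratio()
    fracs = np.arange(1, scheme.n_fractions + 1, dtype=float)
    pos = np.interp(r, grid, fracs)
    clamped = (r < grid[0]) | (r > grid[-1])
    unclamped = pos.copy()
    below = r < grid[0]
    above = r > grid[-1]
    slope_lo = (fracs[1] - fracs[0]) / (grid[1] - grid[0])
    slope_hi = (fracs[-1] - fracs[-2]) / (grid[-1] - grid[-2])
    unclamped[below] = fracs[0] + (r[below] - grid[0]) * slope_lo
    unclamped[above] = fracs[-1] + (r[above] - grid[-1]) * slope_hi
    if np.isscalar(calibrated_log2_ratio) or np.ndim(calibrated_log2_ratio) == 0:
        return float(pos[0]), bool(clamped[0]), float(unclamped[0])
    return pos, clamped, unclamped


def position_to_time(position, geom: GradientGeometry):
    """Elution time at a fractional position via midpoint interpolation.

    Positions between integer fractions interpolate linearly between the
    fraction midpoint times; positions beyond the first or last midpoint
    extrapolate linearly.
    """
    p = np.asarray(position, dtype=float)
    mids = geom.midpoints()
    fracs = np.arange(1, geom.n_fractions + 1, dtype=float)
    t = np.interp(p, fracs, mids)
    lo = p < fracs[0]
    hi = p > fracs[-1]
    if geom.n_fractions > 1:
        t = np.where(lo, mids[0] + (p - fracs[0]) * (mids[1] - mids[0]), t)
        t = np.where(hi, mids[-1] + (p - fracs[-1]) * (mids[-1] - mids[-2]), t)
    return t if t.ndim else float(t)


def decode_experiment(table: pd.DataFrame, scheme: EncodingScheme,
                      dope_set: DopingControlSet, geom: GradientGeometry,
                      ribo_calib: RibosomeCalibration) -> pd.DataFrame:
    """Decode a quality-filtered encoded array into per-feature ribosome numbers.

    Returns one row per non-control feature with the full provenance chain:
    measured and calibrated log2 ratio, fractional position (with clamp flag
    and the unclamped value), interpolated elution time, and the continuous
    average ribosome number.
    """
    validate_feature_table(table)
    controls = table.loc[table["is_control"].astype(bool)]
    dye = fit_dye_calibration(controls, dope_set)
    genes = table.loc[~table["is_control"].astype(bool)].copy()
    calibrated = dye.calibrate(genes["log2_ratio"].to_numpy(dtype=float))
    pos, clamped, unclamped = ratio_to_position(calibrated, scheme)
    t = position_to_time(pos, geom)
    genes["calibrated_log2_ratio"] = calibrated
    genes["position"] = pos
    genes["position_unclamped"] = unclamped
    genes["clamped"] = clamped
    genes["midpoint_time_s"] = t
    genes["avg_ribosomes"] = time_to_ribosomes(ribo_calib, t)
    cols = ["feature_id", "gene_id", "transcript_id", "log2_ratio",
            "calibrated_log2_ratio", "position", "position_unclamped", "clamped",
            "midpoint_time_s", "avg_ribosomes"]
    return genes[cols].reset_index(drop=True)


def normalize_abundance(table: pd.DataFrame,
                        spike_expected: Mapping[str, float]) -> tuple[pd.DataFrame, DyeCalibration]:
    """Normalize an abundance array (sample vs reference) against spike-ins.

    ``spike_expected`` maps spike feature_ids to their known log2
    concentration ratios; at least two distinct levels are required.  The
    affine fit of measured on expected spike ratios is inverted and applied
    to every gene row, so spike-ins doped 1:1 map to 0 after correction.
    Returns the gene rows with a ``log2_abundance_ratio`` column, and the fit.
    """
    if "feature_id" not in table.columns or "log2_ratio" not in table.columns:
        raise ValueError("abundance table needs feature_id and log2_ratio columns")
    spikes = table.loc[table["feature_id"].isin(spike_expected)].copy()
    if spikes.empty:
        raise ValueError("no spike-in rows found in the table")
    expected = spikes["feature_id"].map(spike_expected).to_numpy(dtype=float)
    if np.unique(expected).size < 2:
        raise ValueError("spike-ins at >= 2 distinct known ratios are required")
    measured = spikes["log2_ratio"].to_numpy(dtype=float)
    res = stats.linregress(expected, measured)
    cal = DyeCalibration(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2), n_controls=len(spikes))
    genes = table.loc[~table["feature_id"].isin(spike_expected)].copy()
    genes["log2_abundance_ratio"] = cal.calibrate(genes["log2_ratio"].to_numpy(dtype=float))
    return genes.reset_index(drop=True), cal
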