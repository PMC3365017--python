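"""Per-fraction qRT-PCR profiles and the explicit "encoding" oracle.

Traditional polysome profiling measures a transcript's distribution across
gradient fractions directly by qRT-PCR (triplicate reactions per fraction,
each fraction normalized by its own doping-control reaction, then rescaled so
the gradient sums to one).  Explicitly "encoding" such a profile — weighting
each fraction by the dye split it would have received and summing the two
theoretical channels — yields the Cy5/Cy3 ratio the array would have seen,
which makes the qPCR route a brute-force, array-free check of the decode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decode import position_to_time
from .encoding import EncodingScheme, pool_profile
from .gradient import GradientGeometry, RibosomeCalibration, time_to_ribosomes

__all__ = [
    "QpcrProfile",
    "normalize_qpcr_profile",
    "explicit_encode",
    "ratio_to_fraction_by_regression",
    "oracle_translation_change",
]


@dataclass(frozen=True)
class QpcrProfile:
    """Normalized per-fraction qPCR values for one gene in one condition.

    ``values`` sum to one across the gradient; ``errors`` are the standard
    errors propagated through the doping-control division (the final sum-to-1
    rescale is treated as exact).
    """

    gene_id: str
    condition: str
    values: np.ndarray
    errors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        e = np.asarray(self.errors, dtype=float)
        if v.ndim != 1 or v.size != e.size:
            raise ValueError("values and errors must be equal-length vectors")
        if np.any(v < 0) or np.any(e < 0):
            raise ValueError("values and errors must be nonnegative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("normalized qPCR values must sum to 1 per gradient")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "errors", e)

    @property
    def n_fractions(self) -> int:
        return self.values.size


def normalize_qpcr_profile(raw_means, raw_ses, control_means, control_ses,
                           gene_id: str = "", condition: str = "") -> QpcrProfile:
    """Divide by the doping-control reactions, then rescale to sum to one.

    Per fraction, value_f = raw_f / control_f; relative errors of the raw and
    control means combine in quadrature for the division.  The rescale to a
    unit sum applies the same factor to values and errors (reported as exact).
    """
    raw = np.asarray(raw_means, dtype=float)
    rse = np.asarray(raw_ses, dtype=float)
    ctl = np.asarray(control_means, dtype=float)
    cse = np.asarray(control_ses, dtype=float)
    if not (raw.shape == rse.shape == ctl.shape == cse.shape) or raw.ndim != 1:
        raise ValueError("all four inputs must be equal-length vectors")
    zero = np.flatnonzero(ctl <= 0)
    if zero.size:
        raise ValueError(f"zero/negative control mean in fraction {zero[0] + 1}")
    if np.any(raw < 0):
        raise ValueError("raw means must be nonnegative")
    value = raw / ctl
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(np.where(raw > 0, (rse / raw) ** 2, 0.0) + (cse / ctl) ** 2)
    err = value * rel
    total = value.sum()
    if total <= 0:
        raise ValueError("profile has zero total signal")
    return QpcrProfile(gene_id=gene_id, condition=condition,
                       values=value / total, errors=err / total)


def explicit_encode(profile: QpcrProfile, scheme: EncodingScheme) -> float:
    """Theoretical Cy5/Cy3 ratio of a qPCR profile under the encoding scheme.

    Multiplies each fraction's value by the share that would have been
    labeled with each dye and sums the two channels — the same pooled-sums
    formula applied by :func:`gradecode.encoding.pool_profile`.
    """
    amount_a, amount_b, _ = pool_profile(profile.values, scheme)
    return amount_a / amount_b


def ratio_to_fraction_by_regression(log2_ratio, scheme: EncodingScheme):
    """Map a log2 Cy5/Cy3 ratio to a fraction number via the expected-ratio line.

    Fits expected per-fraction log2 ratio = slope*fraction + intercept by
    least squares and inverts it.  For a scheme linear in log2 ratio this is
    exact and identical to the piecewise inversion used by the array decode.
    Out-of-range results clamp to [1, n_fractions].
    """
    fracs = np.arange(1, scheme.n_fractions + 1, dtype=float)
    res = stats.linregress(fracs, scheme.expected_log2_ratio())
    f = (np.asarray(log2_ratio, dtype=float) - res.intercept) / res.slope
    f = np.clip(f, 1.0, float(scheme.n_fractions))
    return f if f.ndim else float(f)


def oracle_translation_change(treated: QpcrProfile, untreated: QpcrProfile,
                              scheme: EncodingScheme,
                              geom_treated: GradientGeometry,
                              calib_treated: RibosomeCalibration,
                              geom_untreated: GradientGeometry | None = None,
                              calib_untreated: RibosomeCalibration | None = None) -> float:
    """log2 ratio of average ribosome numbers, treated over untreated.

    Each profile is explicitly encoded, expressed as a fraction number via
    the expected-ratio regression line, converted to a midpoint-interpolated
    elution time on its own gradient, and mapped to an average ribosome
    number with that gradient's own peak calibration (gradients are not
    perfectly superimposable, so each run carries its own calibration).
    """
    if treated.n_fractions != untreated.n_fractions:
        raise ValueError("profiles have mismatched fraction counts")
    if treated.n_fractions != scheme.n_fractions:
        raise ValueError("profile and scheme fraction counts differ")
    geom_untreated = geom_untreated or geom_treated
    calib_untreated = calib_untreated or calib_treated

    def _ribosomes(profile, geom, calib):
        ratio = np.log2(explicit_encode(profile, scheme))
        frac = ratio_to_fraction_by_regression(ratio, scheme)
        t = position_to_time(frac, geom)
        return time_to_ribosomes(calib, t)

    k_t = _ribosomes(treated, geom_treated, calib_treated)
    k_u = _ribosomes(untreated, geom_untreated, calib_untreated)
    if k_t <= 0 or k_u <= 0:
        raise ValueError("average ribosome number nonpositive; profile above monosome region")
    return float(np.log2(k_t / k_u))
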