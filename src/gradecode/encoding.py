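"""The two-pool dye encoding of gradient fractions.

Each of the collected fractions is split between pool A (labeled Cy5) and
pool B (labeled Cy3), with the pool-A share ``a[f]`` increasing strictly with
fraction number.  After both pools are hybridized to the same array, the
Cy5/Cy3 ratio of a transcript is the ratio of its pooled sums,

    amount_A = sum_f m_f * a[f],    amount_B = sum_f m_f * (1 - a[f]),

so a single two-color measurement reports the transcript's average position
in the gradient.  Synthetic doping-control mRNAs spiked into single fractions
at known mass reveal the per-fraction expected log2 ratio
``log2(a[f]/(1-a[f]))`` and anchor the dye calibration downstream.

The published pooling table is not reproduced here; by default the scheme is
a ramp linear in the expected log2 ratio (equivalently, logit-linear in the
pool-A share), which makes the per-fraction expected log2 ratio exactly
linear in fraction number — the property the regression-based ratio→fraction
mapping relies on.  A ramp linear in the proportion itself is available via
``ramp="proportion"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EncodingScheme",
    "DopingControlSet",
    "make_encoding_scheme",
    "assign_doping_controls",
    "pool_profile",
]


def _logit2(a: np.ndarray) -> np.ndarray:
    return np.log2(a / (1.0 - a))


@dataclass(frozen=True)
class EncodingScheme:
    """Per-fraction pool-A (Cy5) proportions; fraction f gets a[f-1]."""

    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.ndim != 1 or a.size < 2:
            raise ValueError("need proportions for at least two fractions")
        if np.any((a <= 0) | (a >= 1)):
            raise ValueError("proportions must lie strictly in (0, 1)")
        if not np.all(np.diff(a) > 0):
            raise ValueError("pool-A proportions must be strictly increasing")
        object.__setattr__(self, "a", a)

    @property
    def n_fractions(self) -> int:
        return self.a.size

    def expected_log2_ratio(self, fraction=None) -> np.ndarray:
        """Expected Cy5/Cy3 log2 ratio for given 1-based fraction(s), or all."""
        if fraction is None:
            return _logit2(self.a)
        f = np.asarray(fraction)
        return _logit2(self.a[f - 1])


@dataclass(frozen=True)
class DopingControlSet:
    """Spiked-in control mRNAs, each assigned to exactly one fraction.

    ``controls`` columns: control_id, fraction, mass_pg, expected_log2_ratio.
    """

    controls: pd.DataFrame
    scheme: EncodingScheme

    def __post_init__(self) -> None:
        required = {"control_id", "fraction", "mass_pg", "expected_log2_ratio"}
        missing = required - set(self.controls.columns)
        if missing:
            raise ValueError(f"control table missing columns: {sorted(missing)}")
        if self.controls["control_id"].duplicated().any():
            raise ValueError("each control must be assigned to exactly one fraction")
        present = set(self.controls["fraction"])
        expected = set(range(1, self.scheme.n_fractions + 1))
        if present != expected:
            raise ValueError("every fraction needs at least one doping control")

    def expected_ratio_of(self, control_id: str) -> float:
        row = self.controls.loc[self.controls["control_id"] == control_id]
        if row.empty:
            raise KeyError(control_id)
        return float(row["expected_log2_ratio"].iloc[0])


def make_encoding_scheme(n_fractions: int, a_min: float = 0.1, a_max: float = 0.9,
                         ramp: str = "log-ratio") -> EncodingScheme:
    """Build a monotone encoding scheme between two pool-A endpoints.

    ``ramp="log-ratio"`` (default) spaces fractions evenly in expected log2
    ratio; ``ramp="proportion"`` spaces them evenly in the proportion itself.
    Both are strictly monotone and share their endpoints, and for symmetric
    endpoints (a_min + a_max = 1) both put the middle fraction at 0.5.
    """
    if n_fractions < 2:
        raise ValueError("n_fractions must be >= 2")
    if not 0 < a_min < a_max < 1:
        raise ValueError("need 0 < a_min < a_max < 1")
    if ramp == "proportion":
        a = np.linspace(a_min, a_max, n_fractions)
    elif ramp == "log-ratio":
        r = np.linspace(_logit2(np.array(a_min)), _logit2(np.array(a_max)), n_fractions)
        a = 1.0 / (1.0 + 2.0 ** (-r))
    else:
        raise ValueError("ramp must be 'log-ratio' or 'proportion'")
    return EncodingScheme(a)


def assign_doping_controls(scheme: EncodingScheme, controls_per_fraction: int = 4,
                           mass_pg: float = 100.0) -> DopingControlSet:
    """Assign ``controls_per_fraction`` distinct spike-ins to every fraction.

    Defaults follow the experimental design: 100 pg of each in-vitro
    transcribed control mRNA, 4–6 controls per fraction.
    """
    if controls_per_fraction < 1:
        raise ValueError("controls_per_fraction must be >= 1")
    rows = []
    for f in range(1, scheme.n_fractions + 1):
        exp = float(scheme.expected_log2_ratio(f))
        for i in range(controls_per_fraction):
            rows.append({"control_id": f"DOPE_F{f:02d}_{i + 1}", "fraction": f,
                         "mass_pg": float(mass_pg), "expected_log2_ratio": exp})
    return DopingControlSet(pd.DataFrame(rows), scheme)


def pool_profile(profile, scheme: EncodingScheme):
    """Pool a per-fraction abundance profile into the two dye channels.

    Returns ``(amount_A, amount_B, true_log2_ratio)`` where the amounts are
    the Cy5/Cy3 pooled sums and ``true_log2_ratio = log2(amount_A/amount_B)``.
    Mass is conserved: amount_A + amount_B equals the total profile mass.
    """
    m = np.asarray(profile, dtype=float)
    if m.ndim != 1 or m.size != scheme.n_fractions:
        raise ValueError("profile length must equal the scheme's fraction count")
    if np.any(m < 0):
        raise ValueError("profile must be nonnegative")
    if not np.any(m > 0):
        raise ValueError("transcript absent: all-zero profile cannot be pooled")
    amount_a = float(np.dot(m, scheme.a))
    amount_b = float(np.dot(m, 1.0 - scheme.a))
    return amount_a, amount_b, float(np.log2(amount_a / amount_b))
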