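"""SAM-style moderated statistic, permutation FDR, collapsing, classification."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from gradecode.sam import (TranslationDifferential, classify_translation_only,
                           collapse_oligos, mean_center_columns, sam_fdr,
                           sam_statistic)

LABELS_3V3 = ["untreated"] * 3 + ["treated"] * 3


def brute_force_qvalues(x, n1):
    """Exhaustive-enumeration q-values, written independently of sam_fdr.

    Enumerates every assignment of n1 columns to the reference class,
    recomputes d with the observed s0, and applies the threshold/median
    FDR definition literally with python loops.
    """
    x = mean_center_columns(np.asarray(x, dtype=float))
    n = x.shape[1]

    def d_stat(ref_cols, s0):
        ref = np.array([c in ref_cols for c in range(n)])
        xt, xu = x[:, ~ref], x[:, ref]
        diff = xt.mean(1) - xu.mean(1)
        ss = ((xt - xt.mean(1, keepdims=True)) ** 2).sum(1) + \
             ((xu - xu.mean(1, keepdims=True)) ** 2).sum(1)
        s = np.sqrt((1 / xt.shape[1] + 1 / xu.shape[1]) * ss / (n - 2))
        return diff / (s + s0)

    ref0 = tuple(range(n1))
    ref = np.array([c in ref0 for c in range(n)])
    xt, xu = x[:, ~ref], x[:, ref]
    ss = ((xt - xt.mean(1, keepdims=True)) ** 2).sum(1) + \
         ((xu - xu.mean(1, keepdims=True)) ** 2).sum(1)
    s = np.sqrt((1 / xt.shape[1] + 1 / xu.shape[1]) * ss / (n - 2))
    s0 = float(np.median(s))

    d_obs = d_stat(ref0, s0)
    perms = [d_stat(c, s0) for c in combinations(range(n), n1)]
    pooled = np.concatenate(perms)
    q1, q3 = np.percentile(pooled, [25, 75])
    pi0 = min(1.0, sum(1 for d in d_obs if q1 <= d <= q3) /
              max(1, int(0.5 * len(d_obs))))
    qs = []
    for i in range(len(d_obs)):
        best = np.inf
        for j in range(len(d_obs)):
            tau = abs(d_obs[j])
            if tau > abs(d_obs[i]):
                continue  # threshold does not call row i
            obs_calls = sum(1 for k in range(len(d_obs)) if abs(d_obs[k]) >= tau)
            false = np.median([sum(1 for v in p if abs(v) >= tau) for p in perms])
            best = min(best, 100.0 * pi0 * false / obs_calls)
        qs.append(min(100.0, max(0.0, best)))
    return np.array(d_obs), np.array(qs)


class TestStatistic:
    def test_zero_variance_row(self):
        x = np.array([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]])
        d, s, s0 = sam_statistic(x, LABELS_3V3, s0=0.1, center=False)
        assert d[0] == pytest.approx(10.0)
        assert s[0] == 0.0

    def test_equal_class_means_give_zero(self):
        x = np.array([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]])
        d, _, _ = sam_statistic(x, LABELS_3V3, s0=0.1, center=False)
        assert d[0] == pytest.approx(0.0)

    def test_null_matrix_median_d_near_zero(self, rng):
        x = rng.normal(0, 1, (2000, 6))
        d, _, _ = sam_statistic(x, LABELS_3V3)
        assert abs(np.median(d)) <= 0.05

    def test_one_sample_class_rejected(self):
        with pytest.raises(ValueError):
            sam_statistic(np.zeros((5, 4)), ["untreated", "treated", "treated",
                                             "treated"])

    def test_mean_centering_idempotent(self, rng):
        x = rng.normal(2.0, 1.0, (50, 6))
        once = mean_center_columns(x)
        assert np.allclose(mean_center_columns(once), once)


class TestFdr:
    def test_all_null_call_count_bounded(self, rng):
        x = rng.normal(0, 0.3, (2000, 6))
        _, q, _ = sam_fdr(x, LABELS_3V3, "all")
        assert (q <= 10).sum() <= 60

    def test_spiked_rows_detected(self, rng):
        x = rng.normal(0, 0.3, (2000, 6))
        x[:200, 3:] += 1.5
        _, q, _ = sam_fdr(x, LABELS_3V3, "all")
        assert (q[:200] <= 10).mean() >= 0.8

    def test_relabeled_null_dominance(self, rng):
        x = rng.normal(0, 0.3, (2000, 6))
        x[:200, 3:] += 1.5
        _, q, _ = sam_fdr(x, LABELS_3V3, "all")
        mixed = x[:, [0, 3, 1, 4, 2, 5]]  # classes scrambled: relabeled null
        _, q_null, _ = sam_fdr(mixed, LABELS_3V3, "all")
        assert (q_null <= 10).sum() <= (q <= 10).sum()

    def test_label_swap_negates_d_and_preserves_q(self, rng):
        x = rng.normal(0, 1, (300, 6))
        x[:30, 3:] += 1.0
        d1, q1, _ = sam_fdr(x, LABELS_3V3, "all")
        d2, q2, _ = sam_fdr(x, ["treated"] * 3 + ["untreated"] * 3, "all")
        assert np.allclose(d2, -d1)
        assert np.allclose(q2, q1)

    def test_q_monotone_in_abs_d(self, rng):
        x = rng.normal(0, 1, (500, 6))
        x[:50, 3:] += 1.2
        d, q, _ = sam_fdr(x, LABELS_3V3, "all")
        order = np.argsort(-np.abs(d))
        assert np.all(np.diff(q[order]) >= -1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration_2v2(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (8, 4))
        x[:2, 2:] += 2.0
        labels = ["untreated"] * 2 + ["treated"] * 2
        d, q, _ = sam_fdr(x, labels, "all")
        d_ref, q_ref = brute_force_qvalues(x, 2)
        assert np.allclose(d, d_ref)
        assert np.allclose(q, q_ref)

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            sam_fdr(rng.normal(0, 1, (10, 6)), LABELS_3V3, 1, seed=0)


class TestCollapse:
    def test_mean_and_max_change_modes(self):
        vals = pd.Series({"o1": -1.0, "o2": -2.0})
        mapping = pd.Series({"o1": "g", "o2": "g"})
        assert collapse_oligos(vals, mapping, "mean")["g"] == pytest.approx(-1.5)
        assert collapse_oligos(vals, mapping, "max_change")["g"] == pytest.approx(-2.0)

    def test_single_oligo_identity(self):
        vals = pd.Series({"o1": 0.7})
        mapping = pd.Series({"o1": "g"})
        for mode in ("mean", "max_change"):
            assert collapse_oligos(vals, mapping, mode)["g"] == pytest.approx(0.7)

    def test_max_change_uses_supplied_change(self):
        vals = pd.Series({"o1": 0.1, "o2": 0.9})
        mapping = pd.Series({"o1": "g", "o2": "g"})
        change = pd.Series({"o1": -3.0, "o2": 0.5})
        out = collapse_oligos(vals, mapping, "max_change", change_for_max=change)
        assert out["g"] == pytest.approx(0.1)   # o1 has the larger |change|

    def test_unmapped_oligo_listed(self):
        with pytest.raises(ValueError, match="o2"):
            collapse_oligos(pd.Series({"o1": 1.0, "o2": 2.0}),
                            pd.Series({"o1": "g"}))


class TestClassification:
    def _diff(self, qs):
        return pd.DataFrame({"q": qs})

    def test_at_mean_is_translation_only(self):
        diff = self._diff(pd.Series({"g1": 1.0, "g2": 50.0, "g3": 50.0, "g4": 50.0}))
        da = pd.Series({"g1": 0.0, "g2": 1.0, "g3": -1.0, "g4": 0.0})
        out = classify_translation_only(diff, da)
        assert out["g1"] == "translation_only"

    def test_outside_one_sd_is_both(self):
        genes = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        da = pd.Series(rng.normal(0, 0.5, 40), index=genes)
        q = pd.Series(50.0, index=genes)
        q["g0"] = 1.0
        da["g0"] = da.mean() + 1.5 * da.std(ddof=1)
        out = classify_translation_only(self._diff(q), da)
        assert out["g0"] == "both"

    def test_gene_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_translation_only(self._diff(pd.Series({"g1": 1.0})),
                                      pd.Series({"g2": 0.0}))


class TestModelInterface:
    def test_fit_results_and_summary(self, rng):
        x = rng.normal(0, 0.5, (100, 6))
        x[:10, 3:] += 2.0
        frame = pd.DataFrame(x, columns=pd.MultiIndex.from_product(
            [["untreated", "treated"], [1, 2, 3]]))
        res = TranslationDifferential.from_dataframe(frame).fit()
        assert res.n_significant >= 8
        assert set(res.table.columns) >= {"log2_change", "d", "q", "significant"}
        text = res.summary()
        assert "significant rows" in text and "s0" in text
        lf = res.local_fdr()
        assert len(lf) == 100 and (lf >= 0).all() and (lf <= 100).all()

    def test_incomplete_rows_rejected(self):
        x = np.full((3, 6), 1.0)
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            TranslationDifferential(x, LABELS_3V3)
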