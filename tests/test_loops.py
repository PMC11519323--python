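import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tadshift import synth
from tadshift.balance import ice_balance, select_valid_bins
from tadshift.loops import (
    anchor_overlap_fraction,
    call_loops,
    compare_loop_sets,
    distance_expected_model,
    loop_significance,
)

from conftest import make_bins, make_map


def binom_tail_oracle(obs, n, p):
    """Brute-force upper-tail sum P(X >= obs) via a stable term recurrence."""
    if obs <= 0:
        return 1.0
    k = int(obs)
    log_term = (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )
    term = math.exp(log_term)
    total = 0.0
    for kk in range(k, n + 1):
        total += term
        if term < 1e-30 and kk > n * p:
            break
        term *= (n - kk) / (kk + 1) * (p / (1 - p))
    return min(total, 1.0)


def bh_oracle(pvals):
    """Hand step-up Benjamini-Hochberg."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def pava_nonincreasing(y, w):
    """Pool-adjacent-violators for a non-increasing fit."""
    blocks = [[yi, wi] for yi, wi in zip(y, w)]
    out = []
    for b in blocks:
        out.append(b)
        while len(out) > 1 and out[-2][0] < out[-1][0]:
            y2, w2 = out.pop()
            y1, w1 = out.pop()
            out.append([(y1 * w1 + y2 * w2) / (w1 + w2), w1 + w2])
    fit = []
    i = 0
    for val, wsum in out:
        # expand pooled blocks back to member positions
        acc = 0.0
        while acc < wsum - 1e-9:
            fit.append(val)
            acc += w[i]
            i += 1
    return np.array(fit)


def distance_only_map(n=120, profile=None):
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    if profile is None:
        vals = 1000.0 / (d + 1.0)
    else:
        vals = profile[np.minimum(d, len(profile) - 1)].astype(float)
    return make_map(np.round(vals))


class TestDecayModel:
    def test_distance_only_counts_give_proportional_probabilities(self):
        cmap = distance_only_map()
        biases = np.ones(cmap.n_bins)
        # one occupancy bin per distinct distance: no pooling, pure profile
        model = distance_expected_model(
            cmap, biases, 4000, 40_000, n_occupancy_bins=19, bias_refine_iter=0
        )
        profile = np.round(1000.0 / (model.distances_bp / 2000 + 1))
        ratio = model.prob / profile
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_probabilities_sum_to_one_over_modeled_pairs(self):
        cmap = distance_only_map()
        model = distance_expected_model(cmap, np.ones(cmap.n_bins), 4000, 60_000, 10)
        assert (model.prob * model.n_pairs).sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotonic_matches_pava_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 10, 10)
        w = rng.integers(1, 20, 10).astype(float)
        from sklearn.isotonic import IsotonicRegression

        iso = IsotonicRegression(increasing=False)
        ours = iso.fit_transform(np.arange(10.0), y, sample_weight=w)
        np.testing.assert_allclose(ours, pava_nonincreasing(y, w), atol=1e-9)

    def test_too_few_distances_rejected(self):
        cmap = distance_only_map(n=20)
        with pytest.raises(ValueError, match="distinct distances"):
            distance_expected_model(cmap, np.ones(20), 4000, 10_000, 40)


class TestSignificance:
    def test_zero_observed_p_is_one(self):
        cmap = distance_only_map(n=60)
        cmap.counts[10, 20] = cmap.counts[20, 10] = 0
        model = distance_expected_model(
            cmap, np.ones(60), 4000, 40_000, 5, bias_refine_iter=0
        )
        table = loop_significance(cmap, model, np.ones(60))
        row = table[(table.bin_i == 10) & (table.bin_j == 20)]
        assert row["p_value"].iloc[0] == pytest.approx(1.0)

    def test_binomial_tail_matches_exact_summation(self):
        for n, p, obs in [(1000, 0.001, 5), (5000, 0.002, 25), (200, 0.05, 3)]:
            ours = float(stats.binom.sf(obs - 1, n, p))
            assert ours == pytest.approx(binom_tail_oracle(obs, n, p), abs=1e-10)

    def test_bh_small_example_matches_hand_oracle(self):
        p = [0.01, 0.02, 0.04]
        from statsmodels.stats.multitest import multipletests

        q = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        np.testing.assert_allclose(q, [0.03, 0.03, 0.04], atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    def test_bh_matches_oracle_property(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh_oracle(pvals), atol=1e-12)

    def test_q_ge_p_always(self):
        cmap = distance_only_map(n=80)
        model = distance_expected_model(cmap, np.ones(80), 4000, 40_000, 5)
        table = loop_significance(cmap, model, np.ones(80))
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()

    def test_planted_loop_detected_single_seed(self):
        cfg = synth.demo_config("null", n_bins=300, depth=6e5, seed=2, with_loops=True)
        cmap, truth = synth.simulate(cfg)
        bmap, _ = ice_balance(cmap.with_mask(select_valid_bins(cmap)))
        raw = cmap.with_mask(bmap.mask)
        model = distance_expected_model(raw, bmap.biases)
        table = loop_significance(raw, model, model.biases)
        called = call_loops(table)
        hits = {
            (i, j)
            for i, j in zip(called["bin_i"], called["bin_j"])
        }
        recall = np.mean([t in hits for t in truth.loops])
        assert recall >= 0.8
        assert (called["distance"] >= 4000).all()
        assert (called["distance"] <= 100_000).all()


class TestCallAndCompare:
    def make_table(self, rows):
        return pd.DataFrame(
            rows, columns=["bin_i", "bin_j", "distance", "q_value", "size_class"]
        )

    def test_strict_q_threshold(self):
        t = self.make_table(
            [(0, 5, 10_000, 0.049, ""), (1, 6, 10_000, 0.050, "")]
        )
        out = call_loops(t)
        assert len(out) == 1 and out["q_value"].iloc[0] == 0.049

    def test_size_class_boundaries(self):
        t = self.make_table(
            [
                (0, 4, 8000, 0.0, ""),
                (0, 5, 10_000, 0.0, ""),
                (0, 25, 50_000, 0.0, ""),
                (0, 26, 52_000, 0.0, ""),
            ]
        )
        out = call_loops(t)
        assert list(out["size_class"]) == ["<10kb", "10-50kb", "10-50kb", ">50kb"]

    def test_identical_sets_fully_shared(self):
        t = self.make_table([(0, 5, 10_000, 0.0, "10-50kb")])
        flagged, fracs = compare_loop_sets(t, t.copy())
        assert flagged["shared"].all()
        assert fracs["10-50kb"] == 1.0

    def test_disjoint_sets_unshared(self):
        a = self.make_table([(0, 5, 10_000, 0.0, "10-50kb")])
        b = self.make_table([(50, 80, 60_000, 0.0, ">50kb")])
        flagged, fracs = compare_loop_sets(a, b)
        assert not flagged["shared"].any()

    def test_tolerance_one_bin(self):
        a = self.make_table([(10, 20, 20_000, 0.0, "10-50kb")])
        b = self.make_table([(11, 21, 20_000, 0.0, "10-50kb")])
        assert compare_loop_sets(a, b, tol_bins=1)[0]["shared"].all()
        assert not compare_loop_sets(a, b, tol_bins=0)[0]["shared"].any()


class TestAnchorOverlap:
    def test_fraction_examples(self):
        bins = make_bins(30)
        loops = pd.DataFrame(
            {"bin_i": [2, 4, 6], "bin_j": [10, 10, 12]}
        )  # unique anchors: 2, 4, 6, 10, 12
        genes = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 4000, "end": 6000},  # bin 2
                {"chrom": "chr1", "start": 8500, "end": 9000},  # bin 4
                {"chrom": "chr1", "start": 20_500, "end": 21_000},  # bin 10
            ]
        )
        frac = anchor_overlap_fraction(loops, genes, bins)
        assert frac == pytest.approx(3 / 5)
        assert anchor_overlap_fraction(loops, genes.iloc[:0], bins) == 0.0

    def test_all_anchors_in_genes(self):
        bins = make_bins(10)
        loops = pd.DataFrame({"bin_i": [1], "bin_j": [5]})
        genes = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 20_000}])
        assert anchor_overlap_fraction(loops, genes, bins) == 1.0
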