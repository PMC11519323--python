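import itertools

import numpy as np
import pandas as pd
import pytest

from tadshift import synth
from tadshift.aggregate import (
    decay_curve,
    expression_quintile_anchor_profiles,
    locus_pileup,
    point_profile,
    rank_group_compare,
    rescaled_domain_pileup,
    signal_profile,
    track_correlation,
)
from tadshift.core import InsulationTrack
from tadshift.domains import OEMatrix

from conftest import balanced_from_values, make_bins, make_map


def oe_from_matrix(values):
    values = np.asarray(values, dtype=float)
    return OEMatrix(make_bins(len(values)), values, len(values), {})


def mw_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumeration of group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u_of(idx):
        rx = sum(ranks[pooled[i]] for i in idx)
        return rx - nx * (nx + 1) / 2

    u_obs = u_of(range(nx))
    mean_u = nx * (len(pooled) - nx) / 2
    dev = abs(u_obs - mean_u)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if abs(u_of(idx) - mean_u) >= dev - 1e-12:
            extreme += 1
    return extreme / total


class TestLocusPileup:
    def test_single_locus_is_identity(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 2.0, (30, 30))
        vals = (vals + vals.T) / 2
        oe = oe_from_matrix(vals)
        p = locus_pileup(oe, [15], flank_bp=6000)
        np.testing.assert_allclose(p.matrix, vals[12:19, 12:19])

    def test_uniform_oe_gives_unit_pileup(self):
        oe = oe_from_matrix(np.ones((40, 40)))
        p = locus_pileup(oe, [10, 20, 30], flank_bp=8000)
        np.testing.assert_allclose(p.matrix, 1.0)

    def test_matches_brute_force_over_loci(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.2, 3.0, (60, 60))
        vals = (vals + vals.T) / 2
        oe = oe_from_matrix(vals)
        loci = list(range(5, 55, 2))
        w = 2
        p = locus_pileup(oe, loci, flank_bp=w * 2000)
        acc = np.zeros((2 * w + 1, 2 * w + 1))
        for i in loci:
            acc += vals[i - w : i + w + 1, i - w : i + w + 1]
        np.testing.assert_allclose(p.matrix, acc / len(loci), atol=1e-12)
        assert p.n_loci == len(loci)

    def test_symmetric_input_symmetric_pileup(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.5, 2.0, (40, 40))
        vals = (vals + vals.T) / 2
        p = locus_pileup(oe_from_matrix(vals), [12, 25], flank_bp=10_000)
        np.testing.assert_allclose(p.matrix, p.matrix.T, atol=1e-12)

    def test_out_of_arm_loci_skipped_and_counted(self):
        oe = oe_from_matrix(np.ones((20, 20)))
        p = locus_pileup(oe, [1, 10], flank_bp=8000)
        assert p.n_loci == 1 and p.n_skipped == 1
        with pytest.raises(ValueError, match="no usable loci"):
            locus_pileup(oe, [0], flank_bp=8000)


class TestRescaledPileup:
    def test_identity_resampling(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.5, 2.0, (40, 40))
        vals = (vals + vals.T) / 2
        oe = oe_from_matrix(vals)
        a, b, f = 12, 22, 3
        p = rescaled_domain_pileup(oe, [(a, b)], flank_bp=f * 2000, n_interior=b - a)
        np.testing.assert_allclose(p.matrix, vals[a - f : b + f, a - f : b + f])

    def test_matches_brute_force_resampling(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.5, 2.0, (80, 80))
        vals = (vals + vals.T) / 2
        oe = oe_from_matrix(vals)
        domains = [(10, 25), (30, 50), (55, 70)]
        f, ni = 4, 10
        p = rescaled_domain_pileup(oe, domains, flank_bp=f * 2000, n_interior=ni)
        acc = []
        for a, b in domains:
            length = b - a
            interior = [
                a + min(int((k + 0.5) * length / ni), length - 1) for k in range(ni)
            ]
            sel = list(range(a - f, a)) + interior + list(range(b, b + f))
            acc.append(vals[np.ix_(sel, sel)])
        np.testing.assert_allclose(p.matrix, np.mean(acc, axis=0), atol=1e-12)

    def test_planted_domains_enriched_interior(self, demo):
        m = demo["mutant"]
        p = rescaled_domain_pileup(m.oe, m.truth.domains[1:-1], n_interior=10)
        f = 100_000 // 2000
        interior = p.matrix[f : f + 10, f : f + 10]
        flank = p.matrix[:f, :f]
        assert np.nanmean(interior) > np.nanmean(flank)

    def test_short_domains_skipped(self):
        oe = oe_from_matrix(np.ones((30, 30)))
        with pytest.raises(ValueError, match="no usable domains"):
            rescaled_domain_pileup(oe, [(10, 11)], flank_bp=4000, n_interior=5)


class TestProfiles:
    def test_features_at_borders_concentrate_at_zero(self):
        borders = np.array([100_000.0, 200_000.0])
        p = point_profile(borders, borders, flank_bp=10_000, step_bp=2000)
        center = np.flatnonzero(p.centers_bp == 1000)  # bin [0, 2000)
        assert p.values[center].sum() == pytest.approx(2 / 2)
        assert p.values.sum() == pytest.approx(1.0)

    def test_no_features_in_flank_all_zero(self):
        p = point_profile(np.array([50_000.0]), np.array([500_000.0]), 10_000, 2000)
        assert (p.values == 0).all()

    def test_matches_brute_force_histogram(self):
        rng = np.random.default_rng(5)
        borders = rng.uniform(1e5, 9e5, 10)
        feats = rng.uniform(1e5, 9e5, 200)
        flank, step = 20_000, 4000
        p = point_profile(borders, feats, flank, step)
        edges = np.arange(-flank, flank + step, step)
        acc = np.zeros(len(edges) - 1)
        for b in borders:
            for f in feats:
                d = f - b
                if edges[0] <= d < edges[-1]:
                    acc[int((d - edges[0]) // step)] += 1
        np.testing.assert_allclose(p.values, acc / len(borders), atol=1e-12)

    def test_constant_track_constant_profile(self):
        track = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(0, 200_000, 100),
                "end": np.arange(100, 200_100, 100),
                "value": 3.5,
            }
        )
        p = signal_profile(np.array([100_000.0]), track, 20_000, 4000)
        np.testing.assert_allclose(p.values, 3.5, atol=1e-12)

    def test_overlap_weighted_mean_by_hand(self):
        track = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 1500, "value": 2.0},
                {"chrom": "chr1", "start": 1500, "end": 4000, "value": 6.0},
            ]
        )
        p = signal_profile(np.array([2000.0]), track, flank_bp=2000, step_bp=2000)
        # left step [0, 2000): 1500 bp at 2.0 + 500 bp at 6.0
        assert p.values[0] == pytest.approx((1500 * 2 + 500 * 6) / 2000)
        # right step [2000, 4000): fully 6.0
        assert p.values[1] == pytest.approx(6.0)

    def test_empty_track_gives_nan_not_zero(self):
        track = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        p = signal_profile(np.array([10_000.0]), track, 4000, 2000)
        assert np.isnan(p.values).all()


class TestDecayCurve:
    def test_distance_only_map_returns_profile(self):
        n = 40
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        vals = 100.0 / (d + 1)
        curve = decay_curve(balanced_from_values(vals))
        g = curve[curve.chrom == "*"]
        np.testing.assert_allclose(
            g["mean"].to_numpy(), 100.0 / (g["distance"].to_numpy() / 2000 + 1)
        )

    def test_masked_bins_excluded_brute_force(self):
        n = 20
        rng = np.random.default_rng(6)
        vals = rng.uniform(1, 5, (n, n))
        vals = (vals + vals.T) / 2
        cmap = balanced_from_values(vals)
        cmap.mask[7] = False
        cmap.counts[7, :] = np.nan
        cmap.counts[:, 7] = np.nan
        curve = decay_curve(cmap)
        for dist in (0, 2000, 6000):
            d = dist // 2000
            diag = np.diagonal(cmap.counts, offset=d)
            expect = np.nanmean(diag)
            got = curve[(curve.chrom == "*") & (curve.distance == dist)]["mean"]
            assert got.iloc[0] == pytest.approx(expect)

    def test_simulator_slope_recovered(self):
        cfg = synth.demo_config("null", n_bins=300, depth=1e7, seed=3, bias_sigma=0.0)
        cmap, _ = synth.simulate(cfg)
        curve = decay_curve(cmap)
        g = curve[
            (curve.chrom == "*")
            & (curve.distance >= 20_000)
            & (curve.distance <= 200_000)
        ]
        slope = np.polyfit(np.log(g["distance"]), np.log(g["mean"]), 1)[0]
        assert slope == pytest.approx(-cfg.decay_exponent, abs=0.1)


class TestTrackCorrelation:
    def make_track(self, scores, valid=None):
        scores = np.asarray(scores, dtype=float)
        valid = np.ones(len(scores), bool) if valid is None else valid
        return InsulationTrack(make_bins(len(scores)), scores, valid, 50_000)

    def test_self_and_negation(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=100)
        t = self.make_track(s)
        neg = self.make_track(-s)
        m = track_correlation([t, t, neg])
        assert m[0, 0] == 1.0
        assert m[0, 1] == pytest.approx(1.0)
        assert m[0, 2] == pytest.approx(-1.0)

    def test_independent_noise_near_zero_matches_formula(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        m = track_correlation([self.make_track(a), self.make_track(b)])
        manual = ((a - a.mean()) * (b - b.mean())).sum() / (
            np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        )
        assert m[0, 1] == pytest.approx(manual, abs=1e-12)
        assert abs(m[0, 1]) < 0.1

    def test_too_few_common_bins_undefined(self):
        v1 = np.array([True] * 2 + [False] * 8)
        v2 = np.array([False] * 8 + [True] * 2)
        m = track_correlation(
            [self.make_track(np.arange(10.0), v1), self.make_track(np.arange(10.0), v2)]
        )
        assert np.isnan(m[0, 1])


class TestRankTest:
    def test_exact_small_sample(self):
        p = rank_group_compare([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(mw_exact_oracle([1, 2, 3], [4, 5, 6]))

    def test_matches_enumeration_oracle_random(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = rng.permutation(20)[:4].tolist()
            y = (rng.permutation(20)[:5] + 100).tolist()
            y = [v + rng.uniform(0, 0.1) for v in y]  # keep values distinct
            assert rank_group_compare(x, y) == pytest.approx(mw_exact_oracle(x, y))

    def test_identical_groups_p_one(self):
        assert rank_group_compare([2, 2, 2], [2, 2]) == 1.0

    def test_symmetric_in_arguments(self):
        x, y = [1.0, 5.0, 9.0, 2.0], [3.0, 7.0, 8.0]
        assert rank_group_compare(x, y) == rank_group_compare(y, x)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_group_compare([], [1.0])


class TestQuintiles:
    def make_inputs(self, n_loops=10):
        bins = make_bins(200)
        # gene anchors at even bins, distal anchors far to the right
        loops = pd.DataFrame(
            {
                "bin_i": [2 * k + 2 for k in range(n_loops)],
                "bin_j": [100 + 5 * k for k in range(n_loops)],
            }
        )
        genes = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [(2 * k + 2) * 2000 for k in range(n_loops)],
                "end": [(2 * k + 3) * 2000 for k in range(n_loops)],
                "expression": np.arange(1.0, n_loops + 1),
            }
        )
        track = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(0, 400_000, 1000),
                "end": np.arange(1000, 401_000, 1000),
                "value": 1.0,
            }
        )
        return loops, genes, track, bins

    def test_even_split_into_five(self):
        loops, genes, track, bins = self.make_inputs(10)
        profiles, table = expression_quintile_anchor_profiles(
            loops, genes, track, bins
        )
        assert len(profiles) == 5
        assert sorted(table["quintile"].value_counts()) == [2, 2, 2, 2, 2]

    def test_quintile_sizes_differ_at_most_one(self):
        loops, genes, track, bins = self.make_inputs(13)
        _, table = expression_quintile_anchor_profiles(loops, genes, track, bins)
        counts = table["quintile"].value_counts()
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == 13

    def test_ties_deterministic(self):
        loops, genes, track, bins = self.make_inputs(10)
        genes["expression"] = 1.0
        _, t1 = expression_quintile_anchor_profiles(loops, genes, track, bins)
        _, t2 = expression_quintile_anchor_profiles(loops, genes, track, bins)
        pd.testing.assert_frame_equal(t1, t2)

    def test_signal_follows_expression_grouping(self):
        loops, genes, track, bins = self.make_inputs(10)
        # distal-anchor signal proportional to the interacting gene expression
        track = track.copy()
        vals = np.ones(len(track))
        for k in range(10):
            distal_center = (100 + 5 * k) * 2000 + 1000
            sel = (track["start"] < distal_center + 5000) & (
                track["end"] > distal_center - 5000
            )
            vals[sel.to_numpy()] = k + 1.0
        track["value"] = vals
        profiles, table = expression_quintile_anchor_profiles(
            loops, genes, track, bins, flank_bp=4000
        )
        means = [np.nanmean(p.values) for p in profiles]
        assert all(a < b for a, b in zip(means[:-1], means[1:]))

    def test_too_few_gene_loops_rejected(self):
        loops, genes, track, bins = self.make_inputs(10)
        with pytest.raises(ValueError, match="at least 5"):
            expression_quintile_anchor_profiles(
                loops.iloc[:3], genes, track, bins
            )
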