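"""Copy-number stack: binning, GC correction, CBS, MergeLevels, Lorenz, states."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from barcodewga.cna import (
    GenomeModel,
    Segment,
    SegmentationParams,
    call_states,
    cbs_segment,
    cna_concordance,
    gc_normalize,
    lorenz_auc,
    make_variable_bins,
    merge_levels,
    states_per_bin,
)


def genome_from_weights(weights, gc=None, window=1000, chrom="chr1"):
    n = len(weights)
    gc = np.full(n, 0.45) if gc is None else np.asarray(gc)
    starts = np.arange(n) * window
    win = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + window,
                        "gc": gc, "weight": np.asarray(weights, dtype=float)})
    return GenomeModel(chromosomes=[(chrom, n * window)], windows=win)


class TestVariableBins:
    def test_uniform_weights_equal_bins(self):
        genome = genome_from_weights(np.ones(100))
        scheme = make_variable_bins(genome, 10)
        assert scheme.n_bins == 10
        widths = scheme.bins["end"] - scheme.bins["start"]
        assert (widths == 10_000).all()

    def test_high_weight_region_gets_narrow_bins(self):
        weights = np.ones(200)
        weights[100:] = 2.0  # double read density downstream
        genome = genome_from_weights(weights)
        scheme = make_variable_bins(genome, 30)
        bins = scheme.bins
        mid = 100_000
        left = bins[bins["end"] <= mid]
        right = bins[bins["start"] >= mid]
        assert (right["end"] - right["start"]).median() == pytest.approx(
            (left["end"] - left["start"]).median() / 2, rel=0.3)

    def test_every_window_assigned_once_and_bins_sorted(self, rng):
        genome = genome_from_weights(rng.uniform(0.5, 1.5, 500))
        scheme = make_variable_bins(genome, 40)
        assert len(scheme.window_bin) == 500
        assert (np.bincount(scheme.window_bin) > 0).all()
        assert scheme.bins["start"].is_monotonic_increasing

    def test_weight_balance_bound_on_random_tracks(self, rng):
        """Max/min bin weight stays within 1 + 2*max_window/target across
        50 random weight tracks (windows much lighter than bins)."""
        for _ in range(50):
            n = int(rng.integers(300, 600))
            weights = rng.uniform(0.5, 1.5, n)
            genome = genome_from_weights(weights)
            n_bins = int(rng.integers(5, 20))
            scheme = make_variable_bins(genome, n_bins)
            target = weights.sum() / scheme.n_bins
            w = scheme.bins["weight"]
            assert w.max() / w.min() <= 1 + 2 * weights.max() / target

    def test_zero_weight_error(self):
        genome = genome_from_weights(np.zeros(10))
        with pytest.raises(ValueError):
            make_variable_bins(genome, 2)

    def test_chromosome_boundaries_respected(self, rng):
        win1 = genome_from_weights(np.ones(50)).windows
        win2 = genome_from_weights(np.ones(50), chrom="chr2").windows
        genome = GenomeModel(chromosomes=[("chr1", 50_000), ("chr2", 50_000)],
                             windows=pd.concat([win1, win2], ignore_index=True))
        scheme = make_variable_bins(genome, 10)
        chrom_per_window = genome.windows["chrom"].to_numpy()
        for b in range(scheme.n_bins):
            chroms = set(chrom_per_window[scheme.window_bin == b])
            assert len(chroms) == 1


class TestGcNormalize:
    def test_constant_counts_give_flat_two(self):
        genome = genome_from_weights(np.ones(200), gc=np.linspace(0.3, 0.6, 200))
        scheme = make_variable_bins(genome, 50)
        ratios = gc_normalize(np.full(50, 120), scheme)
        assert np.allclose(ratios, 2.0, atol=1e-9)

    def test_smooth_gc_trend_removed(self, rng):
        """Counts that are a pure smooth function of GC on flat copy number
        normalize back to ~2 everywhere (max deviation < 5%)."""
        gc = np.sort(rng.uniform(0.3, 0.6, 400))
        rng.shuffle(gc)
        genome = genome_from_weights(np.ones(400), gc=gc)
        scheme = make_variable_bins(genome, 400)
        counts = 200 * np.exp(-(scheme.bins["gc"] - 0.45) ** 2 / 0.02)
        ratios = gc_normalize(counts.to_numpy(), scheme)
        assert np.abs(ratios - 2).max() < 0.1  # < 5% of the diploid level 2

    def test_three_copy_region_lands_near_three(self, rng):
        # small aberrant fraction so the mean-2 rescaling barely compresses it
        gc = rng.uniform(0.35, 0.55, 1000)
        genome = genome_from_weights(np.ones(1000), gc=gc)
        scheme = make_variable_bins(genome, 1000)
        copy = np.full(1000, 2.0)
        copy[200:250] = 3.0
        lam = 100 * (copy / 2) * np.exp(-(gc - 0.45) ** 2 / 0.05)
        counts = rng.poisson(lam)
        ratios = gc_normalize(counts, scheme)
        assert ratios[200:250].mean() == pytest.approx(3.0, abs=0.2)

    def test_output_mean_always_two(self, rng):
        genome = genome_from_weights(np.ones(100), gc=rng.uniform(0.3, 0.6, 100))
        scheme = make_variable_bins(genome, 100)
        for _ in range(5):
            counts = rng.poisson(80, size=100) + 1
            assert gc_normalize(counts, scheme).mean() == pytest.approx(2, abs=1e-6)

    def test_all_zero_counts_error(self):
        genome = genome_from_weights(np.ones(50))
        scheme = make_variable_bins(genome, 50)
        with pytest.raises(ValueError):
            gc_normalize(np.zeros(50), scheme)


class TestCBS:
    def test_null_noise_single_segment(self, rng):
        x = rng.normal(2, 0.2, 800)
        assert len(cbs_segment(x, seed=0)) == 1

    def test_step_localized_within_two_bins(self):
        """2 -> 4 step at bin 500, sigma 0.2: breakpoint within +/-2 bins in
        at least 95% of 50 replicates."""
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = np.concatenate([r.normal(2, 0.2, 500), r.normal(4, 0.2, 500)])
            segs = cbs_segment(x, seed=seed)
            breakpoints = [s.start for s in segs[1:]]
            if any(abs(b - 500) <= 2 for b in breakpoints):
                hits += 1
        assert hits >= 48  # 95% of 50 rounds up to 48

    def test_min_width_suppresses_narrow_spike(self, rng):
        x = rng.normal(2, 0.1, 200)
        x[100:103] += 3  # 3-bin spike, below min_width=5
        segs = cbs_segment(x, SegmentationParams(min_width=5), seed=1)
        assert all(s.n_bins >= 5 for s in segs)

    def test_shuffled_ratios_rarely_split(self):
        """Permuting away all spatial structure yields one segment in >=99%
        of 100 replicates at alpha 1e-10."""
        base = np.concatenate([np.full(150, 2.0), np.full(150, 3.0)])
        ones = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.permutation(base + r.normal(0, 0.2, 300))
            ones += len(cbs_segment(x, seed=seed)) == 1
        assert ones >= 99

    def test_permutation_pvalue_mode(self, rng):
        """With a resolvable alpha the permutation branch is exercised."""
        x = np.concatenate([rng.normal(2, 0.3, 40), rng.normal(5, 0.3, 40)])
        segs = cbs_segment(x, SegmentationParams(alpha=0.01, nperm=200), seed=3)
        assert len(segs) == 2

    def test_too_few_bins_single_segment_with_warning(self):
        with pytest.warns(UserWarning):
            segs = cbs_segment(np.ones(6), SegmentationParams(min_width=5))
        assert len(segs) == 1


class TestMergeLevels:
    def test_same_distribution_merged(self):
        """Two segments from one distribution collapse to one level in the
        bulk of replicates (rank test at 0.1 keeps ~90%)."""
        merged_count = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = r.normal(2, 0.2, 200)
            segs = [Segment(0, 99, x[:100].mean()), Segment(100, 199, x[100:].mean())]
            out = merge_levels(segs, x)
            merged_count += len({s.mean for s in out}) == 1
        assert merged_count >= 40

    def test_distinct_levels_not_merged(self):
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = np.concatenate([r.normal(2, 0.1, 100), r.normal(4, 0.1, 100)])
            segs = [Segment(0, 99, 2), Segment(100, 199, 4)]
            out = merge_levels(segs, x)
            assert len({s.mean for s in out}) == 2

    def test_single_segment_unchanged(self):
        x = np.full(50, 2.0)
        segs = [Segment(0, 49, 2.0)]
        assert merge_levels(segs, x)[0].mean == 2.0

    def test_never_increases_level_count(self, rng):
        x = rng.normal(2, 0.3, 300)
        segs = [Segment(0, 99, 0), Segment(100, 199, 0), Segment(200, 299, 0)]
        out = merge_levels(segs, x)
        assert len({s.mean for s in out}) <= 3


class TestLorenz:
    def test_uniform_counts_auc_half(self):
        _, auc = lorenz_auc(np.full(1000, 7.0))
        assert auc == pytest.approx(0.5)

    def test_single_loaded_bin(self):
        n = 50
        counts = np.zeros(n)
        counts[0] = 100
        _, auc = lorenz_auc(counts)
        assert auc == pytest.approx(1 / (2 * n))

    def test_lognormal_matches_gini_closed_form(self, rng):
        """Lognormal(sigma) counts: AUC = (1 - G)/2 with
        G = 2*Phi(sigma/sqrt(2)) - 1 (the lognormal Gini), within 0.01."""
        for sigma in (0.3, 0.6, 1.0):
            counts = rng.lognormal(0, sigma, 10_000)
            _, auc = lorenz_auc(counts)
            gini = 2 * stats.norm.cdf(sigma / np.sqrt(2)) - 1
            assert auc == pytest.approx((1 - gini) / 2, abs=0.01)

    def test_zero_total_error(self):
        with pytest.raises(ValueError):
            lorenz_auc(np.zeros(10))


class TestConcordanceAndStates:
    def test_identical_profiles(self):
        states = np.array(["gain", "neutral", "loss", "neutral"])
        res = cna_concordance(states, states)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_all_neutral_sample(self):
        bulk = np.array(["gain", "neutral", "loss"])
        sample = np.array(["neutral"] * 3)
        res = cna_concordance(sample, bulk)
        assert res.sensitivity == 0.0 and res.specificity == 1.0

    def test_known_miscall_rate_recovered(self, rng):
        """5% random miscalls: both metrics ~0.95."""
        bulk = rng.choice(["gain", "neutral", "loss"], size=20_000,
                          p=[0.25, 0.5, 0.25])
        sample = bulk.copy()
        flip = rng.random(bulk.size) < 0.05
        for i in np.where(flip)[0]:
            sample[i] = rng.choice([s for s in ("gain", "neutral", "loss")
                                    if s != bulk[i]])
        res = cna_concordance(sample, bulk)
        assert res.sensitivity == pytest.approx(0.95, abs=0.01)
        assert res.specificity == pytest.approx(0.95, abs=0.01)

    def test_no_aberrant_bulk_flagged(self):
        res = cna_concordance(np.array(["neutral"]), np.array(["neutral"]))
        assert res.flags and np.isnan(res.sensitivity)

    def test_state_convention_consistent(self):
        segs = call_states([Segment(0, 4, 1.2), Segment(5, 9, 2.1),
                            Segment(10, 14, 3.4)])
        assert [s.state for s in segs] == ["loss", "neutral", "gain"]
        per_bin = states_per_bin(segs, 15)
        assert list(per_bin[[0, 5, 10]]) == ["loss", "neutral", "gain"]
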