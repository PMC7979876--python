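"""Tests of the copy-number pipeline: log2 ratio, CBS, purity, ploidy."""

import math

import numpy as np
import pytest

from somaseq.cna import (
    CbsParams, cbs_segment_series, classify_segments, compute_log2r,
    estimate_purity, max_circular_split,
    purity_from_segment_mean, recentre, run_cna_pipeline, segment_cbs,
    theoretical_mean,
)
from somaseq.io_model import CountMatrix, GenomeWindow, Segment, is_missing
from somaseq.synthetic import (
    CnSegmentSpec, WindowCountSimConfig, simulate_window_counts,
)


def windows_from_counts(pairs, chrom="1", size=100):
    return CountMatrix([
        GenomeWindow(chrom, i * size, (i + 1) * size, t_count=t, n_count=n)
        for i, (t, n) in enumerate(pairs)
    ])


class TestLog2Ratio:
    def test_value_matches_formula_with_fixed_offset(self):
        pairs = [(200, 100), (150, 95), (120, 105), (180, 98), (160, 102)]
        cm = windows_from_counts(pairs)
        offset = math.log2(252 / 187)
        out = compute_log2r(cm, offset=offset)
        assert out.windows[0].log2r == pytest.approx(1.0 - 0.43044, abs=1e-4)

    def test_mask_keeps_only_windows_strictly_above_threshold(self):
        # N = [10]*9 + [4]: threshold = mean - 2 sd ~ 5.48, so the low window
        # is masked while the others survive
        cm = windows_from_counts([(10, 10)] * 9 + [(10, 4)])
        out = compute_log2r(cm, offset=0.0)
        assert is_missing(out.windows[-1].log2r)
        assert not is_missing(out.windows[0].log2r)

    def test_mask_boundary_is_strict(self):
        # with zero spread every window sits exactly at mean - 2 sd = mean,
        # and the strictly-greater rule masks them all
        cm = windows_from_counts([(50, 50)] * 20)
        out = compute_log2r(cm, offset=0.0)
        assert all(is_missing(w.log2r) for w in out.windows)

    def test_equal_counts_and_totals_give_zero(self):
        pairs = [(n, n) for n in (40, 45, 50, 55, 60, 50, 48, 52)]
        cm = windows_from_counts(pairs)
        out = compute_log2r(cm, offset="auto")
        assert all(w.log2r == pytest.approx(0.0) for w in out.windows
                   if not is_missing(w.log2r))
        assert sum(not is_missing(w.log2r) for w in out.windows) >= 6

    def test_zero_tumour_count_masked_not_infinite(self):
        pairs = [(50, n) for n in (40, 45, 50, 55, 60, 50, 48, 52)] + [(0, 50)]
        cm = windows_from_counts(pairs)
        out = compute_log2r(cm, offset=0.0)
        assert is_missing(out.windows[-1].log2r)


def brute_force_max_split(x, min_width):
    """Exhaustive search over all circular arcs; same statistic and the same
    canonical tie-break (smallest (i, j) among statistics within 1e-9 of the
    maximum) as the fast implementation."""
    n = len(x)
    scored = []
    for i in range(0, n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_width or n - k < min_width:
                continue
            arc = x[i:j]
            rest = np.concatenate([x[:i], x[j:]])
            t = abs(arc.mean() - rest.mean()) / math.sqrt(1 / k + 1 / (n - k))
            scored.append((t, i, j))
    if not scored:
        return 0.0, 0, n
    tmax = max(t for t, _, _ in scored)
    i, j = min((i, j) for t, i, j in scored if t >= tmax - 1e-9)
    return tmax, i, j


class TestCbs:
    def test_constant_sequence_single_segment(self):
        segs = cbs_segment_series(np.zeros(100), CbsParams(seed=1))
        assert segs == [(0, 100)]

    def test_clean_step_found_at_change_point(self):
        x = np.concatenate([np.zeros(50), np.ones(50)])
        x += np.random.default_rng(0).normal(0, 0.01, 100)
        segs = cbs_segment_series(x, CbsParams(seed=1))
        assert len(segs) == 2
        boundary = segs[0][1]
        assert abs(boundary - 50) <= CbsParams().min_width

    @pytest.mark.parametrize("min_width", [2, 3])
    def test_max_split_statistic_equals_exhaustive_search(self, min_width, rng):
        for _ in range(60):
            n = int(rng.integers(2 * min_width, 13))
            x = rng.normal(0, 1, n)
            if rng.random() < 0.5:  # plant a shifted arc
                i = int(rng.integers(0, n - min_width))
                j = int(rng.integers(i + min_width, n + 1))
                x[i:j] += rng.normal(1.5, 0.5)
            t_impl, i_impl, j_impl = max_circular_split(x, min_width)
            t_ref, i_ref, j_ref = brute_force_max_split(x, min_width)
            assert t_impl == pytest.approx(t_ref, abs=1e-9)
            assert (i_impl, j_impl) == (i_ref, j_ref)

    @pytest.mark.parametrize("min_width,alpha", [(2, 0.05), (3, 0.05), (2, 0.01)])
    def test_full_segmentation_equals_exhaustive_oracle(self, min_width, alpha, rng):
        """On sequences of length <= 12, recursive CBS with the exhaustive
        split search must reproduce the fast implementation exactly."""
        params = CbsParams(alpha=alpha, min_width=min_width,
                           n_permutations=200, seed=9)
        for _ in range(25):
            n = int(rng.integers(2 * min_width, 13))
            x = rng.normal(0, 0.2, n)
            if rng.random() < 0.7:
                cut = int(rng.integers(1, n))
                x[cut:] += 2.0
            fast = cbs_segment_series(x, params)
            oracle = cbs_segment_series(x, params, max_fn=brute_force_max_split)
            assert fast == oracle

    def test_masked_windows_never_enter_segment_means(self):
        windows = [GenomeWindow("1", i * 100, (i + 1) * 100, 100, 100,
                                log2r=(float("nan") if i % 7 == 0 else 0.5))
                   for i in range(50)]
        segs = segment_cbs(CountMatrix(windows), CbsParams(seed=2))
        assert len(segs) == 1
        assert segs[0].seg_mean == pytest.approx(0.5)
        assert segs[0].n_windows == sum(1 for i in range(50) if i % 7)


class TestRecentre:
    def _seg(self, mean, n=600, chrom="1"):
        return Segment(chrom=chrom, first_window_index=0, last_window_index=n - 1,
                       n_windows=n, seg_mean=mean)

    def test_baseline_is_mean_of_qualifying_segments(self):
        segs = [self._seg(0.09), self._seg(0.10)]
        shifted, baseline = recentre(segs)
        assert baseline == pytest.approx(0.095)
        assert [s.seg_mean for s in shifted] == pytest.approx([-0.005, 0.005])

    def test_centred_data_identity(self):
        segs = [self._seg(0.0)]
        shifted, baseline = recentre(segs)
        assert baseline == 0.0 and shifted[0].seg_mean == 0.0

    def test_qualifying_mean_is_zero_after_recentring(self):
        segs = [self._seg(0.12), self._seg(0.05), self._seg(0.9, n=600),
                self._seg(0.3, n=100)]
        shifted, baseline = recentre(segs)
        qualifying = [s for s in shifted if s.n_windows > 500 and abs(s.seg_mean + baseline) < 0.25]
        weights = [s.n_windows for s in qualifying]
        assert np.average([s.seg_mean for s in qualifying], weights=weights) == pytest.approx(0.0)

    def test_no_qualifying_segment_is_an_error(self):
        with pytest.raises(ValueError, match="baseline"):
            recentre([self._seg(0.9)])


class TestTheoreticalMeans:
    def test_neutral_state_is_zero_for_any_purity(self):
        for alpha in (0.1, 0.5, 0.63, 1.0):
            assert theoretical_mean(2, alpha, 2) == 0.0
            assert theoretical_mean(1, alpha, 1) == 0.0

    def test_pure_tumour_doubling(self):
        assert theoretical_mean(4, 1.0, 2) == pytest.approx(1.0)

    def test_mixture_value_at_typical_purity(self):
        assert theoretical_mean(4, 0.63, 2) == pytest.approx(math.log2(1.63), abs=1e-9)

    def test_strictly_increasing_in_ploidy(self):
        for alpha in (0.2, 0.63, 0.95):
            for g in (1, 2):
                means = [theoretical_mean(p, alpha, g) for p in range(7)]
                assert all(b > a for a, b in zip(means, means[1:]))

    def test_pure_tumour_total_loss_is_negative_infinity(self):
        assert theoretical_mean(0, 1.0, 2) == float("-inf")


class TestPurity:
    def _segs_at(self, alpha, ploidies, n=600):
        return [Segment(chrom="1", first_window_index=0, last_window_index=n - 1,
                        n_windows=n, seg_mean=theoretical_mean(p, alpha, 2))
                for p in ploidies]

    def test_closed_form_inversion_round_trip(self):
        m = math.log2(1.315)
        assert purity_from_segment_mean(m, 3) == pytest.approx(0.63, abs=1e-12)

    def test_single_copy_loss_at_full_purity(self):
        assert purity_from_segment_mean(-1.0, 1) == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha", np.round(np.arange(0.2, 0.96, 0.05), 2).tolist())
    def test_noiseless_round_trip_across_purity_grid(self, alpha):
        # every input segment is aberrant, so no neutral band is needed and
        # noiseless clusters are points (any small gap separates them)
        model = estimate_purity(self._segs_at(alpha, [1, 3, 4]),
                                zero_band=0.0, cluster_gap=0.01)
        assert model.purity == pytest.approx(alpha, abs=1e-12)
        assert set(model.cluster_estimates) == {1, 3, 4}

    def test_neutral_genome_is_an_error(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_purity(self._segs_at(0.6, [2, 2]))

    def test_sex_chromosome_segments_excluded(self):
        segs = self._segs_at(0.5, [1, 3, 4])
        segs.append(Segment(chrom="Y", first_window_index=0, last_window_index=99,
                            n_windows=100, seg_mean=-3.0))
        model = estimate_purity(segs)
        assert model.purity == pytest.approx(0.5, abs=1e-12)


class TestClassification:
    def test_exact_theoretical_mean_classifies_back(self):
        from somaseq.cna import PurityModel
        model = PurityModel(purity=0.63, cluster_estimates={})
        for p in range(7):
            for chrom, g in (("1", 2), ("X", 1)):
                seg = Segment(chrom=chrom, first_window_index=0,
                              last_window_index=9, n_windows=10,
                              seg_mean=theoretical_mean(p, 0.63, g))
                out = classify_segments([seg], model)[0]
                assert out.ploidy_call == p, (p, chrom)

    def test_zero_mean_autosome_is_diploid(self):
        from somaseq.cna import PurityModel
        model = PurityModel(purity=0.63, cluster_estimates={})
        seg = Segment(chrom="5", first_window_index=0, last_window_index=9,
                      n_windows=10, seg_mean=0.0)
        assert classify_segments([seg], model)[0].ploidy_call == 2

    def test_distance_cap_leaves_outliers_unclassified(self):
        from somaseq.cna import PurityModel
        model = PurityModel(purity=0.63, cluster_estimates={})
        seg = Segment(chrom="5", first_window_index=0, last_window_index=9,
                      n_windows=10, seg_mean=9.0)
        assert classify_segments([seg], model, max_distance=0.2)[0].ploidy_call is None


class TestFullPipeline:
    def test_recovers_simulation_purity_and_ploidies(self):
        sim = simulate_window_counts(seed=11)
        result = run_cna_pipeline(sim.counts)
        assert result.model.purity == pytest.approx(0.63, abs=0.03)
        by_chrom = {}
        for seg in result.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for row in sim.truth.itertuples():
            segs = by_chrom[row.chrom]
            dominant = max(segs, key=lambda s: s.n_windows)
            assert dominant.ploidy_call == row.tumour_ploidy, row.chrom

    def test_deterministic_given_seed(self):
        sim = simulate_window_counts(seed=4)
        r1 = run_cna_pipeline(sim.counts, params=CbsParams(seed=3))
        r2 = run_cna_pipeline(sim.counts, params=CbsParams(seed=3))
        assert r1.model.purity == r2.model.purity
        assert [(s.chrom, s.first_window_index, s.last_window_index)
                for s in r1.segments] == [
            (s.chrom, s.first_window_index, s.last_window_index)
            for s in r2.segments]

    def test_neutral_simulation_errors_as_designed(self):
        layout = (CnSegmentSpec("1", 700, 2), CnSegmentSpec("2", 600, 2))
        sim = simulate_window_counts(WindowCountSimConfig(layout=layout), seed=6)
        with pytest.raises(ValueError, match="unidentifiable"):
            run_cna_pipeline(sim.counts)

    def test_pure_tumour_quadruploid_ratio(self):
        layout = (CnSegmentSpec("1", 800, 2), CnSegmentSpec("3", 400, 4))
        cfg = WindowCountSimConfig(layout=layout, purity=1.0, overdispersion=0.0,
                                   masked_fraction=0.0)
        sim = simulate_window_counts(cfg, seed=8)
        t = sim.counts.to_frame()
        chr3 = t[t.chrom == "3"]
        chr1 = t[t.chrom == "1"]
        ratio = chr3.t_count.mean() / chr1.t_count.mean()
        assert ratio == pytest.approx(2.0, rel=0.05)
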