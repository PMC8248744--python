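"""Circularization, the rotation permutation null, QTL calling, the
peak-similarity interval rule and DEG-overlap counting."""

import numpy as np
import pandas as pd
import pytest

from hapbsa.config import DegParams, IntervalParams, PermutationParams
from hapbsa.layout import GenomeLayout
from hapbsa.qtl import (
    QtlCall,
    call_qtls,
    circularize,
    count_degs_in_intervals,
    permutation_null,
    qtl_interval,
    rotate,
    subsidiary_peaks,
)
from hapbsa.scan import WindowTrack, average_pairs


def _track(values, chroms=None, size=100):
    values = np.asarray(values, dtype=float)
    n = len(values)
    if chroms is None:
        chroms = np.repeat("chr1", n)
    chroms = np.asarray(chroms, dtype=object)
    starts = np.empty(n, dtype=np.int64)
    for name in pd.unique(chroms):
        m = chroms == name
        starts[m] = 1 + size * np.arange(m.sum())
    return WindowTrack(chroms, starts, starts + size - 1, np.full(n, 50), values)


def _diff(per_pair_values, chroms=None):
    tracks = [_track(v, chroms) for v in per_pair_values]
    return average_pairs(tracks)


def _layout_for(chroms, size=100):
    names = list(pd.unique(np.asarray(chroms)))
    counts = [int((np.asarray(chroms) == n).sum()) for n in names]
    # decreasing lengths consistent with window counts
    lengths = [size * c for c in counts]
    return GenomeLayout(tuple(zip(names, lengths)))


class TestCircularize:
    def test_three_chromosomes_concatenate_into_one_ring(self):
        chroms = ["chr1"] * 26 + ["chr2"] * 26 + ["chr3"] * 26
        diff = _diff([np.zeros(78)], chroms)
        rings = circularize(diff, _layout_for(chroms))
        assert len(rings) == 78
        # ring neighbours across the seam: last chr3 window joins first chr1
        assert rings.grid.chrom[rings.window_index[-1]] == "chr3"
        assert rings.grid.chrom[rings.window_index[0]] == "chr1"
        assert (rings.window_index[-1] + 1) % len(rings) == rings.window_index[0]

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(0)
        chroms = ["chr1"] * 10 + ["chr2"] * 5
        values = rng.uniform(-1, 1, 15)
        diff = _diff([values], chroms)
        rings = circularize(diff, _layout_for(chroms))
        back = rings.to_linear(rings.rings[0])
        np.testing.assert_allclose(back, values)

    def test_missing_windows_removed_with_positions_remembered(self):
        values = np.array([0.1, np.nan, 0.3, 0.4])
        diff = _diff([values])
        rings = circularize(diff, _layout_for(["chr1"] * 4))
        assert len(rings) == 3
        np.testing.assert_array_equal(rings.window_index, [0, 2, 3])
        back = rings.to_linear(rings.rings[0])
        assert np.isnan(back[1])

    def test_empty_track_rejected(self):
        diff = _diff([np.full(4, np.nan)])
        with pytest.raises(ValueError, match="non-missing"):
            circularize(diff, _layout_for(["chr1"] * 4))


class TestPermutationNull:
    def test_all_zero_rings_give_zero_threshold(self):
        diff = _diff([np.zeros(120)] * 3)
        rings = circularize(diff, _layout_for(["chr1"] * 120))
        null = permutation_null(rings, PermutationParams(200, 0.05, seed=1))
        assert null.threshold == 0.0
        assert np.all(null.maxima == 0.0)

    def test_constant_ring_is_rotation_invariant(self):
        diff = _diff([np.full(80, 0.37)])
        rings = circularize(diff, _layout_for(["chr1"] * 80))
        null = permutation_null(rings, PermutationParams(200, 0.05, seed=1))
        assert np.allclose(null.maxima, 0.37)
        assert null.threshold == pytest.approx(0.37)

    def test_rotation_preserves_value_multiset(self):
        rng = np.random.default_rng(3)
        ring = rng.normal(size=57)
        for offset in (0, 1, 13, 56):
            np.testing.assert_allclose(np.sort(rotate(ring, offset)), np.sort(ring))

    def test_threshold_monotone_in_fdr(self):
        rng = np.random.default_rng(4)
        diff = _diff([rng.normal(0, 0.1, 150) for _ in range(5)])
        rings = circularize(diff, _layout_for(["chr1"] * 150))
        null = permutation_null(rings, PermutationParams(500, 0.05, seed=2))
        thresholds = [null.threshold_at(f) for f in (0.01, 0.05, 0.1, 0.2)]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_threshold_calibration_against_fresh_null_draws(self):
        """For iid Gaussian rings the rotation threshold reproduces the
        intended genome-wide error rate on independent replicate draws."""
        rng = np.random.default_rng(5)
        n_pairs, w, sigma = 11, 100, 0.2
        diff = _diff([rng.normal(0, sigma, w) for _ in range(n_pairs)])
        rings = circularize(diff, _layout_for(["chr1"] * w))
        null = permutation_null(rings, PermutationParams(2000, 0.05, seed=3))
        fresh_max = np.abs(
            rng.normal(0, sigma, size=(3000, n_pairs, w)).mean(axis=1)
        ).max(axis=1)
        rate = float((fresh_max >= null.threshold).mean())
        assert rate == pytest.approx(0.05, abs=0.03)


class TestCallQtls:
    def test_no_exceedance_gives_empty_list(self):
        assert call_qtls(_track([0.1, 0.2, 0.1]), 0.5) == []

    def test_isolated_significant_window(self):
        calls = call_qtls(_track([0.1, 0.6, 0.1]), 0.5)
        assert len(calls) == 1
        assert calls[0].run_first == calls[0].run_last == 1
        assert calls[0].peak_value == pytest.approx(0.6)

    def test_runs_split_by_gaps_and_peaks_leftmost_on_ties(self):
        calls = call_qtls(_track([0.6, 0.6, 0.1, 0.7, 0.7, 0.7]), 0.5)
        assert len(calls) == 2
        assert calls[0].peak_index == 0  # tie in first run: leftmost
        assert calls[1].run_first == 3 and calls[1].run_last == 5

    def test_runs_never_span_chromosomes(self):
        chroms = ["chr1"] * 3 + ["chr2"] * 3
        calls = call_qtls(_track([0.1, 0.6, 0.6, 0.6, 0.6, 0.1], chroms), 0.5)
        assert len(calls) == 2
        assert calls[0].chrom == "chr1" and calls[1].chrom == "chr2"

    def test_negative_deviations_also_significant(self):
        calls = call_qtls(_track([0.0, -0.7, 0.0]), 0.5)
        assert len(calls) == 1
        assert calls[0].peak_value == pytest.approx(-0.7)


class TestQtlInterval:
    def test_flat_plateau_spans_whole_plateau(self):
        values = [0.0, 0.5, 0.5, 0.5, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0]
        track = _track(values)
        call = call_qtls(track, 0.4)[0]
        iv = qtl_interval(track, call, IntervalParams())
        assert (iv.window_first, iv.window_last) == (1, 4)

    def test_isolated_peak_yields_single_window_interval(self):
        values = [0.0, 0.0, 0.0, 0.0, 0.0, 0.6] + [0.0] * 6
        track = _track(values)
        call = call_qtls(track, 0.5)[0]
        iv = qtl_interval(track, call, IntervalParams())
        assert (iv.window_first, iv.window_last) == (5, 5)
        assert iv.start == track.start[5] and iv.end == track.end[5]

    def test_gap_below_block_len_bridges_to_similar_window(self):
        """Peak 0.312 at window 8; a similar 0.309 at window 3 with four
        dissimilar windows between: the stopping rule reaches it."""
        values = [0.0, 0.0, 0.0, 0.309, 0.1, 0.1, 0.1, 0.1, 0.312, 0.0, 0.0, 0.0]
        track = _track(values)
        call = QtlCall("chr1", 8, int(track.start[8]), int(track.end[8]), 0.312, 8, 8)
        iv = qtl_interval(track, call, IntervalParams(similarity_delta=0.005, block_len=5))
        assert (iv.window_first, iv.window_last) == (3, 8)

    def test_gap_of_block_len_stops_extension(self):
        values = [0.309, 0.1, 0.1, 0.1, 0.1, 0.1, 0.312] + [0.0] * 3
        track = _track(values)
        call = QtlCall("chr1", 6, int(track.start[6]), int(track.end[6]), 0.312, 6, 6)
        iv = qtl_interval(track, call, IntervalParams())
        assert iv.window_first == 6  # five dissimilar windows close the walk

    def test_interval_contains_peak_window(self, small_result):
        from hapbsa.pipeline import detect_qtls, dna_scan, infer_sites

        records = infer_sites(small_result)
        diff = dna_scan(small_result, records)
        scan = detect_qtls(diff, small_result, PermutationParams(300, 0.05, seed=1))
        for call, iv in zip(scan.calls, scan.intervals):
            assert iv.window_first <= call.peak_index <= iv.window_last
            assert iv.start <= call.peak_start and iv.end >= call.peak_end


class TestSubsidiaryPeaks:
    def test_top_subthreshold_local_maxima_reported(self):
        values = [0.1, 0.45, 0.1, 0.0, 0.8, 0.0, 0.3, 0.35, 0.3, 0.0]
        track = _track(values)
        subs = subsidiary_peaks(track, 0.5, k=2, min_separation=2)
        assert [s.peak_index for s in subs] == [1, 7]
        assert all(abs(s.peak_value) < 0.5 for s in subs)


class TestDegCounting:
    def _annotation(self):
        return pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3"],
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [100, 5_000, 100],
                "end": [600, 5_400, 600],
            }
        )

    def _interval(self, chrom="chr1", start=1, end=1_000):
        call = QtlCall(chrom, 0, start, end, 0.5, 0, 0)
        from hapbsa.qtl import QtlInterval

        return QtlInterval(chrom, start, end, 0, 0, call)

    def test_empty_table_counts_zero(self):
        de = pd.DataFrame(columns=["gene", "fc", "padj"])
        out = count_degs_in_intervals(de, self._annotation(), [self._interval()])
        assert out["n_degs_in_intervals"] == 0 and out["n_degs_total"] == 0

    def test_inside_and_outside_genes_distinguished(self):
        de = pd.DataFrame(
            {"gene": ["g1", "g2", "g3"], "fc": [3.0, -2.5, 4.0], "padj": [0.01, 0.01, 0.01]}
        )
        out = count_degs_in_intervals(de, self._annotation(), [self._interval()])
        assert out["per_qtl"] == [1]
        assert out["n_degs_in_intervals"] == 1
        assert out["n_degs_total"] == 3

    def test_cutoffs_applied_to_absolute_fc_and_padj(self):
        de = pd.DataFrame(
            {"gene": ["g1", "g2"], "fc": [1.5, -2.0], "padj": [0.01, 0.2]}
        )
        out = count_degs_in_intervals(de, self._annotation(), [self._interval()], DegParams())
        assert out["n_degs_total"] == 0  # fc below cutoff / padj above cutoff

    def test_duplicate_gene_ids_rejected(self):
        de = pd.DataFrame({"gene": ["g1", "g1"], "fc": [3, 3], "padj": [0.01, 0.01]})
        with pytest.raises(ValueError, match="duplicate"):
            count_degs_in_intervals(de, self._annotation(), [self._interval()])

    def test_randomized_counts_match_brute_force_overlap(self):
        rng = np.random.default_rng(6)
        n = 200
        ann = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "chrom": rng.choice(["chr1", "chr2"], n),
                "start": rng.integers(1, 100_000, n),
            }
        )
        ann["end"] = ann["start"] + rng.integers(100, 5_000, n)
        de = pd.DataFrame(
            {
                "gene": ann["gene"],
                "fc": rng.uniform(-4, 4, n),
                "padj": rng.uniform(0, 0.2, n),
            }
        )
        intervals = [
            self._interval("chr1", 10_000, 40_000),
            self._interval("chr2", 50_000, 90_000),
        ]
        out = count_degs_in_intervals(de, ann, intervals)
        # oracle: per-gene loop over intervals
        is_deg = (de["fc"].abs() >= 2) & (de["padj"] <= 0.05)
        expect_per = []
        inside = set()
        for iv in intervals:
            c = 0
            for i in range(n):
                if not is_deg[i]:
                    continue
                if (
                    ann.loc[i, "chrom"] == iv.chrom
                    and ann.loc[i, "start"] <= iv.end
                    and ann.loc[i, "end"] >= iv.start
                ):
                    c += 1
                    inside.add(ann.loc[i, "gene"])
            expect_per.append(c)
        assert out["per_qtl"] == expect_per
        assert out["n_degs_in_intervals"] == len(inside)


class TestRecoveryAccuracy:
    def test_strong_selection_peak_lands_on_true_locus(self, small_result):
        """With one strongly selected locus every called peak lies within
        150 kb of the truth and deviates in the direction of the
        resistant-parent allele."""
        from hapbsa.pipeline import detect_qtls, dna_scan, infer_sites

        records = infer_sites(small_result)
        diff = dna_scan(small_result, records)
        scan = detect_qtls(diff, small_result, PermutationParams(300, 0.05, seed=1))
        assert len(scan.calls) >= 1
        locus = small_result.config.causal_loci[0]
        for call in scan.calls:
            assert call.chrom == locus.chrom
            centre = (call.peak_start + call.peak_end) // 2
            assert abs(centre - locus.pos) <= 150_000
            assert call.peak_value > 0
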