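import numpy as np
import pytest

from peakshift import (
    DepthTrack, Landmark, PeakParams, SampleGroup,
    call_peaks, detect_landmarks, enumerate_candidates, filter_candidates,
    smooth_track,
)
from peakshift.peaks import (
    MAXIMUM, MINIMUM, SLOPE_CHANGE, refine_spans, suppress_overlaps,
)

from conftest import random_track


def track(values, bin_size=10, chrom="chrT"):
    return DepthTrack(chrom, bin_size, np.asarray(values, dtype=float))


def kinds_at(landmarks):
    out = {}
    for lm in landmarks:
        out.setdefault(lm.index, set()).add(lm.kind)
    return out


def brute_force_candidates(smoothed, landmarks, params):
    """Independent O(n^3) oracle: try every index triple, apply the
    landmark-kind predicates, the apex-is-span-maximum rule and the strict
    thresholds directly."""
    d = smoothed.values
    ka = kinds_at(landmarks)
    out = []
    n = len(d)
    for s in range(n):
        if not (ka.get(s, set()) & {MINIMUM, SLOPE_CHANGE}):
            continue
        for a in range(s + 1, n):
            if MAXIMUM not in ka.get(a, set()):
                continue
            for e in range(a + 1, n):
                if not (ka.get(e, set()) & {MINIMUM, SLOPE_CHANGE}):
                    continue
                seg = d[s:e + 1]
                if seg.max() > d[a]:
                    continue
                baseline = (d[s] + d[e]) / 2.0
                max_excess = d[a] - baseline
                area = float(np.maximum(seg - baseline, 0.0).sum())
                if max_excess > params.max_excess_min and area > params.area_min:
                    out.append((s, a, e, baseline, max_excess, area))
    return sorted(out)


class TestSmoothing:
    def test_window_one_is_identity(self):
        t = track([1, 4, 2, 8])
        assert np.array_equal(smooth_track(t, 1).values, t.values)

    def test_shrinking_edge_windows(self):
        out = smooth_track(track([0, 3, 0]), 3).values
        assert np.allclose(out, [1.5, 1.0, 1.5])

    def test_constant_track_unchanged(self):
        out = smooth_track(track([5.0] * 20), 7).values
        assert np.allclose(out, 5.0)

    def test_window_longer_than_track_rejected(self):
        with pytest.raises(ValueError):
            smooth_track(track([1, 2, 3]), 5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_track(track([1, 2, 3, 4]), 2)


class TestLandmarks:
    def test_single_bump(self):
        ka = kinds_at(detect_landmarks(track([0, 5, 0]), PeakParams(window_bins=1)))
        assert MAXIMUM in ka[1] and MINIMUM in ka[0] and MINIMUM in ka[2]

    def test_monotone_ramp_has_only_end_minima(self):
        ka = kinds_at(detect_landmarks(track([0, 1, 2, 3, 4]), PeakParams(window_bins=1)))
        assert set(ka) == {0, 4}
        assert ka[0] == {MINIMUM} and ka[4] == {MINIMUM}

    def test_slope_change_where_diff_ratio_exceeds_factor(self):
        # diffs 1,1,5,5: the 1 -> 5 jump (ratio 5 > 2) marks bin 2
        ka = kinds_at(detect_landmarks(track([0, 1, 2, 7, 12]), PeakParams(window_bins=1)))
        assert SLOPE_CHANGE in ka[2]
        assert all(SLOPE_CHANGE not in ks for i, ks in ka.items() if i != 2)

    def test_plateau_yields_left_center_extremum(self):
        ka = kinds_at(detect_landmarks(track([0, 5, 5, 5, 5, 0]), PeakParams(window_bins=1)))
        assert ka[2] == {MAXIMUM}  # run 1..4, left-center
        ka = kinds_at(detect_landmarks(track([5, 0, 0, 5]), PeakParams(window_bins=1)))
        assert MINIMUM in ka[1]

    def test_zero_slopes_produce_no_slope_change(self):
        ka = kinds_at(detect_landmarks(track([1, 1, 1, 5, 5, 5]), PeakParams(window_bins=1)))
        assert all(SLOPE_CHANGE not in ks for ks in ka.values())


class TestEnumerate:
    def params(self):
        return PeakParams(window_bins=1)

    def test_no_maximum_no_candidates(self):
        t = track([0, 1, 2, 3])
        assert enumerate_candidates(t, detect_landmarks(t, self.params())) == []

    def test_single_bump_single_candidate(self):
        t = track([0, 5, 0])
        cands = enumerate_candidates(t, detect_landmarks(t, self.params()))
        assert len(cands) == 1
        c = cands[0]
        assert (c.start_bin, c.apex_bin, c.end_bin) == (0, 1, 2)
        assert c.baseline == 0 and c.max_excess == 5 and c.integrated_excess == 5

    def test_two_bounds_per_side_gives_four_candidates(self):
        t = track([2, 1, 4, 1, 2])
        cands = enumerate_candidates(t, detect_landmarks(t, self.params()))
        triples = {(c.start_bin, c.apex_bin, c.end_bin) for c in cands}
        assert triples == {(0, 2, 3), (0, 2, 4), (1, 2, 3), (1, 2, 4)}

    def test_higher_maximum_blocks_span(self):
        # apex at 1 (depth 5) cannot span across the higher apex at 3 (depth 9)
        t = track([0, 5, 1, 9, 0])
        cands = enumerate_candidates(t, detect_landmarks(t, self.params()))
        for c in cands:
            if c.apex_bin == 1:
                assert c.end_bin <= 2

    def test_candidate_stats_consistent_with_track(self):
        rng = np.random.default_rng(5)
        t = random_track(rng, 80)
        sm = smooth_track(t, 5)
        for c in enumerate_candidates(sm, detect_landmarks(sm, PeakParams(window_bins=5))):
            d = sm.values
            base = (d[c.start_bin] + d[c.end_bin]) / 2
            assert c.baseline == pytest.approx(base, abs=1e-9)
            assert c.max_excess == pytest.approx(d[c.apex_bin] - base, abs=1e-9)
            seg = d[c.start_bin:c.end_bin + 1]
            assert seg.max() <= d[c.apex_bin]
            assert c.integrated_excess == pytest.approx(
                np.maximum(seg - base, 0).sum(), abs=1e-9
            )


class TestFilter:
    def bump(self, excesses):
        t = track(excesses)
        cands = enumerate_candidates(t, detect_landmarks(t, PeakParams(window_bins=1)))
        return t, cands

    def test_thresholds_are_strict(self):
        _, cands = self.bump([0, 2.5, 0])  # max_excess exactly 2.5
        assert filter_candidates(cands, PeakParams(window_bins=1)) == []
        _, cands = self.bump([0, 2.5 + 1e-9, 2.5 + 1e-9, 0])  # area 5 + 2e-9
        kept = filter_candidates(cands, PeakParams(window_bins=1))
        assert len(kept) == 1

    def test_area_filter(self):
        _, cands = self.bump([0, 3, 6, 3, 0])
        kept = filter_candidates(cands, PeakParams(window_bins=1))
        assert len(kept) == 1
        assert kept[0].max_excess == 6 and kept[0].integrated_excess == 12
        _, cands = self.bump([0, 3, 0])  # max 3 > 2.5 but area 3 < 5
        assert filter_candidates(cands, PeakParams(window_bins=1)) == []

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = random_track(rng)
            sm = smooth_track(t, 5)
            cands = enumerate_candidates(sm, detect_landmarks(sm, PeakParams(window_bins=5)))
            base = PeakParams(window_bins=5)
            kept = {(c.start_bin, c.apex_bin, c.end_bin)
                    for c in filter_candidates(cands, base, deduplicate=False)}
            for stricter in (
                PeakParams(window_bins=5, max_excess_min=4.0),
                PeakParams(window_bins=5, area_min=9.0),
            ):
                sub = {(c.start_bin, c.apex_bin, c.end_bin)
                       for c in filter_candidates(cands, stricter, deduplicate=False)}
                assert sub <= kept


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_tracks(self):
        params = PeakParams(window_bins=5)
        rng = np.random.default_rng(123)
        for _ in range(30):
            sm = smooth_track(random_track(rng), params.window_bins)
            landmarks = detect_landmarks(sm, params)
            got = filter_candidates(
                enumerate_candidates(sm, landmarks), params, deduplicate=False
            )
            got_t = sorted((c.start_bin, c.apex_bin, c.end_bin) for c in got)
            want = [(s, a, e) for s, a, e, *_ in brute_force_candidates(sm, landmarks, params)]
            assert got_t == want


class TestInvariances:
    def detect(self, values, params):
        t = track(values)
        sm = smooth_track(t, params.window_bins)
        cands = enumerate_candidates(sm, detect_landmarks(sm, params))
        return filter_candidates(cands, params)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(17)
        base = random_track(rng, 100).values
        params = PeakParams(window_bins=5)
        shift = 30
        shifted = np.concatenate([np.full(shift, base[0]), base])
        a = self.detect(base, params)
        b = self.detect(shifted, params)
        got = {(c.start_bin, c.apex_bin, c.end_bin) for c in b
               if c.start_bin >= shift}
        want = {(c.start_bin + shift, c.apex_bin + shift, c.end_bin + shift)
                for c in a if c.start_bin >= params.window_bins}
        assert want <= got | {(c.start_bin, c.apex_bin, c.end_bin) for c in b}

    def test_scaling_depth_scales_statistics(self):
        rng = np.random.default_rng(21)
        values = random_track(rng, 100).values
        params = PeakParams(window_bins=5)
        c = 4.0  # power of two: exact scaling, no tie flips from rounding
        t1 = track(values)
        t2 = track(values * c)
        sm1, sm2 = smooth_track(t1, 5), smooth_track(t2, 5)
        cands1 = enumerate_candidates(sm1, detect_landmarks(sm1, params))
        cands2 = enumerate_candidates(sm2, detect_landmarks(sm2, params))
        by_triple = {(x.start_bin, x.apex_bin, x.end_bin): x for x in cands2}
        assert by_triple
        for c1 in cands1:
            c2 = by_triple[(c1.start_bin, c1.apex_bin, c1.end_bin)]
            assert c2.max_excess == pytest.approx(c * c1.max_excess, rel=1e-9)
            assert c2.integrated_excess == pytest.approx(c * c1.integrated_excess, rel=1e-9)


def as_group(label, tracks_by_sample):
    return SampleGroup(label, {
        sid: {t.chrom: t} for sid, t in tracks_by_sample.items()
    })


class TestCallPeaks:
    def test_flat_tracks_yield_nothing(self):
        flat = track([5.0] * 200)
        g1 = as_group("control", {"c1": flat})
        g2 = as_group("mutant", {"m1": flat})
        assert call_peaks([g1, g2], PeakParams(window_bins=5)) == []

    def test_duplicate_samples_match_single_sample(self):
        rng = np.random.default_rng(3)
        t = random_track(rng, 300)
        params = PeakParams(window_bins=5)
        single = call_peaks([as_group("control", {"c1": t})], params)
        doubled = call_peaks(
            [as_group("control", {"c1": t, "c2": DepthTrack(t.chrom, t.bin_size, t.values.copy())})],
            params,
        )
        assert [(c.start_bin, c.apex_bin, c.end_bin) for c in single] == \
               [(c.start_bin, c.apex_bin, c.end_bin) for c in doubled]

    def test_fast_path_equals_composed_pipeline(self):
        """call_peaks' lazy per-apex search must equal the compose of
        enumerate -> filter(+dedup) -> suppress -> refine."""
        rng = np.random.default_rng(31)
        params = PeakParams(window_bins=5)
        for _ in range(25):
            t = random_track(rng)
            got = call_peaks([as_group("control", {"c1": t})], params)
            sm = smooth_track(t, params.window_bins)
            lms = detect_landmarks(sm, params)
            span = params.max_span_bp // t.bin_size
            want = filter_candidates(enumerate_candidates(sm, lms, span), params)
            want = refine_spans(suppress_overlaps(want), sm, params.trim_fraction)
            assert [(c.start_bin, c.apex_bin, c.end_bin) for c in got] == \
                   sorted((c.start_bin, c.apex_bin, c.end_bin) for c in want)

    def test_inconsistent_binning_rejected(self):
        g1 = as_group("control", {"c1": track([1, 2, 3], bin_size=10)})
        g2 = as_group("mutant", {"m1": track([1, 2, 3], bin_size=20)})
        with pytest.raises(ValueError):
            call_peaks([g1, g2], PeakParams(window_bins=1))

    def test_planted_peak_recovery(self, default_dataset, default_peaks, overlap):
        ds = default_dataset
        truth = [(p.start, p.end) for p in ds.truth.peaks]
        called = [(p.start_bp, p.end_bp) for p in default_peaks]
        recall = sum(
            any(overlap(t, c) >= 0.5 for c in called) for t in truth
        ) / len(truth)
        precision = sum(
            any(overlap(t, c) >= 0.5 for t in truth) for c in called
        ) / len(called)
        assert recall >= 0.9 and precision >= 0.9
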