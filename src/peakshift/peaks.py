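"""Custom ChIP-seq peak caller on binned depth tracks.

The method: (1) smooth the genome-wide depth with a centered moving
average; (2) mark landmarks — local minima, local maxima, and points where
the slope between consecutive bins changes more than ``slope_factor``-fold;
(3) exhaustively enumerate (start, apex, end) landmark triples; (4) measure
each candidate against the baseline (mean of the smoothed depth at its start
and end) and keep those whose maximum excess depth exceeds 2.5 and whose
integrated excess depth exceeds 5.0 (both strict); (5) reduce overlapping
candidates to one peak per apex.

All operations work on bin indices of the smoothed track; ``call_peaks``
converts the surviving peaks back to base-pair coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .core_io import DepthTrack, SampleGroup

MINIMUM = "MINIMUM"
MAXIMUM = "MAXIMUM"
SLOPE_CHANGE = "SLOPE_CHANGE"
_KIND_ORDER = {MINIMUM: 0, MAXIMUM: 1, SLOPE_CHANGE: 2}


@dataclass
class PeakParams:
    """Tunable parameters of the peak caller.

    ``max_excess_min`` (2.5, depth units) and ``area_min`` (5.0, depth x bin
    units) are the published filter thresholds; both comparisons are strict.
    With ``baseline_relative=False`` the same thresholds are applied to the
    raw smoothed apex depth and the raw integrated depth instead of the
    baseline-subtracted excess.
    """

    window_bins: int = 21
    slope_factor: float = 2.0
    max_excess_min: float = 2.5
    area_min: float = 5.0
    baseline_relative: bool = True
    #: candidates wider than this many bp are not considered (None = no cap)
    max_span_bp: Optional[int] = 3000
    #: a kept peak's boundaries must lie within this depth of the lowest
    #: candidate-boundary depth on their side (skips shallow flank dips)
    boundary_tolerance: float = 1.0
    #: drop surviving peaks overlapping a stronger surviving peak
    suppress_overlaps: bool = True
    #: after selection, trim peak boundaries inward to where the smoothed
    #: depth first exceeds baseline + trim_fraction * max_excess (0 disables)
    trim_fraction: float = 0.1
    detection: str = "pooled"  # 'pooled' | 'per-group-union'

    def __post_init__(self) -> None:
        if self.window_bins < 1 or self.window_bins % 2 == 0:
            raise ValueError("window_bins must be an odd integer >= 1")
        if self.slope_factor <= 1:
            raise ValueError("slope_factor must be > 1")
        if self.max_excess_min <= 0 or self.area_min <= 0:
            raise ValueError("thresholds must be > 0")
        if self.detection not in ("pooled", "per-group-union"):
            raise ValueError("detection must be 'pooled' or 'per-group-union'")


@dataclass(frozen=True)
class Landmark:
    index: int
    kind: str


@dataclass
class PeakCandidate:
    """A (start, apex, end) region on one smoothed track.

    ``baseline`` is the mean smoothed depth at the start and end bins;
    ``max_excess`` the smoothed apex depth minus the baseline;
    ``integrated_excess`` the sum over [start_bin, end_bin] (inclusive) of
    the smoothed depth above the baseline, clipped at zero.
    """

    chrom: str
    start_bin: int
    apex_bin: int
    end_bin: int
    baseline: float
    max_excess: float
    integrated_excess: float
    apex_depth: float = 0.0         # raw smoothed depth at the apex
    integrated_depth: float = 0.0   # raw smoothed depth summed over the span
    depth_start: float = 0.0        # smoothed depth at the start bin
    depth_end: float = 0.0          # smoothed depth at the end bin
    start_min_bounded: bool = True  # start landmark is a MINIMUM
    end_min_bounded: bool = True
    bin_size: int = 1
    peak_id: str = ""

    @property
    def width_bins(self) -> int:
        return self.end_bin - self.start_bin

    @property
    def start_bp(self) -> int:
        return self.start_bin * self.bin_size

    @property
    def end_bp(self) -> int:
        return (self.end_bin + 1) * self.bin_size

    @property
    def apex_bp(self) -> int:
        return self.apex_bin * self.bin_size + self.bin_size // 2


def smooth_track(track: DepthTrack, window_bins: int) -> DepthTrack:
    """Centered moving average; edges average over the available bins only."""
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be an odd integer >= 1")
    if window_bins > track.n_bins:
        raise ValueError("smoothing window longer than the track")
    if window_bins == 1:
        return DepthTrack(track.chrom, track.bin_size, track.values.copy(), track.origin_bp)
    kernel = np.ones(window_bins)
    sums = np.convolve(track.values, kernel, mode="same")
    counts = np.convolve(np.ones(track.n_bins), kernel, mode="same")
    return DepthTrack(track.chrom, track.bin_size, sums / counts, track.origin_bp)


def detect_landmarks(smoothed: DepthTrack, params: PeakParams) -> List[Landmark]:
    """Local extrema and slope-change points of a smoothed track.

    Plateaus (maximal runs of equal values) bounded by lower (higher)
    neighbors yield one MAXIMUM (MINIMUM) at the run's center, left-center
    on even-length runs. Both track ends count as MINIMUM landmarks so that
    peaks truncated at contig edges remain representable. A SLOPE_CHANGE is
    marked at bin i when the consecutive first differences d[i]-d[i-1] and
    d[i+1]-d[i] are nonzero, share a sign, and their ratio exceeds
    ``slope_factor`` in either direction (strict); zero slopes never produce
    slope-change landmarks.
    """
    d = smoothed.values
    n = len(d)
    kinds: Dict[int, set] = {0: {MINIMUM}}
    kinds.setdefault(n - 1, set()).add(MINIMUM)

    if n >= 3:
        change = np.flatnonzero(np.diff(d) != 0)
        run_starts = np.concatenate(([0], change + 1))
        run_ends = np.concatenate((change, [n - 1]))  # inclusive
        run_vals = d[run_starts]
        for j in range(1, len(run_vals) - 1):
            center = (run_starts[j] + run_ends[j]) // 2
            if run_vals[j] > run_vals[j - 1] and run_vals[j] > run_vals[j + 1]:
                kinds.setdefault(center, set()).add(MAXIMUM)
            elif run_vals[j] < run_vals[j - 1] and run_vals[j] < run_vals[j + 1]:
                kinds.setdefault(center, set()).add(MINIMUM)

        s = np.diff(d)
        same_sign = s[:-1] * s[1:] > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(same_sign, np.abs(s[1:]) / np.abs(s[:-1]), 1.0)
        f = params.slope_factor
        hits = np.flatnonzero(same_sign & ((ratio > f) | (ratio < 1.0 / f)))
        for i in hits:
            kinds.setdefault(int(i) + 1, set()).add(SLOPE_CHANGE)

    out = [
        Landmark(i, k)
        for i in sorted(kinds)
        for k in sorted(kinds[i], key=_KIND_ORDER.get)
    ]
    return out


def _prev_next_greater(d: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """For each bin, the nearest index left/right with strictly greater depth."""
    n = len(d)
    prev = np.full(n, -1, dtype=np.int64)
    nxt = np.full(n, n, dtype=np.int64)
    stack: List[int] = []
    for i in range(n):
        while stack and d[stack[-1]] <= d[i]:
            stack.pop()
        prev[i] = stack[-1] if stack else -1
        stack.append(i)
    stack.clear()
    for i in range(n - 1, -1, -1):
        while stack and d[stack[-1]] <= d[i]:
            stack.pop()
        nxt[i] = stack[-1] if stack else n
        stack.append(i)
    return prev, nxt


def _iter_triples(
    d: np.ndarray, landmarks: Sequence[Landmark], max_span_bins: Optional[int]
) -> Iterator[Tuple[int, int, int]]:
    """All valid (start, apex, end) landmark triples.

    Validity: the apex is a MAXIMUM landmark, both boundaries are MINIMUM or
    SLOPE_CHANGE landmarks, start < apex < end, and no bin in [start, end]
    exceeds the apex depth (which also excludes any higher MAXIMUM inside
    the span and makes the apex the maximum of the span).
    """
    kind_at: Dict[int, set] = {}
    for lm in landmarks:
        kind_at.setdefault(lm.index, set()).add(lm.kind)
    apexes = sorted(i for i, ks in kind_at.items() if MAXIMUM in ks)
    bounds = np.array(
        sorted(i for i, ks in kind_at.items() if ks & {MINIMUM, SLOPE_CHANGE}),
        dtype=np.int64,
    )
    if not apexes or len(bounds) == 0:
        return
    prev, nxt = _prev_next_greater(d)
    for a in apexes:
        lo = prev[a]  # exclusive
        hi = nxt[a]
        if max_span_bins is not None:
            lo = max(lo, a - max_span_bins)
            hi = min(hi, a + max_span_bins)
        left = bounds[np.searchsorted(bounds, lo, "right"):np.searchsorted(bounds, a)]
        right = bounds[np.searchsorted(bounds, a, "right"):np.searchsorted(bounds, hi)]
        for s in left:
            for e in right:
                yield int(s), a, int(e)


def _stats(d: np.ndarray, s: int, a: int, e: int) -> Tuple[float, float, float, float, float]:
    baseline = (d[s] + d[e]) / 2.0
    seg = d[s:e + 1]
    integrated_excess = float(np.maximum(seg - baseline, 0.0).sum())
    return (
        float(baseline),
        float(d[a] - baseline),
        integrated_excess,
        float(d[a]),
        float(seg.sum()),
    )


def enumerate_candidates(
    smoothed: DepthTrack,
    landmarks: Sequence[Landmark],
    max_span_bins: Optional[int] = None,
) -> List[PeakCandidate]:
    """Exhaustive candidate extraction from landmark triples (no filtering)."""
    d = smoothed.values
    kind_at: Dict[int, set] = {}
    for lm in landmarks:
        kind_at.setdefault(lm.index, set()).add(lm.kind)
    out: List[PeakCandidate] = []
    for s, a, e in _iter_triples(d, landmarks, max_span_bins):
        baseline, max_excess, integ, apex_depth, integ_raw = _stats(d, s, a, e)
        out.append(
            PeakCandidate(
                smoothed.chrom, s, a, e, baseline, max_excess, integ,
                apex_depth, integ_raw,
                depth_start=float(d[s]), depth_end=float(d[e]),
                start_min_bounded=MINIMUM in kind_at[s],
                end_min_bounded=MINIMUM in kind_at[e],
                bin_size=smoothed.bin_size,
            )
        )
    return out


def _passes(c: PeakCandidate, params: PeakParams) -> bool:
    if params.baseline_relative:
        return c.max_excess > params.max_excess_min and c.integrated_excess > params.area_min
    return c.apex_depth > params.max_excess_min and c.integrated_depth > params.area_min


def _dedup_key(c: PeakCandidate) -> Tuple:
    # Prefer minima-bounded candidates, then the narrowest span, then the
    # greatest integrated excess, then the leftmost start.
    return (
        not (c.start_min_bounded and c.end_min_bounded),
        c.width_bins,
        -c.integrated_excess,
        c.start_bin,
    )


def filter_candidates(
    candidates: Iterable[PeakCandidate],
    params: PeakParams,
    deduplicate: bool = True,
) -> List[PeakCandidate]:
    """Apply the strict 2.5 / 5.0 thresholds, then reduce to one peak per apex.

    Deduplication keeps, per apex, the surviving candidate whose boundaries
    are *grounded*: each endpoint's smoothed depth lies within
    ``params.boundary_tolerance`` of the lowest endpoint depth reachable on
    its side (computed over the full candidate pool passed in, so shallow
    dips on a peak's flank do not truncate the kept span). Among grounded
    survivors the minima-bounded, narrowest candidate wins; ties go to the
    greater integrated excess, then the leftmost start. If no grounded
    candidate survives the thresholds, the same preference is applied to
    all survivors of that apex.
    """
    candidates = list(candidates)
    survivors = [c for c in candidates if _passes(c, params)]
    if not deduplicate:
        return sorted(survivors, key=lambda c: (c.chrom, c.start_bin, c.apex_bin, c.end_bin))
    floors: Dict[Tuple[str, int], List[float]] = {}
    for c in candidates:
        key = (c.chrom, c.apex_bin)
        f = floors.setdefault(key, [float("inf"), float("inf")])
        f[0] = min(f[0], c.depth_start)
        f[1] = min(f[1], c.depth_end)
    best: Dict[Tuple[str, int], Tuple[bool, Tuple, PeakCandidate]] = {}
    tol = params.boundary_tolerance
    for c in survivors:
        key = (c.chrom, c.apex_bin)
        floor_l, floor_r = floors[key]
        grounded = c.depth_start <= floor_l + tol and c.depth_end <= floor_r + tol
        entry = (not grounded, _dedup_key(c), c)
        if key not in best or entry[:2] < best[key][:2]:
            best[key] = entry
    return sorted((e[2] for e in best.values()),
                  key=lambda c: (c.chrom, c.start_bin, c.apex_bin))


def suppress_overlaps(peaks: Sequence[PeakCandidate]) -> List[PeakCandidate]:
    """Greedy non-maximum suppression of overlapping peaks.

    Peaks are accepted in order of decreasing max excess (ties: leftmost);
    a peak overlapping an already-accepted peak on the same chromosome is
    dropped. This keeps one called peak per summit region when shoulder
    maxima on the flanks of a strong peak survive the thresholds.
    """
    ordered = sorted(peaks, key=lambda c: (-c.max_excess, c.chrom, c.start_bin))
    accepted: List[PeakCandidate] = []
    for c in ordered:
        if all(
            a.chrom != c.chrom or c.end_bin < a.start_bin or c.start_bin > a.end_bin
            for a in accepted
        ):
            accepted.append(c)
    return sorted(accepted, key=lambda c: (c.chrom, c.start_bin, c.apex_bin))


def _best_candidate_for_apex(
    d: np.ndarray,
    a: int,
    left: np.ndarray,
    right: np.ndarray,
    left_min: np.ndarray,
    right_min: np.ndarray,
    params: PeakParams,
    chrom: str,
    bin_size: int,
) -> Optional[PeakCandidate]:
    """The threshold-surviving candidate for one apex that the dedup rule keeps.

    Grounded (boundary depth within ``boundary_tolerance`` of the side's
    floor) pairs are scanned first, in dedup-key order — minima-bounded
    first, then by width — stopping at the end of the first key class that
    contains a survivor; pairs failing the endpoint-only max-excess test are
    skipped without computing the area sum. Equivalent to enumerating all
    candidates, filtering, and deduplicating (property-tested).
    """
    ns, ne = len(left), len(right)
    if ns == 0 or ne == 0:
        return None
    floor_l = float(d[left].min()) + params.boundary_tolerance
    floor_r = float(d[right].min()) + params.boundary_tolerance
    si = np.repeat(np.arange(ns), ne)
    ei = np.tile(np.arange(ne), ns)
    s_arr, e_arr = left[si], right[ei]
    # cheap necessary condition: the max-excess test depends only on the
    # endpoint depths, so pairs failing it never need the area sum
    if params.baseline_relative:
        feasible = d[a] - (d[s_arr] + d[e_arr]) / 2.0 > params.max_excess_min
    else:
        feasible = np.full(len(s_arr), d[a] > params.max_excess_min)
    if not feasible.any():
        return None
    grounded = (d[s_arr] <= floor_l) & (d[e_arr] <= floor_r)

    def scan(mask: np.ndarray) -> Optional[PeakCandidate]:
        sub = np.flatnonzero(mask)
        if len(sub) == 0:
            return None
        s_sub, e_sub = s_arr[sub], e_arr[sub]
        width = e_sub - s_sub
        mixed = ~(left_min[si[sub]] & right_min[ei[sub]])
        order = np.lexsort((s_sub, width, mixed))
        found_key = None
        best: Optional[PeakCandidate] = None
        best_sub = None
        for idx in order:
            key = (bool(mixed[idx]), int(width[idx]))
            if found_key is not None and key != found_key:
                break
            s, e = int(s_sub[idx]), int(e_sub[idx])
            baseline, max_excess, integ, apex_depth, integ_raw = _stats(d, s, a, e)
            cand = PeakCandidate(
                chrom, s, a, e, baseline, max_excess, integ, apex_depth, integ_raw,
                depth_start=float(d[s]), depth_end=float(d[e]),
                start_min_bounded=bool(left_min[si[sub[idx]]]),
                end_min_bounded=bool(right_min[ei[sub[idx]]]),
                bin_size=bin_size,
            )
            if _passes(cand, params):
                sub_key = (-integ, s)
                if found_key is None or sub_key < best_sub:
                    found_key, best, best_sub = key, cand, sub_key
        return best

    best = scan(feasible & grounded)
    if best is None:
        best = scan(feasible & ~grounded)
    return best


def _detect_on_track(track: DepthTrack, params: PeakParams) -> List[PeakCandidate]:
    smoothed = smooth_track(track, params.window_bins)
    landmarks = detect_landmarks(smoothed, params)
    max_span = (
        None if params.max_span_bp is None
        else max(params.max_span_bp // track.bin_size, 2)
    )
    d = smoothed.values
    kind_at: Dict[int, set] = {}
    for lm in landmarks:
        kind_at.setdefault(lm.index, set()).add(lm.kind)
    apexes = sorted(i for i, ks in kind_at.items() if MAXIMUM in ks)
    bounds = np.array(
        sorted(i for i, ks in kind_at.items() if ks & {MINIMUM, SLOPE_CHANGE}),
        dtype=np.int64,
    )
    if not apexes or len(bounds) == 0:
        return []
    bounds_min = np.array([MINIMUM in kind_at[int(i)] for i in bounds])
    prev, nxt = _prev_next_greater(d)
    survivors: List[PeakCandidate] = []
    for a in apexes:
        lo, hi = prev[a], nxt[a]
        if max_span is not None:
            lo = max(lo, a - max_span)
            hi = min(hi, a + max_span)
        i0 = np.searchsorted(bounds, lo, "right")
        i1 = np.searchsorted(bounds, a)
        j0 = np.searchsorted(bounds, a, "right")
        j1 = np.searchsorted(bounds, hi)
        best = _best_candidate_for_apex(
            d, a, bounds[i0:i1], bounds[j0:j1], bounds_min[i0:i1], bounds_min[j0:j1],
            params, track.chrom, track.bin_size,
        )
        if best is not None:
            survivors.append(best)
    if params.suppress_overlaps:
        survivors = suppress_overlaps(survivors)
    survivors = refine_spans(survivors, smoothed, params.trim_fraction)
    return sorted(survivors, key=lambda c: (c.chrom, c.start_bin, c.apex_bin))


def refine_spans(
    peaks: Sequence[PeakCandidate], smoothed: DepthTrack, trim_fraction: float
) -> List[PeakCandidate]:
    """Trim each peak's span to its enriched core.

    Boundaries move inward to the outermost bins whose smoothed depth
    reaches baseline + ``trim_fraction`` x max excess; statistics are then
    recomputed on the trimmed span. Valley-to-valley spans include long
    near-baseline tails (and the moving-average halo), so the reported
    interval tracks the enrichment footprint instead.
    """
    if trim_fraction <= 0:
        return list(peaks)
    d = smoothed.values
    out = []
    for c in peaks:
        level = c.baseline + trim_fraction * c.max_excess
        s, e = c.start_bin, c.end_bin
        while s < c.apex_bin and d[s] < level:
            s += 1
        while e > c.apex_bin and d[e] < level:
            e -= 1
        baseline, max_excess, integ, apex_depth, integ_raw = _stats(d, s, c.apex_bin, e)
        out.append(
            PeakCandidate(
                c.chrom, s, c.apex_bin, e, baseline, max_excess, integ,
                apex_depth, integ_raw,
                depth_start=float(d[s]), depth_end=float(d[e]),
                start_min_bounded=c.start_min_bounded,
                end_min_bounded=c.end_min_bounded,
                bin_size=c.bin_size, peak_id=c.peak_id,
            )
        )
    return out


def call_peaks(groups: Sequence[SampleGroup], params: PeakParams) -> List[PeakCandidate]:
    """Detect peaks on the samples of one or more groups.

    In the default ``pooled`` mode one detection track — the per-bin mean
    over all samples of all groups — is built per chromosome, so a single
    genome-wide peak set is produced and group depths are compared within it
    downstream. In ``per-group-union`` mode detection runs on each group's
    mean track separately and the union of the resulting intervals is kept.
    """
    if not groups:
        raise ValueError("need at least one sample group")
    chroms = groups[0].chromosomes
    for g in groups[1:]:
        if set(g.chromosomes) != set(chroms):
            raise ValueError("groups cover different chromosome sets")
    peaks: List[PeakCandidate] = []
    for chrom in chroms:
        tracks = [t for g in groups for t in g.tracks_for(chrom)]
        ref = tracks[0]
        for t in tracks[1:]:
            if not t.compatible_with(ref) or t.n_bins != ref.n_bins:
                raise ValueError(f"inconsistent binning across samples on {chrom}")
        if params.detection == "pooled":
            mean = DepthTrack(
                chrom, ref.bin_size,
                np.vstack([t.values for t in tracks]).mean(axis=0), ref.origin_bp,
            )
            peaks.extend(_detect_on_track(mean, params))
        else:
            seen = set()
            for g in groups:
                for cand in _detect_on_track(g.mean_track(chrom), params):
                    key = (cand.chrom, cand.start_bin, cand.apex_bin, cand.end_bin)
                    if key not in seen:
                        seen.add(key)
                        peaks.append(cand)
    peaks.sort(key=lambda c: (c.chrom, c.start_bin, c.apex_bin))
    for i, c in enumerate(peaks):
        c.peak_id = f"peak_{i:05d}"
    return peaks


def read_peaks_bed(path, bin_size: int) -> List[PeakCandidate]:
    """Read peaks serialized by :func:`write_peaks_bed` back to bin space."""
    peaks: List[PeakCandidate] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, start, end, pid, apex, _, baseline, mx, integ = \
                line.rstrip("\n").split("\t")
            c = PeakCandidate(
                chrom,
                int(start) // bin_size,
                int(apex) // bin_size,
                int(end) // bin_size - 1,
                float(baseline), float(mx), float(integ),
                bin_size=bin_size, peak_id=pid,
            )
            peaks.append(c)
    return peaks


def write_peaks_bed(peaks: Sequence[PeakCandidate], path) -> None:
    """BED6+ with baseline / max excess / integrated excess extra columns."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tpeak_id\tapex\tstrand\t"
                 "baseline\tmax_excess\tintegrated_excess\n")
        for c in peaks:
            fh.write(
                f"{c.chrom}\t{c.start_bp}\t{c.end_bp}\t{c.peak_id}\t{c.apex_bp}\t.\t"
                f"{c.baseline:.6g}\t{c.max_excess:.6g}\t{c.integrated_excess:.6g}\n"
            )
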