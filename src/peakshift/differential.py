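"""Differential classification of peaks from group mean depths.

For every detected peak the mean (unsmoothed) read depth over the peak
interval is computed per group: [Dp]_ctrl for the control group, [Dp]_mut
for the mutant group. A peak is labeled

* ``PEAKS_2_0`` when [Dp]_ctrl < 0.5 x [Dp]_mut (mutant-enriched),
* ``PEAKS_0_5`` when [Dp]_ctrl > 2.0 x [Dp]_mut (control-enriched),
* ``UNCHANGED`` otherwise,

with strict inequalities, so the two differential labels are mutually
exclusive and no ratio (hence no division) is ever formed: a peak with both
group depths zero is UNCHANGED, while zero control depth against positive
mutant depth is PEAKS_2_0 (0 < 0.5*x for any x > 0) and symmetrically for
PEAKS_0_5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .core_io import SampleGroup
from .peaks import PeakCandidate

PEAKS_2_0 = "PEAKS_2_0"
PEAKS_0_5 = "PEAKS_0_5"
UNCHANGED = "UNCHANGED"


@dataclass
class DifferentialPeak:
    peak: PeakCandidate
    dp_ctrl: float
    dp_mut: float
    label: str
    #: per-mutant-sample mean depths, for the strict all-lines mode
    dp_mut_lines: Dict[str, float] = None

    @property
    def peak_id(self) -> str:
        return self.peak.peak_id


def _label(dp_ctrl: float, dp_mut: float) -> str:
    if dp_ctrl < 0.5 * dp_mut:
        return PEAKS_2_0
    if dp_ctrl > 2.0 * dp_mut:
        return PEAKS_0_5
    return UNCHANGED


def group_mean_depth(peak: PeakCandidate, group: SampleGroup) -> float:
    """Mean over the peak's bins of the per-bin mean across the group's samples.

    Uses the unsmoothed depth; smoothing only guides peak geometry.
    """
    tracks = group.tracks_for(peak.chrom)
    for t in tracks:
        if peak.start_bin < 0 or peak.end_bin >= t.n_bins:
            raise ValueError(
                f"peak [{peak.start_bin}, {peak.end_bin}] outside track bounds "
                f"(track has {t.n_bins} bins)"
            )
    stacked = np.vstack([t.values[peak.start_bin:peak.end_bin + 1] for t in tracks])
    return float(stacked.mean())


def classify_peaks(
    peaks: Sequence[PeakCandidate],
    control: SampleGroup,
    mutants: SampleGroup,
    all_lines: bool = False,
) -> List[DifferentialPeak]:
    """Label every peak PEAKS_2_0 / PEAKS_0_5 / UNCHANGED.

    By default [Dp]_mut is the mean over all mutant samples combined. With
    ``all_lines=True`` a differential label is assigned only when its
    inequality holds against every mutant sample individually (the stricter
    reading of per-line comparison); otherwise the peak is UNCHANGED.
    """
    out: List[DifferentialPeak] = []
    for peak in peaks:
        dp_ctrl = group_mean_depth(peak, control)
        per_line = {
            sid: group_mean_depth(peak, SampleGroup("mutant", {sid: mutants.samples[sid]}))
            for sid in mutants.samples
        }
        dp_mut = float(np.mean(list(per_line.values())))
        if all_lines:
            labels = {_label(dp_ctrl, v) for v in per_line.values()}
            label = labels.pop() if len(labels) == 1 else UNCHANGED
        else:
            label = _label(dp_ctrl, dp_mut)
        out.append(DifferentialPeak(peak, dp_ctrl, dp_mut, label, per_line))
    return out


def partition_counts(diff_peaks: Sequence[DifferentialPeak]) -> Dict[str, int]:
    counts = {PEAKS_2_0: 0, PEAKS_0_5: 0, UNCHANGED: 0}
    for dp in diff_peaks:
        counts[dp.label] += 1
    return counts


def write_differential_tsv(diff_peaks: Sequence[DifferentialPeak], path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tchrom\tstart\tend\tapex\tdp_ctrl\tdp_mut\tlabel\n")
        for dp in diff_peaks:
            p = dp.peak
            fh.write(
                f"{p.peak_id}\t{p.chrom}\t{p.start_bp}\t{p.end_bp}\t{p.apex_bp}\t"
                f"{dp.dp_ctrl:.6g}\t{dp.dp_mut:.6g}\t{dp.label}\n"
            )


def read_differential_tsv(path, bin_size: int) -> List[DifferentialPeak]:
    """Read the classification table back; peak geometry only (no baselines)."""
    out: List[DifferentialPeak] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            pid, chrom, start, end, apex, dp_ctrl, dp_mut, label = \
                line.rstrip("\n").split("\t")
            peak = PeakCandidate(
                chrom,
                int(start) // bin_size,
                int(apex) // bin_size,
                int(end) // bin_size - 1,
                0.0, float("inf"), float("inf"),
                bin_size=bin_size, peak_id=pid,
            )
            out.append(DifferentialPeak(peak, float(dp_ctrl), float(dp_mut), label))
    return out


def write_label_beds(diff_peaks: Sequence[DifferentialPeak], out_dir) -> None:
    from pathlib import Path

    for label, fname in ((PEAKS_2_0, "peaks_2.0.bed"), (PEAKS_0_5, "peaks_0.5.bed")):
        with open(Path(out_dir) / fname, "w") as fh:
            for dp in diff_peaks:
                if dp.label == label:
                    p = dp.peak
                    fh.write(f"{p.chrom}\t{p.start_bp}\t{p.end_bp}\t{p.peak_id}\t0\t.\n")
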