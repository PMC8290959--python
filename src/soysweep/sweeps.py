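"""Empirical outlier thresholds and multi-statistic sweep-region calling.

A window is an outlier for one statistic when its value strictly exceeds
the genome-wide empirical threshold (the ceil(q*W)-th smallest finite
value at top quantile q, so a tie-free track flags exactly the top
(1-q) fraction).  Windows flagged by at least ``min_support`` statistics
are merged into sweep regions, which can then be intersected with gene /
QTL annotation intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from soysweep.diversity import WindowedStatTrack
from soysweep.vcf_io import AnnotationTrack


@dataclass
class SweepRegion:
    """A called sweep: merged outlier windows with per-statistic peaks."""

    chrom: str
    start0: int
    end: int
    supporting: tuple[str, ...]
    peaks: dict[str, float] = field(default_factory=dict)
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.end <= self.start0:
            raise ValueError("region must satisfy end > start0")
        if not self.supporting:
            raise ValueError("a sweep region needs at least one supporting statistic")

    def contains(self, pos0: int) -> bool:
        """Whether a 0-based position falls inside the region."""
        return self.start0 <= pos0 < self.end


def empirical_threshold(track: WindowedStatTrack, top_quantile: float) -> float:
    """Genome-wide outlier threshold: the ceil(q*W)-th smallest finite value.

    A window is flagged iff its value is strictly greater than the
    threshold, so on a tie-free track of W windows exactly
    ``W - ceil(q*W)`` windows are flagged.
    """
    finite = track.values[np.isfinite(track.values)]
    if finite.size < 20:
        raise ValueError(
            f"need >= 20 finite windows for an empirical threshold, got {finite.size}"
        )
    if not 0.5 < top_quantile < 1.0:
        raise ValueError("top_quantile must be in (0.5, 1)")
    rank = math.ceil(top_quantile * finite.size)  # 1-based order statistic
    return float(np.sort(finite)[rank - 1])


def flag_windows(track: WindowedStatTrack, threshold: float) -> np.ndarray:
    """Boolean flags per window: finite and strictly above the threshold."""
    values = track.values
    return np.isfinite(values) & (values > threshold)


def call_sweeps(
    tracks: dict[str, WindowedStatTrack],
    thresholds: dict[str, float],
    min_support: int = 3,
    merge_gap_bp: int = 0,
    support_mode: str = "window",
) -> list[SweepRegion]:
    """Merge outlier windows of several statistics into sweep regions.

    ``support_mode="window"`` (default): a window is sweep-supporting when
    at least ``min_support`` statistics flag that same window; supporting
    windows whose intervals overlap, touch or lie within ``merge_gap_bp``
    merge into one region.

    ``support_mode="region"``: each statistic's flagged windows are first
    merged into per-statistic outlier intervals (bridging gaps up to
    ``merge_gap_bp``); sweep regions are the genomic segments covered by
    at least ``min_support`` of these intervals.  This is the
    appropriate mode when the statistics peak on staggered parts of the
    same sweep -- F_ST on the allele-frequency shoulder, the diversity
    ratio at the deepest pi reduction, XP-EHH where haplotypes extend
    longest -- which tile a region rather than stacking on one window.

    In both modes each region records which statistics flagged windows
    inside it and the per-statistic peak values.  NaN windows are never
    flagged and therefore break merges.
    """
    if not tracks:
        raise ValueError("no tracks given")
    if min_support not in (1, 2, 3):
        raise ValueError("min_support must be 1, 2 or 3")
    if support_mode not in ("window", "region"):
        raise ValueError("support_mode must be 'window' or 'region'")
    names = sorted(tracks)
    first = tracks[names[0]]
    for name in names[1:]:
        if not first.same_windows(tracks[name]):
            raise ValueError(f"track {name!r} does not share windows with {names[0]!r}")
    missing = [n for n in names if n not in thresholds]
    if missing:
        raise ValueError(f"no threshold for tracks {missing}")

    flags = {n: flag_windows(tracks[n], thresholds[n]) for n in names}
    starts, ends = first.starts, first.ends

    if support_mode == "window":
        support = np.sum([flags[n] for n in names], axis=0)
        supporting_windows = np.nonzero(support >= min_support)[0]
        if supporting_windows.size == 0:
            return []
        regions: list[SweepRegion] = []
        block = [supporting_windows[0]]
        block_end = ends[supporting_windows[0]]
        for w in supporting_windows[1:]:
            if starts[w] <= block_end + merge_gap_bp:
                block.append(w)
                block_end = max(block_end, ends[w])
            else:
                regions.append(
                    _build_region(first.chrom, block, tracks, flags, names, starts, ends)
                )
                block = [w]
                block_end = ends[w]
        regions.append(_build_region(first.chrom, block, tracks, flags, names, starts, ends))
        return regions

    # region mode: stack per-statistic outlier intervals
    per_stat = {
        n: _merge_windows(starts, ends, np.nonzero(flags[n])[0], merge_gap_bp)
        for n in names
    }
    events: list[tuple[int, int]] = []
    for intervals in per_stat.values():
        for s, e in intervals:
            events.append((int(s), 1))
            events.append((int(e), -1))
    if not events:
        return []
    events.sort()
    segments = []
    depth = 0
    seg_start = None
    for pos, delta in events:
        prev = depth
        depth += delta
        if prev < min_support <= depth:
            seg_start = pos
        elif prev >= min_support > depth:
            segments.append((seg_start, pos))
            seg_start = None
    merged: list[list[int]] = []
    for s, e in segments:
        if merged and s <= merged[-1][1] + merge_gap_bp:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    regions = []
    for s, e in merged:
        supporting = []
        peaks = {}
        for n in names:
            hit = np.nonzero(flags[n] & (starts < e) & (ends > s))[0]
            if hit.size:
                supporting.append(n)
                peaks[n] = float(np.nanmax(tracks[n].values[hit]))
        regions.append(
            SweepRegion(first.chrom, int(s), int(e), tuple(supporting), peaks)
        )
    return regions


def _merge_windows(starts, ends, idx, merge_gap_bp) -> list[tuple[int, int]]:
    """Merge the listed windows into maximal intervals (gap-bridging)."""
    if len(idx) == 0:
        return []
    intervals = [[int(starts[idx[0]]), int(ends[idx[0]])]]
    for w in idx[1:]:
        if starts[w] <= intervals[-1][1] + merge_gap_bp:
            intervals[-1][1] = max(intervals[-1][1], int(ends[w]))
        else:
            intervals.append([int(starts[w]), int(ends[w])])
    return [(s, e) for s, e in intervals]


def _build_region(chrom, windows, tracks, flags, names, starts, ends) -> SweepRegion:
    windows = np.asarray(windows)
    supporting = []
    peaks = {}
    for name in names:
        hit = windows[flags[name][windows]]
        if hit.size:
            supporting.append(name)
            peaks[name] = float(np.nanmax(tracks[name].values[hit]))
    return SweepRegion(
        chrom=chrom,
        start0=int(starts[windows].min()),
        end=int(ends[windows].max()),
        supporting=tuple(supporting),
        peaks=peaks,
    )


def annotate_regions(
    regions: list[SweepRegion], annotation: AnnotationTrack
) -> list[SweepRegion]:
    """Attach overlapping annotation names, grouped by category, to regions.

    Intervals are 0-based half-open on both sides, so touching intervals
    do not overlap.  Regions are annotated in place and returned.
    """
    df = annotation.intervals
    for region in regions:
        hits: dict[str, list[str]] = {}
        sub = df[df.chrom == region.chrom]
        overlap = sub[(sub.start < region.end) & (sub.end > region.start0)]
        for _, row in overlap.iterrows():
            hits.setdefault(row.category, []).append(row["name"])
        region.annotations = {cat: sorted(names) for cat, names in sorted(hits.items())}
    return regions


def write_regions(regions: list[SweepRegion], path) -> None:
    """Write called regions as a BED-like TSV with supporting statistics."""
    lines = ["chrom\tstart0\tend\tsupporting\tpeaks\tannotations"]
    for r in regions:
        peaks = ",".join(f"{k}={v:.4f}" for k, v in sorted(r.peaks.items()))
        anns = ";".join(
            f"{cat}:{'|'.join(names)}" for cat, names in sorted(r.annotations.items())
        )
        lines.append(
            f"{r.chrom}\t{r.start0}\t{r.end}\t{','.join(r.supporting)}\t{peaks}\t{anns or '.'}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
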