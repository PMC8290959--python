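"""Extended haplotype homozygosity (EHH), its integral and XP-EHH.

EHH at a given extent is the probability that two chromosomes drawn from
the population are identical over all sites from the core out to that
extent (the core site itself is excluded, so EHH at distance 0 is 1).
This is the all-chromosome, two-population form used for XP-EHH rather
than the allele-partitioned form used for iHS.

iHH integrates the EHH decay curve over physical distance (bp, trapezoid
rule) on both flanks, truncating each flank at the first extent where EHH
falls below a small threshold, or at a large inter-site gap.  XP-EHH is
ln(iHH_A / iHH_B) per core site, z-normalized genome-wide; with A the
cultivar and B the wild population, positive scores mean longer
haplotypes (a sweep) in cultivars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from soysweep.diversity import ScanConfig, WindowedStatTrack, make_windows
from soysweep.vcf_io import MISSING, HaplotypeMatrix


@dataclass
class XPEHHResult:
    """Per-core-site XP-EHH scores for one population pair."""

    chrom: str
    positions: np.ndarray  # 1-based bp of core sites
    ihh_a: np.ndarray
    ihh_b: np.ndarray
    raw: np.ndarray  # ln(iHH_A / iHH_B), NaN where either iHH is 0/NaN
    norm: np.ndarray | None = None  # genome-wide z-scores
    edge_clips: int = 0  # flanks that reached the chromosome edge under "clip"


def _ehh_value(ids: np.ndarray) -> float:
    counts = np.bincount(ids)
    n = counts.sum()
    if n < 2:
        return np.nan
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_at(
    matrix: HaplotypeMatrix,
    pop_rows: np.ndarray,
    core_index: int,
    extent_index: int,
    direction: str,
) -> float:
    """EHH of one population from ``core_index`` out to ``extent_index``.

    Chromosomes are grouped by their allele string over the sites strictly
    beyond the core up to and including the extent; EHH is the probability
    two random chromosomes fall in the same group, sum_g C(c_g,2) / C(n,2).
    A chromosome with a missing allele inside the span leaves the
    computation (n is decremented).  Returns NaN when fewer than 2
    chromosomes remain.
    """
    if not matrix.phased:
        raise ValueError("EHH requires a phased matrix")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    if direction == "right" and extent_index < core_index:
        raise ValueError("right extent must be >= core")
    if direction == "left" and extent_index > core_index:
        raise ValueError("left extent must be <= core")
    pop_rows = np.asarray(pop_rows)
    if pop_rows.size < 2:
        raise ValueError("need >= 2 chromosomes")
    if direction == "right":
        span = matrix.alleles[pop_rows, core_index + 1 : extent_index + 1]
    else:
        span = matrix.alleles[pop_rows, extent_index:core_index]
    keep = ~np.any(span == MISSING, axis=1)
    span = span[keep]
    if span.shape[0] < 2:
        return np.nan
    if span.shape[1] == 0:
        return 1.0
    _, ids = np.unique(span, axis=0, return_inverse=True)
    return _ehh_value(ids)


def _ehh_flank(
    sub: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    direction: str,
    config: ScanConfig,
):
    """EHH decay points (distance_bp, ehh) along one flank, incremental.

    ``sub`` holds the population's chromosomes only.  Returns
    (points, status) with status in {"truncated", "gap", "edge", "lost"}.
    Points all have ehh >= the truncation threshold; the first
    sub-threshold extent ends the walk and is not included.  Extension
    sites monomorphic among the active chromosomes cannot refine the
    partition and only extend the current EHH plateau.
    """
    n0 = sub.shape[0]
    n_sites = sub.shape[1]
    ids = np.zeros(n0, dtype=np.int64)
    active = np.ones(n0, dtype=bool)
    all_active = True
    e = 1.0
    points = [(0.0, 1.0)]
    step = 1 if direction == "right" else -1
    j = core_index + step
    core_pos = int(positions[core_index])
    prev_pos = core_pos
    while 0 <= j < n_sites:
        pos = int(positions[j])
        if abs(pos - prev_pos) > config.max_gap_bp:
            return points, "gap"
        col = sub[:, j]
        if (col == MISSING).any():
            newly_missing = active & (col == MISSING)
            if newly_missing.any():
                active &= ~newly_missing
                all_active = False
                if active.sum() < 2:
                    return points, "lost"
        vals = col if all_active else col[active]
        if vals.min() != vals.max():
            combined = (ids if all_active else ids[active]) * 2 + vals
            _, recoded = np.unique(combined, return_inverse=True)
            if all_active:
                ids = recoded
            else:
                ids[active] = recoded
            e = _ehh_value(recoded)
            if e < config.ehh_truncation:
                return points, "truncated"
            points.append((float(abs(pos - core_pos)), e))
            if recoded.size == np.max(recoded) + 1:
                # all singletons: EHH is 0 at the next split, stop early
                return points, "truncated"
        else:
            if not all_active:
                e = _ehh_value(ids[active])
                if e < config.ehh_truncation:
                    return points, "truncated"
            points.append((float(abs(pos - core_pos)), e))
        prev_pos = pos
        j += step
    return points, "edge"


def ihh(
    matrix: HaplotypeMatrix,
    pop_rows: np.ndarray,
    core_index: int,
    config: ScanConfig,
) -> tuple[float, int]:
    """Integrated EHH at one core site, summed over both flanks.

    Each flank's EHH curve is integrated by the trapezoid rule over
    physical distance in bp, truncated at the first extent where EHH drops
    below ``config.ehh_truncation`` or at an inter-site gap exceeding
    ``config.max_gap_bp`` (cut at the gap start).  A flank that reaches the
    chromosome edge above the truncation level is integrated as-is under
    ``edge_policy == "clip"`` (the second return value counts such flanks)
    and makes the whole iHH NaN under ``"discard"``.  NaN is also returned
    when missing data leave fewer than 2 chromosomes on either flank.
    """
    if not matrix.phased:
        raise ValueError("EHH requires a phased matrix")
    pop_rows = np.asarray(pop_rows)
    if pop_rows.size < 2:
        raise ValueError("need >= 2 chromosomes")
    sub = np.ascontiguousarray(matrix.alleles[pop_rows])
    return _ihh_sub(sub, matrix.positions, core_index, config)


def _ihh_sub(
    sub: np.ndarray, positions: np.ndarray, core_index: int, config: ScanConfig
) -> tuple[float, int]:
    total = 0.0
    clips = 0
    for direction in ("left", "right"):
        points, status = _ehh_flank(sub, positions, core_index, direction, config)
        if status == "lost":
            return np.nan, clips
        if status == "edge":
            if config.edge_policy == "discard":
                return np.nan, clips
            clips += 1
        d = np.array([p[0] for p in points])
        e = np.array([p[1] for p in points])
        if len(points) > 1:
            total += float(np.trapezoid(e, d))
    return total, clips


def xpehh_raw(ihh_a: float, ihh_b: float) -> float:
    """Raw XP-EHH score ln(iHH_A / iHH_B); NaN unless both are finite and > 0."""
    if not (np.isfinite(ihh_a) and np.isfinite(ihh_b)) or ihh_a <= 0 or ihh_b <= 0:
        return np.nan
    # log difference, not log of ratio: exactly antisymmetric in floats
    return float(np.log(ihh_a) - np.log(ihh_b))


def xpehh_scan(
    matrix: HaplotypeMatrix,
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    config: ScanConfig,
) -> XPEHHResult:
    """XP-EHH at every core site (pooled MAF >= ``config.core_maf_min``).

    Population A is conventionally the cultivar and B the wild group, so
    positive scores indicate extended haplotypes in cultivars.
    """
    rows_a, rows_b = np.asarray(rows_a), np.asarray(rows_b)
    pooled = np.concatenate([rows_a, rows_b])
    sub = matrix.alleles[pooled]
    present = sub != MISSING
    n = present.sum(axis=0)
    k = np.where(sub == 1, 1, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    cores = np.nonzero((maf >= config.core_maf_min) & (n >= 2))[0]

    sub_a = np.ascontiguousarray(matrix.alleles[rows_a])
    sub_b = np.ascontiguousarray(matrix.alleles[rows_b])
    ihh_a = np.full(cores.size, np.nan)
    ihh_b = np.full(cores.size, np.nan)
    clips = 0
    for i, core in enumerate(cores):
        ihh_a[i], c_a = _ihh_sub(sub_a, matrix.positions, int(core), config)
        ihh_b[i], c_b = _ihh_sub(sub_b, matrix.positions, int(core), config)
        clips += c_a + c_b
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where((ihh_a > 0) & (ihh_b > 0), np.log(ihh_a) - np.log(ihh_b), np.nan)
    return XPEHHResult(
        chrom=matrix.chrom,
        positions=matrix.positions[cores],
        ihh_a=ihh_a,
        ihh_b=ihh_b,
        raw=raw,
        edge_clips=int(clips),
    )


def normalize_xpehh(raw_scores: np.ndarray) -> np.ndarray:
    """Genome-wide z-normalization of raw XP-EHH scores.

    Uses the population standard deviation (divide by N) over all finite
    scores; NaN entries stay NaN.  Raises on fewer than 2 finite scores or
    zero spread.
    """
    raw = np.asarray(raw_scores, dtype=float)
    finite = np.isfinite(raw)
    if finite.sum() < 2:
        raise ValueError("need >= 2 finite raw scores to normalize")
    mean = raw[finite].mean()
    sd = raw[finite].std()  # population sd (ddof=0)
    if sd == 0:
        raise ValueError("raw XP-EHH scores are constant; cannot normalize")
    out = np.full_like(raw, np.nan)
    out[finite] = (raw[finite] - mean) / sd
    return out


def xpehh_window_track(
    result: XPEHHResult,
    config: ScanConfig,
    chrom_length_bp: int,
    stat_name: str = "xpehh_norm",
) -> WindowedStatTrack:
    """Aggregate per-site normalized scores to windows by taking the max.

    Windows with no finite core-site score get NaN.
    """
    if result.norm is None:
        raise ValueError("normalize the result before windowing")
    starts, ends = make_windows(chrom_length_bp, config)
    pos0 = result.positions - 1
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    values = np.full(starts.shape, np.nan)
    for w in range(starts.size):
        if hi[w] > lo[w]:
            chunk = result.norm[lo[w] : hi[w]]
            finite = np.isfinite(chunk)
            if finite.any():
                values[w] = chunk[finite].max()
    return WindowedStatTrack(result.chrom, starts, ends, stat_name, values)
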