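"""Windowed nucleotide diversity and the Hudson two-population F_ST.

Per-site pi is the unbiased mean pairwise difference 2k(n-k)/(n(n-1));
window values divide the summed site contributions by the full window span
in bp, so monomorphic (and absent) sites contribute zero.  F_ST uses the
Hudson estimator with Bhatia-style "ratio of averages" windowing: site
numerators and denominators are summed separately before dividing, which
is robust to low-information sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from soysweep.vcf_io import MISSING, HaplotypeMatrix


@dataclass
class ScanConfig:
    """Tuning knobs of the window scans.

    ``window_bp``/``step_bp`` define the sliding windows, ``top_quantile``
    the empirical genome-wide outlier threshold (0.95 = top 5% of
    windows), ``min_sites_per_window`` the segregating-site count below
    which a window's pi is reported as NaN.  ``ehh_truncation``,
    ``max_gap_bp``, ``edge_policy`` and ``core_maf_min`` govern the
    EHH/XP-EHH stage (see :mod:`soysweep.xpehh`).
    """

    window_bp: int = 40_000
    step_bp: int = 2_000
    top_quantile: float = 0.95
    min_sites_per_window: int = 3
    ehh_truncation: float = 0.05
    max_gap_bp: int = 200_000
    edge_policy: str = "clip"
    core_maf_min: float = 0.05

    def __post_init__(self):
        if not 0 < self.step_bp <= self.window_bp:
            raise ValueError("need 0 < step_bp <= window_bp")
        if not 0.5 < self.top_quantile < 1.0:
            raise ValueError("top_quantile must be in (0.5, 1)")
        if self.edge_policy not in ("clip", "discard"):
            raise ValueError("edge_policy must be 'clip' or 'discard'")
        if not 0 < self.ehh_truncation < 1:
            raise ValueError("ehh_truncation must be in (0, 1)")


@dataclass
class WindowedStatTrack:
    """Values of one named statistic over sliding windows of a chromosome.

    Windows are 0-based half-open ``[start, end)``; values may be NaN.
    ``extra`` holds unclipped/auxiliary per-window values where a
    statistic retains them (e.g. raw F_ST before clipping to [0, 1]).
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    stat_name: str
    values: np.ndarray
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts, ends and values must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("windows must satisfy start < end")
        if len(self.starts) > 1 and np.any(np.diff(self.starts) < 0):
            raise ValueError("windows must be sorted by start")

    def __len__(self) -> int:
        return len(self.starts)

    def same_windows(self, other: "WindowedStatTrack") -> bool:
        return (
            self.chrom == other.chrom
            and len(self) == len(other)
            and bool(np.all(self.starts == other.starts))
            and bool(np.all(self.ends == other.ends))
        )


def make_windows(chrom_length_bp: int, config: ScanConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sliding 0-based half-open windows covering ``[0, chrom_length_bp)``.

    All windows span ``window_bp`` except a possibly shorter terminal one.
    """
    if chrom_length_bp <= 0:
        raise ValueError("chromosome length must be positive")
    starts = np.arange(0, chrom_length_bp, config.step_bp, dtype=np.int64)
    # keep only windows that start new content: a window starting at or past
    # the end would be empty / duplicated coverage
    starts = starts[starts < chrom_length_bp]
    ends = np.minimum(starts + config.window_bp, chrom_length_bp)
    keep = ends > starts
    return starts[keep], ends[keep]


def site_pi(alt_count: int, chrom_count: int) -> float:
    """Mean pairwise difference at one site: 2k(n-k) / (n(n-1))."""
    k, n = alt_count, chrom_count
    if n < 2:
        raise ValueError(f"need >= 2 chromosomes, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"alt count {k} outside [0, {n}]")
    return 2.0 * k * (n - k) / (n * (n - 1.0))


def _site_counts(matrix: HaplotypeMatrix, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site alt counts and non-missing chromosome counts for a subset."""
    sub = matrix.alleles[rows]
    present = sub != MISSING
    n = present.sum(axis=0)
    k = np.where(sub == 1, 1, 0).sum(axis=0)
    return k.astype(np.int64), n.astype(np.int64)


def _window_site_slices(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray):
    """Index ranges of sites per window (positions are 1-based)."""
    pos0 = positions - 1  # 0-based coordinates of sites
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    return lo, hi


def windowed_pi(
    matrix: HaplotypeMatrix,
    pop_rows: np.ndarray,
    config: ScanConfig,
    chrom_length_bp: int | None = None,
    stat_name: str = "pi",
) -> WindowedStatTrack:
    """Nucleotide diversity per bp in sliding windows for one population.

    Window value = sum of per-site pi over sites in [start, end) divided
    by the window span; NaN when fewer than ``min_sites_per_window``
    genotyped variant sites fall in the window (too little data to judge
    -- note a swept window with many monomorphic variant sites validly
    reports 0, not NaN).
    """
    pop_rows = np.asarray(pop_rows)
    if pop_rows.size < 2:
        raise ValueError("need >= 2 chromosomes in the population")
    if chrom_length_bp is None:
        chrom_length_bp = int(matrix.positions[-1]) if matrix.n_sites else config.window_bp
    starts, ends = make_windows(chrom_length_bp, config)
    if len(starts) == 0:
        raise ValueError("empty window list")

    k, n = _site_counts(matrix, pop_rows)
    valid = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(valid, 2.0 * k * (n - k) / np.maximum(n * (n - 1.0), 1.0), 0.0)

    cum_pi = np.concatenate([[0.0], np.cumsum(per_site)])
    cum_sites = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    lo, hi = _window_site_slices(matrix.positions, starts, ends)
    sums = cum_pi[hi] - cum_pi[lo]
    n_sites_w = cum_sites[hi] - cum_sites[lo]
    values = sums / (ends - starts)
    values[n_sites_w < config.min_sites_per_window] = np.nan
    return WindowedStatTrack(matrix.chrom, starts, ends, stat_name, values)


def pi_ratio(track_wild: WindowedStatTrack, track_cultivar: WindowedStatTrack) -> WindowedStatTrack:
    """Per-window diversity ratio pi_S / pi_C (high values flag a cultivar sweep).

    NaN where the denominator is 0 or either input is NaN.
    """
    if not track_wild.same_windows(track_cultivar):
        raise ValueError("pi tracks must share identical windows")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = track_wild.values / track_cultivar.values
    ratio[~np.isfinite(ratio)] = np.nan
    return WindowedStatTrack(
        track_wild.chrom, track_wild.starts, track_wild.ends, "pi_ratio", ratio
    )


def hudson_fst_site(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """Hudson F_ST components for one site.

    Returns (numerator, denominator) with the sample-size bias correction:
    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    den = p1(1-p2) + p2(1-p1).
    """
    if n1 <= 1 or n2 <= 1:
        raise ValueError("need > 1 chromosome per population")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("allele frequencies must be in [0, 1]")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def windowed_fst(
    matrix: HaplotypeMatrix,
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    config: ScanConfig,
    chrom_length_bp: int | None = None,
) -> WindowedStatTrack:
    """Hudson F_ST in sliding windows, ratio-of-averages form.

    Window value = (sum of site numerators) / (sum of site denominators),
    clipped to [0, 1] in ``values``; the raw unclipped ratio is kept in
    ``extra['raw']``.  NaN where the denominator sum is 0.
    """
    rows_a, rows_b = np.asarray(rows_a), np.asarray(rows_b)
    if rows_a.size < 2 or rows_b.size < 2:
        raise ValueError("need >= 2 chromosomes per population")
    if chrom_length_bp is None:
        chrom_length_bp = int(matrix.positions[-1]) if matrix.n_sites else config.window_bp
    starts, ends = make_windows(chrom_length_bp, config)
    if len(starts) == 0:
        raise ValueError("empty window list")

    k1, n1 = _site_counts(matrix, rows_a)
    k2, n2 = _site_counts(matrix, rows_b)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, k1 / np.maximum(n1, 1), 0.0)
        p2 = np.where(n2 > 0, k2 / np.maximum(n2, 1), 0.0)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.maximum(n1 - 1, 1) - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(valid, num, 0.0)
    den = np.where(valid, den, 0.0)

    cum_num = np.concatenate([[0.0], np.cumsum(num)])
    cum_den = np.concatenate([[0.0], np.cumsum(den)])
    lo, hi = _window_site_slices(matrix.positions, starts, ends)
    num_w = cum_num[hi] - cum_num[lo]
    den_w = cum_den[hi] - cum_den[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(den_w > 0, num_w / den_w, np.nan)
    clipped = np.clip(raw, 0.0, 1.0)
    clipped = np.where(np.isnan(raw), np.nan, clipped)
    return WindowedStatTrack(
        matrix.chrom, starts, ends, "fst", clipped, extra={"raw": raw}
    )
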