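"""Replicate-level evaluation: scan a simulated cohort and call sweeps.

Convenience layer used by the recovery analyses: one call simulates a
cohort, runs the three-statistic scan (pi ratio, Hudson F_ST, normalized
XP-EHH), applies the genome-wide top-quantile thresholds and reports the
called regions together with whether the true focal position was
recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from soysweep.diversity import ScanConfig, WindowedStatTrack, pi_ratio, windowed_fst, windowed_pi
from soysweep.simulate import SimulatedCohort, SimulationConfig, simulate_domestication
from soysweep.sweeps import SweepRegion, call_sweeps, empirical_threshold
from soysweep.xpehh import normalize_xpehh, xpehh_scan, xpehh_window_track


@dataclass
class ScanResult:
    """Tracks, thresholds and sweep calls for one cohort."""

    cohort: SimulatedCohort
    tracks: dict[str, WindowedStatTrack]
    thresholds: dict[str, float]
    regions: list[SweepRegion]

    @property
    def focal_recovered(self) -> bool:
        focal0 = self.cohort.truth["focal_position"] - 1
        return any(r.contains(focal0) for r in self.regions)


def population_rows(cohort: SimulatedCohort, code: str) -> np.ndarray:
    matrix = cohort.haplotypes
    return matrix.chromosome_rows(
        [a for a in matrix.accessions if cohort.population_map[a] == code]
    )


def scan_cohort(
    cohort: SimulatedCohort,
    chrom_length_bp: int,
    scan: ScanConfig | None = None,
    min_support: int = 2,
    support_mode: str = "region",
) -> ScanResult:
    """Run the wild-vs-cultivar selection scan on a simulated cohort."""
    scan = scan or ScanConfig()
    matrix = cohort.haplotypes
    rows_s = population_rows(cohort, "S")
    rows_c = population_rows(cohort, "C")
    pi_s = windowed_pi(matrix, rows_s, scan, chrom_length_bp, stat_name="pi_S")
    pi_c = windowed_pi(matrix, rows_c, scan, chrom_length_bp, stat_name="pi_C")
    ratio = pi_ratio(pi_s, pi_c)
    fst = windowed_fst(matrix, rows_s, rows_c, scan, chrom_length_bp)
    xp = xpehh_scan(matrix, rows_c, rows_s, scan)
    xp.norm = normalize_xpehh(xp.raw)
    xp_track = xpehh_window_track(xp, scan, chrom_length_bp)
    tracks = {"pi_ratio": ratio, "fst": fst, "xpehh_norm": xp_track}
    thresholds = {
        name: empirical_threshold(track, scan.top_quantile)
        for name, track in tracks.items()
    }
    regions = call_sweeps(
        tracks, thresholds, min_support=min_support, support_mode=support_mode
    )
    return ScanResult(cohort, tracks, thresholds, regions)


def replicate_recovery(
    seed: int,
    s: float = 0.1,
    config_overrides: dict | None = None,
    min_support: int = 2,
) -> ScanResult:
    """Simulate one replicate at the default demography and scan it."""
    overrides = dict(config_overrides or {})
    config = SimulationConfig(seed=seed, s=s, **overrides)
    cohort = simulate_domestication(config)
    return scan_cohort(
        cohort, config.chrom_length_bp, min_support=min_support
    )
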