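"""Windowed selection scan: pi per subpopulation, pi ratio, F_ST, XP-EHH.

Reads the cohort written by 01_simulate_cohort.py, computes the sliding-
window statistics comparing wild (S) against cultivar (C), and writes the
five stat tracks plus the per-site XP-EHH table under results/scan/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from soysweep import (
    ScanConfig,
    normalize_xpehh,
    pi_ratio,
    read_population_map,
    read_vcf,
    windowed_fst,
    windowed_pi,
    write_stat_track,
    xpehh_scan,
)
from soysweep.xpehh import xpehh_window_track

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default=str(ROOT / "results" / "cohort"))
    ap.add_argument("--out", default=str(ROOT / "results" / "scan"))
    ap.add_argument("--window", type=int, default=40_000)
    ap.add_argument("--step", type=int, default=2_000)
    args = ap.parse_args()

    cohort_dir = Path(args.cohort)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_vcf(cohort_dir / "cohort.vcf")
    pop_map = read_population_map(cohort_dir / "population_map.tsv")
    sim_cfg = json.loads((cohort_dir / "sim_config.json").read_text())
    chrom_length = sim_cfg["chrom_length_bp"]

    scan = ScanConfig(window_bp=args.window, step_bp=args.step)
    rows = {
        p: matrix.chromosome_rows([a for a in matrix.accessions if pop_map[a] == p])
        for p in ("S", "C")
    }
    pi_s = windowed_pi(matrix, rows["S"], scan, chrom_length, stat_name="pi_S")
    pi_c = windowed_pi(matrix, rows["C"], scan, chrom_length, stat_name="pi_C")
    ratio = pi_ratio(pi_s, pi_c)
    fst = windowed_fst(matrix, rows["S"], rows["C"], scan, chrom_length)
    xp = xpehh_scan(matrix, rows["C"], rows["S"], scan)
    xp.norm = normalize_xpehh(xp.raw)
    xp_track = xpehh_window_track(xp, scan, chrom_length)

    for track in (pi_s, pi_c, ratio, fst, xp_track):
        path = out / f"track_{track.stat_name}.tsv"
        write_stat_track(track, path)
        finite = track.values[np.isfinite(track.values)]
        print(
            f"{track.stat_name:<12} windows={len(track)} finite={len(finite)} "
            f"median={np.median(finite):.4g} max={finite.max():.4g} -> {path}"
        )
    site_path = out / "xpehh_sites.tsv"
    with open(site_path, "w") as fh:
        fh.write("chrom\tpos\traw_xpehh\tnorm_xpehh\n")
        for pos, raw, norm in zip(xp.positions, xp.raw, xp.norm):
            fh.write(
                f"{xp.chrom}\t{pos}\t"
                f"{'NA' if np.isnan(raw) else format(raw, '.6f')}\t"
                f"{'NA' if np.isnan(norm) else format(norm, '.6f')}\n"
            )
    print(f"XP-EHH cores: {len(xp.positions)} (edge clips: {xp.edge_clips}) -> {site_path}")


if __name__ == "__main__":
    main()
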