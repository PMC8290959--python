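"""Call sweep regions from the scan tracks with genome-wide thresholds.

Applies the top-5% empirical threshold to pi-ratio, F_ST and normalized
XP-EHH, stacks their outlier intervals (region support, >= 2 statistics),
annotates the calls against the simulated focal locus, and writes
results/sweeps/sweep_regions.tsv.
"""

import argparse
import json
from pathlib import Path

from soysweep import read_stat_track
from soysweep.sweeps import call_sweeps, empirical_threshold, write_regions

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scan", default=str(ROOT / "results" / "scan"))
    ap.add_argument("--cohort", default=str(ROOT / "results" / "cohort"))
    ap.add_argument("--out", default=str(ROOT / "results" / "sweeps"))
    ap.add_argument("--quantile", type=float, default=0.95)
    ap.add_argument("--min-support", type=int, default=2)
    args = ap.parse_args()

    scan_dir = Path(args.scan)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    tracks = {}
    for name in ("pi_ratio", "fst", "xpehh_norm"):
        tracks[name] = read_stat_track(scan_dir / f"track_{name}.tsv")
    thresholds = {
        name: empirical_threshold(track, args.quantile)
        for name, track in tracks.items()
    }
    for name, thr in sorted(thresholds.items()):
        print(f"top-{100 * (1 - args.quantile):.0f}% threshold {name}: {thr:.4f}")

    regions = call_sweeps(
        tracks, thresholds, min_support=args.min_support, support_mode="region"
    )
    regions_path = out / "sweep_regions.tsv"
    write_regions(regions, regions_path)

    truth = json.loads((Path(args.cohort) / "truth.json").read_text())
    focal0 = truth["focal_position"] - 1
    print(f"{len(regions)} region(s) called -> {regions_path}")
    for r in regions:
        mark = "  <-- contains the selected focal site" if r.contains(focal0) else ""
        print(
            f"  {r.chrom}:{r.start0}-{r.end} ({(r.end - r.start0) / 1000:.0f} kb) "
            f"supported by {','.join(r.supporting)}{mark}"
        )


if __name__ == "__main__":
    main()
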