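"""Seed-trait differences among haplotype groups.

Maps each accession to its haplotype group via its homozygous gene-region
haplotype, then compares 100-seed weight, fatty-acid and protein content
across groups with pairwise Student's t-tests and compact letter
displays, overall and restricted to cultivars.  Writes summary tables
under results/traits/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from soysweep import read_population_map, read_trait_table, read_vcf
from soysweep.haplotypes import (
    accession_group_labels,
    assign_major_groups,
    collapse_haplotypes,
    extract_gene_variants,
    mj_network,
)
from soysweep.traits import associate_groups

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default=str(ROOT / "results" / "cohort"))
    ap.add_argument("--out", default=str(ROOT / "results" / "traits"))
    ap.add_argument("--flank", type=int, default=20_000)
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    cohort_dir = Path(args.cohort)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_vcf(cohort_dir / "cohort.vcf")
    pop_map = read_population_map(cohort_dir / "population_map.tsv")
    traits = read_trait_table(cohort_dir / "traits.tsv")
    truth = json.loads((cohort_dir / "truth.json").read_text())
    focal0 = truth["focal_position"] - 1

    gene = extract_gene_variants(matrix, (max(0, focal0 - args.flank), focal0 + args.flank))
    table = collapse_haplotypes(gene, pop_map)
    network = mj_network(table)
    try:
        assignment = assign_major_groups(network, "target_k", 3)
    except ValueError:
        assignment = assign_major_groups(network, "edge_cut", 2)
    labels, excluded = accession_group_labels(gene, assignment)
    print(f"{len(labels)} accessions grouped (excluded: {excluded})")

    for tag, subpop in (("all", None), ("cultivars", "C")):
        result = associate_groups(
            traits, labels, alpha=args.alpha, subpop_filter=subpop, pop_map=pop_map
        )
        result.summary.to_csv(out / f"summary_{tag}.tsv", sep="\t", index=False,
                              float_format="%.6g")
        result.pairwise.to_csv(out / f"pairwise_{tag}.tsv", sep="\t", index=False,
                               float_format="%.6g")
        print(f"--- {tag} ---")
        show = result.summary[["trait", "group", "n", "mean", "sd", "letter"]]
        print(show.to_string(index=False, float_format=lambda v: f"{v:.2f}"))


if __name__ == "__main__":
    main()
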