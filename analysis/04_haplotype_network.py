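"""Gene-region haplotypes, median-joining network and major groups.

Extracts the variants around the selected locus (MAF >= 0.01), collapses
chromosomes into haplotypes with S/L/C counts, builds the median-joining
network, cuts it into three major groups (H_I wild-enriched, H_III
cultivar-enriched), and tests each group's wild-vs-cultivar frequency
shift.  Writes tables and the GraphML/DOT network under results/haplotypes/.
"""

import argparse
import json
from pathlib import Path

from soysweep import read_population_map, read_vcf
from soysweep.haplotypes import (
    assign_major_groups,
    collapse_haplotypes,
    extract_gene_variants,
    haplotype_frequencies,
    mj_network,
    write_haplotype_table,
    write_network,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default=str(ROOT / "results" / "cohort"))
    ap.add_argument("--out", default=str(ROOT / "results" / "haplotypes"))
    ap.add_argument("--flank", type=int, default=20_000,
                    help="half-width of the gene region around the focal site")
    ap.add_argument("--maf-min", type=float, default=0.01)
    ap.add_argument("--groups", type=int, default=3)
    args = ap.parse_args()

    cohort_dir = Path(args.cohort)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_vcf(cohort_dir / "cohort.vcf")
    pop_map = read_population_map(cohort_dir / "population_map.tsv")
    truth = json.loads((cohort_dir / "truth.json").read_text())
    focal0 = truth["focal_position"] - 1
    region = (max(0, focal0 - args.flank), focal0 + args.flank)

    gene = extract_gene_variants(matrix, region, maf_min=args.maf_min)
    print(f"gene region {region[0]}-{region[1]}: {gene.n_sites} variants with MAF >= {args.maf_min}")
    table = collapse_haplotypes(gene, pop_map)
    write_haplotype_table(table, out / "haplotype_table.tsv")
    print(f"{len(table.table)} distinct haplotypes (excluded: {table.excluded})")

    network = mj_network(table)
    write_network(network, out / "network.graphml")
    write_network(network, out / "network.dot", fmt="dot")
    print(
        f"median-joining network: {len(network.observed)} observed + "
        f"{len(network.medians)} median nodes, MST cost {network.total_cost():.0f}"
    )

    try:
        assignment = assign_major_groups(network, "target_k", args.groups)
    except ValueError as err:
        print(f"target_k={args.groups} unreachable ({err}); falling back to edge_cut 2")
        assignment = assign_major_groups(network, "edge_cut", 2)
    with open(out / "haplotype_groups.tsv", "w") as fh:
        fh.write("haplotype_id\tgroup\n")
        for hid, label in sorted(assignment.hap_labels.items()):
            fh.write(f"{hid}\t{label}\n")
    print(f"major groups: {assignment.groups} (cutoff {assignment.cutoff})")

    freqs = haplotype_frequencies(table, assignment)
    freqs.hap_freqs.to_csv(out / "haplotype_frequencies.tsv", sep="\t", float_format="%.6f")
    if freqs.group_tests is not None:
        freqs.group_tests.to_csv(out / "group_frequency_tests.tsv", sep="\t", float_format="%.6g")
        print("wild-vs-cultivar frequency shifts per group:")
        print(freqs.group_tests.to_string(float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
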