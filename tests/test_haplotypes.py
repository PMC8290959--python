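"""Gene-region haplotypes, median-joining networks and major groups."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree

from soysweep.haplotypes import (
    HaplotypeTable,
    accession_group_labels,
    assign_major_groups,
    collapse_haplotypes,
    extract_gene_variants,
    haplotype_frequencies,
    mj_network,
)
from soysweep.vcf_io import SUBPOPULATIONS

from conftest import make_matrix


def table_from_strings(strings, counts_s=None, counts_l=None, counts_c=None):
    k = len(strings)
    counts_s = counts_s or [2] * k
    counts_l = counts_l or [0] * k
    counts_c = counts_c or [0] * k
    df = pd.DataFrame(
        {
            "haplotype": strings,
            "S": counts_s,
            "L": counts_l,
            "C": counts_c,
        }
    )
    df["total"] = df[list(SUBPOPULATIONS)].sum(axis=1)
    df.index = pd.Index([f"Hap_{i + 1:02d}" for i in range(k)], name="haplotype_id")
    return HaplotypeTable(table=df, mode="chromosome")


def mst_cost_oracle(strings):
    arr = np.array([[int(c) for c in s] for s in strings])
    d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return minimum_spanning_tree(d).sum()


class TestExtractGeneVariants:
    def test_maf_boundary_inclusive(self):
        # 200 chromosomes, 2 alt alleles -> maf exactly 0.01: retained
        col_at_boundary = np.zeros(200, dtype=np.int8)
        col_at_boundary[:2] = 1
        col_below = np.zeros(200, dtype=np.int8)
        col_below[0] = 1  # maf 0.005: removed
        alleles = np.stack([col_at_boundary, col_below], axis=1)
        m = make_matrix(alleles, positions=[15, 16])
        sub = extract_gene_variants(m, (0, 100), maf_min=0.01)
        assert list(sub.positions) == [15]

    def test_region_is_half_open(self):
        m = make_matrix(np.array([[0, 1], [1, 0]], dtype=np.int8), positions=[11, 21])
        sub = extract_gene_variants(m, (10, 20), maf_min=0.0)
        assert list(sub.positions) == [11]  # 0-based 20 excluded

    def test_empty_result_allowed(self):
        m = make_matrix(np.array([[0], [1]], dtype=np.int8), positions=[500])
        sub = extract_gene_variants(m, (0, 100))
        assert sub.n_sites == 0


class TestCollapseHaplotypes:
    def test_direct_collapse_counts(self):
        # 3 accessions: (01|01), (01|01), (10|10)
        alleles = np.array(
            [[0, 1], [0, 1], [0, 1], [0, 1], [1, 0], [1, 0]], dtype=np.int8
        )
        m = make_matrix(alleles)
        pop = {"acc1": "S", "acc2": "S", "acc3": "S"}
        table = collapse_haplotypes(m, pop)
        assert dict(zip(table.strings, table.table["total"])) == {"01": 4, "10": 2}

    def test_heterozygote_excluded_in_accession_mode(self):
        alleles = np.array([[0], [1], [0], [0]], dtype=np.int8)  # acc1 het
        m = make_matrix(alleles)
        pop = {"acc1": "C", "acc2": "C"}
        table = collapse_haplotypes(m, pop, mode="accession")
        assert table.excluded["heterozygous"] == 1
        assert table.table["total"].sum() == 2

    def test_missing_alleles_excluded_and_tallied(self):
        alleles = np.array([[0], [-1], [1], [1]], dtype=np.int8)
        m = make_matrix(alleles)
        table = collapse_haplotypes(m, {"acc1": "S", "acc2": "C"})
        assert table.excluded["missing"] == 1
        assert table.table["total"].sum() == 3

    def test_count_conservation_on_random_matrix(self):
        rng = np.random.default_rng(21)
        alleles = rng.integers(0, 2, size=(40, 6)).astype(np.int8)
        m = make_matrix(alleles)
        pop = {f"acc{i + 1}": "SLC"[i % 3] for i in range(20)}
        table = collapse_haplotypes(m, pop)
        assert table.table["total"].sum() == 40
        assert (
            table.table[list(SUBPOPULATIONS)].sum(axis=1) == table.table["total"]
        ).all()

    def test_unmapped_accession_rejected(self):
        m = make_matrix(np.zeros((2, 2), dtype=np.int8))
        with pytest.raises(KeyError):
            collapse_haplotypes(m, {})


class TestHaplotypeFrequencies:
    def test_single_haplotype_gets_proportion_one(self):
        t = table_from_strings(["0101"], counts_s=[4], counts_l=[6], counts_c=[2])
        freqs = haplotype_frequencies(t).hap_freqs
        assert freqs.loc["Hap_01"].tolist() == [1.0, 1.0, 1.0]

    def test_simple_proportions(self):
        t = table_from_strings(["00", "11"], counts_s=[8, 2])
        freqs = haplotype_frequencies(t).hap_freqs
        assert freqs["S"].tolist() == [0.8, 0.2]

    def test_empty_subpopulation_gives_nan(self):
        t = table_from_strings(["00", "11"], counts_s=[3, 1])
        freqs = haplotype_frequencies(t).hap_freqs
        assert freqs["C"].isna().all()

    def test_z_test_matches_hand_formula(self):
        from statsmodels.stats.proportion import proportions_ztest

        # oracle: pooled two-proportion z on counts 30/50 vs 10/50
        p_pool = (30 + 10) / 100
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / 50 + 1 / 50))
        z_expected = (0.6 - 0.2) / se
        z, _ = proportions_ztest([30, 10], [50, 50])
        assert z == pytest.approx(z_expected, abs=1e-9)


class TestMjNetwork:
    def test_two_haplotypes_single_edge(self):
        net = mj_network(table_from_strings(["000", "110"]))
        assert net.medians == []
        assert net.graph.edges["000", "110"]["weight"] == 2
        # distance-3 pair
        net = mj_network(table_from_strings(["000", "111"]))
        assert net.graph.edges["000", "111"]["weight"] == 3

    def test_triplet_gains_median_star(self):
        net = mj_network(table_from_strings(["000", "110", "011"]))
        assert net.medians == ["010"]
        assert net.total_cost() == 3  # star beats the 4-cost MST
        assert all(net.graph.edges[e]["weight"] == 1 for e in net.graph.edges)
        assert net.graph.degree["010"] == 3

    def test_perfect_path_needs_no_medians(self):
        net = mj_network(table_from_strings(["000", "100", "110", "111"]))
        assert net.medians == []
        assert sorted(net.graph.edges) == [
            ("000", "100"),
            ("100", "110"),
            ("110", "111"),
        ]

    def test_cost_never_worse_than_mst_on_random_sets(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n_sites = int(rng.integers(3, 11))
            n_haps = int(rng.integers(2, 9))
            seen = set()
            while len(seen) < n_haps:
                seen.add("".join(map(str, rng.integers(0, 2, n_sites))))
            strings = sorted(seen)
            net = mj_network(table_from_strings(strings))
            assert net.total_cost() <= mst_cost_oracle(strings) + 1e-9
            assert set(strings) <= set(net.graph.nodes)

    def test_medians_have_degree_at_least_two(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            seen = set()
            while len(seen) < 6:
                seen.add("".join(map(str, rng.integers(0, 2, 8))))
            net = mj_network(table_from_strings(sorted(seen)))
            for median in net.medians:
                assert net.graph.degree[median] >= 2

    def test_deterministic_for_fixed_input(self):
        strings = ["0000", "1100", "0011", "1111", "1010"]
        n1 = mj_network(table_from_strings(strings))
        n2 = mj_network(table_from_strings(strings))
        assert sorted(n1.graph.nodes) == sorted(n2.graph.nodes)
        assert sorted(n1.graph.edges) == sorted(n2.graph.edges)

    def test_duplicate_strings_rejected(self):
        with pytest.raises(ValueError):
            mj_network(table_from_strings(["00", "00"]))


class TestAssignMajorGroups:
    def test_star_with_unit_edges_is_one_group(self):
        net = mj_network(table_from_strings(["000", "110", "011"]))
        assignment = assign_major_groups(net, "edge_cut", 2)
        assert len(set(assignment.hap_labels.values())) == 1

    def test_weight_five_bridge_cut_at_three(self):
        strings = ["000000", "100000", "011111", "111111"]
        # pairs (000000,100000) and (011111,111111) distance 1; clusters
        # joined by distance-5 edges
        net = mj_network(table_from_strings(strings))
        assignment = assign_major_groups(net, "edge_cut", 3)
        labels = assignment.hap_labels
        assert len(set(labels.values())) == 2

    def test_target_k_recovers_generating_partition(self):
        rng = np.random.default_rng(77)
        centers = ["0000000000", "1111100000", "0001111111"]
        truth = {}
        seen = set()
        for gi, center in enumerate(centers):
            while sum(1 for s in truth.values() if s == gi) < 3:
                hap = list(center)
                j = int(rng.integers(0, 10))
                hap[j] = str(1 - int(hap[j]))  # within-cluster distance <= 1
                s = "".join(hap)
                if s not in seen:
                    seen.add(s)
                    truth[s] = gi
        strings = sorted(seen)
        net = mj_network(table_from_strings(strings))
        assignment = assign_major_groups(net, "target_k", 3)
        # recovered partition equals the generating one (up to label names)
        by_group = {}
        for s in strings:
            hid = [h for h, d in net.graph.nodes(data=True) if h == s][0]
        recovered = {}
        for node, label in assignment.labels.items():
            if node in truth:
                recovered.setdefault(label, set()).add(truth[node])
        assert all(len(v) == 1 for v in recovered.values())
        assert len(recovered) == 3

    def test_labels_ordered_by_wild_count(self):
        strings = ["000000", "111111"]
        t = table_from_strings(strings, counts_s=[1, 9], counts_c=[8, 2])
        net = mj_network(t)
        assignment = assign_major_groups(net, "edge_cut", 3)
        # the wild-enriched haplotype (9 S chromosomes) gets H_I
        assert assignment.labels["111111"] == "H_I"
        assert assignment.labels["000000"] == "H_II"

    def test_unreachable_target_k_lists_achievable(self):
        net = mj_network(table_from_strings(["00", "11"]))
        with pytest.raises(ValueError, match="achievable"):
            assign_major_groups(net, "target_k", 5)


class TestAccessionGroupLabels:
    def test_homozygous_het_and_missing(self):
        alleles = np.array(
            [[0, 0], [0, 0], [0, 1], [0, 0], [-1, 0], [0, 0], [1, 1], [1, 1]],
            dtype=np.int8,
        )
        m = make_matrix(alleles)
        t = table_from_strings(["00", "11"])
        net = mj_network(t)
        assignment = assign_major_groups(net, "edge_cut", 2)
        labels, excluded = accession_group_labels(m, assignment)
        assert set(labels) == {"acc1", "acc4"}
        assert excluded["heterozygous"] == 1
        assert excluded["missing"] == 1
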