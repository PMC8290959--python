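"""Gene-region haplotypes, median-joining networks and major groups.

The workflow mirrors the classic candidate-gene analysis of a
domestication cohort: restrict the phased matrix to the gene region,
drop rare polymorphisms (minor allele frequency below 1% by default),
collapse chromosomes into distinct haplotypes with per-subpopulation
counts, connect them in a median-joining network (observed haplotypes
plus inferred intermediate "median" vectors that shorten the network),
and cut the network into major haplotype groups (H_I, H_II, ...)
ordered by their enrichment in the wild subpopulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from statsmodels.stats.proportion import proportions_ztest

from soysweep.vcf_io import MISSING, SUBPOPULATIONS, HaplotypeMatrix

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX")


@dataclass
class HaplotypeTable:
    """Distinct gene-region haplotypes with chromosome counts per subpopulation.

    ``table`` is indexed by haplotype id (``Hap_01`` ... in descending
    total-count order) with columns ``haplotype`` (the 0/1 allele string),
    ``S``, ``L``, ``C`` and ``total``.  ``excluded`` tallies chromosomes or
    accessions dropped during collapsing (missing alleles, heterozygotes).
    """

    table: pd.DataFrame
    mode: str
    excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        lengths = self.table["haplotype"].str.len().unique()
        if len(lengths) > 1:
            raise ValueError("haplotype allele strings must have equal length")
        if (self.table[list(SUBPOPULATIONS)].to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def strings(self) -> list[str]:
        return list(self.table["haplotype"])

    def counts(self, subpop: str) -> pd.Series:
        return self.table[subpop]


def extract_gene_variants(
    matrix: HaplotypeMatrix, region: tuple[int, int], maf_min: float = 0.01
) -> HaplotypeMatrix:
    """Sites inside the 0-based half-open ``region`` with MAF >= ``maf_min``.

    The filter removes polymorphisms strictly rarer than the floor, so a
    site at exactly the boundary frequency is retained.  An empty result
    is allowed.
    """
    start, end = region
    if end <= start:
        raise ValueError("region must satisfy start < end")
    pos0 = matrix.positions - 1
    in_region = (pos0 >= start) & (pos0 < end)
    keep = in_region & (matrix.maf() >= maf_min)
    return matrix.subset_sites(keep)


def collapse_haplotypes(
    sub_matrix: HaplotypeMatrix,
    pop_map: dict[str, str],
    mode: str = "chromosome",
) -> HaplotypeTable:
    """Collapse the gene-region matrix into a haplotype count table.

    ``mode="chromosome"`` (default): every chromosome contributes its
    allele string; chromosomes containing a missing allele are excluded
    and tallied.  ``mode="accession"``: only accessions homozygous at all
    retained sites contribute, their string counted twice; heterozygous
    accessions are excluded and tallied.  Counts are split by the S/L/C
    subpopulation of the carrying accession.
    """
    if mode not in ("chromosome", "accession"):
        raise ValueError("mode must be 'chromosome' or 'accession'")
    for acc in sub_matrix.accessions:
        if acc not in pop_map:
            raise KeyError(f"accession {acc!r} missing from population map")

    counts: dict[str, dict[str, int]] = {}
    excluded = {"missing": 0, "heterozygous": 0}

    def add(string: str, pop: str, n: int) -> None:
        entry = counts.setdefault(string, {p: 0 for p in SUBPOPULATIONS})
        entry[pop] += n

    for i, acc in enumerate(sub_matrix.accessions):
        pop = pop_map[acc]
        h1 = sub_matrix.alleles[2 * i]
        h2 = sub_matrix.alleles[2 * i + 1]
        if mode == "chromosome":
            for h in (h1, h2):
                if np.any(h == MISSING):
                    excluded["missing"] += 1
                else:
                    add("".join(map(str, h)), pop, 1)
        else:
            if np.any(h1 == MISSING) or np.any(h2 == MISSING):
                excluded["missing"] += 1
            elif not np.array_equal(h1, h2):
                excluded["heterozygous"] += 1
            else:
                add("".join(map(str, h1)), pop, 2)

    rows = [
        {"haplotype": s, **pops, "total": sum(pops.values())}
        for s, pops in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["haplotype", *SUBPOPULATIONS, "total"])
    df = df.sort_values(
        ["total", "haplotype"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.index = pd.Index([f"Hap_{i + 1:02d}" for i in range(len(df))], name="haplotype_id")
    return HaplotypeTable(table=df, mode=mode, excluded=excluded)


@dataclass
class FrequencyResult:
    """Per-subpopulation haplotype (and group) proportions with shift tests."""

    hap_freqs: pd.DataFrame  # index hap id, columns S/L/C proportions
    group_freqs: pd.DataFrame | None = None
    group_tests: pd.DataFrame | None = None  # two-proportion z-test, S vs C


def haplotype_frequencies(
    table: HaplotypeTable, assignment: "GroupAssignment | None" = None
) -> FrequencyResult:
    """Haplotype proportions within each subpopulation (columns sum to 1).

    With a group assignment, proportions are also aggregated per major
    group and each group's wild-vs-cultivar (S vs C) frequency shift is
    tested with a two-proportion z-test.  Subpopulations with no
    chromosomes get NaN proportions.
    """
    if len(table.table) == 0:
        raise ValueError("empty haplotype table")
    df = table.table
    totals = {p: df[p].sum() for p in SUBPOPULATIONS}
    freqs = pd.DataFrame(
        {
            p: (df[p] / totals[p]) if totals[p] > 0 else np.full(len(df), np.nan)
            for p in SUBPOPULATIONS
        },
        index=df.index,
    )
    group_freqs = group_tests = None
    if assignment is not None:
        labels = pd.Series(
            [assignment.hap_labels[h] for h in df.index], index=df.index, name="group"
        )
        grouped = df.groupby(labels)[list(SUBPOPULATIONS)].sum()
        grouped = grouped.loc[sorted(grouped.index, key=_group_sort_key)]
        group_freqs = grouped.div(
            pd.Series(totals).replace(0, np.nan), axis="columns"
        )
        rows = []
        for group, row in grouped.iterrows():
            if totals["S"] > 0 and totals["C"] > 0:
                stat, p_value = proportions_ztest(
                    count=[row["S"], row["C"]], nobs=[totals["S"], totals["C"]]
                )
            else:
                stat, p_value = np.nan, np.nan
            rows.append(
                {
                    "group": group,
                    "count_S": int(row["S"]),
                    "count_C": int(row["C"]),
                    "freq_S": row["S"] / totals["S"] if totals["S"] else np.nan,
                    "freq_C": row["C"] / totals["C"] if totals["C"] else np.nan,
                    "z": stat,
                    "p_value": p_value,
                }
            )
        group_tests = pd.DataFrame(rows).set_index("group")
    return FrequencyResult(hap_freqs=freqs, group_freqs=group_freqs, group_tests=group_tests)


def _group_sort_key(label: str) -> int:
    return _ROMAN.index(label.split("_", 1)[1])


# ---------------------------------------------------------------------------
# median-joining network


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _mst_cost(strings: list[str]) -> float:
    if len(strings) < 2:
        return 0.0
    arr = np.array([[int(c) for c in s] for s in strings], dtype=np.int8)
    d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return float(minimum_spanning_tree(d).sum())


def _median_vector(a: str, b: str, c: str) -> str:
    """Coordinate-wise majority of three binary haplotype strings."""
    return "".join(
        x if x == y or x == z else y for x, y, z in zip(a, b, c)
    )


def _minimax_edges(strings: list[str], epsilon: int) -> list[tuple[str, str, int]]:
    """Feasible links: pairs whose distance is within epsilon of the minimax
    path distance (epsilon=0 gives the union of all minimum spanning trees)."""
    n = len(strings)
    arr = np.array([[int(c) for c in s] for s in strings], dtype=np.int8)
    d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)
    # minimax (widest-path) distances by Floyd-Warshall-style relaxation
    mm = d.copy()
    for k in range(n):
        mm = np.minimum(mm, np.maximum(mm[:, k][:, None], mm[k, :][None, :]))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= mm[i, j] + epsilon:
                edges.append((strings[i], strings[j], int(d[i, j])))
    return edges


@dataclass
class MJNetwork:
    """Median-joining haplotype network.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes are
    allele strings with attributes ``observed`` (bool), ``hap_id`` (for
    observed nodes) and per-subpopulation counts; edges carry a
    ``weight`` equal to the Hamming (mutational) distance.
    """

    graph: nx.Graph
    epsilon: int = 0

    @property
    def observed(self) -> list[str]:
        return [n for n, obs in self.graph.nodes(data="observed") if obs]

    @property
    def medians(self) -> list[str]:
        return [n for n, obs in self.graph.nodes(data="observed") if not obs]

    def total_cost(self) -> float:
        """Cost of a minimum spanning tree over all nodes of the network."""
        return _mst_cost(sorted(self.graph.nodes))


def mj_network(table: HaplotypeTable, epsilon: int = 0) -> MJNetwork:
    """Median-joining network over the observed haplotypes.

    Iteratively: (1) connect the current node set by its feasible links
    (minimum-spanning network with tolerance ``epsilon``); (2) among the
    coordinate-wise majority (median) vectors of all node triplets, add
    the one that most reduces the minimum-spanning cost of the node set,
    if any; (3) repeat to a fixed point; (4) prune median vectors of
    degree <= 1.  Ties are broken by lexicographic order of the allele
    strings, so the result is deterministic.
    """
    strings = table.strings
    if len(strings) < 2:
        raise ValueError("need >= 2 haplotypes for a network")
    if len(set(strings)) != len(strings):
        raise ValueError("duplicate allele strings; collapse haplotypes first")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")

    observed = set(strings)
    nodes = sorted(observed)
    max_medians = len(strings[0]) * max(len(strings), 2)
    for _ in range(max_medians):
        base_cost = _mst_cost(nodes)
        candidates = set()
        for a, b, c in itertools.combinations(nodes, 3):
            m = _median_vector(a, b, c)
            if m not in observed and m not in nodes:
                candidates.add(m)
        best = None
        for m in sorted(candidates):
            gain = base_cost - _mst_cost(nodes + [m])
            if gain > 0 and (best is None or gain > best[0]):
                best = (gain, m)
        if best is None:
            break
        nodes = sorted(nodes + [best[1]])

    # build the minimum-spanning network, pruning dead-end medians
    while True:
        edges = _minimax_edges(sorted(nodes), epsilon)
        degree: dict[str, int] = {n: 0 for n in nodes}
        for u, v, _ in edges:
            degree[u] += 1
            degree[v] += 1
        dead = [n for n in nodes if n not in observed and degree[n] <= 1]
        if not dead:
            break
        nodes = [n for n in nodes if n not in dead]

    graph = nx.Graph()
    df = table.table
    by_string = {row["haplotype"]: (hid, row) for hid, row in df.iterrows()}
    for n in sorted(nodes):
        if n in observed:
            hid, row = by_string[n]
            graph.add_node(
                n,
                observed=True,
                hap_id=hid,
                counts={p: int(row[p]) for p in SUBPOPULATIONS},
                total=int(row["total"]),
            )
        else:
            graph.add_node(
                n,
                observed=False,
                hap_id=None,
                counts={p: 0 for p in SUBPOPULATIONS},
                total=0,
            )
    for u, v, w in edges:
        graph.add_edge(u, v, weight=w)
    return MJNetwork(graph=graph, epsilon=epsilon)


@dataclass
class GroupAssignment:
    """Major-group labels for every network node.

    ``labels`` maps allele strings (observed haplotypes and medians) to
    group names ``H_I``, ``H_II``, ... ordered by descending
    wild-subpopulation chromosome count; ``hap_labels`` maps observed
    haplotype ids only.
    """

    method: str
    labels: dict[str, str]
    hap_labels: dict[str, str]
    cutoff: int | None = None

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.labels.values()), key=_group_sort_key)


def _components_at_cutoff(network: MJNetwork, cutoff: int) -> list[set[str]]:
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    for u, v, w in network.graph.edges(data="weight"):
        if w < cutoff:
            g.add_edge(u, v)
    return [set(c) for c in nx.connected_components(g)]


def assign_major_groups(
    network: MJNetwork, method: str = "target_k", k_or_cutoff: int = 3
) -> GroupAssignment:
    """Cut the network into major haplotype groups.

    ``method="edge_cut"``: remove every edge of weight >= ``k_or_cutoff``;
    groups are the resulting connected components (median vectors inherit
    their component's label).  ``method="target_k"``: use the smallest
    cutoff whose components contain observed haplotypes in exactly
    ``k_or_cutoff`` groups.  Groups are labelled H_I, H_II, ... by
    descending wild (S) chromosome count, with total count and then
    lexicographic order as tie-breaks.
    """
    if not nx.is_connected(network.graph):
        raise ValueError("network must be connected")
    if method == "edge_cut":
        cutoff = int(k_or_cutoff)
        components = _components_at_cutoff(network, cutoff)
    elif method == "target_k":
        k = int(k_or_cutoff)
        weights = [w for _, _, w in network.graph.edges(data="weight")]
        achievable = {}
        cutoff = None
        for c in range(1, max(weights) + 2):
            comps = _components_at_cutoff(network, c)
            n_observed_groups = sum(
                1 for comp in comps if any(network.graph.nodes[n]["observed"] for n in comp)
            )
            achievable.setdefault(n_observed_groups, c)
            if n_observed_groups == k:
                cutoff = c
                break
        if cutoff is None:
            raise ValueError(
                f"cannot split into {k} groups; achievable component counts: "
                f"{sorted(achievable)}"
            )
        components = _components_at_cutoff(network, cutoff)
    else:
        raise ValueError("method must be 'edge_cut' or 'target_k'")

    def wild_count(comp: set[str]) -> int:
        return sum(network.graph.nodes[n]["counts"]["S"] for n in comp)

    def total_count(comp: set[str]) -> int:
        return sum(network.graph.nodes[n]["total"] for n in comp)

    ordered = sorted(
        components,
        key=lambda comp: (-wild_count(comp), -total_count(comp), min(comp)),
    )
    labels: dict[str, str] = {}
    hap_labels: dict[str, str] = {}
    for rank, comp in enumerate(ordered):
        name = f"H_{_ROMAN[rank]}"
        for n in comp:
            labels[n] = name
            if network.graph.nodes[n]["observed"]:
                hap_labels[network.graph.nodes[n]["hap_id"]] = name
    return GroupAssignment(method=method, labels=labels, hap_labels=hap_labels, cutoff=cutoff)


def accession_group_labels(
    sub_matrix: HaplotypeMatrix, assignment: GroupAssignment
) -> tuple[dict[str, str], dict[str, int]]:
    """Per-accession group labels from the gene-region haplotypes.

    An accession homozygous (both chromosomes identical, no missing
    alleles) over the retained sites gets its haplotype's group;
    heterozygous or incomplete accessions are excluded and tallied.
    Haplotypes absent from the assignment (e.g. removed by collapsing)
    are tallied as ``unassigned``.
    """
    labels: dict[str, str] = {}
    excluded = {"heterozygous": 0, "missing": 0, "unassigned": 0}
    for i, acc in enumerate(sub_matrix.accessions):
        h1 = sub_matrix.alleles[2 * i]
        h2 = sub_matrix.alleles[2 * i + 1]
        if np.any(h1 == MISSING) or np.any(h2 == MISSING):
            excluded["missing"] += 1
            continue
        if not np.array_equal(h1, h2):
            excluded["heterozygous"] += 1
            continue
        string = "".join(map(str, h1))
        if string not in assignment.labels:
            excluded["unassigned"] += 1
            continue
        labels[acc] = assignment.labels[string]
    return labels, excluded


def write_haplotype_table(table: HaplotypeTable, path) -> None:
    table.table.to_csv(path, sep="\t")


def write_network(network: MJNetwork, path, fmt: str = "graphml") -> None:
    """Export the network as GraphML or DOT (counts flattened to attributes)."""
    g = nx.Graph()
    for n, data in network.graph.nodes(data=True):
        g.add_node(
            n,
            observed=bool(data["observed"]),
            hap_id=data["hap_id"] or "",
            total=int(data["total"]),
            **{f"count_{p}": int(c) for p, c in data["counts"].items()},
        )
    for u, v, w in network.graph.edges(data="weight"):
        g.add_edge(u, v, weight=int(w))
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        lines = ["graph haplotypes {"]
        for n, data in g.nodes(data=True):
            shape = "circle" if data["observed"] else "point"
            lines.append(f'  "{n}" [shape={shape}, label="{data["hap_id"] or n}"];')
        for u, v, data in g.edges(data=True):
            lines.append(f'  "{u}" -- "{v}" [label={data["weight"]}];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError("fmt must be 'graphml' or 'dot'")
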