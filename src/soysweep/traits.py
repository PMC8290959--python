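"""Haplotype-group trait comparisons with compact letter displays.

Each trait (100-seed weight in g, fatty-acid and protein content in % of
dry weight) is summarized per haplotype group and compared between all
group pairs with the classical pooled-variance Student's t-test (a Welch
variant is available).  Significance letters follow the usual
insert-and-absorb construction: groups sharing a letter are not
significantly different at the chosen alpha, and 'a' marks the
highest-mean cluster.  No multiple-testing correction is applied by
default (per-pair alpha); Bonferroni is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from soysweep.vcf_io import TRAIT_COLUMNS


def student_t_test(x, y, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test; returns (t, df, two-sided p).

    Default is the pooled-variance Student form with df = n_x + n_y - 2;
    ``welch=True`` uses the Welch-Satterthwaite variant.  Degenerate
    zero-variance input yields p = 1 when the means are equal and p = 0
    (with a warning) when they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per sample")
    pooled_var = (
        ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
        / (x.size + y.size - 2)
    )
    if pooled_var == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        warnings.warn("zero pooled variance with unequal means; p = 0", stacklevel=2)
        return np.inf if x.mean() > y.mean() else -np.inf, float(x.size + y.size - 2), 0.0
    if welch:
        res = stats.ttest_ind(x, y, equal_var=False)
        df = res.df
    else:
        res = stats.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    return float(res.statistic), float(df), float(res.pvalue)


def compact_letter_display(pairwise_p: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Significance letters for groups ordered by descending trait mean.

    ``pairwise_p`` is a symmetric k x k matrix of two-sided p-values with
    rows/columns in descending-mean order.  Two groups share at least one
    letter iff their pair is not significant (p >= ``alpha``; an untested
    NaN pair counts as not significant).  A letter corresponds to a clique
    of the not-significantly-different graph, so the minimal display is
    the smallest set of maximal cliques covering every group and every
    non-significant pair; with few groups this is found exactly by
    exhaustive search over maximal cliques.  Letters are ordered by the
    first (highest-mean) group they cover, so 'a' marks the top cluster.
    """
    import itertools

    import networkx as nx

    p = np.asarray(pairwise_p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("pairwise_p must be a square matrix")
    with np.errstate(invalid="ignore"):
        asym = np.nanmax(np.abs(p - p.T)) if p.size else 0.0
    if asym > 1e-12:
        raise ValueError("pairwise_p must be symmetric")
    k = p.shape[0]
    if k == 0:
        return []
    share = nx.Graph()
    share.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if not (np.isfinite(p[i, j]) and p[i, j] < alpha):
                share.add_edge(i, j)
    cliques = sorted(
        (frozenset(c) for c in nx.find_cliques(share)),
        key=lambda c: (min(c), sorted(c)),
    )
    edges = {frozenset(e) for e in share.edges}
    vertices = set(range(k))
    chosen = None
    for size in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, size):
            covered_v = set().union(*combo)
            if covered_v != vertices:
                continue
            covered_e = {
                frozenset((i, j)) for c in combo for i in c for j in c if i < j
            }
            if edges <= covered_e:
                chosen = combo
                break
        if chosen is not None:
            break
    columns = sorted((set(c) for c in chosen), key=lambda c: (min(c), sorted(c)))
    letters = ["" for _ in range(k)]
    for li, col in enumerate(columns):
        ch = chr(ord("a") + li)
        for g in sorted(col):
            letters[g] += ch
    return letters


@dataclass
class GroupTraitSummary:
    """Per-group trait summaries, pairwise tests and letters for one run."""

    summary: pd.DataFrame  # group x trait: n, mean, sd, median, q1, q3, letter
    pairwise: pd.DataFrame  # trait, group_a, group_b, t, df, p_value
    excluded: dict[str, int] = field(default_factory=dict)
    alpha: float = 0.05


def associate_groups(
    traits: pd.DataFrame,
    group_labels: dict[str, str],
    alpha: float = 0.05,
    subpop_filter: str | None = None,
    pop_map: dict[str, str] | None = None,
    welch: bool = False,
    bonferroni: bool = False,
) -> GroupTraitSummary:
    """Compare every trait across haplotype groups.

    ``traits`` is indexed by accession with the three standard trait
    columns; ``group_labels`` maps accessions to groups (accessions
    missing from it are excluded and tallied).  ``subpop_filter``
    restricts the analysis to one subpopulation (requires ``pop_map``),
    e.g. cultivars only, the usual guard against wild/domesticated
    confounding.  Missing trait values are dropped per trait.  Groups
    with fewer than 2 observations are summarized but not tested.
    """
    excluded = {"unlabelled": 0, "filtered": 0}
    accs = []
    for acc in traits.index:
        if subpop_filter is not None:
            if pop_map is None:
                raise ValueError("subpop_filter requires a population map")
            if pop_map.get(acc) != subpop_filter:
                excluded["filtered"] += 1
                continue
        if acc not in group_labels:
            excluded["unlabelled"] += 1
            continue
        accs.append(acc)
    if not accs:
        raise ValueError("no accessions left after filtering")
    sub = traits.loc[accs]
    labels = pd.Series({a: group_labels[a] for a in accs}, name="group")

    summary_rows = []
    pair_rows = []
    for trait in TRAIT_COLUMNS:
        values = sub[trait].dropna()
        by_group = {g: values[labels.loc[values.index] == g] for g in sorted(set(labels))}
        by_group = {g: v for g, v in by_group.items() if len(v) > 0}
        order = sorted(by_group, key=lambda g: -by_group[g].mean())
        testable = [g for g in order if len(by_group[g]) >= 2]
        k = len(testable)
        pmat = np.full((k, k), np.nan)
        n_pairs = k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                t, df, p = student_t_test(by_group[testable[i]], by_group[testable[j]], welch=welch)
                if bonferroni and n_pairs > 0:
                    p = min(1.0, p * n_pairs)
                pmat[i, j] = pmat[j, i] = p
                pair_rows.append(
                    {
                        "trait": trait,
                        "group_a": testable[i],
                        "group_b": testable[j],
                        "t": t,
                        "df": df,
                        "p_value": p,
                    }
                )
        letters = compact_letter_display(pmat, alpha) if k else []
        letter_of = dict(zip(testable, letters))
        for g in order:
            v = by_group[g]
            summary_rows.append(
                {
                    "trait": trait,
                    "group": g,
                    "n": int(len(v)),
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                    "median": float(v.median()),
                    "q1": float(v.quantile(0.25)),
                    "q3": float(v.quantile(0.75)),
                    "letter": letter_of.get(g, ""),
                }
            )
    return GroupTraitSummary(
        summary=pd.DataFrame(summary_rows),
        pairwise=pd.DataFrame(
            pair_rows, columns=["trait", "group_a", "group_b", "t", "df", "p_value"]
        ),
        excluded=excluded,
        alpha=alpha,
    )
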