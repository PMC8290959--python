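"""Student's t-test, compact letter display and group association."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soysweep.simulate import SimulationConfig, simulate_traits
from soysweep.traits import associate_groups, compact_letter_display, student_t_test
from soysweep.vcf_io import TRAIT_COLUMNS


def cld_oracle(pmat, alpha):
    """Minimal letter count: smallest edge-clique cover of the share graph.

    A letter is a clique of the "not significantly different" graph; every
    group needs a letter and every non-significant pair must share one, so
    the minimal count is the smallest set of maximal cliques covering all
    vertices and all edges (exhaustive over maximal cliques, valid because
    any clique in a cover can be grown to a maximal one).
    """
    import networkx as nx

    k = pmat.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if pmat[i, j] >= alpha:
                g.add_edge(i, j)
    cliques = [frozenset(c) for c in nx.find_cliques(g)]
    edges = {frozenset(e) for e in g.edges}
    vertices = set(range(k))
    for n_letters in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, n_letters):
            covered_v = set().union(*combo)
            covered_e = {
                frozenset((i, j))
                for c in combo
                for i in c
                for j in c
                if i < j
            }
            if covered_v == vertices and edges <= covered_e:
                return n_letters
    return k


def letters_to_columns(letters):
    cols = {}
    for g, ls in enumerate(letters):
        for ch in ls:
            cols.setdefault(ch, set()).add(g)
    return cols


class TestStudentTTest:
    def test_identical_samples(self):
        t, df, p = student_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1.0
        assert df == 4

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([3.0, 4, 5, 6])
        t, df, p = student_t_test(x, y)
        # independently coded pooled-variance formula + scipy CDF oracle
        sp2 = ((3) * x.var(ddof=1) + (3) * y.var(ddof=1)) / 6
        t_exp = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        p_exp = 2 * stats.t.sf(abs(t_exp), 6)
        assert t == pytest.approx(t_exp, abs=1e-9)
        assert df == 6
        assert p == pytest.approx(p_exp, abs=1e-9)

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(1, 1, size=12)
        t1, _, p1 = student_t_test(x, y)
        t2, _, p2 = student_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_zero_variance(self):
        t, _, p = student_t_test([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0
        with pytest.warns(UserWarning):
            t, _, p = student_t_test([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0

    def test_welch_variant(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=8), rng.normal(0, 5, size=30)
        t, df, p = student_t_test(x, y, welch=True)
        res = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            student_t_test([1.0], [1.0, 2.0])


class TestCompactLetterDisplay:
    def test_all_nonsignificant_single_letter(self):
        p = np.full((3, 3), 0.9)
        assert compact_letter_display(p, 0.05) == ["a", "a", "a"]

    def test_all_significant_distinct_letters(self):
        p = np.full((3, 3), 0.001)
        assert compact_letter_display(p, 0.05) == ["a", "b", "c"]

    def test_chain_overlap_a_ab_b(self):
        p = np.array(
            [
                [np.nan, 0.5, 0.01],
                [0.5, np.nan, 0.5],
                [0.01, 0.5, np.nan],
            ]
        )
        assert compact_letter_display(p, 0.05) == ["a", "ab", "b"]

    def test_non_symmetric_rejected(self):
        p = np.array([[np.nan, 0.1], [0.9, np.nan]])
        with pytest.raises(ValueError):
            compact_letter_display(p, 0.05)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            k = int(rng.integers(2, 7))
            p = np.full((k, k), np.nan)
            for i in range(k):
                for j in range(i + 1, k):
                    p[i, j] = p[j, i] = rng.random()
            letters = compact_letter_display(p, 0.3)
            cols = letters_to_columns(letters)
            # sharing relation reconstructed from letters equals threshold
            for i in range(k):
                for j in range(i + 1, k):
                    shares = any(i in c and j in c for c in cols.values())
                    assert shares == (p[i, j] >= 0.3)
            # minimal letter count against exhaustive search
            assert len(cols) == cld_oracle(p, 0.3)


class TestAssociateGroups:
    def _traits(self, labels, cfg):
        return simulate_traits(labels, cfg)

    def test_zero_noise_exact_means_distinct_letters(self):
        cfg = SimulationConfig(
            seed=3,
            trait_noise_sd={t: 0.0 for t in TRAIT_COLUMNS},
        )
        labels = (
            {f"a{k}": "I" for k in range(5)}
            | {f"b{k}": "II" for k in range(5)}
            | {f"c{k}": "III" for k in range(5)}
        )
        traits = self._traits(labels, cfg)
        res = associate_groups(traits, labels, alpha=0.05)
        seed = res.summary[res.summary.trait == "seed_weight_100"].set_index("group")
        assert seed.loc["III", "mean"] == pytest.approx(18.0)
        assert seed.loc["II", "mean"] == pytest.approx(15.0)
        assert seed.loc["I", "mean"] == pytest.approx(12.0)
        assert list(seed["letter"]) == ["a", "b", "c"]  # ordered by mean
        assert (res.pairwise.p_value < 1e-6).all()

    def test_recovers_generator_ordering_with_noise(self):
        cfg = SimulationConfig(seed=8)
        labels = (
            {f"a{k}": "I" for k in range(50)}
            | {f"b{k}": "II" for k in range(50)}
            | {f"c{k}": "III" for k in range(50)}
        )
        traits = self._traits(labels, cfg)
        res = associate_groups(traits, labels, alpha=0.05)
        for trait, ascending in [
            ("seed_weight_100", False),
            ("fatty_acid_pct", False),
            ("protein_pct", True),
        ]:
            sub = res.summary[res.summary.trait == trait]
            order = list(sub.sort_values("mean", ascending=False)["group"])
            expected = ["III", "II", "I"] if not ascending else ["I", "II", "III"]
            assert order == expected
            assert (res.pairwise[res.pairwise.trait == trait].p_value < 0.05).all()

    def test_subpopulation_filter_excludes_other_accessions(self):
        cfg = SimulationConfig(seed=5)
        labels = {"s1": "I", "s2": "I", "c1": "III", "c2": "III", "c3": "I", "c4": "I"}
        traits = self._traits(labels, cfg)
        pop_map = {"s1": "S", "s2": "S", "c1": "C", "c2": "C", "c3": "C", "c4": "C"}
        res = associate_groups(
            traits, labels, subpop_filter="C", pop_map=pop_map
        )
        assert res.excluded["filtered"] == 2
        assert res.summary["n"].groupby(res.summary["trait"]).sum().eq(4).all()

    def test_small_group_reported_but_untested(self):
        labels = {"a": "I", "b": "II", "c": "II", "d": "II"}
        traits = pd.DataFrame(
            {
                "seed_weight_100": [10.0, 14, 15, 16],
                "fatty_acid_pct": [18.0, 19, 20, 21],
                "protein_pct": [45.0, 44, 43, 42],
            },
            index=["a", "b", "c", "d"],
        )
        res = associate_groups(traits, labels)
        sub = res.summary[res.summary.trait == "seed_weight_100"].set_index("group")
        assert sub.loc["I", "n"] == 1
        assert sub.loc["I", "letter"] == ""  # untested
        assert set(res.pairwise.group_a) <= {"II"}
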