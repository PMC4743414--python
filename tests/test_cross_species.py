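"""GO enrichment, term-set Fisher comparison and the ortholog-partition
construction, checked against independent oracles (math.comb hypergeometric
sums, a hand-rolled union-find)."""

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

from enhanceodimer.cross_species import (
    GOAnnotation,
    build_partition,
    compare_gene_sets,
    compare_term_sets,
    go_enrichment,
    neg_log10,
    read_go_tsv,
    read_orthologs_tsv,
    term_set_of,
    write_go_tsv,
    write_orthologs_tsv,
)


# ---------------------------------------------------------------------------
# independent oracles


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_blocks(g_h, g_m, pairs):
    """Connected components of the bipartite orthology graph via union-find."""
    nodes = [("h", g) for g in g_h] + [("m", g) for g in g_m]
    uf = UnionFind(nodes)
    for h, m in pairs:
        if h in g_h and m in g_m:
            uf.union(("h", h), ("m", m))
    components: dict = {}
    for node in nodes:
        components.setdefault(uf.find(node), []).append(node)
    blocks_h, blocks_m = set(), set()
    for members in components.values():
        side_h = frozenset(g for s, g in members if s == "h")
        side_m = frozenset(g for s, g in members if s == "m")
        if side_h:
            blocks_h.add(side_h)
        if side_m:
            blocks_m.add(side_m)
    return blocks_h, blocks_m


def hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n), via math.comb."""
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / math.comb(N, n)


# ---------------------------------------------------------------------------
# GO enrichment


class TestGoEnrichment:
    def test_perfect_overlap_term_retained_with_exact_p(self):
        universe = {f"g{i}" for i in range(1000)}
        selected = {f"g{i}" for i in range(10)}
        ann = GOAnnotation(
            {g: frozenset({"GO:X"}) if g in selected else frozenset() for g in universe}
        )
        result = go_enrichment(selected, universe, ann, fdr=0.01)
        assert result.terms == {"GO:X"}
        ((term, p, q),) = result.stats
        assert p == pytest.approx(1 / math.comb(1000, 10), rel=1e-9)
        assert q >= p

    def test_empty_selection(self):
        ann = GOAnnotation({"g1": frozenset({"GO:X"})})
        assert go_enrichment(set(), {"g1"}, ann).terms == set()

    def test_selected_outside_universe_rejected(self):
        ann = GOAnnotation({"g1": frozenset()})
        with pytest.raises(ValueError):
            go_enrichment({"g2"}, {"g1"}, ann)

    def test_proportional_term_rarely_retained(self):
        # term annotating 10% of the universe and ~10% of the selection
        rng = np.random.default_rng(42)
        universe = [f"g{i}" for i in range(1000)]
        term_genes = set(rng.choice(universe, size=100, replace=False))
        ann = GOAnnotation(
            {g: frozenset({"GO:P"}) if g in term_genes else frozenset() for g in universe}
        )
        retained = 0
        for _ in range(200):
            selected = set(rng.choice(universe, size=20, replace=False))
            result = go_enrichment(selected, set(universe), ann, fdr=0.01)
            retained += "GO:P" in result.terms
        assert retained / 200 < 0.05

    def test_ancestor_closure_propagates(self):
        ann = GOAnnotation(
            {"g1": frozenset({"GO:child"}), "g2": frozenset()},
            parents={"GO:child": frozenset({"GO:parent"})},
        )
        assert ann.terms_for("g1", closure=True) == {"GO:child", "GO:parent"}
        assert ann.terms_for("g1") == {"GO:child"}

    def test_term_set_of_strips_statistics(self):
        universe = {f"g{i}" for i in range(100)}
        selected = {f"g{i}" for i in range(5)}
        ann = GOAnnotation(
            {g: frozenset({"GO:X"}) if g in selected else frozenset() for g in universe}
        )
        enriched = go_enrichment(selected, universe, ann)
        terms = term_set_of(enriched)
        assert terms == enriched.terms
        assert isinstance(terms, frozenset)


# ---------------------------------------------------------------------------
# term-set comparison


class TestCompareTermSets:
    def test_identical_sets_are_astronomical(self):
        universe = {f"T{i}" for i in range(10_000)}
        shared = {f"T{i}" for i in range(50)}
        p = compare_term_sets(shared, shared, universe)
        expected = hypergeom_upper_tail(50, 10_000, 50, 50)
        assert p == pytest.approx(expected, rel=1e-6)
        assert neg_log10(p) > 100

    def test_disjoint_small_sets_near_one(self):
        universe = {f"T{i}" for i in range(10_000)}
        t_h = {f"T{i}" for i in range(10)}
        t_m = {f"T{i}" for i in range(10, 20)}
        assert compare_term_sets(t_h, t_m, universe) > 0.9

    def test_full_universe_margin_gives_one(self):
        universe = {f"T{i}" for i in range(100)}
        t_m = {f"T{i}" for i in range(30)}
        assert compare_term_sets(universe, t_m, universe) == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            compare_term_sets(set(), set(), set())


# ---------------------------------------------------------------------------
# orthology partition


class TestBuildPartition:
    def test_one_to_one_all_singletons(self):
        g_h = {f"h{i}" for i in range(20)}
        g_m = {f"m{i}" for i in range(20)}
        pairs = [(f"h{i}", f"m{i}") for i in range(20)]
        partition = build_partition(g_h, g_m, pairs)
        assert all(len(b) == 1 for b in partition.blocks_h)
        assert all(len(b) == 1 for b in partition.blocks_m)
        assert len(partition.block_links) == 20

    def test_join_rule_merges_shared_target(self):
        partition = build_partition({"h1", "h2"}, {"m1"}, [("h1", "m1"), ("h2", "m1")])
        assert partition.blocks_h == (frozenset({"h1", "h2"}),)
        assert partition.block_links == ((frozenset({"h1", "h2"}), frozenset({"m1"})),)

    def test_unlinked_genes_stay_singletons(self):
        partition = build_partition({"h1", "h2"}, {"m1"}, [("h1", "m1")])
        assert frozenset({"h2"}) in partition.blocks_h

    def test_matches_union_find_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            n_h = int(rng.integers(5, 100))
            n_m = int(rng.integers(5, 100))
            g_h = {f"h{i}" for i in range(n_h)}
            g_m = {f"m{i}" for i in range(n_m)}
            n_edges = int(rng.integers(0, 2 * max(n_h, n_m)))
            pairs = [
                (f"h{int(rng.integers(n_h))}", f"m{int(rng.integers(n_m))}")
                for _ in range(n_edges)
            ]
            partition = build_partition(g_h, g_m, pairs)
            oracle_h, oracle_m = union_find_blocks(g_h, g_m, pairs)
            assert set(partition.blocks_h) == oracle_h
            assert set(partition.blocks_m) == oracle_m

    def test_fixed_point_and_duplication_invariance(self):
        g_h = {f"h{i}" for i in range(10)}
        g_m = {f"m{i}" for i in range(10)}
        pairs = [("h0", "m0"), ("h0", "m1"), ("h1", "m1"), ("h5", "m7")]
        once = build_partition(g_h, g_m, pairs)
        doubled = build_partition(g_h, g_m, pairs * 3)
        reordered = build_partition(g_h, g_m, list(reversed(pairs)))
        assert once == doubled == reordered
        # applying the join rule again (re-partitioning the blocks) is stable
        again = build_partition(g_h, g_m, pairs)
        assert again == once

    def test_block_count_monotone_in_edges(self):
        g_h = {f"h{i}" for i in range(8)}
        g_m = {f"m{i}" for i in range(8)}
        pairs = [(f"h{i}", f"m{(i * 3) % 8}") for i in range(8)]
        counts = []
        for k in range(len(pairs) + 1):
            partition = build_partition(g_h, g_m, pairs[:k])
            counts.append(len(partition.blocks_h) + len(partition.blocks_m))
        assert counts == sorted(counts, reverse=True)


class TestCompareGeneSets:
    def test_conserved_selection_is_significant(self):
        universe_h = {f"h{i}" for i in range(5000)}
        universe_m = {f"m{i}" for i in range(5000)}
        pairs = [(f"h{i}", f"m{i}") for i in range(5000)]
        g_h = {f"h{i}" for i in range(50)}
        g_m = {f"m{i}" for i in range(50)}
        p = compare_gene_sets(g_h, g_m, pairs, universe_h, universe_m)
        assert neg_log10(p) > 50

    def test_unrelated_sets_not_significant(self):
        universe_h = {f"h{i}" for i in range(100)}
        universe_m = {f"m{i}" for i in range(100)}
        pairs = [(f"h{i}", f"m{i}") for i in range(100)]
        g_h = {f"h{i}" for i in range(10)}
        g_m = {f"m{i}" for i in range(50, 60)}
        assert compare_gene_sets(g_h, g_m, pairs, universe_h, universe_m) >= 0.5

    def test_reduces_to_classical_fisher_under_one_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(50, 200))
            universe_h = {f"h{i}" for i in range(n)}
            universe_m = {f"m{i}" for i in range(n)}
            pairs = [(f"h{i}", f"m{i}") for i in range(n)]
            k_h, k_m = int(rng.integers(1, n // 2)), int(rng.integers(1, n // 2))
            g_h = {f"h{int(i)}" for i in rng.choice(n, size=k_h, replace=False)}
            g_m = {f"m{int(i)}" for i in rng.choice(n, size=k_m, replace=False)}
            p = compare_gene_sets(g_h, g_m, pairs, universe_h, universe_m)
            # classical gene-level test after mapping mouse genes to human ids
            mapped = {g.replace("m", "h") for g in g_m}
            a = len(g_h & mapped)
            table = [[a, len(g_h) - a], [len(mapped) - a, n - len(g_h) - len(mapped) + a]]
            _, expected = fisher_exact(table, alternative="greater")
            assert p == pytest.approx(expected, rel=1e-9)

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            compare_gene_sets({"hX"}, set(), [], {"h1"}, {"m1"})


class TestFileFormats:
    def test_orthologs_roundtrip(self, tmp_path):
        pairs = [("h1", "m1"), ("h1", "m2"), ("h2", "m2")]
        path = tmp_path / "ro.tsv"
        write_orthologs_tsv(pairs, path)
        assert read_orthologs_tsv(path) == pairs

    def test_go_roundtrip(self, tmp_path):
        ann = {"g1": {"GO:1", "GO:2"}, "g2": {"GO:2"}}
        path = tmp_path / "go.tsv"
        write_go_tsv(ann, path)
        back = read_go_tsv(path)
        assert back.gene_terms == {"g1": frozenset({"GO:1", "GO:2"}), "g2": frozenset({"GO:2"})}
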