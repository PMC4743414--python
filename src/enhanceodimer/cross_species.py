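"""Human-mouse comparison of dimer-selected gene sets.

Two complementary Fisher-exact comparisons:

* *Term level* - GO terms enriched in each species' selected genes
  (hypergeometric upper tail, Benjamini-Hochberg FDR) are intersected and
  the overlap is tested against the shared term universe.

* *Gene level* - because orthology is many-to-many, the two gene sets are
  first decomposed into the smallest partitions in which any two genes
  orthologous to a common block share a block. That fixed point equals the
  connected components of the bipartite orthology graph restricted to the
  two sets, each component contributing one human-side and one mouse-side
  block. The 2x2 table counts linked vs unlinked blocks against the number
  of equivalence classes of the combined gene universes.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GOAnnotation",
    "EnrichedTermSet",
    "OrthologyPartition",
    "go_enrichment",
    "term_set_of",
    "compare_term_sets",
    "build_partition",
    "compare_gene_sets",
    "neg_log10",
    "read_orthologs_tsv",
    "read_go_tsv",
    "write_go_tsv",
    "write_orthologs_tsv",
]


@dataclass
class GOAnnotation:
    """gene -> GO-term-set map with an optional child -> parents relation."""

    gene_terms: dict[str, frozenset[str]]
    parents: dict[str, frozenset[str]] = field(default_factory=dict)

    def terms_for(self, gene: str, closure: bool = False) -> frozenset[str]:
        terms = set(self.gene_terms.get(gene, frozenset()))
        if closure and terms:
            stack = list(terms)
            while stack:
                term = stack.pop()
                for parent in self.parents.get(term, frozenset()):
                    if parent not in terms:
                        terms.add(parent)
                        stack.append(parent)
        return frozenset(terms)

    @property
    def term_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for terms in self.gene_terms.values():
            out.update(terms)
        return frozenset(out)


@dataclass(frozen=True)
class EnrichedTermSet:
    """Terms retained at the FDR threshold, with their (p, q) statistics."""

    label: str
    fdr_threshold: float
    stats: tuple[tuple[str, float, float], ...]  # (term, p, q), retained only

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(term for term, _, _ in self.stats)


def go_enrichment(
    selected: set[str],
    universe: set[str],
    annotations: GOAnnotation,
    fdr: float = 0.01,
    label: str = "",
    ancestor_closure: bool = False,
) -> EnrichedTermSet:
    """Hypergeometric GO-term enrichment of ``selected`` within ``universe``.

    Per term annotated to >= 1 selected gene: upper-tail p for drawing the
    observed number of term genes in ``len(selected)`` draws from the
    universe; BH q across tested terms; terms with q < fdr are retained.
    """
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    if not selected:
        return EnrichedTermSet(label, fdr, ())

    term_genes: dict[str, set[str]] = defaultdict(set)
    for gene in universe:
        for term in annotations.terms_for(gene, closure=ancestor_closure):
            term_genes[term].add(gene)

    tested = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        k = len(selected & genes)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, len(universe), len(genes), len(selected)))
        tested.append((term, min(1.0, p)))
    if not tested:
        return EnrichedTermSet(label, fdr, ())
    _, q_values, _, _ = multipletests([p for _, p in tested], method="fdr_bh")
    stats = tuple(
        (term, p, max(float(q), p))
        for (term, p), q in zip(tested, q_values)
        if q < fdr
    )
    return EnrichedTermSet(label, fdr, stats)


def term_set_of(enriched: EnrichedTermSet) -> frozenset[str]:
    """The bare enriched-term ids, stripped of statistics."""
    return enriched.terms


def compare_term_sets(
    t_h: set[str], t_m: set[str], term_universe: set[str]
) -> float:
    """One-sided Fisher p that the two enriched-term sets overlap more than
    chance within the shared term universe."""
    if not term_universe:
        raise ValueError("empty term universe")
    if not (set(t_h) <= set(term_universe) and set(t_m) <= set(term_universe)):
        raise ValueError("term sets must lie within the term universe")
    a = len(set(t_h) & set(t_m))
    b = len(t_h) - a
    c = len(t_m) - a
    d = len(term_universe) - a - b - c
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


@dataclass(frozen=True)
class OrthologyPartition:
    """Block decompositions of the two gene sets plus block-level links."""

    blocks_h: tuple[frozenset[str], ...]
    blocks_m: tuple[frozenset[str], ...]
    block_links: tuple[tuple[frozenset[str], frozenset[str]], ...]

    @property
    def linked_h(self) -> int:
        return len({h for h, _ in self.block_links})

    @property
    def linked_m(self) -> int:
        return len({m for _, m in self.block_links})


def build_partition(
    g_h: set[str],
    g_m: set[str],
    r_o: Iterable[tuple[str, str]],
) -> OrthologyPartition:
    """Smallest partitions closed under the join rule: blocks orthologous to
    a common block in the other species are merged, to a fixed point.

    Equivalent to connected components of the bipartite graph on
    ``g_h | g_m`` with the orthology pairs restricted to those sets; genes
    without restricted orthology stay singletons.
    """
    graph = nx.Graph()
    graph.add_nodes_from(("h", g) for g in g_h)
    graph.add_nodes_from(("m", g) for g in g_m)
    for h, m in r_o:
        if h in g_h and m in g_m:
            graph.add_edge(("h", h), ("m", m))

    blocks_h: list[frozenset[str]] = []
    blocks_m: list[frozenset[str]] = []
    links: list[tuple[frozenset[str], frozenset[str]]] = []
    for component in nx.connected_components(graph):
        side_h = frozenset(g for s, g in component if s == "h")
        side_m = frozenset(g for s, g in component if s == "m")
        if side_h:
            blocks_h.append(side_h)
        if side_m:
            blocks_m.append(side_m)
        if side_h and side_m:
            links.append((side_h, side_m))
    blocks_h.sort(key=sorted)
    blocks_m.sort(key=sorted)
    links.sort(key=lambda hm: (sorted(hm[0]), sorted(hm[1])))
    return OrthologyPartition(tuple(blocks_h), tuple(blocks_m), tuple(links))


def compare_gene_sets(
    g_h: set[str],
    g_m: set[str],
    r_o: Iterable[tuple[str, str]],
    universe_h: set[str],
    universe_m: set[str],
) -> float:
    """One-sided Fisher p that the two selected gene sets share more
    ortholog-partition blocks than chance.

    The table rows/columns count human blocks linked to a mouse block (a),
    unlinked human blocks (b), unlinked mouse blocks (c), and the remainder
    of the universe equivalence classes N - a - b - c, where N is the block
    count of the full-universe partition under the full orthology relation.
    """
    if not (g_h <= universe_h and g_m <= universe_m):
        raise ValueError("gene sets must lie within their universes")
    pairs = list(r_o)
    selected = build_partition(g_h, g_m, pairs)
    a = selected.linked_h
    b = len(selected.blocks_h) - a
    a_m = selected.linked_m
    c = len(selected.blocks_m) - a_m
    full = build_partition(universe_h, universe_m, pairs)
    # equivalence classes of the union: a linked pair of blocks is one class
    n_classes = len(full.blocks_h) + len(full.blocks_m) - len(full.block_links)
    d = n_classes - a - b - c
    if d < 0:
        raise ValueError(
            f"universe classes ({n_classes}) fewer than selected blocks ({a + b + c})"
        )
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def neg_log10(p: float, cap: float = 320.0) -> float:
    """-log10(p), capped to keep underflowed p-values finite."""
    if p <= 0:
        return cap
    return min(cap, -math.log10(p))


# ---------------------------------------------------------------------------
# file formats


def read_orthologs_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of many-to-many ortholog pairs (human, mouse)."""
    pairs = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            h, m = line.split("\t")[:2]
            pairs.append((h, m))
    return pairs


def write_orthologs_tsv(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("#human_gene\tmouse_gene\n")
        for h, m in pairs:
            out.write(f"{h}\t{m}\n")


def read_go_tsv(path: str | Path) -> GOAnnotation:
    """Two-column TSV (gene, term), one association per row."""
    gene_terms: dict[str, set[str]] = defaultdict(set)
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            gene_terms[gene].add(term)
    return GOAnnotation({g: frozenset(t) for g, t in gene_terms.items()})


def write_go_tsv(annotations: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("#gene\tterm\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                out.write(f"{gene}\t{term}\n")
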