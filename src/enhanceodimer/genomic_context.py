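"""Genomic-context annotation of dimer instances.

Each instance is represented by its midpoint (floor of the interval average):
the midpoint picks the chromatin state, decides gene membership, and anchors
nearest-gene distances. Gene-selection queries follow the Q0-Q6 scheme:
Q0 selects genes containing an instance midpoint; Qi (i>=1) selects the
nearest gene of an instance whose distance is strictly below the Qi
threshold (100/500/1,000/5,000/10,000/50,000 bp).

Chromatin states use the 15-label ChromHMM vocabulary; the regulatory
"G-plus" group is {Strong_Enhancer, Active_Promoter, Weak_Promoter,
Weak_Enhancer} and its overrepresentation among instance states is scored
with an exact binomial upper tail against a background G-plus probability
(by default the G-plus base-pair fraction of the segmentation itself).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree
from scipy.stats import binom

from ._util import percent
from .dimer_discovery import DimerInstance

__all__ = [
    "GeneModel",
    "StateSegment",
    "G_PLUS",
    "CHROMHMM_STATES",
    "QUERY_THRESHOLDS",
    "UNANNOTATED",
    "midpoint",
    "nearest_gene",
    "select_genes",
    "within_gene_fraction",
    "assign_state",
    "gplus_fraction",
    "gplus_binomial",
    "tss_window_selection",
    "enhancer_overlap_fraction",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_chromhmm_bed",
    "write_chromhmm_bed",
]

G_PLUS = frozenset(
    {"Strong_Enhancer", "Active_Promoter", "Weak_Promoter", "Weak_Enhancer"}
)

# the 15-state vocabulary of the ChromHMM segmentations consumed here
CHROMHMM_STATES = (
    "Active_Promoter",
    "Weak_Promoter",
    "Poised_Promoter",
    "Strong_Enhancer",
    "Weak_Enhancer",
    "Insulator",
    "Txn_Transition",
    "Txn_Elongation",
    "Weak_Txn",
    "Repressed",
    "Heterochrom",
    "Repetitive_CNV_1",
    "Repetitive_CNV_2",
    "Low_Signal",
    "Quiescent",
)

QUERY_THRESHOLDS: dict[str, int] = {
    "Q1": 100,
    "Q2": 500,
    "Q3": 1_000,
    "Q4": 5_000,
    "Q5": 10_000,
    "Q6": 50_000,
}

UNANNOTATED = "Unannotated"


@dataclass(frozen=True)
class GeneModel:
    """Gene interval (0-based half-open) with strand, TSS and exon mask."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: empty gene interval")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for estart, eend in self.exons:
            if not (self.start <= estart < eend <= self.end):
                raise ValueError(f"{self.gene_id}: exon outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class StateSegment:
    chrom: str
    start: int
    end: int
    state_label: str
    cell_type: str = ""


def midpoint(instance: DimerInstance) -> int:
    """floor((start + end) / 2); even-length intervals take the left-of-centre base."""
    if instance.end <= instance.start:
        raise ValueError("instance interval is empty")
    return (instance.start + instance.end) // 2


def nearest_gene(
    pos: int, chrom: str, genes: Sequence[GeneModel]
) -> tuple[GeneModel | None, int | None, bool]:
    """(gene, distance, within_gene) for a genomic position.

    Distance 0 with within_gene=True when the position falls inside a gene;
    otherwise the distance to the nearest gene boundary (start of a
    downstream gene, last base of an upstream one). Ties break by the
    lexicographically smaller gene_id; (None, None, False) when the
    chromosome carries no genes.
    """
    best: tuple[int, str] | None = None
    best_gene: GeneModel | None = None
    for gene in genes:
        if gene.chrom != chrom:
            continue
        if gene.contains(pos):
            distance = 0
        elif pos < gene.start:
            distance = gene.start - pos
        else:
            distance = pos - (gene.end - 1)
        key = (distance, gene.gene_id)
        if best is None or key < best:
            best = key
            best_gene = gene
    if best_gene is None:
        return None, None, False
    return best_gene, best[0], best[0] == 0


def select_genes(
    instances: Sequence[DimerInstance],
    genes: Sequence[GeneModel],
    query: str,
) -> set[str]:
    """Q0-Q6 gene selection; each instance contributes its single nearest gene."""
    if query != "Q0" and query not in QUERY_THRESHOLDS:
        raise ValueError(f"unknown query {query!r}")
    selected: set[str] = set()
    for inst in instances:
        gene, distance, within = nearest_gene(midpoint(inst), inst.chrom, genes)
        if gene is None:
            continue
        if query == "Q0":
            if within:
                selected.add(gene.gene_id)
        elif distance < QUERY_THRESHOLDS[query]:
            selected.add(gene.gene_id)
    return selected


def within_gene_fraction(
    instances: Sequence[DimerInstance], genes: Sequence[GeneModel]
) -> int:
    """Percent (nearest integer) of instances whose midpoint lies in a gene."""
    if not instances:
        raise ValueError("within-gene fraction of zero instances is undefined")
    k = sum(
        1
        for inst in instances
        if nearest_gene(midpoint(inst), inst.chrom, genes)[2]
    )
    return percent(k, len(instances))


def _segment_tree(segments: Iterable[StateSegment]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for seg in segments:
        trees[seg.chrom].addi(seg.start, seg.end, seg.state_label)
    return trees


def assign_state(instance: DimerInstance, segments: Sequence[StateSegment]) -> str:
    """Label of the unique segment containing the instance midpoint."""
    mid = midpoint(instance)
    labels = [
        seg.state_label
        for seg in segments
        if seg.chrom == instance.chrom and seg.start <= mid < seg.end
    ]
    if len(labels) > 1:
        raise ValueError(
            f"overlapping state segments at {instance.chrom}:{mid} ({labels})"
        )
    return labels[0] if labels else UNANNOTATED


def assign_states(
    instances: Sequence[DimerInstance], segments: Sequence[StateSegment]
) -> list[str]:
    """Vectorised :func:`assign_state` using an interval tree."""
    trees = _segment_tree(segments)
    labels = []
    for inst in instances:
        mid = midpoint(inst)
        found = trees.get(inst.chrom, IntervalTree())[mid]
        if len(found) > 1:
            raise ValueError(f"overlapping state segments at {inst.chrom}:{mid}")
        labels.append(next(iter(found)).data if found else UNANNOTATED)
    return labels


def gplus_fraction(segments: Sequence[StateSegment]) -> float:
    """G-plus base-pair fraction of a segmentation (the default binomial p0)."""
    total = sum(seg.end - seg.start for seg in segments)
    if total == 0:
        raise ValueError("empty segmentation")
    plus = sum(seg.end - seg.start for seg in segments if seg.state_label in G_PLUS)
    return plus / total


def gplus_binomial(labels: Sequence[str], p0: float) -> tuple[int, int, float]:
    """(k, n, p) for observing at least k of n instance states in G-plus.

    Exact binomial upper tail P(X >= k), X ~ Binomial(n, p0).
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    n = len(labels)
    k = sum(1 for label in labels if label in G_PLUS)
    p_value = float(binom.sf(k - 1, n, p0)) if n else 1.0
    return k, n, min(1.0, p_value)


def tss_window_selection(
    instances: Sequence[DimerInstance],
    genes: Sequence[GeneModel],
    window: int = 10_000,
    min_instances: int = 3,
) -> set[str]:
    """Genes with >= min_instances instance midpoints strictly within
    +/-window of their TSS."""
    counts: dict[str, int] = defaultdict(int)
    mids = [(inst.chrom, midpoint(inst)) for inst in instances]
    for gene in genes:
        for chrom, mid in mids:
            if chrom == gene.chrom and abs(mid - gene.tss) < window:
                counts[gene.gene_id] += 1
    return {gid for gid, c in counts.items() if c >= min_instances}


def enhancer_overlap_fraction(
    instances: Sequence[DimerInstance],
    enhancers: Iterable[tuple[str, int, int]],
) -> tuple[int, int, int]:
    """(k, n, percent) of instances whose midpoint lies in an enhancer
    interval (enhancer calls are consumed as input, BED3)."""
    if not instances:
        raise ValueError("enhancer overlap of zero instances is undefined")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end in enhancers:
        if end > start:
            trees[chrom].addi(start, end)
    k = sum(
        1
        for inst in instances
        if trees.get(inst.chrom, IntervalTree())[midpoint(inst)]
    )
    n = len(instances)
    return k, n, percent(k, n)


# ---------------------------------------------------------------------------
# file formats


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Gene models from a 6-column TSV: gene_id, chrom, start, end, strand,
    comma-separated exon list 'start-end,start-end' (may be empty)."""
    genes = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene_id, chrom, start, end, strand, exon_field = line.split("\t")
            exons = tuple(
                tuple(int(x) for x in part.split("-"))
                for part in exon_field.split(",")
                if part
            )
            genes.append(GeneModel(gene_id, chrom, int(start), int(end), strand, exons))
    return genes


def write_genes_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("#gene_id\tchrom\tstart\tend\tstrand\texons\n")
        for g in genes:
            exon_field = ",".join(f"{s}-{e}" for s, e in g.exons)
            out.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{exon_field}\n")


def read_chromhmm_bed(path: str | Path, cell_type: str = "") -> list[StateSegment]:
    """ChromHMM segmentation BED: chrom, start, end, state label in column 4."""
    segments = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            segments.append(
                StateSegment(fields[0], int(fields[1]), int(fields[2]), fields[3], cell_type)
            )
    return segments


def write_chromhmm_bed(segments: Iterable[StateSegment], path: str | Path) -> None:
    with open(path, "w") as out:
        for seg in segments:
            out.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.state_label}\n")
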