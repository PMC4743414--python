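"""Seeded generators for every input the pipeline consumes.

The generators emulate the study's input universe - a genome, per-cell-type
open-chromatin peaks, motif matrices, gene models with exon masks, a
15-state chromatin segmentation, block-structured many-to-many orthology and
gene-GO annotations - with planted ground truth, so every downstream stage
is testable without external downloads. Default scales describe the
synthetic study conditions used throughout the test-suite: a 1 Mb
single-chromosome genome, 3 cell types with 100 peaks each, one dimer
structure planted at 30 copies in one cell type.

Each generator draws from its own RNG stream keyed by (seed, generator
name), so adding a generator never perturbs the output of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import ALPHABET, keyed_rng, revcomp
from .dimer_discovery import DimerInstance, DimerStructure, OpenRegion, canonical_structure
from .genomic_context import CHROMHMM_STATES, G_PLUS, GeneModel, StateSegment
from .cross_species import GOAnnotation
from .motif_model import PWM

__all__ = [
    "SyntheticTruth",
    "generate_genome",
    "generate_cell_type",
    "plant_dimer",
    "generate_genes",
    "generate_chromhmm",
    "generate_orthology",
    "generate_go",
    "make_pwm",
    "random_pwm",
    "write_fasta",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic study."""

    seed: int
    planted_structure: DimerStructure | None = None
    planted_cell_type: str | None = None
    planted_instances: list[DimerInstance] = field(default_factory=list)
    g_plus_fraction: float | None = None
    planted_terms: list[str] = field(default_factory=list)
    orthology_blocks: list[tuple[frozenset, frozenset]] = field(default_factory=list)


def generate_genome(length: int, gc: float = 0.41, seed: int = 0) -> str:
    """I.i.d. genome with P(G) + P(C) = gc; deterministic per seed."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = keyed_rng(seed, "genome")
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs)
    return "".join(ALPHABET[i] for i in codes)


def generate_cell_type(
    genome_length: int,
    n_peaks: int = 100,
    peak_len: tuple[int, int] = (150, 400),
    seed: int = 0,
    cell_type: str = "cellA",
    replicate: str = "rep1",
    chrom: str = "chr1",
) -> list[OpenRegion]:
    """Non-overlapping DNase-like peaks with positive signal values.

    One peak is placed uniformly inside each of ``n_peaks`` equal slots, so
    disjointness holds by construction.
    """
    lo, hi = peak_len
    slot = genome_length // n_peaks
    if slot < hi:
        raise ValueError(
            f"cannot pack {n_peaks} peaks of up to {hi} bp into {genome_length} bp"
        )
    rng = keyed_rng(seed, f"peaks:{cell_type}:{replicate}")
    regions = []
    for i in range(n_peaks):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(i * slot, (i + 1) * slot - length + 1))
        signal = float(rng.gamma(2.0, 2.0) + 0.1)
        regions.append(OpenRegion(chrom, start, start + length, signal, cell_type, replicate))
    return regions


def _sample_word(pwm: PWM, rng: np.random.Generator) -> str:
    probs = pwm.probs
    return "".join(
        ALPHABET[int(rng.choice(4, p=probs[i]))] for i in range(pwm.width)
    )


def plant_dimer(
    genome: str,
    pwm_a: PWM,
    pwm_b: PWM,
    orientation: tuple[str, str],
    spacing: int,
    peaks: Sequence[OpenRegion],
    n_copies: int = 30,
    seed: int = 0,
) -> tuple[str, list[DimerInstance]]:
    """Overwrite ``n_copies`` dimer occurrences into distinct target peaks.

    Motif words are drawn per column from the PWMs' smoothed probabilities;
    minus-strand sites receive the reverse complement. The gap bases are
    left as genomic background. Returns the modified genome and the truth
    instances carrying the canonical structure.
    """
    if spacing < 0:
        raise ValueError("planted spacing must be >= 0 (overlap cannot be written)")
    total = pwm_a.width + spacing + pwm_b.width
    suitable = [p for p in peaks if len(p) >= total]
    if n_copies > len(suitable):
        raise ValueError(
            f"cannot plant {n_copies} copies into {len(suitable)} peaks of >= {total} bp"
        )
    if n_copies == 0:
        return genome, []
    rng = keyed_rng(seed, "plant_dimer")
    chosen_idx = rng.choice(len(suitable), size=n_copies, replace=False)
    structure, canon_strand = canonical_structure(
        pwm_a.id, orientation[0], pwm_b.id, orientation[1], spacing
    )
    seq = list(genome)
    truth = []
    for idx in sorted(int(i) for i in chosen_idx):
        peak = suitable[idx]
        start = int(rng.integers(peak.start, peak.end - total + 1))
        word_a = _sample_word(pwm_a, rng)
        word_b = _sample_word(pwm_b, rng)
        if orientation[0] == "-":
            word_a = revcomp(word_a)
        if orientation[1] == "-":
            word_b = revcomp(word_b)
        seq[start : start + pwm_a.width] = word_a
        b_start = start + pwm_a.width + spacing
        seq[b_start : b_start + pwm_b.width] = word_b
        truth.append(
            DimerInstance(
                chrom=peak.chrom,
                start=start,
                end=start + total,
                structure=structure,
                cell_type=peak.cell_type,
                strand_of_canonical_form=canon_strand,
            )
        )
    return "".join(seq), truth


def generate_genes(
    genome_length: int,
    n_genes: int = 40,
    gene_len: tuple[int, int] = (2_000, 10_000),
    n_exons: tuple[int, int] = (1, 4),
    exon_len: tuple[int, int] = (100, 300),
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[list[GeneModel], list[tuple[str, int, int]]]:
    """Disjoint gene models with >= 1 exon each; the mask is the exon union."""
    slot = genome_length // n_genes
    if slot < gene_len[1]:
        raise ValueError(
            f"cannot pack {n_genes} genes of up to {gene_len[1]} bp into {genome_length} bp"
        )
    rng = keyed_rng(seed, "genes")
    genes = []
    mask: list[tuple[str, int, int]] = []
    for i in range(n_genes):
        length = int(rng.integers(gene_len[0], gene_len[1] + 1))
        start = int(rng.integers(i * slot, (i + 1) * slot - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(n_exons[0], n_exons[1] + 1))
        exons = []
        cursor = start
        for _ in range(k):
            remaining = start + length - cursor
            elen = int(rng.integers(exon_len[0], exon_len[1] + 1))
            if remaining < elen:
                break
            estart = cursor + int(rng.integers(0, remaining - elen + 1)) // max(1, k)
            exons.append((estart, estart + elen))
            cursor = estart + elen
        if not exons:
            exons = [(start, min(start + exon_len[0], start + length))]
        genes.append(
            GeneModel(f"g{i:04d}", chrom, start, start + length, strand, tuple(exons))
        )
        mask.extend((chrom, s, e) for s, e in exons)
    return genes, mask


def generate_chromhmm(
    genome_length: int,
    g_plus_fraction: float = 0.1,
    seg_len: tuple[int, int] = (200, 2_000),
    seed: int = 0,
    cell_type: str = "cellA",
    chrom: str = "chr1",
) -> list[StateSegment]:
    """Non-overlapping segments tiling the genome over the 15-state
    vocabulary; the expected G-plus bp fraction equals the request."""
    if not 0 <= g_plus_fraction <= 1:
        raise ValueError("g_plus_fraction must lie in [0, 1]")
    rng = keyed_rng(seed, f"chromhmm:{cell_type}")
    plus_labels = sorted(G_PLUS)
    minus_labels = [s for s in CHROMHMM_STATES if s not in G_PLUS]
    segments = []
    pos = 0
    plus_bp = 0
    while pos < genome_length:
        length = int(rng.integers(seg_len[0], seg_len[1] + 1))
        end = min(pos + length, genome_length)
        # quota steering keeps the realized bp fraction on target
        if plus_bp + (end - pos) / 2 < g_plus_fraction * end:
            label = plus_labels[int(rng.integers(len(plus_labels)))]
            plus_bp += end - pos
        else:
            label = minus_labels[int(rng.integers(len(minus_labels)))]
        segments.append(StateSegment(chrom, pos, end, label, cell_type))
        pos = end
    return segments


def generate_orthology(
    n_h: int,
    n_m: int,
    spectrum: Sequence[tuple[int, int, int]] = ((1, 1, 80),),
    seed: int = 0,
) -> tuple[list[str], list[str], list[tuple[str, str]], list[tuple[frozenset, frozenset]]]:
    """Block-structured many-to-many orthology.

    ``spectrum`` lists (human block size, mouse block size, block count);
    each block is completely connected. Genes left over stay singletons
    without orthology. Returns (human genes, mouse genes, pairs, truth
    blocks).
    """
    need_h = sum(h * c for h, _, c in spectrum)
    need_m = sum(m * c for _, m, c in spectrum)
    if need_h > n_h or need_m > n_m:
        raise ValueError("block spectrum exceeds the gene counts")
    rng = keyed_rng(seed, "orthology")
    genes_h = [f"h{i:05d}" for i in range(n_h)]
    genes_m = [f"m{i:05d}" for i in range(n_m)]
    order_h = list(rng.permutation(n_h))
    order_m = list(rng.permutation(n_m))
    pairs = []
    blocks = []
    ih = im = 0
    for h_size, m_size, count in spectrum:
        for _ in range(count):
            block_h = frozenset(genes_h[order_h[ih + j]] for j in range(h_size))
            block_m = frozenset(genes_m[order_m[im + j]] for j in range(m_size))
            ih += h_size
            im += m_size
            pairs.extend((h, m) for h in sorted(block_h) for m in sorted(block_m))
            blocks.append((block_h, block_m))
    return genes_h, genes_m, pairs, blocks


def generate_go(
    genes: Sequence[str],
    n_terms: int = 200,
    planted: Sequence[tuple[str, Sequence[str], float]] = (),
    base_rate: tuple[float, float] = (0.005, 0.05),
    planted_base_rate: float = 0.025,
    seed: int = 0,
) -> GOAnnotation:
    """Gene-GO annotations with uniform background rates and planted
    over-annotation.

    Each background term annotates every gene independently at a rate drawn
    from ``base_rate``. A planted (term, subset, factor) annotates subset
    members at ``min(1, factor * planted_base_rate)`` and everyone else at
    ``planted_base_rate``; factor 1 reduces to the null.
    """
    gene_list = list(genes)
    gene_set = set(gene_list)
    for term, subset, _ in planted:
        if not set(subset) <= gene_set:
            raise ValueError(f"planted subset of {term} contains unknown genes")
    rng = keyed_rng(seed, "go")
    gene_terms: dict[str, set[str]] = {g: set() for g in gene_list}
    for t in range(n_terms):
        rate = float(rng.uniform(*base_rate))
        mask = rng.random(len(gene_list)) < rate
        term = f"GO:{t:07d}"
        for gene, hit in zip(gene_list, mask):
            if hit:
                gene_terms[gene].add(term)
    for term, subset, factor in planted:
        subset_set = set(subset)
        boosted = min(1.0, factor * planted_base_rate)
        for gene in gene_list:
            rate = boosted if gene in subset_set else planted_base_rate
            if rng.random() < rate:
                gene_terms[gene].add(term)
    return GOAnnotation({g: frozenset(t) for g, t in gene_terms.items()})


def make_pwm(
    motif_id: str,
    consensus: str,
    dominant: float = 0.95,
    total: float = 100.0,
    background: np.ndarray | None = None,
) -> PWM:
    """Information-rich PWM around a consensus word (TRANSFAC-like counts)."""
    if not 0.25 < dominant <= 1.0:
        raise ValueError("dominant fraction must exceed 0.25")
    rows = []
    for base in consensus.upper():
        row = [total * (1 - dominant) / 3] * 4
        row[ALPHABET.index(base)] = total * dominant
        rows.append(row)
    kwargs = {} if background is None else {"background": background}
    return PWM(id=motif_id, counts=np.array(rows), **kwargs)


def random_pwm(
    motif_id: str, width: int, seed: int = 0, concentration: float = 0.5, total: float = 50.0
) -> PWM:
    """Random Dirichlet-column PWM, for oracle and property testing."""
    rng = keyed_rng(seed, f"pwm:{motif_id}")
    counts = rng.dirichlet([concentration] * 4, size=width) * total + 1e-6
    return PWM(id=motif_id, counts=counts)


def write_fasta(records: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as out:
        for name, seq in records.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
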