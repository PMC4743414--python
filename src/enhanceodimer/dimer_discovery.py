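"""Cell-type-specific overrepresentation of TF dimer arrangements.

A *dimer structure* is an unordered motif pair plus mutual orientation and
spacing (gap in bp between the end of the upstream hit and the start of the
downstream one; negative = overlap). Structures are enumerated from motif-hit
pairs inside open-chromatin peaks and each is tested for overrepresentation
in one cell type against the pooled peaks of all other cell types.

The test is an exact one-sided binomial rate comparison: with n_t instances
in b_t bp of target open chromatin and n_b in b_b bp of background,
``X ~ Bin(n_t + n_b, b_t / (b_t + b_b))`` and the p-value is ``P(X >= n_t)``,
with Benjamini-Hochberg correction across the structures tested in that cell
type. This statistic is this package's own; it reproduces the interface, not
the internals, of motif-pair discovery tools built around the same counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .motif_model import MotifHit

__all__ = [
    "OpenRegion",
    "DimerStructure",
    "DimerInstance",
    "EnrichmentResult",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bed3",
    "select_top_regions",
    "apply_masking",
    "canonical_structure",
    "find_dimer_instances",
    "test_overrepresentation",
    "rank_structures",
    "write_enrichment_tsv",
]

_FLIP = {"+": "-", "-": "+"}
_ORIENT_RANK = {("+", "+"): 0, ("+", "-"): 1, ("-", "+"): 2, ("-", "-"): 3}


@dataclass(frozen=True)
class OpenRegion:
    """One open-chromatin peak (0-based half-open) with its DNase signal."""

    chrom: str
    start: int
    end: int
    signal_value: float
    cell_type: str
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.chrom}:{self.start}-{self.end}: empty region")
        if self.signal_value < 0:
            raise ValueError("signal_value must be >= 0")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class DimerStructure:
    """Canonical motif pair + orientation + spacing; the tested unit."""

    pwm_a: str
    pwm_b: str
    orientation: tuple[str, str]
    spacing: int

    def label(self) -> str:
        return (
            f"{self.pwm_a}{self.orientation[0]};{self.pwm_b}{self.orientation[1]}"
            f"@{self.spacing}"
        )


@dataclass(frozen=True)
class DimerInstance:
    """A genomic occurrence of a structure inside one open region."""

    chrom: str
    start: int
    end: int
    structure: DimerStructure
    cell_type: str
    strand_of_canonical_form: str


@dataclass(frozen=True)
class EnrichmentResult:
    structure: DimerStructure
    cell_type: str
    target_count: int
    target_bp: int
    background_count: int
    background_bp: int
    p_value: float
    q_value: float


class NarrowPeakError(ValueError):
    pass


def read_narrowpeak(path: str | Path, cell_type: str, replicate: str = "rep1") -> list[OpenRegion]:
    """ENCODE narrowPeak (BED6+4) reader; signal comes from column 7."""
    regions = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise NarrowPeakError(
                    f"{path} line {lineno}: narrowPeak needs 10 columns, got {len(fields)}"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise NarrowPeakError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            regions.append(
                OpenRegion(chrom, start, end, float(fields[6]), cell_type, replicate)
            )
    return regions


def write_narrowpeak(regions: Iterable[OpenRegion], path: str | Path) -> None:
    with open(path, "w") as out:
        for r in regions:
            out.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t.\t{r.signal_value:g}\t-1\t-1\t"
                f"{(r.end - r.start) // 2}\n"
            )


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    """Plain BED3 intervals (masks, enhancer calls)."""
    out = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def select_top_regions(regions: Sequence[OpenRegion], count: int = 50_000) -> list[OpenRegion]:
    """Per replicate, the ``count`` highest-signal peaks (all if fewer).

    Ties break by (chrom, start) ascending, so the selection is stable.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    by_rep: dict[tuple[str, str], list[OpenRegion]] = defaultdict(list)
    for r in regions:
        by_rep[(r.cell_type, r.replicate)].append(r)
    kept: list[OpenRegion] = []
    for key in sorted(by_rep):
        group = sorted(by_rep[key], key=lambda r: (-r.signal_value, r.chrom, r.start))
        kept.extend(group[:count])
    kept.sort(key=lambda r: (r.cell_type, r.replicate, r.chrom, r.start))
    return kept


def _mask_trees(mask: Iterable[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end in mask:
        if end > start:
            trees[chrom].addi(start, end)
    for tree in trees.values():
        tree.merge_overlaps()
    return trees


def apply_masking(
    regions: Sequence[OpenRegion],
    mask: Iterable[tuple[str, int, int]],
    policy: str = "Majority",
) -> list[OpenRegion]:
    """Drop regions whose masked bases strictly exceed half their length.

    Survivors are returned unchanged (no trimming).
    """
    if policy != "Majority":
        raise ValueError(f"unsupported masking policy {policy!r}")
    trees = _mask_trees(mask)
    kept = []
    for r in regions:
        masked_bp = sum(
            min(r.end, iv.end) - max(r.start, iv.begin)
            for iv in trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end)
        )
        if masked_bp <= len(r) / 2:
            kept.append(r)
    return kept


def canonical_structure(
    pwm_up: str, strand_up: str, pwm_down: str, strand_down: str, spacing: int
) -> tuple[DimerStructure, str]:
    """Canonical form of an ordered (upstream, downstream) hit pair.

    A structure and its reverse-complement image describe the same dimer;
    the canonical form is the lexicographically smaller of the two, ordering
    by (pwm_a, pwm_b) then orientation rank (+,+) < (+,-) < (-,+) < (-,-).
    Returns the structure and the genomic strand carrying the canonical form.
    """
    fwd = (pwm_up, pwm_down, _ORIENT_RANK[(strand_up, strand_down)])
    rc = (pwm_down, pwm_up, _ORIENT_RANK[(_FLIP[strand_down], _FLIP[strand_up])])
    if fwd <= rc:
        structure = DimerStructure(pwm_up, pwm_down, (strand_up, strand_down), spacing)
        return structure, "+"
    structure = DimerStructure(
        pwm_down, pwm_up, (_FLIP[strand_down], _FLIP[strand_up]), spacing
    )
    return structure, "-"


def find_dimer_instances(
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    regions: Sequence[OpenRegion],
    max_gap: int = 50,
) -> list[DimerInstance]:
    """Co-occurrences of an a-hit and a b-hit inside one region.

    Spacing = downstream.start - upstream.end must satisfy |spacing| <=
    max_gap. Homodimer pairs (same PWM) are counted once, unordered, and a
    hit never pairs with itself. Hits may carry coordinates relative to a
    region (``sequence_id`` equal to the region key "{chrom}:{start}-{end}")
    or genomic coordinates (``sequence_id`` equal to the chromosome name);
    an instance must lie entirely within one region.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    homodimer = bool(hits_a) and bool(hits_b) and hits_a[0].pwm_id == hits_b[0].pwm_id

    by_seq_a: dict[str, list[MotifHit]] = defaultdict(list)
    for h in hits_a:
        by_seq_a[h.sequence_id].append(h)
    by_seq_b: dict[str, list[MotifHit]] = defaultdict(list)
    for h in hits_b:
        by_seq_b[h.sequence_id].append(h)

    def candidates(by_seq: dict[str, list[MotifHit]], region: OpenRegion, key: str) -> list[MotifHit]:
        relative = [h for h in by_seq.get(key, []) if h.end <= len(region)]
        genomic = [
            MotifHit(key, h.start - region.start, h.strand, h.score, h.pwm_id, h.width)
            for h in by_seq.get(region.chrom, [])
            if region.start <= h.start and h.end <= region.end
        ]
        return relative + genomic

    instances = []
    for region in regions:
        key = f"{region.chrom}:{region.start}-{region.end}"
        cand_a = candidates(by_seq_a, region, key)
        cand_b = candidates(by_seq_b, region, key)
        seen: set[tuple] = set()
        for ha in cand_a:
            for hb in cand_b:
                if homodimer and (ha.start, ha.strand) == (hb.start, hb.strand):
                    continue
                pair_key = tuple(sorted([(ha.start, ha.strand), (hb.start, hb.strand)]))
                if homodimer and pair_key in seen:
                    continue
                up, down = (ha, hb) if ha.start <= hb.start else (hb, ha)
                spacing = down.start - up.end
                if abs(spacing) > max_gap:
                    continue
                if homodimer:
                    seen.add(pair_key)
                structure, canon_strand = canonical_structure(
                    up.pwm_id, up.strand, down.pwm_id, down.strand, spacing
                )
                instances.append(
                    DimerInstance(
                        chrom=region.chrom,
                        start=region.start + up.start,
                        end=region.start + down.end,
                        structure=structure,
                        cell_type=region.cell_type,
                        strand_of_canonical_form=canon_strand,
                    )
                )
    instances.sort(key=lambda i: (i.chrom, i.start, i.end, i.structure))
    return instances


def test_overrepresentation(
    structure: DimerStructure,
    target_count: int,
    target_bp: int,
    background_count: int,
    background_bp: int,
    cell_type: str,
) -> EnrichmentResult:
    """Exact one-sided binomial test of target rate > background rate.

    Under the null, each of the ``target_count + background_count`` instances
    falls in the target independently with probability
    ``target_bp / (target_bp + background_bp)``; the p-value is the upper
    tail at the observed target count. q_value is filled by
    :func:`rank_structures`.
    """
    total_bp = target_bp + background_bp
    if total_bp <= 0 or target_bp <= 0:
        raise ValueError("open-chromatin bp totals must be positive")
    n = target_count + background_count
    p0 = target_bp / total_bp
    p_value = float(binom.sf(target_count - 1, n, p0)) if n > 0 else 1.0
    return EnrichmentResult(
        structure=structure,
        cell_type=cell_type,
        target_count=target_count,
        target_bp=target_bp,
        background_count=background_count,
        background_bp=background_bp,
        p_value=min(1.0, p_value),
        q_value=1.0,
    )


def rank_structures(
    instances_by_cell: Mapping[str, Sequence[DimerInstance]],
    bp_by_cell: Mapping[str, int],
    target_cell: str,
    min_target_instances: int = 1,
) -> list[EnrichmentResult]:
    """Test every structure seen in the target cell type against the pooled
    background of all other cell types; BH-correct within the cell type.

    Structures with fewer than ``min_target_instances`` target instances are
    skipped. Results are sorted by (q, p, structure).
    """
    target_counts: dict[DimerStructure, int] = defaultdict(int)
    for inst in instances_by_cell.get(target_cell, []):
        target_counts[inst.structure] += 1
    background_counts: dict[DimerStructure, int] = defaultdict(int)
    for cell, instances in instances_by_cell.items():
        if cell == target_cell:
            continue
        for inst in instances:
            background_counts[inst.structure] += 1

    target_bp = bp_by_cell[target_cell]
    background_bp = sum(bp for cell, bp in bp_by_cell.items() if cell != target_cell)

    results = [
        test_overrepresentation(
            structure,
            count,
            target_bp,
            background_counts.get(structure, 0),
            background_bp,
            target_cell,
        )
        for structure, count in sorted(target_counts.items())
        if count >= min_target_instances
    ]
    if results:
        _, q_values, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        results = [
            EnrichmentResult(
                r.structure,
                r.cell_type,
                r.target_count,
                r.target_bp,
                r.background_count,
                r.background_bp,
                r.p_value,
                max(float(q), r.p_value),
            )
            for r, q in zip(results, q_values)
        ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.structure))
    return results


def write_enrichment_tsv(results: Iterable[EnrichmentResult], path: str | Path, header_comment: str | None = None) -> None:
    rows = [
        {
            "cell_type": r.cell_type,
            "pwm_a": r.structure.pwm_a,
            "pwm_b": r.structure.pwm_b,
            "orientation": "".join(r.structure.orientation),
            "spacing": r.structure.spacing,
            "target_count": r.target_count,
            "background_count": r.background_count,
            "target_bp": r.target_bp,
            "background_bp": r.background_bp,
            "p": r.p_value,
            "q": r.q_value,
        }
        for r in results
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "cell_type", "pwm_a", "pwm_b", "orientation", "spacing",
            "target_count", "background_count", "target_bp", "background_bp",
            "p", "q",
        ],
    )
    with open(path, "w") as out:
        if header_comment:
            out.write(f"# {header_comment}\n")
        frame.to_csv(out, sep="\t", index=False)
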