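"""The interferon-beta enhanceosome: sequences, layout and dimer matching.

The enhanceosome is the rigidly structured 57-bp enhancer upstream of the
interferon-beta gene, bound by NF-kB (p50/RelA), ATF-2/c-Jun, IRF proteins
and three HMG I(Y) architectural sites (HMG-A, HMG-B in PRD IV, HMG-C in
PRD II). This module carries the human and mouse sequences with their
genomic anchors, maps motif hits onto them, matches genome-wide dimer
structures to the enhanceosome arrangement within a +/-2 bp tolerance, and
classifies matched dimers into the four site-pair types.

The sign convention for the spacing difference is
``delta = enhanceosome_spacing - structure.spacing``: a positive delta means
the enhanceosome pair is wider than the genome-wide arrangement, so the
recurrent "1 bp wider on the enhanceosome" observation reads delta = +1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dimer_discovery import DimerStructure, canonical_structure
from .motif_model import PWM, MotifHit, balanced_threshold, scan

__all__ = [
    "EnhanceosomeSequence",
    "BindingSiteLayout",
    "ArrangementMatch",
    "DIMER_TYPES",
    "builtin_sequences",
    "compare_sequences",
    "map_enhanceosome_hits",
    "match_structure",
    "classify_dimer_type",
    "spacing_summary",
    "write_builtin_fasta",
    "write_matches_tsv",
]

_HUMAN_SEQ = "TAAATGACATAGGAAAACTGAAAGGGAGAAGTGAAAGTGGGAAATTCCTCTGAATAG"
_MOUSE_SEQ = "AAAATGACAGAGGAAAACTGAAAGGGAGAACTGAAAGTGGGAAATTCCTCTGAGGCA"


@dataclass(frozen=True)
class EnhanceosomeSequence:
    """One species' 57-bp enhanceosome with its genomic anchor.

    ``upstream_offset`` is the distance in bp to the interferon-beta gene.
    """

    species: str
    sequence: str
    assembly: str
    chrom: str
    start_1based: int
    end_1based: int
    upstream_offset: int

    def __post_init__(self) -> None:
        if len(self.sequence) != 57:
            raise ValueError("enhanceosome sequences are exactly 57 bp")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("enhanceosome sequence must be over {A,C,G,T}")


def builtin_sequences() -> tuple[EnhanceosomeSequence, EnhanceosomeSequence]:
    """The human (hg19) and mouse (mm9) enhanceosome sequences as constants."""
    human = EnhanceosomeSequence(
        species="human",
        sequence=_HUMAN_SEQ,
        assembly="hg19",
        chrom="chr9",
        start_1based=21_077_989,
        end_1based=21_078_045,
        upstream_offset=44,
    )
    mouse = EnhanceosomeSequence(
        species="mouse",
        sequence=_MOUSE_SEQ,
        assembly="mm9",
        chrom="chr4",
        start_1based=0,  # locus known only as chr4, 101 bp upstream of Ifnb1
        end_1based=0,
        upstream_offset=101,
    )
    return human, mouse


def compare_sequences(a: str, b: str) -> list[int]:
    """1-based positions where two equal-length sequences differ, ascending."""
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    return [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]


@dataclass(frozen=True)
class BindingSiteLayout:
    """Named activator binding sites as 0-based half-open offsets in the
    57-bp sequence.

    The defaults transcribe the published site architecture: HMG-A and
    HMG-B flank/overlap the ATF-2/c-Jun site in PRD IV, IRF-A and IRF-B
    cover PRD III and PRD I, NF-kB covers PRD II with HMG-C inside it. The
    table is configurable because the architecture is reported graphically,
    not as coordinates.
    """

    sites: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "HMG-A": (0, 6),
            "ATF2": (3, 13),
            "HMG-B": (11, 18),
            "IRF-A": (13, 25),
            "IRF-B": (27, 39),
            "NFKB": (38, 48),
            "HMG-C": (41, 49),
        }
    )

    def __post_init__(self) -> None:
        for name, (start, end) in self.sites.items():
            if not (0 <= start < end <= 57):
                raise ValueError(f"site {name}: offsets must lie within [0, 57)")

    def assign(self, hit: MotifHit) -> str | None:
        """Site with maximal base overlap with the hit; ties to the leftmost
        site; None when nothing overlaps."""
        best: tuple[int, int, str] | None = None
        for name, (start, end) in self.sites.items():
            overlap = min(hit.end, end) - max(hit.start, start)
            if overlap <= 0:
                continue
            key = (-overlap, start, name)
            if best is None or key < best:
                best = key
        return best[2] if best else None


DIMER_TYPES: dict[frozenset, str] = {
    frozenset({"HMG-A", "ATF2"}): "HMG-A;ATF2",
    frozenset({"ATF2", "HMG-B"}): "ATF2;HMG-B",
    frozenset({"IRF-A", "IRF-B"}): "IRF-A;IRF-B",
    frozenset({"IRF-B", "HMG-C"}): "IRF-B;HMG-C",
}


@dataclass(frozen=True)
class ArrangementMatch:
    """A genome-wide structure matched to an enhanceosome hit pair."""

    structure: DimerStructure
    hit_a: MotifHit
    hit_b: MotifHit
    enhanceosome_spacing: int
    delta: int  # enhanceosome_spacing - structure.spacing; + = enh wider
    dimer_type: str


def map_enhanceosome_hits(
    pwms: Sequence[PWM],
    seq: EnhanceosomeSequence,
    thresholds: Mapping[str, float] | None = None,
    balanced_ratio: float = 100.0,
) -> list[MotifHit]:
    """Scan the 57-bp sequence with every PWM at its balanced threshold
    (overridable per PWM via ``thresholds``)."""
    thresholds = dict(thresholds or {})
    hits: list[MotifHit] = []
    for pwm in pwms:
        t = thresholds.get(pwm.id)
        if t is None:
            t = balanced_threshold(pwm, ratio=balanced_ratio)
        hits.extend(scan(pwm, seq.sequence, t, sequence_id=f"enhanceosome_{seq.species}"))
    hits.sort(key=lambda h: (h.start, h.strand, h.pwm_id))
    return hits


def match_structure(
    structure: DimerStructure,
    enh_hits: Sequence[MotifHit],
    tolerance: int = 2,
    layout: BindingSiteLayout | None = None,
) -> list[ArrangementMatch]:
    """Enhanceosome hit pairs realizing the structure within the tolerance.

    A pair matches when its canonical (pair, orientation) equals the
    structure's and |enhanceosome_spacing - structure.spacing| <= tolerance.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    layout = layout or BindingSiteLayout()
    hits_a = [h for h in enh_hits if h.pwm_id == structure.pwm_a]
    hits_b = [h for h in enh_hits if h.pwm_id == structure.pwm_b]
    homodimer = structure.pwm_a == structure.pwm_b

    matches = []
    seen: set[tuple] = set()
    for ha in hits_a:
        for hb in hits_b:
            if homodimer and (ha.start, ha.strand) == (hb.start, hb.strand):
                continue
            pair_key = tuple(sorted([(ha.start, ha.strand), (hb.start, hb.strand)]))
            if homodimer and pair_key in seen:
                continue
            up, down = (ha, hb) if ha.start <= hb.start else (hb, ha)
            enh_spacing = down.start - up.end
            candidate, _ = canonical_structure(
                up.pwm_id, up.strand, down.pwm_id, down.strand, enh_spacing
            )
            if (candidate.pwm_a, candidate.pwm_b, candidate.orientation) != (
                structure.pwm_a,
                structure.pwm_b,
                structure.orientation,
            ):
                continue
            delta = enh_spacing - structure.spacing
            if abs(delta) > tolerance:
                continue
            if homodimer:
                seen.add(pair_key)
            match = ArrangementMatch(
                structure=structure,
                hit_a=up,
                hit_b=down,
                enhanceosome_spacing=enh_spacing,
                delta=delta,
                dimer_type=_pair_type(up, down, layout),
            )
            matches.append(match)
    matches.sort(key=lambda m: (m.hit_a.start, m.hit_b.start, m.delta))
    return matches


def _pair_type(hit_a: MotifHit, hit_b: MotifHit, layout: BindingSiteLayout) -> str:
    site_a = layout.assign(hit_a)
    site_b = layout.assign(hit_b)
    if site_a is None or site_b is None:
        return "other"
    return DIMER_TYPES.get(frozenset({site_a, site_b}), "other")


def classify_dimer_type(match: ArrangementMatch, layout: BindingSiteLayout) -> str:
    """One of the four enhanceosome site-pair types, or "other"."""
    return _pair_type(match.hit_a, match.hit_b, layout)


def spacing_summary(matches: Iterable[ArrangementMatch]) -> pd.DataFrame:
    """Contingency of delta value x dimer type (long form, with counts)."""
    counter = Counter((m.delta, m.dimer_type) for m in matches)
    rows = [
        {"delta": delta, "dimer_type": dtype, "count": count}
        for (delta, dtype), count in sorted(counter.items())
    ]
    return pd.DataFrame(rows, columns=["delta", "dimer_type", "count"])


def write_builtin_fasta(path: str | Path) -> None:
    human, mouse = builtin_sequences()
    with open(path, "w") as out:
        for seq in (human, mouse):
            out.write(f">enhanceosome_{seq.species} {seq.assembly}\n{seq.sequence}\n")


def write_matches_tsv(matches: Iterable[ArrangementMatch], path: str | Path, header_comment: str | None = None) -> None:
    rows = [
        {
            "pwm_a": m.structure.pwm_a,
            "pwm_b": m.structure.pwm_b,
            "orientation": "".join(m.structure.orientation),
            "structure_spacing": m.structure.spacing,
            "enhanceosome_spacing": m.enhanceosome_spacing,
            "delta": m.delta,
            "dimer_type": m.dimer_type,
            "hit_a_start": m.hit_a.start,
            "hit_a_strand": m.hit_a.strand,
            "hit_b_start": m.hit_b.start,
            "hit_b_strand": m.hit_b.strand,
        }
        for m in matches
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "pwm_a", "pwm_b", "orientation", "structure_spacing",
            "enhanceosome_spacing", "delta", "dimer_type",
            "hit_a_start", "hit_a_strand", "hit_b_start", "hit_b_strand",
        ],
    )
    with open(path, "w") as out:
        if header_comment:
            out.write(f"# {header_comment}\n")
        frame.to_csv(out, sep="\t", index=False)
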