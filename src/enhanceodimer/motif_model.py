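"""Position weight matrix models with balanced score thresholds.

A PWM is a per-position count matrix over {A,C,G,T}. Scores are log-odds in
bits against a background base composition. The score cutoff used throughout
the pipeline is the *balanced threshold*: the smallest score ``t`` on a fixed
discretisation grid at which the false positive rate ``P(score >= t | bg)``
does not exceed ``ratio`` times the false negative rate
``P(score < t | motif)``. Both rates come from the exact distribution of the
discretised score, computed by column-wise convolution (no sampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

from ._util import ALPHABET, N_INDEX, encode, revcomp

NEG_INF = float("-inf")

__all__ = [
    "PWM",
    "MotifHit",
    "ScoreDistribution",
    "load_transfac",
    "write_transfac",
    "read_fasta",
    "log_odds_score",
    "score_distribution",
    "balanced_threshold",
    "scan",
]


@dataclass(frozen=True)
class PWM:
    """Binding model of one motif: counts, pseudocount and background.

    ``pseudocount_fraction`` is the fraction of each column's total count
    added as smoothing mass, distributed proportionally to the background.
    """

    id: str
    counts: np.ndarray  # shape (width, 4), nonnegative
    pseudocount_fraction: float = 0.01
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise ValueError(f"{self.id}: counts must be a (width, 4) matrix")
        if (counts < 0).any():
            raise ValueError(f"{self.id}: negative counts")
        if not (counts.sum(axis=1) > 0).all():
            raise ValueError(f"{self.id}: every position needs a positive count")
        if abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
            raise ValueError(f"{self.id}: background must be a positive probability vector")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def probs(self) -> np.ndarray:
        """Pseudocount-smoothed per-position probabilities (rows sum to 1)."""
        totals = self.counts.sum(axis=1, keepdims=True)
        pseudo = self.pseudocount_fraction * totals * self.background
        smoothed = self.counts + pseudo
        return smoothed / smoothed.sum(axis=1, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background), shape (width, 4)."""
        return np.log2(self.probs / self.background)

    def reverse_complement(self) -> "PWM":
        return PWM(
            id=self.id,
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount_fraction=self.pseudocount_fraction,
            background=self.background[::-1].copy(),
        )

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=1))


@dataclass(frozen=True, order=True)
class MotifHit:
    """One scored window on a named sequence; ``start`` is 0-based, forward
    coordinates regardless of strand."""

    sequence_id: str
    start: int
    strand: str  # '+' or '-'
    score: float
    pwm_id: str
    width: int

    @property
    def end(self) -> int:
        return self.start + self.width


class TransfacParseError(ValueError):
    pass


def _validate_transfac_rows(lines: Sequence[str]) -> None:
    """Pre-validate numbered count rows so errors can name the offending line."""
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if not fields:
            continue
        key = fields[0]
        if len(key) == 2 and key.isdigit():
            values = fields[1:]
            # an optional trailing consensus letter is part of the dialect
            if values and not _is_number(values[-1]):
                values = values[:-1]
            if len(values) != 4 or not all(_is_number(v) for v in values):
                raise TransfacParseError(
                    f"line {lineno}: matrix row {key!r} must have 4 numeric "
                    f"columns (A C G T), got {line.rstrip()!r}"
                )


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def load_transfac(
    path: str | Path,
    pseudocount_fraction: float = 0.01,
    background: np.ndarray | None = None,
) -> list[PWM]:
    """Read a TRANSFAC-dialect matrix file (``//``-delimited records,
    ``ID``/``AC`` headers, numbered count rows ordered A C G T)."""
    text = Path(path).read_text()
    if not text.strip():
        warnings.warn(f"{path}: empty TRANSFAC file, no matrices loaded")
        return []
    _validate_transfac_rows(text.splitlines())
    with open(path) as handle:
        try:
            records = bio_motifs.parse(handle, "transfac")
        except ValueError as exc:
            raise TransfacParseError(f"{path}: {exc}") from exc
    if background is None:
        background = np.full(4, 0.25)
    pwms = []
    for record in records:
        motif_id = record.get("ID") or record.get("AC") or f"motif_{len(pwms) + 1}"
        counts = np.column_stack([np.asarray(record.counts[b]) for b in ALPHABET])
        pwms.append(
            PWM(
                id=motif_id,
                counts=counts,
                pseudocount_fraction=pseudocount_fraction,
                background=background,
            )
        )
    return pwms


def write_transfac(pwms: Iterable[PWM], path: str | Path) -> None:
    """Write matrices in the TRANSFAC dialect that :func:`load_transfac` reads."""
    lines: list[str] = []
    for pwm in pwms:
        lines.append(f"ID  {pwm.id}")
        lines.append(f"AC  {pwm.id}")
        lines.append("XX")
        lines.append("P0      A      C      G      T")
        for i in range(pwm.width):
            row = pwm.counts[i]
            cells = "  ".join(f"{v:g}" for v in row)
            lines.append(f"{i + 1:02d}  {cells}  {ALPHABET[int(row.argmax())]}")
        lines.append("XX")
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {id: uppercase sequence} (N allowed)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def log_odds_score(pwm: PWM, seq: str, start: int, strand: str = "+") -> float:
    """Log-odds score (bits) of the width-w window at ``start``.

    On the minus strand the reverse complement of the window is scored.
    Any N inside the window disqualifies it (-inf).
    """
    if start < 0 or start + pwm.width > len(seq):
        raise IndexError(
            f"window [{start}, {start + pwm.width}) out of bounds for "
            f"sequence of length {len(seq)}"
        )
    window = seq[start : start + pwm.width].upper()
    if strand == "-":
        window = revcomp(window)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    codes = encode(window)
    if (codes == N_INDEX).any():
        return NEG_INF
    return float(pwm.log_odds[np.arange(pwm.width), codes].sum())


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact distribution of the discretised window score under one model.

    Each column's log-odds contribution is assigned to the nearest bin,
    ``floor(s / bin_width + 0.5)`` (halves up), and the window score is the
    sum of per-column bins; ``masses[i]`` is the probability of bin
    ``offset + i``.
    """

    bin_width: float
    offset: int
    masses: np.ndarray
    model: str

    @property
    def scores(self) -> np.ndarray:
        """Bin-centre scores aligned with :attr:`masses`."""
        return (self.offset + np.arange(len(self.masses))) * self.bin_width

    def sf(self, threshold: float) -> float:
        """P(score >= threshold) on the discretised support."""
        tbin = discretize(threshold, self.bin_width)
        return float(self.masses[self.scores_bins() >= tbin].sum())

    def cdf_below(self, threshold: float) -> float:
        """P(score < threshold) on the discretised support."""
        return float(1.0 - self.sf(threshold))

    def scores_bins(self) -> np.ndarray:
        return self.offset + np.arange(len(self.masses))


def discretize(score: float, bin_width: float) -> int:
    """Bin index of a score: nearest bin, halves rounded up."""
    return int(np.floor(score / bin_width + 0.5))


def score_distribution(
    pwm: PWM, model: str = "background", bin_width: float = 0.1
) -> ScoreDistribution:
    """Exact discretised score distribution by column-wise convolution.

    ``model='background'`` draws each column i.i.d. from the background;
    ``model='motif'`` draws from the PWM's smoothed column probabilities.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if model == "background":
        weights = np.tile(pwm.background, (pwm.width, 1))
    elif model == "motif":
        weights = pwm.probs
    else:
        raise ValueError(f"model must be 'background' or 'motif', got {model!r}")

    lo = pwm.log_odds
    masses = np.array([1.0])
    offset = 0
    for i in range(pwm.width):
        bins = np.array([discretize(s, bin_width) for s in lo[i]])
        col_lo, col_hi = bins.min(), bins.max()
        col = np.zeros(col_hi - col_lo + 1)
        for b, w in zip(bins, weights[i]):
            col[b - col_lo] += w
        masses = np.convolve(masses, col)
        offset += col_lo
    total = masses.sum()
    if abs(total - 1.0) > 1e-6:
        raise AssertionError(f"score distribution mass {total} drifted from 1")
    masses = masses / total
    return ScoreDistribution(bin_width=bin_width, offset=offset, masses=masses, model=model)


def balanced_threshold(
    pwm: PWM, ratio: float = 100.0, bin_width: float = 0.1
) -> float:
    """Smallest grid score ``t`` with ``FPR(t) <= ratio * FNR(t)``.

    FPR(t) = P(score >= t | background), FNR(t) = P(score < t | motif);
    both from the exact discretised distributions, so the returned threshold
    is a grid point. For a degenerate matrix where no grid point satisfies
    the condition, the maximal achievable score is returned with a warning.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    bg = score_distribution(pwm, "background", bin_width)
    mo = score_distribution(pwm, "motif", bin_width)
    lo_bin = min(bg.offset, mo.offset)
    hi_bin = max(bg.offset + len(bg.masses), mo.offset + len(mo.masses)) - 1

    bg_full = np.zeros(hi_bin - lo_bin + 1)
    bg_full[bg.offset - lo_bin : bg.offset - lo_bin + len(bg.masses)] = bg.masses
    mo_full = np.zeros(hi_bin - lo_bin + 1)
    mo_full[mo.offset - lo_bin : mo.offset - lo_bin + len(mo.masses)] = mo.masses

    # FPR(k) = sum of bg mass in bins >= k; FNR(k) = motif mass in bins < k
    fpr = bg_full[::-1].cumsum()[::-1]
    fnr = np.concatenate([[0.0], mo_full.cumsum()[:-1]])
    ok = fpr <= ratio * fnr
    if not ok.any():
        warnings.warn(
            f"{pwm.id}: no grid threshold reaches FPR <= {ratio} * FNR; "
            "returning the maximal score"
        )
        return hi_bin * bin_width
    k = int(np.argmax(ok))
    return (lo_bin + k) * bin_width


def scan(pwm: PWM, seq: str, threshold: float, sequence_id: str = "seq") -> list[MotifHit]:
    """All windows on both strands scoring >= threshold.

    Hits are sorted by start, then '+' before '-'; overlaps are allowed.
    """
    w = pwm.width
    if len(seq) < w:
        return []
    codes = encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)

    def window_scores(matrix: np.ndarray) -> np.ndarray:
        padded = np.hstack([matrix, np.full((w, 1), NEG_INF)])  # N column
        return padded[np.arange(w)[None, :], windows].sum(axis=1)

    fwd = window_scores(pwm.log_odds)
    rev = window_scores(pwm.reverse_complement().log_odds)

    hits = []
    for start in np.nonzero(fwd >= threshold)[0]:
        hits.append(MotifHit(sequence_id, int(start), "+", float(fwd[start]), pwm.id, w))
    for start in np.nonzero(rev >= threshold)[0]:
        hits.append(MotifHit(sequence_id, int(start), "-", float(rev[start]), pwm.id, w))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
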