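"""Per-codon log-odds enrichment between two sequence sets.

For a focal codon c in synonymous block B, with n1 = count of c in the target
set, s1 = count of c's synonyms (block minus c) in the target set, and n2, s2
the same in the comparator set:

    log_odds = ln((n1 / s1) / (n2 / s2))
    se       = sqrt(1/n1 + 1/n2 + 1/s1 + 1/s2)

One entry per scored codon gives the 59-element enrichment vector (for the
standard partition).  Zero cells are either continuity-corrected (+0.5 on all
four cells, flagged) or dropped, per the ``correction`` setting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genetic_code import GeneticCodePartition, STOP_CODONS, is_valid_codon

UNDEFINED = float("nan")

CORRECTION_HALF_UNIT = "half-unit"
CORRECTION_DROP = "drop"


class WindowStopError(ValueError):
    """A stop codon appeared inside a window that must be stop-free."""


@dataclass
class CodonCounts:
    """Codon occurrence counts over the sense codons."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = dict(self.counts)
        for c, n in other.counts.items():
            merged[c] = merged.get(c, 0) + n
        return CodonCounts(merged)


@dataclass
class LogOddsEntry:
    codon: str
    n_codon_target: float
    n_syn_target: float
    n_codon_comp: float
    n_syn_comp: float
    log_odds: float
    se: float
    corrected: bool = False

    @property
    def defined(self) -> bool:
        return math.isfinite(self.log_odds)


@dataclass
class LogOddsVector:
    """A labelled per-codon enrichment vector, alphabetical codon order."""

    label: str
    entries: dict[str, LogOddsEntry]
    provenance: str = ""

    @property
    def codons(self) -> list[str]:
        return sorted(self.entries)

    def values(self) -> list[float]:
        return [self.entries[c].log_odds for c in self.codons]

    def __getitem__(self, codon: str) -> LogOddsEntry:
        return self.entries[codon]

    def as_dict(self) -> dict[str, float]:
        return {c: self.entries[c].log_odds for c in self.codons}


@dataclass
class PositionalMatrix:
    """One LogOddsVector per codon position, shared codon ordering."""

    positions: list[int]
    vectors: list[LogOddsVector] = field(default_factory=list)

    def vector_at(self, position: int) -> LogOddsVector:
        return self.vectors[self.positions.index(position)]


def count_codons(
    sequences: Iterable[Sequence[str]], code: GeneticCodePartition
) -> CodonCounts:
    """Count sense codons over a collection of codon lists.

    Codons containing non-ACGT characters are silently excluded; a stop codon
    is an error because windows are stop-free by construction.
    """
    counts: dict[str, int] = {}
    for seq in sequences:
        for codon in seq:
            if codon in STOP_CODONS:
                raise WindowStopError(f"stop codon {codon} inside a window")
            if not is_valid_codon(codon):
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts)


def log_odds_cell(
    n1: float,
    s1: float,
    n2: float,
    s2: float,
    correction: str = CORRECTION_HALF_UNIT,
) -> tuple[float, float, bool]:
    """Log odds ratio and its standard error from the four block counts.

    Returns (log_odds, se, corrected).  With any zero cell: the half-unit
    correction adds 0.5 to all four counts and flags the entry; ``drop``
    returns an undefined entry (NaN).  A side with zero codon *and* zero
    synonym counts is undefined regardless.
    """
    if (n1 + s1) <= 0 or (n2 + s2) <= 0:
        return UNDEFINED, UNDEFINED, False
    if min(n1, s1, n2, s2) > 0:
        lo = math.log((n1 / s1) / (n2 / s2))
        se = math.sqrt(1 / n1 + 1 / n2 + 1 / s1 + 1 / s2)
        return lo, se, False
    if correction == CORRECTION_DROP:
        return UNDEFINED, UNDEFINED, False
    if correction != CORRECTION_HALF_UNIT:
        raise ValueError(f"unknown correction {correction!r}")
    n1, s1, n2, s2 = n1 + 0.5, s1 + 0.5, n2 + 0.5, s2 + 0.5
    lo = math.log((n1 / s1) / (n2 / s2))
    se = math.sqrt(1 / n1 + 1 / n2 + 1 / s1 + 1 / s2)
    return lo, se, True


def log_odds_vector(
    target: CodonCounts,
    comparator: CodonCounts,
    code: GeneticCodePartition,
    label: str = "",
    correction: str = CORRECTION_HALF_UNIT,
    provenance: str = "",
) -> LogOddsVector:
    """Per-codon log-odds enrichment of target vs comparator counts.

    The scored-codon set follows ``code``; pass a repartitioned
    GeneticCodePartition (e.g. from ``arg_split_partition``) to redefine
    blocks.
    """
    entries: dict[str, LogOddsEntry] = {}
    for block in code.blocks:
        if len(block) < 2:
            continue
        t_block = sum(target[c] for c in block)
        c_block = sum(comparator[c] for c in block)
        for codon in block:
            n1 = target[codon]
            s1 = t_block - n1
            n2 = comparator[codon]
            s2 = c_block - n2
            lo, se, corr = log_odds_cell(n1, s1, n2, s2, correction)
            entries[codon] = LogOddsEntry(codon, n1, s1, n2, s2, lo, se, corr)
    return LogOddsVector(label=label, entries=entries, provenance=provenance)


def positional_log_odds(
    target_seqs: Sequence[Sequence[str]],
    comparator_seqs: Sequence[Sequence[str]],
    positions: Sequence[int],
    code: GeneticCodePartition,
    position_offset: int = 2,
    label_prefix: str = "pos",
    correction: str = CORRECTION_HALF_UNIT,
) -> PositionalMatrix:
    """One log-odds vector per codon position.

    ``positions`` are 1-based CDS codon positions; a sequence's index 0 codon
    sits at ``position_offset`` (windows usually start at codon position 2).
    """
    matrix = PositionalMatrix(positions=list(positions))
    for p in positions:
        idx = p - position_offset
        for name, seqs in (("target", target_seqs), ("comparator", comparator_seqs)):
            for i, seq in enumerate(seqs):
                if idx < 0 or idx >= len(seq):
                    raise ValueError(
                        f"{name} sequence #{i} does not cover position {p}"
                    )
        t = count_codons([[s[idx]] for s in target_seqs], code)
        c = count_codons([[s[idx]] for s in comparator_seqs], code)
        matrix.vectors.append(
            log_odds_vector(t, c, code, label=f"{label_prefix}{p}", correction=correction)
        )
    return matrix
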