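"""CDS ingest: parse annotated genomes, apply quality filters, slice windows.

Coding sequences come from GenBank/EMBL flat files or a FASTA of CDS.  Records
failing any of the four quality rules (length divisible by 3, terminal stop,
no internal stop, NTG start) are rejected with the first failing reason.
Retained records are sliced into a 5'-window (codons 2-12 by default) and an
equal-length core window centred in the CDS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_code import STOP_CODONS, is_valid_codon

logger = logging.getLogger(__name__)

# Rejection reasons, in the fixed order they are checked.
REASON_LENGTH = "length-not-multiple-of-3"
REASON_TERMINAL_STOP = "no-terminal-stop"
REASON_INTERNAL_STOP = "internal-stop"
REASON_START = "no-NTG-start"
REASON_SHORT = "short"

FLAG_AMBIGUOUS = "contains-ambiguity"
FLAG_SHORT = "short"

_FORMAT_MAP = {"genbank": "genbank", "embl": "embl", "fasta": "fasta"}


@dataclass
class CdsRecord:
    """One coding sequence as an ordered list of codons (start and stop included)."""

    id: str
    genome_id: str
    codons: list[str]
    flags: set[str] = field(default_factory=set)

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def sequence(self) -> str:
        return "".join(self.codons)


@dataclass
class RegionPair:
    """The 5'-window and core-window codon slices of one CDS."""

    gene_id: str
    five_prime: list[str]
    core: list[str]
    overlap_flag: bool


class IngestError(RuntimeError):
    """Fatal problem reading a sequence source."""


def _codons_from_seq(seq: str) -> list[str]:
    seq = seq.upper()
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def parse_cds_collection(
    source: str | Path, format: str = "genbank", genome_id: str | None = None
) -> list[CdsRecord]:
    """Read all CDS from an annotated genome or CDS FASTA, unfiltered.

    For flat-file formats each CDS feature is extracted in its annotated
    reading frame with strand resolved; for FASTA each entry is one CDS and
    the record id is the header up to the first whitespace.
    """
    source = Path(source)
    if format not in _FORMAT_MAP:
        raise IngestError(f"unknown format {format!r}")
    if not source.exists():
        raise IngestError(f"no such file: {source}")
    records: list[CdsRecord] = []
    try:
        seq_records = list(SeqIO.parse(str(source), _FORMAT_MAP[format]))
    except Exception as exc:  # pragma: no cover - biopython raises many types
        raise IngestError(f"could not parse {source} as {format}: {exc}") from exc
    if not seq_records:
        raise IngestError(f"no records parsed from {source} as {format}")

    if format == "fasta":
        gid = genome_id or source.stem
        for rec in seq_records:
            records.append(_make_record(rec.id, gid, str(rec.seq)))
        return records

    for rec in seq_records:
        gid = genome_id or rec.id
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            try:
                seq = str(feat.extract(rec.seq))
            except Exception as exc:
                logger.warning("skipping CDS without extractable sequence: %s", exc)
                continue
            qual = feat.qualifiers
            name = (
                qual.get("locus_tag", qual.get("gene", qual.get("protein_id", ["?"])))
            )[0]
            records.append(_make_record(name, gid, seq))
    return records


def _make_record(name: str, genome_id: str, seq: str) -> CdsRecord:
    codons = _codons_from_seq(seq)
    flags: set[str] = set()
    if any(b not in "ACGT" for b in seq.upper()):
        flags.add(FLAG_AMBIGUOUS)
    rec = CdsRecord(id=name, genome_id=genome_id, codons=codons, flags=flags)
    if len(seq) % 3 != 0:
        # keep the raw length visible to filter_cds via a sentinel flag
        rec.flags.add(f"raw-length:{len(seq)}")
    return rec


def _raw_length(record: CdsRecord) -> int:
    for f in record.flags:
        if f.startswith("raw-length:"):
            return int(f.split(":", 1)[1])
    return 3 * len(record.codons)


def filter_cds(
    records: Iterable[CdsRecord],
) -> tuple[list[CdsRecord], list[tuple[CdsRecord, str]]]:
    """Apply the four CDS quality rules in fixed order.

    Returns (retained, rejected) where each rejected record is paired with the
    first failing reason: length, terminal stop, internal stop, start codon.
    """
    retained: list[CdsRecord] = []
    rejected: list[tuple[CdsRecord, str]] = []
    for rec in records:
        reason = _first_failure(rec)
        if reason is None:
            retained.append(rec)
        else:
            rejected.append((rec, reason))
    return retained, rejected


def _first_failure(rec: CdsRecord) -> str | None:
    if _raw_length(rec) % 3 != 0:
        return REASON_LENGTH
    if not rec.codons or rec.codons[-1] not in STOP_CODONS:
        return REASON_TERMINAL_STOP
    if any(c in STOP_CODONS for c in rec.codons[:-1]):
        return REASON_INTERNAL_STOP
    first = rec.codons[0]
    if not (len(first) == 3 and first[1:] == "TG" and first[0] in "ACGT"):
        return REASON_START
    return None


def slice_regions(
    record: CdsRecord, region_len: int = 11, five_prime_start: int = 2
) -> RegionPair | None:
    """Slice a filtered CDS into 5' and core codon windows.

    Positions are 1-based with position 1 the start codon; the terminal stop
    is never part of either window.  The core starts at
    ``floor((L - region_len) / 2) + 1`` where L is the codon count excluding
    the stop.  Returns None (gene too short) when the 5' window does not fit.
    """
    L = len(record.codons) - 1  # exclude terminal stop
    if L < five_prime_start - 1 + region_len or L < region_len:
        record.flags.add(FLAG_SHORT)
        return None
    fp_lo = five_prime_start - 1
    five_prime = record.codons[fp_lo : fp_lo + region_len]
    core_start = (L - region_len) // 2 + 1  # 1-based
    core = record.codons[core_start - 1 : core_start - 1 + region_len]
    overlap = not (
        core_start + region_len - 1 < five_prime_start
        or five_prime_start + region_len - 1 < core_start
    )
    return RegionPair(record.id, five_prime, core, overlap)


def compute_gc3(records: Sequence[CdsRecord], mode: str = "per-gene-mean") -> float:
    """GC content at third codon positions over sense codons.

    ``per-gene-mean`` (default) averages the per-gene fractions without
    length weighting; ``pooled`` computes a single fraction over all genes'
    third positions.  The terminal stop is excluded, the start codon included.
    """
    if mode not in ("per-gene-mean", "pooled"):
        raise ValueError(f"unknown GC3 mode {mode!r}")
    per_gene: list[float] = []
    gc_total = 0
    n_total = 0
    for rec in records:
        body = rec.codons[:-1] if rec.codons and rec.codons[-1] in STOP_CODONS else rec.codons
        thirds = [c[2] for c in body if is_valid_codon(c) and c not in STOP_CODONS]
        if not thirds:
            continue
        gc = sum(1 for b in thirds if b in "GC")
        per_gene.append(gc / len(thirds))
        gc_total += gc
        n_total += len(thirds)
    if not per_gene:
        raise ValueError("no sense codons available for GC3")
    if mode == "pooled":
        return gc_total / n_total
    return math.fsum(per_gene) / len(per_gene)


def apply_genome_gate(
    manifest_rows: Sequence[dict],
    min_length: int = 500_000,
    one_per_genus: bool = True,
) -> list[dict]:
    """Pre-filter a genome manifest: minimum length and one genome per genus.

    Rows are dicts with at least ``genome_length`` and ``genus``; when several
    genomes share a genus the first in manifest order is kept.
    """
    out: list[dict] = []
    seen_genera: set[str] = set()
    for row in manifest_rows:
        if int(row["genome_length"]) < min_length:
            continue
        genus = str(row.get("genus", ""))
        if one_per_genus and genus:
            if genus in seen_genera:
                continue
            seen_genera.add(genus)
        out.append(dict(row))
    return out


def write_retained_fasta(records: Iterable[CdsRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_rejection_report(
    rejected: Iterable[tuple[CdsRecord, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id\treason\n")
        for rec, reason in rejected:
            fh.write(f"{rec.id}\t{reason}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
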