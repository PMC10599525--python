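"""Transgene construct pipeline: normalized protein levels to a 5' enrichment vector.

Constructs come in synonymous families (nominally 13 variants of the same
N-terminal amino-acid sequence under one promoter/RBS combination).  Reporter
ratios are normalized to the family mean (Prot.FCC), the pooled constructs
are stratified into top/bottom quantile sets, and the per-codon enrichment of
the top set's 5' codons against the bottom set's gives the experimentally
derived initiation-optimality vector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .enrichment import LogOddsVector, count_codons, log_odds_vector
from .genetic_code import GeneticCodePartition

logger = logging.getLogger(__name__)

CENSOR_NONE = "none"
CENSOR_ABOVE = "above-range"
CENSOR_BELOW = "below-range"


@dataclass
class ConstructRecord:
    group_id: str
    variant_id: str
    codons: list[str]  # variable region, codon 1 = start
    protein_ratio: float | None = None
    prot_fcc: float | None = None
    censor: str = CENSOR_NONE
    excluded: bool = False


@dataclass
class ConstructGroup:
    group_id: str
    members: list[ConstructRecord] = field(default_factory=list)


def load_construct_table(path: str | Path) -> list[ConstructGroup]:
    """Read a construct table (TSV/CSV, header-mapped, extra columns ignored)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in df.columns}
    for required in ("group_id", "variant_id", "sequence"):
        if required not in cols:
            raise ValueError(f"{path}: missing column {required!r}")
    groups: dict[str, ConstructGroup] = {}
    for _, row in df.iterrows():
        seq = str(row[cols["sequence"]]).strip().upper()
        codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
        ratio = None
        if "protein_ratio" in cols and pd.notna(row[cols["protein_ratio"]]):
            ratio = float(row[cols["protein_ratio"]])
        fcc = None
        if "prot_fcc" in cols and pd.notna(row[cols["prot_fcc"]]):
            fcc = float(row[cols["prot_fcc"]])
        censor = CENSOR_NONE
        if "censor" in cols and pd.notna(row[cols["censor"]]):
            censor = str(row[cols["censor"]]).strip() or CENSOR_NONE
        gid = str(row[cols["group_id"]])
        rec = ConstructRecord(
            group_id=gid,
            variant_id=str(row[cols["variant_id"]]),
            codons=codons,
            protein_ratio=ratio,
            prot_fcc=fcc,
            censor=censor,
        )
        groups.setdefault(gid, ConstructGroup(gid)).members.append(rec)
    return list(groups.values())


def compute_prot_fcc(
    groups: Sequence[ConstructGroup], use_all_members: bool = False
) -> list[ConstructGroup]:
    """Fill prot_fcc = protein_ratio / mean group ratio for each construct.

    The mean is over uncensored members by default (``use_all_members``
    includes censored ones that still carry a numeric ratio).  Groups with
    fewer than 2 usable members are excluded and logged.
    """
    kept: list[ConstructGroup] = []
    for group in groups:
        usable = []
        for rec in group.members:
            if rec.protein_ratio is None:
                continue
            if rec.protein_ratio <= 0:
                rec.excluded = True
                logger.warning(
                    "non-positive ratio for %s/%s; excluded from mean",
                    group.group_id,
                    rec.variant_id,
                )
                continue
            if use_all_members or rec.censor == CENSOR_NONE:
                usable.append(rec)
        if len(usable) < 2:
            logger.warning("group %s has <2 usable members; excluded", group.group_id)
            continue
        mean_ratio = math.fsum(r.protein_ratio for r in usable) / len(usable)
        for rec in group.members:
            if rec.protein_ratio is not None and rec.protein_ratio > 0:
                rec.prot_fcc = rec.protein_ratio / mean_ratio
        kept.append(group)
    return kept


def _rank_key(rec: ConstructRecord) -> tuple[float, str]:
    if rec.censor == CENSOR_ABOVE:
        value = math.inf
    elif rec.censor == CENSOR_BELOW:
        value = -math.inf
    elif rec.prot_fcc is not None:
        value = rec.prot_fcc
    else:
        value = math.nan
    return value, rec.variant_id


def stratify_constructs(
    records: Sequence[ConstructRecord],
    upper_frac: float = 0.25,
    lower_frac: float = 0.25,
) -> tuple[list[ConstructRecord], list[ConstructRecord]]:
    """Split constructs into top/bottom quantile sets by Prot.FCC.

    Censored records rank at +/- infinity; set sizes are nearest-rank
    (ceil(frac * N)); boundary ties resolve by stable sort on variant_id.
    """
    if upper_frac + lower_frac > 1:
        raise ValueError("upper_frac + lower_frac must not exceed 1")
    usable = [
        r
        for r in records
        if not r.excluded and (r.prot_fcc is not None or r.censor != CENSOR_NONE)
    ]
    if len(usable) < 4:
        raise ValueError("need at least 4 usable constructs to stratify")
    ranked = sorted(usable, key=_rank_key)
    n = len(ranked)
    n_top = math.ceil(upper_frac * n)
    n_bottom = math.ceil(lower_frac * n)
    return ranked[n - n_top :], ranked[:n_bottom]


def derive_edio(
    records: Sequence[ConstructRecord],
    code: GeneticCodePartition,
    upper_frac: float = 0.25,
    lower_frac: float = 0.25,
    position_range: tuple[int, int] = (2, 11),
    label: str = "V_edIO",
) -> LogOddsVector:
    """5'-enrichment vector of high- vs low-expression constructs.

    Codon counts are pooled over 1-based positions ``position_range``
    (inclusive; position 1 = start codon, excluded by the default 2-11).
    """
    top, bottom = stratify_constructs(records, upper_frac, lower_frac)
    lo, hi = position_range
    if lo < 2:
        raise ValueError("position_range must exclude the start codon (start at >= 2)")

    def window(rec: ConstructRecord) -> list[str]:
        if len(rec.codons) < hi:
            raise ValueError(
                f"construct {rec.group_id}/{rec.variant_id} shorter than position {hi}"
            )
        return rec.codons[lo - 1 : hi]

    target = count_codons([window(r) for r in top], code)
    comp = count_codons([window(r) for r in bottom], code)
    return log_odds_vector(
        target,
        comp,
        code,
        label=label,
        provenance=f"top {upper_frac:.0%} vs bottom {lower_frac:.0%} by Prot.FCC, "
        f"codon positions {lo}-{hi}",
    )
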