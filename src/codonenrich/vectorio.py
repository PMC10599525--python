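"""CSV serialization of log-odds vectors and vector tables.

Files are header-mapped: required columns are located by name, extra columns
ignored, so tables produced elsewhere (with additional annotation columns)
load unchanged.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .enrichment import LogOddsEntry, LogOddsVector

_COLUMNS = [
    "codon",
    "log_odds",
    "se",
    "n_codon_target",
    "n_syn_target",
    "n_codon_comp",
    "n_syn_comp",
    "corrected",
]


def write_vector_csv(vector: LogOddsVector, path: str | Path) -> None:
    rows = []
    for codon in vector.codons:
        e = vector.entries[codon]
        rows.append(
            {
                "codon": e.codon,
                "log_odds": e.log_odds,
                "se": e.se,
                "n_codon_target": e.n_codon_target,
                "n_syn_target": e.n_syn_target,
                "n_codon_comp": e.n_codon_comp,
                "n_syn_comp": e.n_syn_comp,
                "corrected": e.corrected,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_vector_csv(path: str | Path, label: str = "") -> LogOddsVector:
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "codon" not in cols or "log_odds" not in cols:
        raise ValueError(f"{path}: need at least 'codon' and 'log_odds' columns")

    def col(name: str, row, default=math.nan):
        if name in cols:
            return row[cols[name]]
        return default

    entries: dict[str, LogOddsEntry] = {}
    for _, row in df.iterrows():
        codon = str(row[cols["codon"]]).strip().upper()
        entries[codon] = LogOddsEntry(
            codon=codon,
            n_codon_target=float(col("n_codon_target", row)),
            n_syn_target=float(col("n_syn_target", row)),
            n_codon_comp=float(col("n_codon_comp", row)),
            n_syn_comp=float(col("n_syn_comp", row)),
            log_odds=float(row[cols["log_odds"]]),
            se=float(col("se", row)),
            corrected=bool(col("corrected", row, False)),
        )
    return LogOddsVector(label=label or Path(path).stem, entries=entries)


def read_vector_table(
    path: str | Path, codon_column: str | None = None
) -> dict[str, LogOddsVector]:
    """Read a multi-vector table (one codon column, one column per vector).

    Matches the layout of published per-contrast vector tables: each numeric
    column becomes a LogOddsVector whose entries carry only log_odds values.
    """
    df = pd.read_csv(path)
    if codon_column is None:
        for c in df.columns:
            sample = df[c].astype(str).str.strip().str.upper()
            if sample.str.fullmatch("[ACGTU]{3}").all():
                codon_column = c
                break
    if codon_column is None:
        raise ValueError(f"{path}: no codon column found")
    codons = df[codon_column].astype(str).str.strip().str.upper().str.replace("U", "T")
    out: dict[str, LogOddsVector] = {}
    for c in df.columns:
        if c == codon_column:
            continue
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.notna().sum() == 0:
            continue
        entries = {
            codon: LogOddsEntry(codon, math.nan, math.nan, math.nan, math.nan, v, math.nan)
            for codon, v in zip(codons, vals)
        }
        out[c] = LogOddsVector(label=c, entries=entries)
    return out
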