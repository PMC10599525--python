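"""Native-gene contrasts: abundance, noise and essentiality vectors plus 5'-vs-core.

Annotation tables (protein abundance, expression noise, essentiality) join to
retained coding sequences by gene id.  Each contrast pools codon counts over
the requested window (5' or core) across target genes versus comparator
genes and produces a labelled log-odds vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import LogOddsVector, count_codons, log_odds_vector
from .genetic_code import GeneticCodePartition
from .ingest import RegionPair
from .stats import CorrelationResult, correlate_vectors


@dataclass
class ContrastSpec:
    """Definition of one target-vs-comparator gene contrast."""

    metric: str
    region: str  # "five_prime" | "core"
    upper_frac: float | None = None
    lower_frac: float | None = None
    target_side: str = "top"  # "top" | "bottom" | "categorical"
    label: str = ""


#: The study's native contrasts. Noise orients LOW noise as the target set.
STANDARD_CONTRASTS: dict[str, ContrastSpec] = {
    "5prot": ContrastSpec("abundance", "five_prime", 0.25, 0.25, "top", "V_5-prot"),
    "to": ContrastSpec("abundance", "core", 0.25, 0.25, "top", "V_TO"),
    "noise": ContrastSpec("noise", "five_prime", 0.40, 0.40, "bottom", "V_noise"),
    "ess": ContrastSpec("essential", "five_prime", None, None, "categorical", "V_ess"),
}


def load_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV/CSV, normalising header names."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.lower().strip() for c in df.columns]
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    return df.set_index("gene_id", drop=False)


def stratify_genes(
    table: pd.DataFrame,
    metric: str,
    upper_frac: float | None = None,
    lower_frac: float | None = None,
    target_side: str = "top",
) -> tuple[list[str], list[str]]:
    """Quantile or categorical split of genes on one annotation column.

    Quantitative: nearest-rank ceil(frac*N) sets from the ranked values,
    genes missing the metric dropped.  Categorical (boolean column): the true
    set is the target.  Target and comparator are disjoint by construction.
    """
    if metric not in table.columns:
        raise ValueError(f"annotation table has no column {metric!r}")
    col = table[metric].dropna()
    if target_side == "categorical":
        flags = col.astype(bool)
        target = list(col.index[flags])
        comp = list(col.index[~flags])
        if not target or not comp:
            raise ValueError(f"categorical contrast on {metric!r} has an empty side")
        return target, comp
    values = pd.to_numeric(col, errors="coerce").dropna()
    if len(values) < 4:
        raise ValueError(f"metric {metric!r} present for fewer than 4 genes")
    order = values.sort_values(kind="stable")
    n = len(order)
    n_hi = math.ceil(upper_frac * n)
    n_lo = math.ceil(lower_frac * n)
    top = list(order.index[n - n_hi :])
    bottom = list(order.index[:n_lo])
    if set(top) & set(bottom):
        raise RuntimeError("quantile sets overlap; fractions too large")
    if target_side == "top":
        return top, bottom
    if target_side == "bottom":
        return bottom, top
    raise ValueError(f"unknown target_side {target_side!r}")


def _region_seqs(
    regions: Mapping[str, RegionPair], ids: Sequence[str], region: str
) -> list[list[str]]:
    attr = {"five_prime": "five_prime", "core": "core"}[region]
    return [getattr(regions[g], attr) for g in ids if g in regions]


def derive_contrast_vector(
    table: pd.DataFrame,
    regions: Mapping[str, RegionPair],
    spec: ContrastSpec,
    code: GeneticCodePartition,
) -> LogOddsVector:
    """Log-odds vector for one annotation contrast (abundance/noise/essential)."""
    target_ids, comp_ids = stratify_genes(
        table, spec.metric, spec.upper_frac, spec.lower_frac, spec.target_side
    )
    assert not set(target_ids) & set(comp_ids)
    t_seqs = _region_seqs(regions, target_ids, spec.region)
    c_seqs = _region_seqs(regions, comp_ids, spec.region)
    if not t_seqs or not c_seqs:
        raise ValueError(f"contrast {spec.label or spec.metric}: empty sequence set")
    return log_odds_vector(
        count_codons(t_seqs, code),
        count_codons(c_seqs, code),
        code,
        label=spec.label or spec.metric,
        provenance=f"{spec.target_side} {spec.metric} {spec.region}",
    )


def derive_five_core(
    regions: Mapping[str, RegionPair],
    code: GeneticCodePartition,
    gene_ids: Sequence[str] | None = None,
    label: str = "V_5-core",
) -> LogOddsVector:
    """All genes' 5' windows versus all genes' core windows."""
    ids = sorted(regions) if gene_ids is None else [g for g in gene_ids if g in regions]
    if not ids:
        raise ValueError("no genes with both windows")
    five = [regions[g].five_prime for g in ids]
    core = [regions[g].core for g in ids]
    return log_odds_vector(
        count_codons(five, code),
        count_codons(core, code),
        code,
        label=label,
        provenance=f"5' vs core over {len(ids)} genes",
    )


def expression_binned_scan(
    table: pd.DataFrame,
    regions: Mapping[str, RegionPair],
    reference: LogOddsVector,
    code: GeneticCodePartition,
    bin_frac: float = 0.2,
    step_percentile: float = 1.0,
    abundance_column: str = "abundance",
    min_bin_warn: int = 50,
) -> pd.DataFrame:
    """Sliding-bin 5'-vs-core correlation against a reference vector.

    Genes are rank-ordered by abundance; a window of ceil(bin_frac*N) genes
    advances by ``step_percentile`` of N.  Each bin's 5'-vs-core vector is
    correlated (Pearson) with the reference; output rows run from the lowest
    to the highest expression bin.
    """
    values = pd.to_numeric(table[abundance_column], errors="coerce").dropna()
    values = values[values.index.isin(regions.keys())]
    order = list(values.sort_values(kind="stable").index)
    n = len(order)
    width = math.ceil(bin_frac * n)
    if width < min_bin_warn:
        import warnings

        warnings.warn(f"bin of {width} genes (<{min_bin_warn}) gives unstable vectors")
    step = max(1, round(step_percentile / 100.0 * n))
    rows = []
    start = 0
    while start + width <= n:
        ids = order[start : start + width]
        vec = derive_five_core(regions, code, gene_ids=ids, label="bin")
        res = _corr_vs_reference(vec, reference)
        rows.append(
            {
                "lower_percentile": 100.0 * start / n,
                "r": res.coefficient,
                "p": res.p_value,
                "n_genes": len(ids),
            }
        )
        if start + width == n:
            break
        start = min(start + step, n - width)
    return pd.DataFrame(rows)


def _corr_vs_reference(vec: LogOddsVector, reference: LogOddsVector) -> CorrelationResult:
    common = sorted(set(vec.codons) & set(reference.codons))
    x = [vec[c].log_odds for c in common]
    y = [reference[c].log_odds for c in common]
    return correlate_vectors(x, y, "pearson")


def join_and_correlate(
    table: pd.DataFrame, col_x: str, col_y: str, method: str = "spearman"
) -> CorrelationResult:
    """Gene-level correlation between two annotation columns (e.g. abundance vs dG)."""
    sub = table[[col_x, col_y]].dropna()
    return correlate_vectors(
        np.asarray(sub[col_x], dtype=float), np.asarray(sub[col_y], dtype=float), method
    )
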