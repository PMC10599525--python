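"""Multi-genome 5'-vs-core survey and its downstream regression models.

One row per genome: the genome's 5'-vs-core log-odds vector, its Pearson
correlation against a reference vector, GC3, and optional externally supplied
covariates (predicted optimal growth temperature, mean folding energies of
the 5' and core windows).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import LogOddsVector
from .genetic_code import GeneticCodePartition
from .ingest import (
    CdsRecord,
    RegionPair,
    apply_genome_gate,
    compute_gc3,
    filter_cds,
    parse_cds_collection,
    slice_regions,
)
from .native import derive_five_core
from .stats import FitResult, correlate_vectors, multivariate_fit

logger = logging.getLogger(__name__)


@dataclass
class GenomeSurveyRow:
    accession: str
    n_genes: int
    vector: LogOddsVector
    r: float
    p: float
    p_bonferroni: float = 1.0
    gc3: float = math.nan
    pogt: float = math.nan
    dg5: float = math.nan
    dgcore: float = math.nan
    unstable: bool = False


@dataclass
class GenomeSurveyTable:
    rows: list[GenomeSurveyRow] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "accession": r.accession,
                    "n_genes": r.n_genes,
                    "r": r.r,
                    "p": r.p,
                    "p_bonferroni": r.p_bonferroni,
                    "gc3": r.gc3,
                    "pogt": r.pogt,
                    "dg5": r.dg5,
                    "dgcore": r.dgcore,
                    "unstable": r.unstable,
                }
                for r in self.rows
            ]
        )

    def __len__(self) -> int:
        return len(self.rows)


def regions_from_records(
    records: Sequence[CdsRecord], region_len: int = 11, five_prime_start: int = 2
) -> dict[str, RegionPair]:
    """Filter records and slice both windows; genes too short are dropped."""
    retained, _ = filter_cds(records)
    out: dict[str, RegionPair] = {}
    for rec in retained:
        pair = slice_regions(rec, region_len, five_prime_start)
        if pair is not None:
            out[rec.id] = pair
    return out


def survey_genomes(
    genomes: Mapping[str, Sequence[CdsRecord]],
    reference: LogOddsVector,
    code: GeneticCodePartition,
    region_len: int = 11,
    five_prime_start: int = 2,
    min_genes_stable: int = 50,
    covariates: pd.DataFrame | None = None,
) -> GenomeSurveyTable:
    """Per-genome 5'-vs-core vector correlated against the reference.

    ``genomes`` maps accession to parsed CDS records; Bonferroni correction
    uses the number of genomes that produced a row.  Output is ordered by
    accession for determinism.
    """
    ref_codons = sorted(reference.codons)
    ref_vals = {c: reference[c].log_odds for c in ref_codons}
    table = GenomeSurveyTable()
    for accession in sorted(genomes):
        records = genomes[accession]
        retained, _ = filter_cds(records)
        regions = {}
        for rec in retained:
            pair = slice_regions(rec, region_len, five_prime_start)
            if pair is not None:
                regions[rec.id] = pair
        if not regions:
            logger.warning("genome %s: no retained CDS; skipped", accession)
            continue
        vec = derive_five_core(regions, code, label=f"V_5-core[{accession}]")
        common = [c for c in ref_codons if c in vec.entries]
        x = [vec[c].log_odds for c in common]
        y = [ref_vals[c] for c in common]
        res = correlate_vectors(x, y, "pearson")
        gc3 = compute_gc3([rec for rec in retained if rec.id in regions])
        table.rows.append(
            GenomeSurveyRow(
                accession=accession,
                n_genes=len(regions),
                vector=vec,
                r=res.coefficient,
                p=res.p_value,
                gc3=gc3,
                unstable=len(regions) < min_genes_stable,
            )
        )
    m = len(table.rows)
    for row in table.rows:
        row.p_bonferroni = min(1.0, row.p * m)
    if covariates is not None:
        cov = covariates.set_index(covariates.columns[0]) if covariates.index.name is None else covariates
        for row in table.rows:
            if row.accession in cov.index:
                for attr in ("pogt", "dg5", "dgcore"):
                    if attr in cov.columns and pd.notna(cov.loc[row.accession, attr]):
                        setattr(row, attr, float(cov.loc[row.accession, attr]))
    return table


def survey_from_manifest(
    manifest_path: str | Path,
    reference: LogOddsVector,
    code: GeneticCodePartition,
    min_length: int = 500_000,
    one_per_genus: bool = True,
    **kwargs,
) -> GenomeSurveyTable:
    """Run the survey from a manifest TSV (accession, file, format, genus, genome_length, …)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    rows = apply_genome_gate(df.to_dict("records"), min_length, one_per_genus)
    genomes: dict[str, Sequence[CdsRecord]] = {}
    cov_rows = []
    for row in rows:
        path = Path(row["file"])
        if not path.is_absolute():
            path = manifest_path.parent / path
        fmt = str(row.get("format", "fasta"))
        genomes[str(row["accession"])] = parse_cds_collection(
            path, fmt, genome_id=str(row["accession"])
        )
        cov_rows.append(
            {
                "accession": str(row["accession"]),
                "pogt": row.get("pogt", math.nan),
                "dg5": row.get("dg5", math.nan),
                "dgcore": row.get("dgcore", math.nan),
            }
        )
    cov = pd.DataFrame(cov_rows).set_index("accession")
    return survey_genomes(genomes, reference, code, covariates=cov, **kwargs)


def bonferroni_summary(
    table: GenomeSurveyTable, alpha: float = 0.05
) -> tuple[float, dict[str, int]]:
    """Fraction of genomes significantly positive after Bonferroni correction."""
    if not table.rows:
        raise ValueError("empty survey table")
    n = len(table.rows)
    sig_pos = sum(1 for r in table.rows if r.p_bonferroni < alpha and r.r > 0)
    sig_neg = sum(1 for r in table.rows if r.p_bonferroni < alpha and r.r < 0)
    counts = {
        "n_genomes": n,
        "significant_positive": sig_pos,
        "significant_negative": sig_neg,
        "not_significant": n - sig_pos - sig_neg,
    }
    return sig_pos / n, counts


def fit_gc3_temperature_model(table: GenomeSurveyTable) -> dict[str, FitResult]:
    """Quadratic GC3, OGT-only and joint models of the per-genome correlation.

    Interaction terms are deliberately excluded.
    """
    df = table.to_dataframe()
    if len(df) < 10:
        raise ValueError("refusing to fit survey models on fewer than 10 genomes")
    r = df["r"].to_numpy()
    gc3 = df["gc3"].to_numpy()
    fits: dict[str, FitResult] = {}
    fits["gc3_quadratic"] = multivariate_fit(r, {"gc3": gc3}, include_quadratic=["gc3"])
    if df["pogt"].notna().any():
        pogt = df["pogt"].to_numpy()
        fits["ogt"] = multivariate_fit(r, {"pogt": pogt})
        fits["joint"] = multivariate_fit(
            r, {"gc3": gc3, "pogt": pogt}, include_quadratic=["gc3"]
        )
    return fits


def stability_differential(table: GenomeSurveyTable) -> tuple[FitResult, float]:
    """OLS of the 5'-minus-core folding-energy difference on GC3.

    Also reports the fraction of genomes whose 5' window is less stable
    (dg5 > dgcore, i.e. less negative).  Requires externally supplied
    folding energies.
    """
    df = table.to_dataframe()
    if df["dg5"].isna().all() or df["dgcore"].isna().all():
        raise ValueError("requires external folding energies (dg5/dgcore columns)")
    sub = df.dropna(subset=["dg5", "dgcore", "gc3"])
    diff = (sub["dg5"] - sub["dgcore"]).to_numpy()
    fit = multivariate_fit(diff, {"gc3": sub["gc3"].to_numpy()})
    frac_less_stable = float(np.mean(sub["dg5"].to_numpy() > sub["dgcore"].to_numpy()))
    return fit, frac_less_stable


def write_survey_tsv(table: GenomeSurveyTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)
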