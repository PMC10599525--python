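"""Synthetic fixtures with planted per-codon effects and known ground truth.

Everything is a pure function of the seed: one ``numpy`` Generator drives a
documented stream order (abundance, lengths, amino acids, codons by regime
and amino acid, annotation noise, essentiality), so identical parameters give
byte-identical outputs.

Planted effects are additive log-weights on codon choice within a synonymous
block.  Because only within-block contrasts are identifiable by the log-odds
estimator, effect draws are centered within each block (a common shift of a
whole block cancels exactly in the odds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import GeneticCodePartition, standard_partition
from .ingest import CdsRecord
from .transgene import CENSOR_ABOVE, CENSOR_BELOW, CENSOR_NONE, ConstructGroup, ConstructRecord

# Spearman(noise, abundance) target -0.5 for a bivariate normal copula.
_NOISE_RHO = 2 * math.sin(math.pi * 0.5 / 6)


@dataclass
class SimulationParams:
    seed: int
    n_genes: int = 500
    min_len: int = 30  # body codons, excluding start and stop
    max_len: int = 120
    five_prime_len: int = 11
    five_prime_start: int = 2
    delta: Mapping[str, float] = field(default_factory=dict)
    coupling: Mapping[str, float] = field(default_factory=dict)
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    coupling_top_frac: float = 0.25
    noise_sigma: float = 0.5
    essential_fraction: float = 0.2
    essential_slope: float = 1.0
    # transgene experiment
    n_groups: int = 200
    variants_per_group: int = 13
    beta: Mapping[str, float] = field(default_factory=dict)
    measurement_sd: float = 0.2
    baseline_sigma: float = 1.0
    censor_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.min_len < 22:
            raise ValueError("min gene body must be >= 22 codons (24 with start/stop)")
        if self.variants_per_group < 2:
            raise ValueError("variants_per_group must be >= 2")


@dataclass
class GroundTruth:
    delta: dict[str, float]
    beta: dict[str, float]
    coupling: dict[str, float]
    abundance: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        codons = sorted(set(self.delta) | set(self.beta) | set(self.coupling))
        return pd.DataFrame(
            {
                "codon": codons,
                "delta": [self.delta.get(c, 0.0) for c in codons],
                "beta": [self.beta.get(c, 0.0) for c in codons],
                "coupling": [self.coupling.get(c, 0.0) for c in codons],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def draw_block_centered_effects(
    rng: np.random.Generator, code: GeneticCodePartition, sd: float
) -> dict[str, float]:
    """Per-codon effects drawn N(0, sd^2) then centered within each block."""
    effects: dict[str, float] = {}
    for block in code.blocks:
        if len(block) < 2:
            continue
        draws = rng.normal(0.0, sd, size=len(block))
        draws -= draws.mean()
        for codon, v in zip(block, draws):
            effects[codon] = float(v)
    return effects


def effects_on_third_base(
    code: GeneticCodePartition, bases: str, value: float
) -> dict[str, float]:
    """Constant planted effect on every scored codon ending in one of ``bases``."""
    return {
        c: value for c in code.scored_codons if c[2] in set(bases.upper())
    }


class _BlockSampler:
    """Vectorized within-block codon choice for one weight regime."""

    def __init__(
        self,
        code: GeneticCodePartition,
        log_weights: Mapping[str, float],
    ) -> None:
        self.aas: list[str] = []
        self.codon_arrays: list[np.ndarray] = []
        self.probs: list[np.ndarray] = []
        for block in code.blocks:
            aa = code.codon_to_aa[block[0]]
            w = np.array([math.exp(log_weights.get(c, 0.0)) for c in block])
            if not np.all(np.isfinite(w)) or w.sum() <= 0:
                raise ValueError(f"infeasible weights for block {block}")
            self.aas.append(aa)
            self.codon_arrays.append(np.array(block))
            self.probs.append(w / w.sum())
        self.aa_index = {aa: i for i, aa in enumerate(self.aas)}

    def sample(
        self, rng: np.random.Generator, aa_idx: np.ndarray, out: np.ndarray, mask: np.ndarray
    ) -> None:
        for i in range(len(self.aas)):
            sel = mask & (aa_idx == i)
            n = int(sel.sum())
            if n == 0:
                continue
            choice = rng.choice(len(self.codon_arrays[i]), size=n, p=self.probs[i])
            out[sel] = self.codon_arrays[i][choice]


def simulate_genome_fixture(
    params: SimulationParams, code: GeneticCodePartition | None = None
) -> tuple[list[CdsRecord], pd.DataFrame, GroundTruth]:
    """Generate a synthetic genome plus annotation table and ground truth.

    Each gene is ATG + body + TAA.  Body amino acids are uniform over the 20;
    the codon within the block is chosen with probability proportional to
    exp(log core weight + delta in the 5' window, + coupling additionally for
    genes in the top abundance quartile).
    """
    code = code or standard_partition()
    rng = np.random.default_rng(params.seed)

    abundance = rng.lognormal(params.abundance_mu, params.abundance_sigma, params.n_genes)
    lengths = rng.integers(params.min_len, params.max_len + 1, params.n_genes)
    cut = np.quantile(abundance, 1 - params.coupling_top_frac)
    top_gene = abundance >= cut

    total = int(lengths.sum())
    aa_letters = np.array(sorted({aa for aa in code.codon_to_aa.values() if aa != "*"}))
    aa_idx_all = rng.integers(0, len(aa_letters), total)

    # regime per body position: 0 = core weights, 1 = 5' window, 2 = 5' window of
    # a top-abundance gene (coupling applied on top of delta)
    regime = np.zeros(total, dtype=np.int8)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    w_lo = params.five_prime_start - 2  # body index of first 5'-window codon
    for g in range(params.n_genes):
        a, b = offsets[g], offsets[g + 1]
        lo = a + w_lo
        hi = min(a + w_lo + params.five_prime_len, b)
        regime[lo:hi] = 2 if top_gene[g] else 1

    zero: dict[str, float] = {}
    five_weights = dict(params.delta)
    top_weights = {
        c: params.delta.get(c, 0.0) + params.coupling.get(c, 0.0)
        for c in set(params.delta) | set(params.coupling)
    }
    samplers = [
        _BlockSampler(code, zero),
        _BlockSampler(code, five_weights),
        _BlockSampler(code, top_weights),
    ]

    # map uniform aa letters onto sampler block indices (same block order in all)
    aa_to_block = {aa: samplers[0].aa_index[aa] for aa in aa_letters}
    block_idx = np.array([aa_to_block[aa] for aa in aa_letters])[aa_idx_all]

    codons = np.empty(total, dtype="<U3")
    for r, sampler in enumerate(samplers):
        sampler.sample(rng, block_idx, codons, regime == r)

    records: list[CdsRecord] = []
    for g in range(params.n_genes):
        body = codons[offsets[g] : offsets[g + 1]].tolist()
        records.append(
            CdsRecord(
                id=f"gene{g:05d}",
                genome_id="synthetic",
                codons=["ATG", *body, "TAA"],
            )
        )

    annotations = _annotation_frame(rng, params, abundance)
    truth = GroundTruth(
        delta=dict(params.delta),
        beta=dict(params.beta),
        coupling=dict(params.coupling),
        abundance=abundance,
    )
    return records, annotations, truth


def _annotation_frame(
    rng: np.random.Generator, params: SimulationParams, abundance: np.ndarray
) -> pd.DataFrame:
    n = len(abundance)
    z = (np.log(abundance) - np.log(abundance).mean()) / np.log(abundance).std()
    eps = rng.normal(size=n)
    noise_latent = -_NOISE_RHO * z + math.sqrt(1 - _NOISE_RHO**2) * eps
    noise = np.exp(params.noise_sigma * noise_latent)
    if params.essential_fraction <= 0:
        essential = np.zeros(n, dtype=bool)
    elif params.essential_fraction >= 1:
        essential = np.ones(n, dtype=bool)
    else:
        logit0 = math.log(params.essential_fraction / (1 - params.essential_fraction))
        p = 1 / (1 + np.exp(-(logit0 + params.essential_slope * z)))
        essential = rng.random(n) < p
    return pd.DataFrame(
        {
            "gene_id": [f"gene{g:05d}" for g in range(n)],
            "abundance": abundance,
            "noise": noise,
            "essential": essential,
        }
    ).set_index("gene_id", drop=False)


def simulate_transgene_table(
    params: SimulationParams, code: GeneticCodePartition | None = None
) -> tuple[list[ConstructGroup], GroundTruth]:
    """Generate a synthetic construct table with a planted expression effect.

    Each group shares one random N-terminal amino-acid sequence; variants are
    uniform synonymous recodings.  Latent expression is group baseline x
    exp(sum of beta over codon positions 2-11) x lognormal measurement noise.
    """
    code = code or standard_partition()
    rng = np.random.default_rng(params.seed)
    aa_letters = sorted({aa for aa in code.codon_to_aa.values() if aa != "*"})
    blocks_by_aa = {code.codon_to_aa[b[0]]: b for b in code.blocks}

    n_pos = 10  # codon positions 2-11 of the 11-codon variable region
    groups: list[ConstructGroup] = []
    ratios: list[float] = []
    flat_records: list[ConstructRecord] = []
    for g in range(params.n_groups):
        aa_seq = [aa_letters[i] for i in rng.integers(0, len(aa_letters), n_pos)]
        baseline = rng.lognormal(0.0, params.baseline_sigma)
        group = ConstructGroup(group_id=f"g{g:04d}")
        for v in range(params.variants_per_group):
            cods = ["ATG"]
            effect = 0.0
            for aa in aa_seq:
                block = blocks_by_aa[aa]
                codon = block[int(rng.integers(0, len(block)))]
                cods.append(codon)
                effect += params.beta.get(codon, 0.0)
            latent = baseline * math.exp(effect) * math.exp(
                rng.normal(0.0, params.measurement_sd)
            )
            rec = ConstructRecord(
                group_id=group.group_id,
                variant_id=f"g{g:04d}v{v:02d}",
                codons=cods,
                protein_ratio=latent,
            )
            group.members.append(rec)
            flat_records.append(rec)
            ratios.append(latent)
        groups.append(group)

    if params.censor_fraction > 0:
        arr = np.array(ratios)
        hi = np.quantile(arr, 1 - params.censor_fraction / 2)
        lo = np.quantile(arr, params.censor_fraction / 2)
        for rec in flat_records:
            if rec.protein_ratio > hi:
                rec.censor = CENSOR_ABOVE
            elif rec.protein_ratio < lo:
                rec.censor = CENSOR_BELOW

    truth = GroundTruth(delta={}, beta=dict(params.beta), coupling={})
    return groups, truth


def simulate_annotations(
    params: SimulationParams, gene_ids: Sequence[str]
) -> pd.DataFrame:
    """Standalone annotation table for an existing gene list."""
    rng = np.random.default_rng(params.seed)
    abundance = rng.lognormal(params.abundance_mu, params.abundance_sigma, len(gene_ids))
    frame = _annotation_frame(rng, params, abundance)
    frame["gene_id"] = list(gene_ids)
    return frame.set_index("gene_id", drop=False)


def write_genome_fasta(records: Sequence[CdsRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_annotations_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_construct_tsv(groups: Sequence[ConstructGroup], path: str | Path) -> None:
    rows = []
    for group in groups:
        for rec in group.members:
            rows.append(
                {
                    "group_id": rec.group_id,
                    "variant_id": rec.variant_id,
                    "sequence": "".join(rec.codons),
                    "protein_ratio": rec.protein_ratio,
                    "censor": rec.censor if rec.censor != CENSOR_NONE else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
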