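"""Standard bacterial genetic code partitioned into synonymous codon blocks.

The unit of analysis everywhere in this package is the synonymous block: the
set of sense codons translating to one amino acid, with the three six-fold
families (Leu, Ser, Arg) kept whole.  Codons with no synonym (ATG, TGG) and
the stop codons are never scored, leaving 59 scored codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

BASES = "ACGT"

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Standard genetic code, codon -> one-letter amino acid ('*' = stop).
CODON_TO_AA: dict[str, str] = {}


def _build_code() -> None:
    table = {
        "F": ["TTT", "TTC"],
        "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
        "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
        "Y": ["TAT", "TAC"],
        "C": ["TGT", "TGC"],
        "W": ["TGG"],
        "P": ["CCT", "CCC", "CCA", "CCG"],
        "H": ["CAT", "CAC"],
        "Q": ["CAA", "CAG"],
        "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
        "I": ["ATT", "ATC", "ATA"],
        "M": ["ATG"],
        "T": ["ACT", "ACC", "ACA", "ACG"],
        "N": ["AAT", "AAC"],
        "K": ["AAA", "AAG"],
        "V": ["GTT", "GTC", "GTA", "GTG"],
        "A": ["GCT", "GCC", "GCA", "GCG"],
        "D": ["GAT", "GAC"],
        "E": ["GAA", "GAG"],
        "G": ["GGT", "GGC", "GGA", "GGG"],
        "*": ["TAA", "TAG", "TGA"],
    }
    for aa, codons in table.items():
        for c in codons:
            CODON_TO_AA[c] = aa


_build_code()

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
)


@dataclass(frozen=True)
class GeneticCodePartition:
    """Sense codons grouped into synonymous families.

    Parameters
    ----------
    codon_to_aa
        Mapping of all 64 codons to amino acid (``'*'`` for stop).
    blocks
        Disjoint synonymous families covering every scored codon.
    """

    codon_to_aa: Mapping[str, str]
    blocks: tuple[tuple[str, ...], ...]
    codon_to_block: Mapping[str, tuple[str, ...]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lookup: dict[str, tuple[str, ...]] = {}
        for block in self.blocks:
            for codon in block:
                if codon in lookup:
                    raise ValueError(f"codon {codon} appears in two blocks")
                lookup[codon] = block
        object.__setattr__(self, "codon_to_block", lookup)

    @property
    def scored_codons(self) -> tuple[str, ...]:
        """Sense codons with at least one synonym, alphabetical order."""
        return tuple(sorted(c for b in self.blocks if len(b) > 1 for c in b))

    def block_of(self, codon: str) -> tuple[str, ...]:
        return self.codon_to_block[codon]

    def with_blocks_replaced(
        self,
        remove: Iterable[Sequence[str]],
        add: Iterable[Sequence[str]],
    ) -> "GeneticCodePartition":
        """Return a new partition with some blocks redefined.

        Used for explicit repartitions such as splitting the six-fold Arg
        family into {AGA, AGG} and {CGT, CGC, CGA, CGG}.
        """
        removed = {tuple(sorted(b)) for b in remove}
        kept = [b for b in self.blocks if tuple(sorted(b)) not in removed]
        new_blocks = kept + [tuple(sorted(b)) for b in add]
        old_cover = {c for b in remove for c in b}
        new_cover = {c for b in add for c in b}
        if old_cover != new_cover:
            raise ValueError("replacement blocks must cover the same codons")
        return GeneticCodePartition(self.codon_to_aa, tuple(new_blocks))


def standard_partition() -> GeneticCodePartition:
    """The default partition: blocks = amino-acid families, six-fold kept whole."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        if aa == "*":
            continue
        by_aa.setdefault(aa, []).append(codon)
    blocks = tuple(tuple(sorted(v)) for _, v in sorted(by_aa.items()))
    return GeneticCodePartition(dict(CODON_TO_AA), blocks)


def arg_split_partition() -> GeneticCodePartition:
    """Arg split into a two-fold AG block and a four-fold CG block."""
    std = standard_partition()
    arg = tuple(sorted(["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"]))
    return std.with_blocks_replaced(
        remove=[arg],
        add=[("AGA", "AGG"), ("CGA", "CGC", "CGG", "CGT")],
    )


def is_valid_codon(codon: str) -> bool:
    """True for an unambiguous trinucleotide over ACGT."""
    return len(codon) == 3 and all(b in BASES for b in codon)
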