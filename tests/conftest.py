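import textwrap
from pathlib import Path

import pytest

from codonenrich import standard_partition
from codonenrich.ingest import CdsRecord


@pytest.fixture(scope="session")
def code():
    return standard_partition()


def make_record(seq: str, name: str = "g1", genome: str = "test") -> CdsRecord:
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    rec = CdsRecord(id=name, genome_id=genome, codons=codons)
    if len(seq) % 3 != 0:
        rec.flags.add(f"raw-length:{len(seq)}")
    return rec


GENBANK_PLUS = textwrap.dedent(
    """\
    LOCUS       TESTSEQ                   60 bp    DNA     linear   BCT 01-JAN-2020
    DEFINITION  minimal fixture.
    ACCESSION   TESTSEQ
    VERSION     TESTSEQ.1
    FEATURES             Location/Qualifiers
         source          1..60
                         /organism="synthetic"
         CDS             7..42
                         /locus_tag="geneA"
    ORIGIN
            1 aaaaaaatgg ctgctgctgc tgctgctgct gctgctgctt aacccccccc cccccccccc
    //
    """
)

GENBANK_MINUS = textwrap.dedent(
    """\
    LOCUS       TESTSEQ                   60 bp    DNA     linear   BCT 01-JAN-2020
    DEFINITION  minimal fixture.
    ACCESSION   TESTSEQ
    VERSION     TESTSEQ.1
    FEATURES             Location/Qualifiers
         source          1..60
                         /organism="synthetic"
         CDS             complement(7..42)
                         /locus_tag="geneA"
    ORIGIN
            1 aaaaaattaa gcagcagcag cagcagcagc agcagcagcc atcccccccc cccccccccc
    //
    """
)


@pytest.fixture
def genbank_plus_file(tmp_path: Path) -> Path:
    p = tmp_path / "plus.gbk"
    p.write_text(GENBANK_PLUS)
    return p


@pytest.fixture
def genbank_minus_file(tmp_path: Path) -> Path:
    p = tmp_path / "minus.gbk"
    p.write_text(GENBANK_MINUS)
    return p


@pytest.fixture
def fasta_file(tmp_path: Path) -> Path:
    p = tmp_path / "cds.fasta"
    p.write_text(
        ">g1 first gene\nATGGCTGCTTAA\n"
        ">g2\nATGAAAGCTTAA\n"
        ">g3 has ambiguity\nATGGNTGCTTAA\n"
    )
    return p
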