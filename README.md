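# codonenrich

Per-codon log-odds enrichment analysis of 5' coding regions in bacteria.

For a focal codon in its synonymous block (six-fold Leu/Ser/Arg families
kept whole), the enrichment of the codon in a target sequence set relative
to a comparator set is

```
log_odds = ln( (n1/s1) / (n2/s2) ),   se = sqrt(1/n1 + 1/n2 + 1/s1 + 1/s2)
```

where `n1, s1` are the counts of the codon and of its synonyms in the target
set and `n2, s2` the same in the comparator. One entry per codon with at
least one synonym gives a 59-element vector. The package derives these
vectors for several contrasts and provides the statistics to compare them:

- **Transgene pipeline** — constructs grouped in synonymous families are
  normalized to the family mean (Prot.FCC), stratified into top/bottom
  expression quantiles, and the 5'-codon enrichment of high vs low
  expressors is computed (`V_edIO`).
- **Native pipeline** — 5'-window (codons 2–12) and core-window contrasts on
  annotated genes: protein abundance (`V_5-prot`, `V_TO`), expression noise
  (`V_noise`), essentiality (`V_ess`), and the all-gene 5'-vs-core vector
  (`V_5-core`), plus an expression-binned sliding scan.
- **Genome survey** — the 5'-vs-core vector for every genome in a manifest
  (length/genus gating), correlated against a reference vector, with
  Bonferroni summaries and GC3/temperature/stability regression models.
- **Vector statistics** — Pearson/Spearman correlation, PCA orthogonal
  (total-least-squares) regression, the 87 oriented within-block pairwise
  synonymous differences, exact two-sided binomial sign tests, multivariate
  OLS, and Cronbach's alpha with Feldt confidence intervals.
- **Synthetic data** — seeded generators for genomes, construct tables and
  annotation tables with planted per-codon effects and persisted ground
  truth, used throughout the test suite for parameter-recovery checks.

## CLI

All functionality is exposed through one entry point:

```bash
# extract, filter and window the CDS of a genome
codonenrich extract --in genome.gbk --format genbank --out-dir out/

# enrichment vector of one window FASTA against another
codonenrich enrich --target five.fasta --comparator core.fasta --label V_x --out v_x.csv

# transgene vector from a construct table
codonenrich transgene --table constructs.tsv --upper 0.25 --lower 0.25 --out v_edio.csv

# native contrasts (5prot | to | noise | ess | 5core)
codonenrich native --genome cds.fasta --format fasta \
    --annotations annotations.tsv --contrast 5prot --out v_5prot.csv

# expression-binned 5'-vs-core scan against a reference vector
codonenrich scan --genome cds.fasta --annotations annotations.tsv \
    --reference v_edio.csv --bin-frac 0.2 --out scan.tsv

# multi-genome survey from a manifest TSV
codonenrich survey --manifest manifest.tsv --reference v_edio.csv --out survey.tsv

# vector comparison / sign test
codonenrich compare --x v_a.csv --y v_b.csv --pairwise-diffs --orthogonal-line
codonenrich signtest --vector v.csv --subset third-base:AT --direction positive

# synthetic fixtures with planted effects
codonenrich simulate --seed 17 --kind genome --n-genes 500 --out-dir fixtures/
```

## Published data

The reproduction checks in
`tests/test_acceptance.py::TestPublishedTableReproduction` and the
corresponding entries of the acceptance report need two per-codon vector
tables from the original study's supplementary material, which are not
redistributed here. To run them, place:

- `data/published/ecoli_vectors.csv` — the per-contrast table (one codon
  column plus columns named like VedIO, V5-core, V5-prot, VTO, Vnoise,
  Vess; column matching is fuzzy on names),
- `data/published/positional_vectors.csv` — the per-position table (codon
  column incl. stop rows plus one numeric column per codon position 2–11).

Without these files those tests fail with an explanatory message and the
acceptance report omits the corresponding keys.

## Layout

```
src/codonenrich/
  genetic_code.py   synonymous-block partition (59 scored codons)
  ingest.py         GenBank/EMBL/FASTA CDS parsing, quality filters, windows, GC3
  enrichment.py     codon counting, log-odds vectors, positional matrices
  vectorio.py       CSV serialization of vectors and vector tables
  transgene.py      Prot.FCC normalization, stratification, V_edIO
  native.py         abundance/noise/essentiality contrasts, V_5-core, binned scan
  survey.py         multi-genome survey, Bonferroni, GC3/OGT/stability models
  simulate.py       seeded synthetic genomes, construct tables, annotations
  stats.py          correlations, TLS fit, pairwise diffs, sign test, OLS, alpha
  cli.py            click command group
```
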