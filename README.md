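# guidescout

Design of guide RNAs for CRISPR-Cas9 genome editing: candidate discovery
in an input sequence, exhaustive genome search for off-target sites,
position-weighted cleavage scoring, and cross-scoring of guides between
two related sequences for allele-specific design.

## Who this is for

Anyone selecting single-guide RNAs for an S. pyogenes Cas9 (or another
Cas9 with a known PAM): the package finds every 20-nt protospacer
adjacent to an NGG PAM in your sequence, filters candidates by sequence
pattern, paired-nickase geometry, or overlap with restriction-enzyme
sites, then ranks each guide by its predicted genome-wide off-target
burden. A second workflow compares two related sequences — the two
alleles of a SNP, two paralogs, an original locus and its engineered
replacement — and ranks guides by how differently they are predicted to
cleave the two, for allele-discriminating (or deliberately
allele-indifferent) design.

## The scoring model

A candidate off-target site is any genomic window within `max_mismatch`
(default 4) Hamming mismatches of the guide whose adjacent PAM window
matches the off-target PAM pattern (default `N[A|G]G$`, admitting the
lower-activity NAG variant). Each site receives a cleavage score on a
0–100 scale built from an experimentally derived per-position mismatch
penalty vector *w*₁…*w*₂₀ (position 1 PAM-distal, position 20
PAM-proximal; seed-region mismatches are penalized hardest):

```
n = 0:  S = 100
n = 1:  S = 100 · (1 − w_p)
n ≥ 2:  S = 100 · Π_p (1 − w_p) · 1 / (((19 − d̄)/19)·4 + 1) · 1/n²
```

where the product runs over mismatched positions and *d̄* is the mean
pairwise distance between mismatches — clustered mismatches hurt more
than spread-out ones, and every additional mismatch costs a factor of
roughly *n*². A perfect match scores 100; a single PAM-proximal mismatch
scores 100·(1−0.583) = 41.7. The weight vector is a `ScoringScheme`
field, so alternative matrices (other Cas9 species, truncated guides)
plug in directly.

Per guide, hits are ranked, truncated to the top N, and summarized as
the sums of the top-5 and top-10 off-target scores — two numbers that
compare guides by how likely their worst off-targets are to be cleaved.

## Worked example

`examples/03_allele_comparison.py` builds a synthetic 160-bp two-allele
locus (a single C/T SNP) and cross-scores every guide:

```
13 guides found across both alleles (7 on the C allele, 6 on the T allele)

guide                          scoreC  scoreT   diff  mismatch
gRNAr2_alleleC_synthetic        100.0     0.0  100.0  -
gRNAf2_alleleC_synthetic        100.0    19.6   80.4  3:T
gRNAf2_alleleT_synthetic         19.6   100.0   80.4  3:C
gRNAf3_alleleC_synthetic        100.0    26.8   73.2  6:T
gRNAf3_alleleT_synthetic         26.8   100.0   73.2  6:C
gRNAf4_alleleC_synthetic        100.0    68.3   31.7  14:T
gRNAf4_alleleT_synthetic         68.3   100.0   31.7  14:C
gRNAf1_alleleC_synthetic        100.0   100.0    0.0  -
...
```

Reading the table: each guide scores 100 on its own allele. `gRNAr2` of
the C allele uses a PAM that only exists on that allele, so it cannot
cleave the T allele at all (difference 100, fully allele-specific).
`gRNAf2`/`gRNAf3` cover the SNP 3 and 6 bp from the PAM, where the
penalty weights are large: their cross-allele scores fall below 30,
making them good allele-discriminating candidates. `gRNAf4` carries the
SNP 14 bp from the PAM where a mismatch is tolerated (68.3), and guides
not covering the SNP score 100 on both alleles (difference 0 — the right
choice when both alleles must be cut).

The other examples cover guide discovery with the pairing and
restriction-site filters (`01`), a genome off-target scan with ranked
hits and top-5/top-10 totals (`02`), and the file-based one-call
workflow with its four tab-delimited reports and GenBank/FASTA exports
(`04`). The same workflows are available from the shell:

```
guidescout offtarget input.fa --genome genome.fa --outdir out
guidescout compare2 alleleC.fa alleleT.fa --outdir out
guidescout fixture --seed 1 --plant ACGT...x20:3,18:TAG --outdir fx
```

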