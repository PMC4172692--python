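# Methods

## Target-site model

A target site for S. pyogenes Cas9 is a 20-nt protospacer followed
immediately 3' by a 3-nt PAM. Guide discovery scans both strands of an
input sequence for every window whose PAM matches the design consensus
(IUPAC `NGG` by default) and whose protospacer satisfies an optional
regular-expression constraint (`^G` for U6 transcription, `^GG` for T7,
`^(?:(?!T{5,}).)+$` to avoid Pol III terminators). Guides are named
`<prefix><f|r><ordinal>_<source id>` with per-strand ordinals in
ascending plus-strand order; all occurrences are reported, including
duplicates at different loci. Coordinates are 1-based inclusive in every
report and refer to the protospacer in the plus-strand frame; internally
0-based half-open arithmetic is used and round-trip extraction is tested.

Bases outside A/C/G/T are treated as unknown: an N in a searched window
never satisfies any pattern symbol (not even pattern N), and an N in a
genome always counts as a protospacer mismatch. This prevents assembly
gaps from fabricating candidate sites. Lowercase (soft-masked) sequence
is searched normally; masking carries no semantics here. RNA input is
not accepted — guides are written as DNA, with T standing for U.

## Cleavage scoring

Off-target sites are scored 0–100 with a position-specific mismatch
penalty vector (the experimentally derived SpCas9 weights shipped as the
default: `0, 0, 0.014, 0, 0, 0.395, 0.317, 0, 0.389, 0.079, 0.445,
0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583`,
position 1 PAM-distal). For mismatch set *M* with |*M*| = n:

- n = 0 → 100;
- n = 1 → 100·(1 − w_p);
- n ≥ 2 → 100 · Π(1 − w_p) · D · n⁻², with
  D = 1 / (((C − d̄)/C)·m + 1), d̄ the mean pairwise distance between
  mismatch positions, and constants C = 19 (the maximum pairwise
  distance on a 20-mer) and m = 4.

The constants are `ScoringScheme` fields; a protospacer length L other
than 20 requires a user-supplied weight vector of length L and scales
C to L − 1. PAM variants admitted by the off-target PAM pattern (NAG)
carry no score penalty of their own: the weight vector covers only the
protospacer, and scoring the PAM would require activity data the scheme
does not include. Ranked output therefore slightly overstates NAG-site
risk relative to measured NAG activity; this is the conservative
direction for guide selection.

## Off-target search

The search contract is exhaustiveness: every window on both strands of
every searched chromosome with (a) a PAM-pattern-satisfying 3-nt
adjacent window and (b) protospacer Hamming distance ≤ `max_mismatch`
yields exactly one hit. The implementation is a numpy sliding-window
comparison (20 vectorized inequality passes per strand) followed by a
PAM regex check on the surviving positions; the test suite certifies it
against an independently written character-by-character scan with early
exit, across mismatch budgets 0–4 and both `NGG$` and `N[A|G]G$` PAM
patterns, on random genomes and on fixtures with planted sites. Hits are
deterministic byte-for-byte across reruns: ranking sorts by score
descending with (chrom, start, strand) tie-breaks.

`min_score` (default 0.5, on the 0–100 scale) is applied before
truncation to `topN`. The per-guide summary reports the sums of the
top-5 and top-10 off-target scores after excluding the on-target hit.
The designated on-target is the zero-mismatch hit when one exists;
otherwise the top-scoring hit is flagged as putative on-target — the
normal situation when the input allele differs from the reference
genome. Which hits the totals exclude is a documented three-way toggle
(`exact` — the default, drop zero-mismatch hits only; `designated`;
`none`), because the published convention does not pin down whether an
allele-mismatched best hit belongs in the totals.

## Pairing and restriction-overlap filters

A nickase pair is a reverse-strand guide whose protospacer lies 5' (in
plus-strand coordinates) of a forward-strand guide — PAM-out geometry —
with a gap, counted as plus-strand bases strictly between the two
protospacer footprints, in `[min_gap, max_gap]` (defaults 0–20). The
published interface exposes only the gap bounds, not the measurement
convention; counting between protospacer edges (PAMs outside, never in
the gap) is this package's documented and configurable choice. Adjacent
protospacers have gap 0, and a guide may appear in several pairs.

The restriction-overlap filter keeps guides for which at least one
enzyme recognition site (IUPAC, matched in both orientations) overlaps
the Cas9 cleavage position — between protospacer positions 17 and 18,
3 bp from the PAM (`overlap_gRNA_positions`, default {17, 18}). The
search window is the protospacer footprint extended by site length − 1
on each side so boundary-spanning sites count. Enzyme tables are
two-column tab-delimited files; sites shorter than
`min_RE_pattern_size` (default 6) are dropped as uninformatively
frequent.

## Two-sequence comparison

Guides are discovered in both inputs (pairing and restriction filters
off by default); each guide is then scored against its best-matching
site in *each* sequence — both strands, PAM pattern `N[A|G]G$`, at most
⌊L/4⌋ mismatches considered (5 for 20-nt guides, far beyond plausible
divergence between related alleles; the bound keeps the scan linear).
A sequence with no admissible window scores 0. Records carry both
scores, the absolute score difference, and mismatch labels written as
`position:base` with positions counted from the PAM (PAM-proximal = 1),
the convention used when discussing seed mismatches at the bench;
internal scoring positions remain PAM-distal-based. Multi-record input
files are rejected rather than silently combined. Swapping the inputs
swaps the two score columns and preserves differences (tested).

## Annotation and flanks

Exon intervals come from BED (0-based half-open, converted on read) or
GFF3 (`exon` rows; gene id from `gene_id`/`gene`/`Parent`/`ID`). A hit
is exonic iff ≥ 1 bp of its protospacer span overlaps an exon on the
same chromosome, strand-agnostic; overlapping gene ids are reported
comma-joined and deduplicated. Queries use an interval tree and are
tested against a quadratic all-pairs oracle. Flanking sequence
(defaults ±200 bp) is returned in plus-strand orientation regardless of
hit strand — primers are designed on genomic coordinates — clipped at
chromosome ends.

## Reports

Four tab-delimited files per analysis (per-guide summary, off-target
table, restriction details, paired spacers), header row first, `.`
decimals, three-decimal floats, `\n` line endings; re-running an
identical analysis is byte-identical. The original tool named these
files `.xls` although their content is tab-delimited; a `legacy_names`
flag reproduces those filenames, the default is `.tsv`. Column names are
this package's documented equivalents (the originals are not published).
Existing files are refused unless `overwrite` is set. Guides export as
FASTA (protospacer+PAM) and GenBank flat files (one `misc_feature` per
guide with `/label`, `complement(..)` for reverse-strand guides), which
sequence viewers render as annotated maps.

## Synthetic data

Two generators define the test and demonstration conditions.

`make_fixture` plants off-target sites for a chosen guide — specified
mismatch positions and PAM — at non-overlapping positions in a uniform
random A/C/G/T genome, then self-scans and redraws the background if any
non-planted hit falls within the budget (for 20-nt guides at ≤ 4
mismatches the chance is of order 10⁻⁶ per position, so redraws are
rare). Its truth table (positions, mismatch sets, expected scores) is
therefore exact. Genome sizes used in the tests and acceptance script
are 8–50 kb: large enough that the vectorized scan dominates runtime
and background statistics are meaningful, small enough to keep the full
suite under a minute of scan time. What the random background does not
emulate: repeat families and segmental duplications, which in a real
genome dominate the off-target landscape, and base-composition bias.
Passing fixture tests show the engine finds exactly what is present —
they say nothing about how many near-matches a real genome contains.

`make_allele_pair` builds a 160-bp two-allele locus differing at a
single SNP, with seven planted PAMs arranged so the design space
contains every qualitatively distinct case: shared guides on both
strands (difference 0), guides covering the SNP 3, 6 and 14 bp from the
PAM (cross-allele scores 19.6, 26.8 and 68.3 — the first two below the
conventional 30 cutoff for allele discrimination), and a minus-strand
PAM created by the C allele itself, whose guide cannot be scored on the
T allele at all (difference 100). The background is A/T-only so that
every PAM is planted and the guide census is exact (7 on the C allele,
6 on the T); the generator verifies census and designed cross-scores
and redraws on the rare accidental near-duplicate window. This is an
idealized locus: real allele pairs have GC-rich background, more PAMs,
and SNPs at arbitrary offsets. It demonstrates and tests the
comparison logic, not the density of designable sites at real loci.

## Numerical and degenerate-input choices

Scores are plain float64 arithmetic; no tolerance is applied internally
and equality tests against the independent oracle pass at 1e-9. Empty
inputs yield empty outputs (never errors) everywhere except malformed
files and out-of-range parameters, which raise with the offending line
or position named. Tie-breaks are lexicographic on (chrom, start,
strand) everywhere a sort occurs, making all outputs deterministic.
The analysis itself is seed-free; randomness exists only in the
generators.

## Known limitations

- No bulge/indel off-targets: sites are Hamming-distance matches only.
- No on-target efficiency prediction; scores rank off-target risk, not
  activity.
- NAG off-target PAMs are not score-penalized (see above).
- The in-memory genome mapping suits targeted loci and model genomes;
  chromosome-scale scans work (the engine streams per chromosome) but
  are single-process and unindexed — a whole human genome at 4
  mismatches is hours, not minutes.
- Exon annotation is overlap-only: no promoter/UTR classes, no
  transcript models.
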