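"""Synthetic genomes and allele pairs with known ground truth.

Two generators back the test fixtures and worked examples:

* :func:`make_fixture` builds a random genome with off-target sites for a
  chosen guide *planted* at specified mismatch positions and PAM
  variants. The generator self-scans the finished genome and retries with
  fresh background until the planted sites are the only hits within the
  mismatch budget, so the truth table it emits is exact.

* :func:`make_allele_pair` builds an idealized two-allele locus — two
  sequences differing at a single SNP — engineered the way an
  allele-discrimination design problem presents itself: several guide
  sites shared by both alleles, sites where the SNP falls near the Cas9
  cleavage point (3 bp from the PAM, where mismatch penalties are
  largest), and one PAM that exists on only one allele. The background
  carries G and C only where sites were planted, which pins down the
  guide census exactly; it is deliberately simpler than real genomic
  sequence (see the methods note).

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .discovery import GuideCandidate, find_guides
from .offtargets import search_offtargets
from .params import DesignParameters


@dataclass(frozen=True)
class PlantedSite:
    """Specification/truth for one planted off-target site."""

    guide: str
    mismatch_positions: tuple[int, ...]
    pam: str
    chrom: str = "chr1"
    start: int = 0                    # 1-based; filled by the generator
    strand: str = "+"
    expected_score: float = 0.0


@dataclass
class Fixture:
    """A generated genome + input sequence + exact truth table."""

    genome: dict[str, str]
    input_id: str
    input_seq: str
    truth: list[PlantedSite]

    def write(self, outdir: str | Path) -> tuple[Path, Path, Path]:
        """Write genome FASTA, input FASTA and truth TSV into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gpath = outdir / "genome.fa"
        with open(gpath, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        ipath = outdir / "input.fa"
        with open(ipath, "w") as fh:
            fh.write(f">{self.input_id}\n")
            for i in range(0, len(self.input_seq), 60):
                fh.write(self.input_seq[i : i + 60] + "\n")
        tpath = outdir / "truth.tsv"
        with open(tpath, "w") as fh:
            fh.write(
                "guide\tchrom\tstart\tstrand\tmismatch_positions\tpam"
                "\texpected_score\n"
            )
            for s in self.truth:
                fh.write(
                    f"{s.guide}\t{s.chrom}\t{s.start}\t{s.strand}\t"
                    + ",".join(str(p) for p in s.mismatch_positions)
                    + f"\t{s.pam}\t{s.expected_score:.6f}\n"
                )
        return gpath, ipath, tpath


_BASES = np.array(list("ACGT"))


def random_genome(rng: np.random.Generator, length: int) -> str:
    """Uniform random A/C/G/T sequence."""
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def random_guide(rng: np.random.Generator, size: int = 20) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=size)])


def mutate(
    rng: np.random.Generator, guide: str, positions: tuple[int, ...]
) -> str:
    """Substitute a different random base at each 1-based position."""
    s = list(guide)
    for p in positions:
        choices = [b for b in "ACGT" if b != s[p - 1]]
        s[p - 1] = choices[rng.integers(0, 3)]
    return "".join(s)


def make_fixture(
    seed: int,
    genome_length: int,
    planted: list[tuple[str, tuple[int, ...], str]],
    params: DesignParameters | None = None,
    max_retries: int = 20,
) -> Fixture:
    """Random genome with planted off-target sites and exact truth.

    ``planted`` lists (guide, mismatch positions, PAM) triples; sites may
    use different guides. Each site is written onto the plus strand at a
    generator-chosen, non-overlapping position. The finished genome is
    self-scanned with every involved guide; if any hit beyond the planted
    ones falls within the mismatch budget (possible by chance in random
    background, vanishingly rare for 20-nt guides) the background is
    redrawn. The accompanying input sequence embeds each distinct guide
    with a TGG PAM in an A/T background so guide discovery recovers
    exactly the planted guides.
    """
    params = params or DesignParameters()
    rng = np.random.default_rng(seed)
    gl, ps = params.gRNA_size, params.PAM_size
    site_len = gl + ps
    for _attempt in range(max_retries):
        genome = list(random_genome(rng, genome_length))
        # non-overlapping slots with a small margin between sites
        n_slots = genome_length // (site_len + 10)
        if n_slots < len(planted):
            raise ValueError(
                f"genome of {genome_length} bp cannot hold "
                f"{len(planted)} sites"
            )
        slot_ids = rng.choice(n_slots, size=len(planted), replace=False)
        truth: list[PlantedSite] = []
        for (guide, mm, pam), slot in zip(planted, slot_ids):
            if len(guide) != gl or len(pam) != ps:
                raise ValueError(
                    "planted guide/PAM lengths must match the parameters"
                )
            site = mutate(rng, guide, tuple(mm)) + pam
            start0 = int(slot) * (site_len + 10) + int(rng.integers(0, 5))
            genome[start0 : start0 + site_len] = list(site)
            truth.append(
                PlantedSite(
                    guide=guide,
                    mismatch_positions=tuple(sorted(mm)),
                    pam=pam,
                    start=start0 + 1,
                    expected_score=params.scheme.score(sorted(mm)),
                )
            )
        genome_str = "".join(genome)
        if _self_scan_clean({"chr1": genome_str}, truth, params):
            break
    else:
        raise RuntimeError(
            f"could not build a clean fixture in {max_retries} attempts"
        )

    input_parts: list[str] = []
    seen: list[str] = []
    for guide, _, _ in planted:
        if guide not in seen:
            seen.append(guide)
    for guide in seen:
        pad = "".join(
            np.array(list("AT"))[rng.integers(0, 2, size=10)]
        )
        input_parts.append(guide + "TGG" + pad)
    input_seq = "".join(input_parts)
    return Fixture(
        genome={"chr1": genome_str},
        input_id="fixture_input",
        input_seq=input_seq,
        truth=truth,
    )


def _self_scan_clean(
    genome: dict[str, str],
    truth: list[PlantedSite],
    params: DesignParameters,
) -> bool:
    """True iff every guide's hits are exactly its planted sites."""
    guides = sorted({t.guide for t in truth})
    for gseq in guides:
        g = GuideCandidate(
            name="self_scan", source_id="self_scan",
            protospacer=gseq, pam=params.PAM, strand="f",
        )
        budget = max(
            [params.max_mismatch]
            + [len(t.mismatch_positions) for t in truth if t.guide == gseq]
        )
        scan = DesignParameters(
            gRNA_size=params.gRNA_size, PAM=params.PAM,
            PAM_size=params.PAM_size, PAM_pattern=params.PAM_pattern,
            max_mismatch=budget, weights=params.weights,
        )
        hits = search_offtargets(g, genome, scan)
        expected = {
            (t.chrom, t.start, t.strand, t.mismatch_positions)
            for t in truth
            if t.guide == gseq
        }
        got = {
            (h.chrom, h.start, h.strand, h.mismatch_positions)
            for h in hits
        }
        if got != expected:
            return False
    return True


# ---------------------------------------------------------------------------
# Two-allele locus


@dataclass
class AllelePair:
    """An idealized SNP locus: two sequences differing at one base."""

    id1: str
    seq1: str                         # allele carrying the C at the SNP
    id2: str
    seq2: str                         # allele carrying the T
    snp_position: int                 # 1-based, same in both sequences

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, seq in ((self.id1, self.seq1), (self.id2, self.seq2)):
            p = outdir / f"{name}.fa"
            with open(p, "w") as fh:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
            paths.append(p)
        return paths[0], paths[1]


def make_allele_pair(seed: int, length: int = 160) -> AllelePair:
    """Two-allele SNP locus with an engineered guide layout.

    The design places (1-based coordinates, SNP at 80):

    * four guide sites away from the SNP, shared by both alleles — two on
      each strand — whose cross-allele score difference is 0;
    * two plus-strand sites whose protospacers cover the SNP at positions
      18 and 15 (3 and 6 bp from the PAM), where the single C/T mismatch
      drops the cross-allele cleavage score below 30;
    * one site covering the SNP at position 7, where the same mismatch is
      tolerated (score ~68);
    * a CC dinucleotide created by the C allele at the SNP itself, which
      is a minus-strand PAM present only on that allele — the guide it
      licenses cannot be scored on the T allele at all (score 0,
      difference 100).

    The background uses A/T only, so every G/C — hence every PAM — is
    planted, which makes the guide census exact: 7 guides on the C allele
    and 6 on the T allele. The generator verifies the census and the
    designed cross-allele scores by running discovery and cross-scoring
    on both alleles, redrawing the random background if an accidental
    near-duplicate window spoils the truth (rare; the background windows
    are random A/T).
    """
    if length < 150:
        raise ValueError("allele locus must be at least 150 bp")
    rng = np.random.default_rng(seed)
    snp = 80
    for _attempt in range(10):
        base = list(
            "".join(np.array(list("AT"))[rng.integers(0, 2, size=length)])
        )

        def put(pos1: int, text: str) -> None:
            base[pos1 - 1 : pos1 - 1 + len(text)] = list(text)

        # shared sites away from the SNP (plus-strand PAM needs GG; a
        # minus-strand PAM reads CC on the plus strand, protospacer 3' of it)
        put(30, "GG")        # plus guide, protospacer 9-28
        put(50, "CC")        # minus guide, protospacer 53-72
        put(110, "CC")       # minus guide, protospacer 113-132
        # SNP-overlapping sites: protospacer position of SNP = 80 - start + 1
        put(84, "GG")        # protospacer 63-82, SNP at position 18
        put(87, "GG")        # protospacer 66-85, SNP at position 15
        put(95, "GG")        # protospacer 74-93, SNP at position 7
        put(81, "C")         # with a C at the SNP this makes CC = minus PAM
        seq_c = base.copy()
        seq_c[snp - 1] = "C"
        seq_t = base.copy()
        seq_t[snp - 1] = "T"
        pair = AllelePair(
            id1="alleleC_synthetic",
            seq1="".join(seq_c),
            id2="alleleT_synthetic",
            seq2="".join(seq_t),
            snp_position=snp,
        )
        if _verify_allele_pair(pair):
            return pair
    raise RuntimeError(
        "could not build a clean allele pair in 10 attempts"
    )


def _verify_allele_pair(pair: AllelePair) -> bool:
    """Check the engineered truth of an allele-pair draw.

    Census 7 (C) / 6 (T); every guide scores 100 on its own allele;
    guides covering the SNP at protospacer positions 18/15/7 take exactly
    the corresponding single-mismatch cross score; the PAM-gain guide has
    no site on the T allele; all other guides have difference 0.
    """
    from .compare import compare_sequence_pair  # local: avoid import cycle
    from .sequence import reverse_complement

    params = DesignParameters.compare_defaults()
    w = params.scheme.weights
    if len(find_guides(pair.id1, pair.seq1, params)) != 7:
        return False
    if len(find_guides(pair.id2, pair.seq2, params)) != 6:
        return False
    records = compare_sequence_pair(
        pair.id1, pair.seq1, pair.id2, pair.seq2, params
    )
    # designed cross score, keyed by protospacer start in the source allele
    designed = {63: 100 * (1 - w[17]), 66: 100 * (1 - w[14]),
                74: 100 * (1 - w[6])}
    for r in records:
        own = r.score_seq1 if r.source == "seq1" else r.score_seq2
        cross = r.score_seq2 if r.source == "seq1" else r.score_seq1
        if own != 100.0:
            return False
        # identify the guide by re-locating its protospacer in its source
        src_seq = pair.seq1 if r.source == "seq1" else pair.seq2
        idx = src_seq.find(r.protospacer)
        if idx < 0:
            idx = src_seq.find(reverse_complement(r.protospacer))
        start1 = idx + 1
        if start1 in designed:
            if abs(cross - designed[start1]) > 1e-9:
                return False
        elif start1 == 83 and r.source == "seq1":
            # the PAM-gain guide: no admissible site on the T allele
            if cross != 0.0 or r.score_difference != 100.0:
                return False
        else:
            if r.score_difference != 0.0:
                return False
    return True


def write_re_table(path: str | Path, entries: list[tuple[str, str]]) -> Path:
    """Write a tab-delimited enzyme table (name, IUPAC site)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# enzyme\trecognition site\n")
        for name, site in entries:
            fh.write(f"{name}\t{site}\n")
    return path
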