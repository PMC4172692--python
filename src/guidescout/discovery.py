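"""Candidate guide discovery and filtering in input sequences.

A candidate guide is a protospacer of ``gRNA_size`` nt immediately 5' of a
PAM matching the design PAM consensus, on either strand of the input.
Discovered guides can then be filtered by a guide-sequence pattern, by
paired-nickase geometry (two guides on opposite strands in PAM-out
orientation with a bounded gap), and by overlap between the Cas9 cleavage
point and a restriction-enzyme recognition site (useful for monitoring
cleavage by RFLP assays).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .params import DesignParameters
from .sequence import (
    PatternError,
    guide_pattern_ok,
    iupac_match,
    normalize,
    reverse_complement,
    reverse_complement_iupac,
    validate_iupac,
)


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer + PAM occurrence in an input sequence.

    ``start``/``end`` are 1-based inclusive coordinates of the protospacer
    in the plus-strand frame of the input (``None`` for guides loaded from
    a pre-computed FASTA, which carry no coordinates). The PAM lies
    immediately 3' of the protospacer on the guide's strand: to the right
    of ``end`` for strand ``f``, to the left of ``start`` for strand ``r``.
    """

    name: str
    source_id: str
    protospacer: str
    pam: str
    strand: str                       # 'f' or 'r'
    start: int | None = None
    end: int | None = None

    @property
    def target_site(self) -> str:
        """Protospacer + PAM, 5'->3' on the guide's strand."""
        return self.protospacer + self.pam


@dataclass(frozen=True)
class GuidePair:
    """A PAM-out (reverse, forward) nickase pair.

    The reverse guide's protospacer lies at lower plus-strand coordinates
    than the forward guide's; ``gap`` counts the plus-strand bases strictly
    between the two protospacer footprints (both PAMs point outward and are
    never part of the gap). Adjacent protospacers have gap 0.
    """

    reverse_guide: GuideCandidate
    forward_guide: GuideCandidate
    gap: int


@dataclass(frozen=True)
class REPattern:
    """A restriction enzyme and its IUPAC recognition site."""

    enzyme: str
    site: str


@dataclass(frozen=True)
class REOverlap:
    """A recognition-site match overlapping a guide's cleavage position."""

    guide_name: str
    enzyme: str
    match_start: int                  # 1-based input coordinate
    matched_window: str


def find_guides(
    source_id: str, sequence: str, params: DesignParameters
) -> list[GuideCandidate]:
    """All candidate guides in an input sequence, both strands.

    Scans every window where a ``PAM_size`` window immediately 3' of a
    ``gRNA_size`` protospacer matches the design PAM (IUPAC), keeping
    protospacers that are fully A/C/G/T and satisfy ``gRNA_pattern``.
    Results are sorted by plus-strand protospacer start, then strand, and
    named ``<prefix><strand><ordinal>_<source_id>`` with per-strand
    ordinals assigned in ascending plus-strand start order.
    """
    seq = normalize(sequence)
    gl, ps = params.gRNA_size, params.PAM_size
    hits: list[tuple[int, int, str, str, str]] = []  # start0, end0, strand, proto, pam
    n = len(seq)
    if n >= gl + ps:
        for i in range(n - gl - ps + 1):
            proto = seq[i : i + gl]
            pam = seq[i + gl : i + gl + ps]
            if "N" in proto:
                continue
            if not iupac_match(params.PAM, pam):
                continue
            if not guide_pattern_ok(proto, params.gRNA_pattern):
                continue
            hits.append((i, i + gl, "f", proto, pam))
        rc = reverse_complement(seq)
        for j in range(n - gl - ps + 1):
            proto = rc[j : j + gl]
            pam = rc[j + gl : j + gl + ps]
            if "N" in proto:
                continue
            if not iupac_match(params.PAM, pam):
                continue
            if not guide_pattern_ok(proto, params.gRNA_pattern):
                continue
            # rc[j : j+gl] occupies plus-strand [n-j-gl, n-j) (0-based).
            hits.append((n - j - gl, n - j, "r", proto, pam))

    out: list[GuideCandidate] = []
    for strand in ("f", "r"):
        strand_hits = sorted(
            (h for h in hits if h[2] == strand), key=lambda h: h[0]
        )
        for ordinal, (s0, e0, _, proto, pam) in enumerate(strand_hits, 1):
            out.append(
                GuideCandidate(
                    name=(
                        f"{params.gRNA_name_prefix}{strand}{ordinal}"
                        f"_{source_id}"
                    ),
                    source_id=source_id,
                    protospacer=proto,
                    pam=pam,
                    strand=strand,
                    start=s0 + 1,
                    end=e0,
                )
            )
    out.sort(key=lambda g: (g.start, g.strand))
    return out


def load_precomputed_guides(
    fasta_path: str | Path, params: DesignParameters
) -> list[GuideCandidate]:
    """Load user-supplied guides from a FASTA of protospacer(+PAM) records.

    Each record must be ``gRNA_size + PAM_size`` nt (protospacer followed
    by PAM) or bare ``gRNA_size`` nt, in which case the design PAM
    consensus is assumed (with a warning). Coordinates are left unset;
    off-target search proceeds normally.
    """
    gl, ps = params.gRNA_size, params.PAM_size
    out: list[GuideCandidate] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = normalize(str(rec.seq))
        if len(seq) == gl + ps:
            proto, pam = seq[:gl], seq[gl:]
        elif len(seq) == gl:
            proto, pam = seq, params.PAM
            warnings.warn(
                f"record {rec.id!r} has no PAM; assuming the design "
                f"consensus {params.PAM!r}",
                stacklevel=2,
            )
        else:
            raise ValueError(
                f"record {rec.id!r} has length {len(seq)}; expected "
                f"{gl + ps} (protospacer+PAM) or {gl} (protospacer only)"
            )
        out.append(
            GuideCandidate(
                name=rec.id,
                source_id=rec.id,
                protospacer=proto,
                pam=pam,
                strand="f",
            )
        )
    return out


def pair_guides(
    guides: list[GuideCandidate], params: DesignParameters
) -> list[GuidePair]:
    """All PAM-out (reverse, forward) pairs with an in-range gap.

    A guide may appear in several pairs. Guides without coordinates are
    ignored. Pairs are sorted by (reverse start, forward start).
    """
    rev = [g for g in guides if g.strand == "r" and g.start is not None]
    fwd = [g for g in guides if g.strand == "f" and g.start is not None]
    pairs: list[GuidePair] = []
    for r in rev:
        for f in fwd:
            gap = f.start - r.end - 1
            if r.end < f.start and params.min_gap <= gap <= params.max_gap:
                pairs.append(GuidePair(r, f, gap))
    pairs.sort(key=lambda p: (p.reverse_guide.start, p.forward_guide.start))
    return pairs


def parse_re_patterns(
    path: str | Path, min_RE_pattern_size: int = 6
) -> list[REPattern]:
    """Read a tab-delimited enzyme table: ``name<TAB>IUPAC site`` per line.

    Lines starting with ``#`` and blank lines are skipped. Sites shorter
    than ``min_RE_pattern_size`` are dropped (short sites match too often
    to be useful); retained patterns keep file order.
    """
    out: list[REPattern] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}: line {lineno}: expected "
                    "'name<TAB>recognition site'"
                )
            try:
                site = validate_iupac(fields[1].strip())
            except PatternError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            if len(site) >= min_RE_pattern_size:
                out.append(REPattern(enzyme=fields[0].strip(), site=site))
    return out


def _cleavage_coords(
    guide: GuideCandidate, positions: tuple[int, ...]
) -> set[int]:
    # Map protospacer positions (1 = 5' end on the guide's strand) to
    # plus-strand input coordinates.
    if guide.strand == "f":
        return {guide.start + p - 1 for p in positions}
    return {guide.end - p + 1 for p in positions}


def filter_by_re_overlap(
    guides: list[GuideCandidate],
    re_patterns: list[REPattern],
    params: DesignParameters,
    sequence: str,
) -> list[tuple[GuideCandidate, list[REOverlap]]]:
    """Keep guides whose cleavage position overlaps a recognition site.

    The Cas9 blunt cut falls between protospacer positions 17 and 18
    (3 bp from the PAM), the default ``overlap_gRNA_positions``. For each
    guide the search window is the protospacer footprint extended by
    (site length - 1) bases on each side, so sites spanning the footprint
    boundary still count; each recognition site is matched in both
    orientations (IUPAC), and all matches hitting a cleavage position are
    reported.
    """
    seq = normalize(sequence)
    n = len(seq)
    kept: list[tuple[GuideCandidate, list[REOverlap]]] = []
    for g in guides:
        if g.start is None:
            continue
        cleave = _cleavage_coords(g, params.overlap_gRNA_positions)
        overlaps: list[REOverlap] = []
        for pat in re_patterns:
            sl = len(pat.site)
            variants = {pat.site, reverse_complement_iupac(pat.site)}
            lo = max(1, g.start - (sl - 1))
            hi = min(n, g.end + (sl - 1))      # inclusive 1-based bounds
            for ms in range(lo, hi - sl + 2):
                window = seq[ms - 1 : ms - 1 + sl]
                if not any(iupac_match(v, window) for v in variants):
                    continue
                if cleave & set(range(ms, ms + sl)):
                    overlaps.append(
                        REOverlap(
                            guide_name=g.name,
                            enzyme=pat.enzyme,
                            match_start=ms,
                            matched_window=window,
                        )
                    )
        if overlaps:
            kept.append((g, overlaps))
    return kept
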