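"""Genome-wide off-target search, cleavage scoring and ranking.

The search contract is exhaustiveness: every position on both strands of
every searched chromosome where the PAM-size window 3' of a protospacer
window satisfies the off-target PAM pattern AND the protospacer Hamming
distance is within the mismatch budget yields exactly one hit. The scan is
a vectorized sliding-window Hamming comparison (numpy); unknown genome
bases (N, or anything outside A/C/G/T) count as mismatches at every
protospacer position and never satisfy a PAM symbol, so assembly gaps
cannot fabricate hits.

Hits are scored with the position-weighted mismatch penalty scheme
(``ScoringScheme``), filtered by a minimum score, ranked, truncated to the
top N per guide, and summarized as the sums of the top-5 and top-10
off-target scores — a compact per-guide measure of genome-wide off-target
burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .discovery import GuideCandidate
from .params import DesignParameters
from .sequence import compile_iupac_regex, reverse_complement

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i       # tolerate soft-masked lowercase


@dataclass
class OffTargetHit:
    """A genomic site matched to a guide within the mismatch budget.

    ``start``/``end`` are 1-based inclusive plus-strand coordinates of the
    protospacer-aligned window; ``site_seq``/``pam_seq`` are read 5'->3'
    on the hit strand so they align with the guide. Mismatch positions are
    1-based with position 1 at the PAM-distal (5') end.
    """

    guide_name: str
    chrom: str
    start: int
    end: int
    strand: str                       # '+' or '-'
    site_seq: str
    pam_seq: str
    mismatch_positions: tuple[int, ...]
    n_mismatch: int
    score: float
    in_exon: bool | None = None
    gene_id: str | None = None
    flank_seq: str | None = None


@dataclass
class GuideSummary:
    """Per-guide off-target burden summary."""

    guide_name: str
    n_hits: int
    top5_offtarget_total: float
    top10_offtarget_total: float
    on_target: OffTargetHit | None = None


def mismatch_positions(guide: str, site: str) -> list[int]:
    """1-based positions (PAM-distal = 1) where guide and site differ.

    A site base outside A/C/G/T (an unknown genome base) always counts as
    a mismatch.
    """
    if len(guide) != len(site):
        raise ValueError(
            f"guide length {len(guide)} != site length {len(site)}"
        )
    g, s = guide.upper(), site.upper()
    return [
        i + 1
        for i, (gb, sb) in enumerate(zip(g, s))
        if sb not in "ACGT" or gb != sb
    ]


def _scan_strand(
    enc: np.ndarray,
    seq: str,
    guide_enc: np.ndarray,
    gl: int,
    ps: int,
    max_mm: int,
    pam_rx,
) -> Iterable[tuple[int, list[int], str, str]]:
    """Yield (start0, mismatch positions, site, pam) on one strand frame."""
    n_pos = len(enc) - gl - ps + 1
    if n_pos <= 0:
        return
    mism = np.zeros(n_pos, dtype=np.int16)
    for p in range(gl):
        mism += enc[p : p + n_pos] != guide_enc[p]
    for i in np.nonzero(mism <= max_mm)[0]:
        pam = seq[i + gl : i + gl + ps]
        if pam_rx.search(pam) is None:
            continue
        site = seq[i : i + gl]
        mm = [
            p + 1
            for p in range(gl)
            if enc[i + p] != guide_enc[p]
        ]
        yield int(i), mm, site, pam


def search_offtargets(
    guide: GuideCandidate,
    genome: Mapping[str, str],
    params: DesignParameters,
) -> list[OffTargetHit]:
    """Exhaustive scan of a genome for candidate off-target sites.

    ``genome`` maps chromosome names to sequences (a dict, or any mapping
    such as a ``pyfaidx.Fasta`` adapter). ``params.chrom_to_search``
    selects ``"all"`` chromosomes, a single named chromosome, or ``""``
    to skip the search entirely. Hits are scored but not filtered or
    ranked; see :func:`filter_and_rank`.
    """
    if params.chrom_to_search == "":
        return []
    if params.chrom_to_search == "all":
        chroms = list(genome.keys())
    else:
        if params.chrom_to_search not in genome:
            raise KeyError(
                f"chromosome {params.chrom_to_search!r} not in genome; "
                f"available: {sorted(genome.keys())}"
            )
        chroms = [params.chrom_to_search]

    gl, ps = params.gRNA_size, params.PAM_size
    if len(guide.protospacer) != gl:
        raise ValueError(
            f"guide {guide.name!r} protospacer length "
            f"{len(guide.protospacer)} != gRNA_size {gl}"
        )
    scheme = params.scheme
    pam_rx = compile_iupac_regex(params.PAM_pattern)
    g_enc = _ENCODE[np.frombuffer(guide.protospacer.encode(), np.uint8)]

    hits: list[OffTargetHit] = []
    for chrom in chroms:
        seq = str(genome[chrom]).upper()
        L = len(seq)
        enc = _ENCODE[np.frombuffer(seq.encode(), np.uint8)]
        for i, mm, site, pam in _scan_strand(
            enc, seq, g_enc, gl, ps, params.max_mismatch, pam_rx
        ):
            hits.append(
                OffTargetHit(
                    guide_name=guide.name,
                    chrom=chrom,
                    start=i + 1,
                    end=i + gl,
                    strand="+",
                    site_seq=site,
                    pam_seq=pam,
                    mismatch_positions=tuple(mm),
                    n_mismatch=len(mm),
                    score=scheme.score(mm),
                )
            )
        rc = reverse_complement(seq)
        enc_rc = _ENCODE[np.frombuffer(rc.encode(), np.uint8)]
        for j, mm, site, pam in _scan_strand(
            enc_rc, rc, g_enc, gl, ps, params.max_mismatch, pam_rx
        ):
            hits.append(
                OffTargetHit(
                    guide_name=guide.name,
                    chrom=chrom,
                    start=L - j - gl + 1,
                    end=L - j,
                    strand="-",
                    site_seq=site,
                    pam_seq=pam,
                    mismatch_positions=tuple(mm),
                    n_mismatch=len(mm),
                    score=scheme.score(mm),
                )
            )
    return hits


def filter_and_rank(
    hits: list[OffTargetHit], params: DesignParameters
) -> list[OffTargetHit]:
    """Drop sub-threshold hits, rank, truncate to the per-guide top N.

    Ordering is score descending with (chrom, start, strand) tie-breaks,
    which makes ranked output deterministic for identical inputs.
    """
    kept = [h for h in hits if h.score >= params.min_score]
    kept.sort(key=lambda h: (-h.score, h.chrom, h.start, h.strand))
    return kept[: params.topN]


def summarize_guide(
    hits: list[OffTargetHit],
    params: DesignParameters,
    on_target_exclusion: str = "exact",
) -> GuideSummary:
    """Sum the top-5 and top-10 off-target scores for one guide.

    The designated on-target is the zero-mismatch hit if one exists,
    otherwise the top-scoring hit is flagged as the putative on-target
    (the common situation when the input allele differs from the reference
    genome, where the best genomic match carries one mismatch).

    ``on_target_exclusion`` controls which hits the totals drop:
    ``"exact"`` (default) drops zero-mismatch hits only; ``"designated"``
    also drops a putative (mismatched) on-target; ``"none"`` keeps every
    hit. The top-10 total actually sums the first
    ``min(10, topN_offtarget_total_score)`` scores.
    """
    if on_target_exclusion not in ("exact", "designated", "none"):
        raise ValueError(
            "on_target_exclusion must be 'exact', 'designated' or 'none'"
        )
    ranked = sorted(
        hits, key=lambda h: (-h.score, h.chrom, h.start, h.strand)
    )
    exact = [h for h in ranked if h.n_mismatch == 0]
    on_target = exact[0] if exact else (ranked[0] if ranked else None)
    if on_target_exclusion == "none":
        counted = ranked
    elif on_target_exclusion == "designated":
        counted = [h for h in ranked if h is not on_target]
    else:
        counted = [h for h in ranked if h.n_mismatch > 0]
    k10 = min(10, params.topN_offtarget_total_score)
    scores = [h.score for h in counted]
    name = hits[0].guide_name if hits else ""
    return GuideSummary(
        guide_name=name,
        n_hits=len(hits),
        top5_offtarget_total=float(sum(scores[:5])),
        top10_offtarget_total=float(sum(scores[:k10])),
        on_target=on_target,
    )
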