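"""Allele-discriminating guide selection: score guides on two sequences.

Given two related input sequences — the two alleles of a SNP, two members
of a gene family, an original sequence and its engineered replacement —
every candidate guide found in either sequence is scored against both,
and guides are ranked by the absolute difference of the two cleavage
scores. A difference of 100 means the guide is predicted to cleave only
one sequence (fully allele-specific); 0 means it cleaves both equally
(useful when both alleles must be targeted with one nuclease). No
genome-wide off-target analysis is performed here; promising guides can be
followed up with the full off-target workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .discovery import GuideCandidate, find_guides
from .offtargets import search_offtargets
from .params import DesignParameters


@dataclass
class ComparisonRecord:
    """One guide's cleavage scores in both input sequences.

    ``mismatch_labels`` describe the best-matching site in the sequence
    the guide did NOT come from, as ``position:base`` with the position
    counted from the PAM (PAM-proximal = 1) and the base taken from that
    site. The guide's score in its own source sequence is 100 whenever an
    exact self-match exists there.
    """

    guide_name: str
    source: str                       # 'seq1' or 'seq2'
    protospacer: str
    pam: str
    target_site_seq1: str | None
    target_site_seq2: str | None
    score_seq1: float
    score_seq2: float
    mismatch_labels: tuple[str, ...]
    score_difference: float


def _best_site(
    guide: GuideCandidate, seq_id: str, sequence: str, params: DesignParameters
) -> tuple[str | None, float, tuple[int, ...], str]:
    """Best-scoring candidate site for a guide within one sequence.

    Scans both strands for protospacer windows followed by a PAM
    satisfying ``PAM_pattern``, allowing up to floor(gRNA_size / 4)
    mismatches — far beyond any plausible divergence between two related
    alleles. Returns (site+PAM, score, mismatch positions PAM-distal,
    site protospacer); a sequence with no admissible window scores 0.
    """
    scan = DesignParameters(
        gRNA_size=params.gRNA_size,
        PAM=params.PAM,
        PAM_size=params.PAM_size,
        PAM_pattern=params.PAM_pattern,
        max_mismatch=params.gRNA_size // 4,
        weights=params.weights,
        min_gap=params.min_gap,
        max_gap=params.max_gap,
        find_paired_only=False,
        find_RE_cut_only=False,
    )
    hits = search_offtargets(guide, {seq_id: sequence}, scan)
    if not hits:
        return None, 0.0, (), ""
    best = max(hits, key=lambda h: (h.score, -h.start))
    return (
        best.site_seq + best.pam_seq,
        best.score,
        best.mismatch_positions,
        best.site_seq,
    )


def compare_sequence_pair(
    id1: str,
    seq1: str,
    id2: str,
    seq2: str,
    params: DesignParameters | None = None,
) -> list[ComparisonRecord]:
    """Find guides in both sequences and cross-score every guide.

    Records are sorted by score difference, largest (most
    allele-discriminating) first.
    """
    params = params or DesignParameters.compare_defaults()
    gl = params.gRNA_size
    records: list[ComparisonRecord] = []
    for source, guides in (
        ("seq1", find_guides(id1, seq1, params)),
        ("seq2", find_guides(id2, seq2, params)),
    ):
        for g in guides:
            site1, s1, mm1, _ = _best_site(g, id1, seq1, params)
            site2, s2, mm2, p2 = _best_site(g, id2, seq2, params)
            if source == "seq1":
                cross_mm, cross_site = mm2, (site2 or "")
            else:
                cross_mm, cross_site = mm1, (site1 or "")
            labels = tuple(
                f"{gl + 1 - p}:{cross_site[p - 1]}"
                for p in cross_mm
                if cross_site
            )
            records.append(
                ComparisonRecord(
                    guide_name=g.name,
                    source=source,
                    protospacer=g.protospacer,
                    pam=g.pam,
                    target_site_seq1=site1,
                    target_site_seq2=site2,
                    score_seq1=s1,
                    score_seq2=s2,
                    mismatch_labels=labels,
                    score_difference=abs(s1 - s2),
                )
            )
    records.sort(key=lambda r: (-r.score_difference, r.guide_name))
    return records


def _read_single_fasta(path: str | Path) -> tuple[str, str]:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 1:
        raise ValueError(
            f"{path}: expected exactly one FASTA record, found {len(recs)}"
        )
    return recs[0].id, str(recs[0].seq)


def compare_two_sequences(
    fasta1: str | Path,
    fasta2: str | Path,
    params: DesignParameters | None = None,
) -> list[ComparisonRecord]:
    """File-based entry point: each input is a single-record FASTA."""
    id1, seq1 = _read_single_fasta(fasta1)
    id2, seq2 = _read_single_fasta(fasta2)
    return compare_sequence_pair(id1, seq1, id2, seq2, params)
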