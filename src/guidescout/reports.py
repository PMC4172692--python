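"""Tab-delimited report writers and GenBank/FASTA guide exports.

Four reports are produced per off-target analysis run — a per-guide
summary, the full off-target table, restriction-site overlap details and
paired-spacer geometry — all tab-separated with a header row, ``.``
decimal separators, three-decimal floats and ``\\n`` line endings, so
re-running an identical analysis yields byte-identical files. Recovered
guides are additionally exported as FASTA (protospacer+PAM) and as a
GenBank flat file with one ``misc_feature`` per guide, which common
sequence viewers render as an annotated map of the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .compare import ComparisonRecord
from .discovery import GuideCandidate, GuidePair, REOverlap
from .offtargets import GuideSummary, OffTargetHit

SUMMARY_COLUMNS = (
    "name", "protospacer", "pam", "n_offtargets",
    "top5_offtarget_total_score", "top10_offtarget_total_score",
    "on_target_locus",
)
OFFTARGET_COLUMNS = (
    "guide_name", "chrom", "start", "end", "strand", "site_seq", "pam_seq",
    "mismatch_positions", "n_mismatch", "score", "in_exon", "gene_id",
    "flank_seq",
)
RE_COLUMNS = ("guide_name", "enzyme", "match_start", "matched_window")
PAIR_COLUMNS = (
    "reverse_name", "forward_name", "gap",
    "reverse_start", "reverse_end", "forward_start", "forward_end",
)
COMPARISON_COLUMNS = (
    "guide_name", "source", "protospacer", "pam",
    "target_site_seq1", "target_site_seq2",
    "score_seq1", "score_seq2", "mismatch_labels", "score_difference",
)

#: Report basenames; ``legacy_names=True`` reproduces the original
#: ``.xls`` filenames (the contents are tab-delimited either way).
REPORT_NAMES = {
    "summary": ("Summary.tsv", "Summary.xls"),
    "offtarget": ("OfftargetAnalysis.tsv", "OfftargetAnalysis.xls"),
    "re_details": ("REcutDetails.tsv", "REcutDetails.xls"),
    "paired": ("pairedSpacers.tsv", "pairedSpacers.xls"),
}


@dataclass
class ReportSet:
    summary_path: Path
    offtarget_path: Path
    re_details_path: Path
    paired_path: Path
    genbank_paths: list[Path]
    fasta_path: Path | None = None


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "TRUE" if x else "FALSE"
    if isinstance(x, float):
        return f"{x:.3f}"
    return str(x)


def _write_tsv(path: Path, columns: tuple[str, ...], rows) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _check_overwrite(paths: list[Path], overwrite: bool) -> None:
    if overwrite:
        return
    existing = [str(p) for p in paths if p.exists()]
    if existing:
        raise FileExistsError(
            "refusing to overwrite existing report files (pass "
            "overwrite=True): " + ", ".join(existing)
        )


def _locus(hit: OffTargetHit | None) -> str:
    if hit is None:
        return ""
    return f"{hit.chrom}:{hit.start}-{hit.end}({hit.strand})"


def write_reports(
    guides: list[GuideCandidate],
    pairs: list[GuidePair],
    re_overlaps: list[REOverlap],
    hits: list[OffTargetHit],
    summaries: list[GuideSummary],
    outdir: str | Path,
    overwrite: bool = False,
    legacy_names: bool = False,
) -> ReportSet:
    """Write the four tab-delimited analysis reports into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    idx = 1 if legacy_names else 0
    paths = {k: outdir / v[idx] for k, v in REPORT_NAMES.items()}
    _check_overwrite(list(paths.values()), overwrite)

    by_name = {s.guide_name: s for s in summaries}
    summary_rows = []
    for g in guides:
        s = by_name.get(g.name)
        summary_rows.append((
            g.name, g.protospacer, g.pam,
            s.n_hits if s else 0,
            s.top5_offtarget_total if s else 0.0,
            s.top10_offtarget_total if s else 0.0,
            _locus(s.on_target) if s else "",
        ))
    _write_tsv(paths["summary"], SUMMARY_COLUMNS, summary_rows)

    _write_tsv(
        paths["offtarget"],
        OFFTARGET_COLUMNS,
        (
            (
                h.guide_name, h.chrom, h.start, h.end, h.strand,
                h.site_seq, h.pam_seq,
                ",".join(str(p) for p in h.mismatch_positions),
                h.n_mismatch, h.score, h.in_exon, h.gene_id, h.flank_seq,
            )
            for h in hits
        ),
    )
    _write_tsv(
        paths["re_details"],
        RE_COLUMNS,
        (
            (o.guide_name, o.enzyme, o.match_start, o.matched_window)
            for o in re_overlaps
        ),
    )
    _write_tsv(
        paths["paired"],
        PAIR_COLUMNS,
        (
            (
                p.reverse_guide.name, p.forward_guide.name, p.gap,
                p.reverse_guide.start, p.reverse_guide.end,
                p.forward_guide.start, p.forward_guide.end,
            )
            for p in pairs
        ),
    )
    return ReportSet(
        summary_path=paths["summary"],
        offtarget_path=paths["offtarget"],
        re_details_path=paths["re_details"],
        paired_path=paths["paired"],
        genbank_paths=[],
    )


def write_comparison_table(
    records: list[ComparisonRecord],
    path: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write the two-sequence comparison table as TSV."""
    path = Path(path)
    _check_overwrite([path], overwrite)
    _write_tsv(
        path,
        COMPARISON_COLUMNS,
        (
            (
                r.guide_name, r.source, r.protospacer, r.pam,
                r.target_site_seq1 or "not found",
                r.target_site_seq2 or "not found",
                r.score_seq1, r.score_seq2,
                ",".join(r.mismatch_labels),
                r.score_difference,
            )
            for r in records
        ),
    )
    return path


def write_genbank(
    record_id: str,
    sequence: str,
    guides: list[GuideCandidate],
    path: str | Path,
    overwrite: bool = False,
) -> Path:
    """Export an input sequence with its guides as GenBank features.

    Each guide becomes a ``misc_feature`` carrying ``/label=<name>``;
    reverse-strand guides are written as ``complement(start..end)``.
    Coordinates span the protospacer only (1-based inclusive in the flat
    file).
    """
    path = Path(path)
    _check_overwrite([path], overwrite)
    n = len(sequence)
    rec = SeqRecord(
        Seq(sequence.upper()),
        id=record_id[:16] or "input",
        name=(record_id[:16] or "input"),
        description=f"{record_id} with candidate guide RNA target sites",
        annotations={"molecule_type": "DNA"},
    )
    for g in guides:
        if g.start is None:
            continue
        if not (1 <= g.start <= g.end <= n):
            raise ValueError(
                f"guide {g.name!r} at {g.start}-{g.end} out of bounds "
                f"for sequence of length {n}"
            )
        rec.features.append(
            SeqFeature(
                FeatureLocation(
                    g.start - 1, g.end, strand=1 if g.strand == "f" else -1
                ),
                type="misc_feature",
                qualifiers={"label": [g.name]},
            )
        )
    SeqIO.write([rec], str(path), "genbank")
    return path


def write_guides_fasta(
    guides: list[GuideCandidate], path: str | Path, overwrite: bool = False
) -> Path:
    """Export guides (protospacer+PAM) as a 60-column-wrapped FASTA."""
    path = Path(path)
    _check_overwrite([path], overwrite)
    records = [
        SeqRecord(Seq(g.target_site), id=g.name, description="")
        for g in guides
    ]
    SeqIO.write(records, str(path), "fasta")
    return path
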