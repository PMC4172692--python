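"""Exon-overlap annotation and flanking-sequence retrieval.

Off-target sites that fall inside coding exons are usually the most
worrying, so each hit is flagged with whether it overlaps an annotated
exon and with the gene id(s) of the overlapping exons. Flanking genomic
sequence around each hit is fetched for designing PCR primers to assay
cleavage at that locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping
from urllib.parse import unquote

from intervaltree import IntervalTree

from .offtargets import OffTargetHit


@dataclass(frozen=True)
class ExonInterval:
    """One exon: 1-based inclusive coordinates after normalization."""

    chrom: str
    start: int
    end: int
    gene_id: str


class AnnotationIntervals:
    """Exon intervals indexed per chromosome for overlap queries."""

    def __init__(self, intervals: list[ExonInterval]):
        self.intervals = intervals
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            if iv.start > iv.end:
                raise ValueError(
                    f"interval start {iv.start} > end {iv.end} on "
                    f"{iv.chrom}"
                )
            # IntervalTree is half-open; store [start, end+1).
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end + 1, iv
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[ExonInterval]:
        """Exons sharing >= 1 base with [start, end] (1-based inclusive)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        found = [hit.data for hit in tree.overlap(start, end + 1)]
        found.sort(key=lambda iv: (iv.start, iv.end, iv.gene_id))
        return found


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = unquote(v.strip())
    return out


def load_annotation(path: str | Path, fmt: str) -> AnnotationIntervals:
    """Read exon intervals from a BED (3-6 column) or GFF3 file.

    BED coordinates (0-based half-open) are converted to 1-based
    inclusive; the name column, if present, supplies the gene id. From
    GFF3 only rows of type ``exon`` are retained, with the gene id taken
    from the ``gene_id``, ``gene``, ``Parent`` or ``ID`` attribute (first
    present).
    """
    fmt = fmt.lower()
    if fmt not in ("bed", "gff3", "gff"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    intervals: list[ExonInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if fmt == "bed" and line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 3:
                        raise ValueError("fewer than 3 columns")
                    chrom = fields[0]
                    start = int(fields[1]) + 1
                    end = int(fields[2])
                    gene = fields[3] if len(fields) > 3 else ""
                else:
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 columns")
                    if fields[2].lower() != "exon":
                        continue
                    chrom = fields[0]
                    start = int(fields[3])
                    end = int(fields[4])
                    attrs = _parse_gff3_attributes(fields[8])
                    gene = (
                        attrs.get("gene_id")
                        or attrs.get("gene")
                        or attrs.get("Parent")
                        or attrs.get("ID")
                        or ""
                    )
                if start > end:
                    raise ValueError(f"start {start} > end {end}")
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            intervals.append(ExonInterval(chrom, start, end, gene))
    return AnnotationIntervals(intervals)


def annotate_hits(
    hits: list[OffTargetHit], ann: AnnotationIntervals
) -> list[OffTargetHit]:
    """Set ``in_exon`` and ``gene_id`` on each hit (in place).

    A hit is exonic iff >= 1 base of its protospacer span overlaps an
    exon on the same chromosome, regardless of strand; ``gene_id`` is the
    comma-joined sorted set of overlapping gene ids.
    """
    for h in hits:
        exons = ann.overlapping(h.chrom, h.start, h.end)
        h.in_exon = bool(exons)
        genes = sorted({e.gene_id for e in exons if e.gene_id})
        h.gene_id = ",".join(genes) if genes else None
    return hits


def fetch_flanks(
    genome: Mapping[str, str],
    hit: OffTargetHit,
    upstream: int = 200,
    downstream: int = 200,
) -> str:
    """Plus-strand sequence [start-upstream, end+downstream], clipped.

    Flanks are always reported in plus-strand orientation regardless of
    hit strand (primers are designed on genomic coordinates); the window
    is clipped at the chromosome ends.
    """
    if hit.chrom not in genome:
        raise KeyError(f"chromosome {hit.chrom!r} not in genome")
    seq = str(genome[hit.chrom]).upper()
    lo = max(1, hit.start - upstream)
    hi = min(len(seq), hit.end + downstream)
    return seq[lo - 1 : hi]
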