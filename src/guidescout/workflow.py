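"""End-to-end workflows: full off-target analysis and two-sequence comparison.

``run_offtarget_analysis`` chains the whole design pipeline — guide
discovery, guide-pattern / paired-nickase / restriction-overlap filters,
per-guide genome scan, scoring, ranking, summarization, exon annotation
and flank retrieval — and writes the four tab-delimited reports plus
GenBank/FASTA guide exports. ``run_compare2`` runs the two-sequence
comparison and writes its table and exports. Stage counts are logged to
stderr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from Bio import SeqIO

from .annotate import annotate_hits, fetch_flanks, load_annotation
from .compare import compare_two_sequences
from .discovery import (
    GuideCandidate,
    filter_by_re_overlap,
    find_guides,
    load_precomputed_guides,
    pair_guides,
    parse_re_patterns,
)
from .offtargets import (
    GuideSummary,
    OffTargetHit,
    filter_and_rank,
    search_offtargets,
    summarize_guide,
)
from .params import DesignParameters
from .reports import (
    ReportSet,
    write_comparison_table,
    write_genbank,
    write_guides_fasta,
    write_reports,
)

log = logging.getLogger("guidescout")


@dataclass
class RunConfig:
    """Paths + parameters for one workflow run."""

    input_path: str | Path
    outdir: str | Path
    genome_path: str | Path | None = None
    input2_path: str | Path | None = None
    annotation_path: str | Path | None = None
    annotation_format: str = "bed"
    re_pattern_path: str | Path | None = None
    find_gRNAs: bool = True          # False: input FASTA holds guides already
    params: DesignParameters = field(default_factory=DesignParameters)
    on_target_exclusion: str = "exact"
    fetch_sequence: bool = True
    legacy_names: bool = False


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA genome into a name -> sequence dict.

    Genomes at the scale this tool is pointed at (targeted loci, small
    model genomes, fixture genomes) fit comfortably in memory; for
    chromosome-scale work pass a ``pyfaidx.Fasta``-backed mapping to the
    engine functions directly.
    """
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def run_offtarget_analysis(config: RunConfig) -> ReportSet:
    """The one-call design workflow; returns the written report set."""
    p = config.params
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(config.input_path), "fasta")
    }
    guides: list[GuideCandidate] = []
    by_source: dict[str, list[GuideCandidate]] = {}
    if config.find_gRNAs:
        for rid, seq in records.items():
            found = find_guides(rid, seq, p)
            by_source[rid] = found
            guides.extend(found)
    else:
        guides = load_precomputed_guides(config.input_path, p)
    log.info("discovered %d candidate guides", len(guides))

    pairs = []
    if p.find_paired_only and config.find_gRNAs:
        kept: list[GuideCandidate] = []
        for rid in by_source:
            rec_pairs = pair_guides(by_source[rid], p)
            pairs.extend(rec_pairs)
            paired_names = {g.name for pr in rec_pairs
                            for g in (pr.reverse_guide, pr.forward_guide)}
            kept.extend(g for g in by_source[rid] if g.name in paired_names)
        guides = kept
        log.info("paired filter: %d guides in %d pairs", len(guides),
                 len(pairs))

    re_overlaps = []
    if p.find_RE_cut_only and config.find_gRNAs:
        if config.re_pattern_path is None:
            patterns = []
        else:
            patterns = parse_re_patterns(
                config.re_pattern_path, p.min_RE_pattern_size
            )
        kept = []
        for rid in by_source:
            in_rec = [g for g in guides if g.source_id == rid]
            for g, overlaps in filter_by_re_overlap(
                in_rec, patterns, p, records[rid]
            ):
                kept.append(g)
                re_overlaps.extend(overlaps)
        guides = kept
        log.info("restriction-overlap filter: %d guides", len(guides))

    if not guides:
        log.warning("no guides survive the filters; writing empty reports")

    hits: list[OffTargetHit] = []
    summaries: list[GuideSummary] = []
    if p.chrom_to_search != "" and config.genome_path is not None:
        genome = load_genome(config.genome_path)
        ann = None
        if p.annotate_exon and config.annotation_path is not None:
            ann = load_annotation(
                config.annotation_path, config.annotation_format
            )
        for g in guides:
            g_hits = filter_and_rank(search_offtargets(g, genome, p), p)
            summaries.append(
                summarize_guide(g_hits, p, config.on_target_exclusion)
            )
            summaries[-1].guide_name = g.name
            if ann is not None:
                annotate_hits(g_hits, ann)
            if config.fetch_sequence:
                for h in g_hits:
                    h.flank_seq = fetch_flanks(
                        genome, h, p.upstream, p.downstream
                    )
            hits.extend(g_hits)
        log.info("off-target search: %d ranked hits for %d guides",
                 len(hits), len(guides))
    else:
        log.info("off-target search skipped (no genome or chromToSearch='')")

    report = write_reports(
        guides, pairs, re_overlaps, hits, summaries, outdir,
        overwrite=p.overwrite, legacy_names=config.legacy_names,
    )
    if config.find_gRNAs:
        for rid, seq in records.items():
            in_rec = [g for g in guides if g.source_id == rid]
            gb = outdir / f"{rid}_guides.gb"
            write_genbank(rid, seq, in_rec, gb, overwrite=p.overwrite)
            report.genbank_paths.append(gb)
    report.fasta_path = write_guides_fasta(
        guides, outdir / "guides.fa", overwrite=p.overwrite
    )
    return report


def run_compare2(config: RunConfig) -> Path:
    """Two-sequence comparison; returns the path of the written table."""
    if config.input2_path is None:
        raise ValueError("run_compare2 requires input2_path")
    p = config.params
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = compare_two_sequences(
        config.input_path, config.input2_path, p
    )
    log.info("compared %d guides across the two inputs", len(records))
    table = write_comparison_table(
        records, outdir / "scoresFor2InputSequences.tsv",
        overwrite=p.overwrite,
    )
    for path in (config.input_path, config.input2_path):
        rec = next(SeqIO.parse(str(path), "fasta"))
        seq = str(rec.seq).upper()
        in_rec = find_guides(rec.id, seq, p)
        write_genbank(
            rec.id, seq, in_rec, outdir / f"{rec.id}_guides.gb",
            overwrite=p.overwrite,
        )
        write_guides_fasta(
            in_rec, outdir / f"{rec.id}_guides.fa", overwrite=p.overwrite
        )
    return table
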