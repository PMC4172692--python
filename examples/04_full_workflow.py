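"""The one-call workflow: input FASTA + genome FASTA -> report files.

Writes a fixture genome and input to disk, runs the full pipeline
(discovery, genome scan, scoring, ranking, summarization, flank
retrieval, report writing), and shows the files a bench scientist would
open. The same run is available from the shell:

    guidescout offtarget input.fa --genome genome.fa --outdir out \
        --no-paired-only --no-re-cut-only
"""

import tempfile
from pathlib import Path

from guidescout import (
    DesignParameters,
    RunConfig,
    make_fixture,
    run_offtarget_analysis,
)

work = Path(tempfile.mkdtemp(prefix="guidescout_demo_"))
fx = make_fixture(
    11, 20_000,
    [("GCATTGCAACGTTGACATGA", (), "TGG"),
     ("GCATTGCAACGTTGACATGA", (5, 12), "TAG")],
)
genome_fa, input_fa, truth_tsv = fx.write(work)

report = run_offtarget_analysis(RunConfig(
    input_path=input_fa,
    genome_path=genome_fa,
    outdir=work / "out",
    params=DesignParameters(find_paired_only=False, find_RE_cut_only=False),
))

for label, path in [
    ("per-guide summary  ", report.summary_path),
    ("off-target table   ", report.offtarget_path),
    ("RE-site details    ", report.re_details_path),
    ("paired spacers     ", report.paired_path),
]:
    n_rows = len(path.read_text().splitlines()) - 1
    print(f"{label}{path.name}: {n_rows} rows")
print(f"GenBank exports    {[p.name for p in report.genbank_paths]}")
print(f"guide FASTA        {report.fasta_path.name}")

print("\n--- Summary.tsv ---")
print(report.summary_path.read_text())
print("(reports live under", work, "- inspect or delete at will)")
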