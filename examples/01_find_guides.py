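"""Find candidate Cas9 guides in a sequence and apply the design filters.

Builds a small input containing a handful of NGG-adjacent sites, discovers
guides on both strands, then shows the paired-nickase and restriction-site
filters that narrow the list to the most assayable candidates.
"""

from guidescout import (
    DesignParameters,
    REPattern,
    filter_by_re_overlap,
    find_guides,
    pair_guides,
)

# A 100-bp input. PAMs: a TGG on the plus strand, a CC (minus-strand PAM)
# downstream of it in PAM-out orientation, and a BamHI site (GGATCC)
# crossing the first guide's cleavage position.
record = (
    "TTATAT"
    + "ATATTATAATTAATGGATCC" + "TGG"       # guide 1: GGATCC at pos 15-20
    + "ATTATAATTA"
    + "CCT" + "TAATATTATAATATTATTAA"       # CC licenses a reverse guide
    + "ATATTATATTTATATATATTATATATATTATATATATA"
)

params = DesignParameters(find_paired_only=False, find_RE_cut_only=False)
guides = find_guides("demo", record, params)
print(f"{len(guides)} candidate guides:")
for g in guides:
    print(f"  {g.name:12s} strand={g.strand} {g.start:3d}-{g.end:<3d} "
          f"{g.protospacer} PAM={g.pam}")

# Paired-nickase geometry: a reverse guide 5' of a forward guide (PAM-out)
# separated by 0-20 bp. This layout has the guides in the wrong order, so
# no pair survives — exactly what the filter is for.
pairs = pair_guides(guides, params)
print(f"\nPAM-out pairs with gap in [0, 20]: {len(pairs)}")

# Restriction-site overlap: keep guides whose cleavage point (between
# protospacer positions 17 and 18, 3 bp from the PAM) falls inside an
# enzyme recognition site, enabling an RFLP cleavage assay.
kept = filter_by_re_overlap(
    guides, [REPattern("BamHI", "GGATCC")], params, record
)
print(f"guides with a BamHI site at the cleavage position: {len(kept)}")
for g, overlaps in kept:
    for o in overlaps:
        print(f"  {g.name}: {o.enzyme} site {o.matched_window} "
              f"at input position {o.match_start}")
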