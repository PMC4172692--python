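"""Guide discovery, pairing geometry and restriction-site overlap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guidescout import (
    DesignParameters,
    GuideCandidate,
    filter_by_re_overlap,
    find_guides,
    load_precomputed_guides,
    pair_guides,
    parse_re_patterns,
    reverse_complement,
)

seq_strategy = st.text(alphabet="ACGT", min_size=0, max_size=120)


def test_too_short_input_yields_nothing(params):
    assert find_guides("x", "ACGT", params) == []


def test_single_forward_guide(params):
    guides = find_guides("x", "G" * 20 + "TGG", params)
    assert len(guides) == 1
    (g,) = guides
    assert (g.strand, g.start, g.end, g.pam) == ("f", 1, 20, "TGG")
    assert g.protospacer == "G" * 20
    assert g.name == "gRNAf1_x"


def test_reverse_guide_coordinates_roundtrip(params):
    # plant a site on the minus strand: plus carries rc(protospacer+PAM)
    proto = "ACGTACGTACGTACGTACGA"
    record = "TT" + reverse_complement(proto + "TGG") + "TT"
    guides = [g for g in find_guides("x", record, params)
              if g.strand == "r"]
    assert len(guides) == 1
    (g,) = guides
    extracted = reverse_complement(record[g.start - 1 : g.end])
    assert extracted == g.protospacer == proto
    # PAM immediately 3' on the guide strand = plus-strand left of start
    assert reverse_complement(record[g.start - 4 : g.start - 1]) == "TGG"


def test_grna_pattern_filters_candidates(params):
    record = "G" * 20 + "TGG" + "A" * 5
    with_g = DesignParameters(
        find_paired_only=False, find_RE_cut_only=False, gRNA_pattern="^G"
    )
    with_a = DesignParameters(
        find_paired_only=False, find_RE_cut_only=False, gRNA_pattern="^A"
    )
    assert len(find_guides("x", record, with_g)) >= 1
    assert all(g.protospacer.startswith("A")
               for g in find_guides("x", record, with_a))


@settings(derandomize=True, max_examples=40)
@given(seq_strategy)
def test_strand_symmetry(seq):
    """Discovery on the reverse complement mirrors strands and sites."""
    params = DesignParameters(
        find_paired_only=False, find_RE_cut_only=False
    )
    fwd = find_guides("x", seq, params)
    rev = find_guides("x", reverse_complement(seq), params)
    flip = {"f": "r", "r": "f"}
    assert sorted((g.protospacer, g.pam, flip[g.strand]) for g in fwd) == \
        sorted((g.protospacer, g.pam, g.strand) for g in rev)
    n = len(seq)
    mirrored = sorted((n - g.end + 1, n - g.start + 1, flip[g.strand])
                      for g in fwd)
    assert mirrored == sorted((g.start, g.end, g.strand) for g in rev)


@settings(derandomize=True, max_examples=40)
@given(seq_strategy)
def test_guides_reextract_from_input(seq):
    params = DesignParameters(
        find_paired_only=False, find_RE_cut_only=False
    )
    for g in find_guides("x", seq, params):
        window = seq[g.start - 1 : g.end]
        if g.strand == "r":
            window = reverse_complement(window)
        assert window == g.protospacer


@settings(derandomize=True, max_examples=40)
@given(seq_strategy)
def test_forward_guide_count_matches_direct_pam_scan(seq):
    """Number of f-strand guides == number of PAM-bearing windows."""
    params = DesignParameters(
        find_paired_only=False, find_RE_cut_only=False
    )
    n_expected = sum(
        1
        for i in range(max(0, len(seq) - 22))
        if seq[i + 21 : i + 23] == "GG"
    )
    n_found = sum(
        1 for g in find_guides("x", seq, params) if g.strand == "f"
    )
    assert n_found == n_expected


# --- pairing ---------------------------------------------------------------


def _mk(name, strand, start, end):
    return GuideCandidate(
        name=name, source_id="x", protospacer="A" * 20, pam="TGG",
        strand=strand, start=start, end=end,
    )


def test_pair_guides_empty(params):
    assert pair_guides([], params) == []


def test_pair_gap_counts_bases_between_footprints(params):
    r = _mk("r1", "r", 11, 30)
    f = _mk("f1", "f", 36, 55)
    (pair,) = pair_guides([r, f], params)
    assert pair.gap == 5
    assert pair.reverse_guide is r and pair.forward_guide is f


def test_pair_gap_out_of_range(params):
    r = _mk("r1", "r", 11, 30)
    f = _mk("f1", "f", 60, 79)   # gap 29 > max_gap 20
    assert pair_guides([r, f], params) == []


def test_pair_wrong_orientation_rejected(params):
    f = _mk("f1", "f", 11, 30)
    r = _mk("r1", "r", 36, 55)   # PAM-in orientation: f before r
    assert pair_guides([f, r], params) == []


def test_pair_guides_equals_bruteforce_on_random_layouts(rng, params):
    for _ in range(20):
        guides = []
        for k in range(rng.integers(2, 10)):
            start = int(rng.integers(1, 300))
            strand = "r" if rng.integers(0, 2) else "f"
            guides.append(_mk(f"g{k}", strand, start, start + 19))
        got = {
            (p.reverse_guide.name, p.forward_guide.name, p.gap)
            for p in pair_guides(guides, params)
        }
        expected = set()
        for a in guides:
            for b in guides:
                if a.strand == "r" and b.strand == "f":
                    between = b.start - a.end - 1
                    if a.end < b.start and 0 <= between <= 20:
                        expected.add((a.name, b.name, between))
        assert got == expected


# --- restriction patterns --------------------------------------------------


def test_parse_re_patterns_filters_short_sites(tmp_path):
    f = tmp_path / "re.txt"
    f.write_text("# comment\nEcoRI\tGGATCC\nXYZ\tGGCC\n")
    pats = parse_re_patterns(f, 6)
    assert [(p.enzyme, p.site) for p in pats] == [("EcoRI", "GGATCC")]


def test_parse_re_patterns_errors_name_line(tmp_path):
    f = tmp_path / "re.txt"
    f.write_text("EcoRI GGATCC\n")       # space, not tab
    with pytest.raises(ValueError, match="line 1"):
        parse_re_patterns(f, 6)
    f.write_text("Bad\tGGQTCC\n")
    with pytest.raises(ValueError, match="line 1"):
        parse_re_patterns(f, 6)


def test_re_overlap_retains_guide_with_site_at_cleavage(params):
    # protospacer positions 15-20 spell GGATCC; cleavage positions {17,18}
    proto = "A" * 14 + "GGATCC"
    record = proto + "TGG" + "AAAA"
    (g,) = [x for x in find_guides("x", record, params)
            if x.strand == "f" and x.start == 1]
    from guidescout import REPattern
    kept = filter_by_re_overlap(
        [g], [REPattern("BamHI", "GGATCC")], params, record
    )
    assert len(kept) == 1
    _, overlaps = kept[0]
    assert overlaps[0].enzyme == "BamHI"
    assert overlaps[0].match_start == 15
    assert overlaps[0].matched_window == "GGATCC"


def test_re_overlap_drops_guide_without_cleavage_overlap(params):
    # GGATCC at protospacer positions 1-6 does not reach {17,18}
    proto = "GGATCC" + "A" * 14
    record = proto + "TGG" + "AAAA"
    (g,) = [x for x in find_guides("x", record, params)
            if x.strand == "f" and x.start == 1]
    from guidescout import REPattern
    assert filter_by_re_overlap(
        [g], [REPattern("BamHI", "GGATCC")], params, record
    ) == []


def test_re_overlap_empty_pattern_list_drops_all(params):
    record = "A" * 20 + "TGG"
    guides = find_guides("x", record, params)
    assert filter_by_re_overlap(guides, [], params, record) == []


def test_re_overlap_matches_reverse_complement_site(params):
    # GAATTC is palindromic; use a non-palindromic site GACGTC? that is
    # palindromic too — use GGTCTC (BsaI), rc GAGACC, placed as the rc.
    proto = "A" * 14 + "GAGACC"
    record = proto + "TGG" + "AAAA"
    (g,) = [x for x in find_guides("x", record, params)
            if x.strand == "f" and x.start == 1]
    from guidescout import REPattern
    kept = filter_by_re_overlap(
        [g], [REPattern("BsaI", "GGTCTC")], params, record
    )
    assert len(kept) == 1


# --- precomputed guides ----------------------------------------------------


def test_load_precomputed_guides(tmp_path, params):
    f = tmp_path / "g.fa"
    f.write_text(">g1\n" + "A" * 20 + "TGG\n")
    (g,) = load_precomputed_guides(f, params)
    assert g.pam == "TGG" and g.start is None

    f.write_text("")
    assert load_precomputed_guides(f, params) == []

    f.write_text(">bad\n" + "A" * 15 + "\n")
    with pytest.raises(ValueError, match="bad"):
        load_precomputed_guides(f, params)

    f.write_text(">bare\n" + "C" * 20 + "\n")
    with pytest.warns(UserWarning):
        (g,) = load_precomputed_guides(f, params)
    assert g.pam == "NGG"
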