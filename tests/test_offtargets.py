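"""Cleavage scoring, genome scanning, ranking and summarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guidescout import (
    DesignParameters,
    GuideCandidate,
    OffTargetHit,
    ScoringScheme,
    filter_and_rank,
    make_fixture,
    mismatch_positions,
    random_genome,
    random_guide,
    reverse_complement,
    score_offtarget,
    search_offtargets,
    summarize_guide,
)

from oracles import oracle_scan, oracle_score

mm_sets = st.sets(st.integers(1, 20), min_size=0, max_size=4)


def _guide(proto, name="g"):
    return GuideCandidate(
        name=name, source_id="src", protospacer=proto, pam="NGG", strand="f"
    )


# --- mismatch positions ----------------------------------------------------


@pytest.mark.parametrize(
    "guide,site,expected",
    [
        ("A" * 20, "A" * 20, []),
        ("A" * 20, "A" * 19 + "G", [20]),
        ("A" * 20, "G" + "A" * 18 + "G", [1, 20]),
        ("A" * 20, "A" * 9 + "N" + "A" * 10, [10]),  # unknown base
    ],
)
def test_mismatch_positions(guide, site, expected):
    assert mismatch_positions(guide, site) == expected


def test_mismatch_positions_length_error():
    with pytest.raises(ValueError):
        mismatch_positions("A" * 20, "A" * 19)


# --- scoring ---------------------------------------------------------------


def test_score_anchor_values():
    assert score_offtarget([]) == 100.0
    assert score_offtarget([20]) == pytest.approx(41.7, abs=1e-12)
    assert score_offtarget([1, 20]) == pytest.approx(10.425, abs=1e-12)
    assert score_offtarget([19, 20]) == pytest.approx(
        oracle_score([19, 20]), abs=1e-12
    )
    assert 0.68 < score_offtarget([19, 20]) < 0.69


def test_score_errors():
    with pytest.raises(ValueError):
        score_offtarget([0])
    with pytest.raises(ValueError):
        score_offtarget([21])
    with pytest.raises(ValueError):
        score_offtarget([5, 5])


@settings(derandomize=True, max_examples=300)
@given(mm_sets)
def test_score_matches_spreadsheet_oracle(mm):
    mm = sorted(mm)
    assert score_offtarget(mm) == pytest.approx(
        oracle_score(mm), abs=1e-9
    )
    assert 0.0 <= score_offtarget(mm) <= 100.0


@settings(derandomize=True, max_examples=200)
@given(mm_sets.filter(lambda s: len(s) >= 1))
def test_score_below_100_when_penalties_apply(mm):
    mm = sorted(mm)
    w = ScoringScheme().weights
    if len(mm) >= 2 or w[mm[0] - 1] > 0:
        assert score_offtarget(mm) < 100.0
    else:
        assert score_offtarget(mm) == 100.0


def test_score_weight_monotonicity():
    base = ScoringScheme()
    for p in (3, 10, 20):
        bumped = list(base.weights)
        bumped[p - 1] = min(1.0, bumped[p - 1] + 0.1)
        higher = ScoringScheme(weights=tuple(bumped))
        for mm in ([p], [p, 1], [p, 7, 13]):
            if base.score(sorted(mm)) > 0:
                assert higher.score(sorted(mm)) < base.score(sorted(mm))


def test_custom_guide_size_scales_distance_constant():
    scheme = ScoringScheme.for_guide_size(10, [0.1] * 10)
    assert scheme.distance_constant == 9.0
    with pytest.raises(ValueError):
        ScoringScheme.for_guide_size(18)   # no default weights for 18


# --- search ----------------------------------------------------------------


def test_exact_planted_site_found(params):
    fx = make_fixture(11, 10000, [("ACGTTGCAACGTTGCAACGT", (), "TGG")])
    (truth,) = fx.truth
    hits = search_offtargets(_guide(truth.guide), fx.genome, params)
    assert len(hits) == 1
    (h,) = hits
    assert (h.start, h.strand, h.mismatch_positions, h.score) == (
        truth.start, "+", (), 100.0
    )


def test_planted_mismatch_site_and_pam_variant(params):
    fx = make_fixture(
        12, 20000,
        [("ACGTTGCAACGTTGCAACGT", (), "TGG"),
         ("ACGTTGCAACGTTGCAACGT", (5, 12), "TAG")],
    )
    hits = search_offtargets(
        _guide("ACGTTGCAACGTTGCAACGT"), fx.genome, params
    )
    by_mm = {h.mismatch_positions: h for h in hits}
    assert set(by_mm) == {(), (5, 12)}
    assert by_mm[(5, 12)].pam_seq == "TAG"
    assert by_mm[(5, 12)].score == pytest.approx(
        oracle_score([5, 12]), abs=1e-9
    )


def test_minus_strand_site_coordinates(params):
    proto = "ACGTTGCAACGTTGCAACGT"
    genome = {"c": "TT" + reverse_complement(proto + "TGG") + "TT"}
    hits = search_offtargets(_guide(proto), genome, params)
    minus = [h for h in hits if h.strand == "-"]
    assert len(minus) == 1
    (h,) = minus
    assert h.site_seq == proto
    assert reverse_complement(genome["c"][h.start - 1 : h.end]) == proto


def test_chrom_selection(params):
    import dataclasses
    proto = "ACGTTGCAACGTTGCAACGT"
    genome = {
        "c1": proto + "TGG",
        "c2": proto + "TGG",
    }
    p_all = params
    assert len(search_offtargets(_guide(proto), genome, p_all)) == 2
    p_c2 = dataclasses.replace(params, chrom_to_search="c2")
    assert {h.chrom for h in search_offtargets(_guide(proto), genome, p_c2)} \
        == {"c2"}
    p_skip = dataclasses.replace(params, chrom_to_search="")
    assert search_offtargets(_guide(proto), genome, p_skip) == []
    p_missing = dataclasses.replace(params, chrom_to_search="c3")
    with pytest.raises(KeyError, match="c1"):
        search_offtargets(_guide(proto), genome, p_missing)


def test_assembly_gap_does_not_match(params):
    proto = "ACGTTGCAACGTTGCAACGT"
    genome = {"c": "N" * 20 + "TGG"}
    p = DesignParameters(
        find_paired_only=False, find_RE_cut_only=False, max_mismatch=4
    )
    assert search_offtargets(_guide(proto), genome, p) == []
    # N in the PAM never satisfies the pattern either
    genome = {"c": proto + "TNG"}
    assert search_offtargets(_guide(proto), genome, p) == []


def test_search_matches_naive_oracle_on_random_genomes(rng):
    """Vectorized scan == character-by-character oracle, with planted sites."""
    for trial in range(4):
        genome = {"chr1": random_genome(rng, 8000)}
        guide = random_guide(rng)
        # plant one 2-mismatch site so the comparison is not vacuous
        from guidescout.synthetic import mutate
        site = mutate(rng, guide, (3, 15)) + "TGG"
        pos = int(rng.integers(0, 8000 - 23))
        s = genome["chr1"]
        genome["chr1"] = s[:pos] + site + s[pos + 23:]
        for max_mm in (0, 2, 4):
            for pam in ("NGG$", "N[A|G]G$"):
                p = DesignParameters(
                    find_paired_only=False, find_RE_cut_only=False,
                    max_mismatch=max_mm, PAM_pattern=pam,
                )
                got = {
                    (h.chrom, h.start, h.strand, h.mismatch_positions,
                     h.pam_seq)
                    for h in search_offtargets(_guide(guide), genome, p)
                }
                expected = set(oracle_scan(guide, genome, max_mm, pam))
                assert got == expected


def test_search_determinism(params, rng):
    genome = {"chr1": random_genome(rng, 5000)}
    g = _guide(random_guide(rng))
    h1 = search_offtargets(g, genome, params)
    h2 = search_offtargets(g, genome, params)
    assert [vars(a) for a in h1] == [vars(b) for b in h2]


# --- ranking and summaries -------------------------------------------------


def _hit(score, chrom="c", start=1, n_mm=1, name="g"):
    return OffTargetHit(
        guide_name=name, chrom=chrom, start=start, end=start + 19,
        strand="+", site_seq="A" * 20, pam_seq="TGG",
        mismatch_positions=(20,) * 0 if n_mm == 0 else tuple(range(1, n_mm + 1)),
        n_mismatch=n_mm, score=score,
    )


def test_filter_and_rank_threshold_and_order(params):
    hits = [_hit(100, start=5), _hit(0.4, start=9), _hit(60, start=2)]
    ranked = filter_and_rank(hits, params)
    assert [h.score for h in ranked] == [100, 60]


def test_filter_and_rank_topn():
    p = DesignParameters(
        find_paired_only=False, find_RE_cut_only=False, topN=1
    )
    assert [h.score for h in filter_and_rank([_hit(100), _hit(60)], p)] \
        == [100]


def test_filter_and_rank_ties_by_locus(params):
    a = _hit(50, chrom="c2", start=7)
    b = _hit(50, chrom="c1", start=9)
    c = _hit(50, chrom="c1", start=3)
    assert filter_and_rank([a, b, c], params) == [c, b, a]


def test_summary_excludes_exact_on_target(params):
    hits = [_hit(100, n_mm=0, start=1), _hit(10, start=30),
            _hit(5, start=60), _hit(2, start=90)]
    s = summarize_guide(hits, params)
    assert s.top5_offtarget_total == pytest.approx(17.0)
    assert s.top10_offtarget_total == pytest.approx(17.0)
    assert s.on_target is hits[0]
    assert s.n_hits == 4


def test_summary_empty():
    s = summarize_guide([], DesignParameters())
    assert (s.top5_offtarget_total, s.top10_offtarget_total) == (0.0, 0.0)
    assert s.on_target is None


def test_summary_counts_top5_vs_top10(params):
    hits = [_hit(1.0, start=10 * i + 1) for i in range(12)]
    s = summarize_guide(hits, params)
    assert s.top5_offtarget_total == pytest.approx(5.0)
    assert s.top10_offtarget_total == pytest.approx(10.0)


def test_summary_exclusion_conventions(params):
    # no exact hit: the top-scoring hit is the putative on-target
    hits = [_hit(41.7, start=1), _hit(10, start=30), _hit(5, start=60)]
    default = summarize_guide(hits, params)
    assert default.on_target is hits[0]
    assert default.top5_offtarget_total == pytest.approx(56.7)
    excl = summarize_guide(hits, params, on_target_exclusion="designated")
    assert excl.top5_offtarget_total == pytest.approx(15.0)
    incl = summarize_guide(hits, params, on_target_exclusion="none")
    assert incl.top5_offtarget_total == pytest.approx(56.7)
    with pytest.raises(ValueError):
        summarize_guide(hits, params, on_target_exclusion="bogus")


def test_summary_top5_le_top10(rng, params):
    for _ in range(20):
        hits = [_hit(float(s), start=int(i) * 25 + 1)
                for i, s in enumerate(rng.uniform(0, 100, size=12))]
        s = summarize_guide(hits, params)
        assert s.top5_offtarget_total <= s.top10_offtarget_total + 1e-12
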