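"""Independent reference implementations used only as test oracles.

Deliberately naive and written without reference to the package
internals: plain character-by-character scans and a spreadsheet-style
score formula, so agreement with the vectorized engine is meaningful.
"""

from __future__ import annotations

from itertools import combinations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

ORACLE_WEIGHTS = [
    0, 0, 0.014, 0, 0, 0.395, 0.317, 0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583,
]


def oracle_revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s.upper()))


def oracle_score(mm: list[int], weights=None) -> float:
    """Spreadsheet-style cleavage score: cell-by-cell arithmetic."""
    weights = ORACLE_WEIGHTS if weights is None else weights
    if len(mm) == 0:
        return 100.0
    product = 100.0
    for p in mm:
        product = product * (1.0 - weights[p - 1])
    if len(mm) == 1:
        return product
    pair_dists = [abs(a - b) for a, b in combinations(mm, 2)]
    mean_d = sum(pair_dists) / len(pair_dists)
    distance_factor = 1.0 / (((19.0 - mean_d) / 19.0) * 4.0 + 1.0)
    count_factor = 1.0 / (len(mm) ** 2)
    return product * distance_factor * count_factor


#: allowed base sets per PAM position for the two patterns under test
PAM_SETS = {
    "NGG$": ({"A", "C", "G", "T"}, {"G"}, {"G"}),
    "N[A|G]G$": ({"A", "C", "G", "T"}, {"A", "G"}, {"G"}),
}


def oracle_scan(
    guide: str,
    genome: dict[str, str],
    max_mm: int,
    pam_pattern: str = "N[A|G]G$",
) -> list[tuple[str, int, str, tuple[int, ...], str]]:
    """Naive exhaustive scan: (chrom, start1, strand, mm positions, pam).

    Coordinates are 1-based inclusive protospacer starts on the plus
    strand, like the engine reports them.
    """
    pam_sets = PAM_SETS[pam_pattern]
    gl, ps = len(guide), len(pam_sets)
    out = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        L = len(seq)
        for i in range(L - gl - ps + 1):
            mm = []
            for p in range(gl):
                c = seq[i + p]
                if c not in "ACGT" or c != guide[p]:
                    mm.append(p + 1)
                    if len(mm) > max_mm:
                        break
            if len(mm) > max_mm:
                continue
            pam = seq[i + gl : i + gl + ps]
            if all(c in s for c, s in zip(pam, pam_sets)):
                out.append((chrom, i + 1, "+", tuple(mm), pam))
        rc = oracle_revcomp(seq)
        for j in range(L - gl - ps + 1):
            mm = []
            for p in range(gl):
                c = rc[j + p]
                if c not in "ACGT" or c != guide[p]:
                    mm.append(p + 1)
                    if len(mm) > max_mm:
                        break
            if len(mm) > max_mm:
                continue
            pam = rc[j + gl : j + gl + ps]
            if all(c in s for c, s in zip(pam, pam_sets)):
                out.append((chrom, L - j - gl + 1, "-", tuple(mm), pam))
    return out


def oracle_overlaps(
    hits: list[tuple[str, int, int]],
    exons: list[tuple[str, int, int, str]],
) -> list[tuple[bool, str]]:
    """Quadratic all-pairs exon overlap: (in_exon, joined gene ids)."""
    out = []
    for chrom, start, end in hits:
        genes = sorted({
            g for (c, s, e, g) in exons
            if c == chrom and s <= end and e >= start and g
        })
        hit_any = any(
            c == chrom and s <= end and e >= start
            for (c, s, e, g) in exons
        )
        out.append((hit_any, ",".join(genes)))
    return out
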