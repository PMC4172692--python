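"""Nucleotide-sequence primitives.

DNA only: the accepted alphabet is {A, C, G, T, N} (T stands for U when a
guide RNA is written as DNA). Degenerate IUPAC codes are supported in
*patterns* (PAM consensus, restriction-enzyme recognition sites), never in
the sequences being searched. An N in a searched window is treated as an
unknown base and never satisfies a pattern symbol — not even pattern N —
so assembly gaps cannot produce spurious matches.
"""

from __future__ import annotations

import re

SEQ_ALPHABET = frozenset("ACGTN")

# IUPAC degenerate nucleotide codes -> the set of concrete bases each matches.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class AlphabetError(ValueError):
    """A sequence contains a character outside {A,C,G,T,N}."""


class PatternError(ValueError):
    """A degenerate pattern or guide-pattern expression is malformed."""


def normalize(seq: str) -> str:
    """Uppercase ``seq`` and validate it over {A,C,G,T,N}.

    Soft-masked (lowercase) input is accepted and searched like any other
    sequence; masking carries no semantics here.
    """
    s = seq.upper()
    for i, ch in enumerate(s):
        if ch not in SEQ_ALPHABET:
            raise AlphabetError(
                f"invalid character {ch!r} at position {i + 1} "
                "(expected A, C, G, T or N)"
            )
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; the complement of N is N."""
    s = normalize(seq)
    return s.translate(_COMPLEMENT)[::-1]


def reverse_complement_iupac(pattern: str) -> str:
    """Reverse complement of a degenerate pattern (R<->Y, K<->M, ...)."""
    p = pattern.upper()
    for i, ch in enumerate(p):
        if ch not in IUPAC_SETS:
            raise PatternError(
                f"invalid IUPAC symbol {ch!r} at position {i + 1}"
            )
    return p.translate(_IUPAC_COMPLEMENT)[::-1]


def validate_iupac(pattern: str) -> str:
    """Uppercase and validate a degenerate pattern over the 15 IUPAC codes."""
    p = pattern.upper()
    for i, ch in enumerate(p):
        if ch not in IUPAC_SETS:
            raise PatternError(
                f"invalid IUPAC symbol {ch!r} at position {i + 1}"
            )
    return p


def iupac_match(pattern: str, window: str) -> bool:
    """True iff each window base is in the pattern symbol's base set.

    The pattern may use any of the 15 IUPAC codes; the window must be a
    concrete sequence over {A,C,G,T,N}. A window N matches nothing — an
    unknown base is never evidence for a site.
    """
    p = validate_iupac(pattern)
    w = window.upper()
    if len(p) != len(w):
        raise ValueError(
            f"pattern length {len(p)} != window length {len(w)}"
        )
    for pc, wc in zip(p, w):
        if wc not in SEQ_ALPHABET:
            raise AlphabetError(f"invalid window character {wc!r}")
        if wc == "N" or wc not in IUPAC_SETS[pc]:
            return False
    return True


def compile_iupac_regex(pattern: str) -> re.Pattern[str]:
    """Compile a regex-with-IUPAC-codes string to a plain regex.

    Degenerate letters outside character classes expand to classes
    (``N`` -> ``[ACGT]``); everything inside ``[...]`` and all regex
    metacharacters pass through unchanged. This is the dialect used for
    off-target PAM patterns such as ``N[A|G]G$`` — anchors and negative
    lookahead are available.
    """
    out: list[str] = []
    depth = 0
    for ch in pattern.upper():
        if ch == "[":
            depth += 1
            out.append(ch)
        elif ch == "]":
            depth = max(0, depth - 1)
            out.append(ch)
        elif depth == 0 and ch in "RYSWKMBDHVN":
            out.append("[" + "".join(sorted(IUPAC_SETS[ch])) + "]")
        else:
            out.append(ch)
    try:
        return re.compile("".join(out))
    except re.error as exc:
        raise PatternError(f"malformed pattern {pattern!r}: {exc}") from exc


def guide_pattern_ok(guide: str, pattern: str) -> bool:
    """Does a protospacer (5'->3', PAM excluded) satisfy a guide pattern?

    The pattern is an extended regular expression with ``^``/``$`` anchors
    and lookahead (e.g. ``^G`` to require a 5' guanine for U6 transcription,
    ``^(?:(?!T{5,}).)+$`` to forbid five consecutive Ts which terminate
    Pol III). An empty pattern disables the filter.
    """
    if pattern == "":
        return True
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise PatternError(
            f"malformed guide pattern {pattern!r}: {exc}"
        ) from exc
    return rx.search(guide.upper()) is not None
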