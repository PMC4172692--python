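"""Parameter sets for guide design, off-target search and scoring.

``DesignParameters`` mirrors the knob set of the classic one-call guide
design workflow for S. pyogenes Cas9: a 20-nt protospacer followed by an
NGG PAM, off-target scanning with up to 4 mismatches and tolerance for NAG
PAM variants, paired-nickase spacer geometry, and restriction-site overlap
filtering. ``ScoringScheme`` carries the position-specific mismatch
penalty weights used for cleavage scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .sequence import validate_iupac

#: Experimentally derived per-position mismatch penalties for SpCas9,
#: position 1 = PAM-distal (5') end of the protospacer, position 20 =
#: PAM-proximal. Seed-region (PAM-proximal) mismatches are most penalized.
HSU_WEIGHTS: tuple[float, ...] = (
    0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583,
)


@dataclass(frozen=True)
class ScoringScheme:
    """Position-weighted mismatch penalty scheme for cleavage scoring.

    Parameters
    ----------
    weights
        One penalty in [0, 1] per protospacer position; index 0 is the
        PAM-distal end. Length must equal the protospacer length.
    distance_constant, distance_multiplier
        Constants of the mean-pairwise-distance penalty applied when two
        or more mismatches are present. For a 20-nt protospacer the
        constant is 19 (the maximum possible pairwise distance); a custom
        protospacer length ``L`` should use ``L - 1``.
    """

    weights: tuple[float, ...] = HSU_WEIGHTS
    distance_constant: float = 19.0
    distance_multiplier: float = 4.0

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("weights must be non-empty")
        if any(w < 0.0 or w > 1.0 for w in self.weights):
            raise ValueError("all weights must lie in [0, 1]")

    @classmethod
    def for_guide_size(
        cls, size: int, weights: Sequence[float] | None = None
    ) -> "ScoringScheme":
        """Scheme for a protospacer of ``size`` nt.

        For the canonical 20-nt SpCas9 protospacer the published weight
        vector is used; any other size requires an explicit weight vector
        of matching length, and the distance constant scales to size-1.
        """
        if weights is None:
            if size != len(HSU_WEIGHTS):
                raise ValueError(
                    f"no default weights for protospacer size {size}; "
                    "supply a weight vector of matching length"
                )
            weights = HSU_WEIGHTS
        if len(weights) != size:
            raise ValueError(
                f"weight vector length {len(weights)} != protospacer "
                f"size {size}"
            )
        return cls(weights=tuple(weights), distance_constant=float(size - 1))

    def score(self, mismatch_positions: Sequence[int]) -> float:
        """Predicted relative cleavage score, 0-100.

        A perfect match scores 100. A single mismatch at position ``p``
        (1-based, PAM-distal = 1) scores ``100 * (1 - w_p)``. For n >= 2
        mismatches the per-position factors are multiplied together and
        two aggregate penalties apply: a mean-pairwise-distance factor
        ``1 / (((C - d) / C) * M + 1)`` — clustered mismatches (small mean
        pairwise distance ``d``) are penalized more than spread-out ones —
        and a mismatch-count factor ``1 / n^2``.
        """
        mm = list(mismatch_positions)
        n = len(mm)
        if n == 0:
            return 100.0
        L = len(self.weights)
        seen: set[int] = set()
        for p in mm:
            if not 1 <= p <= L:
                raise ValueError(
                    f"mismatch position {p} out of range [1, {L}]"
                )
            if p in seen:
                raise ValueError(f"duplicate mismatch position {p}")
            seen.add(p)
        score = 100.0
        for p in mm:
            score *= 1.0 - self.weights[p - 1]
        if n >= 2:
            d_mean = sum(
                abs(a - b) for a, b in combinations(mm, 2)
            ) / (n * (n - 1) / 2)
            denom = (
                (self.distance_constant - d_mean)
                / self.distance_constant
            ) * self.distance_multiplier + 1.0
            score *= 1.0 / denom
            score *= 1.0 / (n * n)
        return score


@dataclass
class DesignParameters:
    """Full knob set for guide discovery and off-target analysis.

    Defaults reproduce the canonical SpCas9 design call: 20-nt guides,
    NGG PAM for discovery, N[A|G]G tolerated for off-target sites, at most
    4 mismatches, paired-nickase and restriction-overlap filters available.
    """

    gRNA_size: int = 20
    PAM: str = "NGG"
    PAM_size: int = 3
    PAM_pattern: str = "N[A|G]G$"
    gRNA_pattern: str = ""
    max_mismatch: int = 4
    min_score: float = 0.5          # on the 0-100 score scale
    topN: int = 100
    topN_offtarget_total_score: int = 10
    min_gap: int = 0
    max_gap: int = 20
    find_paired_only: bool = True
    find_RE_cut_only: bool = True
    min_RE_pattern_size: int = 6
    overlap_gRNA_positions: tuple[int, ...] = (17, 18)
    gRNA_name_prefix: str = "gRNA"
    chrom_to_search: str = "all"
    annotate_exon: bool = True
    upstream: int = 200
    downstream: int = 200
    weights: tuple[float, ...] | None = None
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.gRNA_size < 1:
            raise ValueError("gRNA_size must be positive")
        if self.PAM_size < 1:
            raise ValueError("PAM_size must be positive")
        validate_iupac(self.PAM)
        if len(self.PAM) != self.PAM_size:
            raise ValueError(
                f"PAM {self.PAM!r} length != PAM_size {self.PAM_size}"
            )
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.min_gap > self.max_gap:
            raise ValueError("min_gap must be <= max_gap")
        if self.weights is not None:
            self.weights = tuple(self.weights)
        bad = [
            p for p in self.overlap_gRNA_positions
            if not 1 <= p <= self.gRNA_size
        ]
        if bad:
            raise ValueError(
                f"overlap_gRNA_positions {bad} outside [1, {self.gRNA_size}]"
            )
        self.overlap_gRNA_positions = tuple(self.overlap_gRNA_positions)

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme.for_guide_size(self.gRNA_size, self.weights)

    @classmethod
    def compare_defaults(cls, **kwargs) -> "DesignParameters":
        """Defaults of the two-sequence comparison workflow.

        Identical to the off-target analysis defaults except that the
        pairing and restriction-site filters are off — every candidate
        guide in either input is scored against both sequences.
        """
        kwargs.setdefault("find_paired_only", False)
        kwargs.setdefault("find_RE_cut_only", False)
        return cls(**kwargs)


def score_offtarget(
    mismatch_positions: Sequence[int], scheme: ScoringScheme | None = None
) -> float:
    """Convenience wrapper: cleavage score for a sorted mismatch set."""
    return (scheme or ScoringScheme()).score(mismatch_positions)
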