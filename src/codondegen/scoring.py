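"""Match/mismatch scoring of codons and patterns, and the Smin.S /
Smax.NS family diagnostic.

The scheme scores a pair of unambiguous bases as match, transition
(A<->G, C<->T) or transversion; a pair involving IUPAC ambiguity scores
as the arithmetic mean over the Cartesian product of the two base sets,
so e.g. with the default scheme score(A, R) = (score(A,A) + score(A,G))/2
= (30 + 0)/2 = 15.  All arithmetic is exact rational; the printed,
floored-toward-minus-infinity integers are carried alongside because
that is the convention of the diagnostic tables this reproduces.

The family diagnostic takes a set of codons/patterns labeled with amino
acids and reports

* ``Smin.S``  -- the minimum pairwise score among synonymous members
  (an ambiguous pattern is also paired with itself: its self-score is
  the mean over all expansion pairs, the within-pattern heterogeneity);
* ``Smax.NS`` -- the maximum pairwise score among nonsynonymous members.

A degeneration scheme resolves the nucleotide-vs-amino-acid conflict at
a family when it achieves Smin.S > Smax.NS.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from .iupac import PURINES, expand, normalize_symbol


@dataclass(frozen=True)
class ScoreScheme:
    """Base-pair scores: match / transition / transversion."""

    s_match: Fraction = Fraction(30)
    s_transition: Fraction = Fraction(0)
    s_transversion: Fraction = Fraction(-30)

    def __post_init__(self) -> None:
        for name in ("s_match", "s_transition", "s_transversion"):
            object.__setattr__(self, name, Fraction(getattr(self, name)))

    def unambiguous(self, x: str, y: str) -> Fraction:
        if x == y:
            return self.s_match
        if (x in PURINES) == (y in PURINES):
            return self.s_transition
        return self.s_transversion


DEFAULT_SCHEME = ScoreScheme()


@lru_cache(maxsize=None)
def _base_score(x: str, y: str, scheme: ScoreScheme) -> Fraction:
    ex, ey = expand(x), expand(y)
    total = sum(scheme.unambiguous(a, b) for a in ex for b in ey)
    return Fraction(total, len(ex) * len(ey))


def base_score(x: str, y: str, scheme: ScoreScheme = DEFAULT_SCHEME) -> Fraction:
    """Score a pair of IUPAC symbols, averaging over ambiguity."""
    return _base_score(normalize_symbol(x), normalize_symbol(y), scheme)


def codon_score(
    p1: str, p2: str, scheme: ScoreScheme = DEFAULT_SCHEME
) -> Fraction:
    """Position-wise sum of base scores over two 3-symbol patterns.

    Equals the mean of the unambiguous codon scores over all expansion
    pairs, because the mean distributes over the position-wise sum.
    """
    if len(p1) != 3 or len(p2) != 3:
        raise ValueError(
            f"codon patterns must have length 3, got {p1!r}, {p2!r}"
        )
    return sum(base_score(a, b, scheme) for a, b in zip(p1, p2))


@dataclass(frozen=True)
class FamilyCase:
    """A labeled set of codons/patterns over which the diagnostic runs.

    ``members`` holds (pattern, amino-acid) pairs; patterns with the
    same amino acid are synonymous, all others nonsynonymous.
    """

    members: tuple
    label: str = ""

    def __post_init__(self) -> None:
        members = tuple(
            ("".join(normalize_symbol(ch) for ch in p), aa.upper())
            for p, aa in self.members
        )
        object.__setattr__(self, "members", members)
        for p, aa in members:
            if len(p) != 3:
                raise ValueError(f"pattern {p!r} is not a 3-symbol codon")

    @classmethod
    def from_groups(
        cls, groups: Mapping[str, Iterable[str]], label: str = ""
    ) -> "FamilyCase":
        """Build a case from {amino acid: patterns}, e.g.
        ``{"L": ["YTR", "CTN"], "F": ["TTY"]}``."""
        members = tuple(
            (p, aa) for aa, pats in groups.items() for p in pats
        )
        return cls(members=members, label=label)


@dataclass(frozen=True)
class FamilyStats:
    """Exact and floored Smin.S / Smax.NS for one family case."""

    smin_s: Fraction
    smax_ns: Fraction
    smin_s_floor: int
    smax_ns_floor: int

    @property
    def conflict_resolved(self) -> bool:
        return self.smin_s > self.smax_ns


def _is_ambiguous_pattern(p: str) -> bool:
    return any(len(expand(ch)) > 1 for ch in p)


def family_stats(
    case: FamilyCase, scheme: ScoreScheme = DEFAULT_SCHEME
) -> FamilyStats:
    """Compute Smin.S and Smax.NS over a family case.

    Synonymous pairs are all unordered pairs of distinct members with
    the same amino acid, plus each ambiguous pattern paired with itself
    (self-pairs of unambiguous codons score the trivial 3x match and
    are excluded).  Nonsynonymous pairs are all cross-amino-acid pairs.
    """
    syn_scores: list[Fraction] = []
    ns_scores: list[Fraction] = []
    for (p1, aa1), (p2, aa2) in itertools.combinations(case.members, 2):
        s = codon_score(p1, p2, scheme)
        (syn_scores if aa1 == aa2 else ns_scores).append(s)
    for p, _aa in case.members:
        if _is_ambiguous_pattern(p):
            syn_scores.append(codon_score(p, p, scheme))
    if not ns_scores:
        raise ValueError(
            "Smax.NS undefined: no nonsynonymous pair in the case"
        )
    if not syn_scores:
        raise ValueError(
            "Smin.S undefined: no synonymous pair or ambiguous pattern"
        )
    smin, smax = min(syn_scores), max(ns_scores)
    return FamilyStats(
        smin_s=smin,
        smax_ns=smax,
        smin_s_floor=math.floor(smin),
        smax_ns_floor=math.floor(smax),
    )
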