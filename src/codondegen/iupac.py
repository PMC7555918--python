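"""IUPAC nucleotide ambiguity algebra.

The 15 IUPAC symbols are in bijection with the 15 nonempty subsets of
{A, C, G, T}; ``expand`` and ``cover`` are the two directions of that
bijection.  Gap characters are not ambiguity symbols and are rejected
here; alignment-level code decides what to do with them.
"""

from __future__ import annotations

from typing import FrozenSet, Iterable

GAP_CHARS = frozenset("-.")
MISSING_CHARS = frozenset("?")

_SYMBOL_TO_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "W": "AT", "S": "CG",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

EXPANSIONS: dict[str, FrozenSet[str]] = {
    s: frozenset(b) for s, b in _SYMBOL_TO_BASES.items()
}
_COVER = {bases: s for s, bases in EXPANSIONS.items()}

IUPAC_SYMBOLS = frozenset(EXPANSIONS)
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def normalize_symbol(symbol: str) -> str:
    """Uppercase and map RNA 'U' to 'T'; reject anything not IUPAC."""
    s = symbol.upper()
    if s == "U":
        s = "T"
    if s not in IUPAC_SYMBOLS:
        raise ValueError(f"not an IUPAC nucleotide symbol: {symbol!r}")
    return s


def expand(symbol: str) -> FrozenSet[str]:
    """Base set denoted by an IUPAC symbol (e.g. R -> {A, G})."""
    return EXPANSIONS[normalize_symbol(symbol)]


def cover(bases: Iterable[str]) -> str:
    """The unique IUPAC symbol whose expansion equals the given base set."""
    bs = frozenset(normalize_symbol(b) for b in bases)
    if not bs:
        raise ValueError("cover() of an empty base set is undefined")
    if not bs <= frozenset("ACGT"):
        bad = sorted(bs - frozenset("ACGT"))
        raise ValueError(f"cover() takes unambiguous bases only, got {bad}")
    return _COVER[bs]


def is_ambiguous(symbol: str) -> bool:
    return len(expand(symbol)) > 1


def expand_pattern(pattern: str) -> list[str]:
    """All unambiguous strings covered by an IUPAC string (codon-sized in practice)."""
    out = [""]
    for sym in pattern:
        bases = sorted(expand(sym))
        out = [prefix + b for prefix in out for b in bases]
    return out
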