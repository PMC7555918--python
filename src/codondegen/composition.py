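"""Nucleotide- and codon-composition diagnostics.

These are the quantities used to diagnose compositional bias before
and after degeneration: per-sequence base proportions (P_A .. P_T),
G+C content at third codon positions (GC3), and the split of an amino
acid's usage across its codon blocks — e.g. for Leu, P_CUN, the
fraction of Leu codons drawn from the CTN block rather than TTR.
Lineages that have converged on similar base composition (e.g. C-rich
mitochondrial genomes) show similar P_C and P_CUN regardless of their
phylogenetic affinity, which is exactly the signal degeneration
removes.

All counting is exact rational; gaps and ambiguity symbols are
excluded from denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

from .alignment import SequenceRecord
from .degeneration import build_map, codon_blocks
from .genetic_codes import GeneticCode, _normalize_nt, synonymous_family
from .iupac import GAP_CHARS, MISSING_CHARS, expand

_BASES = "ACGT"


def _seq_of(item) -> str:
    return item.seq if isinstance(item, SequenceRecord) else str(item)


def nt_proportions(seq) -> dict:
    """Proportions of A/C/G/T over unambiguous bases (exact Fractions)."""
    s = _normalize_nt(_seq_of(seq))
    counts = {b: s.count(b) for b in _BASES}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous bases in sequence")
    return {b: Fraction(c, total) for b, c in counts.items()}


def gc3(seq) -> Fraction:
    """G+C fraction among unambiguous third-codon-position bases."""
    s = _normalize_nt(_seq_of(seq))
    if len(s) % 3 != 0:
        raise ValueError(f"sequence length {len(s)} is not divisible by 3")
    thirds = [s[i] for i in range(2, len(s), 3) if s[i] in _BASES]
    if not thirds:
        raise ValueError("no unambiguous third-position bases")
    gc = sum(1 for b in thirds if b in "GC")
    return Fraction(gc, len(thirds))


@dataclass(frozen=True)
class SubfamilyUsage:
    """Pooled codon-block usage of one amino acid across sequences."""

    aa: str
    counts: Mapping[str, int]        # block pattern -> pooled codon count
    proportions: Mapping[str, Fraction]
    per_sequence: tuple              # (id, {pattern: count}) in input order
    single_block: bool               # True when the aa has only one block

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", MappingProxyType(dict(self.counts)))
        object.__setattr__(
            self, "proportions", MappingProxyType(dict(self.proportions))
        )


def _block_catalogue(code: GeneticCode, aa: str) -> dict:
    """For each block of ``aa``: the strings that count toward it.

    A codon counts toward a block if it is one of the block's literal
    codons or the block's third_only / principled pattern, so usage can
    be measured identically before and after degeneration.
    """
    synonymous_family(code, aa)  # raises if aa is absent
    third = build_map(code, "third_only")
    princ = build_map(code, "principled")
    catalogue = {}
    for (block_aa, prefix), codons in codon_blocks(code).items():
        if block_aa != aa:
            continue
        label = third[codons[0]]
        members = set(codons) | {third[codons[0]], princ[codons[0]]}
        catalogue[label] = members
    return catalogue


def subfamily_usage(
    seqs: Iterable, code: GeneticCode, aa: str
) -> SubfamilyUsage:
    """Count an amino acid's codons by block, pooled across sequences.

    The group-level proportion is computed from pooled counts (one
    P_CUN per group), not as a mean of per-sequence ratios.  Codons
    containing ambiguity symbols that match no block pattern are
    excluded from the denominator.
    """
    aa = aa.upper()
    catalogue = _block_catalogue(code, aa)
    lookup = {
        member: label
        for label, members in catalogue.items()
        for member in members
    }
    pooled = {label: 0 for label in catalogue}
    per_sequence = []
    for item in seqs:
        rec_id = item.id if isinstance(item, SequenceRecord) else None
        s = _normalize_nt(_seq_of(item))
        if len(s) % 3 != 0:
            raise ValueError(
                f"sequence length {len(s)} is not divisible by 3"
            )
        counts = {label: 0 for label in catalogue}
        for i in range(0, len(s), 3):
            label = lookup.get(s[i : i + 3])
            if label is not None:
                counts[label] += 1
        for label, c in counts.items():
            pooled[label] += c
        per_sequence.append((rec_id, counts))
    total = sum(pooled.values())
    proportions = {
        label: Fraction(c, total) if total else Fraction(0)
        for label, c in pooled.items()
    }
    return SubfamilyUsage(
        aa=aa,
        counts=pooled,
        proportions=proportions,
        per_sequence=tuple(per_sequence),
        single_block=len(catalogue) == 1,
    )
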