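"""Detection and removal of codon sites mixing the two serine blocks.

Serine is encoded by two disjoint codon blocks (TCN and AGY in the
standard and most mitochondrial codes); no degeneration can make them
similar at the nucleotide level without spanning other amino acids
(AGY is one transition away from Arg AGR).  A codon column at which
some sequences carry TCN and others AGY therefore injects a purely
non-historical conflict into nucleotide-level analysis, and the usual
remedy is to drop such columns — or to keep only them, to check how
much signal they carry.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from .alignment import CodonAlignment
from .genetic_codes import GeneticCode, synonymous_family
from .iupac import GAP_CHARS, MISSING_CHARS, expand

#: Ser codons in codes where Ser is exactly TCN + AGY.
STANDARD_SER_CODONS = frozenset(
    {"TCA", "TCC", "TCG", "TCT", "AGC", "AGT"}
)


@dataclass(frozen=True)
class SerSiteReport:
    """Mixed TCN/AGY codon sites of one alignment (1-based indices)."""

    mixed_sites: tuple
    counts: Mapping[int, tuple]  # site -> (n TCN-type, n AGY-type)
    n_codons: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", MappingProxyType(dict(self.counts)))


def _is_gap_codon(codon: str) -> bool:
    return any(ch in GAP_CHARS or ch in MISSING_CHARS for ch in codon)


def _matches_tcn(codon: str) -> bool:
    return codon[:2] == "TC"


def _matches_agy(codon: str) -> bool:
    return codon[:2] == "AG" and expand(codon[2]) <= frozenset("CT")


def _ser_block_of(codon: str, code: GeneticCode) -> str | None:
    # translation-based variant: any Ser codon, classified by prefix
    if code.codon_to_aa.get(codon) != "S":
        return None
    return "TCN" if codon[:2] == "TC" else "AGY" if codon[:2] == "AG" else None


def find_mixed_ser_sites(
    aln: CodonAlignment,
    code: GeneticCode,
    *,
    by_translation: bool = False,
    force: bool = False,
) -> SerSiteReport:
    """List every codon column carrying both a TCN and an AGY codon.

    Matching is on literal bases (TC* versus AG[CT], third position may
    be an ambiguity symbol covered by {C,T}), so it also works on
    degenerated input; ``by_translation=True`` instead matches any
    Ser-translating codon and classifies it by prefix.  Gap-containing
    codons are ignored.

    Codes in which Ser is not exactly TCN + AGY (5, 9, 12, 14, 21, 24,
    33) are refused unless ``force=True``, because matched codons there
    may not be Ser, or Ser codons may fall outside both blocks.
    """
    if synonymous_family(code, "S") != STANDARD_SER_CODONS and not force:
        raise ValueError(
            f"genetic code {code.table_id} does not encode Ser as exactly "
            "TCN + AGY; matched codons may not be serines. "
            "Pass force=True to filter anyway."
        )
    mixed = []
    counts = {}
    for site in range(aln.n_codons):
        n_tcn = n_agy = 0
        for codon in aln.codon_column(site):
            if _is_gap_codon(codon):
                continue
            if by_translation:
                block = _ser_block_of(codon, code)
                n_tcn += block == "TCN"
                n_agy += block == "AGY"
            else:
                n_tcn += _matches_tcn(codon)
                n_agy += _matches_agy(codon)
        if n_tcn and n_agy:
            mixed.append(site + 1)
            counts[site + 1] = (n_tcn, n_agy)
    return SerSiteReport(
        mixed_sites=tuple(mixed), counts=counts, n_codons=aln.n_codons
    )


def _check_report(aln: CodonAlignment, report: SerSiteReport) -> None:
    if report.n_codons != aln.n_codons:
        raise ValueError(
            f"stale report: built for {report.n_codons} codon sites, "
            f"alignment has {aln.n_codons}"
        )


def remove_sites(aln: CodonAlignment, report: SerSiteReport) -> CodonAlignment:
    """Drop the reported codon columns; column order preserved."""
    _check_report(aln, report)
    drop = {s - 1 for s in report.mixed_sites}
    keep = [s for s in range(aln.n_codons) if s not in drop]
    return aln.take_codon_sites(keep)


def keep_only_sites(aln: CodonAlignment, report: SerSiteReport) -> CodonAlignment:
    """Retain exactly the reported codon columns."""
    _check_report(aln, report)
    return aln.take_codon_sites([s - 1 for s in report.mixed_sites])
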