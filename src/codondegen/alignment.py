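"""Sequence records and the codon-alignment container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

from .iupac import GAP_CHARS, IUPAC_SYMBOLS, MISSING_CHARS

_ALLOWED = IUPAC_SYMBOLS | GAP_CHARS | MISSING_CHARS


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: id is the first whitespace token of the header."""

    id: str
    seq: str
    description: str = ""
    rna_normalized: bool = False  # True when 'U' was rewritten to 'T' on read

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record with empty id")

    def with_seq(self, seq: str) -> "SequenceRecord":
        return replace(self, seq=seq)


def _validate_alphabet(rec: SequenceRecord) -> None:
    bad = sorted(set(rec.seq) - _ALLOWED)
    if bad:
        raise ValueError(
            f"record {rec.id!r} contains non-IUPAC characters: {bad}"
        )


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length aligned sequences over the DNA + IUPAC + gap alphabet.

    The reading frame is assumed to start at column 1; operations that
    support a frame offset take it explicitly.
    """

    records: tuple

    def __post_init__(self) -> None:
        records = tuple(
            r if isinstance(r, SequenceRecord) else SequenceRecord(*r)
            for r in self.records
        )
        object.__setattr__(self, "records", records)
        if not records:
            raise ValueError("empty alignment")
        widths = {len(r.seq) for r in records}
        if len(widths) != 1:
            raise ValueError(
                f"sequences differ in length: {sorted(widths)}"
            )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        for r in records:
            _validate_alphabet(r)

    @property
    def width(self) -> int:
        return len(self.records[0].seq)

    @property
    def n_codons(self) -> int:
        if self.width % 3 != 0:
            raise ValueError(
                f"alignment width {self.width} is not divisible by 3"
            )
        return self.width // 3

    @property
    def ids(self) -> tuple:
        return tuple(r.id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def codon_column(self, site: int) -> list:
        """Codons of all sequences at 0-based codon site ``site``."""
        start = 3 * site
        return [r.seq[start : start + 3] for r in self.records]

    def take_codon_sites(self, sites: Sequence[int]) -> "CodonAlignment":
        """New alignment keeping the given 0-based codon sites, in order."""
        n = self.n_codons
        for s in sites:
            if not 0 <= s < n:
                raise IndexError(f"codon site {s} out of range 0..{n - 1}")
        return CodonAlignment(
            tuple(
                r.with_seq(
                    "".join(r.seq[3 * s : 3 * s + 3] for s in sites)
                )
                for r in self.records
            )
        )
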