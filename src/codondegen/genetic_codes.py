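"""Registry of NCBI genetic codes with translation and synonymy queries.

Table data comes verbatim from Biopython's copy of the NCBI "Genetic
Codes" compilation (translation tables 1-6, 9-16 and 21-33; the other
numbers were never assigned or have been retired by NCBI).  Everything
is DNA-alphabet internally: RNA input is normalized with U -> T.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from Bio.Data import CodonTable as _BioCodonTable

from .iupac import GAP_CHARS, expand_pattern

STOP_SYMBOL = "*"
GAP_AA = "-"
UNKNOWN_AA = "X"

#: All 64 unambiguous DNA codons in lexicographic order.
ALL_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)


@dataclass(frozen=True)
class GeneticCode:
    """One NCBI translation table.

    Attributes
    ----------
    table_id:
        The NCBI translation-table number (e.g. 1 = standard,
        2 = vertebrate mitochondrial).
    name:
        NCBI's name for the table.
    codon_to_aa:
        Mapping from each of the 64 unambiguous DNA codons to a
        one-letter amino acid, or ``'*'`` for a stop codon.
    start_codons:
        NCBI's alternative initiation codons (metadata only; nothing in
        this package treats starts specially).
    """

    table_id: int
    name: str
    codon_to_aa: Mapping[str, str]
    start_codons: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "codon_to_aa", MappingProxyType(dict(self.codon_to_aa))
        )
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code {self.table_id} has "
                f"{len(self.codon_to_aa)} codons, expected 64"
            )

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(
            c for c, aa in self.codon_to_aa.items() if aa == STOP_SYMBOL
        )

    @property
    def amino_acids(self) -> frozenset:
        """Amino acids encoded by this table (stops excluded)."""
        return frozenset(self.codon_to_aa.values()) - {STOP_SYMBOL}


def _build_registry() -> dict[int, GeneticCode]:
    registry: dict[int, GeneticCode] = {}
    for table_id, table in _BioCodonTable.unambiguous_dna_by_id.items():
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP_SYMBOL
        name = next((n for n in table.names if n), f"Table {table_id}")
        registry[table_id] = GeneticCode(
            table_id=table_id,
            name=name,
            codon_to_aa=mapping,
            start_codons=frozenset(table.start_codons),
        )
    return registry


_REGISTRY: dict[int, GeneticCode] = _build_registry()

#: Defined NCBI table numbers, ascending (numbering has gaps: 7, 8 and
#: 17-20 were never assigned / withdrawn by NCBI).
TABLE_IDS = tuple(sorted(_REGISTRY))


def get_code(table_id: int) -> GeneticCode:
    """Return the genetic code for an NCBI translation-table number."""
    try:
        return _REGISTRY[table_id]
    except KeyError:
        raise LookupError(
            f"no NCBI translation table {table_id!r}; defined tables are "
            f"{', '.join(map(str, TABLE_IDS))}"
        ) from None


def list_codes() -> list[GeneticCode]:
    return [_REGISTRY[i] for i in TABLE_IDS]


def _normalize_nt(seq: str) -> str:
    return seq.upper().replace("U", "T")


def translate(seq: str, code: GeneticCode) -> str:
    """Translate an in-frame DNA/RNA string, IUPAC ambiguity allowed.

    An ambiguous codon translates to its amino acid when every
    expansion agrees, to 'X' otherwise; a codon containing any gap
    character translates to '-'.
    """
    s = _normalize_nt(seq)
    if len(s) % 3 != 0:
        raise ValueError(
            f"sequence length {len(s)} is not divisible by 3"
        )
    out = []
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if any(ch in GAP_CHARS for ch in codon):
            out.append(GAP_AA)
            continue
        aas = {code.codon_to_aa[c] for c in expand_pattern(codon)}
        out.append(aas.pop() if len(aas) == 1 else UNKNOWN_AA)
    return "".join(out)


def synonymous_family(code: GeneticCode, aa: str) -> frozenset:
    """The exact set of sense codons translating to ``aa`` under ``code``."""
    aa = aa.upper()
    if aa == STOP_SYMBOL:
        raise ValueError("stop codons do not form a synonymous family")
    family = frozenset(
        c for c, a in code.codon_to_aa.items() if a == aa
    )
    if not family:
        raise ValueError(
            f"amino acid {aa!r} is not encoded by table {code.table_id}"
        )
    return family
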