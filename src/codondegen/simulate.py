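"""Synthetic in-frame CDS generation with controllable composition.

The generator draws amino acids uniformly over a genetic code's
repertoire and then chooses codons so that two compositional dials can
be turned independently: the probability that a third-codon-position
base is G or C (``gc3_bias``), and the probability that a Leu codon
comes from the CTN block rather than TTR (``leu_ctn_bias``).  This
mimics the contrast that motivates degeneration — lineages that differ
only in composition, not in protein sequence — without simulating
evolution along a tree.

Blocks whose thirds all fall in one G+C class (e.g. Met ATG, Trp TGG)
cannot respond to ``gc3_bias``; they are drawn as is, which pulls the
realized GC3 a little toward their class (about +0.02 at high bias
under the standard code).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import SequenceRecord
from .degeneration import codon_blocks
from .genetic_codes import GeneticCode, get_code

_GC = frozenset("GC")


@dataclass(frozen=True)
class CdsSimSpec:
    """Parameters of one simulated CDS set."""

    table_id: int = 1
    n_sequences: int = 4
    n_codons: int = 300
    gc3_bias: float = 0.5       # target P(third position is G or C)
    leu_ctn_bias: float = 0.5   # P(Leu codon drawn from the CTN block)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1 or self.n_sequences < 1:
            raise ValueError("need at least one sequence and one codon")
        for name in ("gc3_bias", "leu_ctn_bias"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def _block_table(code: GeneticCode):
    """Per amino acid: list of (prefix, thirds) blocks."""
    table: dict = {}
    for (aa, prefix), codons in codon_blocks(code).items():
        table.setdefault(aa, []).append((prefix, tuple(c[2] for c in codons)))
    return {aa: sorted(blocks) for aa, blocks in table.items()}


def _draw_third(thirds, gc3_bias: float, rng) -> str:
    gc = [t for t in thirds if t in _GC]
    at = [t for t in thirds if t not in _GC]
    if gc and at:
        pool = gc if rng.random() < gc3_bias else at
    else:
        pool = list(thirds)  # single-class block: bias not applicable
    return pool[rng.integers(len(pool))]


def simulate_cds(spec: CdsSimSpec) -> list:
    """Generate ``n_sequences`` in-frame CDS (no internal stops).

    Identical specs (including the seed) give byte-identical output.
    """
    code = get_code(spec.table_id)
    rng = np.random.default_rng(spec.seed)
    blocks = _block_table(code)
    amino_acids = sorted(code.amino_acids)
    leu_blocks = blocks.get("L", [])
    ctn_like = [b for b in leu_blocks if b[0] == "CT"]
    ttr_like = [b for b in leu_blocks if b[0] == "TT"]
    leu_dial_usable = bool(ctn_like) and bool(ttr_like)
    if not leu_dial_usable and "L" in blocks:
        warnings.warn(
            f"genetic code {spec.table_id} lacks distinct CTN/TTR Leu "
            "blocks; leu_ctn_bias ignored (uniform block choice)",
            stacklevel=2,
        )
    records = []
    for s in range(spec.n_sequences):
        codons = []
        for _ in range(spec.n_codons):
            aa = amino_acids[rng.integers(len(amino_acids))]
            aa_blocks = blocks[aa]
            if aa == "L" and leu_dial_usable:
                chosen = (
                    ctn_like if rng.random() < spec.leu_ctn_bias else ttr_like
                )
                prefix, thirds = chosen[rng.integers(len(chosen))]
            else:
                prefix, thirds = aa_blocks[rng.integers(len(aa_blocks))]
            codons.append(prefix + _draw_third(thirds, spec.gc3_bias, rng))
        records.append(
            SequenceRecord(id=f"sim{s + 1}", seq="".join(codons))
        )
    return records
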