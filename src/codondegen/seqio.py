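"""FASTA input/output, codon threading onto a protein alignment, and
supermatrix concatenation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .alignment import CodonAlignment, SequenceRecord
from .genetic_codes import GeneticCode, STOP_SYMBOL, translate
from .iupac import GAP_CHARS


def read_fasta(path) -> list:
    """Read FASTA into SequenceRecords.

    Sequences are uppercased and RNA 'U' is rewritten to 'T' (the
    ``rna_normalized`` flag records that this happened).  Duplicate
    ids, empty records and non-FASTA content are errors.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.read(1)
        if first != ">":
            raise ValueError(f"{path} does not look like FASTA (no '>')")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq).upper()
        seq = raw.replace("U", "T")
        description = rec.description[len(rec.id):].strip()
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=seq,
                description=description,
                rna_normalized=seq != raw,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable, path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping at ``wrap`` columns (0 = no wrap)."""
    records = list(records)
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            if wrap and wrap > 0:
                for i in range(0, len(rec.seq), wrap):
                    handle.write(rec.seq[i : i + wrap] + "\n")
            else:
                handle.write(rec.seq + "\n")


def _strip_gaps(seq: str) -> str:
    return "".join(ch for ch in seq if ch not in GAP_CHARS)


def thread_codons(
    cds: Sequence, aa_aln: Sequence, code: GeneticCode,
    *, allow_terminal_stop: bool = True,
) -> CodonAlignment:
    """Thread unaligned coding sequences onto an aligned protein alignment.

    Each amino-acid gap becomes a codon gap ``---``; each residue is
    replaced by its source codon in order, after verifying that the
    translated CDS matches the gap-stripped protein row residue by
    residue ('X' on either side is tolerated).  Stripping gaps from the
    output recovers the input CDS exactly.
    """
    cds_by_id = {r.id: r for r in cds}
    aa_ids = [r.id for r in aa_aln]
    missing = sorted(set(aa_ids) - set(cds_by_id))
    extra = sorted(set(cds_by_id) - set(aa_ids))
    if missing or extra:
        raise ValueError(
            f"id mismatch between CDS and protein alignment: "
            f"missing from CDS {missing}, absent from alignment {extra}"
        )
    out = []
    for aa_rec in aa_aln:
        cds_rec = cds_by_id[aa_rec.id]
        cds_seq = _strip_gaps(cds_rec.seq)
        residues = _strip_gaps(aa_rec.seq).upper()
        if allow_terminal_stop and len(cds_seq) == 3 * len(residues) + 3:
            tail = translate(cds_seq[-3:], code)
            if tail == STOP_SYMBOL:
                cds_seq = cds_seq[:-3]
        if len(cds_seq) != 3 * len(residues):
            raise ValueError(
                f"{aa_rec.id}: CDS length {len(cds_seq)} is not 3 x "
                f"{len(residues)} aligned residues"
            )
        translated = translate(cds_seq, code)
        for i, (got, want) in enumerate(zip(translated, residues), start=1):
            if got != want and "X" not in (got, want):
                raise ValueError(
                    f"{aa_rec.id}: translation mismatch at residue {i}: "
                    f"CDS gives {got!r}, alignment has {want!r}"
                )
        threaded = []
        k = 0
        for ch in aa_rec.seq:
            if ch in GAP_CHARS:
                threaded.append("---")
            else:
                threaded.append(cds_seq[3 * k : 3 * k + 3])
                k += 1
        out.append(aa_rec.with_seq("".join(threaded)))
    return CodonAlignment(tuple(out))


@dataclass(frozen=True)
class Partition:
    """One gene's span in a concatenated alignment (1-based codon coords)."""

    name: str
    start: int
    end: int


def concatenate(
    alignments: Sequence, names: Sequence | None = None
) -> tuple:
    """Column-wise concatenation of codon alignments sharing one id set.

    Returns the supermatrix and a partition table of (name, start, end)
    in 1-based inclusive codon coordinates, in input order.
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    if names is None:
        names = [f"gene{i + 1}" for i in range(len(alignments))]
    ref_ids = set(alignments[0].ids)
    for i, aln in enumerate(alignments[1:], start=2):
        if set(aln.ids) != ref_ids:
            only_ref = sorted(ref_ids - set(aln.ids))
            only_this = sorted(set(aln.ids) - ref_ids)
            raise ValueError(
                f"alignment {i} id set differs: missing {only_ref}, "
                f"extra {only_this}"
            )
    order = alignments[0].ids
    parts = []
    pos = 0
    for name, aln in zip(names, alignments):
        parts.append(Partition(name=name, start=pos + 1, end=pos + aln.n_codons))
        pos += aln.n_codons
    by_id = [
        {r.id: r.seq for r in aln} for aln in alignments
    ]
    records = tuple(
        SequenceRecord(id=i, seq="".join(m[i] for m in by_id))
        for i in order
    )
    return CodonAlignment(records), parts
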