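"""Codon degeneration maps and their application to alignments.

A degeneration map sends each of the 64 codons of a genetic code to a
3-symbol IUPAC pattern so that synonymous codons become identical, or
as similar as possible, at the nucleotide level.  Three modes are
provided:

``third_only``
    Within each codon *block* (synonymous codons sharing positions 1
    and 2), the third position is replaced by the minimal IUPAC cover
    of the thirds present; positions 1-2 are untouched.  Standard-code
    Leu becomes TTR and CTN, Phe TTY.

``principled``
    Starts from ``third_only`` and additionally merges pairs of blocks
    of the same amino acid whose position-1/2 prefixes differ at
    exactly one position: that position is degenerated *in the smaller
    block only*, to the cover of both blocks' bases there, and only if
    the resulting pattern still expands exclusively to codons of the
    same amino acid.  Standard-code Leu becomes YTR and CTN, Arg MGR
    and CGN; blocks differing at both prefix positions (Ser TCN / AGY)
    stay independent.  The governing rule is that a degenerate pattern
    must never span two amino acids, so the degenerated alignment still
    translates to the original protein.

``full_union``
    Every codon of an amino acid maps to the position-wise cover of the
    union over *all* its codons (the historically used, unprincipled
    variant: Leu -> YTN, Arg -> MGN).  These patterns can span amino
    acids; ``report_principle_violations`` enumerates where.

Stop codons always map to themselves and never join a sense block.

``ry_recode`` is the coarser purine/pyrimidine degeneration used for
rRNA and other non-coding sequence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from types import MappingProxyType
from typing import Iterable, Mapping

from .alignment import CodonAlignment
from .genetic_codes import ALL_CODONS, STOP_SYMBOL, GeneticCode
from .iupac import (
    GAP_CHARS,
    MISSING_CHARS,
    PURINES,
    PYRIMIDINES,
    cover,
    expand,
    expand_pattern,
    is_ambiguous,
)

logger = logging.getLogger(__name__)

MODES = ("principled", "third_only", "full_union")


@dataclass(frozen=True)
class DegenerationMap:
    """Per-code, per-mode map from each of the 64 codons to a pattern."""

    table_id: int
    mode: str
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", MappingProxyType(dict(self.mapping)))
        if set(self.mapping) != set(ALL_CODONS):
            raise ValueError("degeneration map must cover all 64 codons")

    def __getitem__(self, codon: str) -> str:
        return self.mapping[codon]


def codon_blocks(code: GeneticCode) -> dict:
    """Sense codons grouped by (amino acid, positions-1-2 prefix)."""
    blocks: dict = {}
    for codon, aa in code.codon_to_aa.items():
        if aa == STOP_SYMBOL:
            continue
        blocks.setdefault((aa, codon[:2]), []).append(codon)
    return {k: tuple(sorted(v)) for k, v in blocks.items()}


def _pattern_is_synonymous(pattern: str, aa: str, code: GeneticCode) -> bool:
    return all(code.codon_to_aa[c] == aa for c in expand_pattern(pattern))


def _third_only_patterns(code: GeneticCode) -> dict:
    return {
        (aa, prefix): prefix + cover(c[2] for c in codons)
        for (aa, prefix), codons in codon_blocks(code).items()
    }


def _merge_position(pattern: str, other: str, pos: int) -> str:
    merged = cover(expand(pattern[pos]) | expand(other[pos]))
    return pattern[:pos] + merged + pattern[pos + 1 :]


def _principled_patterns(code: GeneticCode) -> dict:
    patterns = _third_only_patterns(code)
    blocks = codon_blocks(code)
    by_aa: dict = {}
    for (aa, prefix) in blocks:
        by_aa.setdefault(aa, []).append(prefix)
    for aa, prefixes in by_aa.items():
        if len(prefixes) < 2:
            continue
        pairs = []
        for pa, pb in itertools.combinations(sorted(prefixes), 2):
            diff = [i for i in range(2) if pa[i] != pb[i]]
            if len(diff) == 1:
                pairs.append((pa, pb, diff[0]))
        # smaller blocks are merged first; prefix order breaks ties
        pairs.sort(
            key=lambda t: (
                min(len(blocks[(aa, t[0])]), len(blocks[(aa, t[1])])),
                t[0],
                t[1],
            )
        )
        for pa, pb, pos in pairs:
            size_a = len(blocks[(aa, pa)])
            size_b = len(blocks[(aa, pb)])
            pat_a = patterns[(aa, pa)]
            pat_b = patterns[(aa, pb)]
            if size_a == size_b:
                cand_a = _merge_position(pat_a, pat_b, pos)
                cand_b = _merge_position(pat_b, pat_a, pos)
                if _pattern_is_synonymous(
                    cand_a, aa, code
                ) and _pattern_is_synonymous(cand_b, aa, code):
                    patterns[(aa, pa)] = cand_a
                    patterns[(aa, pb)] = cand_b
                else:
                    logger.info(
                        "code %d %s: equal-size blocks %s/%s left unmerged "
                        "(merging would span amino acids)",
                        code.table_id, aa, pa, pb,
                    )
                continue
            small, big = (pa, pb) if size_a < size_b else (pb, pa)
            cand = _merge_position(
                patterns[(aa, small)], patterns[(aa, big)], pos
            )
            if _pattern_is_synonymous(cand, aa, code):
                patterns[(aa, small)] = cand
    return patterns


def _full_union_patterns(code: GeneticCode) -> dict:
    families: dict = {}
    for codon, aa in code.codon_to_aa.items():
        if aa != STOP_SYMBOL:
            families.setdefault(aa, []).append(codon)
    union_pattern = {
        aa: "".join(
            cover({c[i] for c in codons}) for i in range(3)
        )
        for aa, codons in families.items()
    }
    return {
        (aa, prefix): union_pattern[aa]
        for (aa, prefix) in codon_blocks(code)
    }


def build_map(code: GeneticCode, mode: str) -> DegenerationMap:
    """Build the codon -> pattern degeneration map for one genetic code."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    builder = {
        "third_only": _third_only_patterns,
        "principled": _principled_patterns,
        "full_union": _full_union_patterns,
    }[mode]
    patterns = builder(code)
    mapping = {}
    for codon in ALL_CODONS:
        aa = code.codon_to_aa[codon]
        if aa == STOP_SYMBOL:
            mapping[codon] = codon
        else:
            mapping[codon] = patterns[(aa, codon[:2])]
    return DegenerationMap(table_id=code.table_id, mode=mode, mapping=mapping)


def report_principle_violations(
    dmap: DegenerationMap, code: GeneticCode
) -> list:
    """All (pattern, offending codon, its amino acid) triples where a
    pattern's expansion includes a codon of a different amino acid (or
    a stop).  Empty for principled and third_only maps by construction."""
    violations = set()
    for codon in ALL_CODONS:
        aa = code.codon_to_aa[codon]
        if aa == STOP_SYMBOL:
            continue
        pattern = dmap[codon]
        for other in expand_pattern(pattern):
            other_aa = code.codon_to_aa[other]
            if other_aa != aa:
                violations.add((pattern, other, other_aa))
    return sorted(violations)


@dataclass(frozen=True)
class DegenerationResult:
    """Degenerated alignment plus a per-sequence codon tally."""

    alignment: CodonAlignment
    #: one dict per sequence: id, degenerated, ambiguous, gap, stop
    report: tuple


def _degenerate_seq(
    seq: str, dmap: DegenerationMap, code: GeneticCode,
    frame: int, gap_codon: str, on_partial: str,
) -> tuple:
    counts = {"degenerated": 0, "ambiguous": 0, "gap": 0, "stop": 0}
    out = [seq[:frame]]
    body_end = frame + ((len(seq) - frame) // 3) * 3
    if (len(seq) - frame) % 3 != 0 and on_partial == "error":
        raise ValueError(
            f"alignment width {len(seq)} minus frame {frame} is not "
            "divisible by 3 (pass on_partial='keep' to pass the tail through)"
        )
    for i in range(frame, body_end, 3):
        codon = seq[i : i + 3]
        if any(ch in GAP_CHARS or ch in MISSING_CHARS for ch in codon):
            counts["gap"] += 1
            out.append("---" if gap_codon == "mask" else codon)
        elif any(is_ambiguous(ch) for ch in codon):
            counts["ambiguous"] += 1
            out.append(codon)
        elif code.codon_to_aa[codon] == STOP_SYMBOL:
            counts["stop"] += 1
            out.append(codon)
        else:
            counts["degenerated"] += 1
            out.append(dmap[codon])
    out.append(seq[body_end:])
    return "".join(out), counts


def degenerate_alignment(
    aln: CodonAlignment,
    dmap: DegenerationMap,
    *,
    frame: int = 0,
    gap_codon: str = "keep",
    on_partial: str = "error",
) -> DegenerationResult:
    """Apply a degeneration map codon-wise to an alignment.

    Fully unambiguous sense codons are replaced by their pattern; stop
    codons are left as is; codons containing gaps are kept (or masked
    to ``---`` with ``gap_codon='mask'``); codons already containing
    ambiguity symbols are passed through untouched and tallied, since
    their intended amino acid may be undefined.  Columns before
    ``frame`` and any trailing partial codon (with ``on_partial='keep'``)
    pass through unchanged.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if gap_codon not in ("keep", "mask"):
        raise ValueError("gap_codon must be 'keep' or 'mask'")
    if on_partial not in ("error", "keep"):
        raise ValueError("on_partial must be 'error' or 'keep'")
    code = _code_for(dmap)
    new_records = []
    report = []
    for rec in aln:
        new_seq, counts = _degenerate_seq(
            rec.seq, dmap, code, frame, gap_codon, on_partial
        )
        new_records.append(rec.with_seq(new_seq))
        report.append({"id": rec.id, **counts})
    return DegenerationResult(
        alignment=CodonAlignment(tuple(new_records)), report=tuple(report)
    )


def _code_for(dmap: DegenerationMap) -> GeneticCode:
    from .genetic_codes import get_code

    return get_code(dmap.table_id)


def ry_recode(seq: str) -> str:
    """Collapse nucleotides to purine (R) / pyrimidine (Y).

    IUPAC symbols whose expansion is purine-only map to R, pyrimidine-
    only to Y, mixed to N; gap and missing characters are preserved.
    """
    out = []
    for ch in seq:
        if ch in GAP_CHARS or ch in MISSING_CHARS:
            out.append(ch)
            continue
        bases = expand(ch)
        if bases <= PURINES:
            out.append("R")
        elif bases <= PYRIMIDINES:
            out.append("Y")
        else:
            out.append("N")
    return "".join(out)
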