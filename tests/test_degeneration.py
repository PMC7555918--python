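"""Degeneration maps: the published pattern names, the synonymy
principle for every genetic code, and alignment-level application."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codondegen import (
    ALL_CODONS,
    TABLE_IDS,
    build_map,
    degenerate_alignment,
    get_code,
    report_principle_violations,
    ry_recode,
    translate,
)
from codondegen.iupac import expand_pattern


@pytest.mark.parametrize(
    "table_id,codon,pattern",
    [
        # standard code: Leu / Arg / Ser / Phe
        (1, "TTA", "YTR"), (1, "TTG", "YTR"),
        (1, "CTA", "CTN"), (1, "CTC", "CTN"),
        (1, "AGA", "MGR"), (1, "AGG", "MGR"), (1, "CGT", "CGN"),
        (1, "TCA", "TCN"), (1, "AGC", "AGY"), (1, "TTC", "TTY"),
        # reassigned codes
        (25, "TGA", "KGA"), (25, "GGC", "GGN"),
        (24, "AGG", "ARG"), (24, "AAA", "AAR"),
        (33, "AGG", "ARG"), (33, "AAA", "AAR"),
        (13, "AGA", "RGR"), (13, "AGG", "RGR"), (13, "GGT", "GGN"),
    ],
)
def test_principled_patterns_match_published_names(table_id, codon, pattern):
    dmap = build_map(get_code(table_id), "principled")
    assert dmap[codon] == pattern


def test_third_only_patterns(third_only_map_1):
    assert third_only_map_1["TTA"] == "TTR"
    assert third_only_map_1["CTC"] == "CTN"
    assert third_only_map_1["AGA"] == "AGR"
    assert third_only_map_1["TTT"] == "TTY"


def test_full_union_patterns(standard_code):
    dmap = build_map(standard_code, "full_union")
    assert dmap["TTA"] == "YTN"
    assert dmap["CTC"] == "YTN"
    assert dmap["AGA"] == "MGN"
    assert dmap["CGG"] == "MGN"


def test_stop_codons_map_to_themselves():
    for tid in (1, 2, 25):
        code = get_code(tid)
        for mode in ("principled", "third_only", "full_union"):
            dmap = build_map(code, mode)
            for stop in code.stop_codons:
                assert dmap[stop] == stop


def test_unknown_mode_rejected(standard_code):
    with pytest.raises(ValueError, match="mode"):
        build_map(standard_code, "fourth_only")


def test_synonymy_preservation_exhaustive_all_codes():
    """Conceptual principle: no degenerate pattern may span amino acids,
    checked over all 64 codons of every registered code."""
    for tid in TABLE_IDS:
        code = get_code(tid)
        for mode in ("principled", "third_only"):
            dmap = build_map(code, mode)
            for codon, aa in code.codon_to_aa.items():
                if aa == "*":
                    continue
                for exp in expand_pattern(dmap[codon]):
                    assert code.codon_to_aa[exp] == aa, (tid, mode, codon)
            assert report_principle_violations(dmap, code) == []


def test_third_only_consistency_exhaustive_all_codes():
    """Every codon covered by a third_only pattern maps to that same
    pattern, so the map is closed over its own output."""
    for tid in TABLE_IDS:
        code = get_code(tid)
        dmap = build_map(code, "third_only")
        for codon, aa in code.codon_to_aa.items():
            if aa == "*":
                continue
            for exp in expand_pattern(dmap[codon]):
                assert dmap[exp] == dmap[codon], (tid, codon)


def test_principled_patterns_contain_their_codons():
    """Principled merging pulls a smaller block's pattern over a larger
    block's codons (YTR covers CTA), so map closure cannot hold; what
    must hold is that each codon lies in its own pattern's expansion."""
    for tid in TABLE_IDS:
        code = get_code(tid)
        dmap = build_map(code, "principled")
        for codon, aa in code.codon_to_aa.items():
            if aa != "*":
                assert codon in expand_pattern(dmap[codon])


def test_monotone_refinement_across_modes():
    """third_only subset principled subset full_union, codon by codon."""
    for tid in TABLE_IDS:
        code = get_code(tid)
        maps = {m: build_map(code, m) for m in
                ("third_only", "principled", "full_union")}
        for codon, aa in code.codon_to_aa.items():
            if aa == "*":
                continue
            third = set(expand_pattern(maps["third_only"][codon]))
            princ = set(expand_pattern(maps["principled"][codon]))
            full = set(expand_pattern(maps["full_union"][codon]))
            assert third <= princ <= full, (tid, codon)


def test_full_union_violations_enumerated(standard_code):
    dmap = build_map(standard_code, "full_union")
    violations = report_principle_violations(dmap, standard_code)
    assert ("YTN", "TTC", "F") in violations
    assert ("YTN", "TTT", "F") in violations
    assert ("MGN", "AGC", "S") in violations
    assert ("MGN", "AGT", "S") in violations


def test_degenerate_alignment_basic(make_alignment, principled_map_1):
    aln = make_alignment(("a", "TTACTC"), ("b", "---ATG"))
    result = degenerate_alignment(aln, principled_map_1)
    assert [r.seq for r in result.alignment] == ["YTRCTN", "---ATG"]
    by_id = {row["id"]: row for row in result.report}
    assert by_id["a"]["degenerated"] == 2
    assert by_id["b"]["gap"] == 1 and by_id["b"]["degenerated"] == 1


def test_degenerate_alignment_skips_ambiguous_and_stops(
    make_alignment, principled_map_1
):
    aln = make_alignment(("a", "TTNTAATTA"))
    result = degenerate_alignment(aln, principled_map_1)
    assert result.alignment.records[0].seq == "TTNTAAYTR"
    row = result.report[0]
    assert (row["ambiguous"], row["stop"], row["degenerated"]) == (1, 1, 1)


def test_degenerate_alignment_idempotent(make_alignment, principled_map_1):
    aln = make_alignment(("a", "TTACTCAGATCAAGC"), ("b", "CTGTTTCGCAGTTCC"))
    once = degenerate_alignment(aln, principled_map_1).alignment
    twice = degenerate_alignment(once, principled_map_1).alignment
    assert [r.seq for r in twice] == [r.seq for r in once]


def test_degenerate_alignment_preserves_translation(make_alignment):
    code = get_code(2)
    aln = make_alignment(("a", "TTACTCAGACGATGG"))
    for mode in ("principled", "third_only"):
        out = degenerate_alignment(aln, build_map(code, mode)).alignment
        assert translate(out.records[0].seq, code) == translate(
            aln.records[0].seq, code
        )


def test_degenerate_alignment_frame_and_partial(make_alignment, principled_map_1):
    aln = make_alignment(("a", "GTTACT"))
    with pytest.raises(ValueError, match="frame"):
        degenerate_alignment(aln, principled_map_1, frame=3)
    out = degenerate_alignment(aln, principled_map_1, frame=1, on_partial="keep")
    assert out.alignment.records[0].seq == "GYTRCT"
    with pytest.raises(ValueError, match="divisible by 3"):
        degenerate_alignment(aln, principled_map_1, frame=1)


def test_degenerate_alignment_gap_masking(make_alignment, principled_map_1):
    aln = make_alignment(("a", "A-GTTA"))
    out = degenerate_alignment(aln, principled_map_1, gap_codon="mask")
    assert out.alignment.records[0].seq == "---YTR"


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ACGT", "RYRY"),
        ("R", "R"),
        ("M", "N"),
        ("Y", "Y"),
        ("A-C.T?", "R-Y.Y?"),
    ],
)
def test_ry_recode(seq, expected):
    assert ry_recode(seq) == expected


@settings(derandomize=True, max_examples=100)
@given(st.text(alphabet="ACGTRYMKWSBDHVN-.?", max_size=30))
def test_ry_recode_idempotent(seq):
    assert ry_recode(ry_recode(seq)) == ry_recode(seq)


def test_ry_recode_rejects_invalid():
    with pytest.raises(ValueError):
        ry_recode("AXC")
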