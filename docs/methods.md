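# Methods

## The problem

An in-frame codon alignment carries two signals that are not
proportional to divergence time. First, base composition: lineages can
converge on similar nucleotide frequencies (C-rich mitochondrial
genomes, AT-rich parasite genomes) through shared mutation or
selection pressure, and distance or likelihood methods that assume a
stationary process read that convergence as relatedness. Second,
nucleotide-versus-protein conflict: in most genetic codes some
synonymous codons are farther apart at the nucleotide level than they
are from nonsynonymous codons. Standard-code examples: Leu TTA/TTG are
one transition from Phe TTC/TTT but two changes including a
transversion from Leu CTC/CTT; Arg AGA/AGG are one transition from Ser
AGC/AGT but a transversion away from Arg CGC/CGT. Mitochondrial code
reassignments create more cases: Gly TGA vs Trp TGG (table 25), Lys
AGG vs Ser AGA (tables 24 and 33), Gly AGR vs Ser AGY (table 13).

Codon degeneration rewrites codons as IUPAC ambiguity patterns so that
synonymous codons become identical or maximally similar, removing both
signals at once while keeping the alignment usable by standard
phylogenetic software (which treats ambiguity codes as partial
information).

## The degeneration rules

All modes operate on codon *blocks*: synonymous codons of one amino
acid sharing positions 1–2 (Leu = {TTR block, CTN block}; blocks are
per amino acid, so ATG Met and ATH Ile are distinct blocks despite the
shared prefix).

- **third_only.** Each codon's third position is replaced by the
  minimal IUPAC cover of the thirds present in its block. Positions
  1–2 are untouched. This mode removes third-position composition bias
  only.
- **principled.** Starts from third_only. For each amino acid with
  several blocks, block pairs whose prefixes differ at exactly one
  position are candidates for merging: the differing position is
  degenerated *in the smaller block only*, to the cover of both
  blocks' bases at that position — and only if the resulting pattern
  still expands exclusively to codons of that amino acid (the
  *conceptual principle*: a degenerate pattern must never span two
  amino acids, otherwise the alignment loses its protein identity).
  Blocks differing at both prefix positions are left independent
  (Ser TCN / AGY). With more than two mergeable blocks, pairs are
  processed in ascending order of smaller-block size, re-checking the
  principle after each change. Results for the standard code:
  Leu → YTR + CTN, Arg → MGR + CGN; table 25 Gly → KGA + GGN; tables
  24/33 Lys → ARG + AAR; table 13 Gly → RGR + GGN.
- **full_union.** Every codon of an amino acid maps to the
  position-wise cover of the union over all its codons (Leu → YTN,
  Arg → MGN). This historical variant violates the conceptual
  principle — YTN covers Phe TTY, MGN covers Ser AGY — and
  `report_principle_violations` enumerates exactly where. It is
  provided for comparison, not recommended use.

Design choices where the rules are silent:

- **Equal-size block pairs.** The smaller-block rule does not decide
  ties. Both blocks are degenerated at the differing position if and
  only if both resulting patterns preserve amino-acid identity;
  otherwise neither is, and the event is logged. This ranks the
  conceptual principle above the operational rule.
- **Stop codons** map to themselves in every mode and never merge with
  sense blocks.
- **Input codons already containing ambiguity** are passed through
  untouched and tallied in the run report: their intended amino acid
  may be undefined, so degenerating them could launder uncertainty
  into a definite pattern.
- **Gap-containing codons** are passed through by default
  (`gap_codon="mask"` rewrites them to `---`). The reading frame is
  column 1; a frame offset of 1 or 2 passes the leading columns
  through unchanged.
- RNA input is normalized to DNA (U → T) on read.

Properties guaranteed by construction and tested exhaustively for all
27 registered codes: principled and third_only patterns never span
amino acids; each codon lies in its own pattern's expansion;
`translate(degenerate(x)) == translate(x)`; third_only ⊆ principled ⊆
full_union expansion-wise; alignment-level degeneration is idempotent.
Note that the stronger closure property — every codon covered by a
pattern maps to that same pattern — holds for third_only but *cannot*
hold for principled maps: YTR covers CTA, which belongs to the CTN
block. Idempotence at alignment level still holds because patterns
containing ambiguity are never re-degenerated.

## The Smin.S / Smax.NS diagnostic

Base pairs score match = 30, transition (A↔G, C↔T) = 0, transversion
= −30; a pair involving ambiguity symbols scores the arithmetic mean
over the Cartesian product of the two expansions (score(A,R) = 15;
score(N,N) = −7.5). Codon scores are the position-wise sum, which
equals the mean of unambiguous codon scores over all expansion pairs.
All arithmetic is exact `fractions.Fraction`; displayed integers are
floored toward −∞ (22.5 → 22, −7.5 → −8), the convention under which
the published diagnostic tables are reproduced cell for cell. The
transversion value is not printed in the source tables; −30 is fixed
by the undegenerated Arg case (AGA vs CGC = −30 + 30 − 30 = −30) and
verified against every other cell.

For a family case (patterns labeled with amino acids), Smin.S is the
minimum score over synonymous pairs — including each ambiguous pattern
paired with itself, whose self-score is the mean over expansion pairs
and measures within-pattern heterogeneity (this is what makes the
full-union Leu case come out Smin.S = Smax.NS = 37) — and Smax.NS is
the maximum over nonsynonymous pairs. Conflict is resolved when
Smin.S > Smax.NS. Scores are scheme-parameterized; every score scales
linearly with the scheme.

One illustrated case (table 24, Lys vs Ser) is only reproducible with
the Ser side as the literal codon AGA shown in the source figure; the
map itself degenerates the code-24 Ser block {AGA, AGC, AGT} to AGH by
the operational rule. The table-reproduction tests therefore feed
explicit patterns for that case; all other cases' patterns come
straight out of the maps.

## Serine site filter

Ser is the one family no degeneration can fix: its TCN and AGY blocks
differ at both prefix positions, and AGY is a transition away from Arg
AGR. Codon columns at which some sequences carry TCN and others AGY
inject pure nucleotide-level conflict, so the filter lists such
columns and removes them (or keeps only them, to measure how much
signal they carry). Matching is on literal bases (TC·, AG[CT] with the
third position allowed to be an ambiguity code covered by {C,T}), so
it works identically before and after degeneration; a
`by_translation` variant matches any Ser-translating codon and
classifies it by prefix. Codes in which Ser is not exactly TCN + AGY
(5, 9, 12, 14, 21, 24, 33 — detected from the table, not hard-coded)
are refused without `force`, since matched codons there may not be
serines. Reported site indices are 1-based codon positions.

## Composition diagnostics

Per-sequence base proportions and GC3 exclude gaps and ambiguity
symbols from denominators and are exact rationals. Codon-block usage
(e.g. P_CTN, the fraction of Leu codons in the CTN block) is pooled
across a sequence group — one proportion per group from summed counts,
not a mean of per-sequence ratios. Codons are assigned to blocks by
literal membership or by matching the block's third_only/principled
pattern, so usage computed on degenerated output equals usage on the
original input.

## Synthetic CDS generator

The generator emulates the compositional contrasts that motivate
degeneration — lineages differing in GC3 and Leu-block usage while
encoding comparable proteins — without simulating evolution along a
tree. Per codon: an amino acid is drawn uniformly over the code's
repertoire (stops excluded, so sequences never contain internal
stops); for Leu the block is CTN-type with probability
``leu_ctn_bias`` (when the code has the CTN/TTR contrast; otherwise
uniform with a warning); the third position is drawn from the block's
G/C thirds with probability ``gc3_bias`` when the block offers both
classes. Blocks whose thirds are all one class (Met ATG, Trp TGG)
cannot respond to the dial and pull realized GC3 toward their class by
roughly (2/20)·|1 − gc3_bias| under the standard code (≈ +0.02 at
gc3_bias = 0.8), which the parameter-recovery tests account for with a
0.03 tolerance at 10⁴ codons. A single `numpy` generator seeded from
the `CdsSimSpec` makes output byte-identical across runs.

Because sequences are i.i.d. across sites and lineages, passing tests
show correctness of the transforms and diagnostics, not phylogenetic
performance on real data: the generator has no tree, no rate
variation, no indels, and no within-site dependence.

## Problem sizes and scope

The test suite runs in seconds: exhaustive 64-codon enumeration over
all 27 codes for the map invariants, 10⁴ random pattern pairs against
a brute-force expansion-averaging oracle, and 10⁴-codon simulations
for parameter recovery. The study-scale quantities from the original
mitochondrial analyses — the 40 and 14 mixed UCN/AGY sites in the
mammal and ratite supermatrices, group P_CUN values near 0.88, aligned
gene lengths, and all tree topologies and support values — depend on
GenBank genome retrieval, external alignment (MAFFT) and tree
inference (PhyML), and are out of scope here; the package produces the
inputs such an analysis would consume (degenerated, filtered,
concatenated FASTA plus partition tables).
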