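# codondegen

Codon degeneration and codon-alignment diagnostics for deep phylogenetics.

Animal mitochondrial genes evolve fast and accumulate two kinds of
non-historical signal that mislead tree inference: **compositional
bias** (distant lineages converging on similar base frequencies) and
**conflict between nucleotide and amino-acid similarity** — some
synonymous codons are *less* similar to each other at the nucleotide
level than to nonsynonymous codons. In the standard genetic code the
Leu codons TTA/TTG are one transversion away from the four CTN Leu
codons but only one transition away from the Phe codons TTC/TTT, so a
nucleotide-level analysis sees a Leu↔Phe affinity that the protein
does not have.

`codondegen` transforms in-frame codon alignments before tree
inference to remove those signals, for **every NCBI genetic code**
(translation tables 1–6, 9–16, 21–33):

- **Principled codon degeneration** — replace codons with IUPAC
  ambiguity patterns so that synonymous codons become maximally
  similar *without any pattern ever spanning two amino acids*. Within
  each codon block (synonymous codons sharing positions 1–2) the third
  position is degenerated to its minimal cover; between two blocks of
  one amino acid whose prefixes differ at a single position, that
  position is degenerated **in the smaller block only** (Leu → YTR +
  CTN, Arg → MGR + CGN; Ser's disjoint TCN/AGY blocks stay apart).
  The degenerated alignment still translates to the original protein.
- **Third-position-only** and **full-union** (Leu → YTN, Arg → MGN)
  comparison modes, plus a report of where full-union patterns violate
  the amino-acid-identity principle.
- **RY recoding** (purine/pyrimidine collapse) for non-coding sequence.
- The **Smin.S / Smax.NS diagnostic**: with a match/transition/
  transversion scheme of 30 / 0 / −30 and ambiguity symbols scored as
  the average over their expansions (score(A,R) = (30+0)/2 = 15),
  Smin.S is the minimum alignment score among synonymous codons and
  Smax.NS the maximum among nonsynonymous ones; a degeneration
  resolves the conflict at a family when Smin.S > Smax.NS.
- A **serine site filter** (remove or keep-only codon columns carrying
  both TCN and AGY serines), **composition diagnostics** (P_A…P_T,
  GC3, and codon-block usage such as P_CTN for Leu), **codon
  threading** of CDS onto a protein alignment, supermatrix
  **concatenation** with partition tables, and a seeded **synthetic
  CDS generator** with controllable GC3 and Leu-block bias.

## Worked example

Degenerate a two-sequence standard-code alignment (five codons:
Leu, Leu, Arg, Ser, Ser per row):

```sh
$ printf '>human\nTTACTCAGATCAAGC\n>mouse\nTTGCTTCGCAGTAGC\n' > demo.fasta
$ codondegen degen --code 1 --mode principled \
    --in demo.fasta --out degen.fasta --report report.tsv
degen: 2 sequences, 15 columns, mode=principled, code=1 -> degen.fasta
$ cat degen.fasta
>human
YTRCTNMGRTCNAGY
>mouse
YTRCTNCGNAGYAGY
```

The synonymous Leu codons TTA/TTG and CTC/CTT are now the identical
columns YTR and CTN in both rows; Arg AGA became MGR (one ambiguous
position away from mouse's CGN) while the Ser codons stay in their own
TCN/AGY blocks. Scoring the degenerated Leu/Phe family shows the
conflict is gone:

```sh
$ printf 'pattern\taa\nYTR\tL\nCTN\tL\nTTY\tF\n' > case.tsv
$ codondegen score --case case.tsv
Smin.S	75/2	37
Smax.NS	45/2	22
conflict_resolved	True
```

The worst synonymous pair (YTR vs CTN) scores 37.5 — floored to 37 —
while the best nonsynonymous pair scores only 22.5 → 22, i.e.
Smin.S > Smax.NS. Before degeneration the same family has Smin.S = 0
and Smax.NS = 60. The same library calls are available in Python:

```python
>>> from codondegen import build_map, get_code, family_stats, FamilyCase
>>> build_map(get_code(1), "principled")["TTA"]
'YTR'
>>> family_stats(FamilyCase.from_groups({"L": ["YTR", "CTN"], "F": ["TTY"]}))
FamilyStats(smin_s=Fraction(75, 2), smax_ns=Fraction(45, 2), smin_s_floor=37, smax_ns_floor=22)
```

Other subcommands: `codes`, `map`, `violations`, `ser-filter`,
`compose`, `thread`, `concat`, `simulate` (see `codondegen --help`).

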