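# Methods

This note records the models, rules and numerical choices behind phiskit, and
what the synthetic-data tests do and do not demonstrate.

## The discovery model

PHIS elements are cut-and-paste DNA transposons: a terminal-inverted-repeat
(TIR) bounded element that, on insertion, leaves a group-specific signature
at the target site. The pipeline mirrors how such elements are curated by
hand: find transposase homology, recruit the homologous copies, let the
multiple alignment of flank-extended copies reveal where the element ends,
then read the TIRs and target-site duplications (TSDs) off the copies.

### Translated homology search

Six-frame translations of the genome are scanned with exact 4-mer protein
seeds against the query set; two seeds on one diagonal within 40 residues
trigger an ungapped X-drop extension (BLOSUM62, X = 25). Significance uses
the ungapped Karlin–Altschul formula `E = K·m·n·e^{-λS}` with λ = 0.318,
K = 0.13, m the query length in residues and n the genome length in bases;
hits with `E < 1e-4` (default) are kept. Overlapping hits of one query are
unioned into a locus, and loci from different queries that overlap by ≥ 50%
collapse to the best-scoring one. Gapped refinement is deliberately omitted:
locus boundaries come from the union of seed extensions, which is accurate to
a few codons whenever divergence is substitution-dominated; an adapter for an
external search engine can be slotted in at the same interface if frameshifted
queries matter.

### Copy recruitment

A nucleotide probe recruits copies with exact 11-mer seeds chained into
diagonal clusters (drift ≤ 30, gap ≤ 400, ≥ 2 seeds). Each cluster window is
aligned with edlib (infix mode); the unit-cost path is rescored with the
classical +1/−2 match/mismatch and −5/−2 affine gap scheme, trimmed to its
maximum-scoring contiguous segment, and the ends are polished by greedy exact
extension (edlib's edit-distance optimum is not unique and may trade terminal
matches for mismatches). Identity is matches over alignment columns, gaps
included. The membership thresholds are strict inequalities — `E < 1e-5`,
length > 50 bp, identity > 0.80 — so copies at exactly 80.0% identity or
exactly 50 bp are excluded. Fragment re-alignments of an already-found locus
are removed by score-ranked overlap resolution (a contained fragment never
outscores the hit containing it).

### Element boundaries

Copies are extended 2 kb each side, oriented to one element strand, and
aligned with MAFFT (`--retree 2 --maxiterate 0`, single thread; at most 15
copies, longest cores first — consensus from any ≥ 10-copy subset differs
negligibly). Per column, the consistency score is occupancy × majority
agreement; columns under 50% occupancy (single-row insertions) are set aside,
the score is smoothed with an 11-column mean, and the longest run ≥ 0.6 and
≥ 50 columns is the rough element.

Conservation alone cannot place the exact edges: target-site bases are
conserved across copies (the T and A of `TWA`, ISL2EU's `A AT`/`AT T`, Spy's
`AAA`/`TTT`) and would be absorbed into the element. The edges are therefore
refined over a ±15-column window by junction evidence: a candidate edge pair
must be supported by ≥ 50% of spanning copies (identical left-flank suffix and
right-flank prefix of some length L ≤ 10, or a Spy-style join across a split
of `AAATTT`), and that support must be significant against its chance rate
(binomial tail < 1e-4 at a per-copy chance of 0.25^L) — a 1 bp flank match
recurs in a quarter of copies by chance and only counts when near-unanimous.
Among supported candidates the score
`terminal-inverted-repeat score + min(L, 3)` decides, where the repeat score
is the per-row mean of the best end-anchored matches-minus-mismatches.
Scoring the repeat per copy, not on the column consensus, stops randomly
agreeing flank columns from faking a repeat. The TSD bonus resolves the parse
ambiguity of palindromic targets — reading `TWA + element + TWA` as
`W + [A·element·T] + W` gains one complementary terminal pair but loses two
duplicated bases — and its 3 bp cap encodes the biological prior that PHIS
duplications are at most 3 bp, which is exactly how the `C|TNA|G` site of a
`GG…CC`-terminated element is settled in favour of a 3 bp `TNA` duplication
rather than a 5 bp `CTNAG` one (the alternative is still reported on the TSD
model). Ties go to the longer element, i.e. the maximal terminal repeat:
an element whose palindromic termini also read as a short TSD keeps its
termini. This refinement is the package's automated replacement for manual
boundary curation.

The consensus is majority-rule over the element columns (≥ 50% occupancy,
ties by the fixed order A < C < G < T).

### Structure models

*TIRs* are found end-anchored only: the 5′ prefix is compared position by
position against the reverse complement of the 3′ suffix, and the best
repeat length maximizes matches − mismatches subject to a mismatch fraction
≤ 0.2 and length within [5, 1100]. A copy is *full-length* when both termini
match the family TIRs with ≤ 2 mismatches.

*TSDs* are inferred from full-length copies (≥ 3 required): for each
L = 1..10, support is the fraction of copies whose left flank ends with the
same L-mer their right flank starts with (exact by default); the chosen
length is the largest L with support ≥ 0.5. The consensus is the minimal
IUPAC cover of bases with per-position frequency ≥ 0.2; a base just outside
the duplication is reported as conserved when its frequency is ≥ 0.8, and
conserved bases on both sides are echoed as an alternative longer reading of
the duplication. TSD-less families are tested for the Spy preference: a copy
supports it when its flanks join across some split of `AAATTT`.

*Empty sites*: the pre-insertion locus is reconstructed as 30 bp of left
flank plus the right flank with the leading duplicated TSD removed — one
copy of the target retained — and searched against the genome (identity
≥ 0.85, ≥ 15 bp on each side of the junction, matches overlapping family
copies excluded). A hit is a paralogous empty site confirming the cut
mechanics.

*Logos* are emitted as matrices: per-position base frequencies and
information content `2 − H` bits (Shannon entropy, no small-sample
correction, since the matrices feed plotting tools that apply their own).

### ORFs, domains, activity

ORFs are Met-to-stop, ≥ 100 codons, on all six frames; overlapping same-frame
ORFs reduce to the longest, and "intact" requires the terminating stop to be
present. Domains are called with small PSSMs shipped as TSV fixtures
(BLOSUM62 row per consensus position; threshold 0.55 × self-score, placed
between diverged true instances and shuffled decoys); the DDE call further
requires D, D and E residues at the triad columns ± 1. A family is
*potentially active* when intact ORFs realise its group's layout — two
co-oriented non-overlapping ORFs with the expected domains for all groups
except Spy, whose single DDE ORF suffices. The co-orientation/non-overlap
requirement keeps chance antisense open frames from standing in for a
disrupted accessory ORF.

### Classification

The group is a function of the TSD evidence, in precedence order:
outer-conserved signatures first (`A|AT|T` → ISL2EU; `C|TNA|G` → NuwaII,
which must precede the plain patterns because TWA ⊂ TNA), then plain 3 bp
patterns (TWA → PIF/Harbinger, CWG → NuwaI, ANT → Pangu), then
no-duplication + Spy-motif support ≥ 0.5 → Spy. Compatibility means every
observed per-position base set is contained in the pattern's IUPAC set, so a
sampled `TAA` classifies as PIF/Harbinger with an ambiguity note. Families
matching nothing stay "unclassified" — never force-assigned — and an ORF
layout conflicting with the group expectation is noted but does not override
the TSD rule.

## The synthetic genomes

The generator emulates the study conditions the pipeline targets. Background
sequence is i.i.d. at a configurable GC content (default 0.42). Each family
plants `n_copies` (default 20) at group-target motif occurrences, pairwise
≥ 500 bp apart, with the exact cut mechanics of its group; a seeding pass
writes extra target motifs when a composition-starved background lacks them.
Elements are TIR + spacers + real ORFs: proteins are built from the shipped
domain profiles with per-group conservative variants (≈ 30% of non-catalytic
positions substituted, each group toward a different BLOSUM62 partner) and
back-translated under a per-group codon-usage bias. Both choices keep
homologous domains of different groups far below the 80% nucleotide-identity
family threshold, as separate transposase lineages should be, while the
protein-level similarity still drives the homology search. Defaults per
family: element 2,500 bp, divergence 1% (substitutions only; indels
config-exposed and off by default), 20% of copies truncated at a uniformly
drawn terminus, random strand, group TIR defaults within the published
ranges (PIF 14, ISL2EU 16, Spy 15, Pangu 20, NuwaI 24 with `GGG`, NuwaII 18
with `GG`; Spy's lead base is set to `G`, a choice the source literature
leaves open). Four bases inside each TIR are pinned to `C` so the planted
repeat ends exactly where the truth says it does. An optional segmental
duplication plants a target-motif-bearing block twice and forces one
insertion into one copy, producing a guaranteed paralogous empty site.

What this does *not* emulate: nested insertions, MITE-style non-autonomous
derivatives, codon-usage realism, flank homoplasy, assembly gaps, or
divergence heterogeneity along the element. Passing tests therefore show the
method's correctness under clean cut-and-paste mechanics, not its recall on
degraded real repeats.

## Problem sizes and determinism

The default fixture is a 1 Mb genome with one family per group and 20 copies
each; unit tests use 120–500 kb genomes with 4–8 copies per family. These
sizes give every stage tens of copies to work with while a full pipeline run
completes in well under a minute. All randomness flows from
`numpy.random.default_rng(seed)`; the pipeline itself is deterministic, and a
rerun on identical inputs reproduces every output file checksum.

## Known limitations

* Frameshifted or heavily gapped transposase copies weaken the translated
  search (ungapped extensions only).
* Families with < 3 full-length copies get no TSD model and stay
  unclassified, as in manual curation.
* The boundary refinement assumes TIR-bearing elements; TIR-less repeats fall
  back to the consistency-score block.
* Cross-family recruitment between highly similar same-group families merges
  them, consistent with the 80%-identity family definition.
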