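# Methods

`beante` re-implements, at desk scale, the combined structure- and
homology-based transposable-element (TE) annotation workflow used for the
common bean (*Phaseolus vulgaris*) genome: de novo discovery of LTR
retrotransposons from paired direct repeats, translated homology search for
transposase/reverse-transcriptase domains, rule-based superfamily
classification, single-linkage family clustering into a representative
library, EST-based expression summaries, screening for extra ORFs
(envelope-like and antisense ORF2 arrangements), and neighbor-joining
phylogenetics of RT domains.  Because the original inputs (a 521-Mb
assembly and ~148k GenBank ESTs) are not desk-scale, every stage is
exercised and validated on synthetic genomes with planted, exactly-known
elements.

## Synthetic genomes

The simulator plants elements of nine superfamilies (Ty1-copia, Ty3-gypsy,
CACTA, hAT, MULE, PIF/Harbinger, Helitron, LINE, SINE) into an i.i.d.
background at a configurable GC content (default 0.35, a typical plant
genomic value).  Each element carries the structural hallmarks its
annotation relies on:

- **TSD** — a literal duplication of the host sequence at the insertion
  point, written on both flanks; lengths follow the superfamily rule table
  (LTR retros 4–6 bp, CACTA 2–3, hAT 8, MULE 9–11, PIF/Harbinger 3,
  LINE 5–29, SINE 5–15, Helitron none).
- **Termini** — TG…CA LTRs (length drawn from 200–600 bp by default),
  CACTA/ATGTG motifs (the 3′ motif is configurable between the literal
  `ATGTG` and the canonical reverse complement `TAGTG`), terminal inverted
  repeats (hAT 15 bp, MULE 60 bp, PIF/Harbinger 14 bp), and ≥12 bp polyA
  tails on LINEs/SINEs.
- **Coding regions** — each coding superfamily embeds a fixed 180-aa
  synthetic domain peptide (one per superfamily, shipped in
  `beante.domains`) inside an ATG…stop ORF padded with random sense
  codons.  The peptide is encoded with *random synonymous codons per
  family consensus*: families conserve the domain at the protein level
  while drifting apart in DNA, so family clustering cannot ride on a
  verbatim shared DNA block while the translated search still sees the
  domain exactly.
- **Extra ORFs** — configurable numbers of Ty1-copia families carry a
  sense extra ORF downstream of the retrotransposase (envelope-like
  layout) and Ty3-gypsy families an antisense extra ORF between the
  retrotransposase ORF and the 3′ LTR (ORF2 layout).

Divergence is substitutions-only.  Per element, a divergence is drawn
(default 0–10 % from the family consensus; LTR pairs additionally diverge
0–5 % from each other, so an undiverged pair is exactly identical —
the "recent insertion" signature).  Two deliberate departures from a pure
mutation model:

- substitutions that would create a stop codon inside a planted reading
  frame are re-drawn among the remaining bases (purifying selection on
  young, potentially active elements), and
- the diagnostic terminal bases (TG/CA dinucleotides, CACTA motifs, the
  outermost TIR bases, polyA tails) are exempt from mutation.

Both choices make the recovery benchmarks measure detector behaviour
rather than motif erosion; really degenerate elements would simply not be
"intact" in the sense the benchmarks target.  The generator does not
simulate nested or fragmented insertions, solo LTRs, indels, isochores or
repeat shadows — recovery rates on real genomes will be lower than on
these synthetic ones for exactly those reasons.

ESTs are sampled as (default) 200–500 bp reads, a configurable fraction
(default 0.3) from planted element bodies and the rest from the non-TE
background, with 1–2 % substitution error and random strand; every read's
description records its true source.

## LTR detection

`find_direct_repeat_pairs` is a seed-and-extend detector: exact 15-mer
seeds within the distance window are grouped by diagonal, clustered, and
extended by an X-drop score (+1 match / −3 mismatch, drop 12) trimmed to
the best-scoring endpoints.  The stiff mismatch penalty makes spurious
outward extension into the flanks die quickly while a ≤10 %-diverged LTR
interior still scores forward.  Candidate pairs must satisfy the study's
geometry — both repeats ≥50 bp, internal distance ≥50 bp, total ≤15 kb
(chosen to cover the largest reported element, 13.6 kb, with margin) —
and a global-alignment identity ≥80 %.

Score-trimmed boundaries are only accurate to a few bp when the repeat
termini carry mismatches, so a refinement step then snaps the outer
boundaries (window ±15 bp) to joint evidence: a TG at the element start
and a CA at the end **in both repeat copies**, plus a flanking TSD in the
4–6 bp range.  Requiring the dinucleotides in both copies is what makes
chance parses vanish: when a TSD itself ends in TG (or the LTR tail reads
CACA) a ±2 bp-shifted parse is otherwise fully consistent, and the longer
TSD is then the correct tiebreak (the shifted parse carries a truncated
duplication).  Refinement requires the full evidence triple; repeats that
are not LTR-like are left at their maximal-extension boundaries, which is
also the mode (`refine_boundaries=False`) used to verify the detector
against an exhaustive diagonal-scan oracle.

`inspect_candidate` automates the manual inspection step: boundary shifts
of ≤3 bp that improve joint TG…CA + TSD evidence, TSD search in 20-bp
flank windows, and rejection of tandem arrays (the left repeat aligns
locally into the internal region with a score ≥ half its length —
identical tandem units score their full length there, unrelated sequence
stays near the random noise floor).  Overlapping candidates are resolved
greedily by (identity, length), leftmost on ties.  Accepted candidates
with 100 % LTR identity are flagged as recent insertions.

Measured on 288 planted intact elements (twelve 400-kb genomes,
divergence ≤10 %), 99.3 % are recovered with both boundaries within
±3 bp and the exact TSD; element-free 1-Mb controls yield zero accepted
candidates.

## Translated homology search

A TBLASTN-like stage: the genome is translated in six frames (stops break
segments), exact 3-aa seeds with a two-hit rule on a shared diagonal
trigger a windowed Smith–Waterman extension (BLOSUM62, gap open −11 /
extend −1, via Biopython's PairwiseAligner).  Scores are converted to
bits as raw/2 (BLOSUM62 is in half-bit units) and E-values use the
conservative fixed-parameter bound E = m·n·2^(−bits) with m the total
translated residues and n the query length — deterministic and adequate
for thresholding at the study's E < 1e-20, with the cutoff configurable.
Overlapping hits to the same query are merged keeping the best.  10-kb
flanks are extracted around hits for boundary definition, clipped at
sequence ends.

## Superfamily classification

The rule table encodes one entry per superfamily: CACTA by its terminal
motifs plus 2–3 bp TSD; MULE, hAT and PIF/Harbinger by TIRs (≥40, ≥10 and
≥10 bp respectively, at ≥80 % identity) plus their diagnostic TSD
lengths; LINE/SINE by a polyA tail plus a 5–29 bp TSD (SINE additionally
≤700 bp and non-coding); Helitron by homology only (no TSD — structural
5′TC/3′CTRR detection is deliberately omitted).  TSD matching is exact;
the TSD is defined as the longest common string that is simultaneously a
suffix of the left flank and a prefix of the right flank, with length in
the rule's range.

`classify_candidate` slides each region end by ≤50 bp to maximize joint
evidence, tests both strands, and prefers structural evidence
(motif > TIR > polyA) over homology alone; regions with neither are
"unclassified".  `locate_element` performs the wider search used for
homology-discovered elements, scanning the 10-kb flank window for
rule-consistent boundaries enclosing the hit (motif pairs, TIR seeds, or
polyA runs anchoring a TSD probe search).  `find_mite_like` discovers
short non-coding TIR elements de novo; because it has no transposase
support, its defaults are stricter than the classification rules (12 bp
TIR, ≥3 bp non-homopolymer TSD) — chance inverted 10-mers with 2-bp
"TSDs" are otherwise abundant in megabase sequence.  De novo SINE
discovery is not attempted (the polyA-only signature is too weak without
a copy-number argument); SINE regions supplied by the user classify
normally.

## Families and the library

Pairwise similarity is an infix (semi-global) edit-distance alignment of
the shorter element against the longer, on both strands, computed with
edlib; identity is matched columns over alignment columns.  Aligning the
*whole* shorter sequence is what the coverage threshold is for — a short
shared domain cannot by itself carry two unrelated multi-kb elements over
the similarity bar.  Families are single-linkage connected components
over the >70 % identity graph (the similarity leg of the 80-80-80
tradition; the threshold is configurable), ordered by descending size
then leftmost coordinate, with Wicker-style three-letter prefixes
(RLC/RLG/RLX/RIL/RSX/DTC/DTA/DTM/DTH/DHH).  The representative is the
intact (complete) member with the longest span, falling back to the
longest fragment, ties to the smallest id.  The library FASTA uses
RepeatMasker-compatible `family#Class/Superfamily` headers, and the
summary table computes class subtotals and the grand total from the
category counts — totals are never stored.  Per-family chromosomal
distributions count member midpoints in non-overlapping windows (default
100 kb).

## EST expression

Each EST is aligned (both strands) against every library representative
by 11-mer seeded local alignment (+1/−2, gap open −2 / extend −1) around
the densest diagonal; the single best hit below E = m·n·2^(−S) < 1e-5
(m = total library length, n = EST length) assigns its superfamily, ties
going to the earliest library record (logged).  Percentages are printed
to one decimal with half-up rounding — the printed precision of the
study's numbers — against a caller-supplied total that need not equal the
sum of category counts.  The DNA-transposon subtotal covers Helitron,
CACTA, MULE, hAT and PIF/Harbinger.

## ORF layouts

ORFs are called stop-to-stop (ATG-initiated, ≥150 codons by default — the
smallest reported extra ORF is 211 aa — no splicing; TE coding regions
are treated as intronless) in all six frames; within a frame the earliest
ATG after the previous stop defines the ORF.  ORFs overlapping an RT
domain hit take the retrotransposase role, their union span accommodating
frameshift-split polyproteins; element orientation is the strand of the
longest such ORF (shorter overlapping calls on the opposite strand are
translation shadows).  An extra ORF whose midpoint lies downstream of the
retrotransposase ORF's 3′ end — toward the 3′ LTR in element orientation
— classifies the element: env-like when sense (the longest downstream
extra decides), ORF2 when antisense; no extra ORF means
retrotransposase-only, and no anchored ORF at all means no-coding.
Whether extra ORFs must be ATG-initiated is not recorded in the source
material; this implementation requires ATG.

## RT phylogenetics

Distances are p-distances from pairwise global alignment of RT peptides
(BLOSUM62; identities over aligned positions, terminal gaps excluded) —
a deliberate replacement for progressive MSA plus manual removal of
ambiguous regions; its effect on clade composition is not asserted.  The
neighbor-joining implementation is the classic Q-criterion algorithm with
Studier–Keppler distance updates; ties in Q break by the
lexicographically smallest pair of cluster tags (each cluster tagged by
its smallest descendant leaf), so the topology is invariant to input
order.  Negative branch estimates are clamped to zero and the clamped
total logged.  Trees are dendropy objects serialized as newick; on
additive matrices the tree reproduces the input distances to 1e-9 and
agrees topologically with dendropy's independent NJ.  Clade reports test
whether an annotated leaf set is exactly the leaf set of some edge
bipartition (unrooted monophyly) and report the smallest edge-bounded
cluster containing it.  No bootstrap is computed.

## Pipeline

`run_pipeline` executes simulate → LTR → homology → classify → families →
EST → ORF → phylogeny from one YAML config (unknown keys rejected), each
stage writing outputs plus a manifest of parameters, counts and file
hashes; re-running with unchanged parameters reuses cached stage outputs.
Element sets combine accepted LTR candidates (superfamily from enclosed
RT hits, else unclassified-LTR), homology-located elements, and MITE
candidates, with overlap priority in that order.  `recovery_report`
scores predictions against truth at ±3 bp boundary tolerance and reports
the exact-TSD rate and the Rand index of the family partition.

## Problem sizes and validation

The test suite and the acceptance script run the recovery benchmark on a
1-Mb genome with 24 planted intact LTR elements plus a 1-Mb element-free
control; family recovery on a 400-kb genome with five 3-member families
(within-family consensus divergence 2–7 %, so pairwise ≤ ~14 %;
between-family similarity is background-level); and layout
classification on seven undiverged LTR elements (2 env-like, 2 ORF2, 3
plain).  Oracle checks (exhaustive diagonal repeat scan, pure-Python
Smith–Waterman, codon-walk ORF enumeration, four-point-condition and
path-length checks for NJ) run on ≤20-kb inputs.  These sizes exercise
every code path while keeping a full run in minutes on one CPU; the same
operations scale linearly in genome length.

## Known limitations

- No nested/fragmented element simulation or solo-LTR handling; the
  detector reports the outermost consistent pair and does not resolve
  nests.
- No indel mutation model; boundary-exact recovery is a fair test only
  under substitutions.
- Helitron annotation is homology-only; boundaries are fragment-level.
- E-values use a conservative fixed-parameter bound, not fitted
  Karlin–Altschul statistics; absolute E-values are not comparable to
  BLAST's, though the ranking is.
- The EST stage assigns whole reads to single categories; chimeric reads
  and TE-derived gene fragments are not distinguished.
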