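# beante

Transposable-element (TE) annotation toolkit modelled on the combined
structure- and homology-based workflow used to build the common bean
(*Phaseolus vulgaris*) transposon database — with a truth-tracked
synthetic-genome simulator so that every stage is testable end to end
without any external downloads.

TEs dominate plant genomes, and annotating them means juggling several
kinds of evidence at once. `beante` implements the full chain:

- **Synthetic genomes** (`beante.simulate`) — plants elements of nine
  superfamilies (Ty1-copia, Ty3-gypsy, CACTA, hAT, MULE, PIF/Harbinger,
  Helitron, LINE, SINE) with known coordinates, target-site duplications
  (TSDs), terminal motifs, LTR identities and ORF layouts, plus an EST
  pool with labelled sources.
- **LTR retrotransposon detection** (`beante.ltr`) — paired direct
  repeats found by k-mer seeding and X-drop extension (minimum LTR
  length 50 bp, minimum inter-LTR distance 50 bp), boundaries snapped to
  joint TG…CA + TSD evidence, and an automated inspection step that
  rejects tandem arrays and TSD-less candidates. 100 %-identical LTR
  pairs are flagged as recent insertions.
- **Translated homology search** (`beante.homology`) — a TBLASTN-like
  six-frame search of conserved transposase/reverse-transcriptase (RT)
  domain peptides (E < 1e-20 by default, 10-kb flank extraction).
- **Superfamily classification** (`beante.classify`) — terminal motifs
  (CACTA…ATGTG with 2–3 bp TSD), terminal inverted repeats with
  diagnostic TSD lengths (hAT 8 bp, MULE 9–11 bp, PIF/Harbinger 3 bp),
  polyA tails with 5–29 bp TSDs for LINEs/SINEs, homology-only
  Helitrons, and a MITE-style scan for short non-coding TIR elements.
- **Family clustering and the library** (`beante.families`) —
  single-linkage families over the >70 % similarity graph, intact or
  longest representatives, a RepeatMasker-style library FASTA, a
  Table-style category summary with computed totals, and per-family
  chromosomal distribution profiles.
- **EST expression** (`beante.est`) — best-hit classification of ESTs
  against the library at E < 1e-5 with per-superfamily counts and
  one-decimal percentages.
- **ORF layouts** (`beante.orfs`) — six-frame stop-to-stop ORF calling
  in LTR-element internal regions and classification into
  retrotransposase-only, envelope-like (sense extra ORF downstream of
  the retrotransposase) and ORF2 (antisense extra ORF between the
  retrotransposase and the 3′ LTR).
- **RT phylogenetics** (`beante.phylo`) — pairwise p-distances of RT
  peptides, an in-repo neighbor-joining implementation with
  order-invariant tie-breaking, newick output, and clade exclusivity
  reports.
- **Pipeline + CLI** (`beante.pipeline`, `bean-te`) — one-config
  orchestration with per-stage manifests and caching.

## Worked example

Percentage summaries follow the printed one-decimal convention. Given
per-superfamily EST counts and a stated total of 5,328 TE-related ESTs:

```python
from beante.est import summarize_est_hits, summary_frame

counts = {"Ty3-gypsy": 2633, "Ty1-copia": 546, "LTR-unclassified": 356,
          "LINE": 893, "Helitron": 322, "CACTA": 284, "MULE": 156,
          "hAT": 72, "PIF/Harbinger": 4}
print(summary_frame(summarize_est_hits(counts, 5328)).to_string(index=False))
```

```
               superfamily  count  percent
                     CACTA    284      5.3
                  Helitron    322      6.0
                      LINE    893     16.8
          LTR-unclassified    356      6.7
                      MULE    156      2.9
             PIF/Harbinger      4      0.1
                 Ty1-copia    546     10.2
                 Ty3-gypsy   2633     49.4
                       hAT     72      1.4
DNA transposons (subtotal)    838     15.7
```

Ty3-gypsy elements account for 49.4 % of TE-related ESTs and the five
DNA-transposon superfamilies together for 15.7 % — transcriptional
activity concentrated in the gypsy retroelements.

On the synthetic side, simulate a 1-Mb genome with 36 planted elements
and scan it for LTR retrotransposons:

```sh
$ bean-te simulate --out demo --seed 7
wrote 1000000 bp genome, 36 planted elements, 500 ESTs to demo
$ bean-te ltr-scan --genome demo/genome.fa --out demo_ltr
14 candidates, 14 accepted
$ head -4 demo_ltr/ltr_report.tsv
seq_id  start   end     ltr_identity    recent_insertion
chr1    102235  105162  97.81   False
chr1    260899  264179  96.2    False
chr1    288933  293043  98.17   False
```

All 14 planted LTR retroelements (6 Ty1-copia + 8 Ty3-gypsy) are
recovered; `ltr_identity` is the percent identity of the two LTR copies,
whose divergence dates the insertion (100 % would flag a recent one).
`demo/truth.gff3` holds the planted coordinates for comparison, and
`bean-te run --config pipeline.yaml` chains all stages with a recovery
report against that truth.

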