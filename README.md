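# rtscout

Reverse transcriptases (RTs) are widespread in bacteria and archaea far
beyond their textbook role in retroviruses: they power group II intron
mobility, retron anti-phage defense, diversity-generating
retroelements (DGRs), spacer acquisition in some CRISPR-Cas systems,
and abortive-infection (Abi) phage defense. `rtscout` finds RT genes
in genome or metagenome assemblies, assigns each one to an RT class,
and characterizes its genomic neighborhood — the flanking genes and
fused domains that often reveal what an RT is actually doing.

## Method

Prediction runs as a cascade:

1. **Candidate detection.** Every predicted protein is scanned against
   a library of class-specific profile models built from per-class
   alignments of the RT core domain (RVT_1). Hits at E ≤ 10⁻³ become
   candidates. Profiles are position-specific log-odds matrices
   (bits) with affine gap penalties; each profile carries a Gumbel
   null fitted to local-alignment scores of random sequences, so raw
   scores convert to E-values.
2. **Refinement.** Candidates are re-scanned against a broad domain
   library; a candidate with no RT-related domain there (e.g. a plain
   DNA-binding protein that weakly resembled one RT model) is a false
   positive and is dropped.
3. **Class assignment.** Hits are collapsed to the best E-value per
   class. One class only → assigned. Top class 10⁵-fold better than
   the runner-up → assigned. Otherwise the top three classes are kept
   and the query is placed on a reference tree of known RTs
   (least-squares distance placement): a leaf placement takes the
   leaf's class; an internal placement takes the distal subtree's
   majority class if ≥ 90% of its leaves agree. The placement
   confidence is the best edge weight, zeroed when the top two
   weights differ by < 0.25. A placement class consistent with the
   top-three profile hits becomes the final call; otherwise all
   candidate classes are reported.
4. **Neighborhood.** Up to two genes on each side of the RT are
   collected, walking outward and stopping at the first intergenic
   gap > 2 kb. The locus is annotated against the broad library;
   envelopes on the RT protein outside the RT domain are reported as
   fused domains. A CRISPR call with no nearby *cas* gene is
   downgraded to **CRISPR-like**.

Across predictions, `rtscout.stats` builds co-occurrence tables over
non-redundant RTs (90%-identity greedy clustering) and computes each
domain's *specificity score* for a class — that class's share of all
the domain's neighborhood occurrences.

## Worked example

The package ships a seeded generator that emulates the study design:
five RT class families, a reference tree, a broad domain library and a
three-contig genome with ten planted RTs (one CRISPR flanked by *cas*
genes, one without) plus a DNA-binding decoy.

```bash
python examples/01_find_rts_in_genome.py
```

```
gene                               planted  called       method        neighbors
contig0_4758_5807_+                GII      GII          evalue_ratio  -2,-1,+1,+2
contig0_11984_12994_+              Retrons  Retrons      evalue_ratio  -2,-1,+1,+2
contig0_22345_23391_+              DGRs     DGRs         evalue_ratio  -1,+1,+2
contig1_4176_5222_+                CRISPR   CRISPR       evalue_ratio  -2,-1,+1,+2
contig1_11055_12080_+              CRISPR   CRISPR-like  evalue_ratio  -2,-1,+1,+2
...
10 predictions, 10 matching the planted class
```

All ten plants are recovered with the planted class; the decoy and all
background genes are rejected; the cas-less CRISPR plant is reported
CRISPR-like; the third RT keeps only its in-range left neighbor
because the next gene sits behind a 3 kb gap. The other examples show
profile building and E-values (`02`), phylogenetic placement (`03`),
and neighborhood statistics (`04`), where a domain seen near 207
Retron, 2 GII and 1 UG7 RTs gets Retron specificity 207/210 → 0.99.

The same pipeline is available from the shell:

```bash
rtscout simulate fixture --seed 2
rtscout build-lib fixture/rt_alignments rtlib --kind rt
rtscout build-lib fixture/broad_alignments broadlib --kind broad
rtscout predict --genome fixture/genome.fasta --gff fixture/genes.gff3 \
    --rt-lib rtlib --broad-lib broadlib \
    --tree fixture/reference.nwk --leaf-classes fixture/leaf_classes.tsv \
    --ref-align fixture/reference_alignment.fasta -o out
```

which writes `predictions.tsv`, `predictions.gff3` and
`neighborhood.json`. Without a GFF, a naive six-frame ORF caller
stands in for a real gene finder (supply gene calls for real data).

## Layout

```
src/rtscout/      seqio, profiledb, search, detect, classify, phylo,
                  neighborhood, stats, synthetic, pipeline, cli
examples/         one short narrative script per capability
tests/            pytest suite with independent oracles
docs/methods.md   modeling choices, defaults, and limitations
```
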