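# sporescreen

Comparative-genomics screening for functional non-coding RNAs whose
**secondary structure** is conserved across the four fission-yeast species
(*Schizosaccharomyces pombe*, *S. cryophilus*, *S. octosporus*,
*S. japonicus*), for people who want to rank an annotated ncRNA pool by
structural conservation before committing to wet-lab knockouts.

Most ncRNA sequence conservation is weak even between close relatives, but
functional ncRNAs often keep their base-paired architecture: a substitution
on one side of a stem is tolerated when the partner base co-substitutes to
restore a canonical pair (G:C → A:U, etc.). The screen exploits exactly this
signal.

## What the pipeline does

1. **Catalog** — parse GenBank chromosome annotation and extract every gene
   typed `misc_RNA` (the ncRNA pool), categorize each as
   tRNA/rRNA/snRNA/snoRNA/pseudogene/unconventional, and classify overlaps
   with protein-coding features from GFF3 (antisense-to-CDS vs CDS-free vs
   UTR-only).
2. **Conservation filter** — ingest pairwise whole-genome alignments (MAF)
   against each related species; keep genes with ≥ 50 aligned exonic bases
   in at least one species and assemble per-gene cross-species families.
3. **Structure screen** — align each family (reference-anchored star
   alignment, or ingest an external alignment), digest alignments into
   120-column windows overlapping by 80 columns, and score each window on
   four criteria:
   * thermodynamic z-score `z = (E − μ_shuffle) / σ_shuffle` (stability),
   * structure conservation index `SCI = E_consensus / mean(E_individual)`
     where the consensus folding rewards compensatory (covarying) pairs,
   * mean pairwise identity (sequence similarity),
   * number of aligned species.
   A calibrated logistic decision function maps these to an RNA-class
   probability `P ∈ [0, 1]`; windows with `P > 0.5` are significant.
   Significant windows of a gene that overlap or abut in reference
   coordinates fuse into **CSMs** (conserved secondary structure motifs),
   and genes carrying a CSM supported by ≥ 1 non-reference species become
   **CSGs** (conserved secondary structure genes).
4. **Evaluation** — shuffle-null false discovery rate (randomize each
   gene's alignment, re-run the screen, report the fraction still called:
   `FDR = 100 · positives / input genes`), detection sensitivity on
   canonical ncRNAs (`DS = 100 · canonical recovered / canonical total`),
   and the FDR/DS trade-off across probability cutoffs. The
   mating-efficiency statistic `2Z / (2Z + U)` used to quantify the
   hyper-mating phenotype of candidate knockouts is included.
5. **Designer** — to destroy a motif while preserving composition, generate
   k-let-preserving shuffles (Euler paths on the (k−1)-mer transition
   multigraph), score each candidate's mean loop-forming probability
   (per-base unpaired probability under the partition function), and keep
   the most loop-forming candidate.
6. **Synthetic genomes** — a generator that emits GenBank/GFF3/FASTA/MAF
   bundles with planted, compensatorily maintained stem-loops plus
   unstructured background genes and truth labels, so the whole pipeline is
   testable end to end without any downloads.

Two energy backends drive all folding: a self-contained `simple` pair-score
model (brute-force verifiable; used by the screen and the tests) and the
`full` nearest-neighbour model via the ViennaRNA bindings (kcal/mol; used
for physically calibrated loop probabilities).

## Worked example

Generate a small synthetic 4-species data set and screen it:

```bash
sporescreen simulate --structured 5 --background 10 --canonical 3 --seed 11 -o demo
sporescreen screen --genbank demo/genome.gbk \
    --maf demo/S_pombe_vs_S_cryophilus.maf \
    --maf demo/S_pombe_vs_S_japonicus.maf \
    --maf demo/S_pombe_vs_S_octosporus.maf \
    --seed 11 -o demo/screen
# 19 genes, 62 windows, 8 CSMs, 8 CSGs -> demo/screen
head -4 demo/screen/csgs.tsv
# gene_id      n_csms  n_support_species  supporting_species                      max_p
# SYNCAN.0001  1       3                  S_cryophilus,S_japonicus,S_octosporus   0.881487
# SYNCAN.0002  1       3                  S_cryophilus,S_japonicus,S_octosporus   0.934728
# SYNCAN.0003  1       3                  S_cryophilus,S_japonicus,S_octosporus   0.970747
```

The 19 input genes are the 18 generated ones plus one decoy overlapping
ncRNA; 8 are called structurally conserved, each supported by all three
non-reference species. Evaluating the same inputs:

```bash
sporescreen evaluate --genbank demo/genome.gbk --maf demo/*.maf \
    --seed 11 -o demo/eval.json
# FDR 0.0% (0, 19); report -> demo/eval.json
```

so none of the 19 genes survives the screen once its sequence is shuffled
(FDR 0.0%), while all 3 planted canonical ncRNAs are recovered
(DS 100.0%). From Python, the thermodynamic core is direct:

```python
>>> from sporescreen import fold_mfe, loop_probability
>>> fold_mfe("GGGAAAACCC")
FoldResult(structure='(((....)))', energy=-9.0)
>>> round(loop_probability("GGGAAAACCC").mean_loop_prob, 4)
0.4671
```

Three G:C pairs at −3 each give the −9 hairpin; the mean unpaired
probability 0.467 is the quantity the shuffle designer maximizes.

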