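# Methods

This note records the models, parameter choices and numerical conventions
behind `sporescreen`, and what the synthetic benchmark does and does not
demonstrate.

## Energy models and folding

All structures are pseudoknot-free; only {AU, UA, GC, CG, GU, UG} may pair,
`N` never pairs, and every hairpin encloses at least `min_hairpin = 3`
unpaired bases.

* **simple** (default for the screen and the test suite): each pair
  contributes a fixed energy — GC −3, AU −2, GU −1, arbitrary units. The
  minimum-energy structure is found by a Nussinov-style dynamic program
  (numba-accelerated O(n³) fill); the traceback is deterministic — at every
  interval the left end is paired with its smallest admissible partner
  before being left unpaired — so structures are bit-reproducible across
  platforms. The exhaustive enumerator (`brute_force_fold`, ≤ 16 nt) walks
  the same decision order, which is what makes structure-level equality
  with the DP a meaningful oracle rather than an energy-only check.
* **full**: the complete nearest-neighbour (Turner) parameter set at 37 °C
  via the ViennaRNA bindings — used when physically calibrated energies or
  loop probabilities are wanted. The published loop-probability pair for
  the nc1669 motif (0.4496 original / 0.5819 shuffled) lives on this scale;
  reproducing the pair verbatim additionally requires the supplementary
  mutant sequence, which is not redistributed here, so the package
  demonstrates the mechanism on synthetic 117-nt motifs instead.

The rationale for two backends: the simple model makes every screen
quantity verifiable against exhaustive enumeration at small n, which no
full-energy implementation allows; the full model provides fidelity where
the numbers themselves matter.

**Partition function.** Base-pair probabilities come from a
McCaskill-style inside/outside recursion over the *identical* structure
space as the DP, with Boltzmann weights `exp(−E)` (unit inverse
temperature on the simple scale). The outside pass is reorganized into
O(n³) by accumulating, for every enclosing pair candidate, its
contribution to all interior column pairs. Probability mass is conserved
by construction (`q_i + Σ_j p_ij = 1`); the test suite checks agreement
with direct Boltzmann enumeration to 1e-9 on sequences up to 12 nt.
Weights stay within float64 range for the ≤ ~200-nt inputs the screen
produces; global folding is used throughout (no maximal-span constraint).

**Loop-forming probability** is defined as the mean per-base unpaired
probability, ℓ = (1/L) Σ q_i. Other aggregates of the unpaired profile are
conceivable; the mean is the one the designer maximizes and the one
reported everywhere.

**Thermodynamic z-score.** `z = (E − μ)/σ` against mononucleotide shuffles
drawn from a seeded stream (sample sd, ddof = 1); σ = 0 (e.g. a
homopolymer) yields z = 0 by convention. The screen uses 20 shuffles per
row — enough to place a window's stability within ~0.2 sd while keeping a
200-gene screen in minutes; the standalone function defaults to 100.

**Consensus folding and SCI.** Column pair (i, j) scores

    mean pair energy over rows  −  B·(distinct pair types − 1)
                                +  Δ·(fraction of rows that cannot pair)

with gaps counting as non-pairing, B = 2 (covariance bonus) and Δ = 1
(inconsistency penalty); only stabilizing (score < 0) column pairs enter
the structure space. On identical rows this reduces exactly to the
single-sequence model, so SCI = E_cons / mean(E_individual) is exactly 1
there, and 0 by convention when no row is structurable. B = 2 was chosen
so that one confirmed compensatory pair type outweighs the mean-energy
loss of the substitution itself (pair energies differ by at most 2 units);
SCI can exceed 1 on covarying alignments, which is precisely the signal
the classifier rewards.

## The window classifier

The four criteria (z̄, SCI, MPI, n_rows/4) feed a logistic decision
function `P = σ(w·x + b)`. The weights are not hand-set: they are fitted
(deterministic lbfgs logistic regression) on labelled synthetic windows —
positives from planted-structure families across divergences 0.05–0.20,
negatives from structureless background families plus
reference-row-shuffled copies of the positives — and the fitted artifact
(weights, bias, provenance, calibration report) ships in
`sporescreen/data/default_classifier.json`. At calibration the window-level
false-positive rate at P > 0.5 was ≈ 6% with ≈ 20% false negatives; the
gene level recovers most of the miss rate because a gene needs only one
firing window. Consequence: P values are on this package's calibrated
scale and are *not* numerically comparable to any externally trained
screen's probabilities.

## Screen geometry and calling rules

* Windows are 120 alignment columns with 80-column overlap (step 40),
  cut in alignment space; genomic projections use the reference column
  map and skip reference-gap columns. An end-anchored tail window covers
  any trailing columns the regular grid would miss; alignments shorter
  than 120 columns give one full-length window when ≥ 50 columns exist.
* Row filter: rows with > 25% gaps in a window are dropped; a window is
  rejected if the reference row is lost, fewer than 2 rows remain, or
  fewer than 50 ungapped reference bases remain.
* Significance is strict (`P > cutoff`, default 0.5); only the forward
  orientation of alignments is evaluated.
* CSM fusion: significant windows of one gene whose reference projections
  overlap or directly abut (merge gap 0, configurable) fuse; the CSM
  interval is the bounding union and its score the member maximum.
* A gene becomes a CSG when ≥ 1 of its CSMs is supported by at least one
  non-reference species (the inclusive reading of "conserved in more than
  one species"; a switch for the stricter ≥ 2-other-species reading is the
  `n_support_species` field the caller can threshold).

The multiple alignment is a reference-anchored star: every member is
globally aligned to the reference (match 2, mismatch −1, gap open −4,
extend −1) and the pairwise alignments are merged on reference
coordinates. Since every family contains the reference exactly once and
all downstream coordinates are reference projections, anchoring on the
reference is simpler and easier to verify than a guide-tree progressive
scheme; structure-aware external alignments can be ingested instead and
are validated row-by-row against the family.

## Evaluation layer

FDR shuffles each gene's alignment once and re-runs the complete
window → CSM → CSG calling; the reported percentage always carries its raw
counts, and rounding (half-up, one decimal) happens only at the report
boundary. Two shuffle modes exist because the described procedure (shuffle
the reference fragment) and the cited tool (shuffle the alignment) differ:
`ref_row` permutes the reference row's nucleotides within its gap pattern;
`columns` permutes whole alignment columns. `ref_row` is the default; note
that it leaves the non-reference rows structured, so its null is
conservative in a different way than `columns`. The FDR/DS trade-off table
is computed once from per-gene maximum probabilities and emitted under
both comparator semantics (strict `>` and inclusive `≥`), labelled.

## Synthetic data generator

The generator emulates what the screen assumes about real data: a
reference chromosome of ncRNA genes (140–240 nt, ~20% minus-strand, a few
two-exon genes, antisense-CDS/UTR/ncRNA overlaps for the catalog layer),
three related species evolved independently on a star tree at rates
0.10 / 0.12 / 0.20 substitutions per site (the third species deliberately
the most divergent), indels (1–2 nt, rate 0.01/site) outside stems only,
and planted stem-loops (stems 3–10 bp, loops 3–7 nt, one stem-loop per
~55 nt so roughly a third to a half of a structured gene is paired,
comparable to canonical structured ncRNAs). Substitutions hitting a
planted pair co-substitute the partner to a canonical pair with
probability `compensatory_rate` (default 1.0); background genes evolve
identically but with no structure and no compensation. A master seed fans
out to per-gene child seeds, so any subset regenerates identically, and
the emitted MAF carries the generator's true alignments, making the
ingestion path exactly invertible (tested).

What passing on this benchmark shows: the pipeline detects covariant,
thermodynamically stable structure against a composition- and
divergence-matched background, with a calibrated false-positive rate.
What it does not show: robustness to alignment error from real aligners,
non-stationary base composition, structured-but-non-compensatory
conservation, overlapping transcription, or genome-scale contiguity —
real screens inherit those from their upstream alignments.

## Problem sizes and determinism

The shipped benchmark sizes are 40 planted + 160 background (+ 20
canonical-labelled) genes — large enough that the recall-vs-background
comparison is decided at p < 0.01 by a one-sided binomial test, small
enough to run in minutes on one CPU. All stochastic steps (shuffles,
z-scores, evolution, design candidates) derive child seeds from a single
master seed via a stable CRC construction, so every reported number is
bit-reproducible; candidate streams in the designer are prefix-nested in
N (same seed + larger N evaluates a superset).

## Known limitations

* The simple energy model has no stacking, dangles or loop-length terms;
  its z-scores and SCI are internally consistent but not kcal/mol.
* `ref_row` FDR leaves non-reference rows intact; on strongly structured
  families the null retains real signal, and the two shuffle modes can
  legitimately disagree.
* The star alignment does not use base-pair probabilities (no Q-INS-i
  equivalent); heavily diverged families may align worse than with a
  structure-aware aligner, which the external-ingestion mode exists for.
* Reverse-strand screening, CSM structural clustering and span-limited
  (local) folding are out of scope.
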