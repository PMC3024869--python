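# Methods

This note records the models, conventions and numerical choices behind
divergon, and what its synthetic validation does and does not show.

## Pair detection and distance conventions

Coordinates are 1-based inclusive. A gene's TSS is the GFF3 `start` on
the `+` strand and `end` on the `-` strand; the simple TSV dialect
carries strand-resolved TSS/TES directly. A head-to-head pair is a
minus-strand gene M and plus-strand gene P on one chromosome with

- signed distance `d = TSS_P − TSS_M ≤ max_distance` (default 1000 bp,
  the conventional upper bound for a bidirectional promoter),
- no other gene's TSS strictly between the two TSSs (the adjacency
  rule; "adjacent" has no universal definition, and this is the
  weakest rule that forbids an intervening transcription unit),
- overlap `−d ≤ max_overlap` (default 2000 bp). The cap is needed
  because a convergent tail-to-tail neighbour pair also has opposite
  strands, no intervening TSS and a (very negative) `d`; only modest
  TSS overlaps correspond to genuinely divergent units. `None` lifts
  the cap.

`d ≤ 0` marks an overlapping pair. Distance histograms use left-open
right-closed bins `(lo, hi]` (so a 100 bp promoter falls in (0, 100]),
with explicit `overlapping` and overflow categories so counts always
sum to the pair total.

Controls: the *same-strand adjacent* set pairs every h2h gene with its
nearest same-strand neighbour on each side (deduplicated); the *random*
set draws uniform gene pairs with replacement across replicates,
forbidding self-pairs, from a single seeded generator.

## Conservation stratification

A pair is conserved in a partner species when both genes have
one-to-one orthologs (many-to-many rows are dropped, with a logged
count — the simplest reproducible rule, no synteny arbitration) and
those orthologs themselves form an h2h pair there. Levels are prefix
based over the species order (mouse, chicken, fugu by default):
conservation in fugu counts only if mouse and chicken also agree, which
makes the sets H ⊇ HM ⊇ HMC ⊇ HMCF nested by construction. A flag to
accept mere adjacency instead of strict h2h arrangement in the partner
species is deliberately not provided; strictness is the conservative
choice and matches the nested-set design.

Trends in proportions across the ordered levels use the
Cochran–Armitage chi-squared (1 df) with scores 1..k. Because the level
sets are nested rather than independent, the pipeline also reports the
same test on the disjoint complements (H\HM, HM\HMC, HMC\HMCF, HMCF);
both are labelled in the output. Empty levels are dropped from the test
rather than zero-padded.

## Coexpression statistics

Correlations are Pearson (default) or Spearman with pairwise-complete
deletion (≥ 3 complete samples required). Two-sided p-values come from
the t transform `t = r·sqrt((n−2)/(1−r²))` on n−2 df for both methods;
for Spearman this is the usual large-sample approximation — adequate
for n ≥ 10, and noted as approximate below that. |r| within 1e-12 of 1
is treated as exact dependence (p = 0). Zero-variance vectors yield an
undefined-correlation flag and are excluded downstream instead of
raising.

Neighbour ranks are computed against every other gene in the matrix,
ordered by descending correlation with ties broken by ascending gene
id, so all ranks are deterministic integers. MR is the geometric mean
of the two reciprocal ranks, RR their minimum; both are symmetric and
satisfy RR ≤ MR ≤ max rank.

SPR/SNR/SR divide the number of datasets in which a pair is
significantly positively / negatively / at-all correlated (p < α,
default 0.05 two-sided) by the number of *usable* datasets — those
containing both genes with defined correlation. Excluding unmeasured
datasets from the denominator keeps SPR + SNR = SR exact per pair; the
denominator is reported alongside.

Inter-pair coexpression enumerates all unordered pairs among the h2h
genes of a level, removes the actual pairs, and summarises PCC and MR
from the full correlation/rank matrices of the primary (first listed)
dataset, which plays the role of the deep expression compendium; the
multi-dataset collection feeds only the significance ratios.

## Functional similarity

Only `is_a` edges are honoured, keeping each subsystem (BP/MF/CC) a
single rooted DAG; `part_of` is ignored. Annotations are closed over
ancestors (true-path rule) before estimating `p(t)` = annotated genes
at t / annotated genes at the subsystem root — the subsystem, not the
genome, is the corpus, which forces p(root) = 1 and IC(root) = 0. IC
uses the natural logarithm (Resnik values are in nats; Lin is
base-invariant). Terms with zero propagated annotations get no IC and
are excluded from similarity rather than assigned infinite IC.

The minimum subsumer of two terms is their common inclusive ancestor of
maximal IC (ties broken by term id); its IC is the Resnik similarity,
and Lin = 2·IC_ms/(IC₁+IC₂), defined as 0 when both ICs are 0 (the
root-vs-root 0/0 case). Gene-level similarity combines term-level Lin
over the cross pairs of the two genes' *direct* (pre-closure)
annotations; `max` is the default (one strongly shared function
suffices to call two genes related), with best-match-average and mean
as options recorded in the output. The representative similarity of a
pair is the maximum over the subsystems in which both genes are
annotated; a pair annotated in no common subsystem is undefined and
excluded, not zero. The random control samples pair sets of the same
size from annotated genes, 100 iterations by default, from a seeded
generator.

## Two-stage verdicts

Stage 1 compares set H against its control (Welch t-test for value
features, chi-squared for the sharing proportion, rank-sum for
similarity) at α = 0.05; stage 2 requires the level statistics to move
non-strictly monotonically in the claimed direction across at least
three levels, ignoring levels with fewer than `min_level_n` (default
20) observations, whose estimates are too noisy to falsify a trend.
Significant-and-monotone ⇒ *inherent*; non-significant or
wrong-direction ⇒ *negated*; significant but non-monotone ⇒
*postponed*. The monotonicity rule is one formalisation of "consistent
direction across levels" and is labelled as such in the report. No
multiple-testing correction is applied by default; the Welch (unequal
variance) t-test is used throughout in preference to the pooled form.

## The synthetic study

The generator emulates the statistical structure the analysis assumes,
with defaults sized for a desk run (seconds to generate, ~10 s to
analyse):

- **Genome**: 5 chromosomes × 600 genes, 500 planted pairs. TSS
  distances draw from an interval mixture (8% overlapping, 14% in
  (0,100], 20% (100,200], 21% (200,400], 37% (400,1000]) echoing the
  observed predominance of sub-400 bp promoters. Filler genes are
  spaced > 2 kb apart so the planted pairs are exactly the detectable
  ones (verified by a round-trip test).
- **Conservation**: a Bernoulli chain per species step with higher
  success for short (≤ 100 bp) promoters — P(step) = 0.55/0.30, then
  0.60/0.40, then 0.50/0.30 (short/other) — yielding ≈ 500/160/80/30
  nested counts and a built-in short-promoter trend.
- **Expression**: 4 datasets × 100 samples from a factor model: pair
  genes share a pair factor (within-pair r = 0.45/0.55/0.60/0.65 by
  level), all pair genes a weak common factor (r = 0.2), background
  independent; marginals are standard normal because every downstream
  statistic is correlation- or rank-based (a log-normal option exists
  for cosmetic realism). Validity requires
  0 ≤ rho_background ≤ rho_inter ≤ rho_pair < 1, which is exactly the
  positive-semidefiniteness condition of the implied correlation
  matrix and is checked at construction.
- **TF map**: 200 TFs, 3 per gene for the 80% of genes that are
  TF-associated; planted pairs share ≥ 1 TF with probability
  0.25/0.50/0.70/0.85 by level (two TFs in 35% of sharing events, so
  the multi-share class is populated); 2% of pairs get one gene
  recorded as a TF of its partner, feeding the self-regulation scan.
- **Ontology**: per subsystem a 4-level ternary tree plus 3 shortcut
  `is_a` edges (levelled construction keeps it acyclic and single
  rooted); genes draw 2 random terms per subsystem with probability
  0.85, and planted pairs are co-annotated to one shared term with
  probability 0.30/0.50/0.65/0.80 by level.

Per-level effect sizes increase with conservation because that is the
structure the stratified analysis is designed to detect; they were
fixed once, at magnitudes a coexpression practitioner would call
moderate-to-strong, before any downstream comparison.

**What passing tests show — and don't.** The suite demonstrates that
the statistics are implemented correctly (brute-force equivalence,
analytic calibration: type-I error ≈ α under the null, SPR matching
Fisher-z power, planted correlations recovered to ±0.03) and that the
pipeline's decision logic recovers planted effects of realistic size.
It does not show anything about real genomes: the generator has no GC
or CpG structure, no alternative promoters or isoform-specific TSSs,
no expression batch effects or heavy-tailed noise, orthology is given
rather than inferred, and the TF and GO layers are plain bipartite /
tree-plus-shortcut abstractions of far messier curation. Published
values from curated snapshots are therefore not reproduction targets.

## Problem sizes and determinism

Default analyses use the 3000-gene, 500-pair study with one
3000×3000 correlation/rank matrix, 100 random-control replicates and
100 similarity-control iterations — chosen so a complete run stays
interactive on a laptop. Every random draw flows from one integer seed
(dataset streams are offset sub-seeds), and identical configurations
produce byte-identical output files; the report regeneration test
asserts this.

## Known limitations

- Transcript-isoform-aware TSS selection is out of scope; one TSS per
  gene is assumed.
- Spearman p-values are approximate for n < 10.
- The exact rank-sum null is enumerated only for tie-free groups of
  ≤ 20; otherwise the tie-corrected normal approximation is used.
- Whether the rank lists of the emulated compendium were built on raw
  or log-ratio expression is immaterial here (ranks are monotone
  invariant), but matters when substituting real matrices; the package
  takes matrices as given.
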