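# divergon

Conservation-stratified analysis of **head-to-head (h2h) gene pairs** —
adjacent genes transcribed divergently from opposite DNA strands, whose
facing transcription start sites (TSSs) flank a shared *bidirectional
promoter* (typically < 1 kb). The package is for regulatory genomicists
who want to test which properties of this gene arrangement are inherent
to it: it detects h2h pairs from annotations, stratifies them into
nested evolutionary-conservation sets, and compares the sets on promoter
length, coexpression, transcription-factor sharing and functional
similarity, against matched controls.

## What it computes

**Detection and stratification.** From a GFF3/TSV annotation, every
(minus-strand M, plus-strand P) pair with no intervening TSS and signed
distance `d = TSS_P − TSS_M ≤ max_distance` (`d ≤ 0` = overlapping) is an
h2h pair. Pairs whose orthologs are also h2h in mouse, mouse+chicken,
mouse+chicken+fugu form the sequentially inclusive sets
`H ⊇ HM ⊇ HMC ⊇ HMCF`.

**Coexpression indices.** For genes A, B with expression correlation
rank `Rank(A→B)` (position of B among A's neighbours by descending
correlation):

- Mutual Rank `MR = sqrt(Rank(A→B) · Rank(B→A))`
- Relative Rank `RR = min(Rank(A→B), Rank(B→A))`
- across a dataset collection, the significant-positive / -negative /
  total ratios `SPR`, `SNR`, `SR = SPR + SNR` (fraction of datasets with
  two-sided correlation p < α).

**TF sharing.** For TF-associated pairs, the TF similarity is the
Jaccard fraction `|shared TFs| / |union TFs|`; sharing proportions are
compared with a 2×2 chi-squared test, trends across conservation levels
with a Cochran–Armitage test.

**Functional similarity.** Information content `IC(t) = −ln p(t)` from
propagated GO annotations; Resnik similarity = IC of the minimum
subsumer; Lin similarity `2·IC_ms / (IC(t1)+IC(t2)) ∈ [0,1]`; gene pairs
combine term similarities (max by default) per subsystem, with the
maximum over BP/MF/CC as the representative value.

A two-stage decision rule labels each candidate feature **inherent**
(differs from control *and* moves monotonically across conservation
levels), **negated**, or **postponed**.

Because the original curated databases (pair catalogues, expression
compendia, TF-target and GO annotation sets) are not redistributable, a
seeded generator (`divergon.synthetic`) produces all inputs with planted
ground truth — known pair distances, conservation chains, correlation
structure, TF sharing and co-annotation — so every stage is validated
end to end.

## Worked example

```bash
divergon simulate --seed 1 --out simdata/
divergon detect-pairs --annotation simdata/annotation.tsv --out pairs.tsv
# -> 500 h2h pairs -> pairs.tsv
divergon conserve --pairs pairs.tsv \
  --species mouse:simdata/orthologs_mouse.tsv:simdata/annotation_mouse.tsv \
  --species chicken:simdata/orthologs_chicken.tsv:simdata/annotation_chicken.tsv \
  --species fugu:simdata/orthologs_fugu.tsv:simdata/annotation_fugu.tsv \
  --out pairs_lvl.tsv
# -> level counts: {'H': 500, 'HM': 159, 'HMC': 84, 'HMCF': 28}
```

or, from Python, the full stratified run:

```python
from divergon import SimulationConfig, simulate_all, write_simulation
from divergon import RunConfig, run_pipeline

data = simulate_all(SimulationConfig(seed=1))
paths = write_simulation(data, "simdata")
report = run_pipeline(RunConfig(
    annotation=paths["annotation"], expression_manifest=paths["manifest"],
    tfmap=paths["tf"], obo=paths["obo"], annotations=paths["annot"],
    species=[(s, paths[f"orthologs_{s}"], paths[f"annotation_{s}"])
             for s in ("mouse", "chicken", "fugu")],
    seed=1, out_dir="results_run"))
print(report.counts)    # {'H': 500, 'HM': 159, 'HMC': 84, 'HMCF': 28}
print(report.verdicts)
# {'positive_coexpression': 'inherent', 'negative_coexpression': 'negated',
#  'tf_sharing': 'inherent', 'functional_similarity': 'inherent'}
```

Reading the numbers: the 500 planted pairs average a Pearson correlation
of 0.48 in the primary dataset versus 0.02 for random gene pairs, their
TF-sharing proportion is 42% versus 5% in the same-strand adjacent
control, and the mean representative functional similarity is 0.75
versus a 0.56 random-pair null — so the pipeline declares positive
coexpression, TF sharing and functional similarity inherent, while
negative correlation (planted nowhere) is negated. The short-promoter
trend test rejects (p ≈ 6e-7): deeper conservation sets are enriched for
pairs with (0, 100] bp TSS distance, exactly as planted.

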