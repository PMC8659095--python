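# screenaudit

Evaluation and bias diagnosis for structure-based virtual screening.

Virtual screening ranks a compound library against a protein target so that
true binders surface early. Judging whether a scoring method actually does
this — and whether its apparent success comes from protein–ligand modelling
or from artifacts of how the benchmark was built — requires more than a
single AUC. `screenaudit` packages that whole evaluation:

* **Score aggregation** from per-pose, per-receptor tables to one prediction
  per (target, compound): best-pose, worst-pose (a pose-sensitivity probe),
  the pose-probability × affinity product, and affinity-at-best-pose.
* **Early-recognition metrics with uncertainty**: ROC-AUC, enrichment factor
  EFα, and the normalized enrichment factor NEFα, with stratified bootstrap
  confidence intervals, Mann-Whitney method comparisons across targets, and
  paired-bootstrap per-target win counts.
* **Cross-docking pose evaluation**: fraction of (ligand, non-cognate
  template) tasks with a ≤2 Å pose among the top-n ranked poses, against the
  sampling ceiling.
* **Ligand-only bias audit**: six regression families fit to affinity data on
  cheap 2D descriptors (6-feature and 17-feature sets, ECFP4), screened on
  the benchmark — the enrichment attainable without any protein information.
* **Training-set similarity**: average maximum ECFP4 Tanimoto similarity of
  benchmark actives to a training pool, correlated with per-target
  enrichment (Spearman).
* **Synthetic benchmarks with known ground truth** for every stage, so each
  statistic has a parameter-recovery test without external data.

It is written for computational chemists benchmarking docking/rescoring
methods and for ML practitioners who need to know whether a model's screening
performance would survive a decoy-bias audit.

## The statistics at the core

For a library of N compounds with A actives, ranked by descending score:

* **AUC** = P(random active outranks random inactive), ties at half credit
  (midranks). Perfect ranking 1.0, random 0.5.
* **EFα** = (a/k) / (A/N), where k = ⌈αN⌉ and a is the number of actives in
  the top k. EF1% is the standard early-recognition choice.
* **NEFα** = EFα / EFα_max with EFα_max = (min(k, A)/k)/(A/N). NEF ∈ [0, 1]
  and is comparable across benchmarks with different active rates; 1.0 means
  as many actives as possible sit in the top fraction, 0 means none do.

Confidence intervals are stratified percentile bootstraps (classes resampled
separately); method comparisons use the two-sided Mann-Whitney U rank test on
per-target metric distributions (exact for small tie-free samples). The
synthetic generator uses the equal-variance binormal model — actives
~ N(d, 1), inactives ~ N(0, 1) — whose closed-form AUC Φ(d/√2) anchors the
recovery tests. See `docs/methods.md` for conventions and limitations.

## Worked example

Generate a synthetic 5-target benchmark with two scorers — a strong one
(separation d = 1.19, true AUC 0.8) and a moderate one (d = 0.74, true AUC
0.7) — evaluate both protocols, and summarize:

```bash
cat > sim.yaml <<EOF
n_targets: 5
n_actives: 100
n_inactives: 1900
poses_per_compound: 5
methods:
  - [cnn, 1.19]
  - [vina, 0.74]
n_train: 500
EOF
screenaudit simulate --config sim.yaml --seed 7 --out bundle
screenaudit evaluate --scores bundle/scores.csv \
    --protocols best_pose,worst_pose --boot 500 --seed 0 --out eval
screenaudit report --metrics eval/metrics.csv
```

which prints (abridged):

```
benchmark          method metric  alpha   median  n_targets  is_best  p_vs_best  indistinguishable_from_best
      all   cnn:best_pose    auc    NaN 0.790884          5     True   1.000000                         True
      all  cnn:worst_pose    auc    NaN 0.748942          5    False   0.150794                         True
      all  vina:best_pose    auc    NaN 0.707032          5    False   0.007937                        False
      all vina:worst_pose    auc    NaN 0.694611          5    False   0.007937                        False
      all   cnn:best_pose    nef   0.01 0.450000          5     True   1.000000                         True
      all  vina:best_pose    nef   0.01 0.150000          5    False   0.019624                        False
```

Reading it: the strong scorer's median AUC (0.791) and the moderate one's
(0.707) recover their planted values (0.8 and 0.7) to within sampling error;
`is_best` flags the best method per column, and `p_vs_best` is the
Mann-Whitney p-value of each method's per-target distribution against the
best — the moderate scorer is significantly worse (p ≈ 0.008 < 0.05), while
the strong scorer's worst-pose variant is not distinguishable from its
best-pose ranking on only five targets. Per-target values with bootstrap CIs
are in `eval/metrics.csv`; `bundle/truth.json` holds the generating
parameters.

The other subcommands follow the same pattern: `screenaudit pose-eval`
(good-pose fractions vs. the sampling ceiling), `screenaudit bias-audit`
(ligand-only baseline screening), `screenaudit similarity` (average max
Tanimoto to a training pool). Everything is also importable:
`screenaudit.metrics`, `screenaudit.protocols`, `screenaudit.pose_eval`,
`screenaudit.baselines`, `screenaudit.similarity`, `screenaudit.synthetic`,
`screenaudit.pipeline`.

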