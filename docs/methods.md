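# Methods

## Scope and model of the data

`screenaudit` evaluates structure-based virtual screening output and audits it
for benchmark bias. The unit of input is a *scored pose table*: for each
benchmark target, every library compound was docked against one or more
receptor structures, and each retained pose carries one or more score channels
(a docking energy, a CNN pose probability, a predicted affinity in pK units)
and optionally an RMSD to a reference pose. Activity labels are strictly
binary; compounds with ambiguous labels are rejected at ingest because every
statistic downstream is a binary-classification quantity.

Score direction is canonicalized once, at ingest: channels declared
lower-is-better (energies) are negated, so the whole package ranks by
descending score. The alternative — per-metric direction flags — was rejected
because mixing energy-like and probability-like channels in one run makes
per-call flags a reliable source of sign bugs. Negation is involutive, so raw
values are always recoverable.

## Aggregation protocols

A method's prediction for a (target, compound) pair is its best (maximum)
canonical score over all poses and all receptors, a flat maximum with poses
and receptors treated symmetrically (a two-stage max over receptors then
poses gives the identical result; the flat contract is simpler). The
worst-pose protocol is the mirror (minimum) and serves as a pose-sensitivity
probe: a scorer that still enriches actives when fed each compound's worst
pose is drawing on ligand-only information.

Two pose/affinity combinations are provided. The product score multiplies a
pose probability with the predicted affinity *per pose*, then takes the
best-pose maximum. Multiplying aggregated values instead would mix the
probability of one pose with the affinity of another, so the per-pose-then-max
order is the one implemented. Negative predicted affinities are clipped to 0
before multiplying to keep the product on a higher-is-better scale; pK values
of screening-relevant compounds are positive, so the clip is a guard, not a
modeling choice. The second combination returns the predicted affinity of the
pose with the best pose score; ties in pose score break by lower pose rank,
then lexicographic receptor id, making output deterministic.

Compounds with no docked pose at all are ranked last (score −∞) with a logged
warning — the conservative interpretation for a screening campaign, where an
undockable compound would not be advanced.

## Metrics

* **AUC** — midrank (tie-aware) pair-counting form, computed from
  `scipy.stats.rankdata`. Equals the probability an active outranks an
  inactive with half credit for ties.
* **EFα** — active rate among the top `k = ceil(α·N)` compounds over the
  library active rate. `ceil` guarantees `k ≥ 1` for any non-empty library.
  Ties at the k-boundary break by (score descending, compound id ascending):
  deterministic, no fractional credit. Users who prefer fractional tie credit
  can jitter scores before calling.
* **NEFα** — EFα over the best achievable EFα `(min(k, A)/k)/(A/N)`; lies in
  [0, 1] and is comparable across libraries with different active rates,
  which raw EF is not.

Uncertainty uses a stratified percentile bootstrap: actives and inactives are
resampled separately with replacement, preserving class counts so every
resample keeps both classes and the metrics stay defined. Defaults:
10,000 resamples, 95% level, seeded. In pipeline output the percentile
interval is widened, when necessary, to bracket the point estimate (finite
resampling can place a percentile a hair past it).

Method comparisons across targets use the two-sided Mann-Whitney U test on
the unpaired per-target metric distributions — exact enumeration when both
sides have n ≤ 8 and no ties, the normal approximation with tie correction
otherwise. Fully tied input is defined as p = 1.

Per-target significance between two methods uses a *paired* bootstrap: the
same compound resample is scored by both methods and the difference of the
metric is collected; a target counts as a win when the percentile CI of the
difference excludes zero. Pairing on the resample removes the shared
compound-sampling noise that an unpaired comparison would double-count.

## Cross-docking pose evaluation

Tasks are (crystal ligand, non-cognate receptor template) pairs; cognate
pairs are excluded. A task succeeds at rank n if its top-n poses by the score
channel contain one with RMSD ≤ 2 Å (threshold configurable). Fractions are
averaged per target first, then across targets, so a target contributing many
ligand/template pairs does not dominate; each (ligand, template) pair counts
as one task within its target. The sampling ceiling — the fraction of tasks
with *any* good pose — bounds every rank fraction and is what a perfect
re-ranker (e.g. ranking by RMSD itself) attains at rank 1. RMSD is consumed
as data; computing symmetry-corrected RMSD from coordinates is the docking
pipeline's job.

## Ligand-only baselines

Six regression families (Lasso, k-NN, decision tree, random forest, gradient
boosting, SVR — all scikit-learn) are fit to affinity data on cheap 2D
descriptors and then used to *rank* a benchmark by predicted affinity. Any
early enrichment they achieve is attainable with zero protein information and
caps how much of a structure-based method's enrichment can be credited to
modelling the interaction.

Descriptor conventions (the feature names alone do not fix these):

* HBA = Lipinski N/O acceptor count; HBD = Lipinski N-H/O-H donor count.
* logP = Crippen (Wildman–Crippen) atomic contributions; cross-checked
  against Open Babel's implementation of the same scheme.
* net charge = formal charge sum.
* ring systems = connected components of the ring-bond subgraph (fused
  systems count once); chiral centers = potential stereocenters including
  unassigned ones. Counting assigned-only stereocenters is the plausible
  alternative; flagged here because registration conventions differ between
  toolkits.
* ECFP4 = Morgan fingerprint, radius 2, folded to 2048 bits by default (the
  folded length is configurable; 2048 is the common choice).

Hyperparameter grids ship in `screenaudit/data/baseline_grids.yaml` and are
deliberately small — the audit needs honest, not maximal, baselines.
Model selection is grid-search CV on squared error with a shuffled, seeded
K-fold; the winning point is refit on all data. Descriptor computation sits
behind an adapter: every fitting/screening entry point accepts a plain
numeric table, so precomputed descriptors can be supplied and the statistical
core never requires a chemistry toolkit.

## Training-set similarity

Per target: mean over benchmark actives of the maximum ECFP4 Tanimoto
similarity to any training-pool compound. Only actives are used because
affinity training pools contain no inactives. Empty-fingerprint pairs are
defined to have similarity 0 (avoiding 0/0). The per-target statistic is
correlated with per-target early enrichment by Spearman rank correlation
(midranks, two-sided p), pooled across benchmarks, with per-benchmark
breakdowns available.

## Synthetic benchmarks and what they do (not) show

The generator plants known truth for every stage:

* **Scores**: equal-variance binormal — actives `N(d, 1)`, inactives
  `N(0, 1)` — chosen because its AUC has the closed form `Φ(d/√2)`, giving an
  exact recovery oracle. Pose ensembles assign the compound-level draw to the
  best pose and strictly lower scores to the rest, so best-pose aggregation
  reconstructs the draw.
* **Pose quality**: a task holds a good pose (RMSD ~ U(0, 2)) with
  probability `p_good_pose`, other poses draw RMSD ~ U(2, 10); a coupling
  parameter interpolates between the good pose always scoring first
  (coupling 1) and a uniform score rank (coupling 0). Planted ranks are
  written to the truth sidecar for exact comparison.
* **Descriptors**: independent standard-normal features; benchmark actives
  are shifted by `active_shift` along the same unit vector that generates
  training affinities `pK = 6 + w·x + N(0, σ)` — the simplest structure the
  baseline models can exploit, and the knob for type-I/power checks of the
  bias audit.
* **Fingerprints**: random bit vectors at density 0.05; actives are bit-flip
  copies of training-pool members at `flip_rate`, making average-max
  similarity controllable (flip 0 ⇒ similarity 1).

Defaults emulate a DUD-E-like target: 5% active rate (250 actives, 4,750
inactives), nine poses per compound, method separations spanning a strong
scorer (AUC 0.8), a moderate one (AUC 0.7) and a null control. All randomness
derives from one seed through spawned child streams, so adding one output
block never perturbs another and identical configs give byte-identical files.

None of this mimics real chemistry: no valid molecules are generated,
descriptor tables are numeric stand-ins, and score distributions are
Gaussian. Passing recovery tests therefore demonstrates the *statistical
machinery* is correct — not that any particular scoring method performs well
on real benchmarks, whose label noise, similarity clumping and non-Gaussian
score shapes the generator does not reproduce. Molecule-level code paths are
tested against tiny hand-written SMILES cases instead.

## Problem sizes in shipped checks

The self-checks run at desk scale, chosen to keep statistical resolution
honest: closed-form AUC recovery at 5,000 compounds/target within 3
Hanley–McNeil standard errors for separations {0, 0.5, 1.19, 2}; bootstrap
coverage at 500 replicates of 500-compound targets with 500 resamples each
(coverage required in [0.92, 0.98]); bias-audit type-I/power on 6 targets of
5,000 compounds at shifts {0, 0.5, 1, 2}; exact Mann-Whitney agreement
enumerated for all layouts up to 6 per side; metric/oracle equivalence on
1,000 random instances of up to 20 compounds.

## Known limitations

* EF tie handling is deterministic-ordinal, not fractional; rankings with
  massive score degeneracy at the cutoff will see id-order-dependent EF (NEF
  inherits this). AUC is tie-correct via midranks.
* The percentile bootstrap slightly undercovers for extreme AUC (→ 1) or
  very few actives; the stratified design mitigates but does not remove this.
* The win-count rule (paired-difference CI excluding zero) is a bootstrap
  analogue of a significance test, not an exact test; at small compound
  counts its per-target error rate is approximate.
* `ecfp4` bit-collision behaviour depends on the folded length; Tanimoto
  values at 2048 bits are not numerically identical to unfolded-fingerprint
  values, and implementations differ across toolkits in rare ring-perception
  corner cases.
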