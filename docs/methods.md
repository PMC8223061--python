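# Methods

## The classification model

`mbsarc` treats medulloblastoma subgrouping as four-class classification of
log-scale expression profiles and searches for the smallest gene panel that
preserves accuracy. The searcher (SARC: SVM attribute ranking and
combinations) is built from linear soft-margin SVMs because their weight
vector is directly interpretable: after per-gene standardization, `w_g²`
measures how much gene `g` contributes to separating one subgroup pair.

Steps, with the conventions this implementation pins down:

1. **Pairwise models.** One linear SVM per unordered subgroup pair, classes
   ordered canonically (WNT, SHH, Group3, Group4); a positive decision
   value votes for the second class of the sorted pair. The solver is
   libsvm's deterministic SMO (scikit-learn `SVC(kernel="linear")`).
   Regularization defaults to `C = 1.0`, the customary SMO default, and is
   configurable. Features are z-scored per gene using the training samples
   of the pair only; the scaling is stored in the model so it is applied
   identically at prediction time. Standardization can be switched off (the
   analytic two-point test does this). Squared weights are taken from the
   standardized-scale model; on raw scale the ranking would conflate
   discriminative power with expression variance.
2. **Ranking.** Rank 1 = largest `w²`; exact ties break by lexicographic
   gene ID, so the ranking is always a permutation of `1..n_genes`.
3. **Aggregation.** A gene's subgroup-level score is the *sum* of its
   integer ranks over the pairwise models involving that subgroup (three
   models with four classes, `n − 1` in general). The mean would give the
   same order; the sum is what is computed. Ties again break by gene ID.
4. **Combinations.** Candidates are unions of per-subgroup top-`k` genes
   over the Cartesian product of per-subgroup `k` grids (default `0..12`),
   excluding the all-zero vector. Overlapping top genes are de-duplicated,
   so a candidate can be smaller than its `k` sum. The grid is fully
   configurable; no particular reduced candidate count is hard-coded. An
   optional cap aborts (rather than truncates) oversized grids.
5. **Evaluation and frontier.** Each candidate is scored by seeded,
   class-stratified k-fold CV (default 10) of a one-vs-one committee:
   majority vote over all pairwise models, ties broken by the largest
   summed signed decision margin toward the class, then canonical class
   order. Stratification is used because realistic subgroup imbalance
   (e.g. 70/223/144/326) would otherwise risk folds with an empty class.
   Accuracies are grouped into levels at two decimals in percent; per level
   only minimal-size candidates are kept, and dominated candidates are
   removed, giving a Pareto frontier ordered by accuracy then size.

**Rank scope.** By default the entire ranking (steps 1–3) is recomputed
inside every CV training split (`rank_scope="per_fold"`), so the genes
evaluated on a held-out fold were chosen without seeing it. This is the
honest estimate: with `rank_scope="global"` (rank once on all data, as
pipelines that pre-rank do), CV accuracy inherits selection bias from genes
chosen on the full dataset. Both modes are exposed; the interpretable
rankings reported in `SarcReport` always come from the full matrix.

## Independent validation

`evaluate_independent` trains the committee once on the training cohort
restricted to the panel and predicts every test sample (`mode="transfer"`);
`mode="refit_cv"` instead cross-validates the fixed panel inside the test
cohort, reproducing the alternative reading in which the panel, not the
fitted model, is what transfers. Because cohorts come from different array
platforms, each dataset is z-scored per gene independently before the
committee is applied (`harmonize="zscore"`, default, logged); this removes
platform location/scale shifts but assumes comparable within-cohort
subgroup composition.

t-SNE (1 000 iterations, perplexity 30 by default, seeded, PCA
initialization) is quality control only; no classification decision is made
from coordinates. Perplexity is clamped to `(n − 1)/3` with a recorded
warning for small cohorts, where 30 is infeasible. The silhouette of the
embedded coordinates against the labels makes "clearly separated clusters"
an objective scalar.

## qPCR classification

Cycle thresholds are normalized per sample as dCt = Ct(gene) − Ct(reference
gene, default GAPDH); lower dCt = higher relative expression, and any
per-sample offset (loading, efficiency) cancels. No ddCt fold change is
computed — the procedure assumes no control tissue. Undetermined wells
either abort (default) or are censored at the cycle ceiling (default 40)
behind an explicit flag.

Samples are clustered agglomeratively on Euclidean distances between dCt
profiles under the Ward criterion in the **ward.D2 convention**: the
Lance-Williams recurrence runs on squared Euclidean distances and merge
heights are reported on the distance scale (two singletons merge at their
Euclidean distance). The agglomeration is written out explicitly so its tie
rule is pinned — exact merge-cost ties go to the lexicographically smallest
pair of cluster indices — making dendrograms bit-reproducible across
platforms; scipy's `linkage(..., "ward")` implements the same convention
and serves as an independent cross-check in the tests, not as the
implementation.

Cluster stability is an **ordinary bootstrap proportion (BP)**: each
replicate resamples genes (rows) with replacement, reclusters, and a node
scores a hit when its exact leaf set reappears. The approximately-unbiased
(AU) multiscale-bootstrap correction is deliberately not implemented — it
is a separate published method, and BP preserves the decision semantics
(high support = stable cluster). Outputs label support values "BP" to avoid
confusion with AU p-values, and with a six-gene panel the support
resolution is inherently coarse (resampling 6 rows), which reports note.

Unlabeled samples inherit the majority class of their smallest enclosing
cluster containing at least one labeled sample, with that cluster's BP as
confidence; a tied majority is reported as unresolved, never guessed.

## Synthetic data

The generator emulates a four-subgroup bulk expression study after RMA-style
normalization: all cells Gaussian with common SD; noise genes centered at a
baseline intensity (default 7.0 log2 units, SD 1.0) everywhere; each
subgroup's marker genes shifted by `effect_size × noise_sd` in that
subgroup only (upward by default; a "down" fraction exists for realism and
defaults to 0). Class imbalance is expressed directly through per-class
counts. The default study condition used by the acceptance checks is 4 × 50
samples, 2 000 noise genes, 5 markers per subgroup at effect size 2 — a
moderate signal chosen so recovery is non-trivial. The Ct simulator mirrors
an 18-patient-scale qPCR cohort (SHH/Group3/Group4; 5/3/8 by default):
marker genes amplify `delta` cycles earlier (default 5) in their own class
with well noise SD 0.2, and the reference gene is constant.

What the generator does **not** model: gene–gene correlation, batch and
platform effects, probe-level artifacts, heavy-tailed intensities, NanoString
count distributions, or subgroup substructure. Passing tests therefore show
the machinery is correct and well-calibrated under its own assumptions —
not that any particular accuracy will be attained on clinical cohorts,
which is why validation on real, independently labeled data remains part of
the intended workflow.

## Numerical and design choices

- **Determinism.** Every stochastic step (simulation, fold assignment,
  t-SNE, bootstrap, permutations) takes an explicit seed; a full run is a
  pure function of inputs + config, and pipeline artifacts are
  byte-identical across reruns (manifests/logs differ only in timestamps).
  Matrices round-trip bit-exactly through TSV/CSV (shortest-repr floats on
  write, correctly rounded strtod on read).
- **Degenerate inputs.** Constant genes get unit scale during z-scoring
  (contributing nothing); a pairwise training set whose samples are all
  identical is rejected; classes with fewer samples than folds are
  rejected; a class with zero truth samples reports sensitivity as NaN,
  never 0.
- **Probe collapse.** When several probes map to one symbol, the probe with
  the highest across-sample variance is kept (ties to the smallest probe
  ID) — a deterministic rule that favors the most informative measurement.
- **Aliases.** Subgroup names are normalized through a fixed table (WNT =
  Group 1/A, SHH = Group 2/B, Group3 = Group C, Group4 = Group D); unknown
  names are errors, not guesses.
- **Config.** The pipeline config is TOML; unknown keys or sections are
  rejected before any computation; CLI flags override config values.

## Problem sizes used by the checks

The acceptance checks and `scripts/acceptance.py` run the study condition
above with 3 data seeds for recovery/frontier estimates, 5 label
permutations for the null, 10 cohort seeds for the qPCR chain (nboot = 200),
and a per-subgroup combination grid of k ∈ {0, 1, 3, 5} (255 candidates)
for the cross-validated search; the full 13⁴ − 1 = 28 560-candidate
enumeration is exercised combinatorially without per-candidate CV. These
sizes keep a complete run in the minutes range on one CPU while leaving
every estimate's precision adequate for its threshold. Note that the null's
best-of-candidates accuracy is a maximum statistic: individual candidates
are unbiased at chance under permutation (observed median ≈ the majority
proportion), while the maximum over 255 of them sits a few points above it,
which is why the permutation null is summarized by its average over
shuffles.

## Known limitations

- The reported CV accuracy of the *frontier's best* candidate is itself a
  maximum over candidates and is optimistic by selection, even with
  per-fold ranking; an untouched validation cohort remains the honest final
  estimate.
- With very small classes, stratified CV and the pairwise SVMs run but
  their variance is large; the package refuses only the degenerate cases it
  can detect (class count < folds, empty classes).
- The qPCR classifier is unsupervised; it assumes the panel separates the
  classes in dCt space and that each class has at least one labeled anchor
  in the tree. WNT behavior under the six-gene dCt clustering is untested
  anywhere and is not simulated as if known.
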