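# Methods

This document records the statistical model behind each analysis stage, the
default parameters, what the synthetic generators do and do not emulate, and
the numerical choices that matter for reproducing results.

## 1. Presence-absence matrix and featured families

Orthogroup gene-count tables follow the OrthoFinder `Orthogroups.GeneCount.tsv`
dialect (first column `Orthogroup`, one integer column per species, optional
trailing `Total` column which is dropped on read). Binarization marks a
family present in a species iff it has at least one member gene; the
presence-absence matrix is species × families.

A family is **saltwater-featured** at cutoff *c* when

    frac_salt > c   and   (1 − frac_fresh) > c

with strict inequalities, and freshwater-featured by the mirrored rule; a
family can satisfy at most one side. `frac_salt`/`frac_fresh` are presence
fractions within each habitat; outgroup species never enter them. The
default cutoff is 0.6.

**Association statistic.** The default 2×2 table pools presence calls over
all featured families (rows: saltwater/freshwater species; columns:
present/absent). The test is the Pearson chi-square with df = 1 and no
continuity correction (a Yates-corrected variant is available); the effect
size is Cramér's V = √(χ²/N), since min(r−1, c−1) = 1. The 95% CI for V is
a seeded percentile bootstrap (default 1000 replicates) resampling species
*within* habitat. A caveat of the pooled table: when salt- and
fresh-featured sets are equally large and equally penetrant, their presence
fractions cancel between habitats and the pooled χ² approaches zero even
though each individual family is strongly associated. Real data (and the
generator defaults) are habitat-skewed, which is what the pooled statistic
measures.

**Ordination.** Species PCA uses column mean-centering only (no scaling)
via SVD, so it makes no distributional assumption about binary data.

## 2. Two-stage model-combination search

Saltwater is the positive class (1), freshwater 0; outgroups are excluded
from training.

- **Stage 1 (selection).** A selector with embedded selection is fit on the
  training species: tree ensembles keep families with impurity importance at
  or above the mean importance; sparse linear models (lasso / elastic net at
  a cross-validation-chosen penalty) keep features with nonzero
  coefficients. The kept features are ranked by descending score with ties
  broken by column order.
- **Stage 2 (classification).** Classifiers with embedded selection are fit
  on the whole candidate set. Unconstrained classifiers are evaluated on
  growing top-k prefixes of the ranking (k = 50, 100, … plus a final
  partial batch) and the k with the best mean CV accuracy is kept (ties →
  smaller k).
- **Cross-validation.** All combinations in one search are scored against
  identical stratified 5-fold assignments, making the leaderboard a paired
  comparison. Crucially, stage-1 selection is **re-run inside each training
  fold**: selecting features on the full data before cross-validating the
  classifier leaks test-fold labels into the feature set and inflates CV
  accuracy to ≈ 0.7 even under permuted labels. With fold-internal
  selection, permuted labels score at chance, as they must. The final
  reported model (selected families and weights) is refit with the
  full-data ranking.
- **Tie-break.** Best combination = max CV accuracy, then fewest features
  used, then registry order. Note the parsimony tie-break deliberately
  favors minimal models; when the goal is *recovering the full planted set*
  rather than the smallest separator, restrict the registry to a
  high-capacity combination (the study's best performer was random-forest
  selection followed by an elastic-net [α = 0.6] classifier).
- **Weight categorization** requires a linear final stage: positive weights
  push toward the positive (saltwater) class.

The componentwise linear boosting classifier is implemented in-package
(L2-boosting with single-feature least-squares base learners, 150 steps,
learning rate 0.2) because no equivalent is available in scikit-learn.

## 3. Metagene co-expression network

Each orthogroup shared by all contributing species becomes a metagene: the
per-sample sum of its member genes. Constant rows are dropped. The network
is WGCNA-style:

- unsigned adjacency a_ij = |cor(x_i, x_j)|^β (signed variant available);
- β is the smallest power in 1..12 whose scale-free fit index exceeds 0.9,
  where the fit index is the *signed* R² of log10(frequency) on log10(mean
  connectivity) over 10 connectivity bins (sign flipped when the slope is
  positive); if no power passes, the maximizer is used and flagged —
  synthetic data with a handful of equal-size planted modules is not
  scale-free, so a flagged fit is expected there;
- topological overlap TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) /
  (min(k_i, k_j) + 1 − a_ij) with k the connectivity excluding self,
  validated against a literal triple-loop evaluation to 1e-10;
- modules are cut from average-linkage clustering of 1 − TOM at a static
  height (default 0.99); clusters below 30 members fall into the unassigned
  `grey` label; modules are named M1, M2, … by decreasing size for
  determinism;
- the module eigengene is the first principal component of the z-scored
  member rows, sign-oriented to correlate positively with the module's mean
  profile;
- module–trait significance is inclusive: |r| ≥ 0.75 **and** p ≤ 0.005
  (Student-t p with n − 2 df); constant traits yield NaN and are never
  significant.

## 4. Metabolites, transcript–metabolite network, triage

- **Differential abundance:** log2FC = log2(mean_b / mean_a) on the raw
  scale, two-sided Welch t on log2 abundances, significant iff
  |log2FC| ≥ 1 and p ≤ 0.05 (inclusive).
- **Network edges:** Pearson correlation of log2FC profiles over a shared
  condition axis (≥ 3 conditions), edge iff PCC > 0.90 and p < 0.001
  (strict). The rule is one-sided: strong *negative* correlations are
  excluded by design.
- **Triage** applies three conjunctive rules per orthogroup (grey modules
  skipped): (1) freshwater mean expression above focal mean, in a
  freshwater-associated non-focal-specific module; (2) focal expression
  lower under high than low salinity, in a saltwater-associated
  focal-specific module; (3) copy number expanded in freshwater species
  relative to the focal species (majority comparator by default; mean
  available), in a freshwater-associated non-focal-specific module.
- **Summary statistics:** Wald t = β/SE with Student-t p and 95% CI;
  Bonferroni and Benjamini–Hochberg adjustments (with optional test-count
  override) for multiple testing.

## 5. Synthetic generators

All generators are deterministic under their seed; a root seed fans out to
independent substreams (`presence`, `expression`, `metabolites`) via
`numpy.random.SeedSequence`, so adding one generator call never perturbs
another. Default problem sizes are this package's own desk-scale choices.

- **Presence-absence** (default 20 + 20 species, 2000 families): planted
  saltwater families are present with p_hi = 0.9 in saltwater species and
  p_lo = 0.05 in freshwater species (mirrored for freshwater-planted);
  background families are present with p_bg = 0.3 everywhere. Present
  entries get 1 + Poisson(1) gene copies. Defaults plant 10 saltwater vs 20
  freshwater families: the asymmetry mirrors the fresh-skew of real
  featured sets and is required for the *pooled* association table to carry
  signal (see the cancellation caveat above). The balanced 20/20 habitat
  split keeps the expected false-discovery proportion of the cutoff rule
  below 20% at p_bg = 0.3.
- **Expression** (default 300 metagenes over a 24-sample design: 2 species
  × 2 salinity levels × 2 timepoints × 3 replicates): metagene profiles
  follow the factor model x = loading · f + ε with ε ~ N(0, 0.3²) and f a
  standardized design factor. Default planted modules (3 × 40 metagenes,
  loading 0.9) use the three mutually **orthogonal** factorial axes —
  freshwater-strain indicator, stress duration, stress/damage indicator.
  Salinity severity is a linear mix of strain and stress in this design
  (cor ≈ −0.89 with strain), so severity-planted modules would not be
  identifiable as separate clusters; orthogonality is what makes "module
  recovery" well-posed. Latent profiles map to FPKM-like abundances by
  20 + 5x clipped at zero (downstream correlations are shift-invariant),
  and each metagene splits into 1–3 gene copies per species with fixed
  random weights, so aggregation recovers the metagene exactly.
- **Metabolites** (default 451 compounds, 150 differentially abundant,
  3 replicates): true |log2FC| uniform in [1, 4] with random sign;
  replicate noise is lognormal with CV 0.1, mean-corrected to 1.

**Scope and limitations.** The generators emulate the statistical structure
each stage assumes, not algal biology: no phylogenetic correlation between
species, no gene-length/GC biases, no count overdispersion, and no planted
coupling between transcripts and metabolites — with only three replicate
contrasts and the strict p < 0.001 edge rule, the synthetic
transcript–metabolite network is typically empty, which is the correct
behavior, not a defect. Pipeline triage rules 1 and 3 fire through the
strain-linked module; rule 2 may legitimately yield no candidates on
synthetic data.

## 6. Pipeline and reproducibility

`run_pipeline` executes simulate → featured → mlselect → coexpress →
integrate in one working directory. Per-stage seeds derive from the root
seed via CRC32-keyed `SeedSequence`, recorded in `manifest.json` together
with the full config echo, per-stage wall time and SHA-256 digests of every
output file. Reruns under the same seed are byte-identical. The end-to-end
default registry is a compact set of sparse/importance selectors × linear
classifiers (10 combinations) so weight-based categorization is always
available; the full 130-combination registry is reachable with
`mlselect --full-registry`.

Transcript log2FC profiles in the integrate stage pair the focal species'
high- vs low-salinity replicates at the latest timepoint (matching when a
metabolome is typically sampled), giving profile length = replicate count.

Numerical notes: all float TSV output uses the `%.10g` format; module and
family orderings are fully deterministic (no hash iteration order);
scikit-learn estimators are pinned to fixed `random_state` seeds and
single-threaded (`n_jobs=1`).
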