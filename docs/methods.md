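# Methods

This note documents the models and procedures `nifcast` implements,
the defaults it ships, and what its synthetic benchmarks do and do not
demonstrate.

## Problem setting

Each sample is a bacterial strain with measured nitrogenase activity
(acetylene reduction, nmol C₂H₄/mg protein/hour), its nitrogenase
protein sequences, the coding sequences of its nif genes, and a genome
annotation slice.  Two supervised tasks are posed on a cohort of such
strains: classify high vs low activity at a 50-unit threshold (ties at
exactly 50 count as high — the raw rule covers only strictly above /
below, so a documented tie rule is required), and regress the
transformed activity y = log₁₀(x + 2).  The +2 offset keeps y finite
at x = 0 and the log compresses the heavy right tail so that
mean-squared losses are not dominated by a few hyperactive strains;
the inverse map x = 10ʸ − 2 restores the measurement scale.

## Feature blocks

**Pooled embedding (1024).**  A backend maps a protein of length L to
an L × 1024 per-residue matrix; the mean over residues gives the
strain-level vector.  The backend is a contract: the default
`MockEmbedder` assigns each residue identity a fixed seeded
pseudo-random unit vector, so the pooled vector is exactly a
composition-weighted average — deterministic, dependency-free, and
carrying genuine composition signal.  An optional adapter
(`nifcast.plm`) plugs a real transformer protein language model into
the same contract; nothing in the package or its tests requires it.
When a strain has several nitrogenase proteins, each protein is
encoded separately and the encodings averaged (a config-level choice;
pooling residues across proteins before encoding would weight long
proteins more).

**Conjoint triads (343).**  The 20 residues are grouped into 7 classes
by side-chain dipole and volume — {A,G,V}, {I,L,F,P}, {Y,M,T,S},
{H,N,Q,W}, {R,K}, {D,E}, {C}, the canonical clustering of this scheme —
and the frequencies of all 7³ class triples over the L−2 windows are
recorded.  Window-count normalization (divide by L−2) makes vectors
length-independent probability vectors.

**Dipeptide composition (400).**  Adjacent-pair frequencies over the
L−1 windows, same normalization rationale.

**Pseudo-amino-acid composition (50 = 20 + λ).**  Chou's scheme with
λ = 30 and weight w = 0.05: 20 composition components and λ
sequence-order correlation factors θⱼ, where θⱼ averages, over
positions i, the mean squared difference of three physicochemical
scales (hydrophobicity, hydrophilicity, side-chain mass, each z-scored
over the 20 residues) between residues i and i+j.  The published
dimensionality fixes only the 20+30 split; λ and w are the standard
defaults and are exposed as parameters.  Sequences must be longer than
λ.

**Codon statistics.**  All statistics run over the 61 sense codons of
the standard code minus the single-codon families ATG and TGG — the 59
codons where a synonymous choice exists.  Including the single-codon
families would not change ECD (their RSCU is identically 1) but 59 is
the documented convention.

* RSCU(c) = count(c) / mean count in its family; families absent from
  a gene are neutral (all 1).
* ECD = √Σ(RSCUᵢ − 1)² over the 59 codons — the genome's codon-bias
  strength, 0 for perfectly uniform synonymous usage.
* Relative adaptiveness w(c) = count(c)/max count in family, from a
  reference set of highly expressed genes; zero-count codons get the
  Sharp–Li floor w = 0.01, unobserved families are neutral (w = 1).
  CAI is the geometric mean of w over a gene's scoreable codons; Fop
  the fraction of codons with w = 1.
* E: per family of size k with within-family frequencies f, the
  total-variation distance d = ½Σ|f − 1/k| to uniform usage; E is the
  codon-share-weighted average of d over families.  The verbal
  definition ("deviation from uniform, weighted average") admits
  several weightings; codon share is simple and oracle-testable, and
  is the one implemented.  Gene-level E values serve as expression
  proxies (biased usage correlates with high expression).
* Per-strain features: `Average_<gene>_{E,Fop,CAI}` over the copies of
  each configured gene (default repertoire: lnA/nifA alias, nifB,
  nifD, nifH, nifK, nifE, nifN, nifX), the genome ECD, and the 59
  genome RSCU values.  Missing genes yield NaN, imputed downstream.
  For real data the reference set should be user-supplied ribosomal
  protein CDSs; the default fallback derives it from the cohort's
  pooled CDSs.

**Gene context.**  Distances dist_nifD_nifK, dist_nifK_nifH,
dist_nifD_nifH are the minimal start-minus-end gap over copy pairs on
a shared contig (0 when intervals overlap), strand-agnostic; the gap
convention (rather than midpoint or start-to-start) best reflects
proximity to shared regulatory regions.  Cross-contig or absent pairs
are NaN — an honest missing value for the imputer, not an arbitrary
large constant.  Copy numbers are exact annotation counts per
normalized gene token over a 15-gene nif repertoire
(nifB/D/E/F/H/K/M/N/S/T/U/V/W/X/Z).

## Splits and evaluation

The stratified 80/20 split takes exactly ⌊0.8·nₖ⌋ training samples per
class, remainder to test — the unique simple rounding rule that maps a
209/193 cohort to (167, 154) train and (42, 39) test.  Counts are a
deterministic function of class sizes; the seed only shuffles
membership.  Five-fold cross-validation runs inside the training set
(stratified for classification, plain partition for regression); each
fold's model is scored on its training part, its validation fold, and
the one fixed test set, and metrics are averaged over folds.  RMSE is
recomputed from the fold-averaged MSE so MSE = RMSE² holds in every
report row.  Classification reports AUC, precision, recall, F1 (the
operating point is probability ≥ 0.5); regression reports R², RMSE,
MSE, MAE on the transformed scale.

## Models and stacking

Six families with fixed, config-overridable defaults and no automated
tuning: random forest (200 trees), RBF-kernel SVM/SVR (C = 1,
Platt-scaled probabilities for classification), XGBoost (200 trees,
depth 4, lr 0.1, hist), LightGBM (200 trees), classic gradient
boosting (100 trees), and a one-hidden-layer MLP (128 units).  Every
estimator sits in a pipeline with median imputation (fit on its
training partition only; empty features are kept so the schema never
changes width) plus standardization for SVM/MLP, behind a wrapper that
freezes the ordered feature-name schema at fit time.

The stacked model trains layer 1 on the embedding block and layer 2 on
the layer-1 prediction concatenated with the auxiliary block.  Layer
2's *training* input uses layer-1 out-of-fold predictions — fitting
layer 2 on in-sample layer-1 fits would leak the training labels into
its input and overstate the first-layer feature — while inference uses
layer 1's direct prediction.  In the benchmark harness, stacked
variants are built for the top-3 regression families by validation R²,
with the same family in both layers.

## Attribution

Three Shapley backends, chosen by model family, all satisfying local
accuracy (base value + Σ attributions = prediction):

* **Tree-path attribution** (in-package, float64) for sklearn forests
  and gradient boosting: the polynomial-time EXTEND/UNWIND recursion
  whose conditional expectations follow the trees' training cover.
  Exact — verified against brute-force subset enumeration — with
  additivity gaps ~1e−15.
* **Native contributions** for XGBoost/LightGBM (`pred_contribs`):
  the same algorithm inside those libraries, computed in float32, so
  additivity holds to ~1e−6.
* **Kernel attribution** (in-package) for SVM/MLP: interventional
  coalition values against a background sample (default 100 seeded
  training rows), solved by constrained weighted least squares; the
  constraint makes additivity exact, and full coalition enumeration
  (feature counts ≤ 13) makes the values exactly Shapley.  Cost grows
  with 2^M or the sampling budget, so kernel attribution is for
  compact feature sets; wide models should use a tree layer 2.

Attributions for pipeline models are computed after the column-wise
imputation/scaling steps, so attribution i maps 1:1 to input feature i.
Reported summaries are computed on the held-out test partition (the
generalization-relevant choice).  `sign_analysis` reports, per feature,
the mean |attribution| and the Pearson correlation between feature
value and attribution; a constant feature has no defined direction and
reports NaN rather than 0.  `copy_shap_table` averages the copy-number
feature's attribution over the strains showing each observed copy
count, and `minimal_cluster` picks, per prevalent gene (present in
strictly more than half of strains), the copy number with the highest
mean attribution, ties resolving to fewer copies (parsimony).

## Synthetic cohort

`generate_strains` draws, per strain, one latent state that coherently
drives all feature blocks: an amino-acid composition
(Dirichlet, concentration 30 — fraction s.d. ≈ 0.04, comparable to
composition variation across real nitrogenases) shapes the NifH/D/K
proteins; a per-family codon preference (Dirichlet α = 0.5, giving
clearly biased genomes) combined with a per-gene-copy bias intensity
(Beta(2,2) mixture toward uniform) shapes the back-translated CDSs and
hence E/Fop/CAI and ECD; copy numbers are 1 + Poisson(0.4) for
structural genes and present-with-0.85 for the rest; genes are laid on
one contig with log-uniform gaps (≈30 bp–20 kb), so nifD–nifK distance
varies over orders of magnitude.  CDSs translate back to their
proteins exactly.

Transformed activity is y = 2.05 + Σ coeffₖ·z(featureₖ) + N(0, 0.3),
where z is the cohort z-score of the *realized* feature value
(computed with the package's own measures) and the default effects are
+0.3 on Ala and Gln content and on Average_nifD_E / Average_nifK_E,
−0.3 on dist_nifD_nifK.  The baseline puts the cohort median activity
near 110 units, populating both classes (≈ ⅔ high-activity) while
keeping the zero-activity floor rare: raw activities are clipped at 0
(the domain of the log transform) and the clipping rate at these
defaults stays below 1% and is reported in the ground-truth table.

For the stacking comparison, the study condition "activity depends
only on the embedding block" is realized by planting effects directly
on pooled-embedding coordinates (`emb_000d`).  Planting composition
effects would not realize that condition: the auxiliary PAAC block
carries composition just as directly as the mock embedding does, which
would make the auxiliary-only baseline an equal-information competitor
rather than a control.

**What the benchmarks show — and don't.**  Passing sign recovery shows
the pipeline can attribute planted, approximately linear effects with
the right directions at realistic cohort sizes (n = 500) and noise.
Real activity data differ in ways the generator deliberately omits:
phylogenetic correlation between strains, non-linear and interacting
effects, annotation errors, multi-contig assemblies, and an embedding
that reflects structure rather than pure composition.  Benchmarks here
validate the machinery, not the biology; headline performance numbers
on real cohorts require the real curated dataset and a real embedder.

## Numerical choices and degenerate inputs

Probability-vector encoders are exact to 1e−12 in tests.  Codons
containing N are skipped by all codon statistics.  A gene with no
degenerate-family codons cannot be CAI/Fop-scored and errors; a gene
absent from a strain yields NaN features.  Protein sanitization drops
the non-standard codes X/B/Z/U/J/O/* and rejects records losing more
than 10% of residues.  RSCU of an unobserved family is neutral (1).
Ties: activity exactly at threshold → positive; equal mean attribution
across copy numbers → smaller copy.  Fold counts differ by at most
one sample; stratified folds keep each fold's class count within one
of the proportional share.

## Problem sizes used by the shipped benchmarks

Sign recovery runs 5 seeds at n = 500; the stacking comparison 5 seeds
at n = 300; additivity at n = 120; the formula oracles at 100 random
CDSs and 200 score/label pairs.  These sizes give stable verdicts
(observed margins are comfortable) at desk-scale runtimes.

## Known limitations

* The E statistic follows the verbal definition above; other codon
  packages implement related but not identical expression measures, so
  absolute E values are not interchangeable across tools.
* Kernel attribution is exponential in features when exact and
  sampling-approximate beyond 13 features; classifier attribution for
  sklearn forests/GBMs is not implemented (use xgboost/lightgbm
  families there).
* The stacked model passes a single scalar from layer 1 to layer 2;
  richer interfaces (per-fold ensembles, uncertainty) are out of scope.
* The mock embedder is order-blind by construction; sequence-order
  effects reach the models only through triads, dipeptides and PAAC θ.
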