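# Methods

## Model

`tnbayes` treats a compound as a binary pattern **x** ∈ {0,1}^L and scores
each activity class ω_j with the tapered discriminant

    g_j(x) = Σ_l x_l log p(ω_j|x_l=1)
           + λ Σ_l (1−x_l) log p(ω_j|x_l=0)
           − (L−1) log p(ω_j),     0 ≤ λ ≤ 1,

predicting argmax_j g_j(x).  λ=1 is the standard Bernoulli Naive Bayes
(SNB) written in per-feature-posterior form; λ=0 discards the
absent-feature sum and is the Laplacian-corrected modified Naive Bayes
(LCMNB); intermediate λ attenuates ("tapers") the absence contribution.
The taper is restricted to [0,1] because in the sparse high-dimensional
regime the absence sum is the term whose evidence the conditional
independence assumption overstates — amplifying it (λ>1) has no rationale.
`score()` accepts `strict_lambda=False` to lift the bound for research
use; the default is strict.

The modelling assumptions are those of any Bernoulli Naive Bayes:
features conditionally independent given the class, stationary
class-conditional Bernoulli rates, and 0/1 loss.  At λ=1 the softmax of
the scores is the exact model posterior, because the feature-marginal
terms dropped from the full Bayes decomposition are class-independent.
For λ<1 the softmax is a normalised score, not a calibrated probability.

## Estimation

Sufficient statistics are the class sizes N_ωj and the per-(class,
feature) presence counts N_lj.  Rates are Beta-smoothed,

    p(x_l=1|ω_j) = (N_lj + α_j) / (N_ωj + α_j + β_j),

with α_j = β_j = 1 (Laplace) by default; any strictly positive per-class
values are accepted.  The class prior is empirical, p(ω_j) = N_ωj/N, with
a uniform option (the prior enters the stored posteriors *and* the
(L−1)·log p(ω_j) correction, and the uniform option replaces it
everywhere consistently).  The feature marginal p(x_l) = Σ_j
p(x_l|ω_j) p(ω_j) is built from the smoothed conditionals and the model
prior, so every stored probability lies strictly inside (0,1) and the
per-feature class posteriors sum to one to ~1e−16.  No stored logarithm
is ever −∞, regardless of zero counts.

Numerical conventions: natural logarithms throughout (any base gives the
same argmax); all scoring is a pair of matrix products in log space;
score ties are broken toward the smallest class index, which makes
predictions independent of row order and reproducible.

## Evaluation protocol

* **Stratified k-fold CV** (k=10 default): within each class, members are
  shuffled by a seeded generator and dealt round-robin to folds, so
  per-class fold counts differ by at most one.  A class that fails to
  reach some training fold raises an error suggesting a smaller k.
* **Feature selection inside the loop**: by default the
  mutual-information ranking is recomputed on each fold's training
  portion (no test-set leakage); a `global` scope ranks once on the full
  dataset for comparison.  Selection keeps the top p% of the ranking,
  with k = round(p/100 · L) rounded half away from zero and floored at 1;
  this convention reproduces the published subset sizes of a 23,324-bit
  fingerprint universe (20% → 4,665, 38% → 8,863, 40% → 9,330, …).
* **Pooled confusion matrix**: held-out predictions from all folds are
  pooled into one J×J matrix before computing MCC.  Pooling was chosen
  over averaging per-fold MCCs because per-fold class counts are small;
  per-fold confusion matrices remain available through the report.
* **Multiclass MCC**: Gorodkin's R_K statistic
  (c·s − Σ p_k t_k) / √((s²−Σp_k²)(s²−Σt_k²)), defined as 0 when either
  variance factor vanishes.  It reduces exactly to the classic binary MCC
  at J=2 (cross-checked against scikit-learn in the tests).  Per-class
  values are the binary MCC of the one-vs-rest collapse of the pooled
  matrix — the conventional reading of per-target columns.
* **McNemar's test** on the pooled CV predictions of two classifiers:
  b = #(A wrong, B right), c = #(A right, B wrong),
  χ² = (b−c)²/(b+c) with df 1 (0 when b+c=0), compared against 3.84
  (χ²₀.₀₅; asserted at import against the scipy quantile).  The
  continuity-corrected (|b−c|−1)²/(b+c) variant sits behind a flag; the
  uncorrected statistic is the default.  Applying the test to pooled CV
  predictions ignores the dependence between folds; treat borderline
  verdicts with caution.
* **Grid sweep**: every (λ, percent) cell of the Cartesian grid is
  cross-validated on identical fold assignments, so a sweep cell is
  arithmetically identical to a standalone run.  The default schedule is
  λ ∈ {0, 0.2, …, 1.0} over percents {1, 2, 4, 6, …, 98, 100}, with an
  optional second stage refining λ ∈ [0.05, 0.35] in 0.05 steps.  The
  winning cell is the maximum MCC; ties go to the smaller λ, then the
  smaller percent.

## Synthetic data

The generator draws class-conditional Bernoulli fingerprints: J classes,
L bits, n_per_class patterns per class.  The first n_informative bits are
diagnostic — bit l fires at `signal_rate` in class l mod J and at
`base_rate` elsewhere — and are always drawn independently.  The
remaining bits form the uninformative tail, partitioned into consecutive
blocks of `block_size`.  Per pattern and block a latent "concept" toggle
is drawn Bernoulli(base_rate); each tail bit copies the toggle with
probability `block_corr` and otherwise draws independently at base_rate.
This mechanism leaves every marginal rate exactly equal to the returned
θ matrix — only the dependence structure changes — so the same θ serves
both rate-recovery tests and Bayes-oracle baselines.  An earlier design
with a Bernoulli(0.5) toggle was rejected: it distorts the marginals to
c/2+(1−c)θ, destroys sparsity, and its correlated component carries no
structure a presence-only classifier could be differentially robust to.

The defaults (J=10, L=4,000, n=150/class, 100 informative bits,
base_rate 0.02, signal_rate 0.3, blocks of 80 at copy probability 0.8)
are a desk-scale version of a curated bioactivity corpus: a few thousand
compounds, tens of classes, ~2% bit density, an L/N ratio well above 1,
ten reliable diagnostic bits per class, and a large redundant tail of
co-occurring bits.  Under these conditions the characteristic phenomena
appear: at full feature length LCMNB beats SNB (the correlated tail's
absence terms swamp the short presence sum), at the
mutual-information-optimal cut SNB beats LCMNB (absence of a diagnostic
bit is genuine evidence, and presence-poor compounds need it), and at
full length some interior λ matches or beats both endpoints.

What the generator does *not* emulate: heterogeneous per-bit signal
strengths, bits shared between classes, class imbalance, hash collisions,
and activity-threshold noise.  Passing the tapering tests therefore shows
that the implementation reproduces the mechanism, not that any particular
λ generalises to a given screening corpus — λ and the feature percentage
should always be re-optimised per dataset, which is what `sweep` is for.

Curation helpers mirror standard practice: all-zero fingerprint columns
can be pruned, and the activity cutoff is mean + 1 sample SD (ddof = 1)
of the −log10 activities; a flag skips the transform when the input is
already in pKi/pIC50 form.

## Problem sizes

The test suite and the acceptance script run at deliberately modest
sizes chosen for tight statistical control: exhaustive oracle comparison
at L=10/J=3 (1,024 patterns), rate recovery at J=4, L=300, n=2,000 per
class, and a ten-replicate taper study at the generator defaults
(1,500×4,000 per replicate, full λ×percent grid, ten folds).  The whole
acceptance run completes in well under a minute on one core.

## Known limitations

* Scores are linear discriminants; no calibration of posteriors at λ<1.
* Binary features only — count or continuous descriptors are out of
  scope, as is computing fingerprints from structures.
* McNemar on pooled CV predictions has optimistic variance (see above).
* The fold-wise MI ranking makes sweeps O(k·L·N) per grid column; at the
  default sizes this is seconds, but for L in the hundreds of thousands
  the global-ranking mode is markedly faster at some leakage cost.
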