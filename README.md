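# tnbayes — Tapered Naive Bayes for binary fingerprints

`tnbayes` classifies compounds represented by sparse binary fingerprints
(e.g. ECFP4 bit vectors) into activity classes, for ligand-based virtual
screening and target prediction.  It implements the family of Bernoulli
Naive Bayes classifiers that differ only in how they treat the *absence*
of a feature, together with the full evaluation protocol needed to compare
them: mutual-information feature ranking, stratified k-fold
cross-validation, the multiclass Matthews correlation coefficient, and
McNemar's paired test.

## The model

A compound is a binary vector **x** ∈ {0,1}^L; classes are ω₁…ω_J.  The
tapered log score of class ω_j is

    g_j(x) = Σ_l x_l · log p(ω_j | x_l = 1)
           + λ · Σ_l (1 − x_l) · log p(ω_j | x_l = 0)
           − (L − 1) · log p(ω_j),        λ ∈ [0, 1]

and the predicted class is argmax_j g_j(x).

* λ = 1 — **SNB**, the standard Bernoulli Naive Bayes: presence and
  absence both count.
* λ = 0 — **LCMNB**, the Laplacian-corrected modified Naive Bayes:
  absence is discarded entirely.
* 0 < λ < 1 — **TNB**, the tapered classifier: absence is attenuated.

The per-feature posteriors come from Beta-smoothed Bernoulli estimates
(α_j = β_j = 1, Laplace's rule),

    p(x_l=1 | ω_j) = (N_lj + α_j) / (N_ω_j + α_j + β_j),
    p(ω_j | x_l=v) = p(x_l=v | ω_j) p(ω_j) / p(x_l=v),

with p(ω_j) = N_ω_j / N (or uniform) and
p(x_l) = Σ_j p(x_l|ω_j) p(ω_j).  All scoring is done in log space.

Why taper?  In the sparse high-dimensional regime nearly every bit is
absent, so the absence sum runs over thousands of weak, mutually
correlated terms whose evidence the independence assumption overcounts;
the presence sum is short and reliable.  Discarding absence (λ=0) throws
away genuine signal; keeping it fully (λ=1) drowns the score in
correlated noise.  An intermediate λ — found by cross-validated grid
search — typically beats both.

## Worked example

```
$ tnbayes simulate --out data                      # default synthetic study conditions
wrote 1500 x 4000 dataset to data
$ tnbayes cv --in data/train.fps --lambda 1 --percent 100 --k 10 --out snb
mcc=0.2107 (10-fold, lambda=1, percent=100)
$ tnbayes cv --in data/train.fps --lambda 0 --percent 100 --k 10 --out lcmnb
mcc=0.3019 (10-fold, lambda=0, percent=100)
$ tnbayes cv --in data/train.fps --lambda 0.2 --percent 100 --k 10 --out tnb
mcc=0.3117 (10-fold, lambda=0.2, percent=100)
$ tnbayes mcnemar --in data/train.fps --report-a snb/report.json --report-b lcmnb/report.json
chi2=57.091 (df=1, b=194, c=71): classifiers different at the 0.05 level
$ tnbayes sweep --in data/train.fps --two-stage --k 10 --out sw
best mcc=0.8290 at lambda=1, percent=4
```

The simulated dataset holds 1,500 compounds in 10 classes over 4,000 bits
(10 truly diagnostic bits per class; a large correlated uninformative
tail).  At full feature length the presence-only classifier (λ=0,
MCC 0.30) clearly beats the standard one (λ=1, MCC 0.21) — McNemar's test
confirms the difference is real (χ² = 57.1 ≫ 3.84) — and a partial taper
(λ=0.2, MCC 0.31) edges out both endpoints.  The full grid sweep shows
that mutual-information feature selection changes the picture entirely:
once the correlated tail is cut away (top 4% of bits), absence evidence
becomes an asset again and the best cell of the whole grid keeps it in
full (MCC 0.83 at λ=1).  The same commands run on any dataset in the
dense CSV (`id,label,f1,…,fL`) or sparse index-list (`.fps`) format.

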