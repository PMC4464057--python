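"""Bernoulli Naive Bayes variants for binary fingerprints: SNB, LCMNB, TNB.

The three classifiers share one discriminant.  For a pattern ``x`` in
``{0,1}^L`` and class ``w_j`` the tapered score is

    g_j(x) = sum_l x_l log p(w_j | x_l = 1)
             + lambda * sum_l (1 - x_l) log p(w_j | x_l = 0)
             - (L - 1) log p(w_j)

with the taper ``lambda`` in [0, 1].  ``lambda = 1`` is the standard
Bernoulli ("SNB") discriminant, ``lambda = 0`` discards the absent-feature
term and recovers the Laplacian-corrected modified Naive Bayes ("LCMNB");
intermediate values attenuate the absence contribution, which is the useful
regime when the features are high-dimensional, sparse and correlated.

Per-feature class posteriors come from Beta-smoothed Bernoulli estimates

    p(x_l=1 | w_j) = (N_lj + alpha_j) / (N_wj + alpha_j + beta_j)

with class prior ``p(w_j) = N_wj / N`` (or uniform), marginal
``p(x_l) = sum_j p(x_l | w_j) p(w_j)`` and Bayes inversion
``p(w_j | x_l) = p(x_l | w_j) p(w_j) / p(x_l)``.  All scoring is done with
sums of natural logarithms to avoid underflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fingerprints_io import LabeledDataset

__all__ = [
    "ClassCounts",
    "SmoothingParams",
    "NBModel",
    "ScoreVector",
    "ConditionDiagnostics",
    "tally_counts",
    "estimate_model",
    "fit",
    "score",
    "score_matrix",
    "classify",
    "posterior_probabilities",
    "brute_force_posterior",
    "condition_diagnostics",
]


@dataclass(frozen=True)
class ClassCounts:
    """Sufficient statistics of a training set.

    ``n_total`` is N, ``n_class[j]`` is the number of training patterns in
    class j, and ``n_present[j, l]`` counts how often feature l is set (=1)
    among the class-j patterns.
    """

    n_total: int
    n_class: np.ndarray  # (J,)
    n_present: np.ndarray  # (J, L)
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if int(self.n_class.sum()) != self.n_total:
            raise ValueError("class counts must sum to the total")
        if (self.n_present > self.n_class[:, None]).any() or (self.n_present < 0).any():
            raise ValueError("need 0 <= N_lj <= N_wj")


@dataclass(frozen=True)
class SmoothingParams:
    """Per-class Beta prior parameters; ``alpha = beta = 1`` is Laplace's rule."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if (alpha <= 0).any() or (beta <= 0).any():
            raise ValueError("smoothing parameters must be strictly positive")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    @staticmethod
    def laplace(n_classes: int) -> "SmoothingParams":
        return SmoothingParams(np.ones(n_classes), np.ones(n_classes))


@dataclass(frozen=True)
class ScoreVector:
    """Unnormalised per-class log scores of one pattern at a given taper."""

    scores: np.ndarray  # (J,)
    lam: float


@dataclass(frozen=True)
class ConditionDiagnostics:
    """Per-pattern magnitudes of the two score terms, for checking whether
    discarding the absence term is harmless.

    Discarding absence is benign when (1) the absent-term sum is (nearly)
    class-independent, and (2) the present-term magnitude dominates the
    absent-term magnitude.  ``absent_range`` is the across-class range of
    the absent-term per pattern (condition 1 holds when it is ~0);
    comparing ``present_abs`` with ``absent_abs`` checks condition 2.
    """

    present_abs: np.ndarray  # (N, J) |sum_l x_l log p(w_j|x_l=1)|
    absent_abs: np.ndarray  # (N, J) |sum_l (1-x_l) log p(w_j|x_l=0)|
    absent_range: np.ndarray  # (N,) max_j - min_j of the absent term


class NBModel:
    """Fitted model: log prior and per-(class, feature) log posteriors.

    Stores ``log p(w_j)``, ``log p(w_j | x_l = 1)`` and
    ``log p(w_j | x_l = 0)`` — everything the tapered discriminant needs.
    """

    def __init__(
        self,
        log_prior: np.ndarray,
        log_post_present: np.ndarray,
        log_post_absent: np.ndarray,
        prior_mode: str = "empirical",
        class_names: tuple[str, ...] | None = None,
        smoothing: SmoothingParams | None = None,
    ) -> None:
        self.log_prior = np.asarray(log_prior, dtype=float)
        self.log_post_present = np.asarray(log_post_present, dtype=float)
        self.log_post_absent = np.asarray(log_post_absent, dtype=float)
        self.prior_mode = prior_mode
        self.n_classes, self.n_features = self.log_post_present.shape
        self.class_names = class_names or tuple(
            f"class{j + 1}" for j in range(self.n_classes)
        )
        self.smoothing = smoothing
        if self.log_post_absent.shape != self.log_post_present.shape:
            raise ValueError("posterior tables must share one (J, L) shape")
        if self.log_prior.shape != (self.n_classes,):
            raise ValueError("log_prior must have length J")
        for arr in (self.log_prior, self.log_post_present, self.log_post_absent):
            if not (np.isfinite(arr).all() and (arr < 0).all()):
                raise ValueError("stored log probabilities must be finite and < 0")

    # -- persistence ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "J": self.n_classes,
            "L": self.n_features,
            "prior_mode": self.prior_mode,
            "class_names": list(self.class_names),
            "log_prior": self.log_prior.tolist(),
            "log_post_present": self.log_post_present.tolist(),
            "log_post_absent": self.log_post_absent.tolist(),
        }
        if self.smoothing is not None:
            doc["alpha"] = self.smoothing.alpha.tolist()
            doc["beta"] = self.smoothing.beta.tolist()
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(doc, fh)
            fh.write("\n")

    @staticmethod
    def from_json(path: str | Path) -> "NBModel":
        with Path(path).open(encoding="utf-8") as fh:
            doc = json.load(fh)
        smoothing = None
        if "alpha" in doc:
            smoothing = SmoothingParams(np.asarray(doc["alpha"]), np.asarray(doc["beta"]))
        return NBModel(
            np.asarray(doc["log_prior"]),
            np.asarray(doc["log_post_present"]),
            np.asarray(doc["log_post_absent"]),
            prior_mode=doc["prior_mode"],
            class_names=tuple(doc["class_names"]),
            smoothing=smoothing,
        )


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def tally_counts(train: LabeledDataset) -> ClassCounts:
    """Exact integer sufficient statistics; independent of row order."""
    if train.n_patterns < 1 or train.n_features < 1:
        raise ValueError("empty training set")
    J = train.n_classes
    n_class = np.bincount(train.labels, minlength=J)
    n_present = np.zeros((J, train.n_features), dtype=np.int64)
    for j in range(J):
        n_present[j] = train.patterns[train.labels == j].sum(axis=0)
    return ClassCounts(
        n_total=train.n_patterns,
        n_class=n_class.astype(np.int64),
        n_present=n_present,
        class_names=train.class_names,
    )


def estimate_model(
    counts: ClassCounts,
    smoothing: SmoothingParams | None = None,
    prior_mode: str = "empirical",
) -> NBModel:
    """Turn counts into the log-probability tables of an :class:`NBModel`.

    ``prior_mode="uniform"`` replaces the empirical prior by 1/J everywhere
    the prior enters (including the feature marginal p(x_l)).
    """
    J, L = counts.n_present.shape
    if J < 2:
        raise ValueError("need at least two classes to build a classifier")
    if prior_mode not in ("empirical", "uniform"):
        raise ValueError("prior_mode must be 'empirical' or 'uniform'")
    if smoothing is None:
        smoothing = SmoothingParams.laplace(J)
    alpha = np.broadcast_to(smoothing.alpha, (J,)).astype(float)
    beta = np.broadcast_to(smoothing.beta, (J,)).astype(float)

    # Beta-smoothed Bernoulli rates; strictly inside (0, 1) for alpha,beta > 0.
    p_present = (counts.n_present + alpha[:, None]) / (
        counts.n_class + alpha + beta
    )[:, None]
    p_absent = 1.0 - p_present
    if prior_mode == "uniform":
        prior = np.full(J, 1.0 / J)
    else:
        prior = counts.n_class / counts.n_total
        if (prior == 0).any():
            raise ValueError("empirical prior undefined: a class has no patterns")
    p_feat = prior @ p_present  # p(x_l = 1), length L
    post_present = p_present * prior[:, None] / p_feat
    post_absent = p_absent * prior[:, None] / (1.0 - p_feat)
    return NBModel(
        log_prior=np.log(prior),
        log_post_present=np.log(post_present),
        log_post_absent=np.log(post_absent),
        prior_mode=prior_mode,
        class_names=counts.class_names,
        smoothing=SmoothingParams(alpha, beta),
    )


def fit(
    train: LabeledDataset,
    smoothing: SmoothingParams | None = None,
    prior_mode: str = "empirical",
) -> NBModel:
    """Convenience: ``estimate_model(tally_counts(train))``."""
    train.require_trainable()
    return estimate_model(tally_counts(train), smoothing, prior_mode)


# ---------------------------------------------------------------------------
# scoring and decision
# ---------------------------------------------------------------------------

def _check_lambda(lam: float, strict: bool = True) -> float:
    lam = float(lam)
    if strict and not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lam


def _as_pattern_matrix(model: NBModel, patterns: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(patterns)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != model.n_features:
        raise ValueError(
            f"pattern length {arr.shape[1]} does not match model L={model.n_features}"
        )
    if arr.size and (arr.max() > 1 or arr.min() < 0):
        raise ValueError("pattern entries must be 0 or 1")
    return arr.astype(float), single


def score_matrix(
    model: NBModel, patterns: np.ndarray, lam: float, strict_lambda: bool = True
) -> np.ndarray:
    """Tapered scores for a batch: returns an ``(N, J)`` array."""
    lam = _check_lambda(lam, strict_lambda)
    X, _ = _as_pattern_matrix(model, patterns)
    present = X @ model.log_post_present.T
    absent = (1.0 - X) @ model.log_post_absent.T
    prior_term = (model.n_features - 1) * model.log_prior
    return present + lam * absent - prior_term[None, :]


def score(
    model: NBModel, pattern: np.ndarray, lam: float, strict_lambda: bool = True
) -> ScoreVector:
    """Per-class tapered log score of one pattern."""
    return ScoreVector(score_matrix(model, pattern, lam, strict_lambda)[0], float(lam))


def classify(model: NBModel, patterns: np.ndarray, lam: float) -> np.ndarray | int:
    """Maximum-score class (0-based code); ties go to the smallest code."""
    _, single = _as_pattern_matrix(model, patterns)
    codes = np.argmax(score_matrix(model, patterns, lam), axis=1)
    return int(codes[0]) if single else codes


def posterior_probabilities(
    model: NBModel, patterns: np.ndarray, lam: float
) -> np.ndarray:
    """Softmax of the tapered scores.

    At ``lam = 1`` this equals the exact Naive Bayes posterior, because the
    terms dropped from the full Bayes decomposition are class-independent
    and cancel under normalisation.  For other tapers it is a normalised
    score, not a calibrated probability.
    """
    s = score_matrix(model, patterns, lam)
    s = s - s.max(axis=1, keepdims=True)
    p = np.exp(s)
    p /= p.sum(axis=1, keepdims=True)
    _, single = _as_pattern_matrix(model, patterns)
    return p[0] if single else p


def brute_force_posterior(
    cond_present: np.ndarray, prior: np.ndarray, pattern: np.ndarray
) -> np.ndarray:
    """Testing oracle: exact Bayes posterior by direct probability products.

    ``cond_present[j, l] = p(x_l = 1 | w_j)``; the class-conditional pattern
    likelihood is the plain product over features of the matching Bernoulli
    factor, normalised across classes.  Only sensible for small L.
    """
    cond_present = np.asarray(cond_present, dtype=float)
    prior = np.asarray(prior, dtype=float)
    x = np.asarray(pattern)
    J, L = cond_present.shape
    if x.shape != (L,):
        raise ValueError("pattern length must equal L")
    if not np.isclose(prior.sum(), 1.0):
        raise ValueError("prior must sum to 1")
    like = np.ones(J)
    for l in range(L):
        like *= cond_present[:, l] if x[l] == 1 else (1.0 - cond_present[:, l])
    joint = like * prior
    return joint / joint.sum()


def condition_diagnostics(
    model: NBModel, patterns: np.ndarray, lam: float = 1.0
) -> ConditionDiagnostics:
    """Measure the present-term and absent-term magnitudes per pattern/class.

    The absent-term is reported after applying the taper ``lam`` (default 1,
    i.e. the raw SNB term).  In the sparse high-dimensional regime the
    absent-term typically dwarfs the present-term, which is the empirical
    motivation for tapering it.
    """
    lam = _check_lambda(lam)
    X, _ = _as_pattern_matrix(model, patterns)
    present = X @ model.log_post_present.T
    absent = lam * ((1.0 - X) @ model.log_post_absent.T)
    return ConditionDiagnostics(
        present_abs=np.abs(present),
        absent_abs=np.abs(absent),
        absent_range=absent.max(axis=1) - absent.min(axis=1),
    )
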