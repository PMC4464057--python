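"""Evaluation protocol: stratified k-fold CV, multiclass MCC, McNemar's test,
and the (taper x feature-percentage) grid sweep.

The headline experiment cross-validates a tapered Naive Bayes classifier at
every cell of a ``lambda x percent`` grid, where ``percent`` is the share of
top mutual-information-ranked features retained, pools the held-out
predictions of the ten folds into one confusion matrix, and scores it with
the multiclass Matthews correlation coefficient (Gorodkin's R_K).  Two
classifiers are compared on the same held-out predictions with McNemar's
chi-squared test on discordant pairs (df = 1, critical value 3.84 at the
0.05 level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .fingerprints_io import LabeledDataset
from .naive_bayes_core import SmoothingParams, estimate_model, score_matrix, tally_counts
from .feature_ranking import mutual_information, rank_features, select_top_percent

__all__ = [
    "MCNEMAR_CRITICAL",
    "FoldAssignment",
    "ConfusionMatrix",
    "McNemarResult",
    "EvaluationReport",
    "SweepResult",
    "stratified_folds",
    "confusion_from_predictions",
    "multiclass_mcc",
    "per_class_mcc",
    "mcnemar",
    "cross_validate",
    "sweep",
    "COARSE_LAMBDA_GRID",
    "REFINE_LAMBDA_GRID",
]

# chi-squared critical value, df=1, alpha=0.05; checked against scipy at import.
MCNEMAR_CRITICAL = 3.84
assert abs(stats.chi2.ppf(0.95, df=1) - MCNEMAR_CRITICAL) < 0.005

# Two-stage taper schedule: coarse scan, then refinement at fine steps.
COARSE_LAMBDA_GRID: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
REFINE_LAMBDA_GRID: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35)


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index (0-based, in 0..k-1) per pattern."""

    fold_of: np.ndarray
    k: int
    seed: int


@dataclass(frozen=True)
class ConfusionMatrix:
    """J x J counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def true_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def pred_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))


@dataclass(frozen=True)
class McNemarResult:
    """Discordant-pair counts and the chi-squared statistic (df = 1).

    ``only_a_wrong`` counts items misclassified by A but not B;
    ``only_b_wrong`` the reverse.  The statistic is symmetric in A and B.
    """

    only_a_wrong: int
    only_b_wrong: int
    statistic: float
    continuity: bool
    df: int = 1

    @property
    def significant_at_0_05(self) -> bool:
        return self.statistic >= MCNEMAR_CRITICAL


@dataclass(frozen=True)
class EvaluationReport:
    """Pooled cross-validation outcome for one (lambda, percent) setting."""

    predictions: np.ndarray  # (N,) 0-based predicted class codes
    fold_of: np.ndarray  # (N,)
    confusion: ConfusionMatrix
    mcc_global: float
    mcc_per_class: np.ndarray  # (J,)
    settings: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "settings": self.settings,
            "mcc_global": self.mcc_global,
            "mcc_per_class": self.mcc_per_class.tolist(),
            "confusion": self.confusion.counts.tolist(),
            "predictions": self.predictions.tolist(),
            "fold_of": self.fold_of.tolist(),
        }
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def stratified_folds(
    labels: np.ndarray | Sequence[int], k: int, seed: int
) -> FoldAssignment:
    """Shuffle each class with a seeded generator and deal members to folds
    round-robin, so per-class fold counts differ by at most one."""
    labels = np.asarray(labels)
    n = labels.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of patterns N={n}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=np.intp)
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        rng.shuffle(members)
        fold_of[members] = np.arange(members.size) % k
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_from_predictions(
    truth: np.ndarray, predictions: np.ndarray, n_classes: int
) -> ConfusionMatrix:
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (np.asarray(truth), np.asarray(predictions)), 1)
    return ConfusionMatrix(counts)


def multiclass_mcc(confusion: ConfusionMatrix) -> float:
    """Gorodkin's R_K correlation from the full confusion matrix.

    Reduces to the classic binary MCC for J = 2; defined as 0 when either
    variance factor of the denominator vanishes (e.g. a single predicted
    class).
    """
    C = confusion.counts.astype(float)
    s = C.sum()
    if s < 1:
        raise ValueError("empty confusion matrix")
    t = C.sum(axis=1)
    p = C.sum(axis=0)
    c = np.trace(C)
    cov = c * s - p @ t
    var_p = s * s - p @ p
    var_t = s * s - t @ t
    if var_p == 0 or var_t == 0:
        return 0.0
    return float(cov / np.sqrt(var_p * var_t))


def per_class_mcc(confusion: ConfusionMatrix, j: int) -> float:
    """Binary MCC of the one-vs-rest collapse of class ``j`` (0-based)."""
    C = confusion.counts
    tp = C[j, j]
    fn = C[j].sum() - tp
    fp = C[:, j].sum() - tp
    tn = C.sum() - tp - fn - fp
    return multiclass_mcc(ConfusionMatrix(np.array([[tp, fn], [fp, tn]])))


def mcnemar(
    truth: np.ndarray | Sequence,
    preds_a: np.ndarray | Sequence,
    preds_b: np.ndarray | Sequence,
    continuity: bool = False,
) -> McNemarResult:
    """McNemar's paired test on the discordant predictions of two classifiers.

    statistic = (b - c)^2 / (b + c), optionally with Edwards' continuity
    correction (|b - c| - 1)^2 / (b + c); 0 when there are no discordant
    pairs.
    """
    truth = np.asarray(truth)
    preds_a = np.asarray(preds_a)
    preds_b = np.asarray(preds_b)
    if not (truth.shape == preds_a.shape == preds_b.shape) or truth.ndim != 1:
        raise ValueError("truth and both prediction vectors must share one length")
    if truth.size < 1:
        raise ValueError("need at least one prediction")
    a_ok = preds_a == truth
    b_ok = preds_b == truth
    b_count = int(np.sum(~a_ok & b_ok))  # A wrong, B right
    c_count = int(np.sum(a_ok & ~b_ok))  # A right, B wrong
    n_disc = b_count + c_count
    if n_disc == 0:
        statistic = 0.0
    elif continuity:
        statistic = (abs(b_count - c_count) - 1) ** 2 / n_disc
    else:
        statistic = (b_count - c_count) ** 2 / n_disc
    return McNemarResult(b_count, c_count, float(statistic), continuity)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fold_grid_predictions(
    data: LabeledDataset,
    folds: FoldAssignment,
    lambdas: Sequence[float],
    percents: Sequence[float],
    ranking_scope: str,
    smoothing: SmoothingParams | None,
    prior_mode: str,
) -> dict[tuple[float, float], np.ndarray]:
    """Held-out predictions for every (lambda, percent) grid cell.

    Shares the per-fold counting and ranking work across cells, so a sweep
    cell is arithmetically identical to a standalone run at that cell.
    """
    if ranking_scope not in ("fold", "global"):
        raise ValueError("ranking_scope must be 'fold' or 'global'")
    L = data.n_features
    need_ranking = any(p < 100.0 for p in percents)
    global_ranking = (
        rank_features(mutual_information(data))
        if need_ranking and ranking_scope == "global"
        else None
    )
    preds = {
        (lam, pct): np.empty(data.n_patterns, dtype=np.intp)
        for lam in lambdas
        for pct in percents
    }
    for fold in range(folds.k):
        test_mask = folds.fold_of == fold
        if not test_mask.any():
            continue
        train = data.subset(np.flatnonzero(~test_mask))
        try:
            train.require_trainable()
        except ValueError as exc:
            raise ValueError(
                f"fold {fold + 1}: {exc}; lower k so every class reaches "
                "every training fold"
            ) from exc
        counts = tally_counts(train)
        if need_ranking:
            ranking = (
                global_ranking
                if global_ranking is not None
                else rank_features(mutual_information(train))
            )
        test_X = data.patterns[test_mask]
        for pct in percents:
            if pct >= 100.0:
                sub_counts, X = counts, test_X
            else:
                sel = select_top_percent(ranking, L, pct)
                sub_counts = tally_counts(train.select_features(sel))
                X = test_X[:, sel]
            model = estimate_model(sub_counts, smoothing, prior_mode)
            for lam in lambdas:
                scores = score_matrix(model, X, lam)
                preds[(lam, pct)][test_mask] = np.argmax(scores, axis=1)
    return preds


def _report(
    data: LabeledDataset,
    folds: FoldAssignment,
    predictions: np.ndarray,
    settings: dict,
) -> EvaluationReport:
    confusion = confusion_from_predictions(data.labels, predictions, data.n_classes)
    return EvaluationReport(
        predictions=predictions,
        fold_of=folds.fold_of,
        confusion=confusion,
        mcc_global=multiclass_mcc(confusion),
        mcc_per_class=np.array(
            [per_class_mcc(confusion, j) for j in range(data.n_classes)]
        ),
        settings=settings,
    )


def cross_validate(
    data: LabeledDataset,
    lam: float,
    percent: float = 100.0,
    k: int = 10,
    seed: int = 0,
    ranking_scope: str = "fold",
    smoothing: SmoothingParams | None = None,
    prior_mode: str = "empirical",
) -> EvaluationReport:
    """Stratified k-fold cross-validation of a tapered classifier.

    Per fold: rank features by mutual information on the training portion
    (unless ``ranking_scope='global'``), keep the top ``percent``, estimate
    the smoothed model, and classify the held-out fold at taper ``lam``.
    Held-out predictions are pooled into a single confusion matrix.
    """
    data.require_trainable()
    folds = stratified_folds(data.labels, k, seed)
    preds = _fold_grid_predictions(
        data, folds, [lam], [percent], ranking_scope, smoothing, prior_mode
    )[(lam, percent)]
    settings = {
        "lambda": lam,
        "percent": percent,
        "k": k,
        "seed": seed,
        "ranking_scope": ranking_scope,
        "prior_mode": prior_mode,
    }
    return _report(data, folds, preds, settings)


@dataclass(frozen=True)
class SweepResult:
    """All grid cells (lambda, percent, pooled MCC) plus the winning cell.

    Ties are broken toward the smaller lambda, then the smaller percent.
    """

    cells: tuple[tuple[float, float, float], ...]
    best_lambda: float
    best_percent: float
    best_mcc: float

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("lambda\tpercent\tmcc\n")
            for lam, pct, mcc in self.cells:
                fh.write(f"{lam:g}\t{pct:g}\t{mcc:.10g}\n")

    def mcc_at(self, lam: float, percent: float) -> float:
        for cell in self.cells:
            if cell[0] == lam and cell[1] == percent:
                return cell[2]
        raise KeyError((lam, percent))


def sweep(
    data: LabeledDataset,
    lambda_grid: Iterable[float],
    percent_grid: Iterable[float],
    k: int = 10,
    seed: int = 0,
    ranking_scope: str = "fold",
    smoothing: SmoothingParams | None = None,
    prior_mode: str = "empirical",
    two_stage: bool = False,
) -> SweepResult:
    """Cross-validate every cell of the Cartesian (lambda, percent) grid.

    With ``two_stage=True`` the coarse scan is followed by a refinement pass
    over ``REFINE_LAMBDA_GRID`` (0.05-step tapers in [0.05, 0.35]) on the
    same percent grid, mirroring the coarse-then-fine taper schedule.
    """
    lambdas = sorted({float(l) for l in lambda_grid})
    percents = sorted({float(p) for p in percent_grid})
    if not lambdas or not percents:
        raise ValueError("lambda and percent grids must be non-empty")
    data.require_trainable()
    folds = stratified_folds(data.labels, k, seed)

    def run(lams: Sequence[float]) -> list[tuple[float, float, float]]:
        preds = _fold_grid_predictions(
            data, folds, lams, percents, ranking_scope, smoothing, prior_mode
        )
        out = []
        for lam in lams:
            for pct in percents:
                confusion = confusion_from_predictions(
                    data.labels, preds[(lam, pct)], data.n_classes
                )
                out.append((lam, pct, multiclass_mcc(confusion)))
        return out

    cells = run(lambdas)
    if two_stage:
        extra = [l for l in REFINE_LAMBDA_GRID if l not in lambdas]
        if extra:
            cells.extend(run(extra))
    # winner: max MCC, ties toward smaller lambda then smaller percent
    best = max(cells, key=lambda cell: (cell[2], -cell[0], -cell[1]))
    cells.sort(key=lambda cell: (cell[0], cell[1]))
    return SweepResult(
        cells=tuple(cells),
        best_lambda=best[0],
        best_percent=best[1],
        best_mcc=best[2],
    )
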