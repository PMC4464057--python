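"""Data model, text I/O and curation helpers for binary fingerprint matrices.

A dataset is a dense ``N x L`` binary matrix (compounds by fingerprint bits)
plus one class label per compound.  Two plain-text dialects are supported:

* **dense CSV** — header ``id,label,f1,...,fL``; one compound per row; matrix
  cells strictly ``0``/``1``.
* **sparse FPS** — first line ``#L=<int>``; then one line per compound:
  ``id<TAB>label<TAB><space-separated ascending 1-based indices of present
  features>`` (the index list may be empty).

Feature indices are 1-based in files and 0-based everywhere in memory.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FingerprintFormatError",
    "LabeledDataset",
    "SyntheticSpec",
    "read_dense_csv",
    "write_dense_csv",
    "read_sparse_fps",
    "write_sparse_fps",
    "prune_empty_features",
    "activity_threshold",
    "generate_synthetic",
]


class FingerprintFormatError(ValueError):
    """Raised when a fingerprint file violates its dialect."""


@dataclass(frozen=True)
class LabeledDataset:
    """Binary pattern matrix with class labels.

    Parameters
    ----------
    patterns:
        ``(N, L)`` array with entries in ``{0, 1}``.
    labels:
        ``(N,)`` integer class codes in ``0..J-1`` (the code is the position
        of the class in ``class_names``).
    class_names:
        Length-``J`` class identifiers; defines the code <-> name mapping.
    feature_names:
        Optional length-``L`` feature identifiers (default ``f1..fL``).
    ids:
        Optional length-``N`` compound identifiers.
    """

    patterns: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]
    feature_names: tuple[str, ...] | None = None
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        patterns = np.ascontiguousarray(self.patterns, dtype=np.uint8)
        labels = np.asarray(self.labels, dtype=np.intp)
        if patterns.ndim != 2:
            raise ValueError("patterns must be a 2-D matrix")
        if labels.ndim != 1 or labels.shape[0] != patterns.shape[0]:
            raise ValueError("labels must be 1-D with one entry per pattern")
        if patterns.size and patterns.max() > 1:
            raise ValueError("pattern entries must be 0 or 1")
        if len(labels) and (labels.min() < 0 or labels.max() >= len(self.class_names)):
            raise ValueError("label code outside 0..J-1")
        if self.feature_names is not None and len(self.feature_names) != patterns.shape[1]:
            raise ValueError("feature_names length must equal L")
        if self.ids is not None and len(self.ids) != patterns.shape[0]:
            raise ValueError("ids length must equal N")
        object.__setattr__(self, "patterns", patterns)
        object.__setattr__(self, "labels", labels)

    # -- basic geometry -------------------------------------------------
    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_features(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def require_trainable(self) -> None:
        """Check the invariants a training set must satisfy (J>=2, all
        classes represented, at least one pattern and feature)."""
        if self.n_patterns < 1 or self.n_features < 1:
            raise ValueError("training set needs N >= 1 and L >= 1")
        if self.n_classes < 2:
            raise ValueError("training set needs at least two classes")
        present = np.bincount(self.labels, minlength=self.n_classes)
        if (present == 0).any():
            missing = [self.class_names[j] for j in np.flatnonzero(present == 0)]
            raise ValueError(f"classes absent from training set: {missing}")

    def subset(self, rows: np.ndarray | Sequence[int]) -> "LabeledDataset":
        rows = np.asarray(rows)
        return replace(
            self,
            patterns=self.patterns[rows],
            labels=self.labels[rows],
            ids=None if self.ids is None else tuple(np.asarray(self.ids, dtype=object)[rows]),
        )

    def select_features(self, cols: np.ndarray | Sequence[int]) -> "LabeledDataset":
        cols = np.asarray(cols)
        return replace(
            self,
            patterns=self.patterns[:, cols],
            feature_names=None
            if self.feature_names is None
            else tuple(np.asarray(self.feature_names, dtype=object)[cols]),
        )

    @staticmethod
    def from_string_labels(
        patterns: np.ndarray,
        string_labels: Sequence[str],
        feature_names: Sequence[str] | None = None,
        ids: Sequence[str] | None = None,
    ) -> "LabeledDataset":
        """Build a dataset from raw string labels; classes are ordered by
        first appearance."""
        seen: dict[str, int] = {}
        codes = np.empty(len(string_labels), dtype=np.intp)
        for i, lab in enumerate(string_labels):
            codes[i] = seen.setdefault(str(lab), len(seen))
        return LabeledDataset(
            patterns=patterns,
            labels=codes,
            class_names=tuple(seen),
            feature_names=None if feature_names is None else tuple(feature_names),
            ids=None if ids is None else tuple(ids),
        )


# ---------------------------------------------------------------------------
# dense CSV dialect
# ---------------------------------------------------------------------------

def read_dense_csv(path: str | Path) -> LabeledDataset:
    """Read the dense CSV dialect; row order is preserved."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FingerprintFormatError(f"{path}: empty file") from None
        if len(header) < 3 or header[0] != "id" or header[1] != "label":
            raise FingerprintFormatError(
                f"{path}: header must start with 'id,label' followed by feature columns"
            )
        feature_names = tuple(header[2:])
        ids: list[str] = []
        labels: list[str] = []
        rows: list[list[int]] = []
        seen_ids: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FingerprintFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            cid = row[0]
            if cid in seen_ids:
                raise FingerprintFormatError(f"{path}:{lineno}: duplicate compound id {cid!r}")
            seen_ids.add(cid)
            bits = []
            for col, cell in enumerate(row[2:], start=1):
                if cell == "0":
                    bits.append(0)
                elif cell == "1":
                    bits.append(1)
                else:
                    raise FingerprintFormatError(
                        f"{path}:{lineno}: non-binary cell {cell!r} in column "
                        f"{feature_names[col - 1]!r} (row id {cid!r})"
                    )
            ids.append(cid)
            labels.append(row[1])
            rows.append(bits)
    if not rows:
        raise FingerprintFormatError(f"{path}: no data rows")
    return LabeledDataset.from_string_labels(
        np.asarray(rows, dtype=np.uint8), labels, feature_names, ids
    )


def write_dense_csv(data: LabeledDataset, path: str | Path) -> None:
    path = Path(path)
    names = data.feature_names or tuple(f"f{l + 1}" for l in range(data.n_features))
    ids = data.ids or tuple(f"c{i + 1}" for i in range(data.n_patterns))
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", *names])
        for i in range(data.n_patterns):
            writer.writerow(
                [ids[i], data.class_names[data.labels[i]], *data.patterns[i].tolist()]
            )


# ---------------------------------------------------------------------------
# sparse FPS dialect
# ---------------------------------------------------------------------------

def read_sparse_fps(path: str | Path) -> LabeledDataset:
    """Read the sparse index-list dialect; entry ``(i, l)`` is 1 iff 1-based
    index ``l+1`` is listed on line ``i``."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#L="):
            raise FingerprintFormatError(f"{path}: first line must be '#L=<int>'")
        try:
            n_features = int(header[3:])
        except ValueError:
            raise FingerprintFormatError(f"{path}: bad feature count in {header!r}") from None
        if n_features < 1:
            raise FingerprintFormatError(f"{path}: L must be >= 1")
        ids: list[str] = []
        labels: list[str] = []
        rows: list[np.ndarray] = []
        seen_ids: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FingerprintFormatError(
                    f"{path}:{lineno}: expected 'id<TAB>label<TAB>indices'"
                )
            cid, label, idx_field = parts
            if cid in seen_ids:
                raise FingerprintFormatError(f"{path}:{lineno}: duplicate compound id {cid!r}")
            seen_ids.add(cid)
            row = np.zeros(n_features, dtype=np.uint8)
            if idx_field.strip():
                try:
                    idx = [int(tok) for tok in idx_field.split()]
                except ValueError:
                    raise FingerprintFormatError(
                        f"{path}:{lineno}: non-integer feature index"
                    ) from None
                for l in idx:
                    if l < 1 or l > n_features:
                        raise FingerprintFormatError(
                            f"{path}:{lineno}: feature index {l} outside 1..{n_features}"
                        )
                if len(set(idx)) != len(idx):
                    raise FingerprintFormatError(f"{path}:{lineno}: duplicate feature index")
                row[np.asarray(idx) - 1] = 1
            ids.append(cid)
            labels.append(label)
            rows.append(row)
    if not rows:
        raise FingerprintFormatError(f"{path}: no data rows")
    return LabeledDataset.from_string_labels(np.vstack(rows), labels, None, ids)


def write_sparse_fps(data: LabeledDataset, path: str | Path) -> None:
    path = Path(path)
    ids = data.ids or tuple(f"c{i + 1}" for i in range(data.n_patterns))
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#L={data.n_features}\n")
        for i in range(data.n_patterns):
            present = np.flatnonzero(data.patterns[i]) + 1  # 1-based on disk
            fh.write(
                f"{ids[i]}\t{data.class_names[data.labels[i]]}\t"
                + " ".join(map(str, present.tolist()))
                + "\n"
            )


# ---------------------------------------------------------------------------
# curation helpers
# ---------------------------------------------------------------------------

def prune_empty_features(data: LabeledDataset) -> tuple[LabeledDataset, np.ndarray]:
    """Drop feature columns that are zero for every compound.

    Returns the restricted dataset and the ascending 0-based indices of the
    surviving original columns.  N and the labels are never touched.
    """
    if data.n_patterns < 1:
        raise ValueError("empty dataset")
    kept = np.flatnonzero(data.patterns.any(axis=0))
    if kept.size == 0:
        raise ValueError("all feature columns are empty; no usable features")
    if kept.size == data.n_features:
        return data, kept
    return data.select_features(kept), kept


def activity_threshold(
    activities: Sequence[float] | np.ndarray, already_neglog: bool = False
) -> float:
    """Active/inactive cutoff: mean plus one sample standard deviation of the
    negative log10 activities (pKi / pIC50 convention).

    ``already_neglog=False`` treats the input as raw Ki/IC50 values and
    applies ``-log10`` first; raw values must then be strictly positive.
    """
    values = np.asarray(activities, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need at least two activity values")
    if not already_neglog:
        if (values <= 0).any():
            raise ValueError("raw activities must be strictly positive")
        values = -np.log10(values)
    return float(values.mean() + values.std(ddof=1))


# ---------------------------------------------------------------------------
# synthetic class-conditional Bernoulli fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for class-conditional Bernoulli fingerprint data.

    The generator emulates the sparse high-dimensional regime of ECFP-style
    fingerprints: most bits are rarely set (``base_rate``), a subset of
    ``n_informative`` bits fires at ``signal_rate`` in exactly one class
    (bits are dealt to classes round-robin), and the remaining uninformative
    bits form latent "concept" blocks whose within-block correlation
    violates the Naive Bayes independence assumption — the redundant,
    weakly relevant tail of a real fingerprint universe.

    Correlation mechanism: the uninformative features are partitioned into
    consecutive blocks of ``block_size``.  Per pattern and block a latent
    toggle is drawn Bernoulli(``base_rate``); each feature in the block
    copies the toggle with probability ``block_corr`` and otherwise draws
    independently at ``base_rate``.  The marginal rate of every feature is
    therefore exactly the returned ``theta`` regardless of ``block_corr``;
    only the dependence structure changes.  Informative features are always
    drawn independently, so the class signal itself is clean.

    The defaults are the study conditions used for the tapering
    experiments: 10 classes, 4,000 bits of which 100 are informative
    (10 per class), 150 compounds per class, 2% background sparsity, 30%
    within-class firing of an informative bit, and a strongly correlated
    uninformative tail (blocks of 80 bits, copy probability 0.8).  With
    only ten diagnostic bits per class, a sizeable minority of compounds
    show little presence evidence, so the absence term genuinely matters;
    at the same time the huge redundant tail makes the full-length absence
    sum noisy — the tension the taper resolves.
    """

    J: int = 10
    L: int = 4000
    n_per_class: int = 150
    n_informative: int = 100
    base_rate: float = 0.02
    signal_rate: float = 0.3
    block_size: int = 80
    block_corr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1 or self.L < 1 or self.n_per_class < 1:
            raise ValueError("J, L and n_per_class must be positive")
        if not 0 <= self.n_informative <= self.L:
            raise ValueError("n_informative must lie in 0..L")
        for name in ("base_rate", "signal_rate", "block_corr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    @staticmethod
    def from_json(path: str | Path) -> "SyntheticSpec":
        with Path(path).open(encoding="utf-8") as fh:
            return SyntheticSpec(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2)
            fh.write("\n")


def generate_synthetic(spec: SyntheticSpec) -> tuple[LabeledDataset, np.ndarray]:
    """Draw a dataset from ``spec``; returns (dataset, true J x L rate matrix).

    Deterministic: the same spec (including seed) always yields the same
    dataset.  Class ``j`` receives ``n_per_class`` patterns; informative
    feature ``l`` (for ``l < n_informative``) fires at ``signal_rate`` in
    class ``l mod J`` and at ``base_rate`` elsewhere.  ``theta[j, l]`` is
    the true marginal Bernoulli rate of feature ``l`` in class ``j``; it is
    exact even when ``block_corr > 0`` (the block mechanism preserves
    marginals and only introduces dependence within the uninformative tail).
    """
    rng = np.random.default_rng(spec.seed)
    J, L, n = spec.J, spec.L, spec.n_per_class
    theta = np.full((J, L), spec.base_rate)
    for l in range(spec.n_informative):
        theta[l % J, l] = spec.signal_rate
    labels = np.repeat(np.arange(J, dtype=np.intp), n)
    rates = theta[labels]  # (N, L) per-cell rate
    patterns = (rng.random((J * n, L)) < rates).astype(np.uint8)
    n_tail = L - spec.n_informative
    if spec.block_corr > 0.0 and n_tail > 0:
        # correlated uninformative tail: block-level latent concept toggles
        n_blocks = -(-n_tail // spec.block_size)
        toggles = rng.random((J * n, n_blocks)) < spec.base_rate
        template = np.repeat(toggles, spec.block_size, axis=1)[:, :n_tail]
        copy = rng.random((J * n, n_tail)) < spec.block_corr
        tail = np.where(copy, template, patterns[:, spec.n_informative :])
        patterns[:, spec.n_informative :] = tail
    data = LabeledDataset(
        patterns=patterns,
        labels=labels,
        class_names=tuple(f"class{j + 1}" for j in range(J)),
        feature_names=tuple(f"f{l + 1}" for l in range(L)),
        ids=tuple(f"c{i + 1}" for i in range(J * n)),
    )
    return data, theta
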