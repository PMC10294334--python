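"""Cell-type similarity (confusion) matrices.

The similarity matrix ``M`` is a K×K matrix whose entry ``m[i, j]`` is the
probability that a cell whose genuine type is ``i`` is assigned label ``j``
by the clustering step.  Three construction strategies are provided:

* :func:`uniform_similarity` — an unbiased confusion level ``epsilon``
  spread evenly over all types;
* :func:`knn_similarity` — neighbour-label frequencies on a KNN graph;
* :func:`classifier_similarity` — an out-of-fold SVM confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DomainError, ValidationError

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-9


@dataclass
class SimilarityMatrix:
    """A K×K cell-type assignment-probability matrix.

    Parameters
    ----------
    labels
        Ordered cell-type names indexing both rows (genuine type) and
        columns (assigned type).
    m
        The matrix itself; entries in [0, 1].  Rows of KNN-, classifier-
        and user-supplied matrices sum to one; the literal uniform matrix
        has row sums ``1 - epsilon/K`` (see :func:`uniform_similarity`).
    source
        One of ``{"uniform", "knn", "classifier", "user"}``.
    epsilon
        Confusion level, only meaningful for the uniform source.
    """

    labels: list[str]
    m: np.ndarray
    source: str = "user"
    epsilon: float | None = None

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.labels = list(self.labels)
        k = len(self.labels)
        if self.m.shape != (k, k):
            raise ValidationError(
                f"similarity matrix shape {self.m.shape} does not match "
                f"{k} labels"
            )
        if len(set(self.labels)) != k:
            raise ValidationError("duplicate cell-type labels")
        if np.any(self.m < 0) or np.any(self.m > 1):
            raise ValidationError("similarity entries must lie in [0, 1]")
        rowsums = self.m.sum(axis=1)
        if self.source != "uniform" and np.any(
            np.abs(rowsums - 1.0) > _ROW_SUM_TOL
        ):
            raise ValidationError(
                f"rows of a {self.source!r} similarity matrix must sum to 1; "
                f"got row sums {rowsums}"
            )

    @property
    def k(self) -> int:
        return len(self.labels)

    def reorder(self, labels: Sequence[str]) -> "SimilarityMatrix":
        """Return a copy with rows/columns permuted to match ``labels``."""
        missing = set(labels) - set(self.labels)
        if missing or len(labels) != self.k:
            raise ValidationError(
                f"cannot reorder similarity matrix: label mismatch {sorted(missing)}"
            )
        idx = [self.labels.index(l) for l in labels]
        return SimilarityMatrix(
            list(labels), self.m[np.ix_(idx, idx)], self.source, self.epsilon
        )

    def row_stochastic(self) -> "SimilarityMatrix":
        """Return a copy with each row divided by its sum."""
        m = self.m / self.m.sum(axis=1, keepdims=True)
        return SimilarityMatrix(self.labels, m, self.source, self.epsilon)


@dataclass
class KnnGraph:
    """A per-cell neighbour list with cluster labels.

    ``neighbors[c]`` holds the indices (into ``cell_ids``) of cell ``c``'s
    neighbours; counts may vary per cell and self-loops are kept as given.
    """

    cell_ids: list[str]
    labels: list[str]
    neighbors: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if len(self.labels) != n or len(self.neighbors) != n:
            raise ValidationError("cell_ids, labels and neighbors lengths differ")
        self.neighbors = [np.asarray(nb, dtype=int) for nb in self.neighbors]
        for c, nb in enumerate(self.neighbors):
            if nb.size and (nb.min() < 0 or nb.max() >= n):
                raise ValidationError(
                    f"cell {self.cell_ids[c]!r} has out-of-range neighbor indices"
                )


def _default_labels(k: int) -> list[str]:
    return [f"type{i + 1}" for i in range(k)]


def uniform_similarity(
    k: int,
    epsilon: float = 0.05,
    renormalize: bool = False,
    labels: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Uniform confusion matrix ``(1 - eps*(K+1)/K) I + eps/K``.

    The literal formula gives diagonal ``1 - eps`` and off-diagonal
    ``eps/K``, so each row sums to ``1 - eps/K`` rather than 1; pass
    ``renormalize=True`` to rescale rows to exact stochasticity.
    """
    if k < 2:
        raise DomainError(f"need at least 2 cell types, got K={k}")
    if not (0 <= epsilon < 1):
        raise DomainError(f"epsilon must lie in [0, 1), got {epsilon}")
    m = (1 - epsilon * (k + 1) / k) * np.eye(k) + epsilon / k
    if renormalize:
        m = m / m.sum(axis=1, keepdims=True)
    elif epsilon > 0:
        logger.info(
            "uniform similarity rows sum to %.6g (literal mode); "
            "pass renormalize=True for row-stochastic rows",
            1 - epsilon / k,
        )
    return SimilarityMatrix(
        list(labels) if labels is not None else _default_labels(k),
        m,
        source="uniform",
        epsilon=epsilon,
    )


def knn_similarity(graph: KnnGraph) -> SimilarityMatrix:
    """Similarity matrix from neighbour-label frequencies.

    Row ``i`` tallies, over every cell clustered as type ``i``, how many of
    its neighbours carry each label, then normalizes the row to sum to one:
    ``m[i, j] = sum_x n_{x,j} / sum_j sum_x n_{x,j}``.
    """
    labels = sorted(set(graph.labels))
    lab_idx = {l: i for i, l in enumerate(labels)}
    k = len(labels)
    tally = np.zeros((k, k), dtype=float)
    cell_lab = np.array([lab_idx[l] for l in graph.labels])
    for c, nb in enumerate(graph.neighbors):
        if nb.size == 0:
            continue
        counts = np.bincount(cell_lab[nb], minlength=k)
        tally[cell_lab[c]] += counts
    rowsums = tally.sum(axis=1)
    bad = np.flatnonzero(rowsums == 0)
    if bad.size:
        names = ", ".join(labels[i] for i in bad)
        raise ValidationError(
            f"cluster(s) {names} have no cells or no neighbors; "
            "cannot form a similarity row"
        )
    return SimilarityMatrix(labels, tally / rowsums[:, None], source="knn")


def classifier_similarity(
    features: np.ndarray,
    labels: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    n_pcs: int | None = None,
) -> SimilarityMatrix:
    """Confusion matrix of a cross-validated SVM classifier.

    Cells are split into ``folds`` stratified folds; each fold is predicted
    by an SVM trained on the others and the out-of-fold (true cluster →
    predicted cluster) tallies are row-normalized.  Features are used as
    given; set ``n_pcs`` to project onto that many principal components
    first.
    """
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValidationError("features contain non-finite values")
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValidationError("need at least 2 clusters")
    counts = {c: int((labels == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < folds]
    if small:
        raise ValidationError(
            f"cluster(s) {small} have fewer cells than folds={folds}; "
            "cannot stratify"
        )
    if n_pcs is not None:
        n_pcs = min(n_pcs, *features.shape)
        features = PCA(n_components=n_pcs, random_state=seed).fit_transform(features)
    lab_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([lab_idx[l] for l in labels])
    k = len(classes)
    tally = np.zeros((k, k), dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(features, y):
        clf = SVC(kernel="rbf", random_state=seed)
        clf.fit(features[train], y[train])
        pred = clf.predict(features[test])
        np.add.at(tally, (y[test], pred), 1.0)
    return SimilarityMatrix(
        classes, tally / tally.sum(axis=1, keepdims=True), source="classifier"
    )
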