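"""Dirichlet-multinomial simulation of cell-type count tables.

Three generators mirror the study designs used to exercise the test:

* :func:`simulate_dirichlet_multinomial` — per-condition genuine
  compositions, between-replicate variability through a Dirichlet with
  concentration ``scale * proportions``, multinomial cell counts, and an
  optional misclassification step driven by a similarity matrix;
* :func:`simulate_count_units` — conditions specified as per-type count
  units, capturing the compositional side effect of one type ballooning;
* :func:`simulate_with_covariates` — additive age and sex effects on the
  concentration parameters, for confounder-control experiments.

Defaults reproduce the canonical scenarios: three cell types at
[1/3, 1/3, 1/3] vs [1/3, 1/2, 1/6] with concentration scale 70, 2 and 3
replicates, 2000 cells per sample; count units [1, 4, ..., 4] vs
[20, 4, ..., 4] over eight types, 3 replicates, 3000 cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CellCountTable
from .errors import ValidationError
from .model import DesignMatrix
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

_CONC_FLOOR = 1e-3

THEORETICAL_PROPORTIONS = (
    np.array([1 / 3, 1 / 3, 1 / 3]),
    np.array([1 / 3, 1 / 2, 1 / 6]),
)
COUNT_UNITS = (
    np.array([1.0, 4, 4, 4, 4, 4, 4, 4]),
    np.array([20.0, 4, 4, 4, 4, 4, 4, 4]),
)


def theoretical_confusion(labels: list[str] | None = None) -> SimilarityMatrix:
    """The 3-type confusion used in the canonical scenario.

    Type 1 is never confused; types 2 and 3 swap with probability 0.3,
    which turns genuine [1/3, 1/2, 1/6] into observed [0.33, 0.40, 0.27].
    """
    m = np.array([[1.0, 0.0, 0.0], [0.0, 0.7, 0.3], [0.0, 0.3, 0.7]])
    return SimilarityMatrix(labels or ["type1", "type2", "type3"], m, source="user")


@dataclass
class SimScenario:
    """A two-condition Dirichlet-multinomial simulation design."""

    genuine_proportions: tuple[np.ndarray, np.ndarray] = THEORETICAL_PROPORTIONS
    concentration_scale: float = 70.0
    replicates: tuple[int, int] = (2, 3)
    total_cells: int = 2000
    similarity: SimilarityMatrix | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        p1, p2 = (np.asarray(p, dtype=float) for p in self.genuine_proportions)
        if p1.shape != p2.shape:
            raise ValidationError("condition proportion vectors differ in length")
        for p in (p1, p2):
            if abs(p.sum() - 1) > 1e-8 or np.any(p < 0):
                raise ValidationError("proportions must be nonnegative and sum to 1")
        if min(self.replicates) < 1 or self.total_cells <= 0:
            raise ValidationError("replicates must be >= 1 and total_cells > 0")
        self.genuine_proportions = (p1, p2)

    @property
    def k(self) -> int:
        return len(self.genuine_proportions[0])

    @property
    def truth(self) -> np.ndarray:
        """Per-type indicator of a genuine compositional change."""
        p1, p2 = self.genuine_proportions
        return ~np.isclose(p1, p2)


@dataclass
class SimOutput:
    """Counts, design and ground truth from one simulation run."""

    counts: CellCountTable
    design: DesignMatrix
    truth: np.ndarray
    provenance: dict = field(default_factory=dict)


def _clip_concentration(alpha: np.ndarray) -> np.ndarray:
    if np.any(alpha <= 0):
        logger.warning("nonpositive concentration parameters clipped to %g", _CONC_FLOOR)
        alpha = np.maximum(alpha, _CONC_FLOOR)
    return alpha


def apply_misclassification(
    counts_row: np.ndarray, m: SimilarityMatrix, rng: np.random.Generator
) -> np.ndarray:
    """Reassign cells between types according to the confusion matrix.

    Each genuine type's cells are scattered over observed labels by a
    multinomial draw from that type's similarity row; the total number of
    cells is preserved.
    """
    counts_row = np.asarray(counts_row)
    mat = m.m.copy()
    rowsums = mat.sum(axis=1)
    if np.any(np.abs(rowsums - 1) > 1e-6):
        logger.warning("similarity rows renormalized before misclassification")
        mat = mat / rowsums[:, None]
    out = np.zeros_like(counts_row)
    for i, c in enumerate(counts_row):
        if c > 0:
            out += rng.multinomial(int(c), mat[i])
    return out


def _sample_counts(
    alpha_rows: list[np.ndarray],
    total_cells: int,
    similarity: SimilarityMatrix | None,
    rng: np.random.Generator,
) -> np.ndarray:
    rows = []
    for alpha in alpha_rows:
        p = rng.dirichlet(_clip_concentration(alpha))
        row = rng.multinomial(total_cells, p)
        if similarity is not None:
            row = apply_misclassification(row, similarity, rng)
        rows.append(row)
    return np.array(rows)


def _package(
    counts: np.ndarray,
    condition: np.ndarray,
    truth: np.ndarray,
    labels: list[str],
    provenance: dict,
    extra_covariates: dict[str, np.ndarray] | None = None,
) -> SimOutput:
    sample_ids = [f"s{i + 1}" for i in range(len(condition))]
    cov = {"condition": condition.astype(float)}
    if extra_covariates:
        cov.update({k: np.asarray(v, dtype=float) for k, v in extra_covariates.items()})
    design = DesignMatrix(
        sample_ids, pd.DataFrame(cov), tested=["condition"]
    )
    return SimOutput(
        counts=CellCountTable(sample_ids, labels, counts),
        design=design,
        truth=np.asarray(truth, dtype=bool),
        provenance=provenance,
    )


def simulate_dirichlet_multinomial(scenario: SimScenario) -> SimOutput:
    """Draw a two-condition count table from the scenario."""
    rng = np.random.default_rng(scenario.seed)
    p1, p2 = scenario.genuine_proportions
    alphas = [scenario.concentration_scale * p1] * scenario.replicates[0] + [
        scenario.concentration_scale * p2
    ] * scenario.replicates[1]
    counts = _sample_counts(alphas, scenario.total_cells, scenario.similarity, rng)
    condition = np.repeat([0, 1], scenario.replicates)
    labels = (
        scenario.similarity.labels
        if scenario.similarity is not None
        else [f"type{i + 1}" for i in range(scenario.k)]
    )
    return _package(
        counts,
        condition,
        scenario.truth,
        list(labels),
        {"design": "theoretical", "seed": scenario.seed,
         "scale": scenario.concentration_scale},
    )


def simulate_count_units(
    units_by_condition: tuple[np.ndarray, np.ndarray] = COUNT_UNITS,
    replicates: tuple[int, int] = (3, 3),
    total_cells: int = 3000,
    concentration_scale: float = 70.0,
    similarity: SimilarityMatrix | None = None,
    seed: int = 0,
) -> SimOutput:
    """Simulate conditions defined by per-type count units.

    Units are normalized within each condition to genuine proportions, so
    inflating one type's units deflates every other type's proportion —
    the compositional side effect the reference normalization targets.
    Truth marks only types whose *units* differ.
    """
    u1, u2 = (np.asarray(u, dtype=float) for u in units_by_condition)
    if u1.shape != u2.shape:
        raise ValidationError("unit vectors differ in length")
    if np.any(u1 <= 0) or np.any(u2 <= 0):
        raise ValidationError("count units must be positive")
    scenario = SimScenario(
        genuine_proportions=(u1 / u1.sum(), u2 / u2.sum()),
        concentration_scale=concentration_scale,
        replicates=replicates,
        total_cells=total_cells,
        similarity=similarity,
        seed=seed,
    )
    out = simulate_dirichlet_multinomial(scenario)
    out.truth = ~np.isclose(u1, u2)
    out.provenance = {"design": "count_units", "seed": seed,
                      "scale": concentration_scale}
    return out


def simulate_with_covariates(
    base_concentrations: tuple[np.ndarray, np.ndarray] | None = None,
    age_slopes: np.ndarray | None = None,
    gender_shifts: np.ndarray | None = None,
    replicates: tuple[int, int] = (10, 10),
    age_range: tuple[int, int] = (15, 45),
    total_cells: int = 3000,
    similarity: SimilarityMatrix | None = None,
    seed: int = 0,
) -> SimOutput:
    """Two conditions with additive age and sex concentration effects.

    Per sample: age is an integer year uniform on ``age_range``, sex is
    Bernoulli(1/2) (male = 1), and type ``k``'s Dirichlet concentration is
    ``base_k + age_slope_k * (age - age_range[0]) + gender_shift_k * male``,
    floored at a small positive value.  Defaults follow the canonical
    confounded design: eight types, condition shifts in types 1, 2, 6, 8;
    age slope −0.05 on types 1 and 5, +0.05 on types 2 and 6; sex shift −2
    on types 1 and 5, +2 on types 2 and 6.
    """
    if base_concentrations is None:
        base = (
            70 * np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.2, 0.2]),
            70 * np.array([0.05, 0.15, 0.1, 0.1, 0.1, 0.2, 0.2, 0.1]),
        )
    else:
        base = tuple(np.asarray(b, dtype=float) for b in base_concentrations)
    k = len(base[0])
    if age_slopes is None:
        age_slopes = np.zeros(k)
        if k >= 6:
            age_slopes[[0, 4]] = -0.05
            age_slopes[[1, 5]] = 0.05
    if gender_shifts is None:
        gender_shifts = np.zeros(k)
        if k >= 6:
            gender_shifts[[0, 4]] = -2.0
            gender_shifts[[1, 5]] = 2.0
    age_slopes = np.asarray(age_slopes, dtype=float)
    gender_shifts = np.asarray(gender_shifts, dtype=float)
    if len(age_slopes) != k or len(gender_shifts) != k:
        raise ValidationError("slopes/shifts must have one entry per cell type")

    rng = np.random.default_rng(seed)
    n_samples = sum(replicates)
    condition = np.repeat([0, 1], replicates)
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n_samples)
    males = rng.integers(0, 2, size=n_samples)
    alphas = [
        base[c] + age_slopes * (a - age_range[0]) + gender_shifts * g
        for c, a, g in zip(condition, ages, males)
    ]
    counts = _sample_counts(alphas, total_cells, similarity, rng)
    truth = ~np.isclose(base[0], base[1])
    labels = [f"type{i + 1}" for i in range(k)]
    return _package(
        counts,
        condition,
        truth,
        labels,
        {"design": "covariates", "seed": seed},
        extra_covariates={"age": ages, "gender": males},
    )
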