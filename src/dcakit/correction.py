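"""EM de-biasing of observed cell counts under a misclassification model.

Observed labels are a confusion of the genuine types: if the genuine
composition is ``z`` and the similarity matrix ``M`` gives assignment
probabilities, the observed counts are multinomial with parameter
``nu = z @ M``.  The EM algorithm below recovers the maximum-likelihood
genuine composition ``z`` from observed counts, one sample at a time
(the likelihood factorizes over samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .counts import CellCountTable
from .errors import ValidationError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrectionResult:
    """Per-sample output of :func:`em_correct`."""

    z: np.ndarray  # S×K corrected compositions, rows sum to 1
    corrected_counts: np.ndarray  # S×K integers, row sums = observed totals
    loglik_trace: list[np.ndarray]  # per-sample monotone LL traces
    iterations: np.ndarray
    converged: np.ndarray


def transform_proportions(z: np.ndarray, m: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Adjusted composition ``nu = z @ M`` seen after misclassification."""
    mat = m.m if isinstance(m, SimilarityMatrix) else np.asarray(m, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != mat.shape[0]:
        raise ValidationError(
            f"composition length {z.shape[-1]} does not match matrix dim {mat.shape[0]}"
        )
    return z @ mat


def confusion_loglik(
    counts: np.ndarray, z: np.ndarray, m: SimilarityMatrix | np.ndarray
) -> float:
    """Multinomial log-likelihood of genuine composition ``z``.

    Returns ``sum_j n_j log(nu_j)`` with ``nu = z @ M``; the multinomial
    coefficient is constant in ``z`` and omitted.  ``-inf`` when a type
    with zero adjusted probability has observed cells.
    """
    counts = np.asarray(counts, dtype=float)
    nu = transform_proportions(z, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(nu), 0.0)
    if np.any(np.isnan(terms) | np.isneginf(terms)):
        logger.warning("zero adjusted proportion with positive observed count")
        return -np.inf
    return float(terms.sum())


def largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integerize ``fractions * total`` conserving the total exactly."""
    target = np.asarray(fractions, dtype=float) * total
    floor = np.floor(target).astype(np.int64)
    short = int(total - floor.sum())
    # hand the leftover units to the largest fractional parts
    order = np.argsort(-(target - floor), kind="stable")
    floor[order[:short]] += 1
    return floor


def _em_single(
    counts: np.ndarray, m: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    n = counts.sum()
    # strictly positive start: +0.5 pseudocount on zeros, used only here
    start = counts.astype(float)
    start[start == 0] = 0.5
    z = start / start.sum()
    trace = [confusion_loglik(counts, z, m)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        nu = z @ m  # length K, nu_j = sum_i z_i m_ij
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = (m * z[:, None]) / nu[None, :]  # mu[i, j] = P(true i | assigned j)
        mu = np.nan_to_num(mu)
        weighted = mu @ counts  # sum_j mu_{j,i} n_j per true type i
        z = weighted / weighted.sum()
        trace.append(confusion_loglik(counts, z, m))
        if abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1.0) < tol:
            converged = True
            break
    return z, np.array(trace), it, converged


def em_correct(
    table: CellCountTable,
    m: SimilarityMatrix,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> CorrectionResult:
    """Recover genuine compositions per sample by EM.

    Alternates the posterior-responsibility E-step
    ``mu[j, i] = m[i, j] z_i / sum_t m[t, j] z_t`` with the M-step
    ``z_i = sum_j mu[j, i] n_j / sum_t sum_j mu[j, t] n_j`` until the
    relative log-likelihood gain drops below ``tol``.  Corrected integer
    counts conserve each sample's observed total (largest-remainder
    rounding of ``z * n_s``).
    """
    if m.k != table.k:
        raise ValidationError(
            f"similarity dimension {m.k} does not match {table.k} cell types"
        )
    if m.labels != table.labels:
        m = m.reorder(table.labels)
    if np.any(table.totals == 0):
        bad = [s for s, t in zip(table.sample_ids, table.totals) if t == 0]
        raise ValidationError(f"samples with zero total cells: {bad}")
    zs, cc, traces, iters, conv = [], [], [], [], []
    for s in range(table.n_samples):
        z, trace, it, ok = _em_single(table.counts[s], m.m, tol, max_iter)
        if not ok:
            logger.warning(
                "EM did not converge for sample %s after %d iterations",
                table.sample_ids[s],
                max_iter,
            )
        zs.append(z)
        cc.append(largest_remainder(z, int(table.totals[s])))
        traces.append(trace)
        iters.append(it)
        conv.append(ok)
    return CorrectionResult(
        z=np.array(zs),
        corrected_counts=np.array(cc),
        loglik_trace=traces,
        iterations=np.array(iters),
        converged=np.array(conv),
    )


def corrected_table(table: CellCountTable, result: CorrectionResult) -> CellCountTable:
    """Wrap EM-corrected integer counts back into a count table."""
    return CellCountTable(table.sample_ids, table.labels, result.corrected_counts)
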