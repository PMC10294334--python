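"""Beta-binomial regression with a logit link.

Counts ``z_s`` out of totals ``n_s`` follow a beta-binomial whose mean
``pbar_s`` is linked to covariates by ``logit(pbar_s) = x_s @ w`` and whose
overdispersion ``phi`` lies in (0, 1), via the reparameterization
``alpha = pbar (1/phi - 1)``, ``beta = (1 - pbar)(1/phi - 1)``.  As
``phi -> 0`` the model collapses to the binomial; larger ``phi`` inflates
between-sample variance.

Fitting maximizes the likelihood over ``(w, logit phi)`` by bounded
quasi-Newton (L-BFGS-B), optionally with ``phi`` held fixed — the device
used to share one global dispersion across cell types when replicates are
scarce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, expit, gammaln, logit
from scipy.stats import chi2

from .counts import CellCountTable
from .errors import DomainError, ValidationError

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-8  # clip for pbar inside the likelihood
_PHI_INIT_LO, _PHI_INIT_HI = 1e-4, 0.5


@dataclass
class BetaBinFit:
    """Maximum-likelihood fit of one beta-binomial GLM."""

    weights: np.ndarray  # coefficients in design-column order
    phi: float
    loglik: float
    converged: bool
    fixed_phi: bool
    n_obs: int


@dataclass
class LrtResult:
    """Likelihood-ratio test of nested beta-binomial fits."""

    statistic: float
    df: int
    p_value: float


def betabin_loglik(
    successes: np.ndarray,
    totals: np.ndarray,
    mean_p: np.ndarray,
    phi: float,
) -> float:
    """Sum of log beta-binomial pmfs, via log-gamma for stability."""
    z = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    p = np.asarray(mean_p, dtype=float)
    if np.any(z < 0) or np.any(z > n):
        raise DomainError("successes must satisfy 0 <= successes <= totals")
    if not 0 < phi < 1:
        raise DomainError(f"phi must lie in (0, 1), got {phi}")
    if np.any(p <= 0) or np.any(p >= 1):
        raise DomainError("mean_p must lie strictly in (0, 1)")
    nu = 1.0 / phi - 1.0
    a = p * nu
    b = (1.0 - p) * nu
    log_binom = gammaln(n + 1) - gammaln(z + 1) - gammaln(n - z + 1)
    if nu > 1e6 and np.allclose(z, np.round(z)) and np.allclose(n, np.round(n)):
        # near the binomial limit gammaln differences cancel catastrophically;
        # integer counts allow the exact sum-of-logs form instead
        zi_, ni_, ai_, bi_ = np.broadcast_arrays(
            np.round(z), np.round(n), p * nu, (1.0 - p) * nu
        )
        ll = log_binom + np.array(
            [
                _gammaln_rise(ai, int(zi))
                + _gammaln_rise(bi, int(ni - zi))
                - _gammaln_rise(ai + bi, int(ni))
                for ai, bi, zi, ni in zip(
                    ai_.ravel(), bi_.ravel(), zi_.ravel(), ni_.ravel()
                )
            ]
        )
    else:
        ll = log_binom + betaln(z + a, n - z + b) - betaln(a, b)
    return float(np.sum(ll))


def _gammaln_rise(a: float, m: int) -> float:
    """log Gamma(a + m) - log Gamma(a) for integer m >= 0, exactly."""
    return float(np.log(a + np.arange(m)).sum())


def _nll(params, z, n, x, fixed_phi):
    w = params if fixed_phi is not None else params[:-1]
    phi = fixed_phi if fixed_phi is not None else float(expit(params[-1]))
    phi = min(max(phi, 1e-12), 1 - 1e-12)
    p = expit(x @ w)
    p = np.clip(p, _P_FLOOR, 1 - _P_FLOOR)
    try:
        return -betabin_loglik(z, n, p, phi)
    except DomainError:
        return np.inf


def _moment_phi(z: np.ndarray, n: np.ndarray) -> float:
    """Method-of-moments overdispersion, clipped to a sane init range."""
    p_hat = z / n
    pbar = z.sum() / n.sum()
    denom = pbar * (1 - pbar)
    if denom <= 0 or len(z) < 2:
        return 0.01
    s2 = p_hat.var(ddof=1)
    inv_n = float(np.mean(1.0 / n))
    phi = (s2 / denom - inv_n) / (1.0 - inv_n)
    return float(np.clip(phi, _PHI_INIT_LO, _PHI_INIT_HI))


def fit_betabin(
    successes: np.ndarray,
    totals: np.ndarray,
    design: np.ndarray,
    fixed_phi: float | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    extra_inits: list[np.ndarray] | None = None,
) -> BetaBinFit:
    """Fit a beta-binomial GLM by maximum likelihood.

    ``design`` is the full observation-by-covariate matrix, including the
    intercept column if one is wanted (nothing is added implicitly).
    Zero-total observations are dropped with a warning.  ``seed`` only
    feeds the jittered restarts attempted when the first optimization
    fails to converge.
    """
    z = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    x = np.atleast_2d(np.asarray(design, dtype=float))
    if x.shape[0] != len(z) or len(n) != len(z):
        raise ValidationError("design rows must align with observations")
    keep = n > 0
    if not np.all(keep):
        logger.warning("dropping %d zero-total observations", int((~keep).sum()))
        z, n, x = z[keep], n[keep], x[keep]
    if len(z) == 0:
        raise ValidationError("no observations with positive totals")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("design columns are linearly dependent")
    if fixed_phi is not None and not 0 < fixed_phi < 1:
        raise DomainError(f"fixed_phi must lie in (0, 1), got {fixed_phi}")

    pooled = float(np.clip(z.sum() / n.sum(), _P_FLOOR, 1 - _P_FLOOR))
    w0 = np.zeros(x.shape[1])
    # put the pooled logit on the (first) intercept-like column if present
    const_cols = np.flatnonzero(np.all(x == x[0], axis=0) & (x[0] != 0))
    if const_cols.size:
        w0[const_cols[0]] = logit(pooled) / x[0, const_cols[0]]
    elif np.all(np.any(x != 0, axis=0)):
        # indicator-style designs: start every column at the pooled logit
        w0[:] = logit(pooled)
    phi0 = _moment_phi(z, n)
    init = w0 if fixed_phi is not None else np.append(w0, logit(phi0))

    inits = [init]
    if extra_inits:
        inits.extend(np.asarray(e, dtype=float) for e in extra_inits)
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(n_restarts + len(inits)):
        if trial < len(inits):
            p0 = inits[trial]
        else:
            p0 = inits[0] + rng.normal(scale=0.5, size=len(inits[0]))
        res = minimize(
            _nll,
            p0,
            args=(z, n, x, fixed_phi),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if trial + 1 >= len(inits) and best.success and np.isfinite(best.fun):
            break
    if not best.success:
        logger.warning("beta-binomial fit did not converge: %s", best.message)

    if fixed_phi is not None:
        w, phi = best.x, float(fixed_phi)
    else:
        w, phi = best.x[:-1], float(expit(best.x[-1]))
    p_fit = expit(x @ w)
    if np.any(p_fit < 10 * _P_FLOOR) or np.any(p_fit > 1 - 10 * _P_FLOOR):
        logger.warning("fitted means at the boundary; possible separation")
    return BetaBinFit(
        weights=np.asarray(w, dtype=float),
        phi=phi,
        loglik=float(-best.fun),
        converged=bool(best.success),
        fixed_phi=fixed_phi is not None,
        n_obs=len(z),
    )


def lrt(fit_alt: BetaBinFit, fit_null: BetaBinFit, df: int) -> LrtResult:
    """Likelihood-ratio test: ``2 (LL_alt - LL_null)`` against chi2(df)."""
    if df < 1:
        raise ValidationError("df must be a positive integer")
    delta = fit_alt.loglik - fit_null.loglik
    if delta < -1e-6:
        logger.warning(
            "alternative log-likelihood below null by %.3g; "
            "statistic clipped at 0 (optimizer artefact)",
            -delta,
        )
    stat = max(0.0, 2.0 * delta)
    return LrtResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def estimate_global_phi(table: CellCountTable, seed: int = 0) -> float:
    """One shared overdispersion, pooled across cell types.

    Stacks every (sample, cell type) observation into a single joint GLM
    whose design is the K cell-type indicator columns (no separate
    intercept) and fits one common ``phi``, to be fixed in the per-type
    tests.  Cell types with all-zero counts are excluded.
    """
    counts = table.counts
    totals = table.totals
    keep = [j for j in range(table.k) if counts[:, j].sum() > 0]
    dropped = set(range(table.k)) - set(keep)
    if dropped:
        logger.warning(
            "excluding all-zero cell types from global phi: %s",
            [table.labels[j] for j in sorted(dropped)],
        )
    if not keep:
        raise ValidationError("all cell types have zero counts")
    k = len(keep)
    z = np.concatenate([counts[:, j] for j in keep]).astype(float)
    n = np.tile(totals.astype(float), k)
    design = np.kron(np.eye(k), np.ones((table.n_samples, 1)))
    fit = fit_betabin(z, n, design, fixed_phi=None, seed=seed)
    return float(fit.phi)
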