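"""Differential composition model: the end-to-end test.

:class:`CompositionModel` bundles a cell count table, a per-sample design
and an optional similarity matrix; :meth:`CompositionModel.fit` runs the
full procedure — EM bias correction (when a similarity matrix is given),
global-overdispersion estimation, and one beta-binomial likelihood-ratio
test per (cell type, tested covariate) — returning a
:class:`CompositionResults` whose ``.table`` is the tidy result frame.

Functional wrappers (:func:`dcats_test`, :func:`detect_reference`,
:func:`use_reference`) expose the same machinery for scripted use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import betabin
from .correction import CorrectionResult, corrected_table, em_correct
from .counts import CellCountTable
from .errors import ValidationError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "cell_type",
    "covariate",
    "coef",
    "lrt_stat",
    "df",
    "pval",
    "qval",
    "phi",
    "normalization",
    "corrected",
]


@dataclass
class DesignMatrix:
    """Per-sample covariates for the GLM mean model.

    ``covariates`` holds one column per covariate (continuous real or
    binary 0/1; expand categoricals to indicators beforehand); ``tested``
    names the covariates whose effect on composition is tested, the rest
    acting as confounders under the full mode.
    """

    sample_ids: list[str]
    covariates: pd.DataFrame
    tested: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.covariates) != len(self.sample_ids):
            raise ValidationError("covariate rows must match sample_ids")
        self.covariates = self.covariates.reset_index(drop=True).astype(float)
        if not self.tested:
            self.tested = list(self.covariates.columns)
        unknown = set(self.tested) - set(self.covariates.columns)
        if unknown:
            raise ValidationError(f"tested covariates not in design: {sorted(unknown)}")
        for name in self.tested:
            col = self.covariates[name].to_numpy()
            if np.all(col == col[0]):
                raise ValidationError(f"tested covariate {name!r} is constant")
        for name, col in self.covariates.items():
            vals = np.unique(col.to_numpy())
            if len(vals) == 2 and not set(vals) <= {0.0, 1.0}:
                logger.info("covariate %r is two-valued but not 0/1 coded", name)

    @property
    def names(self) -> list[str]:
        return list(self.covariates.columns)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, tested: Sequence[str] | None = None
    ) -> "DesignMatrix":
        """Build from a DataFrame indexed by sample id."""
        return cls(list(df.index.astype(str)), df, list(tested or []))

    def reorder(self, sample_ids: Sequence[str]) -> "DesignMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"design missing samples: {missing}")
        idx = [pos[s] for s in sample_ids]
        return DesignMatrix(
            list(sample_ids), self.covariates.iloc[idx], list(self.tested)
        )


def use_reference(
    counts_row: np.ndarray, j: int, reference: Sequence[int] | None
) -> tuple[int, int]:
    """Successes/totals for cell type ``j`` under the chosen normalization.

    With no reference the denominator is the sample total.  With a
    reference group ``R`` the denominator is ``z_j`` plus the reference
    counts, the tested type being excluded from its own denominator so the
    fraction stays inside binomial support.
    """
    row = np.asarray(counts_row)
    z = int(row[j])
    if reference is None:
        return z, int(row.sum())
    ref = [r for r in reference if r != j]
    if not ref:
        raise ValidationError(
            "reference group must contain at least one type besides the tested one"
        )
    return z, z + int(row[ref].sum())


class CompositionModel:
    """Differential cell-type composition model.

    Parameters
    ----------
    counts
        Sample-by-cell-type integer counts.
    design
        Per-sample covariates with the tested subset marked.
    similarity
        Optional confusion matrix; when given, counts are EM-corrected
        before testing.
    mode
        ``"full"`` tests each covariate against the all-covariate model
        with that coefficient zeroed (confounder control); ``"null"``
        compares intercept-only against intercept-plus-that-covariate.
    phi
        ``"global"`` (one dispersion pooled over cell types, then fixed),
        ``"per_type"`` (free dispersion per test) or a float in (0, 1).
    reference
        Optional reference cell types used as the normalization
        denominator instead of the sample total.
    """

    def __init__(
        self,
        counts: CellCountTable,
        design: DesignMatrix,
        similarity: SimilarityMatrix | None = None,
        mode: str = "full",
        phi: str | float = "global",
        reference: Sequence[str] | None = None,
    ) -> None:
        if design.sample_ids != counts.sample_ids:
            design = design.reorder(counts.sample_ids)
        if mode not in ("full", "null"):
            raise ValidationError(f"mode must be 'full' or 'null', got {mode!r}")
        if isinstance(phi, str) and phi not in ("global", "per_type"):
            raise ValidationError(
                f"phi must be 'global', 'per_type' or a float, got {phi!r}"
            )
        if similarity is not None and similarity.labels != counts.labels:
            similarity = similarity.reorder(counts.labels)
        if reference is not None:
            ref = list(reference)
            unknown = set(ref) - set(counts.labels)
            if unknown:
                raise ValidationError(f"unknown reference cell types: {sorted(unknown)}")
            if not ref:
                raise ValidationError("reference group must be nonempty")
        self.counts = counts
        self.design = design
        self.similarity = similarity
        self.mode = mode
        self.phi = phi
        self.reference = list(reference) if reference is not None else None

    @classmethod
    def from_dataframes(
        cls,
        counts: pd.DataFrame,
        design: pd.DataFrame,
        tested: Sequence[str] | None = None,
        **kwargs,
    ) -> "CompositionModel":
        """Build from a counts frame and a design frame, both sample-indexed."""
        return cls(
            CellCountTable.from_frame(counts),
            DesignMatrix.from_frame(design, tested),
            **kwargs,
        )

    # -- internals ---------------------------------------------------------

    def _working_counts(self) -> tuple[CellCountTable, CorrectionResult | None]:
        if self.similarity is None:
            return self.counts, None
        res = em_correct(self.counts, self.similarity)
        return corrected_table(self.counts, res), res

    def _response(self, table: CellCountTable, j: int) -> tuple[np.ndarray, np.ndarray]:
        ref_idx = (
            None
            if self.reference is None
            else [table.labels.index(r) for r in self.reference]
        )
        pairs = [
            use_reference(table.counts[s], j, ref_idx)
            for s in range(table.n_samples)
        ]
        z = np.array([p[0] for p in pairs], dtype=float)
        n = np.array([p[1] for p in pairs], dtype=float)
        zero = np.flatnonzero(n == 0)
        if zero.size:
            raise ValidationError(
                f"normalization total is zero for sample(s) "
                f"{[table.sample_ids[s] for s in zero]}"
            )
        return z, n

    def fit(self, seed: int = 0) -> "CompositionResults":
        """Run correction, dispersion estimation and per-type LRTs."""
        table, correction = self._working_counts()

        if isinstance(self.phi, float):
            phi_global: float | None = float(self.phi)
        elif self.phi == "global":
            phi_global = betabin.estimate_global_phi(table, seed=seed)
        else:
            phi_global = None

        cov = self.design.covariates
        x_full = np.column_stack(
            [np.ones(table.n_samples)] + [cov[c].to_numpy() for c in self.design.names]
        )
        col_of = {c: i + 1 for i, c in enumerate(self.design.names)}

        rows = []
        for j, cell_type in enumerate(table.labels):
            if table.counts[:, j].sum() == 0:
                logger.warning("cell type %r has zero counts; NA result", cell_type)
                for cname in self.design.tested:
                    rows.append(
                        dict.fromkeys(RESULT_COLUMNS)
                        | {"cell_type": cell_type, "covariate": cname, "df": 1}
                    )
                continue
            z, n = self._response(table, j)
            for cname in self.design.tested:
                if self.mode == "null":
                    x_alt = x_full[:, [0, col_of[cname]]]
                    x_null = x_full[:, [0]]
                    coef_idx = 1
                else:
                    x_alt = x_full
                    keep = [i for i in range(x_full.shape[1]) if i != col_of[cname]]
                    x_null = x_full[:, keep]
                    coef_idx = col_of[cname]
                fit_null = betabin.fit_betabin(
                    z, n, x_null, fixed_phi=phi_global, seed=seed
                )
                # seed the alternative with the null solution (tested coef 0)
                warm = np.insert(fit_null.weights, coef_idx, 0.0)
                if phi_global is None:
                    warm = np.append(warm, _logit_safe(fit_null.phi))
                fit_alt = betabin.fit_betabin(
                    z, n, x_alt, fixed_phi=phi_global, seed=seed, extra_inits=[warm]
                )
                test = betabin.lrt(fit_alt, fit_null, df=1)
                rows.append(
                    {
                        "cell_type": cell_type,
                        "covariate": cname,
                        "coef": float(fit_alt.weights[coef_idx]),
                        "lrt_stat": test.statistic,
                        "df": test.df,
                        "pval": test.p_value,
                        "qval": np.nan,
                        "phi": fit_alt.phi,
                        "normalization": (
                            "total"
                            if self.reference is None
                            else "reference:" + ",".join(self.reference)
                        ),
                        "corrected": self.similarity is not None,
                    }
                )
        frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        ok = frame["pval"].notna()
        if ok.any():
            frame.loc[ok, "qval"] = multipletests(
                frame.loc[ok, "pval"].to_numpy(), method="fdr_bh"
            )[1]
        return CompositionResults(self, frame, correction, phi_global, seed)


def _logit_safe(p: float) -> float:
    p = min(max(p, 1e-10), 1 - 1e-10)
    return float(np.log(p / (1 - p)))


@dataclass
class CompositionResults:
    """Fitted differential-composition results.

    ``table`` has one row per (cell type, tested covariate) with the
    coefficient on the logit scale, the LRT statistic and its p-value,
    a BH-adjusted q-value, the dispersion used and run metadata.
    """

    model: CompositionModel
    table: pd.DataFrame
    correction: CorrectionResult | None
    phi_global: float | None
    seed: int

    def pvalues(self, covariate: str | None = None) -> pd.Series:
        tab = self.table
        if covariate is not None:
            tab = tab[tab["covariate"] == covariate]
        elif len(self.model.design.tested) == 1:
            pass
        return pd.Series(
            tab["pval"].to_numpy(), index=tab["cell_type"].to_numpy(), name="pval"
        )

    def summary(self) -> str:
        model = self.model
        lines = [
            "Differential composition analysis (beta-binomial LRT)",
            "=" * 56,
            f"samples: {model.counts.n_samples}   cell types: {model.counts.k}",
            f"mode: {model.mode}   bias corrected: {model.similarity is not None}",
            f"normalization: "
            + ("total" if model.reference is None else f"reference {model.reference}"),
        ]
        if self.phi_global is not None:
            lines.append(f"global overdispersion phi: {self.phi_global:.4g}")
        lines.append("")
        with pd.option_context("display.float_format", "{:.4g}".format):
            lines.append(
                self.table[
                    ["cell_type", "covariate", "coef", "lrt_stat", "pval", "qval"]
                ].to_string(index=False)
            )
        return "\n".join(lines)


# -- functional wrappers ---------------------------------------------------


def dcats_test(
    counts: CellCountTable,
    design: DesignMatrix,
    similarity: SimilarityMatrix | None = None,
    mode: str = "full",
    phi_strategy: str | float = "global",
    reference: Sequence[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One-call differential composition test; returns the result table."""
    model = CompositionModel(
        counts, design, similarity=similarity, mode=mode, phi=phi_strategy,
        reference=reference,
    )
    return model.fit(seed=seed).table


def detect_reference(
    counts: CellCountTable,
    design: DesignMatrix,
    min_fraction: float = 0.25,
    min_types: int = 2,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Rank cell types as reference candidates and recommend a set.

    Runs the total-normalization test, orders cell types from least to
    most significant, and returns the shortest prefix holding at least
    ``min_types`` members and at least ``min_fraction`` of all cells.
    """
    if counts.k < 3:
        raise ValidationError("reference detection needs at least 3 cell types")
    if min_types < 2 or min_types > counts.k - 1:
        raise ValidationError(
            "min_types must be >= 2 and leave at least one testable type"
        )
    table = dcats_test(counts, design, seed=seed)
    agg = (
        table.dropna(subset=["pval"])
        .groupby("cell_type", sort=False)["pval"]
        .min()
    )
    ranked = list(agg.sort_values(ascending=False, kind="stable").index)
    frac = counts.counts.sum(axis=0) / counts.counts.sum()
    frac_of = dict(zip(counts.labels, frac))
    cum = 0.0
    for size in range(1, len(ranked) + 1):
        cum += frac_of[ranked[size - 1]]
        if size >= min_types and cum >= min_fraction:
            return ranked, ranked[:size]
    raise ValidationError(
        f"cannot satisfy min_types={min_types}, min_fraction={min_fraction}"
    )
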