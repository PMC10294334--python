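"""Simulate → test → evaluate loops for the canonical scenarios."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .correction import corrected_table, em_correct
from .evaluate import classification_metrics, fisher_pooled
from .model import dcats_test
from .simulate import (
    SimScenario,
    simulate_dirichlet_multinomial,
    theoretical_confusion,
)

THEORETICAL_METHODS = (
    "dcats_corrected",
    "dcats_uncorrected",
    "fisher_corrected",
    "fisher_uncorrected",
)


def run_theoretical_benchmark(
    seeds: range | list[int] = range(1, 51),
    phi_strategy: str | float = "global",
) -> pd.DataFrame:
    """The misclassification benchmark: 3 types, confusion on types 2–3.

    For each seed: draw the two-condition Dirichlet-multinomial table with
    misclassification injected by the canonical confusion matrix, then
    test each cell type four ways — the beta-binomial LRT and the pooled
    Fisher baseline, each with and without EM correction using the true
    confusion matrix.  Returns a long frame of (seed, method, cell type,
    p-value, truth).
    """
    m = theoretical_confusion()
    rows = []
    for seed in seeds:
        scenario = SimScenario(similarity=m, seed=int(seed))
        sim = simulate_dirichlet_multinomial(scenario)
        corrected = corrected_table(sim.counts, em_correct(sim.counts, m))
        condition = sim.design.covariates["condition"].to_numpy()

        per_method = {
            "dcats_corrected": dcats_test(
                sim.counts, sim.design, similarity=m,
                phi_strategy=phi_strategy, seed=int(seed),
            ).set_index("cell_type")["pval"],
            "dcats_uncorrected": dcats_test(
                sim.counts, sim.design, phi_strategy=phi_strategy, seed=int(seed)
            ).set_index("cell_type")["pval"],
            "fisher_corrected": fisher_pooled(corrected, condition),
            "fisher_uncorrected": fisher_pooled(sim.counts, condition),
        }
        for method, pvals in per_method.items():
            for label, truth in zip(sim.counts.labels, sim.truth):
                rows.append(
                    {
                        "seed": int(seed),
                        "method": method,
                        "cell_type": label,
                        "pval": float(pvals[label]),
                        "truth": bool(truth),
                    }
                )
    return pd.DataFrame(rows)


def pooled_auc(results: pd.DataFrame) -> pd.Series:
    """Pooled ROC AUC per method over all (run, cell type) pairs."""
    out = {}
    for method, grp in results.groupby("method", sort=False):
        met = classification_metrics(
            grp["pval"].to_numpy(), grp["truth"].to_numpy()
        )
        out[method] = met["roc_auc"]
    return pd.Series(out, name="roc_auc")
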