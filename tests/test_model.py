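import numpy as np
import pandas as pd
import pytest

import dcakit as dk
from dcakit.errors import ValidationError
from dcakit.simulate import SimScenario, simulate_dirichlet_multinomial


@pytest.fixture(scope="module")
def sim_two_groups():
    """A 3-type two-condition dataset with a genuine shift in types 2–3."""
    return simulate_dirichlet_multinomial(
        SimScenario(replicates=(4, 4), seed=11)
    )


class TestUseReference:
    def test_full_reference_equals_total(self):
        row = np.array([30, 50, 20])
        z, n = dk.use_reference(row, 0, [0, 1, 2])
        assert (z, n) == (30, 100)
        assert dk.use_reference(row, 0, None) == (30, 100)

    def test_outside_reference(self):
        z, n = dk.use_reference(np.array([30, 50, 20]), 0, [1, 2])
        assert (z, n) == (30, 100)

    def test_tested_type_excluded_from_own_denominator(self):
        z, n = dk.use_reference(np.array([30, 50, 20]), 1, [1, 2])
        assert (z, n) == (50, 70)


class TestCompositionModel:
    def test_summary_and_table_schema(self, sim_two_groups):
        model = dk.CompositionModel(sim_two_groups.counts, sim_two_groups.design)
        res = model.fit(seed=0)
        assert list(res.table.columns) == [
            "cell_type", "covariate", "coef", "lrt_stat", "df", "pval",
            "qval", "phi", "normalization", "corrected",
        ]
        assert len(res.table) == 3
        assert res.table["pval"].between(0, 1).all()
        text = res.summary()
        assert "beta-binomial" in text and "type2" in text

    def test_from_dataframes_roundtrip(self, sim_two_groups):
        model = dk.CompositionModel.from_dataframes(
            sim_two_groups.counts.to_frame(),
            sim_two_groups.design.covariates.set_axis(
                sim_two_groups.counts.sample_ids
            ),
            tested=["condition"],
        )
        direct = dk.CompositionModel(sim_two_groups.counts, sim_two_groups.design)
        assert np.allclose(
            model.fit(seed=0).table["pval"], direct.fit(seed=0).table["pval"]
        )

    def test_null_and_full_mode_agree_with_one_covariate(self, sim_two_groups):
        p_full = dk.dcats_test(
            sim_two_groups.counts, sim_two_groups.design, mode="full", seed=0
        )["pval"]
        p_null = dk.dcats_test(
            sim_two_groups.counts, sim_two_groups.design, mode="null", seed=0
        )["pval"]
        assert np.allclose(p_full, p_null, atol=1e-5)

    def test_sample_order_invariance(self, sim_two_groups):
        counts, design = sim_two_groups.counts, sim_two_groups.design
        perm = [3, 0, 6, 1, 7, 2, 5, 4]
        shuffled = counts.select_samples(perm)
        res_a = dk.dcats_test(counts, design, seed=0)
        res_b = dk.dcats_test(shuffled, design, seed=0)
        assert np.allclose(res_a["pval"], res_b["pval"], atol=1e-6)

    def test_cell_type_permutation_equivariance(self, sim_two_groups, confusion3):
        counts, design = sim_two_groups.counts, sim_two_groups.design
        res_a = dk.dcats_test(counts, design, similarity=confusion3, seed=0)
        perm = [2, 0, 1]
        counts_p = dk.CellCountTable(
            counts.sample_ids,
            [counts.labels[i] for i in perm],
            counts.counts[:, perm],
        )
        res_b = dk.dcats_test(counts_p, design, similarity=confusion3, seed=0)
        a = res_a.set_index("cell_type")["pval"]
        b = res_b.set_index("cell_type")["pval"]
        # column order perturbs the optimizer path slightly; equivariance
        # holds to optimizer tolerance
        assert np.allclose(a[counts.labels], b[counts.labels], rtol=1e-3, atol=1e-6)

    def test_qvalues_monotone_in_pvalues(self, sim_two_groups):
        tab = dk.dcats_test(sim_two_groups.counts, sim_two_groups.design, seed=0)
        ordered = tab.sort_values("pval")
        assert ordered["qval"].is_monotonic_increasing
        assert (ordered["qval"] >= ordered["pval"] - 1e-12).all()

    def test_unknown_reference_rejected(self, sim_two_groups):
        with pytest.raises(ValidationError, match="unknown reference"):
            dk.dcats_test(
                sim_two_groups.counts, sim_two_groups.design,
                reference=["nonesuch"], seed=0,
            )

    def test_all_zero_cell_type_gives_na_row(self, two_group_design):
        counts = dk.CellCountTable(
            ["s1", "s2", "s3", "s4"],
            ["A", "B", "C"],
            np.array([[30, 70, 0], [25, 75, 0], [40, 60, 0], [35, 65, 0]]),
        )
        tab = dk.dcats_test(counts, two_group_design, phi_strategy=0.05, seed=0)
        assert tab.loc[tab["cell_type"] == "C", "pval"].isna().all()
        assert tab.loc[tab["cell_type"] != "C", "pval"].notna().all()

    def test_constant_tested_covariate_rejected(self, small_counts):
        with pytest.raises(ValidationError, match="constant"):
            dk.DesignMatrix(
                small_counts.sample_ids,
                pd.DataFrame({"condition": [1.0, 1.0, 1.0, 1.0]}),
                tested=["condition"],
            )

    def test_detects_planted_shift_and_controls_covariates(self):
        sim = dk.simulate_with_covariates(seed=5)
        design = dk.DesignMatrix(
            sim.design.sample_ids, sim.design.covariates,
            tested=["condition", "age", "gender"],
        )
        tab = dk.dcats_test(sim.counts, design, seed=5)
        assert set(tab["covariate"]) == {"condition", "age", "gender"}
        assert len(tab) == 3 * sim.counts.k
        cond = tab[tab["covariate"] == "condition"].set_index("cell_type")
        # the strongest condition shifts (types 1 and 8 double/halve) rank
        # below the unaffected types
        assert cond.loc["type1", "pval"] < cond.loc["type3", "pval"]


class TestDetectReference:
    def test_equal_proportions_recommends_smallest_prefix(self, rng):
        counts = dk.CellCountTable(
            [f"s{i}" for i in range(6)],
            ["A", "B", "C"],
            rng.multinomial(900, [1 / 3] * 3, size=6),
        )
        design = dk.DesignMatrix(
            counts.sample_ids,
            pd.DataFrame({"condition": [0.0, 0, 0, 1, 1, 1]}),
            tested=["condition"],
        )
        ranked, rec = dk.detect_reference(counts, design, seed=0)
        assert len(ranked) == 3
        assert len(rec) == 2

    def test_too_few_types_rejected(self, rng):
        counts = dk.CellCountTable(
            ["s1", "s2"], ["A", "B"], np.array([[10, 20], [30, 40]])
        )
        design = dk.DesignMatrix(
            ["s1", "s2"], pd.DataFrame({"condition": [0.0, 1.0]})
        )
        with pytest.raises(ValidationError):
            dk.detect_reference(counts, design)
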