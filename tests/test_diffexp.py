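import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gdref import diffexp, probes, simulate
from gdref.diffexp import (
    DesignInfo,
    adjust_fdr,
    fit_gene_model,
    moderate_statistics,
    summarize_genes,
)

from conftest import make_annotations, matrix_from_values


def _design(conditions, reps, reference="MI16"):
    labels = [f"{c}_r{i}" for c in conditions for i in range(1, reps + 1)]
    return labels, DesignInfo.from_labels(labels, reference)


class TestDesignInfo:
    def test_parses_labels(self):
        labels, design = _design(["MI16", "MII24"], 2)
        assert design.conditions() == ["MI16", "MII24"]
        assert design.contrasts() == ["MII24"]

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            DesignInfo.from_labels(["MI16_r1", "MI16_r2", "MII24_r1"])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            DesignInfo.from_labels(["MII24_r1", "MII24_r2"])

    def test_unparseable_label(self):
        with pytest.raises(ValueError, match="parse"):
            DesignInfo.from_labels(["whatever"])


class TestSummarizeGenes:
    def _matrix(self, ann, rows):
        values = pd.DataFrame(rows, index=ann["probe_id"])
        return probes.ExpressionMatrix(values, probes.assign_weights(ann))

    def test_equal_weights_average(self):
        ann = make_annotations(2)
        ann["gene_ids"] = "G1"
        m = self._matrix(ann, {"MI16_r1": [1.0, 3.0]})
        out = summarize_genes(m, ann)
        assert out.values.loc["G1", "MI16_r1"] == pytest.approx(2.0)

    def test_downweighted_probe_barely_counts(self):
        ann = make_annotations(1, n_crosshyb=1)
        ann["gene_ids"] = "G1"
        m = self._matrix(ann, {"MI16_r1": [1.0, 100.0]})
        out = summarize_genes(m, ann)
        expected = (1.0 + 100.0 * 1e-6) / (1.0 + 1e-6)
        assert out.values.loc["G1", "MI16_r1"] == pytest.approx(expected, abs=1e-12)

    def test_gene_with_only_invalid_probes_dropped(self, caplog):
        ann = make_annotations(1, n_crosshyb=1)
        # crosshyb probe maps to its own gene -> that gene has no valid probe
        m = self._matrix(ann, {"MI16_r1": [1.0, 5.0]})
        with caplog.at_level("WARNING"):
            out = summarize_genes(m, ann)
        assert list(out.values.index) == ["G000001"]
        assert "dropping" in caplog.text

    def test_simulator_truth_zero_noise(self):
        effects = {"G0003": {"MII24": 1.5, "MII48": 1.5, "MII72": 1.5}}
        config = simulate.SimulationConfig(
            n_genes=10, probes_per_gene=3, noise_sd=0.0, seed=1,
            frac_crosshyb=0.0, frac_intergenic=0.0, effect_table=effects,
        )
        scans, ann, truth = simulate.generate_array_dataset(config)
        m = probes.build_matrix(scans, ann)
        genes = summarize_genes(m, ann)
        design = DesignInfo.from_labels(genes.values.columns)
        fit = fit_gene_model(genes, design)
        np.testing.assert_allclose(
            fit.mc.to_numpy(),
            truth.effects.drop(columns="MI16").loc[fit.mc.index].to_numpy(),
            atol=1e-12,
        )


class TestFitGeneModel:
    def test_exact_means_zero_variance(self):
        labels, design = _design(["MI16", "MII24", "MII48", "MII72"], 3)
        values = {}
        for label in labels:
            cond = label.rpartition("_r")[0]
            values[label] = [0.0 if cond == "MI16" else 2.0]
        m = matrix_from_values(values)
        fit = fit_gene_model(m, design)
        np.testing.assert_allclose(fit.mc.to_numpy(), 2.0)
        assert fit.sigma2.iloc[0] == pytest.approx(0.0)

    def test_pooled_variance_oracle_two_conditions(self):
        labels, design = _design(["MI16", "MII24"], 2)
        m = matrix_from_values(dict(zip(labels, [[0.0], [1.0], [3.0], [5.0]])))
        fit = fit_gene_model(m, design)
        assert fit.mc.loc[0, "MII24"] == pytest.approx(3.5)
        # pooled two-sample variance with df = 4 - 2
        a, b = np.array([0.0, 1.0]), np.array([3.0, 5.0])
        pooled = (a.var(ddof=1) + b.var(ddof=1)) / 2
        assert fit.sigma2.iloc[0] == pytest.approx(pooled)
        assert fit.df_resid == 2

    def test_column_order_invariance(self):
        rng = np.random.default_rng(0)
        labels, design = _design(["MI16", "MII24"], 3)
        rows = rng.normal(size=(5, 6))
        m1 = matrix_from_values(dict(zip(labels, rows.T)))
        shuffled = [labels[i] for i in [3, 0, 5, 2, 1, 4]]
        m2 = probes.ExpressionMatrix(m1.values[shuffled])
        fit1 = fit_gene_model(m1, design)
        fit2 = fit_gene_model(m2, design)
        pd.testing.assert_frame_equal(fit1.mc, fit2.mc)
        pd.testing.assert_series_equal(fit1.sigma2, fit2.sigma2)

    def test_uncovered_column_rejected(self):
        _, design = _design(["MI16", "MII24"], 2)
        m = matrix_from_values({"weird": [1.0], "MI16_r1": [1.0]})
        with pytest.raises(ValueError, match="cover"):
            fit_gene_model(m, design)


def _simulated_fit(n_genes=50, noise_sd=0.3, seed=0, effects=None):
    config = simulate.SimulationConfig(
        n_genes=n_genes, probes_per_gene=2, noise_sd=noise_sd, seed=seed,
        effect_table=effects or {},
    )
    scans, ann, truth = simulate.generate_array_dataset(config)
    m = probes.build_matrix(scans, ann, probes.assign_weights(ann))
    genes = summarize_genes(m, ann)
    design = DesignInfo.from_labels(genes.values.columns)
    return fit_gene_model(genes, design), truth


class TestModerateStatistics:
    def test_zero_prior_df_gives_ordinary_t(self):
        fit, _ = _simulated_fit(seed=3)
        res = moderate_statistics(fit, df_prior=0.0)
        n = fit.n_per_condition
        for cond in fit.mc.columns:
            v = 1.0 / n[cond] + 1.0 / n[fit.reference]
            ordinary = fit.mc[cond] / np.sqrt(fit.sigma2 * v)
            suffix = diffexp.contrast_suffix(cond)
            np.testing.assert_allclose(
                res.table[f"t_{suffix}"].to_numpy(), ordinary.to_numpy(), atol=1e-9
            )

    def test_hand_set_hyperparameters_formula(self):
        # three genes, forced d0 = 4, s0 = 1: check the posterior variance
        labels, design = _design(["MI16", "MII24"], 2)
        m = matrix_from_values(
            dict(zip(labels, [[0.0, 0, 0], [1.0, 2, 3], [3.0, 1, 0], [5.0, 3, 1]]))
        )
        fit = fit_gene_model(m, design)
        res = moderate_statistics(fit, df_prior=4.0, s0_sq=1.0, min_genes=1)
        d = fit.df_resid
        s2_post = (4.0 * 1.0 + d * fit.sigma2.to_numpy()) / (4.0 + d)
        v = 1.0 / 2 + 1.0 / 2
        expected_t = fit.mc["MII24"].to_numpy() / np.sqrt(s2_post * v)
        np.testing.assert_allclose(res.table["t_24"].to_numpy(), expected_t)
        # p-values use the augmented degrees of freedom
        expected_p = 2 * stats.t.sf(np.abs(expected_t), d + 4.0)
        np.testing.assert_allclose(res.table["p_24"].to_numpy(), expected_p)

    def test_brute_force_oracle_small_instance(self):
        # <= 10 genes with forced hyperparameters: every number recomputed
        # from scratch with plain numpy/scipy
        rng = np.random.default_rng(12)
        labels, design = _design(["MI16", "MII24", "MII48", "MII72"], 3)
        data = rng.normal(0, 0.5, size=(8, 12))
        m = matrix_from_values(dict(zip(labels, data.T)))
        fit = fit_gene_model(m, design)
        d0, s0_sq = 3.0, 0.2
        res = moderate_statistics(fit, df_prior=d0, s0_sq=s0_sq, min_genes=1)
        conds = ["MI16", "MII24", "MII48", "MII72"]
        for g in range(8):
            y = data[g].reshape(4, 3)  # condition x replicate
            means = y.mean(axis=1)
            sse = ((y - means[:, None]) ** 2).sum()
            s2 = sse / (12 - 4)
            s2_post = (d0 * s0_sq + 8 * s2) / (d0 + 8)
            for ci, suffix in [(1, "24"), (2, "48"), (3, "72")]:
                mc = means[ci] - means[0]
                t = mc / np.sqrt(s2_post * (1 / 3 + 1 / 3))
                p = 2 * stats.t.sf(abs(t), 8 + d0)
                assert res.table.iloc[g][f"Mc_{suffix}"] == pytest.approx(mc)
                assert res.table.iloc[g][f"t_{suffix}"] == pytest.approx(t)
                assert res.table.iloc[g][f"p_{suffix}"] == pytest.approx(p)

    def test_all_zero_variance_falls_back(self):
        labels, design = _design(["MI16", "MII24"], 2)
        m = matrix_from_values(dict(zip(labels, [[0.0] * 12, [0.0] * 12, [1.0] * 12, [1.0] * 12])))
        fit = fit_gene_model(m, design)
        with pytest.warns(RuntimeWarning, match="ordinary"):
            res = moderate_statistics(fit)
        assert np.isinf(res.table["t_24"]).all()

    def test_null_type_i_error(self, null_results):
        table = null_results.table
        for suffix in ("24", "48", "72"):
            frac = (table[f"p_{suffix}"] < 0.05).mean()
            assert 0.01 <= frac <= 0.10

    def test_few_genes_rejected(self):
        fit, _ = _simulated_fit(n_genes=50)
        small = diffexp.GeneFit(
            coef=fit.coef.iloc[:3],
            mc=fit.mc.iloc[:3],
            sigma2=fit.sigma2.iloc[:3],
            df_resid=fit.df_resid,
            n_per_condition=fit.n_per_condition,
            reference=fit.reference,
        )
        with pytest.raises(ValueError, match="genes"):
            moderate_statistics(small)


class TestParameterRecovery:
    def test_mae_and_power(self):
        effect_values = [-3, -2, -1, 1, 2, 3]
        effects = {
            f"G{i:04d}": {c: float(effect_values[(i - 1) % 6])
                          for c in ("MII24", "MII48", "MII72")}
            for i in range(1, 31)
        }
        fit, truth = _simulated_fit(
            n_genes=200, noise_sd=0.2, seed=5, effects=effects
        )
        res = moderate_statistics(fit)
        err = (fit.mc - truth.effects.drop(columns="MI16").loc[fit.mc.index]).abs()
        assert err.mean().mean() < 0.15
        strong = [g for g, e in effects.items() if abs(e["MII24"]) >= 2]
        hits = (res.table.loc[strong, ["fdr_24", "fdr_48", "fdr_72"]] < 0.05).all(axis=1)
        assert hits.mean() >= 0.90

    def test_mean_recovery_over_replicates(self):
        # parameter-recovery property: mean Mc over >= 20 stochastic
        # replicates within 0.05 of the configured effect at noise 0.2
        effect = 1.5
        effects = {"G0001": {"MII24": effect, "MII48": effect, "MII72": effect}}
        recovered = []
        for seed in range(20):
            fit, _ = _simulated_fit(
                n_genes=30, noise_sd=0.2, seed=seed, effects=effects
            )
            recovered.append(fit.mc.loc["G0001"].to_numpy())
        mean = np.mean(recovered, axis=0)
        np.testing.assert_allclose(mean, effect, atol=0.05)


class TestAdjustFdr:
    def test_forced_example(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.3]), [0.3])

    def test_against_statsmodels(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=1000)
        ours = adjust_fdr(p)
        reference = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, reference, atol=1e-12)

    def test_against_naive_definition(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=25)
        m = len(p)
        order = np.argsort(p)
        naive = np.empty(m)
        # step-up from the largest rank, carrying the running minimum
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            naive[idx] = running
        np.testing.assert_allclose(adjust_fdr(p), naive, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            adjust_fdr([-0.1])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50)
    )
    def test_properties(self, p):
        adjusted = adjust_fdr(p)
        assert np.all(adjusted >= np.asarray(p) - 1e-12)
        assert np.all(adjusted <= 1.0)
        # adjustment preserves the significance ordering
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-12)
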