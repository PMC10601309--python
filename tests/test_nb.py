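"""NB engine: size factors, dispersion, GLM fitting, Wald, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import brute_force_bh
from ptreg import nb
from ptreg.simulate import SimulationConfig, make_ground_truth, simulate_count_matrices


def _meta(columns, stage_of, assay_of):
    return pd.DataFrame(
        {"sample": columns, "assay": [assay_of(c) for c in columns], "stage": [stage_of(c) for c in columns]}
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        c = pd.DataFrame({"a": [3, 9, 2], "b": [3, 9, 2], "c": [3, 9, 2]})
        assert np.allclose(nb.estimate_size_factors(c), 1.0)

    def test_hand_computed_doubling_example(self):
        c = pd.DataFrame({"s1": [10, 100], "s2": [20, 200]})
        sf = nb.estimate_size_factors(c)
        assert sf["s1"] == pytest.approx(0.7071, abs=1e-4)
        assert sf["s2"] == pytest.approx(1.4142, abs=1e-4)

    def test_invariant_to_feature_order(self):
        rng = np.random.default_rng(3)
        c = pd.DataFrame(rng.integers(1, 500, size=(30, 4)), columns=list("abcd"))
        shuffled = c.sample(frac=1.0, random_state=7)
        pd.testing.assert_series_equal(
            nb.estimate_size_factors(c), nb.estimate_size_factors(shuffled)
        )

    def test_no_all_positive_feature_raises(self):
        c = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            nb.estimate_size_factors(c)


class TestDispersions:
    @staticmethod
    def _simulate(alpha, mu=500.0, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        if alpha > 0:
            lam = rng.gamma(1 / alpha, alpha * mu, size=(n, 6))
        else:
            lam = np.full((n, 6), mu)
        mat = rng.poisson(lam)
        c = pd.DataFrame(mat, columns=[f"s{i}" for i in range(6)])
        sf = pd.Series(1.0, index=c.columns)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=c.columns)
        return c, sf, groups

    def test_poisson_data_estimates_near_zero(self):
        c, sf, g = self._simulate(alpha=0.0)
        d = nb.estimate_dispersions(c, sf, g)
        assert np.median(d) <= 0.01

    def test_recovers_moderate_dispersion(self):
        c, sf, g = self._simulate(alpha=0.1)
        d = nb.estimate_dispersions(c, sf, g)
        assert 0.05 <= np.median(d) <= 0.2

    def test_constant_counts_hit_the_floor(self):
        c = pd.DataFrame(np.full((20, 6), 7), columns=[f"s{i}" for i in range(6)])
        g = pd.Series(["A"] * 3 + ["B"] * 3, index=c.columns)
        d = nb.estimate_dispersions(c, pd.Series(1.0, index=c.columns), g)
        assert np.allclose(d, nb.DISPERSION_FLOOR)

    def test_no_replicated_group_raises(self):
        c = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        g = pd.Series(["A", "B"], index=c.columns)
        with pytest.raises(ValueError, match="replicates"):
            nb.estimate_dispersions(c, pd.Series(1.0, index=c.columns), g)

    def test_heterogeneous_dispersions_not_flattened(self):
        # adaptive shrinkage must keep a 0.01-vs-0.3 split distinguishable
        rng = np.random.default_rng(1)
        mu = 500.0
        lam_lo = rng.gamma(100, 0.01 * mu, size=(800, 6))
        lam_hi = rng.gamma(1 / 0.3, 0.3 * mu, size=(800, 6))
        mat = rng.poisson(np.vstack([lam_lo, lam_hi]))
        c = pd.DataFrame(mat, columns=[f"s{i}" for i in range(6)])
        g = pd.Series(["A"] * 3 + ["B"] * 3, index=c.columns)
        d = nb.estimate_dispersions(c, pd.Series(1.0, index=c.columns), g).to_numpy()
        assert np.median(d[:800]) < 0.05 < np.median(d[800:])


class TestGLM:
    def test_null_coefficients_near_zero_at_high_counts(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        sf = np.ones(6)
        coefs = [
            nb.fit_nb_glm(rng.poisson(1000.0, size=6), X, 1e-8, sf).coef[1] for _ in range(50)
        ]
        assert np.mean(np.abs(coefs)) < 0.05

    def test_two_group_fold_change_recovery(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        sf = np.ones(6)
        ests = []
        for _ in range(200):
            mu = np.array([100.0] * 3 + [400.0] * 3)
            lam = rng.gamma(100.0, mu / 100.0)
            fit = nb.fit_nb_glm(rng.poisson(lam), X, 0.01, sf)
            ests.append(fit.coef[1] / np.log(2))
        assert np.mean(ests) == pytest.approx(2.0, abs=0.15)

    def test_offset_invariance(self):
        rng = np.random.default_rng(6)
        y = rng.poisson(200.0, size=6).astype(float)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        f1 = nb.fit_nb_glm(y, X, 0.05, np.ones(6))
        f2 = nb.fit_nb_glm(y, X, 0.05, np.full(6, 2.0))
        assert f1.coef[1] == pytest.approx(f2.coef[1], abs=1e-6)

    def test_poisson_limit_matches_poisson_glm_oracle(self):
        # at alpha -> 0 the Wald p must agree with an independent Poisson GLM
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(8), [0] * 4 + [1] * 4])
        agree = 0
        n_trials = 60
        for _ in range(n_trials):
            y = rng.poisson(300.0, size=8).astype(float)
            fit = nb.fit_nb_glm(y, X, 1e-12, np.ones(8))
            _, p_ours = nb.wald_test(
                fit.coef[1] / np.log(2), np.sqrt(fit.cov[1, 1]) / np.log(2)
            )
            oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            p_ref = 2 * stats.norm.sf(abs(oracle.params[1] / oracle.bse[1]))
            if abs(p_ours - p_ref) < 0.01:
                agree += 1
        assert agree / n_trials >= 0.95


class TestWaldAndBH:
    def test_zero_coefficient_gives_p_one(self):
        assert nb.wald_test(0.0, 1.0)[1] == pytest.approx(1.0)

    def test_known_normal_quantile(self):
        _, p = nb.wald_test(1.96, 1.0)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_sign_symmetry(self):
        assert nb.wald_test(0.7, 0.2)[1] == nb.wald_test(-0.7, 0.2)[1]

    def test_bh_hand_example(self):
        padj = nb.adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(padj, 0.04)

    def test_single_p_unchanged(self):
        assert nb.adjust_bh(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_nan_excluded_from_family(self):
        padj = nb.adjust_bh(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(padj[1])
        assert np.allclose(padj[[0, 2]], brute_force_bh(np.array([0.01, 0.04])))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 40)))
        assert np.allclose(nb.adjust_bh(p), brute_force_bh(p), atol=1e-12)


class TestDesignsEndToEnd:
    def test_concordant_fold_change_gives_null_interaction(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(200)]
        cols_c = [f"chro_{s}_r{i}" for s in "AB" for i in range(3)]
        cols_r = [f"rna_{s}_r{i}" for s in "AB" for i in range(3)]
        mu = np.array([200.0] * 3 + [800.0] * 3)  # same 4x change in both assays
        chro = pd.DataFrame(rng.poisson(mu, size=(200, 6)), index=genes, columns=cols_c)
        rna = pd.DataFrame(rng.poisson(mu, size=(200, 6)), index=genes, columns=cols_r)
        meta = _meta(
            cols_c + cols_r,
            stage_of=lambda c: c.split("_")[1],
            assay_of=lambda c: c.split("_")[0],
        )
        res = nb.two_factor_interaction(chro, rna, meta, "A", "B")
        assert abs(res["log2FC"].mean()) < 0.05

    def test_interaction_recovers_designed_discordance(self):
        cfg = SimulationConfig(
            n_genes=400,
            frac_pt=0.25,
            frac_transcriptional=0.0,
            effect_log2fc=2.0,
            nb_dispersion=0.01,
            mean_expression_log_range=(3.7, 4.2),
            seed=12,
        )
        truth = make_ground_truth(cfg)
        chro, rna, meta = simulate_count_matrices(truth, cfg)
        res = nb.two_factor_interaction(chro, rna, meta, "DE", "Duo")
        planted = truth.genes["pt_log2fc"]
        for sign in (1, -1):
            mask = planted == sign * 2.0
            assert res.loc[mask, "log2FC"].mean() == pytest.approx(sign * 2.0, abs=0.15)

    def test_swapping_assay_labels_negates_interaction(self):
        cfg = SimulationConfig(n_genes=60, seed=13)
        truth = make_ground_truth(cfg)
        chro, rna, meta = simulate_count_matrices(truth, cfg)
        res = nb.two_factor_interaction(chro, rna, meta, "DE", "Duo")
        meta_sw = meta.copy()
        meta_sw["assay"] = meta_sw["assay"].map({"chro": "rna", "rna": "chro"})
        res_sw = nb.two_factor_interaction(rna, chro, meta_sw, "DE", "Duo")
        assert np.allclose(res["log2FC"], -res_sw["log2FC"], atol=1e-6, equal_nan=True)

    def test_missing_design_cell_raises(self):
        cfg = SimulationConfig(n_genes=20, seed=14)
        truth = make_ground_truth(cfg)
        chro, rna, meta = simulate_count_matrices(truth, cfg)
        rna_a_cols = meta[(meta["assay"] == "rna") & (meta["stage"] == "DE")]["sample"]
        with pytest.raises(ValueError, match="design cell"):
            nb.two_factor_interaction(chro, rna.drop(columns=rna_a_cols), meta, "DE", "Duo")

    def test_result_table_has_stable_column_order(self):
        cfg = SimulationConfig(n_genes=20, seed=15)
        truth = make_ground_truth(cfg)
        chro, rna, meta = simulate_count_matrices(truth, cfg)
        res = nb.two_factor_interaction(chro, rna, meta, "DE", "Duo")
        assert list(res.columns) == nb.FITRESULT_COLUMNS
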