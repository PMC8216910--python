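"""Kinship, structure, relatedness exclusion, scans and thresholds."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from polygwas import (DataError, ENGINE_PRESETS, FilterSettings, RunConfig,
                      SimulationSpec, bonferroni_threshold,
                      exclude_first_degree, fit_null_mlm, inflation_factor,
                      kinship_matrix, principal_components, run_engine,
                      scan_glm, scan_mlm, simulate_dataset)

from conftest import make_genotype


def naive_config(**kwargs):
    defaults = dict(
        genotype_path="<mem>", phenotype_path="<mem>", gwas_model="naive",
        test_model="additive",
        filters=FilterSettings(maf=None, mind=None, geno=None, hwe=None))
    defaults.update(kwargs)
    return RunConfig(**defaults)


# ---------------------------------------------------------------------------
# kinship / PCs / relatedness
# ---------------------------------------------------------------------------

class TestKinship:
    def test_hand_computed_fixture(self):
        dosage = np.array([
            [0, 2, 4],
            [1, 1, 3],
            [4, 0, 0],
            [2, 2, 0],
        ], dtype=float)
        Z = dosage - dosage.mean(axis=1, keepdims=True)
        Z /= dosage.std(axis=1, keepdims=True)
        expected = Z.T @ Z / 4
        np.testing.assert_allclose(kinship_matrix(dosage), expected, atol=1e-12)

    def test_identical_samples_match_diagonal(self):
        rngl = np.random.default_rng(0)
        d = rngl.integers(0, 5, size=(30, 4)).astype(float)
        d[:, 1] = d[:, 0]
        K = kinship_matrix(d)
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_permutation_equivariance(self):
        rngl = np.random.default_rng(1)
        d = rngl.integers(0, 5, size=(25, 6)).astype(float)
        perm = np.array([3, 0, 5, 1, 4, 2])
        K = kinship_matrix(d)
        Kp = kinship_matrix(d[:, perm])
        np.testing.assert_allclose(Kp, K[np.ix_(perm, perm)], atol=1e-12)

    def test_too_few_polymorphic_markers(self):
        with pytest.raises(DataError):
            kinship_matrix(np.ones((3, 5)))


class TestPrincipalComponents:
    def test_separates_two_subpopulations(self):
        data = simulate_dataset(SimulationSpec(
            n_samples=80, n_markers=150, n_causal=0, n_subpops=2,
            subpop_fst=0.3, seed=11))
        pcs = principal_components(data.genotype.dosage, 2)
        groups = np.arange(80) % 2
        # silhouette-like check: PC1 group means separated beyond group sds
        mu = [pcs[groups == g, 0].mean() for g in (0, 1)]
        sd = [pcs[groups == g, 0].std() for g in (0, 1)]
        assert abs(mu[0] - mu[1]) > (sd[0] + sd[1])

    def test_zero_components_empty_block(self):
        d = np.random.default_rng(2).integers(0, 5, size=(10, 6)).astype(float)
        assert principal_components(d, 0).shape == (6, 0)

    def test_duplicated_samples_identical_coordinates(self):
        rngl = np.random.default_rng(3)
        d = rngl.integers(0, 5, size=(40, 5)).astype(float)
        d = np.hstack([d, d[:, [0]]])
        pcs = principal_components(d, 3)
        np.testing.assert_allclose(pcs[0], pcs[-1], atol=1e-8)

    def test_n_too_large_errors(self):
        d = np.random.default_rng(4).integers(0, 5, size=(10, 4)).astype(float)
        with pytest.raises(DataError):
            principal_components(d, 4)


class TestExcludeFirstDegree:
    def test_unrelated_panel_fully_retained(self):
        K = np.eye(5) + 0.05
        ids = [f"s{i}" for i in range(5)]
        assert exclude_first_degree(K, ids) == ids

    def test_duplicated_sample_one_of_pair_removed(self):
        rngl = np.random.default_rng(5)
        d = rngl.integers(0, 5, size=(60, 5)).astype(float)
        d[:, 4] = d[:, 0]  # duplicate
        K = kinship_matrix(d)
        ids = ["a", "b", "c", "d", "e"]
        kept = exclude_first_degree(K, ids)
        assert len(kept) == 4
        assert ("a" in kept) != ("e" in kept)

    def test_hub_sample_removed_first(self):
        # trio: c tied to both a and b (parent-like hub), a-b unrelated
        K = np.eye(5)
        K[0, 2] = K[2, 0] = 0.6   # a ~ c
        K[1, 2] = K[2, 1] = 0.55  # b ~ c
        kept = exclude_first_degree(K, ["a", "b", "c", "d", "e"], threshold=0.5)
        # removing the hub alone resolves every tie; a and b survive
        assert kept == ["a", "b", "d", "e"]


# ---------------------------------------------------------------------------
# GLM scan
# ---------------------------------------------------------------------------

class TestScanGLM:
    def test_causal_marker_attains_minimum_p(self, rng):
        d = rng.integers(0, 5, size=(50, 80)).astype(float)
        geno = make_genotype(d)
        y = 5.0 * d[17] + rng.normal(0, 0.1, size=80)
        table = scan_glm(y, None, geno, ["additive"])[0]
        assert table.best_ranked(1) == ["m18"]

    def test_orthogonal_marker_f_near_zero(self, rng):
        d = rng.integers(0, 5, size=(2, 40)).astype(float)
        geno = make_genotype(d)
        x = d[0] - d[0].mean()
        y = rng.normal(size=40)
        resid = y - (y @ x) / (x @ x) * x  # orthogonalize vs marker 1
        table = scan_glm(resid, None, geno, ["additive"])[0]
        p1 = table.frame.set_index("marker").loc["m1", "pvalue"]
        assert p1 > 0.99

    def test_single_column_f_equals_squared_t(self, rng):
        d = rng.integers(0, 5, size=(1, 30)).astype(float)
        geno = make_genotype(d)
        y = 0.5 * d[0] + rng.normal(size=30)
        table = scan_glm(y, None, geno, ["additive"])[0]
        lr = stats.linregress(d[0], y)
        assert table.frame["pvalue"].iloc[0] == pytest.approx(lr.pvalue, rel=1e-9)

    def test_missing_dosages_dropped_per_marker(self, rng):
        d = rng.integers(0, 5, size=(1, 30)).astype(float)
        keep = np.ones(30, bool)
        keep[:5] = False
        y = rng.normal(size=30)
        d_miss = d.copy()
        d_miss[0, ~keep] = np.nan
        p_miss = scan_glm(y, None, make_genotype(d_miss), ["additive"])[0]
        p_sub = scan_glm(y[keep], None, make_genotype(d[:, keep]), ["additive"])[0]
        assert p_miss.frame["pvalue"].iloc[0] == pytest.approx(
            p_sub.frame["pvalue"].iloc[0], rel=1e-12)


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def structured_K():
    """Kinship with real structure (two subpopulations), so the
    genetic/residual split is identifiable."""
    data = simulate_dataset(SimulationSpec(
        n_samples=60, n_markers=300, n_causal=0, n_subpops=2,
        subpop_fst=0.3, seed=31))
    return kinship_matrix(data.genotype.dosage)


class TestMixedModel:
    def test_noise_trait_gives_small_genetic_fraction(self, structured_K, rng):
        """Per-draw REML estimates are noisy at n=60; the median over draws
        of the genetic fraction must be near zero for an i.i.d. trait."""
        fracs = []
        for _ in range(10):
            vc = fit_null_mlm(rng.normal(size=60), None, structured_K)
            fracs.append(vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2))
        assert np.median(fracs) < 0.3

    def test_vanishing_genetic_variance_scan_equals_glm(self, rng):
        """With sg2 ~ 0 the whitening is isotropic and the scan is the GLM."""
        from polygwas import VarianceComponents
        d = rng.integers(0, 5, size=(60, 50)).astype(float)
        geno = make_genotype(d)
        K = kinship_matrix(d)
        y = rng.normal(size=50)
        vc = VarianceComponents(sigma_g2=1e-12, sigma_e2=1.0, loglik=0.0)
        glm = scan_glm(y, None, geno, ["additive"])[0]
        mlm = scan_mlm(y, None, K, geno, ["additive"], vc=vc)[0]
        np.testing.assert_allclose(mlm.frame["score"], glm.frame["score"], atol=1e-6)

    def test_pure_genetic_trait_boundary_handled(self, structured_K, rng):
        L = np.linalg.cholesky(structured_K + 1e-8 * np.eye(60))
        y = L @ rng.normal(size=60)
        vc = fit_null_mlm(y, None, structured_K)  # se2 -> 0 boundary: no crash
        assert np.isfinite(vc.loglik)
        assert vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2) > 0.5

    def test_identity_kinship_equals_glm(self, rng):
        d = rng.integers(0, 5, size=(60, 50)).astype(float)
        geno = make_genotype(d)
        y = 1.5 * d[7] + rng.normal(size=50)
        glm = scan_glm(y, None, geno, ["additive"])[0]
        mlm = scan_mlm(y, None, np.eye(50), geno, ["additive"])[0]
        np.testing.assert_allclose(mlm.frame["score"], glm.frame["score"], atol=1e-8)

    def test_constant_trait_errors(self):
        with pytest.raises(DataError):
            fit_null_mlm(np.ones(20), None, np.eye(20))


# ---------------------------------------------------------------------------
# thresholds and inflation
# ---------------------------------------------------------------------------

class TestThresholds:
    def test_bonferroni_arithmetic(self):
        assert bonferroni_threshold(0.05, 400) == pytest.approx(
            -np.log10(1.25e-4), abs=1e-12)
        assert bonferroni_threshold(0.05, 1) == pytest.approx(-np.log10(0.05))

    def test_zero_markers_errors(self):
        with pytest.raises(DataError):
            bonferroni_threshold(0.05, 0)

    def test_fdr_flags_follow_benjamini_hochberg(self, rng):
        d = rng.integers(0, 5, size=(60, 120)).astype(float)
        geno = make_genotype(d)
        y = 2.0 * d[3] + 1.5 * d[40] + rng.normal(size=120)
        table = scan_glm(y, None, geno, ["additive"], alpha=0.05,
                         correction="fdr")[0]
        from statsmodels.stats.multitest import multipletests
        expected = multipletests(table.frame["pvalue"], alpha=0.05,
                                 method="fdr_bh")[0]
        np.testing.assert_array_equal(table.frame["significant"], expected)
        # flag/threshold invariant
        f = table.frame
        np.testing.assert_array_equal(f["significant"],
                                      f["score"] >= table.threshold_score)


class TestInflationFactor:
    def test_all_half_is_exactly_one(self):
        assert inflation_factor([0.5] * 20) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_null_near_one(self, rng):
        p = rng.uniform(size=10_000)
        assert inflation_factor(p) == pytest.approx(1.0, abs=0.05)

    def test_squared_pvalues_inflate(self, rng):
        p = rng.uniform(size=2_000)
        assert inflation_factor(p ** 2) > 1.0

    def test_invalid_pvalues_error(self):
        with pytest.raises(DataError):
            inflation_factor([0.0] * 20)
        with pytest.raises(DataError):
            inflation_factor([0.5] * 5)


# ---------------------------------------------------------------------------
# engine presets
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def data():
    return simulate_dataset(SimulationSpec(
        n_samples=70, n_markers=60, n_causal=3, seed=21))


class TestEngines:
    def trait(self, data):
        return data.phenotype.trait_vector("trait", data.genotype.samples)

    def test_poly_naive_runs_additive_and_general(self, data):
        tables = run_engine("poly_naive", data.genotype, self.trait(data),
                            naive_config(test_model="all"))
        assert [t.model for t in tables] == ["additive", "general"]

    def test_dip_a_additive_single_table_on_diploidized_calls(self, data):
        tables = run_engine("dip_a", data.genotype, self.trait(data),
                            naive_config(test_model="additive"))
        assert len(tables) == 1 and tables[0].model == "additive"

    def test_poly_full_all_gives_eight_tables(self, data):
        tables = run_engine("poly_full", data.genotype, self.trait(data),
                            naive_config(test_model="all", gwas_model="full"))
        assert len(tables) == 8

    def test_preset_invariants(self):
        naive_preset = ENGINE_PRESETS["poly_naive"]
        assert not naive_preset.use_structure and not naive_preset.use_kinship
        assert naive_preset.exclude_relatives
        assert set(ENGINE_PRESETS["dip_a"].models) == {"additive", "dominant"}
        assert set(ENGINE_PRESETS["dip_b"].models) == {"general", "additive", "dominant"}
        assert len(ENGINE_PRESETS["poly_full"].models) == 8

    def test_per_model_m_accounting(self, data):
        """Tested + degenerate markers sum to the marker count per model."""
        tables = run_engine("poly_full", data.genotype, self.trait(data),
                            naive_config(test_model="all"))
        for t in tables:
            assert t.m_tested + t.n_degenerate == data.genotype.n_markers

    def test_permuted_phenotype_loses_enrichment(self, data, rng):
        """Permutation destroys the causal signal: best scores drop to null level."""
        y = self.trait(data)
        table = run_engine("poly_full", data.genotype, y,
                           naive_config())[0]
        top_true = table.frame["score"].max()
        perm_tops = []
        for _ in range(20):
            yp = rng.permutation(y)
            tp = run_engine("poly_full", data.genotype, yp, naive_config())[0]
            perm_tops.append(tp.frame["score"].max())
        assert top_true > np.quantile(perm_tops, 0.9)
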