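"""Quality-control filters and the exact Hardy-Weinberg tests."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest

from polygwas import (DataError, FilterSettings, allele_frequency, apply_qc,
                      filter_geno, filter_hwe, filter_maf, filter_mind,
                      hwe_exact_pvalue, hwe_test_tetraploid, intersect_samples)

from conftest import make_genotype, make_phenotype


# ---------------------------------------------------------------------------
# sample intersection & allele frequency
# ---------------------------------------------------------------------------

class TestIntersectSamples:
    def test_common_subset_in_genotype_order(self):
        geno = make_genotype(np.zeros((2, 3)), samples=["a", "b", "c"])
        pheno = make_phenotype([1, 2, 3], samples=["b", "c", "d"])
        g2, p2 = intersect_samples(geno, pheno)
        assert g2.samples == ["b", "c"] == p2.samples

    def test_identical_sets_unchanged(self):
        geno = make_genotype(np.zeros((2, 3)))
        pheno = make_phenotype([1, 2, 3])
        g2, p2 = intersect_samples(geno, pheno)
        assert g2.samples == geno.samples

    def test_disjoint_sets_error(self):
        geno = make_genotype(np.zeros((2, 2)), samples=["a", "b"])
        pheno = make_phenotype([1.0], samples=["z"])
        with pytest.raises(DataError):
            intersect_samples(geno, pheno)


@pytest.mark.parametrize("dosages,ploidy,expected", [
    ([0, 1, 2], 4, 0.25),
    ([4, 4, 4], 4, 1.0),
    ([1, 1], 2, 0.5),
    ([0, np.nan, 2], 4, 0.25),  # missing ignored
])
def test_allele_frequency(dosages, ploidy, expected):
    assert allele_frequency(np.array(dosages, float), ploidy) == pytest.approx(expected)


def test_allele_frequency_all_missing_errors():
    with pytest.raises(DataError):
        allele_frequency(np.array([np.nan, np.nan]), 4)


# ---------------------------------------------------------------------------
# marker/sample filters: strict boundary semantics
# ---------------------------------------------------------------------------

class TestThresholdFilters:
    def test_maf_below_removed_at_boundary_retained(self):
        # 25 samples: one ALT allele in 100 -> MAF 0.01 exactly; second marker
        # has MAF 0.005 in 10 samples of 40 alleles? use 0.5/100 via nan trick
        m1 = np.zeros(25); m1[0] = 1          # freq 1/100 = 0.01
        m2 = np.zeros(25)                     # monomorphic, MAF 0
        geno = make_genotype(np.vstack([m1, m2]))
        kept, removed = filter_maf(geno, 0.01)
        assert removed == ["m2"]
        assert list(kept.markers["marker"]) == ["m1"]

    def test_mind_exceeding_removed_boundary_retained(self):
        dosage = np.zeros((10, 3))
        dosage[0, 0] = np.nan                  # s1 missing 10% exactly
        dosage[0:2, 1] = np.nan                # s2 missing 20%
        geno = make_genotype(dosage)
        kept, removed = filter_mind(geno, 0.1)
        assert removed == ["s2"]
        assert kept.samples == ["s1", "s3"]

    def test_geno_mirrors_mind_on_markers(self):
        dosage = np.zeros((3, 10))
        dosage[0, 0] = np.nan                  # m1: 10% exactly -> retained
        dosage[1, :3] = np.nan                 # m2: 30% -> removed
        geno = make_genotype(dosage)
        kept, removed = filter_geno(geno, 0.1)
        assert removed == ["m2"]
        assert list(kept.markers["marker"]) == ["m1", "m3"]

    def test_fully_typed_sample_always_retained(self):
        geno = make_genotype(np.ones((4, 2)))
        kept, removed = filter_mind(geno, 0.0)
        assert removed == []


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def oracle_hwe_pvalue(counts, ploidy=4):
    """Independent oracle: enumerate every dosage assignment outcome.

    Probabilities come straight from the multinomial with HWE class
    probabilities at the conditional allele frequency; the tail sums all
    count configurations with the same sample size and ALT-allele total
    that are no more probable than the observed one.
    """
    counts = np.asarray(counts, int)
    n = counts.sum()
    alt = int((counts * np.arange(ploidy + 1)).sum())
    p = alt / (ploidy * n)
    if p in (0.0, 1.0):
        return 1.0
    class_probs = np.array([comb(ploidy, k) * p**k * (1 - p)**(ploidy - k)
                            for k in range(ploidy + 1)])

    def multinomial_prob(cfg):
        prob = 1.0
        total = n
        coef = 1.0
        for k, c in enumerate(cfg):
            coef *= comb(total, c)
            total -= c
            prob *= class_probs[k] ** c
        return coef * prob

    configs = [cfg for cfg in itertools.product(range(n + 1), repeat=ploidy + 1)
               if sum(cfg) == n
               and sum(k * c for k, c in enumerate(cfg)) == alt]
    probs = np.array([multinomial_prob(c) for c in configs])
    probs = probs / probs.sum()
    obs = probs[configs.index(tuple(counts))]
    return float(probs[probs <= obs + 1e-12].sum())


class TestHWEExact:
    def test_monomorphic_p_is_one(self):
        assert hwe_test_tetraploid([7, 0, 0, 0, 0]) == 1.0
        assert hwe_test_tetraploid([0, 0, 0, 0, 3]) == 1.0

    def test_small_fixture_matches_enumeration(self):
        counts = [2, 0, 2, 0, 0]
        assert hwe_test_tetraploid(counts) == pytest.approx(
            oracle_hwe_pvalue(counts), abs=1e-12)

    @pytest.mark.parametrize("ploidy", [2, 4])
    def test_all_configurations_match_oracle_up_to_n6(self, ploidy):
        for n in range(1, 7):
            for cfg in itertools.product(range(n + 1), repeat=ploidy + 1):
                if sum(cfg) != n:
                    continue
                got = hwe_exact_pvalue(cfg, ploidy)
                want = oracle_hwe_pvalue(cfg, ploidy)
                assert got == pytest.approx(want, abs=1e-10), cfg

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            hwe_test_tetraploid([3, -1, 0, 0, 0])

    def test_null_calibration(self, rng):
        """Under tetraploid HWE the rejection rate at alpha=0.05 sits inside
        the binomial 99% CI (n=200 individuals, p=0.3, 2000 draws)."""
        from scipy.stats import binom

        reps, alpha = 2000, 0.05
        hits = 0
        for _ in range(reps):
            d = rng.binomial(4, 0.3, size=200)
            counts = np.bincount(d, minlength=5)
            hits += hwe_exact_pvalue(counts, 4) < alpha
        lo, hi = binom.ppf([0.005, 0.995], reps, alpha)
        assert lo <= hits <= hi


class TestFilterHWE:
    def test_threshold_behavior(self, rng):
        # m1 drawn from HWE; m2 grossly out of equilibrium (only extremes)
        hwe_marker = rng.binomial(4, 0.5, size=60).astype(float)
        skewed = np.array([0.0] * 30 + [4.0] * 30)
        geno = make_genotype(np.vstack([hwe_marker, skewed]))
        kept, removed = filter_hwe(geno, 0.05)
        assert removed == ["m2"]

    def test_disabled_filter_removes_nothing(self):
        geno = make_genotype(np.array([[0.0] * 5 + [4.0] * 5]))
        kept, removed = filter_hwe(geno, 0.0)  # p-value < 0 impossible
        assert removed == []


# ---------------------------------------------------------------------------
# full QC pass
# ---------------------------------------------------------------------------

class TestApplyQC:
    def build(self):
        # marker m3 is low-MAF (1/(4*25)); sample s1 misses 2 of 4 markers
        rngl = np.random.default_rng(7)
        base = rngl.binomial(4, 0.5, size=(4, 25)).astype(float)
        base[3] = 0.0
        base[3, 1] = 1.0  # MAF just at 0.01 after MIND -> retained at default
        base[2] = 0.0
        base[2, 1] = 0.0  # monomorphic -> MAF 0, removed
        base[0, 0] = np.nan
        base[1, 0] = np.nan  # s1 misses 50% -> removed by MIND
        return make_genotype(base)

    def test_constructed_removals_accounted(self):
        geno = self.build()
        pheno = make_phenotype(np.arange(25, dtype=float))
        out_geno, out_pheno, report = apply_qc(geno, pheno, FilterSettings())
        assert report.removed_samples["mind"] == ["s1"]
        assert report.removed_markers["maf"] == ["m3"]
        assert report.n_samples_before == report.n_samples_after + report.n_samples_removed
        assert report.n_markers_before == report.n_markers_after + report.n_markers_removed
        assert out_pheno.samples == out_geno.samples

    def test_all_filters_disabled_identity(self):
        geno = self.build()
        pheno = make_phenotype(np.arange(25, dtype=float))
        off = FilterSettings(maf=None, mind=None, geno=None, hwe=None)
        out_geno, _, report = apply_qc(geno, pheno, off)
        np.testing.assert_array_equal(out_geno.dosage, geno.dosage)
        assert report.n_markers_removed == 0 and report.n_samples_removed == 0

    def test_maf_evaluated_after_mind(self):
        """Removing a gappy sample flips a marker across the MAF boundary."""
        # 6 samples; s6 misses half the markers and carries m1's only ALT copies
        dosage = np.array([
            [0, 0, 0, 0, 0, 2],      # ALT only in s6
            [1, 2, 1, 2, 1, np.nan],
            [2, 1, 2, 1, 2, np.nan],
            [1, 1, 2, 2, 1, np.nan],
        ], dtype=float)
        geno = make_genotype(dosage)
        pheno = make_phenotype(np.arange(6, dtype=float))
        filters = FilterSettings(maf=0.05, mind=0.5, geno=1.0, hwe=None)
        _, _, report = apply_qc(geno, pheno, filters)
        # s6 missing 3/4 markers -> removed; m1 then monomorphic -> MAF removal
        assert report.removed_samples["mind"] == ["s6"]
        assert "m1" in report.removed_markers["maf"]

    def test_idempotent_at_fixed_thresholds(self):
        geno = self.build()
        pheno = make_phenotype(np.arange(25, dtype=float))
        g1, p1, _ = apply_qc(geno, pheno, FilterSettings())
        g2, _, report2 = apply_qc(g1, p1, FilterSettings())
        assert report2.n_markers_removed == 0
        assert report2.n_samples_removed == 0
        np.testing.assert_array_equal(g1.dosage, g2.dosage)

    def test_everything_removed_is_an_error(self):
        geno = make_genotype(np.zeros((2, 5)))  # all monomorphic
        pheno = make_phenotype(np.arange(5, dtype=float))
        with pytest.raises(DataError, match="relax"):
            apply_qc(geno, pheno, FilterSettings(maf=0.01))
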