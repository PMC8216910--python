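"""Quality control: sample intersection and the MAF / MIND / GENO / HWE filters.

Filters run in a fixed order — intersect samples, then MIND (sample
missingness), GENO (marker missingness), MAF (minor allele frequency)
and HWE (Hardy-Weinberg exact test) — with rates recomputed after each
step, so a marker's MAF is evaluated on the samples that survived MIND.

The Hardy-Weinberg test is an exact conditional multinomial test.  Under
autotetraploid (polysomic) equilibrium the dosage classes follow
``P(dosage=k) = C(4,k) p^k (1-p)^(4-k)``; the test conditions on the
observed sample size and total ALT-allele count and sums the conditional
probabilities of every dosage-class configuration no more probable than
the observed one.  For diploids the same machinery reduces to the
classical 3-class exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .exceptions import DataError
from .io import FilterSettings, GenotypeMatrix, PhenotypeTable

__all__ = [
    "QCReport", "intersect_samples", "allele_frequency", "marker_allele_frequencies",
    "filter_maf", "filter_mind", "filter_geno", "hwe_exact_pvalue",
    "hwe_test_tetraploid", "filter_hwe", "apply_qc",
]


@dataclass
class QCReport:
    """Accounting of what quality control removed.

    Conservation invariant: before = after + removed on both axes.
    """

    n_samples_before: int = 0
    n_samples_after: int = 0
    n_markers_before: int = 0
    n_markers_after: int = 0
    removed_samples: dict[str, list[str]] = field(default_factory=dict)
    removed_markers: dict[str, list[str]] = field(default_factory=dict)
    allele_freq: pd.Series | None = None  # ALT frequency per retained marker

    @property
    def n_samples_removed(self) -> int:
        return sum(len(v) for v in self.removed_samples.values())

    @property
    def n_markers_removed(self) -> int:
        return sum(len(v) for v in self.removed_markers.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("samples", "before", self.n_samples_before),
                ("samples", "after", self.n_samples_after)]
        rows += [("samples", f"removed_{k}", len(v))
                 for k, v in self.removed_samples.items()]
        rows += [("markers", "before", self.n_markers_before),
                 ("markers", "after", self.n_markers_after)]
        rows += [("markers", f"removed_{k}", len(v))
                 for k, v in self.removed_markers.items()]
        return pd.DataFrame(rows, columns=["axis", "stage", "count"])


def intersect_samples(geno: GenotypeMatrix, pheno: PhenotypeTable
                      ) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Restrict both datasets to the common samples, in genotype order."""
    common = [s for s in geno.samples if s in set(pheno.samples)]
    if not common:
        raise DataError("genotype and phenotype share no samples")
    if common == geno.samples and set(pheno.samples) == set(common):
        return geno, pheno.subset_samples(common)
    return geno.subset_samples(common), pheno.subset_samples(common)


def allele_frequency(dosages: np.ndarray, ploidy: int) -> float:
    """ALT allele frequency of one marker (missing dosages ignored)."""
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    if not ok.any():
        raise DataError("all dosages missing; allele frequency undefined")
    return float(d[ok].sum() / (ploidy * ok.sum()))


def marker_allele_frequencies(geno: GenotypeMatrix) -> pd.Series:
    """ALT frequency per marker; NaN where every call is missing."""
    d = geno.dosage
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nansum(d, axis=1) / (geno.ploidy * np.sum(~np.isnan(d), axis=1))
    return pd.Series(freq, index=geno.marker_ids, name="alt_freq")


def filter_maf(geno: GenotypeMatrix, x: float) -> tuple[GenotypeMatrix, list[str]]:
    """Remove markers with minor allele frequency strictly below ``x``."""
    freq = marker_allele_frequencies(geno).to_numpy()
    maf = np.minimum(freq, 1.0 - freq)
    keep = ~(maf < x)  # NaN-frequency markers (all calls missing) fall to GENO
    removed = geno.markers.loc[~keep, "marker"].tolist()
    return geno.subset_markers(keep), removed


def filter_mind(geno: GenotypeMatrix, x: float) -> tuple[GenotypeMatrix, list[str]]:
    """Remove samples whose missing-genotype rate strictly exceeds ``x``."""
    miss = np.isnan(geno.dosage).mean(axis=0)
    keep = miss <= x
    removed = [s for s, k in zip(geno.samples, keep) if not k]
    kept = [s for s, k in zip(geno.samples, keep) if k]
    if not kept:
        raise DataError("MIND filter removed every sample; relax the threshold")
    return geno.subset_samples(kept), removed


def filter_geno(geno: GenotypeMatrix, x: float) -> tuple[GenotypeMatrix, list[str]]:
    """Remove markers whose missing-call rate strictly exceeds ``x``."""
    miss = np.isnan(geno.dosage).mean(axis=1)
    keep = miss <= x
    removed = geno.markers.loc[~keep, "marker"].tolist()
    return geno.subset_markers(keep), removed


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _hwe_configs(n: int, alt_total: int, ploidy: int) -> np.ndarray:
    """All dosage-class count vectors with ``n`` individuals and ``alt_total`` ALT alleles.

    Returns an int array of shape (n_configs, ploidy+1); column k is the
    count of individuals with dosage k.
    """
    rows: list[tuple[int, ...]] = []

    def rec(k: int, remaining_alt: int, remaining_n: int, acc: list[int]) -> None:
        if k == 1:
            c1 = remaining_alt
            if c1 <= remaining_n:
                c0 = remaining_n - c1
                rows.append((c0, c1, *reversed(acc)))
            return
        for ck in range(min(remaining_n, remaining_alt // k) + 1):
            acc.append(ck)
            rec(k - 1, remaining_alt - k * ck, remaining_n - ck, acc)
            acc.pop()

    rec(ploidy, alt_total, n, [])
    return np.array(rows, dtype=np.int64)


@lru_cache(maxsize=4096)
def _hwe_config_logprobs(n: int, alt_total: int, ploidy: int) -> tuple[np.ndarray, np.ndarray]:
    """Configurations and their log conditional probabilities under HWE.

    The multinomial class probabilities are C(ploidy,k) p^k q^(ploidy-k);
    conditioned on the total ALT count the p/q terms are constant across
    configurations and cancel, leaving the multinomial coefficient plus
    the binomial-coefficient weights.
    """
    configs = _hwe_configs(n, alt_total, ploidy)
    k = np.arange(ploidy + 1)
    log_binom = gammaln(ploidy + 1) - gammaln(k + 1) - gammaln(ploidy - k + 1)
    logp = (gammaln(n + 1) - gammaln(configs + 1).sum(axis=1)
            + configs @ log_binom)
    logp = logp - logsumexp(logp)
    return configs, logp


def hwe_exact_pvalue(counts, ploidy: int = 4) -> float:
    """Exact Hardy-Weinberg p-value from dosage-class counts.

    Parameters
    ----------
    counts : sequence of int, length ploidy+1
        ``counts[k]`` = number of individuals with ALT dosage k.

    Returns the probability, conditional on the sample size and total
    ALT-allele count, of observing a dosage-class configuration no more
    probable than the observed one.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (ploidy + 1,):
        raise ValueError(f"expected {ploidy + 1} dosage-class counts, got {counts.shape}")
    if (counts < 0).any():
        raise ValueError("negative dosage-class counts")
    n = int(counts.sum())
    if n < 1:
        raise ValueError("at least one individual required")
    alt_total = int((counts * np.arange(ploidy + 1)).sum())
    if alt_total == 0 or alt_total == ploidy * n:
        return 1.0  # monomorphic: the observed configuration is the only one
    configs, logp = _hwe_config_logprobs(n, alt_total, ploidy)
    obs = np.flatnonzero((configs == counts).all(axis=1))
    obs_logp = logp[obs[0]]
    tail = logp <= obs_logp + 1e-9  # include probability ties
    return float(min(1.0, np.exp(logsumexp(logp[tail]))))


def hwe_test_tetraploid(counts) -> float:
    """Exact autotetraploid Hardy-Weinberg test on dosage-class counts 0..4."""
    return hwe_exact_pvalue(counts, ploidy=4)


def filter_hwe(geno: GenotypeMatrix, x: float) -> tuple[GenotypeMatrix, list[str]]:
    """Remove markers whose HWE exact-test p-value is strictly below ``x``."""
    keep = np.ones(geno.n_markers, dtype=bool)
    for i in range(geno.n_markers):
        d = geno.dosage[i]
        ok = ~np.isnan(d)
        if not ok.any():
            continue
        counts = np.bincount(d[ok].astype(int), minlength=geno.ploidy + 1)
        if hwe_exact_pvalue(counts, geno.ploidy) < x:
            keep[i] = False
    removed = geno.markers.loc[~keep, "marker"].tolist()
    return geno.subset_markers(keep), removed


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def apply_qc(geno: GenotypeMatrix, pheno: PhenotypeTable,
             filters: FilterSettings | None = None
             ) -> tuple[GenotypeMatrix, PhenotypeTable, QCReport]:
    """Intersect samples and apply MIND -> GENO -> MAF -> HWE in order."""
    filters = filters or FilterSettings()
    report = QCReport(
        n_samples_before=geno.n_samples,
        n_markers_before=geno.n_markers,
    )
    before_samples = list(geno.samples)
    geno, pheno = intersect_samples(geno, pheno)
    dropped = sorted(set(before_samples) - set(geno.samples))
    if dropped:
        report.removed_samples["not_in_phenotype"] = dropped
    if filters.mind is not None:
        geno, removed = filter_mind(geno, filters.mind)
        report.removed_samples["mind"] = removed
        pheno = pheno.subset_samples(geno.samples)
    if filters.geno is not None:
        geno, removed = filter_geno(geno, filters.geno)
        report.removed_markers["geno"] = removed
    if filters.maf is not None:
        geno, removed = filter_maf(geno, filters.maf)
        report.removed_markers["maf"] = removed
    if filters.hwe is not None:
        geno, removed = filter_hwe(geno, filters.hwe)
        report.removed_markers["hwe"] = removed
    if geno.n_markers == 0:
        raise DataError("quality control removed every marker; relax the thresholds")
    report.n_samples_after = geno.n_samples
    report.n_markers_after = geno.n_markers
    report.allele_freq = marker_allele_frequencies(geno)
    return geno, pheno, report
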