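"""Association scans: kinship, structure, naive GLM and full Q+K mixed model.

The trait model is ``y = Xb + Sa + Qv + Zu + e``: fixed covariates, the
tested marker's gene-action encoding, population-structure covariates
(principal components of the dosage matrix) and a polygenic random
effect ``u ~ N(0, sg2 * K)`` with K the realized-relationship (kinship)
matrix.  The naive scan drops Q and the polygene and reduces to ordinary
least squares; the full scan estimates the variance components once
under the null by REML (EMMA-style spectral decomposition, one
1-D optimization over the variance ratio) and then tests every marker by
generalized least squares with that covariance fixed (P3D/EMMAX).

Four engine presets mirror the behavior of the four GWAS programs the
consensus framework emulates: a polyploid mixed-model engine with the
eight tetraploid gene-action models, a polyploid naive engine that
instead excludes cryptic first-degree relatives, and two diploidized
engines with additive/dominant (and general) codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, eigh
from statsmodels.stats.multitest import multipletests

from .encoding import DIPLOID_MODELS, TETRAPLOID_MODELS, design_matrix, diploidize
from .exceptions import DataError
from .io import GenotypeMatrix, RunConfig

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationTable", "VarianceComponents", "EngineConfig", "ENGINE_PRESETS",
    "kinship_matrix", "principal_components", "exclude_first_degree",
    "scan_glm", "fit_null_mlm", "scan_mlm", "bonferroni_threshold",
    "inflation_factor", "run_engine",
]

#: median of the chi-square(1) distribution, the genomic-control reference
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

_P_FLOOR = 1e-300  # keep p strictly inside (0, 1]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AssociationTable:
    """Per-marker association results for one engine x gene-action model."""

    engine: str
    model: str
    frame: pd.DataFrame  # marker, chrom, pos, pvalue, score, threshold, significant
    m_tested: int
    n_degenerate: int
    lambda_gc: float
    threshold_score: float

    def best_ranked(self, n: int) -> list[str]:
        """The n markers with lowest p (ties broken lexicographically)."""
        if n < 1:
            raise DataError("n_best must be >= 1")
        f = self.frame.dropna(subset=["pvalue"])
        f = f.sort_values(["pvalue", "marker"], kind="mergesort")
        return f["marker"].head(n).tolist()

    def significant_markers(self) -> list[str]:
        f = self.frame
        return f.loc[f["significant"].fillna(False), "marker"].tolist()

    def to_output_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(3, "model", self.model)
        return out[["marker", "chrom", "pos", "model", "pvalue", "score",
                    "threshold", "significant"]]


@dataclass
class VarianceComponents:
    """REML variance components of the null polygenic model."""

    sigma_g2: float
    sigma_e2: float
    loglik: float

    @property
    def delta(self) -> float:
        """Residual-to-genetic variance ratio sigma_e2 / sigma_g2."""
        return self.sigma_e2 / self.sigma_g2 if self.sigma_g2 > 0 else np.inf


@dataclass
class EngineConfig:
    """One engine preset of the multi-analysis stage."""

    name: str
    ploidy_mode: str  # "tetraploid" or "diploidized"
    models: tuple[str, ...]
    use_structure: bool
    use_kinship: bool
    exclude_relatives: bool
    n_pcs: int = 5


ENGINE_PRESETS: dict[str, EngineConfig] = {
    # polyploid mixed-model engine: all eight tetraploid gene-action models
    "poly_full": EngineConfig(
        name="poly_full", ploidy_mode="tetraploid", models=TETRAPLOID_MODELS,
        use_structure=True, use_kinship=True, exclude_relatives=False),
    # polyploid naive engine: no structure/kinship, removes close relatives
    "poly_naive": EngineConfig(
        name="poly_naive", ploidy_mode="tetraploid", models=("additive", "general"),
        use_structure=False, use_kinship=False, exclude_relatives=True),
    # diploidized engine with additive/dominant recodes
    "dip_a": EngineConfig(
        name="dip_a", ploidy_mode="diploidized", models=("additive", "dominant"),
        use_structure=True, use_kinship=True, exclude_relatives=False),
    # diploidized engine with general/additive/dominant models
    "dip_b": EngineConfig(
        name="dip_b", ploidy_mode="diploidized", models=DIPLOID_MODELS,
        use_structure=True, use_kinship=True, exclude_relatives=False),
}


# ---------------------------------------------------------------------------
# kinship, structure, relatedness
# ---------------------------------------------------------------------------

def _standardized_marker_matrix(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages, center and scale each marker row.

    Monomorphic markers (zero variance) are dropped.  Used for kinship
    and principal components only; scans keep missingness explicit.
    """
    Z = np.array(dosages, dtype=float)
    means = np.nanmean(Z, axis=1)
    nan_idx = np.where(np.isnan(Z))
    Z[nan_idx] = np.take(means, nan_idx[0])
    Z -= means[:, None]
    sd = Z.std(axis=1)
    keep = sd > 0
    return Z[keep] / sd[keep, None]


def kinship_matrix(dosages: np.ndarray) -> np.ndarray:
    """Realized-relationship matrix K = Z' Z / m from standardized dosages.

    ``dosages`` is markers x samples; missing values are mean-imputed per
    marker for this computation only, monomorphic markers are skipped.
    """
    Z = _standardized_marker_matrix(dosages)
    if Z.shape[0] < 2:
        raise DataError("kinship needs at least 2 polymorphic markers")
    return (Z.T @ Z) / Z.shape[0]


def principal_components(dosages: np.ndarray, n: int = 5) -> np.ndarray:
    """Top-n principal components of the centered dosage matrix (samples x n).

    Deterministic sign convention: within each component the marker
    loading of largest magnitude is made positive.  ``n = 0`` returns an
    empty covariate block (naive fallback).
    """
    n_samples = dosages.shape[1]
    if n >= n_samples:
        raise DataError(f"n_pcs={n} must be < n_samples={n_samples}")
    if n == 0:
        return np.empty((n_samples, 0))
    Z = _standardized_marker_matrix(dosages)  # markers x samples
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    n = min(n, s.size)
    scores = Vt[:n].T * s[:n]  # samples x n
    for j in range(n):
        lead = np.argmax(np.abs(U[:, j]))
        if U[lead, j] < 0:
            scores[:, j] *= -1
    return scores


def exclude_first_degree(K: np.ndarray, sample_ids: list[str],
                         threshold: float = 0.5,
                         missing_counts: np.ndarray | None = None) -> list[str]:
    """Greedily drop samples until no standardized kinship exceeds ``threshold``.

    K is standardized by its mean diagonal so that self-relatedness is
    ~1 and first-degree pairs sit near 0.5.  While any off-diagonal entry
    exceeds the threshold, the sample with the most such ties is removed
    (ties: more missing data first, then lexicographically smaller id).
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    Ks = K / np.mean(np.diag(K))
    if missing_counts is None:
        missing_counts = np.zeros(n)
    active = list(range(n))
    while True:
        sub = Ks[np.ix_(active, active)].copy()
        np.fill_diagonal(sub, 0.0)
        ties = (sub > threshold).sum(axis=1)
        if ties.max(initial=0) == 0:
            break
        order = sorted(
            range(len(active)),
            key=lambda i: (-ties[i], -missing_counts[active[i]], sample_ids[active[i]]),
        )
        if len(active) == 1:
            raise DataError("relatedness threshold would remove every sample")
        active.pop(order[0])
        if not active:
            raise DataError("relatedness threshold removed every sample")
    return [sample_ids[i] for i in active]


# ---------------------------------------------------------------------------
# test machinery
# ---------------------------------------------------------------------------

def _partial_f_pvalue(y: np.ndarray, X0: np.ndarray, X1: np.ndarray) -> float:
    """Partial F-test p-value for adding block X1 to the design X0."""
    n = y.shape[0]
    full = np.hstack([X0, X1])
    beta0, rss0_arr, rank0, _ = np.linalg.lstsq(X0, y, rcond=None)
    beta1, rss1_arr, rank1, _ = np.linalg.lstsq(full, y, rcond=None)
    rss0 = float(rss0_arr[0]) if rss0_arr.size else float(np.sum((y - X0 @ beta0) ** 2))
    rss1 = float(rss1_arr[0]) if rss1_arr.size else float(np.sum((y - full @ beta1) ** 2))
    q = rank1 - rank0
    df = n - rank1
    if q < 1 or df < 1:
        return np.nan
    if rss1 <= 0:
        return _P_FLOOR
    fstat = max(0.0, (rss0 - rss1) / q) / (rss1 / df)
    return float(max(_P_FLOOR, stats.f.sf(fstat, q, df)))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide threshold score -log10(alpha / m)."""
    if m < 1:
        raise DataError("no testable markers (m = 0)")
    return float(-np.log10(alpha / m))


def inflation_factor(p_values) -> float:
    """Genomic-control inflation factor.

    lambda = median of the chi-square(1) quantiles of (1 - p), divided by
    the chi-square(1) median 0.4549364.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 10:
        raise DataError("inflation factor needs at least 10 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def _significance_cutoff(pvals: np.ndarray, alpha: float, correction: str,
                         m: int) -> float:
    """P-value cutoff whose -log10 is the report's red line.

    Bonferroni: alpha/m.  FDR: the largest Benjamini-Hochberg-rejected
    p-value (when nothing is rejected, min(p) > alpha/m by the step-up
    definition, so alpha/m keeps the flag/threshold invariant intact).
    """
    if correction == "bonferroni":
        return alpha / m
    ok = ~np.isnan(pvals)
    reject = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")[0]
    if reject.any():
        return float(np.max(pvals[ok][reject]))
    return alpha / m


def _assemble_table(engine: str, model: str, geno: GenotypeMatrix,
                    pvals: np.ndarray, tested: np.ndarray,
                    alpha: float, correction: str) -> AssociationTable:
    m_tested = int(tested.sum())
    if m_tested < 1:
        raise DataError(f"model '{model}': no testable markers")
    cutoff = _significance_cutoff(pvals, alpha, correction, m_tested)
    threshold = float(-np.log10(cutoff))
    score = np.where(np.isnan(pvals), np.nan, -np.log10(np.clip(pvals, _P_FLOOR, 1.0)))
    sig = np.where(np.isnan(score), False, score >= threshold)
    frame = pd.DataFrame({
        "marker": geno.markers["marker"].to_numpy(),
        "chrom": geno.markers["chrom"].to_numpy(),
        "pos": geno.markers["pos"].to_numpy(),
        "pvalue": pvals,
        "score": score,
        "threshold": threshold,
        "significant": sig,
    }).loc[tested].reset_index(drop=True)
    lam = inflation_factor(frame["pvalue"]) if frame["pvalue"].notna().sum() >= 10 else np.nan
    return AssociationTable(
        engine=engine, model=model, frame=frame,
        m_tested=m_tested, n_degenerate=int((~tested).sum()),
        lambda_gc=lam, threshold_score=threshold,
    )


def scan_glm(y: np.ndarray, covariates: np.ndarray | None, geno: GenotypeMatrix,
             models, alpha: float = 0.05, correction: str = "bonferroni",
             engine: str = "glm") -> list[AssociationTable]:
    """Naive scan: ordinary least squares of y on [1 | covariates | marker].

    Samples with a missing phenotype, covariate or dosage are dropped per
    marker; the marker block's partial F-test gives the p-value.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    base = np.hstack([np.ones((n, 1)), C])
    base_ok = np.isfinite(y) & np.all(np.isfinite(base), axis=1)
    tables = []
    for model in models:
        pvals = np.full(geno.n_markers, np.nan)
        tested = np.zeros(geno.n_markers, dtype=bool)
        for i in range(geno.n_markers):
            X1, degenerate = design_matrix(geno.dosage[i], model, geno.ploidy)
            if degenerate:
                continue
            tested[i] = True
            mask = base_ok & np.all(np.isfinite(X1), axis=1)
            if mask.sum() < base.shape[1] + X1.shape[1] + 3:
                pvals[i] = np.nan
                continue
            pvals[i] = _partial_f_pvalue(y[mask], base[mask], X1[mask])
        tables.append(_assemble_table(engine, model, geno, pvals, tested,
                                      alpha, correction))
    return tables


# ---------------------------------------------------------------------------
# mixed model (EMMA-style REML + P3D scan)
# ---------------------------------------------------------------------------

def _reml_neg_loglik(log_delta: float, s: np.ndarray, Uty: np.ndarray,
                     UtW: np.ndarray, logdet_WtW: float) -> float:
    delta = np.exp(log_delta)
    w = s + delta
    n, q = UtW.shape
    Winv = UtW / w[:, None]
    A = UtW.T @ Winv
    try:
        c = cho_factor(A)
    except np.linalg.LinAlgError:
        return np.inf
    beta = cho_solve(c, Winv.T @ Uty)
    r = Uty - UtW @ beta
    rss = float(r @ (r / w))
    if rss <= 0:
        return np.inf
    df = n - q
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (df * (np.log(2 * np.pi * rss / df) + 1)
                 + np.sum(np.log(w)) + logdet_A - logdet_WtW)
    return -ll


def fit_null_mlm(y: np.ndarray, covariates: np.ndarray | None, K: np.ndarray
                 ) -> VarianceComponents:
    """REML fit of y = Wb + u + e with u ~ N(0, sg2 K), e ~ N(0, se2 I).

    Spectral decomposition of K turns the profiled REML likelihood into a
    1-D function of the variance ratio delta = se2/sg2, optimized on a
    log grid refined by bounded scalar minimization.  Deterministic.
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if covariates is not None:
        ok &= np.all(np.isfinite(covariates), axis=1)
    y = y[ok]
    n = y.shape[0]
    if np.std(y) == 0:
        raise DataError("phenotype is constant; variance components undefined")
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)[ok]
    W = np.hstack([np.ones((n, 1)), C])
    Ksub = np.asarray(K, dtype=float)[np.ix_(ok, ok)]
    s, U = eigh(Ksub)
    s = np.clip(s, 0.0, None)
    Uty, UtW = U.T @ y, U.T @ W
    sign, logdet_WtW = np.linalg.slogdet(W.T @ W)
    grid = np.linspace(np.log(1e-6), np.log(1e6), 50)
    vals = [_reml_neg_loglik(g, s, Uty, UtW, logdet_WtW) for g in grid]
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), method="bounded",
        args=(s, Uty, UtW, logdet_WtW))
    log_delta = res.x if np.isfinite(res.fun) else grid[best]
    neg_ll = _reml_neg_loglik(log_delta, s, Uty, UtW, logdet_WtW)
    if not np.isfinite(neg_ll):
        raise DataError("non-finite REML likelihood")
    delta = float(np.exp(log_delta))
    w = s + delta
    Winv = UtW / w[:, None]
    A = UtW.T @ Winv
    beta = np.linalg.solve(A, Winv.T @ Uty)
    r = Uty - UtW @ beta
    df = n - W.shape[1]
    sigma_g2 = float(r @ (r / w)) / df
    return VarianceComponents(sigma_g2=sigma_g2, sigma_e2=sigma_g2 * delta,
                              loglik=float(-neg_ll))


def scan_mlm(y: np.ndarray, covariates: np.ndarray | None, K: np.ndarray,
             geno: GenotypeMatrix, models, alpha: float = 0.05,
             correction: str = "bonferroni", engine: str = "mlm",
             vc: VarianceComponents | None = None) -> list[AssociationTable]:
    """Full Q+K scan with variance components fixed from the null fit (P3D).

    The null covariance ``sg2 K + se2 I`` whitens the phenotype, the
    covariates and each marker's encoding; the marker block is then
    tested with a partial F (Wald) statistic on the whitened system.
    Markers with missing dosages are tested on the sample subset with a
    covariance recomputed on that subset.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    base = np.hstack([np.ones((n, 1)), C])
    base_ok = np.isfinite(y) & np.all(np.isfinite(base), axis=1)
    if vc is None:
        vc = fit_null_mlm(y, C if C.shape[1] else None, K)
    K = np.asarray(K, dtype=float)
    # whitening transform for the full (base_ok) sample set
    idx_full = np.flatnonzero(base_ok)
    V = vc.sigma_g2 * K[np.ix_(idx_full, idx_full)]
    V[np.diag_indices_from(V)] += vc.sigma_e2 + 1e-12 * (vc.sigma_g2 + vc.sigma_e2)
    s, U = eigh(V)
    s = np.clip(s, 1e-12 * s.max(), None)
    M_full = U / np.sqrt(s)  # whitener: M'x, since V^-1 = M M'
    y_full = M_full.T @ y[idx_full]
    base_full = M_full.T @ base[idx_full]

    tables = []
    for model in models:
        pvals = np.full(geno.n_markers, np.nan)
        tested = np.zeros(geno.n_markers, dtype=bool)
        for i in range(geno.n_markers):
            X1, degenerate = design_matrix(geno.dosage[i], model, geno.ploidy)
            if degenerate:
                continue
            tested[i] = True
            marker_ok = np.all(np.isfinite(X1), axis=1)
            if np.all(marker_ok[idx_full]):
                pvals[i] = _partial_f_pvalue(y_full, base_full, M_full.T @ X1[idx_full])
                continue
            idx = np.flatnonzero(base_ok & marker_ok)
            if idx.size < base.shape[1] + X1.shape[1] + 3:
                continue
            Vs = vc.sigma_g2 * K[np.ix_(idx, idx)]
            Vs[np.diag_indices_from(Vs)] += vc.sigma_e2 + 1e-12 * (vc.sigma_g2 + vc.sigma_e2)
            ss, Us = eigh(Vs)
            ss = np.clip(ss, 1e-12 * ss.max(), None)
            Ms = Us / np.sqrt(ss)
            pvals[i] = _partial_f_pvalue(Ms.T @ y[idx], Ms.T @ base[idx],
                                         Ms.T @ X1[idx])
        tables.append(_assemble_table(engine, model, geno, pvals, tested,
                                      alpha, correction))
    return tables


# ---------------------------------------------------------------------------
# engine dispatch
# ---------------------------------------------------------------------------

def _models_for_test(engine: EngineConfig, test_model: str) -> tuple[str, ...]:
    """Restrict an engine's model list to the requested test option."""
    if test_model == "all":
        return engine.models
    if test_model == "additive":
        return ("additive",) if "additive" in engine.models else ()
    # dominant
    if engine.name == "poly_naive":
        # single-locus additive regression only; no dominance encoding exists,
        # but the engine still participates (with its additive scan)
        return ("additive",)
    if engine.ploidy_mode == "tetraploid":
        dom = tuple(m for m in engine.models if "dom" in m)
        return dom
    return ("dominant",) if "dominant" in engine.models else ()


def run_engine(engine: EngineConfig | str, geno: GenotypeMatrix, y: np.ndarray,
               run_config: RunConfig) -> list[AssociationTable]:
    """Run one engine preset on QC'd data and return its association tables.

    ``y`` is the trait vector aligned with ``geno.samples``.  Dispatches
    diploidization, relative exclusion, structure covariates and the
    naive/full scan according to the preset and the run configuration.
    """
    if isinstance(engine, str):
        engine = ENGINE_PRESETS[engine]
    models = _models_for_test(engine, run_config.test_model)
    if not models:
        logger.warning("engine %s supports no model under test_model=%s",
                       engine.name, run_config.test_model)
        return []
    work = geno
    y = np.asarray(y, dtype=float)
    if engine.ploidy_mode == "diploidized" and geno.ploidy == 4:
        work = diploidize(geno)
    if engine.exclude_relatives:
        K = kinship_matrix(work.dosage)
        missing = np.isnan(work.dosage).sum(axis=0)
        retained = exclude_first_degree(K, list(work.samples),
                                        missing_counts=missing)
        if len(retained) < len(work.samples):
            logger.info("engine %s: excluded %d first-degree relatives",
                        engine.name, len(work.samples) - len(retained))
            keep_idx = [work.samples.index(s) for s in retained]
            work = work.subset_samples(retained)
            y = y[keep_idx]
    full = run_config.gwas_model == "full" and (engine.use_structure or engine.use_kinship)
    covariates = None
    if full and engine.use_structure and engine.n_pcs > 0:
        covariates = principal_components(work.dosage, engine.n_pcs)
    if full and engine.use_kinship:
        K = kinship_matrix(work.dosage)
        return scan_mlm(y, covariates, K, work, models,
                        alpha=run_config.significance,
                        correction=run_config.correction, engine=engine.name)
    return scan_glm(y, covariates, work, models,
                    alpha=run_config.significance,
                    correction=run_config.correction, engine=engine.name)
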