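"""Synthetic tetraploid genotype/phenotype data with known causal markers.

Emulates a tetraploid diversity panel: per marker an ALT allele
frequency is drawn (Uniform(0.05, 0.95) by default), per sample the
dosage is Binomial(4, p).  Ten of the markers (by default) are causal
with effect magnitudes drawn from Gamma(shape 0.2, scale 5), random
sign, acting either additively (effect proportional to dosage) or as
simplex dominance (any ALT copy expresses the effect).  Residual noise
is scaled so the genetic values explain a target heritability.

This parametric founder model stands in for a real diversity panel, so
relative patterns across engines and consensus levels — not absolute
true/false-positive rates — are the quantities it is designed to study.
The module also evaluates engines and consensus sets against the
simulated truth with TPR/TNR confusion rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association import ENGINE_PRESETS, run_engine
from .exceptions import DataError
from .io import FilterSettings, GenotypeMatrix, PhenotypeTable, RunConfig
from .model_selection import select_best_model

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec", "SimulatedDataset", "EvalResult", "simulate_founders",
    "simulate_phenotype", "simulate_dataset", "evaluate", "consensus_sets",
    "run_replicates",
]

BASES = ("A", "C", "G", "T")


@dataclass
class SimulationSpec:
    """Study-design parameters of one simulated dataset."""

    n_samples: int = 150
    n_markers: int = 400
    n_causal: int = 10
    effect_shape: float = 0.2    # gamma shape of effect magnitudes
    effect_scale: float = 5.0    # gamma scale of effect magnitudes
    action: str = "additive"     # "additive" or "dominant"
    heritability: float = 0.5
    freq_low: float = 0.05       # founder ALT-frequency range
    freq_high: float = 0.95
    n_subpops: int = 1
    subpop_fst: float = 0.1      # drift between subpopulation frequencies
    ploidy: int = 4
    n_chromosomes: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_causal > self.n_markers:
            raise DataError("n_causal cannot exceed n_markers")
        if not (0.0 < self.heritability < 1.0):
            raise DataError("heritability must lie in (0, 1)")
        if self.action not in ("additive", "dominant"):
            raise DataError("action must be 'additive' or 'dominant'")


@dataclass
class SimulatedDataset:
    genotype: GenotypeMatrix
    phenotype: PhenotypeTable
    truth: pd.DataFrame  # marker, effect, action

    @property
    def causal_markers(self) -> set[str]:
        return set(self.truth["marker"])


@dataclass
class EvalResult:
    """Confusion counts of a predicted marker set against the simulated truth."""

    group: str
    criterion: str
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else np.nan

    def as_row(self) -> dict:
        return {"group": self.group, "criterion": self.criterion,
                "TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp,
                "TPR": self.tpr, "TNR": self.tnr}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _subpop_assignment(spec: SimulationSpec) -> np.ndarray:
    return np.arange(spec.n_samples) % spec.n_subpops


def simulate_founders(spec: SimulationSpec,
                      rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw a founder panel of binomial-dosage tetraploid genotypes.

    With ``n_subpops > 1`` each subpopulation gets its own per-marker
    frequency, drawn around the ancestral one with a Balding-Nichols
    (beta) drift of strength ``subpop_fst``, which induces genuine
    population structure.
    """
    rng = rng or np.random.default_rng(spec.seed)
    p_anc = rng.uniform(spec.freq_low, spec.freq_high, size=spec.n_markers)
    groups = _subpop_assignment(spec)
    if spec.n_subpops > 1:
        fst = spec.subpop_fst
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        p_sub = rng.beta(a[:, None], b[:, None],
                         size=(spec.n_markers, spec.n_subpops))
        p_sub = np.clip(p_sub, 0.01, 0.99)
        p_mat = p_sub[:, groups]
    else:
        p_mat = np.repeat(p_anc[:, None], spec.n_samples, axis=1)
    dosage = rng.binomial(spec.ploidy, p_mat).astype(float)
    width = len(str(spec.n_markers))
    ref_idx = rng.integers(0, 4, size=spec.n_markers)
    alt_shift = rng.integers(1, 4, size=spec.n_markers)
    markers = pd.DataFrame({
        "marker": [f"M{i + 1:0{width}d}" for i in range(spec.n_markers)],
        "chrom": [f"chr{(i % spec.n_chromosomes) + 1}" for i in range(spec.n_markers)],
        "pos": [1000 * (i // spec.n_chromosomes + 1) for i in range(spec.n_markers)],
        "ref": [BASES[r] for r in ref_idx],
        "alt": [BASES[(r + s) % 4] for r, s in zip(ref_idx, alt_shift)],
    })
    samples = [f"S{j + 1:03d}" for j in range(spec.n_samples)]
    return GenotypeMatrix(ploidy=spec.ploidy, markers=markers, samples=samples,
                          dosage=dosage)


def simulate_phenotype(geno: GenotypeMatrix, spec: SimulationSpec,
                       rng: np.random.Generator | None = None,
                       trait: str = "trait"
                       ) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Build a quantitative trait from gamma-distributed causal effects.

    Causal markers are sampled without replacement; each effect magnitude
    is Gamma(effect_shape, effect_scale) with a random sign.  Genetic
    value g = sum beta_i * x_i with x_i the dosage (additive action) or
    the ALT-carrier indicator 1{dosage >= 1} (dominant action).  The
    residual is N(0, Var(g)(1-h2)/h2); with zero causal markers the
    phenotype is unit-variance noise.
    """
    rng = rng or np.random.default_rng(spec.seed)
    ids = list(geno.markers["marker"])
    causal_idx = rng.choice(geno.n_markers, size=spec.n_causal, replace=False) \
        if spec.n_causal else np.array([], dtype=int)

    def draw_effects() -> np.ndarray:
        mags = rng.gamma(spec.effect_shape, spec.effect_scale, size=spec.n_causal)
        signs = rng.choice([-1.0, 1.0], size=spec.n_causal)
        return mags * signs

    def genetic_value(effects: np.ndarray) -> np.ndarray:
        g = np.zeros(geno.n_samples)
        for k, i in enumerate(causal_idx):
            d = np.nan_to_num(geno.dosage[i], nan=np.nanmean(geno.dosage[i]))
            x = d if spec.action == "additive" else (d >= 1).astype(float)
            g += effects[k] * x
        return g

    def degenerate(g: np.ndarray) -> bool:
        # relative guard: a numerically-constant g must not pass on rounding noise
        v = np.var(g)
        return v == 0 or v < 1e-20 * (np.mean(g) ** 2 + v)

    if spec.n_causal:
        effects = draw_effects()
        g = genetic_value(effects)
        if degenerate(g):  # degenerate draw: resample once, then give up
            effects = draw_effects()
            g = genetic_value(effects)
            if degenerate(g):
                raise DataError("degenerate genetic values (Var(g)=0) after resampling")
        h2 = spec.heritability
        sigma_e = np.sqrt(np.var(g) * (1 - h2) / h2)
        y = g + rng.normal(0.0, sigma_e, size=geno.n_samples)
    else:
        effects = np.array([])
        y = rng.normal(0.0, 1.0, size=geno.n_samples)
    pheno = PhenotypeTable(
        samples=list(geno.samples),
        traits=pd.DataFrame({trait: y}, index=geno.samples),
    )
    truth = pd.DataFrame({
        "marker": [ids[i] for i in causal_idx],
        "effect": effects,
        "action": spec.action,
    })
    return pheno, truth


def simulate_dataset(spec: SimulationSpec,
                     rng: np.random.Generator | None = None) -> SimulatedDataset:
    rng = rng or np.random.default_rng(spec.seed)
    geno = simulate_founders(spec, rng)
    pheno, truth = simulate_phenotype(geno, spec, rng)
    return SimulatedDataset(genotype=geno, phenotype=pheno, truth=truth)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(predicted: set[str], truth: set[str], all_markers: set[str],
             group: str = "", criterion: str = "best_ranked") -> EvalResult:
    """Confusion counts of a predicted causal-marker set against the truth."""
    if not all_markers:
        raise DataError("empty marker universe")
    predicted, truth = set(predicted), set(truth)
    if not predicted <= all_markers:
        raise DataError("predicted markers outside the marker universe")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(all_markers) - tp - fp - fn
    return EvalResult(group=group, criterion=criterion, tp=tp, fn=fn, tn=tn, fp=fp)


def consensus_sets(sets: dict[str, set[str]], k: int) -> set[str]:
    """Markers predicted by at least k engines (k=1 union ... k=len intersection)."""
    if not 1 <= k <= len(sets):
        raise DataError(f"k={k} outside 1..{len(sets)}")
    counts: dict[str, int] = {}
    for s in sets.values():
        for m in s:
            counts[m] = counts.get(m, 0) + 1
    return {m for m, c in counts.items() if c >= k}


def run_replicates(spec: SimulationSpec, engines=None, reps: int = 10,
                   criteria=("best_ranked", "significant"),
                   n_best: int | None = None, base_seed: int | None = None
                   ) -> pd.DataFrame:
    """Simulate -> scan -> evaluate, ``reps`` times.

    Each replicate draws a fresh dataset, runs the selected engines with
    the evaluation protocol of the simulation study (naive scan, no
    filtering, Bonferroni correction, the gene action of the simulated
    effects), and scores every engine plus every consensus level
    k = 1..n_engines against the known causal markers, for the
    best-ranked and the significant criterion.  Returns a tidy frame,
    one row per (replicate, group, criterion).
    """
    if reps < 1:
        raise DataError("reps must be >= 1")
    engines = list(engines or ENGINE_PRESETS)
    n_best = n_best or max(spec.n_causal, 10)
    base_seed = spec.seed if base_seed is None else base_seed
    run_config = RunConfig(
        genotype_path="<simulated>", phenotype_path="<simulated>",
        ploidy=spec.ploidy, gwas_model="naive", test_model=spec.action,
        correction="bonferroni", n_best=n_best,
        filters=FilterSettings(maf=None, mind=None, geno=None, hwe=None),
        engines=tuple(engines),
    )
    rows = []
    for rep in range(reps):
        rng = np.random.default_rng((base_seed + rep) % 2**31)
        data = simulate_dataset(replace(spec, seed=int(rng.integers(2**31))), rng)
        geno = data.genotype
        y = data.phenotype.trait_vector("trait", geno.samples)
        truth = data.causal_markers
        universe = set(geno.markers["marker"])
        predicted: dict[str, dict[str, set[str]]] = {c: {} for c in criteria}
        for engine in engines:
            tables = run_engine(engine, geno, y, run_config)
            if not tables:
                continue
            chosen = select_best_model(tables, n_best)
            if "best_ranked" in criteria:
                predicted["best_ranked"][engine] = set(chosen.best_ranked(n_best))
            if "significant" in criteria:
                predicted["significant"][engine] = set(chosen.significant_markers())
        for criterion in criteria:
            sets = predicted[criterion]
            for engine, pred in sets.items():
                r = evaluate(pred, truth, universe, engine, criterion)
                rows.append({"rep": rep, **r.as_row()})
            for k in range(1, len(engines) + 1):
                pred = consensus_sets(sets, k) if sets else set()
                r = evaluate(pred, truth, universe, f"consensus_{k}", criterion)
                rows.append({"rep": rep, **r.as_row()})
    return pd.DataFrame(rows)


def summarize_replicates(results: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd of TPR and TNR per group and criterion (boxplot-ready input)."""
    return (results.groupby(["criterion", "group"], sort=False)[["TPR", "TNR"]]
            .agg(["mean", "std"]).reset_index())
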