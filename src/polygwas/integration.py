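"""Integration of per-engine results into the consensus report surfaces.

Produces the best-ranked and significant marker sets per engine, the
consensus membership table with Venn region counts, pairs of candidate
markers in linkage disequilibrium (squared Pearson correlation of dosage
vectors), per-marker genotype/phenotype profiles, Manhattan and Q-Q plot
data, and a self-contained HTML report with the underlying delimited
tables and figures.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssociationTable
from .exceptions import DataError
from .io import GenotypeMatrix
from .qc import QCReport

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusReport", "SNPProfile", "best_ranked", "consensus", "ld_pairs",
    "snp_profile", "manhattan_qq_data", "build_consensus_report", "render_report",
]


# ---------------------------------------------------------------------------
# consensus sets
# ---------------------------------------------------------------------------

def best_ranked(table: AssociationTable, n: int) -> list[str]:
    """The N lowest-p markers (lexicographic tie-break), as reported per engine."""
    return table.best_ranked(n)


def consensus(sets: dict[str, set[str]]) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Engine-membership table and Venn region counts for marker sets.

    Returns a frame with one row per marker in the union (columns: one
    bool per engine plus ``n_engines``) and a dict mapping each nonempty
    engine combination to the number of markers exactly in that region.
    """
    engines = list(sets)
    if not 2 <= len(engines) <= 4:
        raise DataError(f"consensus expects 2-4 engine sets, got {len(engines)}")
    union = sorted(set().union(*sets.values()))
    rows = {}
    for m in union:
        membership = tuple(m in sets[e] for e in engines)
        rows[m] = membership
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=engines)
    frame.index.name = "marker"
    frame["n_engines"] = frame[engines].sum(axis=1)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(engines) + 1):
        for combo in itertools.combinations(engines, r):
            mask = np.ones(len(frame), dtype=bool)
            for e in engines:
                mask &= frame[e].to_numpy() == (e in combo)
            regions[combo] = int(mask.sum())
    return frame, regions


def consensus_shared_table(tables: dict[str, AssociationTable], n_best: int
                           ) -> pd.DataFrame:
    """Long table of each engine's best-ranked markers with their statistics."""
    rows = []
    for engine, table in tables.items():
        chosen = set(table.best_ranked(n_best))
        f = table.frame
        sub = f[f["marker"].isin(chosen)]
        for _, r in sub.iterrows():
            rows.append({
                "marker": r["marker"], "engine": engine, "model": table.model,
                "chrom": r["chrom"], "pos": int(r["pos"]), "score": r["score"],
                "threshold": r["threshold"], "significant": bool(r["significant"]),
            })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["marker", "engine"], kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_pairs(candidates: list[str], geno: GenotypeMatrix, r2_threshold: float
             ) -> pd.DataFrame:
    """All candidate pairs with dosage-correlation r^2 >= threshold.

    Qualifying pairs get sequential ids ``LD_SNP1, LD_SNP2, ...`` in
    decreasing r^2 order.  Monomorphic candidates (undefined correlation)
    are skipped with a warning.
    """
    if len(candidates) < 2:
        raise DataError("LD pairing needs at least 2 candidate markers")
    idx = {m: i for i, m in enumerate(geno.markers["marker"])}
    usable = []
    for m in candidates:
        if m not in idx:
            continue
        d = geno.dosage[idx[m]]
        if np.nanstd(d) == 0:
            warnings.warn(f"marker {m} is monomorphic; skipped in LD pairing")
            continue
        usable.append(m)
    rows = []
    for a, b in itertools.combinations(sorted(usable), 2):
        da, db = geno.dosage[idx[a]], geno.dosage[idx[b]]
        ok = ~np.isnan(da) & ~np.isnan(db)
        if ok.sum() < 3 or np.std(da[ok]) == 0 or np.std(db[ok]) == 0:
            continue
        r = np.corrcoef(da[ok], db[ok])[0, 1]
        r2 = float(r * r)
        if r2 >= r2_threshold:
            rows.append({"snp1": a, "snp2": b, "r2": r2})
    out = pd.DataFrame(rows, columns=["snp1", "snp2", "r2"])
    out = out.sort_values(["r2", "snp1", "snp2"], ascending=[False, True, True],
                          kind="mergesort").reset_index(drop=True)
    out.insert(0, "ld_snp", [f"LD_SNP{i}" for i in range(1, len(out) + 1)])
    return out


# ---------------------------------------------------------------------------
# SNP profiles
# ---------------------------------------------------------------------------

@dataclass
class SNPProfile:
    """Genotype classes (major allele first) and phenotype per sample for one marker."""

    marker: str
    class_order: list[str]               # e.g. AAAA, AAAT, AATT, ATTT, TTTT
    per_sample: pd.DataFrame             # sample, genotype, phenotype
    class_means: pd.Series               # mean phenotype per genotype class


def snp_profile(marker: str, geno: GenotypeMatrix, phenotype: np.ndarray,
                trait: str = "trait") -> SNPProfile:
    """Group samples of one marker by genotype class, ordered major -> minor."""
    ids = list(geno.markers["marker"])
    if marker not in ids:
        raise DataError(f"marker {marker} not present")
    i = ids.index(marker)
    d = geno.dosage[i]
    if np.all(np.isnan(d)):
        raise DataError(f"marker {marker} missing for all samples")
    ref, alt = geno.markers["ref"].iloc[i], geno.markers["alt"].iloc[i]
    alt_freq = np.nansum(d) / (geno.ploidy * np.sum(~np.isnan(d)))
    dosage_order = range(geno.ploidy + 1) if alt_freq <= 0.5 else \
        range(geno.ploidy, -1, -1)
    labels = {k: ref * (geno.ploidy - k) + alt * k for k in range(geno.ploidy + 1)}
    class_order = [labels[k] for k in dosage_order]
    ok = ~np.isnan(d) & np.isfinite(phenotype)
    per_sample = pd.DataFrame({
        "sample": np.array(geno.samples)[ok],
        "genotype": [labels[int(k)] for k in d[ok]],
        "phenotype": phenotype[ok],
    })
    # deterministic ordering: genotype class (major first), then phenotype
    cat = pd.Categorical(per_sample["genotype"], categories=class_order, ordered=True)
    per_sample = per_sample.assign(genotype=cat).sort_values(
        ["genotype", "phenotype", "sample"], kind="mergesort").reset_index(drop=True)
    means = per_sample.groupby("genotype", observed=False)["phenotype"].mean()
    means = means.reindex(class_order)
    return SNPProfile(marker=marker, class_order=class_order,
                      per_sample=per_sample, class_means=means)


# ---------------------------------------------------------------------------
# plot data
# ---------------------------------------------------------------------------

def manhattan_qq_data(table: AssociationTable, n_best: int,
                      shared: set[str] | None = None) -> dict:
    """Plot-ready Manhattan and Q-Q records for one engine table.

    Manhattan: cumulative genome coordinate and score per marker, the
    red line at the significance threshold score, the blue line at the
    Nth-best score, and a flag for markers shared between engines.
    Q-Q: expected vs observed -log10(p) plus the inflation factor.
    """
    f = table.frame.dropna(subset=["pvalue"]).copy()
    chrom_order = list(dict.fromkeys(f["chrom"]))
    offset, offsets = 0, {}
    for c in chrom_order:
        offsets[c] = offset
        offset += int(f.loc[f["chrom"] == c, "pos"].max()) + 1
    f["genome_pos"] = f.apply(lambda r: offsets[r["chrom"]] + int(r["pos"]), axis=1)
    f["shared"] = f["marker"].isin(shared or set())
    ranked = f.sort_values(["pvalue", "marker"], kind="mergesort")
    blue = float(ranked["score"].iloc[min(n_best, len(ranked)) - 1])
    obs = np.sort(f["score"].to_numpy())[::-1]
    exp = -np.log10((np.arange(1, obs.size + 1) - 0.5) / obs.size)
    return {
        "manhattan": f[["marker", "chrom", "pos", "genome_pos", "score", "shared"]],
        "red_line": float(table.threshold_score),
        "blue_line": blue,
        "qq": pd.DataFrame({"expected": exp, "observed": obs}),
        "lambda": table.lambda_gc,
    }


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class ConsensusReport:
    """Everything the per-trait report is rendered from."""

    trait: str
    n_best: int
    tables: dict[str, AssociationTable]          # chosen table per engine
    best_sets: dict[str, set[str]]
    significant_sets: dict[str, set[str]]
    best_membership: pd.DataFrame
    best_regions: dict[tuple[str, ...], int]
    sig_membership: pd.DataFrame | None
    sig_regions: dict[tuple[str, ...], int] | None
    shared_table: pd.DataFrame
    ld_table: pd.DataFrame
    profiles: dict[str, SNPProfile]
    model_scores: dict[str, pd.DataFrame]        # per engine


def build_consensus_report(tables: dict[str, AssociationTable],
                           geno: GenotypeMatrix, phenotype: np.ndarray,
                           trait: str, n_best: int, ld_r2: float,
                           model_scores: dict[str, pd.DataFrame] | None = None
                           ) -> ConsensusReport:
    """Assemble all integration outputs from the chosen per-engine tables."""
    best_sets = {e: set(t.best_ranked(n_best)) for e, t in tables.items()}
    sig_sets = {e: set(t.significant_markers()) for e, t in tables.items()}
    if len(tables) >= 2:
        best_membership, best_regions = consensus(best_sets)
        sig_membership, sig_regions = consensus(sig_sets)
    else:
        only = next(iter(best_sets.values()))
        best_membership = pd.DataFrame(
            {e: True for e in best_sets}, index=sorted(only))
        best_membership["n_engines"] = 1
        best_regions = {tuple(best_sets): len(only)}
        sig_membership, sig_regions = None, None
    shared_table = consensus_shared_table(tables, n_best)
    candidates = sorted(set().union(*best_sets.values()))
    if len(candidates) >= 2:
        ld_table = ld_pairs(candidates, geno, ld_r2)
    else:
        ld_table = pd.DataFrame(columns=["ld_snp", "snp1", "snp2", "r2"])
    shared_markers = best_membership.index[best_membership["n_engines"] >= 2]
    profiles = {}
    for m in shared_markers:
        try:
            profiles[m] = snp_profile(m, geno, phenotype, trait)
        except DataError:
            continue
    return ConsensusReport(
        trait=trait, n_best=n_best, tables=tables, best_sets=best_sets,
        significant_sets=sig_sets, best_membership=best_membership,
        best_regions=best_regions, sig_membership=sig_membership,
        sig_regions=sig_regions, shared_table=shared_table, ld_table=ld_table,
        profiles=profiles, model_scores=model_scores or {},
    )


def _region_frame(regions: dict[tuple[str, ...], int]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"engines": "+".join(c), "n_engines": len(c), "count": v}
         for c, v in regions.items()]
    ).sort_values(["n_engines", "engines"]).reset_index(drop=True)


def _plot_engine(ax_man, ax_qq, table: AssociationTable, n_best: int,
                 shared: set[str]) -> None:
    data = manhattan_qq_data(table, n_best, shared)
    f = data["manhattan"]
    colors = np.where(f["shared"], "green", "steelblue")
    ax_man.scatter(f["genome_pos"], f["score"], s=8, c=colors)
    ax_man.axhline(data["red_line"], color="red", lw=1)
    ax_man.axhline(data["blue_line"], color="blue", lw=1)
    ax_man.set_title(f"{table.engine} ({table.model})", fontsize=9)
    ax_man.set_ylabel("-log10 p", fontsize=8)
    qq = data["qq"]
    ax_qq.scatter(qq["expected"], qq["observed"], s=6, c="black")
    lim = max(qq["expected"].max(), qq["observed"].max())
    ax_qq.plot([0, lim], [0, lim], color="red", lw=1)
    lam = data["lambda"]
    ax_qq.set_title(f"lambda = {lam:.2f}" if np.isfinite(lam) else "lambda: n/a",
                    fontsize=9)


def render_report(report: ConsensusReport, qc: QCReport, out_dir: str | Path
                  ) -> Path:
    """Write the HTML report, its delimited tables and figures for one trait.

    Returns the trait output directory.  Deterministic: re-rendering the
    same report produces byte-identical tables.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tabdir = out / "tables"
    figdir = out / "figures"
    tabdir.mkdir(exist_ok=True)
    figdir.mkdir(exist_ok=True)

    # delimited tables
    qc.to_frame().to_csv(tabdir / "qc_report.csv", index=False)
    report.shared_table.to_csv(tabdir / "shared_snps.csv", index=False)
    report.ld_table.to_csv(tabdir / "ld_pairs.csv", index=False)
    report.best_membership.to_csv(tabdir / "best_ranked_membership.csv")
    _region_frame(report.best_regions).to_csv(tabdir / "venn_best_ranked.csv", index=False)
    if report.sig_regions is not None:
        report.sig_membership.to_csv(tabdir / "significant_membership.csv")
        _region_frame(report.sig_regions).to_csv(tabdir / "venn_significant.csv", index=False)
    for engine, scores in report.model_scores.items():
        scores.to_csv(tabdir / f"model_scores_{engine}.csv", index=False)
    for engine, table in report.tables.items():
        table.to_output_frame().to_csv(tabdir / f"associations_{engine}.csv", index=False)

    # figures: one Manhattan + Q-Q row per engine
    shared = set(report.best_membership.index[report.best_membership["n_engines"] >= 2])
    n_eng = len(report.tables)
    fig, axes = plt.subplots(n_eng, 2, figsize=(9, 2.4 * n_eng), squeeze=False,
                             gridspec_kw={"width_ratios": [2.2, 1]})
    for row, (engine, table) in enumerate(report.tables.items()):
        _plot_engine(axes[row, 0], axes[row, 1], table, report.n_best, shared)
    fig.tight_layout()
    fig.savefig(figdir / "manhattan_qq.png", dpi=110)
    plt.close(fig)

    if report.profiles:
        marker, profile = next(iter(report.profiles.items()))
        fig, ax = plt.subplots(figsize=(6, 3))
        for k, cls in enumerate(profile.class_order):
            vals = profile.per_sample.loc[
                profile.per_sample["genotype"] == cls, "phenotype"]
            ax.scatter(np.full(len(vals), k), vals, s=10, alpha=0.6)
            if np.isfinite(profile.class_means.get(cls, np.nan)):
                ax.hlines(profile.class_means[cls], k - 0.3, k + 0.3,
                          color="cyan", lw=2)
        ax.set_xticks(range(len(profile.class_order)), profile.class_order)
        ax.set_title(f"{marker}: {report.trait}", fontsize=9)
        fig.tight_layout()
        fig.savefig(figdir / "snp_profile.png", dpi=110)
        plt.close(fig)

    html = _render_html(report, qc)
    (out / "report.html").write_text(html)
    return out


def _render_html(report: ConsensusReport, qc: QCReport) -> str:
    def section(title: str, body: str) -> str:
        return f"<h2>{title}</h2>\n{body}\n"

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>Consensus GWAS report: {report.trait}</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:"
        "collapse}td,th{border:1px solid #999;padding:3px 8px;font-size:12px}"
        "</style></head><body>",
        f"<h1>Consensus GWAS report — trait: {report.trait}</h1>",
        section("Quality control", qc.to_frame().to_html(index=False)),
    ]
    lam_rows = pd.DataFrame(
        [{"engine": e, "model": t.model, "lambda": t.lambda_gc,
          "m_tested": t.m_tested, "threshold_score": t.threshold_score,
          "n_significant": len(t.significant_markers())}
         for e, t in report.tables.items()])
    parts.append(section("Engines", lam_rows.to_html(index=False)))
    for engine, scores in report.model_scores.items():
        parts.append(section(f"Gene-action model scores — {engine}",
                             scores.to_html(index=False)))
    if len(report.shared_table):
        parts.append(section("Best-ranked and significant associations",
                             report.shared_table.to_html(index=False)))
    else:
        parts.append(section("Best-ranked and significant associations",
                             "<p>No associations to report.</p>"))
    sig_any = any(report.significant_sets.values())
    if not sig_any:
        parts.append("<p><em>No marker reached significance in any engine.</em></p>")
    parts.append(section("Best-ranked consensus (Venn regions)",
                         _region_frame(report.best_regions).to_html(index=False)))
    if report.sig_regions is not None:
        parts.append(section("Significant consensus (Venn regions)",
                             _region_frame(report.sig_regions).to_html(index=False)))
    if len(report.ld_table):
        parts.append(section("Candidate SNP pairs in LD",
                             report.ld_table.to_html(index=False)))
    else:
        parts.append(section("Candidate SNP pairs in LD",
                             "<p>No pair reached the r² threshold.</p>"))
    parts.append("<h2>Figures</h2>"
                 "<img src='figures/manhattan_qq.png' style='max-width:100%'>")
    if report.profiles:
        parts.append("<img src='figures/snp_profile.png' style='max-width:60%'>")
    parts.append("</body></html>")
    return "\n".join(parts)
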