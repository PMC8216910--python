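# Methods

This note documents the statistical models, the numerical choices, the
synthetic-data generator, and the design decisions behind `polygwas`.

## Data model

Genotypes are biallelic SNPs stored as ALT-allele dosage, an integer in
`0..ploidy` (ploidy 2 or 4), with `NaN` for missing calls, plus a marker
map (id, chromosome, 1-based position, ref/alt single bases). Letter
genotypes (`AAAT`) are derived views: ref repeated `ploidy − d` times,
then alt `d` times. Five input dialects (letter table, VCF via cyvcf2,
wide dosage matrix, and two long dosage-caller layouts) all normalize to
this representation; for the long layouts only the posterior-mode dosage
column is consumed. Missing-genotype spellings `NA`, `.`, `./././.` and
the empty string map to one sentinel. Multi-allelic VCF records are
skipped with a warning; imputation and phasing are out of scope.

Chromosome handling: contig size is approximated by the highest variant
position; contigs are ordered by size, descending, and names that are
purely numeric or longer than 10 characters (a package choice; no
biological meaning) are replaced by `contig<rank>`. The operation is
idempotent.

## Quality control

Filters run in a fixed order — intersect genotype/phenotype samples,
then MIND (sample missingness), GENO (marker missingness), MAF, HWE —
with rates recomputed after each step, so e.g. a marker's MAF is
evaluated on the samples surviving MIND. "Below"/"exceeding" are read
as strict inequalities: MAF removes markers with minor frequency `< x`,
MIND/GENO remove at missingness `> x`. Defaults: MAF 0.01, MIND 0.1,
GENO 0.1, HWE off (enable by giving a threshold).

### Exact Hardy–Weinberg test

Under autotetraploid (polysomic) equilibrium, dosage classes follow
`P(D = k) = C(4,k) p^k (1−p)^{4−k}`. The test conditions on the sample
size `n` and the total ALT-allele count `A` and computes the probability
of every dosage-class configuration with that `(n, A)` that is no more
probable than the observed one (a Levene-style exact conditional test
generalized to five classes). Conditioning cancels the `p`-dependent
terms, so only multinomial and binomial coefficients enter; the
implementation enumerates configurations (cached per `(n, A)`) and works
in log space. For diploids the same machinery is the classical 3-class
exact test. The unit suite verifies exact agreement with a brute-force
enumeration oracle for every configuration with `n ≤ 6`, and a null
calibration (n = 200, p = 0.3, 2000 draws) that the rejection rate at
α = 0.05 lies in the exact binomial 99% CI.

## Gene-action encodings

For tetraploid dosage `d`: additive = `d`; simplex dominant (alt) =
`1{d ≥ 1}`; simplex dominant (ref) = `1{d ≤ 3}`; duplex dominant (alt) =
`1{d ≥ 2}`; duplex dominant (ref) = `1{d ≤ 2}`; diplo-additive =
0/1/2 for d = 0 / 1–3 / 4; diplo-general = the same three levels as
free classes; general = five free classes. Diploid models: additive
0/1/2, dominant `1{d = 1}`, general three classes. Simplex means one
copy of the allele suffices for the effect, duplex means two.

Class models enter the design as treatment indicators with the most
frequent class as reference (ties toward the lower class). A marker
whose encoding is constant across samples is *degenerate under that
model*: it is excluded from the scan and from that model's tested-marker
count `m`, which is why Bonferroni thresholds differ between gene-action
models of the same engine.

Diploidization collapses tetraploid calls for the diploid engines:
homozygotes stay homozygous, every dosage 1–3 becomes the ref/alt
heterozygote.

## Association scans

**Naive (GLM).** Per marker, ordinary least squares of the trait on
`[1 | covariates | encoding]`; the p-value is the partial F-test of the
encoding block. Samples with a missing trait, covariate or dosage are
dropped per marker (no imputation), keeping the test exact.

**Full (Q + K mixed model).** Structure covariates Q are the top
principal components (default 5) of the mean-imputed, marker-
standardized dosage matrix, with a deterministic sign convention
(largest-magnitude loading positive). Kinship is `K = Z'Z/m` on the
same standardized matrix (monomorphic markers skipped). Variance
components of `y = Wb + u + e`, `u ~ N(0, σ²g K)`, are estimated once
under the null by REML: a spectral decomposition of K reduces the
profiled likelihood to one dimension in the ratio δ = σ²e/σ²g,
optimized on a log grid (ln δ ∈ [−13.8, 13.8], 50 points) refined by
bounded scalar minimization — deterministic, and robust at both
boundaries (pure-noise and pure-genetic traits). Each marker is then
tested by GLS with the null covariance fixed (P3D/EMMAX): the
covariance whitens y, the covariates and the encoding, and the partial
F (Wald) statistic is computed on the whitened system. Markers with
missing dosages are tested on their sample subset with the covariance
re-factorized on that subset. With K = I the scan reduces exactly to
the GLM (verified to 1e−8 in −log10 p).

A small diagonal jitter (1e−12 of the total variance) keeps the
whitening factorization stable when σ²e → 0.

**Inflation factor.** λ = median(χ²₁ quantiles of 1 − p) / 0.4549364
(the χ²₁ median), the standard genomic-control estimator; λ = 1 exactly
when all p = 0.5.

**Thresholds.** Bonferroni (default): the red-line score is
−log10(α/m) with the per-model m; a marker is significant iff its score
reaches the line. FDR: Benjamini–Hochberg step-up at level α; the line
sits at the largest rejected p-value (when nothing is rejected,
min(p) > α/m by the step-up definition, so α/m preserves the
flag/threshold equivalence).

### Engine presets

* `poly_full`: tetraploid dosages, all 8 gene-action models, Q + K.
* `poly_naive`: tetraploid dosages, additive + general, never uses Q or
  K; instead it greedily removes samples with cryptic first-degree
  relatedness (standardized kinship > 0.5; the sample with the most
  ties goes first, ties broken by more missing data, then id). Under
  the dominant test option this engine still runs — with its additive
  single-locus scan, since it has no dominance encoding — mirroring how
  a naive single-locus tool participates in a dominant-action study.
* `dip_a`: diploidized dosages, additive + dominant recodes, Q + K.
* `dip_b`: diploidized dosages, general + additive + dominant, Q + K.

The test option restricts models: `additive` → the additive model
everywhere; `dominant` → all four simplex/duplex variants for
`poly_full` (the option does not say which dominance order is meant, so
both are scanned) and the diploid dominant recode for the diploidized
engines; `all` → every model the engine supports. When an engine
returns several tables for one run, the model-selection score picks the
one that is reported and fed into the consensus.

All engines share the same kinship/PC definitions. That is a deliberate
simplification: it strengthens cross-engine comparability at the cost
of not reproducing each emulated tool's private covariance estimator.

## Model selection

`score(Mᵢ) = Iᵢ + Rᵢ + Sᵢ` with `Iᵢ = 1 − |1 − λ(Mᵢ)|` (maximal at
λ = 1, symmetric, allowed to go negative so a badly inflated model is
penalized into losing), `Rᵢ` = the sum over other models of the top-N
best-ranked overlap `|Mᵢ∼Mⱼ|`, normalized by the maximum such row-sum,
and `Sᵢ` = the model's significant-marker count normalized by the size
of the union of all pairwise top-N intersections. Both normalizations
are genuinely ambiguous design points; the alternatives ((k−1)·N for R,
N for S) are implemented behind keyword switches for sensitivity
checks. Self-overlap never counts. Best model = argmax of the total,
ties broken by larger S, then input order.

## Integration

Best-ranked sets are the N lowest-p markers per engine (ties broken
lexicographically — deterministic). Consensus membership and Venn
region counts are computed for 2–4 engines over both the best-ranked
and the significant sets; cross-engine marker identity is by marker id,
valid because all engines scan the same input matrix. LD pairing takes
the union of the engines' best-ranked sets and reports every pair with
squared Pearson correlation of dosage vectors ≥ the configured r²
(composite dosage LD; haplotype phase is never inferred), labelled
`LD_SNP1, LD_SNP2, …` in descending r²; monomorphic candidates are
skipped with a warning. SNP profiles group samples by genotype class
ordered major allele first, with per-class phenotype means; ordering is
deterministic (class, then phenotype, then sample id) rather than
clustered. The per-trait report folder contains the HTML summary, all
tables as CSV, and the Manhattan/Q–Q and profile figures; re-rendering
is byte-identical.

## Simulator

The generator emulates a tetraploid diversity panel at the default
study design: 150 samples × 400 biallelic SNPs, 10 causal SNPs with
effect magnitudes from Γ(shape 0.2, scale 5) and random signs (the
magnitude distribution is right-skewed: a few large effects, many
negligible ones). Per marker an ancestral ALT frequency is uniform on
(0.05, 0.95); per sample the dosage is Binomial(4, p) —
Hardy–Weinberg founders. Optional subpopulations draw their own
frequencies by a Balding–Nichols beta drift (default Fst 0.1),
producing genuine structure for the Q + K tests. Genetic values are
`g = Σ βᵢ xᵢ` with `xᵢ` the dosage (additive action) or the carrier
indicator `1{d ≥ 1}` (dominant action, i.e. simplex dominance);
residual noise is scaled to a target heritability (default h² = 0.5,
a package choice typical of moderately heritable agronomic traits).
A numerically-degenerate genetic value (e.g. a monomorphic carrier
indicator) triggers one effect resample, then an error.

What the generator does *not* emulate: linkage disequilibrium between
markers (all markers independent), real allele-frequency spectra,
pedigree structure, genotyping error. Passing consensus benchmarks on
this generator therefore demonstrates the *relative* behavior of the
engines and consensus levels (TPR falls and TNR rises with the
agreement level; structure correction recalibrates λ), not absolute
detection rates on real panels.

The replicate evaluation protocol matches the simulation study design:
naive scans, no filtering, Bonferroni, gene action matched to the
simulated action, N best = the causal count; engines and consensus
levels k = 1..4 ("predicted by at least k engines") are scored as
TPR = TP/(TP+FN), TNR = TN/(TN+FP) against exact marker identity
(LD credit is not given — markers are independent here anyway).

## Determinism and problem sizes

Every stochastic routine takes an explicit seed (`SimulationSpec.seed`,
default 42); scans, REML, PCs and reports are fully deterministic given
inputs, and engine execution order never changes any output. The
acceptance script runs its checks at 150 × 200–400 with 10–200
replicates per quantity, sizes at which every consensus and calibration
property it reports is stable across seeds while the whole script stays
fast; the unit suite uses smaller panels chosen the same way.

## Known limitations

* Only ploidies 2 and 4; quantitative traits only (no case/control).
* P3D keeps variance components fixed across markers; per-marker REML
  would be slightly more powerful for very large effects.
* The emulated tools' exact statistics are not reproduced — the presets
  mirror their modelling choices (models, structure handling, relative
  exclusion), not their implementations.
* The exact HWE test enumerates dosage-class configurations; it is
  exact but its cost grows with sample size times allele count (cached
  per configuration; comfortable for panels of hundreds of samples).
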