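# polygwas

Consensus genome-wide association for diploid and autotetraploid
organisms.

Genome-wide association studies (GWAS) in autotetraploids — potato,
alfalfa, many wild polyploids — face two practical problems: most GWAS
software assumes diploid genotypes, and results replicate poorly across
tools because each one makes different modelling choices. `polygwas`
addresses both by running **four internal association engines in
parallel on the same cleaned dosage matrix** and integrating their
results into a single consensus report:

| engine       | genotypes    | gene-action models                 | correction            |
|--------------|--------------|------------------------------------|-----------------------|
| `poly_full`  | tetraploid   | 8 (general … diplo-additive)       | Q + K mixed model     |
| `poly_naive` | tetraploid   | additive, general                  | none; drops relatives |
| `dip_a`      | diploidized  | additive, dominant                 | Q + K mixed model     |
| `dip_b`      | diploidized  | general, additive, dominant        | Q + K mixed model     |

A marker that several engines rank highly is far less likely to be an
artifact of one tool's assumptions; the package quantifies exactly that.

## The model

Each scan fits, per marker,

```
y = Xβ + Sα + Qν + Zμ + e
```

where `y` is the quantitative trait, `Sα` the tested marker's
gene-action encoding, `Qν` population-structure covariates (the first
five principal components of the dosage matrix) and `Zμ` a polygenic
random effect with covariance `σ²g K` built from the realized-relationship
(kinship) matrix `K = Z'Z/m`. The *naive* model drops Q and the
polygene and reduces to ordinary least squares; the *full* (Q + K)
model estimates `(σ²g, σ²e)` once under the null by REML (EMMA-style
spectral decomposition) and tests every marker by generalized least
squares with that covariance fixed (P3D/EMMAX). Significance uses a
per-model Bonferroni threshold `α/m` (or Benjamini–Hochberg FDR), where
`m` counts only the markers testable under that gene-action encoding.

Around the scans the package provides: parsing of five genotype
dialects (letter tables, VCF, dosage matrix, and two dosage-caller
table layouts) into a canonical ALT-dosage representation; quality
control (MAF / sample- and marker-missingness / an **exact
autotetraploid Hardy–Weinberg test**); a score
`score(Mᵢ) = Iᵢ + Rᵢ + Sᵢ` that picks the best gene-action model from
its inflation factor λ, its agreement with the other models and its
significant hits; consensus (Venn) membership across engines; dosage-r²
LD pairing of candidate SNPs; SNP genotype/phenotype profiles; and a
simulator with known causal SNPs for TPR/TNR benchmarking of the
consensus levels.

## Worked example

`examples/run_full_pipeline.py` simulates a 60-sample × 80-SNP
tetraploid panel with 4 causal SNPs, writes the genotype/phenotype/
config files, and runs all four engines:

```
simulated causal SNPs: ['M13', 'M18', 'M56', 'M80']

per-engine inflation factors (lambda ~ 1 means calibrated):
  poly_full  model=additive  lambda=1.05 significant=1
  poly_naive model=additive  lambda=1.05 significant=1
  dip_a      model=additive  lambda=1.04 significant=1
  dip_b      model=additive  lambda=1.04 significant=1

best-ranked markers detected by >= 2 engines:
        poly_full  poly_naive  dip_a  dip_b  n_engines
M18          True        True   True   True          4
M19          True        True   True   True          4
M40          True        True   True   True          4
...
```

All four engines are calibrated (λ ≈ 1). Three markers sit in the
central consensus (all four engines), among them the causal `M18`;
markers backed by only one tool are down-weighted by construction. The
HTML report with the Manhattan/Q–Q figures, consensus tables and LD
pairs lands in `out-demo/<trait>/`.

Other examples: `hardy_weinberg_qc.py` (the exact tetraploid HWE test
inside the QC chain), `gene_action_models.py` (the eight encodings and
the model-selection score), `consensus_evaluation.py` (replicate
TPR/TNR evaluation of the consensus levels).

The same pipeline is scriptable from a shell:

```bash
polygwas run Test01.config          # -> out-Test01/<trait>/report.html
polygwas simulate sim.spec --out simulated
polygwas evaluate sim.spec --reps 10 --out evaluation
```

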