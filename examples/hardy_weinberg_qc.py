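"""Quality control on a tetraploid panel, featuring the exact
autotetraploid Hardy-Weinberg test.

Each p-value below is the exact conditional probability of dosage-class
counts at least as extreme as observed under polysomic equilibrium
P(dosage = k) = C(4,k) p^k (1-p)^(4-k); markers far out of equilibrium
(e.g. only extreme homozygotes) get small p and are filtered.
"""

import numpy as np

from polygwas import (FilterSettings, SimulationSpec, apply_qc,
                      hwe_test_tetraploid, simulate_dataset)

print("exact tetraploid HWE p-values (counts of dosage classes 0..4):")
for counts in ([12, 40, 56, 35, 7],   # near-equilibrium draw
               [2, 0, 2, 0, 0],       # tiny sample, mildly off
               [30, 0, 0, 0, 30]):    # only extreme homozygotes: strong excess
    print(f"  counts={counts}: p = {hwe_test_tetraploid(counts):.4g}")

# run the full filter chain on a simulated panel with an injected bad marker
data = simulate_dataset(SimulationSpec(n_samples=100, n_markers=50, n_causal=0,
                                       seed=7))
geno = data.genotype
geno.dosage[0] = np.array([0.0] * 50 + [4.0] * 50)  # heterozygote deficit
filters = FilterSettings(maf=0.01, mind=0.1, geno=0.1, hwe=1e-4)
clean, pheno, report = apply_qc(geno, data.phenotype, filters)
print("\nQC summary (markers/samples before vs after, removals per filter):")
print(report.to_frame().to_string(index=False))
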