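"""Shared fixtures: small hand-constructed datasets built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polygwas import GenotypeMatrix, PhenotypeTable


def make_genotype(dosage, ploidy=4, ref="A", alt="T", chrom=None, samples=None,
                  marker_prefix="m"):
    """Build a GenotypeMatrix from a dosage array (markers x samples)."""
    dosage = np.asarray(dosage, dtype=float)
    m, n = dosage.shape
    markers = pd.DataFrame({
        "marker": [f"{marker_prefix}{i + 1}" for i in range(m)],
        "chrom": chrom if chrom is not None else ["chr1"] * m,
        "pos": [100 * (i + 1) for i in range(m)],
        "ref": [ref] * m,
        "alt": [alt] * m,
    })
    samples = samples or [f"s{j + 1}" for j in range(n)]
    return GenotypeMatrix(ploidy=ploidy, markers=markers, samples=samples,
                          dosage=dosage)


def make_phenotype(values, samples=None, trait="trait"):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j + 1}" for j in range(len(values))]
    return PhenotypeTable(samples=samples,
                          traits=pd.DataFrame({trait: values}, index=samples))


@pytest.fixture
def tiny_tetraploid():
    """4 markers x 6 samples with one missing call."""
    dosage = np.array([
        [0, 1, 2, 3, 4, 0],
        [0, 0, 1, 1, 2, 2],
        [4, 4, 3, 2, 1, 0],
        [0, np.nan, 0, 1, 0, 2],
    ], dtype=float)
    return make_genotype(dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
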