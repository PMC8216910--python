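"""Gene-action encodings and diploidization.

For a biallelic tetraploid marker the ALT dosage d takes values 0..4.
Each gene-action model maps dosage to a regression code:

==================  =========================================================
model               code
==================  =========================================================
additive            d itself (linear in dosage)
simplex_dom_alt     1 if d >= 1 (one ALT copy suffices)
simplex_dom_ref     1 if d <= 3 (one REF copy suffices)
duplex_dom_alt      1 if d >= 2 (two ALT copies suffice)
duplex_dom_ref      1 if d <= 2 (two REF copies suffice)
diplo_additive      0 / 1 / 2 for d = 0 / 1-3 / 4
diplo_general       three free classes {0, heterozygous, 4}
general             five free classes, one per dosage
==================  =========================================================

Diploid markers (d in 0..2) support ``additive`` (0/1/2), ``dominant``
(1 for the heterozygote, 0 for both homozygotes) and ``general`` (three
free classes).  Class-type models enter the design matrix as treatment
indicators with the most frequent class as reference.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DataError
from .io import GenotypeMatrix

TETRAPLOID_MODELS = (
    "general", "additive",
    "simplex_dom_ref", "simplex_dom_alt",
    "duplex_dom_ref", "duplex_dom_alt",
    "diplo_general", "diplo_additive",
)
DIPLOID_MODELS = ("general", "additive", "dominant")

#: models whose codes are unordered class labels (indicator columns)
CLASS_MODELS = frozenset({"general", "diplo_general"})


def models_for_ploidy(ploidy: int) -> tuple[str, ...]:
    return TETRAPLOID_MODELS if ploidy == 4 else DIPLOID_MODELS


def diploidize(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Collapse tetraploid calls to diploid ones.

    Homozygotes stay homozygous (AAAA -> AA); every heterozygous dosage
    1-3 becomes the ref/alt heterozygote (AAAT -> AT, CCCG -> CG).
    Missing calls stay missing.
    """
    if geno.ploidy != 4:
        raise DataError("diploidize expects a tetraploid genotype matrix")
    d = geno.dosage
    collapsed = np.where(np.isnan(d), np.nan, np.clip(d, None, 1) + (d == 4))
    return GenotypeMatrix(
        ploidy=2,
        markers=geno.markers.copy(),
        samples=list(geno.samples),
        dosage=collapsed,
    )


def encode(dosage, model: str, ploidy: int) -> np.ndarray:
    """Map dosages to gene-action codes (NaN preserved).

    For class models the returned values are class labels, not effect
    sizes; use :func:`design_matrix` to obtain indicator columns.
    """
    valid = models_for_ploidy(ploidy)
    if model not in valid:
        raise DataError(f"model '{model}' undefined for ploidy {ploidy}; valid: {valid}")
    d = np.asarray(dosage, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((d < 0) | (d > ploidy) | (~np.isnan(d) & (d != np.round(d)))):
            raise DataError(f"dosage outside 0..{ploidy}")
    nan = np.isnan(d)

    def masked(values) -> np.ndarray:
        out = np.asarray(values, dtype=float)
        out[nan] = np.nan
        return out

    if model == "additive":
        return d.copy()
    if ploidy == 2:
        if model == "dominant":
            return masked(d == 1)
        return d.copy()  # general: labels are the dosages themselves
    if model == "simplex_dom_alt":
        return masked(d >= 1)
    if model == "simplex_dom_ref":
        return masked(d <= 3)
    if model == "duplex_dom_alt":
        return masked(d >= 2)
    if model == "duplex_dom_ref":
        return masked(d <= 2)
    if model in ("diplo_additive", "diplo_general"):
        return masked(np.clip(d, None, 1) + (d == 4))
    return d.copy()  # general


def design_matrix(dosage, model: str, ploidy: int) -> tuple[np.ndarray, bool]:
    """Design columns for one marker under one gene-action model.

    Returns ``(X, degenerate)`` where ``X`` has shape (n_samples, q) with
    NaN rows at missing dosages.  Scalar models give one column; class
    models give k-1 treatment indicators, dropping the most frequent
    class (ties resolved toward the lower class label).  ``degenerate``
    is True when the encoded values are constant across the non-missing
    samples — the marker is untestable under this model and must not
    count toward that model's number of tested markers.
    """
    codes = encode(dosage, model, ploidy)
    ok = ~np.isnan(codes)
    levels = np.unique(codes[ok])
    if levels.size < 2:
        return codes[:, None].copy(), True
    if model not in CLASS_MODELS:
        return codes[:, None].copy(), False
    counts = {lv: int(np.sum(codes[ok] == lv)) for lv in levels}
    reference = min(levels, key=lambda lv: (-counts[lv], lv))
    others = [lv for lv in levels if lv != reference]
    X = np.full((codes.shape[0], len(others)), np.nan)
    for col, lv in enumerate(others):
        X[ok, col] = (codes[ok] == lv).astype(float)
    return X, False
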