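"""Scoring gene-action models within an engine.

When several gene-action models are scanned, each model M_i receives

    score(M_i) = I_i + R_i + S_i

with an inflation component ``I_i = 1 - |1 - lambda(M_i)|`` (maximal, 1,
exactly at lambda = 1; symmetric penalty on both deflation and
inflation, possibly negative for badly inflated scans), a replication
component R_i counting how many of M_i's top-N markers also appear in
the other models' top-N sets, and a significance component S_i counting
M_i's significant markers.

Both normalizations are ambiguous as stated in words, so they are
switches here:

* ``r_norm="max_rowsum"`` (default): R_i = sum_j |M_i ~ M_j| divided by
  the maximum of that row-sum over models.  Alternative ``"kn"``:
  divide by (k-1) * N, the theoretical maximum.
* ``s_norm="union"`` (default): S_i = #significant(M_i) divided by the
  size of the union of all pairwise top-N intersections.  Alternative
  ``"n_best"``: divide by N.

The diagonal (self-sharing) never enters a row-sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationTable
from .exceptions import DataError

__all__ = ["ModelScore", "shared_counts", "score_models", "select_best_model"]


@dataclass
class ModelScore:
    model: str
    lambda_gc: float
    inflation: float      # I_i = 1 - |1 - lambda|
    replication: float    # R_i in [0, 1]
    significance: float   # S_i >= 0
    total: float

    def as_row(self) -> dict:
        return {
            "model": self.model, "lambda": self.lambda_gc, "I": self.inflation,
            "R": self.replication, "S": self.significance, "score": self.total,
        }


def shared_counts(tables: list[AssociationTable], n_best: int) -> pd.DataFrame:
    """Pairwise |M_i ~ M_j|: overlap of the models' top-N best-ranked sets.

    The diagonal holds the size of each model's own top-N set
    (= min(N, m_tested)).
    """
    if len(tables) < 2:
        raise DataError("shared_counts needs at least 2 models")
    if n_best < 1:
        raise DataError("n_best must be >= 1")
    names = [t.model for t in tables]
    sets = [set(t.best_ranked(n_best)) for t in tables]
    k = len(sets)
    mat = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            mat[i, j] = len(sets[i]) if i == j else len(sets[i] & sets[j])
    return pd.DataFrame(mat, index=names, columns=names)


def score_models(tables: list[AssociationTable], n_best: int,
                 r_norm: str = "max_rowsum", s_norm: str = "union"
                 ) -> tuple[list[ModelScore], str]:
    """Score every gene-action model and return (scores, best model name).

    Best = argmax of the total; ties broken by larger S_i, then by the
    order the tables were given in.
    """
    if not tables:
        raise DataError("score_models needs at least one table")
    if len(tables) == 1:
        t = tables[0]
        inflation = 1.0 - abs(1.0 - t.lambda_gc) if np.isfinite(t.lambda_gc) else 0.0
        only = ModelScore(t.model, t.lambda_gc, inflation, 0.0, 0.0, inflation)
        return [only], t.model
    shared = shared_counts(tables, n_best)
    k = len(tables)
    off = shared.to_numpy().astype(float)
    np.fill_diagonal(off, 0.0)
    rowsums = off.sum(axis=1)
    if r_norm == "max_rowsum":
        r_den = rowsums.max()
    elif r_norm == "kn":
        r_den = float((k - 1) * n_best)
    else:
        raise DataError(f"unknown r_norm '{r_norm}'")
    R = rowsums / r_den if r_den > 0 else np.zeros(k)

    # universe of markers appearing in any pairwise top-N intersection
    sets = [set(t.best_ranked(n_best)) for t in tables]
    shared_union: set[str] = set()
    for i in range(k):
        for j in range(i + 1, k):
            shared_union |= sets[i] & sets[j]
    if s_norm == "union":
        s_den = float(len(shared_union))
    elif s_norm == "n_best":
        s_den = float(n_best)
    else:
        raise DataError(f"unknown s_norm '{s_norm}'")
    scores: list[ModelScore] = []
    for i, t in enumerate(tables):
        lam = t.lambda_gc
        inflation = 1.0 - abs(1.0 - lam) if np.isfinite(lam) else 0.0
        n_sig = len(t.significant_markers())
        S = n_sig / s_den if s_den > 0 else 0.0
        total = inflation + R[i] + S
        scores.append(ModelScore(t.model, lam, inflation, float(R[i]), S, total))
    order = sorted(range(k), key=lambda i: (-scores[i].total, -scores[i].significance, i))
    return scores, scores[order[0]].model


def select_best_model(tables: list[AssociationTable], n_best: int,
                      **kwargs) -> AssociationTable:
    """The table of the best-scoring gene-action model (single table passes through)."""
    if len(tables) == 1:
        return tables[0]
    _, best = score_models(tables, n_best, **kwargs)
    return next(t for t in tables if t.model == best)


def scores_frame(scores: list[ModelScore]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in scores])
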