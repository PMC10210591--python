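"""Analytic hierarchy process ranking of genotypes by immunogenic potential.

The hierarchy has one first-level criterion (immunogenic potential) and two
second-level criteria — per-epitope abundances and per-"type" abundances.
Leaves are individual epitopes (weighted by an external immunogenicity
screening score) and individual amplicon types (weighted uniformly).  For each
leaf, genotypes are compared pairwise: the log2 fold change of their
abundances is mapped onto the Saaty 1-9 scale (``round(|x|)+1`` clamped to 9,
reciprocal for negative x), giving a positive reciprocal matrix whose
principal eigenvector is the per-leaf priority.

Epitopes receive equal or greater weight than types: the epitope-vs-type
comparison takes each Saaty intensity s = 1..9 in favor of the epitopes,
yielding nine global scores per genotype whose mean (+/- standard error)
defines the final ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .epitope_engine import variant_log2fc

__all__ = [
    "log2fc_to_intensity",
    "build_pairwise",
    "priority_vector",
    "score_genotypes",
    "RankingResult",
    "SAATY_RANDOM_INDEX",
]

#: Saaty's random consistency index by matrix order (order 1 and 2 are 0).
SAATY_RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
    8: 1.41, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56,
    14: 1.57, 15: 1.59,
}


def log2fc_to_intensity(x: float) -> float:
    """Map a log2 fold change onto the Saaty scale.

    ``|x|`` is rounded half-up, shifted by one so x=0 gives 1 (equal
    importance), and clamped at 9; negative x returns the reciprocal.
    """
    if not np.isfinite(x):
        raise ValueError("log2FC must be finite (use the eps-protected form)")
    intensity = min(9, int(np.floor(abs(x) + 0.5)) + 1)
    return float(intensity) if x >= 0 else 1.0 / intensity


def build_pairwise(abundances: Sequence[float]) -> np.ndarray:
    """Pairwise Saaty matrix over genotypes for one leaf's abundances."""
    a = np.asarray(abundances, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two genotypes")
    n = a.size
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = log2fc_to_intensity(float(variant_log2fc(a[i], a[j])))
            m[i, j] = v
            m[j, i] = 1.0 / v
    return m


def priority_vector(
    m: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[np.ndarray, float, float]:
    """Principal-eigenvector priorities of a positive reciprocal matrix.

    Power iteration to ``tol``; returns ``(weights, consistency_ratio,
    lambda_max)``.  The consistency ratio is reported, never enforced: CR =
    ((lambda_max - n)/(n - 1)) / RI(n), 0 for n <= 2.
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n) or (m <= 0).any():
        raise ValueError("matrix must be square and positive")
    if not np.allclose(m * m.T, 1.0, rtol=1e-8):
        raise ValueError("matrix must be reciprocal")
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = m @ w
        nxt /= nxt.sum()
        if np.abs(nxt - w).max() < tol:
            w = nxt
            break
        w = nxt
    lambda_max = float(np.mean((m @ w) / w))
    if n <= 2:
        cr = 0.0
    else:
        ri = SAATY_RANDOM_INDEX.get(n, SAATY_RANDOM_INDEX[15])
        cr = ((lambda_max - n) / (n - 1)) / ri
    return w, cr, lambda_max


@dataclass
class RankingResult:
    """Per-genotype scores for the nine epitope-vs-type weight settings."""

    scores: pd.DataFrame       # genotype x s1..s9
    mean: pd.Series
    se: pd.Series              # sample SD of the nine scores / 3
    rank: pd.Series            # 1 = highest immunogenic potential
    consistency: pd.DataFrame  # leaf x CR

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out["mean"] = self.mean
        out["se"] = self.se
        out["rank"] = self.rank
        out.to_csv(path, sep="\t", index_label="genotype")


def _leaf_priorities(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    priorities = {}
    crs = {}
    for leaf in table.columns:
        w, cr, _ = priority_vector(build_pairwise(table[leaf].to_numpy()))
        priorities[leaf] = w
        crs[leaf] = cr
    return (
        pd.DataFrame(priorities, index=table.index),
        pd.Series(crs, dtype=float),
    )


def score_genotypes(
    epitope_table: pd.DataFrame,
    type_table: pd.DataFrame,
    epitope_scores: pd.Series | Mapping[str, float] | None = None,
    epitope_weights: pd.Series | None = None,
    type_weights: pd.Series | None = None,
) -> RankingResult:
    """Nine-setting AHP scores for every genotype.

    ``epitope_table`` / ``type_table`` are genotype x leaf percent tables
    sharing the genotype index.  Epitope leaf weights are proportional to the
    supplied immunogenicity scores (uniform if none); type leaf weights are
    uniform.  Explicit ``epitope_weights`` / ``type_weights`` override both.
    """
    if not epitope_table.index.equals(type_table.index):
        type_table = type_table.reindex(epitope_table.index)
        if type_table.isna().any().any():
            raise ValueError("epitope and type tables disagree on genotypes")
    genotypes = epitope_table.index

    if epitope_weights is None:
        if epitope_scores is None:
            epitope_weights = pd.Series(1.0, index=epitope_table.columns)
        else:
            epitope_weights = pd.Series(epitope_scores).reindex(
                epitope_table.columns
            )
            med = epitope_weights.median()
            epitope_weights = epitope_weights.fillna(1.0 if pd.isna(med) else med)
    epitope_weights = epitope_weights / epitope_weights.sum()
    if type_weights is None:
        type_weights = pd.Series(1.0, index=type_table.columns)
    type_weights = type_weights / type_weights.sum()

    epi_prio, epi_cr = _leaf_priorities(epitope_table)
    typ_prio, typ_cr = _leaf_priorities(type_table)
    epi_component = epi_prio @ epitope_weights.loc[epi_prio.columns]
    typ_component = typ_prio @ type_weights.loc[typ_prio.columns]

    scores = pd.DataFrame(index=genotypes, dtype=float)
    for s in range(1, 10):
        w_epi = s / (s + 1.0)  # priority of the 2x2 branch matrix [[1,s],[1/s,1]]
        scores[f"s{s}"] = w_epi * epi_component + (1.0 - w_epi) * typ_component

    mean = scores.mean(axis=1)
    se = scores.std(axis=1, ddof=1) / 3.0
    rank = mean.rank(ascending=False, method="min").astype(int)
    consistency = pd.concat(
        [epi_cr.rename("cr"), typ_cr.rename("cr")],
        keys=["epitopes", "types"], names=["branch", "leaf"],
    ).to_frame()
    return RankingResult(scores, mean, se, rank, consistency)
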