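"""Group comparisons, correlation-distance clustering, and PCA summaries.

Two-group epitope comparisons (e.g. rye-translocation carriers vs
non-carriers) use Welch's t-test for variables that pass a Shapiro-Wilk
normality screen in both groups and the Mann-Whitney-Wilcoxon test otherwise.
The Mann-Whitney p-value is exact (full enumeration with midrank ties) for
small pooled samples and a tie- and continuity-corrected normal approximation
otherwise.  Raw p-values are reported with a Benjamini-Hochberg column
alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "mann_whitney",
    "welch_t",
    "group_compare",
    "correlation_distance",
    "hcluster",
    "dendrogram_to_newick",
    "pca",
    "PCAResult",
]

_VAR_FLOOR = 1e-12


def mann_whitney(
    a: Sequence[float], b: Sequence[float], exact_limit: int = 12
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)`` with U for group a.

    For pooled sizes up to ``exact_limit`` the null distribution of U is
    enumerated over all group assignments (midranks handle ties); larger
    samples use the normal approximation with tie correction and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 1 or nb < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)
    m = na * nb
    if na + nb <= exact_limit:
        lo, hi = min(u_a, m - u_a), max(u_a, m - u_a)
        n_extreme = 0
        for idx in combinations(range(na + nb), na):
            u = ranks[list(idx)].sum() - na * (na + 1) / 2
            if u <= lo + 1e-9 or u >= hi - 1e-9:
                n_extreme += 1
        p = min(1.0, n_extreme / comb(na + nb, na))
        return u_a, p
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_a, float(res.pvalue)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: ``(t, df, two-sided p)``.

    Variances are floored at 1e-12 so two constant groups with different
    means give a huge |t| and p ~ 0 instead of a division error; constant
    equal groups give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    va = max(a.var(ddof=1), _VAR_FLOOR)
    vb = max(b.var(ddof=1), _VAR_FLOOR)
    sa, sb = va / len(a), vb / len(b)
    denom = np.sqrt(sa + sb)
    t = float((a.mean() - b.mean()) / denom)
    df = float(
        (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    )
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p


def group_compare(
    table: pd.DataFrame,
    groups: pd.Series,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable two-group comparison with automatic test selection.

    ``table`` is genotype x variable; ``groups`` maps genotypes to exactly two
    labels.  A variable is tested by Welch's t when both groups pass
    Shapiro-Wilk at ``normality_alpha`` (and have enough observations),
    otherwise by Mann-Whitney.  Adds a Benjamini-Hochberg adjusted column.
    """
    groups = groups.reindex(table.index)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    rows = []
    for var in table.columns:
        x = table.loc[groups == labels[0], var].dropna().to_numpy()
        y = table.loc[groups == labels[1], var].dropna().to_numpy()
        normal = False
        if len(x) >= 3 and len(y) >= 3 and x.var() > 0 and y.var() > 0:
            normal = (
                sps.shapiro(x).pvalue > normality_alpha
                and sps.shapiro(y).pvalue > normality_alpha
            )
        if normal:
            t, _, p = welch_t(x, y)
            rows.append({"variable": var, "test": "t", "statistic": t, "p_value": p})
        else:
            u, p = mann_whitney(x, y)
            rows.append(
                {"variable": var, "test": "mann-whitney", "statistic": u, "p_value": p}
            )
    out = pd.DataFrame(rows)
    out["p_bh"] = sps.false_discovery_control(out["p_value"], method="bh")
    return out


def correlation_distance(
    matrix: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, list]:
    """Distance ``d = 1 - r`` between columns; returns (distances, flagged).

    ``flagged`` lists zero-variance columns, whose correlations are undefined
    (their distances are left as NaN for the caller to drop or impute).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns")
    flagged = matrix.columns[matrix.std(ddof=0) == 0].tolist()
    d = 1.0 - matrix.corr(method=method)
    np.fill_diagonal(d.values, 0.0)
    return d, flagged


def hcluster(distance: pd.DataFrame, linkage: str = "complete") -> np.ndarray:
    """Agglomerative clustering of a symmetric distance matrix.

    Returns the standard (n-1) x 4 merge table (item, item, height, size).
    Complete linkage is the default, matching heatmap-tool convention;
    ``linkage="average"`` is also supported.
    """
    if linkage not in ("complete", "average"):
        raise ValueError("linkage must be 'complete' or 'average'")
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    return hierarchy.linkage(squareform(d, checks=False), method=linkage)


def dendrogram_to_newick(merges: np.ndarray, labels: Sequence[str]) -> str:
    """Render a merge table as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(merges)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dropped_columns: list


def pca(matrix: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA by SVD of the centered (and by default unit-scaled) matrix.

    Zero-variance columns are dropped with a note in ``dropped_columns``.
    Explained variance fractions sum to 1 over the retained components.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix")
    sd = matrix.std(ddof=0)
    dropped = matrix.columns[sd == 0].tolist()
    x = matrix.drop(columns=dropped)
    centered = x - x.mean()
    if scale:
        centered = centered / x.std(ddof=0)
    u, s, vt = np.linalg.svd(centered.to_numpy(dtype=float), full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    n_pc = len(s)
    pcs = [f"PC{i + 1}" for i in range(n_pc)]
    scores = pd.DataFrame(u * s, index=matrix.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=x.columns, columns=pcs)
    return PCAResult(scores, loadings, ratio, dropped)
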