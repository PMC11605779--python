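"""Community ecology: alpha diversity, Bray–Curtis dissimilarity, and a
permutational multivariate ANOVA (PERMANOVA) on a distance matrix.

The PERMANOVA follows Anderson's partitioning of squared inter-point
distances: with n samples in a groups, the total sum of squares is
SS_T = (1/n)·Σ_{i<j} d_ij², the within-group sum is
SS_W = Σ_groups (1/n_g)·Σ_{i<j in g} d_ij², and the pseudo-F statistic is
F = (SS_A/(a−1)) / (SS_W/(n−a)) with SS_A = SS_T − SS_W.  Significance comes
from freely permuting the group labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "shannon",
    "simpson",
    "bray_curtis",
    "bray_curtis_matrix",
    "PermanovaResult",
    "permanova",
    "alpha_diversity_contrast",
    "collapse_to_rank",
]


def _proportions(counts) -> np.ndarray:
    c = np.asarray(counts, float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("empty sample")
    return c / total


def shannon(counts) -> float:
    """Shannon index H = −Σ pᵢ ln pᵢ (natural log), zero-count taxa ignored."""
    p = _proportions(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Simpson diversity D = 1 − Σ pᵢ² (the Gini–Simpson variant)."""
    p = _proportions(counts)
    return float(1.0 - (p**2).sum())


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) ∈ [0, 1]."""
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    if xv.shape != yv.shape:
        raise ValueError("samples must share the taxon set")
    if np.any(xv < 0) or np.any(yv < 0):
        raise ValueError("negative abundances")
    denom = (xv + yv).sum()
    if denom == 0:
        raise ValueError("both samples are all-zero")
    return float(np.abs(xv - yv).sum() / denom)


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Bray–Curtis distances for a samples x taxa abundance table."""
    d = squareform(pdist(table.to_numpy(float), metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


@dataclass(frozen=True)
class PermanovaResult:
    """PERMANOVA summary: R² is the between-group fraction of total SS."""

    pseudo_f: float
    r_squared: float
    p: float
    n_permutations: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R² from a squared-distance matrix and integer labels."""
    n = d2.shape[0]
    groups = np.unique(labels)
    a = groups.size
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(
    distances,
    grouping,
    n_permutations: int = 9999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """PERMANOVA with free label permutation.

    ``distances`` is a square symmetric zero-diagonal matrix (ndarray or
    DataFrame); ``grouping`` assigns each sample a group label.  The p-value
    is (1 + #{permuted F >= observed F}) / (1 + n_permutations); with
    ``exhaustive=True`` every distinct label permutation is enumerated
    instead and the identity counts once in both numerator and denominator.
    """
    d = np.asarray(distances, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    labels, counts = _encode_labels(grouping)
    if counts.size < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 members each")
    d2 = d**2
    f_obs, r2 = _pseudo_f(d2, labels)

    if exhaustive:
        perms = set(itertools.permutations(labels))
        hits = sum(_pseudo_f(d2, np.asarray(p))[0] >= f_obs - 1e-12 for p in perms)
        return PermanovaResult(f_obs, r2, hits / len(perms), len(perms))

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm)[0] >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(f_obs, r2, p, n_permutations)


def _encode_labels(grouping) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(grouping))
    _, labels = np.unique(arr, return_inverse=True)
    counts = np.bincount(labels)
    return labels, counts


def alpha_diversity_contrast(treatment_alpha, control_alpha) -> tuple[float, float]:
    """Paired t-test of a per-donor alpha-diversity index between arms."""
    t = np.asarray(treatment_alpha, float)
    c = np.asarray(control_alpha, float)
    if t.shape != c.shape or t.size < 2:
        raise ValueError("paired contrast needs >= 2 matched donors")
    if np.all(t == c):
        return 0.0, 1.0
    stat, p = stats.ttest_rel(t, c)
    return float(stat), float(p)


def collapse_to_rank(genus_table: pd.DataFrame, taxonomy: dict) -> pd.DataFrame:
    """Sum a genus-level count table (genera x samples) to a coarser rank via
    a genus -> higher-taxon map."""
    missing = [g for g in genus_table.index if g not in taxonomy]
    if missing:
        raise KeyError(f"taxonomy map lacks genera: {missing[:5]}")
    return genus_table.groupby([taxonomy[g] for g in genus_table.index]).sum()
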