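"""Simplified multi-block discriminant integration and relevance network.

One sparse latent component per block: the loading vector is the covariance
of each (centred, unit-scaled) feature with the centred group indicator,
hard-thresholded to the keepX largest-magnitude entries and renormalised to
unit norm.  This keeps the fixed, tuned sparsity of the full multiblock
sPLS-DA (30 taxa / 3 parent components / 5 catabolites, one component) while
dropping the design-matrix weighting and cross-validated tuning machinery.

Cross-block feature associations are summarised as a relevance network: by
default the similarity-matrix approximation (product of each feature's
correlation with the averaged pair of block scores), with a direct pairwise
Pearson fallback; edges keep |r| above the cutoff (0.6 by default) and never
join features of the same block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metabolome_stats import bh_fdr

__all__ = [
    "DEFAULT_KEEPX",
    "ComponentModel",
    "NetworkEdge",
    "clr_transform",
    "fit_block_component",
    "relevance_network",
    "edge_table",
    "group_contrast_taxa",
]

#: fixed per-block sparsity: taxa / parent components / catabolites
DEFAULT_KEEPX = {"taxa": 30, "parents": 3, "catabolites": 5}


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform, samples in rows.

    log(x + pseudocount) minus the per-sample mean log; each transformed row
    sums to zero, and the result is invariant to per-sample scaling."""
    x = counts.to_numpy(float)
    if np.any(x < 0):
        raise ValueError("negative counts")
    if pseudocount <= 0 and np.any(x == 0):
        raise ValueError("a positive pseudocount is required with zero counts")
    logs = np.log(x + pseudocount)
    out = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


@dataclass
class ComponentModel:
    """One latent component per block: sparse unit-norm loadings and scores."""

    loadings: dict[str, pd.Series] = field(default_factory=dict)
    scores: dict[str, pd.Series] = field(default_factory=dict)
    keepx: dict[str, int] = field(default_factory=dict)

    def selected(self, block: str) -> list:
        w = self.loadings[block]
        return list(w.index[w != 0])


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def fit_block_component(
    blocks: dict[str, pd.DataFrame],
    groups,
    keepx: dict[str, int] | None = None,
    seed: int | None = None,
) -> ComponentModel:
    """Fit the one-component sparse discriminant model.

    ``blocks`` maps block name -> donors x features DataFrame (identical donor
    ordering); ``groups`` is the per-donor two-level label.  ``seed`` is
    accepted for interface stability; the fit itself is deterministic (sign
    fixed so the largest-|loading| feature is positive).
    """
    del seed
    keepx = dict(DEFAULT_KEEPX if keepx is None else keepx)
    y = pd.get_dummies(pd.Series(list(groups))).to_numpy(float)
    if y.shape[1] != 2:
        raise ValueError("exactly two groups are required")
    yv = y[:, 0] - y[:, 0].mean()
    if np.allclose(yv, 0):
        raise ValueError("single-group data")

    model = ComponentModel(keepx=keepx)
    index0 = None
    for name, X in blocks.items():
        if index0 is None:
            index0 = list(X.index)
        elif list(X.index) != index0:
            raise ValueError(f"block {name!r} has a different donor ordering")
        k = keepx.get(name, X.shape[1])
        if k > X.shape[1]:
            raise ValueError(f"keepX={k} exceeds width of block {name!r}")
        Xs = _standardize(X.to_numpy(float))
        w = Xs.T @ yv / (len(yv) - 1)  # covariance with the group indicator
        # hard-threshold to the keepX largest |loadings|
        if k < w.size:
            cut = np.sort(np.abs(w))[-k]
            w[np.abs(w) < cut] = 0.0
            if np.count_nonzero(w) > k:  # ties at the threshold: stable trim
                extra = np.count_nonzero(w) - k
                tied = np.flatnonzero(np.abs(w) == cut)
                w[tied[-extra:]] = 0.0
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(f"block {name!r} has zero covariance with the groups")
        w = w / norm
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        model.loadings[name] = pd.Series(w, index=X.columns)
        model.scores[name] = pd.Series(Xs @ w, index=X.index)
    return model


@dataclass(frozen=True)
class NetworkEdge:
    """A cross-block association retained by the relevance network."""

    block_a: str
    feature_a: str
    block_b: str
    feature_b: str
    r: float

    @property
    def sign(self) -> int:
        return 1 if self.r > 0 else -1


def relevance_network(
    model: ComponentModel,
    blocks: dict[str, pd.DataFrame],
    cutoff: float = 0.6,
    method: str = "similarity",
) -> list[NetworkEdge]:
    """Cross-block edges among the model's selected features with |r| > cutoff.

    ``method="similarity"`` (default) scores a pair as the product of each
    feature's Pearson correlation with the averaged block-score pair — the
    rank-one approximation used by relevance networks; ``method="direct"``
    uses the plain pairwise Pearson correlation between the features.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    names = list(blocks)
    edges: list[NetworkEdge] = []
    for i, a in enumerate(names):
        sel_a = model.selected(a)
        if not sel_a:
            raise ValueError(f"no selected features in block {a!r}")
        for b in names[i + 1 :]:
            sel_b = model.selected(b)
            if method == "similarity":
                t = (model.scores[a] + model.scores[b]) / 2.0
                ca = {f: _pearson(blocks[a][f], t) for f in sel_a}
                cb = {f: _pearson(blocks[b][f], t) for f in sel_b}
                for fa in sel_a:
                    for fb in sel_b:
                        r = ca[fa] * cb[fb]
                        if abs(r) > cutoff:
                            edges.append(NetworkEdge(a, fa, b, fb, r))
            elif method == "direct":
                for fa in sel_a:
                    for fb in sel_b:
                        r = _pearson(blocks[a][fa], blocks[b][fb])
                        if abs(r) > cutoff:
                            edges.append(NetworkEdge(a, fa, b, fb, r))
            else:
                raise ValueError(f"unknown method {method!r}")
    return edges


def _pearson(x, y) -> float:
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1])


def edge_table(edges: list[NetworkEdge]) -> pd.DataFrame:
    """Edge list as a DataFrame ready for delimited output."""
    return pd.DataFrame(
        [
            {
                "block_a": e.block_a,
                "feature_a": e.feature_a,
                "block_b": e.block_b,
                "feature_b": e.feature_b,
                "r": e.r,
            }
            for e in edges
        ],
        columns=["block_a", "feature_a", "block_b", "feature_b", "r"],
    )


def group_contrast_taxa(
    genus_counts: pd.DataFrame,
    groups,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-genus independent t-test on clr abundances between two groups.

    ``genus_counts`` is samples x genera.  All-zero genera are excluded with
    a warning.  Returns a DataFrame with t, p and BH q per genus, sorted by p.
    """
    empty = genus_counts.columns[(genus_counts == 0).all()]
    if len(empty):
        warnings.warn(f"excluding all-zero taxa: {list(empty)}", UserWarning)
        genus_counts = genus_counts.drop(columns=list(empty))
    clr = clr_transform(genus_counts, pseudocount)
    g = np.asarray(list(groups))
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError("exactly two groups are required")
    a = clr[g == levels[0]]
    b = clr[g == levels[1]]
    t_stat, p = stats.ttest_ind(a.to_numpy(), b.to_numpy(), axis=0)
    out = pd.DataFrame({"t": t_stat, "p": p}, index=clr.columns)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p")
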