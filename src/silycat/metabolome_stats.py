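"""Effect statistics on the quantified fermentation metabolome.

Machinery for the NMR metabolite effect table: below-detection imputation,
log10 transform with a uniform increment, paired t-test of treatment vs
control AUCs (with mean pairwise relative change), independent t-test for
group contrasts, and Benjamini–Hochberg q-values computed within each cohort
family (overall, young, elder).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kinetics import auc_trapezoid

__all__ = [
    "EffectResult",
    "impute_below_detection",
    "log10_with_increment",
    "default_increment",
    "paired_effect_test",
    "independent_effect_test",
    "bh_fdr",
    "metabolite_auc",
    "effect_table",
]


def impute_below_detection(m: pd.DataFrame) -> pd.DataFrame:
    """Replace missing (below-detection) entries by one third of the lowest
    recorded concentration anywhere in the matrix."""
    values = m.to_numpy(float)
    if np.all(np.isnan(values)):
        raise ValueError("matrix has no recorded concentrations")
    fill = float(np.nanmin(values)) / 3.0
    return m.fillna(fill)


def default_increment(values) -> float:
    """Uniform increment for the log transform when zeros are present: half
    the smallest positive value (the choice is recorded in run provenance)."""
    v = np.asarray(values, float)
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("no positive values to set an increment from")
    return float(pos.min()) / 2.0


def log10_with_increment(values, increment: float = 0.0):
    """log10(v + increment); increment must be positive when zeros occur."""
    v = np.asarray(values, float)
    if np.any(v < 0):
        raise ValueError("negative values cannot be log-transformed")
    if increment < 0 or (increment == 0 and np.any(v == 0)):
        raise ValueError("a positive increment is required with zero values")
    return np.log10(v + increment)


@dataclass
class EffectResult:
    """Treatment effect on one metabolite: test on log10 AUCs plus the mean
    pairwise relative change (Treatment − Control)/Control × 100."""

    metabolite: str
    n: int
    t_stat: float
    p: float
    relative_change_pct: float
    q: float | None = None
    degenerate: bool = False


def paired_effect_test(
    treatment, control, metabolite: str = "", increment: float = 0.0
) -> EffectResult:
    """Two-sided paired t-test on log10-transformed paired AUCs."""
    T = np.asarray(treatment, float)
    C = np.asarray(control, float)
    if T.shape != C.shape:
        raise ValueError("treatment and control must be paired (equal length)")
    if T.size < 3:
        raise ValueError("paired test needs at least 3 pairs")
    lt = log10_with_increment(T, increment)
    lc = log10_with_increment(C, increment)
    d = lt - lc
    rel = float(np.mean((T - C) / C) * 100.0)
    if np.allclose(d, d[0]):
        # zero variance of differences: p undefined (constant shift), flagged
        return EffectResult(metabolite, T.size, np.inf if d[0] else 0.0, np.nan, rel, degenerate=True)
    t_stat, p = stats.ttest_rel(lt, lc)
    return EffectResult(metabolite, T.size, float(t_stat), float(p), rel)


def independent_effect_test(group_a, group_b, increment: float = 0.0) -> tuple[float, float]:
    """Two-sided two-sample t-test on log10-transformed values; returns (t, p)."""
    a = log10_with_increment(np.asarray(group_a, float), increment)
    b = log10_with_increment(np.asarray(group_b, float), increment)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        raise ValueError("zero pooled variance")
    t_stat, p = stats.ttest_ind(a, b)
    return float(t_stat), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def metabolite_auc(
    metabolites: pd.DataFrame, meta: pd.DataFrame, arm: str
) -> pd.DataFrame:
    """Trapezoidal AUC over the incubation per metabolite and donor, one arm.

    ``metabolites`` is metabolite x well; ``meta`` indexes wells with columns
    donor/arm/timepoint.  Returns metabolite x donor."""
    wells = [c for c in metabolites.columns if c in meta.index]
    m = meta.loc[wells]
    m = m[m["arm"] == arm]
    timepoints = sorted(m["timepoint"].unique())
    t = np.asarray(timepoints, float)
    donors = sorted(m["donor"].unique())
    out = {}
    for donor in donors:
        sel = m[m["donor"] == donor].sort_values("timepoint")
        vals = metabolites[list(sel.index)].to_numpy(float)
        out[donor] = [auc_trapezoid(t, vals[i]) for i in range(vals.shape[0])]
    return pd.DataFrame(out, index=metabolites.index)


def effect_table(
    metabolites: pd.DataFrame,
    meta: pd.DataFrame,
    increment: float | None = None,
) -> pd.DataFrame:
    """Treatment-effect report over AUCs: one row per metabolite, one column
    family per cohort (overall / young / elder), each with p, BH q (computed
    within the family) and mean relative change %.

    ``meta`` must carry ``age_group`` in {young, elder} per well.
    """
    auc_t = metabolite_auc(metabolites, meta, "treatment")
    auc_c = metabolite_auc(metabolites, meta, "control")
    donors = [d for d in auc_t.columns if d in auc_c.columns]
    donor_group = (
        meta.drop_duplicates("donor").set_index("donor")["age_group"].to_dict()
    )
    if increment is None:
        allv = np.concatenate([auc_t.to_numpy().ravel(), auc_c.to_numpy().ravel()])
        increment = 0.0 if np.all(allv > 0) else default_increment(allv)

    families = {
        "overall": donors,
        "young": [d for d in donors if donor_group.get(d) == "young"],
        "elder": [d for d in donors if donor_group.get(d) == "elder"],
    }
    out = pd.DataFrame(index=metabolites.index)
    for fam, cols in families.items():
        if len(cols) < 3:
            warnings.warn(f"cohort {fam!r} has <3 donors; skipped", UserWarning)
            continue
        ps, rels = [], []
        for met in metabolites.index:
            res = paired_effect_test(
                auc_t.loc[met, cols], auc_c.loc[met, cols], met, increment
            )
            ps.append(res.p)
            rels.append(res.relative_change_pct)
        ps = np.asarray(ps)
        qs = np.full_like(ps, np.nan)
        ok = ~np.isnan(ps)
        if ok.any():
            qs[ok] = bh_fdr(ps[ok])
        out[f"p_{fam}"] = ps
        out[f"q_{fam}"] = qs
        out[f"rel_change_pct_{fam}"] = rels
    out.attrs["increment"] = increment
    return out
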