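"""Feature filtering, parent matching and rule-based catabolite annotation.

Replaces manual curation of an aligned LC-MS feature matrix with explicit,
auditable rules: a paired Wilcoxon signed-rank filter per timepoint keeps
features that respond to treatment, features matching a known silymarin
constituent by (m/z, RT) are labelled parents, and the rest are annotated as
catabolites via their mass shift against the flavonolignan reference ion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .chem_masses import (
    DEFAULT_TOLERANCE_DA,
    REFERENCE_MZ,
    MassMatch,
    match_reactions,
    render_formula,
)
from .reference import PARENT_COMPONENTS, ParentComponent

__all__ = [
    "AmbiguousParentError",
    "CataboliteAnnotation",
    "filter_treatment_features",
    "match_parent",
    "name_feature",
    "annotate_catabolites",
    "annotation_table",
]

DEFAULT_MZ_TOL = 0.005  # Da
DEFAULT_RT_TOL = 0.15  # min


class AmbiguousParentError(ValueError):
    """Two parent components are equally consistent with an observed feature."""


def _round_half_up(x: float, ndigits: int) -> str:
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def name_feature(mz: float, rt: float) -> str:
    """Canonical catabolite name: m/z to 3 decimals and RT to 1, joined by '@'.

    Rounding is half-away-from-zero, so (485.1442, 11.25) -> "485.144@11.3".
    """
    if mz <= 0 or rt < 0:
        raise ValueError("m/z must be positive and RT non-negative")
    return f"{_round_half_up(mz, 3)}@{_round_half_up(rt, 1)}"


def _paired_wilcoxon_p(treatment: np.ndarray, control: np.ndarray) -> float:
    """Exact two-sided signed-rank p; zero differences dropped; all-zero -> 1."""
    d = np.asarray(treatment, float) - np.asarray(control, float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tie fallback warns; the fallback is fine
        res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.pvalue)


def filter_treatment_features(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Per-timepoint paired Wilcoxon filter of an LC-MS feature matrix.

    Parameters
    ----------
    features
        One row per feature (index = feature id), columns ``mz``, ``rt``, then
        one intensity column per well named as in ``meta``'s index.
    meta
        One row per well with columns ``donor``, ``arm`` (treatment/control),
        ``timepoint``; index holds the well/column names.
    alpha
        Per-timepoint significance threshold (no multiplicity correction at
        this stage).

    Returns
    -------
    dict with ``per_timepoint`` (timepoint -> list of retained feature ids),
    ``retained`` (features significant at >= 1 timepoint, original order) and
    ``pvalues`` (DataFrame feature x timepoint).
    """
    wells = [c for c in features.columns if c in meta.index]
    if not wells:
        raise ValueError("no feature columns match the metadata well index")
    m = meta.loc[wells]
    timepoints = sorted(m["timepoint"].unique())
    donors = sorted(m["donor"].unique())
    if len(donors) < 6:
        warnings.warn(
            f"only {len(donors)} donor pairs; the exact signed-rank test is degenerate",
            UserWarning,
            stacklevel=2,
        )

    pvals = pd.DataFrame(index=features.index, columns=timepoints, dtype=float)
    for t in timepoints:
        t_wells, c_wells = [], []
        for donor in donors:
            sel = m[(m["donor"] == donor) & (m["timepoint"] == t)]
            tw = sel.index[sel["arm"] == "treatment"]
            cw = sel.index[sel["arm"] == "control"]
            if len(tw) != 1 or len(cw) != 1:
                raise ValueError(f"donor {donor!r} is not paired at timepoint {t}")
            t_wells.append(tw[0])
            c_wells.append(cw[0])
        T = features[t_wells].to_numpy(float)
        C = features[c_wells].to_numpy(float)
        pvals[t] = [_paired_wilcoxon_p(T[i], C[i]) for i in range(len(features))]

    per_tp = {t: list(features.index[pvals[t] < alpha]) for t in timepoints}
    keep_mask = (pvals < alpha).any(axis=1)
    return {
        "per_timepoint": per_tp,
        "retained": list(features.index[keep_mask]),
        "pvalues": pvals,
    }


def match_parent(
    mz: float,
    rt: float,
    parents: tuple[ParentComponent, ...] = PARENT_COMPONENTS,
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> ParentComponent | None:
    """Match a feature to a silymarin parent component by m/z and RT.

    The flavonolignan isomers share m/z 483.1287 and are separated only by
    retention time, so when several parents fall within both tolerances the
    unique nearest one by RT wins (with a warning); an exact RT tie raises
    :class:`AmbiguousParentError` rather than choosing silently.
    """
    candidates = [
        p for p in parents if abs(p.mz - mz) <= mz_tol and abs(p.rt - rt) <= rt_tol
    ]
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    candidates.sort(key=lambda p: abs(p.rt - rt))
    d0, d1 = abs(candidates[0].rt - rt), abs(candidates[1].rt - rt)
    if d0 == d1:
        raise AmbiguousParentError(
            f"feature ({mz}, {rt}) is equidistant from parents "
            f"{candidates[0].name!r} and {candidates[1].name!r}"
        )
    warnings.warn(
        f"feature ({mz}, {rt}) within tolerance of {len(candidates)} parents; "
        f"resolved to nearest-by-RT {candidates[0].name!r}",
        UserWarning,
        stacklevel=2,
    )
    return candidates[0]


@dataclass
class CataboliteAnnotation:
    """A retained non-parent feature with its mass-shift interpretation."""

    feature_id: str
    name: str
    mz: float
    rt: float
    delta: float
    matches: list[MassMatch] = field(default_factory=list)
    formula: str | None = None
    relative_auc: float | None = None
    kinetic_class: str | None = None

    @property
    def reactions(self) -> str:
        if not self.matches:
            return ""
        return self.matches[0].reaction.name


def _ion_loss_gain(match: MassMatch) -> tuple[str, str]:
    """Loss/addition in the protonated-ion convention: a net −CH2 on the
    neutral shows as loss CH3 / addition H on the ion; a pure gain (e.g. +H2)
    has no loss column."""
    loss = dict(match.reaction.loss)
    gain = dict(match.reaction.gain)
    if not loss:
        return "", render_formula(gain)
    loss["H"] = loss.get("H", 0) + 1
    gain["H"] = gain.get("H", 0) + 1
    return render_formula(loss), render_formula(gain)


def annotate_catabolites(
    features: pd.DataFrame,
    retained: list,
    parents: tuple[ParentComponent, ...] = PARENT_COMPONENTS,
    reference_mz: float = REFERENCE_MZ,
    max_steps: int = 2,
    tolerance_da: float = DEFAULT_TOLERANCE_DA,
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> tuple[list[CataboliteAnnotation], dict]:
    """Split retained features into parent assignments and catabolite annotations.

    Returns ``(catabolites, parent_assignments)`` where parent_assignments
    maps feature id -> parent name.  Each catabolite carries its Δm/z against
    ``reference_mz``, the matched reactions (possibly none — some shifts are
    not explainable by short reaction combinations) and its canonical name.
    """
    catabolites: list[CataboliteAnnotation] = []
    parent_hits: dict = {}
    for fid in retained:
        row = features.loc[fid]
        mz, rt = float(row["mz"]), float(row["rt"])
        parent = match_parent(mz, rt, parents, mz_tol=mz_tol, rt_tol=rt_tol)
        if parent is not None:
            parent_hits[fid] = parent.name
            continue
        delta = delta_round(mz - reference_mz)
        matches = match_reactions(
            mz - reference_mz, max_steps=max_steps, tolerance_da=tolerance_da
        )
        catabolites.append(
            CataboliteAnnotation(
                feature_id=fid,
                name=name_feature(mz, rt),
                mz=mz,
                rt=rt,
                delta=delta,
                matches=matches,
            )
        )
    return catabolites, parent_hits


def delta_round(delta: float) -> float:
    """Report a mass shift to 4 decimals (half-away-from-zero)."""
    sign = -1.0 if delta < 0 else 1.0
    return sign * float(_round_half_up(abs(delta), 4))


def annotation_table(catabolites: list[CataboliteAnnotation]) -> pd.DataFrame:
    """Render annotations as a delimited-ready report, ordered by relative AUC
    descending (unranked entries last, by |Δ| ascending)."""
    rows = []
    for c in catabolites:
        loss = addition = ""
        if c.matches:
            loss, addition = _ion_loss_gain(c.matches[0])
        rows.append(
            {
                "name": c.name,
                "mz": c.mz,
                "rt": c.rt,
                "delta_mz": c.delta,
                "formula": c.formula or "",
                "loss": loss,
                "addition": addition,
                "reactions": c.reactions,
                "relative_auc_pct": c.relative_auc,
                "kinetic_class": c.kinetic_class or "",
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            by=["relative_auc_pct", "name"],
            ascending=[False, True],
            na_position="last",
        ).reset_index(drop=True)
    return df
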