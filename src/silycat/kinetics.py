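"""Time-course summarisation: trapezoidal AUC, relative-AUC ranking, and the
transient / early-final / late-final kinetic classifier.

A catabolite is *transient* when its donor-mean intensity peaks mid-incubation
(4 or 8 h) and then declines; otherwise it is a *final* catabolite, called
*early* when first detected at 2 or 4 h and *late* when first detected at
>= 8 h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "KineticClass",
    "auc_trapezoid",
    "relative_auc",
    "classify_kinetics",
    "feature_kinetics",
]

DEFAULT_TIMEPOINTS = (0.0, 2.0, 4.0, 8.0, 24.0)

TRANSIENT_PEAK_HOURS = frozenset({4.0, 8.0})
EARLY_DETECTION_HOURS = frozenset({2.0, 4.0})


def auc_trapezoid(times, values) -> float:
    """Area under a piecewise-linear time course (value·h, trapezoidal rule)."""
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if t.size < 2:
        raise ValueError("AUC needs at least two timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if np.any(v < 0):
        raise ValueError("negative intensities")
    return float(np.trapezoid(v, t))


def relative_auc(aucs: dict) -> dict:
    """Express each entity's AUC as a percentage of the largest one."""
    if not aucs:
        raise ValueError("empty AUC map")
    top = max(aucs.values())
    if top <= 0:
        raise ValueError("all AUCs are zero")
    return {k: 100.0 * v / top for k, v in aucs.items()}


@dataclass(frozen=True)
class KineticClass:
    """Classification of a catabolite time course."""

    label: str  # transient | final_early | final_late | undetected
    t_max: float | None
    t_first_detected: float | None


def classify_kinetics(times, values, detection_threshold: float = 0.0) -> KineticClass:
    """Classify a (donor-mean) catabolite time course.

    Rules: transient when the maximum falls at 4 or 8 h; otherwise final,
    sub-classified early (first detection at 2 or 4 h) or late (first
    detection at >= 8 h).  A tied maximum resolves to the *later* timepoint —
    a transient is defined by a mid-course peak with subsequent decline, so a
    plateau held to the end is not one.  A course never exceeding the
    detection threshold is reported as ``undetected``, not a class.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    detected = v > detection_threshold
    if not detected.any():
        return KineticClass("undetected", None, None)
    vmax = v.max()
    t_max = float(t[v == vmax][-1])  # tie -> later timepoint
    t_first = float(t[detected][0])
    if t_max in TRANSIENT_PEAK_HOURS:
        label = "transient"
    elif t_first in EARLY_DETECTION_HOURS or t_first == 0.0:
        label = "final_early"
    else:
        label = "final_late"
    return KineticClass(label, t_max, t_first)


def feature_kinetics(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    arm: str = "treatment",
    detection_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-feature AUC, relative AUC and kinetic class.

    AUC is computed per donor on the given arm and averaged; classification
    runs on the donor-mean curve.  Returns a DataFrame indexed by feature id
    with columns ``auc``, ``relative_auc_pct``, ``kinetic_class``, ``t_max``,
    ``t_first_detected`` plus per-donor AUC columns ``auc_<donor>``.
    """
    wells = [c for c in features.columns if c in meta.index]
    m = meta.loc[wells]
    m = m[m["arm"] == arm]
    timepoints = sorted(m["timepoint"].unique())
    donors = sorted(m["donor"].unique())

    donor_wells = {}
    for donor in donors:
        sel = m[m["donor"] == donor].sort_values("timepoint")
        if list(sel["timepoint"]) != timepoints:
            raise ValueError(f"donor {donor!r} lacks a complete {arm} time course")
        donor_wells[donor] = list(sel.index)

    t = np.asarray(timepoints, float)
    out = []
    for fid, row in features.iterrows():
        per_donor = {
            donor: auc_trapezoid(t, row[cols].to_numpy(float))
            for donor, cols in donor_wells.items()
        }
        mean_curve = np.mean(
            [row[cols].to_numpy(float) for cols in donor_wells.values()], axis=0
        )
        kc = classify_kinetics(t, mean_curve, detection_threshold)
        rec = {
            "auc": float(np.mean(list(per_donor.values()))),
            "kinetic_class": kc.label,
            "t_max": kc.t_max,
            "t_first_detected": kc.t_first_detected,
        }
        rec.update({f"auc_{d}": a for d, a in per_donor.items()})
        out.append(pd.Series(rec, name=fid))
    result = pd.DataFrame(out)
    if len(result) and result["auc"].max() > 0:
        rel = relative_auc(dict(result["auc"]))
        result.insert(1, "relative_auc_pct", pd.Series(rel))
    else:
        result.insert(1, "relative_auc_pct", np.nan)
    return result
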