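"""Developmental maturity: behavior classification, indices, trajectories.

Each motor domain (vocal, postural, locomotor) contains behaviors whose use
falls with age (immature: cries, righting reflexes, crawling) and behaviors
whose use rises (mature: phees, hindlimb support, walking).  Classification
is empirical: a mixed-effects trend of each behavior's session time share
against postnatal day, Holm-corrected within domain.  The per-session
maturity index m/(m+im) then tracks each domain's immature->mature
transition; penalized smoothing splines over postnatal day give individual
(p=0.03) and population (p=0.01) trajectories, and the transition day is
the earliest sustained 0.5-crossing of the population curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import SmoothingSpline, fit_spline

__all__ = [
    "TrajectoryFit", "category_proportions", "classify_behaviors",
    "maturity_index", "maturity_points", "fit_trajectory", "transition_day",
]

PROPORTION_SUM_TOL = 1e-9


@dataclass
class TrajectoryFit:
    category: str
    level: str                      # "individual" | "population"
    spline: SmoothingSpline
    p: float
    transition_day: float | None = None


def _events_to_category_frame(calls: pd.DataFrame | None,
                              behaviors: pd.DataFrame | None) -> pd.DataFrame:
    """Unify call and behavior tables into (category, behavior, duration)."""
    parts = []
    if calls is not None and len(calls):
        c = calls.copy()
        c["category"] = "vocal"
        c["behavior"] = c["call_type"]
        parts.append(c[["category", "behavior", "onset_s", "offset_s"]])
    if behaviors is not None and len(behaviors):
        parts.append(behaviors[["category", "behavior", "onset_s", "offset_s"]])
    if not parts:
        return pd.DataFrame(columns=["category", "behavior", "onset_s", "offset_s"])
    return pd.concat(parts, ignore_index=True)


def category_proportions(bundles) -> pd.DataFrame:
    """Per session and domain: each behavior's share of scored domain time.

    Overlapping same-category events are summed per behavior without
    de-overlap (convention; flagged by the > 1 + tol check).  Sessions with
    zero scored time in a domain contribute no rows for it.
    """
    rows = []
    for b in bundles:
        ev = _events_to_category_frame(b.calls, b.behaviors)
        if not len(ev):
            continue
        ev = ev.assign(duration=ev["offset_s"] - ev["onset_s"])
        if (ev["duration"] <= 0).any():
            raise ValueError(f"non-positive event interval in session {b.session_id}")
        for category, grp in ev.groupby("category"):
            total = grp["duration"].sum()
            if total <= 0:
                continue
            for behavior, g in grp.groupby("behavior"):
                rows.append({"subject": b.subject, "session": b.session_id,
                             "pnd": b.pnd, "category": category,
                             "behavior": behavior,
                             "proportion": g["duration"].sum() / total})
    return pd.DataFrame(rows, columns=["subject", "session", "pnd", "category",
                                       "behavior", "proportion"])


def classify_behaviors(props: pd.DataFrame, fit_trend=None, alpha=0.05) -> pd.DataFrame:
    """Label each behavior immature / mature / NA from its developmental trend.

    For every behavior, fits proportion ~ day with by-subject day slopes
    (mixed model), Holm-adjusts p-values within each domain, then labels
    mature (slope > 0, adjusted p < alpha), immature (slope < 0, adjusted
    p < alpha), else NA.

    Sessions where the domain was scored but a given behavior never
    occurred contribute an explicit zero proportion for it; omitting those
    zeros would bias every trend toward sessions where the behavior
    happened to appear.
    """
    from . import mixedmodels as mm
    if fit_trend is None:
        fit_trend = mm.fit_proportion_trend

    completed = []
    for category, grp in props.groupby("category"):
        wide = grp.pivot_table(index=["subject", "session", "pnd"],
                               columns="behavior", values="proportion",
                               fill_value=0.0)
        long = wide.reset_index().melt(id_vars=["subject", "session", "pnd"],
                                       var_name="behavior",
                                       value_name="proportion")
        long["category"] = category
        completed.append(long)
    props = pd.concat(completed, ignore_index=True) if completed else props

    rows = []
    for (category, behavior), grp in props.groupby(["category", "behavior"]):
        try:
            beta, se, p = fit_trend(grp)
        except Exception as exc:  # unfittable behavior -> NA with note
            rows.append({"category": category, "behavior": behavior,
                         "beta": np.nan, "se": np.nan, "p_raw": np.nan,
                         "p_adj": np.nan, "classification": "NA",
                         "note": f"model failed: {exc}"})
            continue
        rows.append({"category": category, "behavior": behavior, "beta": beta,
                     "se": se, "p_raw": p, "p_adj": np.nan,
                     "classification": "NA", "note": ""})
    out = pd.DataFrame(rows)
    from .mixedmodels import holm_adjust
    for category, grp in out.groupby("category"):
        ok = grp["p_raw"].notna()
        if ok.any():
            adj = holm_adjust(grp.loc[ok, "p_raw"].to_numpy())
            out.loc[grp.index[ok], "p_adj"] = adj
    sig = out["p_adj"] < alpha
    out.loc[sig & (out["beta"] > 0), "classification"] = "mature"
    out.loc[sig & (out["beta"] < 0), "classification"] = "immature"
    return out


def maturity_index(m_time: float, im_time: float) -> float:
    """m / (m + im); below 0.5 immature behavior dominates the session."""
    if m_time < 0 or im_time < 0:
        raise ValueError("times must be nonnegative")
    total = m_time + im_time
    if total == 0:
        raise ValueError("no immature or mature time: index undefined")
    return m_time / total


def maturity_points(bundles, classification: pd.DataFrame) -> pd.DataFrame:
    """Per-session maturity indices for every domain with scored m/im time.

    ``classification`` is the output of :func:`classify_behaviors`; only
    behaviors labelled immature/mature contribute.  Sessions with zero
    combined time in a domain are skipped (index undefined).
    """
    lab = {(r["category"], r["behavior"]): r["classification"]
           for _, r in classification.iterrows()}
    rows = []
    for b in bundles:
        ev = _events_to_category_frame(b.calls, b.behaviors)
        if not len(ev):
            continue
        ev = ev.assign(duration=ev["offset_s"] - ev["onset_s"])
        for category, grp in ev.groupby("category"):
            m = sum(g["duration"].sum() for beh, g in grp.groupby("behavior")
                    if lab.get((category, beh)) == "mature")
            im = sum(g["duration"].sum() for beh, g in grp.groupby("behavior")
                     if lab.get((category, beh)) == "immature")
            if m + im > 0:
                rows.append({"subject": b.subject, "session": b.session_id,
                             "pnd": b.pnd, "category": category,
                             "index": maturity_index(m, im),
                             "m_time": m, "im_time": im})
    return pd.DataFrame(rows, columns=["subject", "session", "pnd", "category",
                                       "index", "m_time", "im_time"])


def fit_trajectory(points: pd.DataFrame, level="population",
                   p_individual=0.03, p_population=0.01,
                   category="", with_transition=True) -> TrajectoryFit:
    """Smoothing-spline maturity trajectory over postnatal day.

    Individual fits use p=0.03 on one subject's sessions; the population fit
    pools every subject's session points at p=0.01.
    """
    if level not in ("individual", "population"):
        raise ValueError(f"unknown level {level!r}")
    p = p_individual if level == "individual" else p_population
    if len(points) < 4:
        raise ValueError("need at least 4 maturity points")
    spline = fit_spline(points["pnd"].to_numpy(float),
                        points["index"].to_numpy(float), p=p)
    fit = TrajectoryFit(category=category, level=level, spline=spline, p=p)
    if with_transition:
        fit.transition_day = transition_day(fit)
    return fit


def transition_day(fit: TrajectoryFit, lo=1.0, hi=61.0, persist_days=3.0,
                   step=0.05) -> float | None:
    """Earliest day where the trajectory reaches 0.5 and stays there 3 days.

    The persistence guard suppresses noise-driven first crossings.  Returns
    None when the curve never sustains 0.5.
    """
    grid = np.arange(lo, hi + step / 2, step)
    vals = fit.spline(grid)
    above = vals >= 0.5
    k = int(round(persist_days / step))
    for i in range(len(grid)):
        j = min(i + k + 1, len(grid))
        if above[i:j].all():
            return float(grid[i])
    return None
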