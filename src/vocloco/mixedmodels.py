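"""Mixed-effects model suite and Holm multiplicity correction.

Twelve model groups cover the analysis: developmental trends of behavior
time shares (per domain), a logistic model of maturity indices, links from
locomotor activity to call acoustics, call-type contrasts of locomotion and
arousal, early/late age-group contrasts, and the arousal-coordination model
with month-split reruns.  Gaussian models are REML linear mixed models
(statsmodels MixedLM); the logistic maturity model is fit as a gaussian LMM
on the empirical logit of the index weighted implicitly by its definition
(see docs/methods.md) — the tested surface is the sign and approximate
magnitude of fixed effects, not printed p-values, whose denominator-df
method is software-specific.

The nested random structure (x | day/subject) is expressed as day-level
random slopes plus variance components for subject intercepts and slopes
within day; on singular or non-converging fits a simplification ladder is
applied and recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = ["ModelSpec", "build_suite", "fit_model", "holm_adjust",
           "fit_proportion_trend", "EARLY_BIN", "LATE_BIN", "MONTH_BINS"]

EARLY_BIN = (1, 10)     # infant calls transition around day 10
LATE_BIN = (52, 61)
MONTH_BINS = ((1, 30), (31, 61))


@dataclass
class ModelSpec:
    name: str                       # suite label, "1.1" ... "1.12"
    response: str
    fixed: str                      # patsy right-hand side
    random: str                     # "(x|subject)" or "(x|day/subject)" form
    family: str = "gaussian"        # "gaussian" | "binomial-logit"
    subset: dict = field(default_factory=dict)
    splits: tuple = (None,)         # optional pnd-range reruns
    description: str = ""

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed} + {self.random}"


def build_suite() -> list:
    """The twelve model groups, in suite order."""
    return [
        ModelSpec("1.1", "proportion", "pnd", "(pnd|subject)",
                  subset={"category": "vocal"},
                  description="vocal time-share trends per call type"),
        ModelSpec("1.2", "proportion", "pnd", "(pnd|subject)",
                  subset={"category": "postural"},
                  description="postural time-share trends per behavior"),
        ModelSpec("1.3", "proportion", "pnd", "(pnd|subject)",
                  subset={"category": "locomotor"},
                  description="locomotor time-share trends per behavior"),
        ModelSpec("1.4", "index", "category + pnd",
                  "(category|subject) + (pnd|subject)", family="binomial-logit",
                  description="maturity index vs day and domain (logistic)"),
        ModelSpec("1.5", "duration_s", "locomotor_activity",
                  "(locomotor_activity|day/subject)",
                  description="call duration vs locomotion during the call"),
        ModelSpec("1.6", "wiener_entropy", "locomotor_activity",
                  "(locomotor_activity|day/subject)",
                  description="call entropy vs locomotion during the call"),
        ModelSpec("1.7", "locomotor_activity", "call_type",
                  "(call_type|day/subject)",
                  description="locomotion during calls, cry vs phee"),
        ModelSpec("1.8", "locomotor_activity", "age_group",
                  "(age_group|day/subject)",
                  subset={"call_type": "phee", "age_bins": (EARLY_BIN, LATE_BIN)},
                  description="locomotion during mature calls, early vs late"),
        ModelSpec("1.9", "heart_rate", "call_type", "(call_type|day/subject)",
                  description="arousal during calls, cry vs phee"),
        ModelSpec("1.10", "heart_rate", "age_group", "(age_group|day/subject)",
                  subset={"call_type": "phee", "age_bins": (EARLY_BIN, LATE_BIN)},
                  description="arousal during mature calls, early vs late"),
        ModelSpec("1.11", "heart_rate", "age_group", "(age_group|day/subject)",
                  subset={"event": "locomotor", "age_bins": (EARLY_BIN, LATE_BIN)},
                  description="arousal during locomotor bouts, early vs late"),
        ModelSpec("1.12", "heart_rate", "locomotor_activity",
                  "(locomotor_activity|day/subject)",
                  subset={"call_type": "phee"},
                  splits=(None,) + MONTH_BINS,
                  description="arousal vs locomotion during mature calls, "
                              "overall and per month of development"),
    ]


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm-Bonferroni adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _apply_subset(data: pd.DataFrame, spec: ModelSpec, split=None) -> pd.DataFrame:
    d = data
    sub = spec.subset
    for col in ("category", "call_type", "event"):
        if col in sub and col in d.columns:
            d = d[d[col] == sub[col]]
    if "age_bins" in sub:
        (e0, e1), (l0, l1) = sub["age_bins"]
        early = d["pnd"].between(e0, e1)
        late = d["pnd"].between(l0, l1)
        d = d[early | late].copy()
        d["age_group"] = np.where(d["pnd"] <= e1, "early", "late")
    if split is not None:
        d = d[d["pnd"].between(*split)]
    return d


def _empirical_logit(y):
    eps = 0.025
    y = np.clip(np.asarray(y, float), eps, 1 - eps)
    return np.log(y / (1 - y))


def _re_vars(spec: ModelSpec):
    import re as _re
    return [t[0].strip() for t in _re.findall(r"\(([^|]+)\|([^)]+)\)", spec.random)]


def _re_term(spec: ModelSpec):
    vars_ = _re_vars(spec)
    return vars_[0] if vars_ else "1"


def _mixedlm_attempts(spec: ModelSpec, data: pd.DataFrame):
    """Yield (label, fit-callable) down the random-structure ladder."""
    fixed = spec.fixed
    rhs = f"{spec.response} ~ {fixed}" if spec.family == "gaussian" \
        else f"_logit_response ~ {fixed}"
    re_term = "+".join(_re_vars(spec)) or "1"
    re_formula = "~" + re_term
    nested = "day/subject" in spec.random

    def make(groups, re_f, vc):
        def _fit():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = MixedLM.from_formula(rhs, groups=groups, re_formula=re_f,
                                          vc_formula=vc, data=data)
                return md.fit(reml=True, method=["lbfgs", "powell"])
        return _fit

    if nested:
        x = re_term
        slope_vc = {"subj": "0 + C(subject)"}
        if x not in ("1",):
            slope_vc = {"subj": "0 + C(subject)",
                        "subj_slope": f"0 + C(subject):{_vc_term(x, data)}"}
        yield spec.random, make("pnd", re_formula, slope_vc)
        yield "(1|day/subject)", make("pnd", "~1", {"subj": "0 + C(subject)"})
        yield "(1|subject)", make("subject", "~1", None)
    else:
        yield spec.random, make("subject", re_formula, None)
        yield "(1|subject)", make("subject", "~1", None)


def _vc_term(x, data):
    # categorical slopes need explicit coding inside variance components
    if x in data.columns and not pd.api.types.is_numeric_dtype(data[x]):
        return f"C({x})"
    return x


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Fit one model group; one output row per fixed-effect term and split.

    Columns: model_id, split, term, beta, se, stat, p_raw, n_obs,
    converged, fallback_used.  ``p_raw`` uses a normal approximation to the
    t statistic.  Raises ValueError when the data cannot support the model.
    """
    rows = []
    for split in spec.splits:
        d = _apply_subset(data, spec, split).copy()
        d = d.dropna(subset=[spec.response] + [c for c in ("pnd", "subject")
                                               if c in d.columns])
        need = [t for t in ("locomotor_activity", "call_type", "age_group")
                if t in spec.fixed]
        for c in need:
            if c not in d.columns:
                raise ValueError(f"column {c!r} required by model {spec.name} is missing")
            d = d.dropna(subset=[c])
        if d["subject"].nunique() < 2:
            raise ValueError(f"model {spec.name}: need >= 2 subjects, "
                             f"got {d['subject'].nunique()}")
        if spec.family == "binomial-logit":
            d["_logit_response"] = _empirical_logit(d[spec.response])

        # standardize numeric covariates for the variance-parameter search;
        # slopes on raw day scale (~1e-2 per day against unit responses)
        # put the random-slope variance so close to zero that the REML
        # surface is nearly flat and optimizers stall at spurious optima
        scales = {}
        for col in set(spec.fixed.replace("+", " ").split()) | {_re_term(spec)}:
            if col in d.columns and pd.api.types.is_numeric_dtype(d[col]) \
                    and col != spec.response:
                sd = float(d[col].std())
                if sd > 0:
                    d[col] = (d[col] - d[col].mean()) / sd
                    scales[col] = sd

        result, used, err = None, None, None
        for label, attempt in _mixedlm_attempts(spec, d):
            try:
                res = attempt()
                terms = [t for t in res.fe_params.index if t != "Intercept"]
                if np.isfinite(res.fe_params[terms].to_numpy()).all() and \
                        np.isfinite(res.bse.reindex(terms).to_numpy()).all():
                    result, used = res, label
                    break
            except Exception as exc:
                err = exc
        if result is None:
            raise ValueError(f"model {spec.name} unfittable: {err}")

        for term in result.fe_params.index:
            if term == "Intercept":
                continue
            beta = float(result.fe_params[term])
            se = float(result.bse[term])
            if term in scales:  # back to original covariate units
                beta /= scales[term]
                se /= scales[term]
            stat = beta / se if se > 0 else np.nan
            p = 2 * norm.sf(abs(stat)) if np.isfinite(stat) else np.nan
            rows.append({"model_id": spec.name,
                         "split": "" if split is None else f"pnd{split[0]}-{split[1]}",
                         "term": term, "beta": beta, "se": se, "stat": stat,
                         "p_raw": p, "n_obs": int(len(d)),
                         "converged": bool(getattr(result, "converged", True)),
                         "fallback_used": "" if used == spec.random else used})
    return pd.DataFrame(rows)


def fit_proportion_trend(grp: pd.DataFrame):
    """(beta, se, p) of day for one behavior: proportion ~ day + (day|subject)."""
    spec = ModelSpec("trend", "proportion", "pnd", "(pnd|subject)")
    res = fit_model(spec, grp)
    row = res[res["term"] == "pnd"].iloc[0]
    return float(row["beta"]), float(row["se"]), float(row["p_raw"])
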