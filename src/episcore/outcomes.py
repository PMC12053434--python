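"""Epi-score-driven outcome models.

Survival: the epi-infection score (the MMLR-predicted infection-risk value)
enters a Cox proportional-hazards model of time to infection over a 365-day
window, restricted by default to CMV-seropositive subjects as in the study
design.  Day-resolution times guarantee ties; the partial likelihood uses
the Efron approximation (lifelines' default).  The score enters
continuously; Kaplan-Meier display uses a median split.

Moderation: OLS of predicted age (EpiAge) on chronological age, a binary
moderator, and their interaction; a significant interaction means the
moderator changes the epigenetic-aging slope ("age acceleration").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io import ValidationError
from .mmlr import EpiScorePanel

__all__ = [
    "build_survival_table",
    "fit_cox",
    "CoxFit",
    "plot_km_by_score",
    "moderation_analysis",
    "ModerationFit",
]


def build_survival_table(metadata: pd.DataFrame, panel: EpiScorePanel,
                         cmv_filter: bool = True,
                         use_sample: str = "pre") -> pd.DataFrame:
    """One survival record per subject with epi-score covariates.

    Paired samples collapse to one record; the representative epi score is
    the pre-transplant sample's by default (``use_sample='post'`` to switch;
    unpaired subjects use their only sample).  CMV-negative subjects are
    excluded when ``cmv_filter`` is on.  Censoring: subjects uninfected
    through follow-up carry the censoring time with event_observed false.
    """
    if use_sample not in ("pre", "post"):
        raise ValidationError("use_sample must be 'pre' or 'post'")
    meta = metadata.set_index("sample_id", drop=False)
    scores = panel.scores
    rows = []
    for subject, grp in meta.groupby("subject_id", sort=True):
        if cmv_filter and (grp["cmv"] != "positive").all():
            continue
        pick = grp[grp["transplant"] == use_sample]
        rep = pick.iloc[0] if len(pick) else grp.iloc[0]
        time = rep.get("days_to_infection")
        event = rep.get("event_observed") == "yes"
        if pd.isna(time):
            if event:
                raise ValidationError(f"subject {subject!r} has an event but no time")
            continue
        row = {"subject_id": subject, "time": float(time), "event": bool(event),
               "atg": float(rep["atg"] == "yes")}
        sid = rep["sample_id"]
        if sid in scores.index:
            for trait in scores.columns:
                row[f"epi_{trait}"] = float(scores.loc[sid, trait])
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table) and (table["time"] <= 0).any():
        raise ValidationError("survival times must be positive")
    return table


@dataclass
class CoxFit:
    """Per-covariate Cox estimates plus the model log partial likelihood."""

    summary: pd.DataFrame      # index covariate: coef, hr, ci_lower, ci_upper, p
    log_likelihood: float
    score_sd: pd.Series        # covariate SDs, so HRs can be read per-SD


def fit_cox(records: pd.DataFrame, covariates: list[str]) -> CoxFit:
    """Cox proportional hazards on time-to-event records (Efron ties).

    Constant covariates are dropped with a warning (their log-hazard is
    inestimable); no events at all is an error, as is failure to converge
    (complete separation / monotone likelihood surfaces as a lifelines
    ConvergenceError with diagnostics).
    """
    if not records["event"].any():
        raise ValidationError("no observed events; Cox model is not estimable")
    usable = []
    for c in covariates:
        if c not in records.columns:
            raise ValidationError(f"unknown covariate {c!r}")
        if records[c].nunique() <= 1:
            warnings.warn(f"dropping constant covariate {c!r} (inestimable)", stacklevel=2)
        else:
            usable.append(c)
    if not usable:
        raise ValidationError("no non-constant covariates remain")
    df = records[["time", "event", *usable]].astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "ci_lower": np.exp(s["coef lower 95%"]),
        "ci_upper": np.exp(s["coef upper 95%"]),
        "p": s["p"],
    })
    return CoxFit(summary=summary,
                  log_likelihood=float(cph.log_likelihood_),
                  score_sd=df[usable].std())


def plot_km_by_score(records: pd.DataFrame, score: str, split: str = "median",
                     threshold: float | None = None, ax=None):
    """Kaplan-Meier curves for high vs low score strata + log-rank p.

    Returns (per-stratum KM DataFrames, log-rank p, matplotlib axis or None).
    """
    if score not in records.columns:
        raise ValidationError(f"unknown score column {score!r}")
    if split == "median":
        cut = records[score].median()
    elif split == "threshold":
        if threshold is None:
            raise ValidationError("threshold split requires a threshold")
        cut = threshold
    else:
        raise ValidationError("split must be 'median' or 'threshold'")
    hi = records[score] > cut
    if hi.all() or (~hi).all():
        raise ValidationError("empty stratum under the requested split")
    if ax is None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        _, ax = plt.subplots(figsize=(5, 4))
    curves = {}
    for name, mask in (("high", hi), ("low", ~hi)):
        km = KaplanMeierFitter()
        km.fit(records.loc[mask, "time"], records.loc[mask, "event"], label=name)
        curves[name] = km.survival_function_
        km.plot_survival_function(ax=ax)
    ax.set_xlabel("days")
    ax.set_ylabel("infection-free fraction")
    lr = logrank_test(records.loc[hi, "time"], records.loc[~hi, "time"],
                      records.loc[hi, "event"], records.loc[~hi, "event"])
    return curves, float(lr.p_value), ax


@dataclass
class ModerationFit:
    """Age x moderator interaction model of predicted age."""

    coef: pd.Series            # intercept, age, moderator, age:moderator
    interaction_p: float
    slope_moderator0: float
    slope_moderator1: float


def moderation_analysis(epiage, age, moderator) -> ModerationFit:
    """Test whether a binary factor moderates the EpiAge-vs-age slope.

    Fits EpiAge ~ age + moderator + age x moderator by OLS; the two-sided
    t-test on the interaction term is the moderation test.  Per-group slopes
    are implied by the combined model (slope_1 - slope_0 equals the
    interaction coefficient exactly).
    """
    epiage = np.asarray(epiage, dtype=float)
    age = np.asarray(age, dtype=float)
    moderator = np.asarray(moderator, dtype=float)
    if len(epiage) < 6:
        raise ValidationError("moderation analysis needs n >= 6")
    if np.ptp(age) == 0:
        raise ValidationError("age is constant; slope undefined")
    if len(np.unique(moderator)) != 2:
        raise ValidationError("moderator must have both levels")
    X = pd.DataFrame({
        "intercept": 1.0,
        "age": age,
        "moderator": moderator,
        "age:moderator": age * moderator,
    })
    fit = sm.OLS(epiage, X).fit()
    coef = fit.params
    return ModerationFit(
        coef=coef,
        interaction_p=float(fit.pvalues["age:moderator"]),
        slope_moderator0=float(coef["age"]),
        slope_moderator1=float(coef["age"] + coef["age:moderator"]),
    )
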