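"""Behavioral impulsivity scores and the accompanying statistical checks.

The headline behavioral measure is the SbS score: the number of
smaller-but-sooner choices among the 100 non-control trials of a session,
averaged over the three sessions (out of a 100-trial base this count and the
percentage coincide).  The fitted discount rate K is heavy-tailed across
subjects, so parametric tests operate on ln K; a one-sample
Kolmogorov-Smirnov test against a moment-matched normal motivates the
transform.  Control trials feed an exact binomial test for left/right
response bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task_design import StudyDesign

__all__ = [
    "SubjectScore",
    "StatResult",
    "sbs_score",
    "side_bias_test",
    "log_k",
    "ks_normality",
    "pearson",
    "two_sample_t",
]


@dataclass(frozen=True)
class SubjectScore:
    sbs_per_session: tuple[float, ...]
    sbs_mean: float
    log_k: float | None = None


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def sbs_score(choices: pd.DataFrame, design: StudyDesign) -> SubjectScore:
    """Per-session SbS counts over non-control trials and their mean.

    ``choices`` is one subject's ChoiceTable (session, trial, chose_sbs);
    raises listing the trials if any non-control choice is missing.
    """
    design_df = design.to_frame()
    merged = design_df.merge(choices, on=["session", "trial"], how="left", validate="1:1")
    exp = merged[merged["is_control"] == 0]
    bad = exp[pd.isna(exp["chose_sbs"]) | (exp["chose_sbs"] < 0)]
    if len(bad):
        missing = [f"s{int(r.session)}t{int(r.trial)}" for r in bad.itertuples()][:10]
        raise ValueError(f"missing choices on non-control trials: {', '.join(missing)}")
    counts = exp.groupby("session")["chose_sbs"].sum()
    per_session = tuple(float(c) for c in counts)
    return SubjectScore(sbs_per_session=per_session, sbs_mean=float(np.mean(per_session)))


def side_bias_test(control_choices) -> StatResult:
    """Exact two-sided binomial test of left responses on control trials vs 0.5.

    ``control_choices`` is a sequence of sides ('left'/'right') or a
    ChoiceTable restricted to control trials.
    """
    if isinstance(control_choices, pd.DataFrame):
        sides = control_choices["chose_side"].to_numpy()
    else:
        sides = np.asarray(control_choices)
    n = len(sides)
    if n == 0:
        raise ValueError("no control trials to test")
    k = int(np.sum(sides == "left"))
    res = stats.binomtest(k, n, 0.5, alternative="two-sided")
    return StatResult(test_name="exact binomial side bias", statistic=float(k),
                      p_value=float(res.pvalue))


def log_k(K: float) -> float:
    """Natural log of a fitted discount rate; K must be strictly positive."""
    if K <= 0:
        raise ValueError("K must be positive for the log transform")
    return float(np.log(K))


def ks_normality(values) -> StatResult:
    """One-sample KS test against a normal with the sample's mean and SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample has no distribution to test")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return StatResult(test_name="Kolmogorov-Smirnov normality", statistic=float(stat),
                      p_value=float(p))


def pearson(x, y) -> StatResult:
    """Pearson correlation with the t-based two-sided p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return StatResult(test_name="Pearson correlation", statistic=float(r),
                      p_value=float(p), df=float(x.size - 2))


def two_sample_t(a, b, equal_var: bool = True) -> StatResult:
    """Student two-sample t test (e.g. men vs women on a DD parameter)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    if a.std() == 0 and b.std() == 0 and np.mean(a) == np.mean(b):
        return StatResult(test_name="two-sample t", statistic=0.0, p_value=1.0,
                          df=float(a.size + b.size - 2))
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else None
    return StatResult(test_name="two-sample t", statistic=float(t), p_value=float(p),
                      df=float(df) if df is not None else None)
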