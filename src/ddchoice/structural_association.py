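"""Covariate-controlled association battery: DD parameters vs subcortical volumes.

Each cell of the battery is a partial correlation between one behavioral
parameter (SbS score or ln K) and the gray-matter volume of one subcortical
region-hemisphere (caudate, putamen, pallidum, hippocampus, amygdala,
nucleus accumbens; left/right), controlling for whole-brain volume and,
under the default preset, gender and age.  With 6 regions x 2 hemispheres x
2 parameters the battery has 24 tests and the Bonferroni-adjusted critical
p-value is 0.05/24 ~ 0.002.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .behavioral_metrics import StatResult

__all__ = [
    "REGIONS",
    "HEMISPHERES",
    "COVARIATE_PRESETS",
    "partial_correlation",
    "bonferroni_threshold",
    "association_battery",
]

REGIONS = ("caudate", "putamen", "pallidum", "hippocampus", "amygdala", "accumbens")
HEMISPHERES = ("left", "right")

COVARIATE_PRESETS = {
    "wbv": ("whole_brain_volume",),
    "wbv+gender+age": ("whole_brain_volume", "gender", "age"),
}


def partial_correlation(x, y, covariates=None) -> StatResult:
    """Partial Pearson correlation of x and y given a covariate matrix.

    Both variables are residualized on [intercept | covariates] by least
    squares and the residuals correlated; the p-value uses a t reference with
    df = n - 2 - n_covariates.  With no covariates this is the plain Pearson
    correlation.  Rank-deficient covariates raise, naming the collinear
    columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None or (hasattr(covariates, "size") and np.asarray(covariates).size == 0):
        C = np.empty((n, 0))
        names = []
    elif isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        names = [f"c{j}" for j in range(C.shape[1])]
    q = C.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, covariates={q})")

    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [names[j] for j in range(q)
                     if np.linalg.matrix_rank(np.delete(X, j + 1, axis=1)) == rank]
        raise ValueError(f"collinear covariate column(s): {', '.join(collinear) or 'intercept'}")

    coef, *_ = np.linalg.lstsq(X, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - X @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - q
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return StatResult(test_name="partial correlation", statistic=r, p_value=p, df=float(df))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted critical p-value alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha / m


def association_battery(
    volumes: pd.DataFrame,
    scores: pd.DataFrame,
    dd_parameters: tuple[str, ...] = ("sbs_mean", "log_k"),
    covariate_set: str | tuple[str, ...] = "wbv+gender+age",
    alpha: float = 0.05,
    regions: tuple[str, ...] = REGIONS,
) -> tuple[pd.DataFrame, dict]:
    """Run the full region x hemisphere x parameter partial-correlation battery.

    ``volumes`` has one row per subject with columns ``{hemi}_{region}`` in
    mm^3 plus ``whole_brain_volume``, ``age`` and ``gender``; ``scores`` has
    the behavioral parameters.  Tables are inner-joined on ``subject``;
    subjects present in only one table, or with missing volumes, are dropped
    and listed in the join report.  The Bonferroni flag uses m = the number of
    tests actually run.

    Returns the association table and a report dict (n used, dropped
    subjects, covariates, Bonferroni threshold).
    """
    covs = COVARIATE_PRESETS[covariate_set] if isinstance(covariate_set, str) else tuple(covariate_set)
    # demographics/covariates are owned by the volume table; drop duplicates
    # from the score table so the join stays unambiguous
    overlap = [c for c in scores.columns if c != "subject" and c in volumes.columns]
    merged = volumes.merge(scores.drop(columns=overlap), on="subject",
                           how="inner", validate="1:1")
    all_subjects = set(volumes["subject"]) | set(scores["subject"])
    dropped = sorted(all_subjects - set(merged["subject"]))

    needed = [f"{h}_{r}" for r in regions for h in HEMISPHERES] + list(covs) + list(dd_parameters)
    incomplete = merged[merged[needed].isna().any(axis=1)]["subject"].tolist()
    if incomplete:
        dropped += [f"{s} (missing values)" for s in incomplete]
        merged = merged.dropna(subset=needed)

    if merged.empty:
        raise ValueError("no overlapping subjects between volume and score tables")
    if len(merged) < 10:
        raise ValueError(f"only {len(merged)} subjects after join; need >= 10")

    C = merged[list(covs)]
    rows = []
    for region in regions:
        for hemi in HEMISPHERES:
            vol = merged[f"{hemi}_{region}"]
            for param in dd_parameters:
                res = partial_correlation(merged[param], vol, C)
                rows.append({
                    "region": region, "hemisphere": hemi, "dd_parameter": param,
                    "partial_r": res.statistic, "p_value": res.p_value, "df": res.df,
                })
    table = pd.DataFrame(rows)
    threshold = bonferroni_threshold(alpha, len(table))
    table["significant_bonferroni"] = table["p_value"] < threshold
    report = {
        "n_subjects": int(len(merged)),
        "n_tests": int(len(table)),
        "covariates": list(covs),
        "alpha": alpha,
        "bonferroni_threshold": threshold,
        "dropped_subjects": dropped,
    }
    return table, report
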