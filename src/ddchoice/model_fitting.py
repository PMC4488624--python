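"""Per-subject maximum-likelihood estimation and AIC model scoring.

Each subject's non-control choices (pooled over sessions by default) are fit
under both valuation models by minimizing the negative log-likelihood of the
softmax choice rule.  Optimization runs in a transformed space (log K, r,
log beta) because K and beta are positive and heavy-tailed across subjects;
multiple restarts drawn from the cohort priors guard against local optima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .choice_models import MODEL_IDS, PROB_FLOOR, SubjectParams, choice_prob, option_values
from .task_design import StudyDesign

__all__ = ["FitResult", "FitBounds", "nll", "aic", "fit_subject", "fit_cohort"]

N_PARAMS = {"du": 3, "hyp": 2}


@dataclass(frozen=True)
class FitBounds:
    """Box bounds for the ML search, wide enough to bracket observed cohorts
    (K per day, r per euro, beta dimensionless)."""

    k_min: float = 1e-6
    k_max: float = 100.0
    r_min: float = -1.0
    r_max: float = 1.0
    beta_min: float = 1e-3
    beta_max: float = 100.0

    def transformed(self, model_id: str) -> list[tuple[float, float]]:
        b = [(np.log(self.k_min), np.log(self.k_max))]
        if model_id == "du":
            b.append((self.r_min, self.r_max))
        b.append((np.log(self.beta_min), np.log(self.beta_max)))
        return b


@dataclass(frozen=True)
class FitResult:
    params: SubjectParams
    nll: float
    aic: float
    n_trials: int
    n_starts_agreeing: int
    boundary_flag: bool


def _trial_arrays(trials) -> tuple[np.ndarray, ...]:
    """Accept a StudyDesign or a trial DataFrame; return non-control arrays."""
    if isinstance(trials, StudyDesign):
        df = trials.to_frame()
    else:
        df = trials
    df = df[df["is_control"] == 0] if "is_control" in df.columns else df
    return (
        df["small_amount"].to_numpy(dtype=float),
        df["small_delay"].to_numpy(dtype=float),
        df["large_amount"].to_numpy(dtype=float),
        df["large_delay"].to_numpy(dtype=float),
    )


def nll(params: SubjectParams, trials, choices) -> float:
    """Negative log-likelihood (nats) of a 0/1 SbS-choice vector.

    ``trials`` is a StudyDesign or trial table; control trials are excluded
    and the choice vector must align with the remaining trials.
    """
    sa, sd, la, ld = _trial_arrays(trials)
    y = np.asarray(choices, dtype=float)
    if y.shape[0] != sa.shape[0]:
        raise ValueError(
            f"choices length {y.shape[0]} does not match {sa.shape[0]} non-control trials"
        )
    v_s, v_l = option_values(params, sa, sd, la, ld)
    p = choice_prob(v_s, v_l, params.beta)
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def aic(nll_value: float, k: int) -> float:
    """Akaike Information Criterion 2k + 2*NLL (lower is better)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if nll_value < 0:
        raise ValueError("negative log-likelihood cannot be negative")
    return 2.0 * k + 2.0 * nll_value


def _unpack(x: np.ndarray, model_id: str) -> SubjectParams:
    if model_id == "du":
        return SubjectParams(K=float(np.exp(x[0])), r=float(x[1]),
                             beta=float(np.exp(x[2])), model_id="du")
    return SubjectParams(K=float(np.exp(x[0])), beta=float(np.exp(x[1])), model_id="hyp")


def _objective(x, model_id, sa, sd, la, ld, y):
    p = _unpack(x, model_id)
    v_s, v_l = option_values(p, sa, sd, la, ld)
    pr = choice_prob(v_s, v_l, p.beta)
    return -np.sum(y * np.log(pr) + (1.0 - y) * np.log1p(-pr))


def _draw_starts(n_starts: int, model_id: str, bounds: FitBounds,
                 rng: np.random.Generator) -> np.ndarray:
    """First start is a canonical mid-range point; the rest are drawn from the
    cohort priors (log-normal K, normal r, gamma beta), clipped into bounds."""
    tb = np.array(bounds.transformed(model_id))
    starts = np.empty((n_starts, len(tb)))
    log_k = np.concatenate([[np.log(0.03)], rng.normal(np.log(0.03), 1.5, n_starts - 1)])
    log_b = np.concatenate([[np.log(5.0)],
                            np.log(np.maximum(rng.gamma(0.72, 9.74, n_starts - 1), 1e-3))])
    starts[:, 0] = log_k
    if model_id == "du":
        starts[:, 1] = np.concatenate([[0.03], rng.normal(0.03, 0.10, n_starts - 1)])
        starts[:, 2] = log_b
    else:
        starts[:, 1] = log_b
    return np.clip(starts, tb[:, 0], tb[:, 1])


def fit_subject(trials, choices, model_id: str = "du", n_starts: int = 10,
                seed: int = 0, bounds: FitBounds | None = None,
                agree_tol: float = 1e-3) -> FitResult:
    """Best-of-``n_starts`` maximum-likelihood fit of one subject.

    Deterministic given the seed.  ``boundary_flag`` is set when any estimate
    lands within 1e-6 of its (transformed) bound -- e.g. an all-SbS choice
    vector drives K and beta to their upper bounds rather than raising.
    ``n_starts_agreeing`` counts starts ending within ``agree_tol`` nats of
    the best, a cheap convergence diagnostic.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    bounds = bounds or FitBounds()
    sa, sd, la, ld = _trial_arrays(trials)
    y = np.asarray(choices, dtype=float)
    if y.shape[0] != sa.shape[0]:
        raise ValueError("choices do not align with non-control trials")
    if y.shape[0] < 20:
        raise ValueError("need at least 20 non-control trials with choices to fit")

    rng = np.random.default_rng(seed)
    tb = bounds.transformed(model_id)
    starts = _draw_starts(n_starts, model_id, bounds, rng)

    results = []
    for x0 in starts:
        res = minimize(_objective, x0, args=(model_id, sa, sd, la, ld, y),
                       method="L-BFGS-B", bounds=tb)
        if np.isfinite(res.fun):
            results.append(res)
    if not results:
        raise RuntimeError(f"optimizer failed on all {n_starts} starts for model {model_id}")

    best = min(results, key=lambda r: r.fun)
    agreeing = sum(r.fun <= best.fun + agree_tol for r in results)
    at_bound = any(
        abs(xi - lo) < 1e-6 or abs(xi - hi) < 1e-6
        for xi, (lo, hi) in zip(best.x, tb)
    )
    params = _unpack(best.x, model_id)
    best_nll = float(best.fun)
    return FitResult(params=params, nll=best_nll, aic=aic(best_nll, N_PARAMS[model_id]),
                     n_trials=int(y.shape[0]), n_starts_agreeing=int(agreeing),
                     boundary_flag=bool(at_bound))


def fit_cohort(choices: pd.DataFrame, design: StudyDesign,
               models: tuple[str, ...] = MODEL_IDS, n_starts: int = 10,
               seed: int = 0, bounds: FitBounds | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Fit every subject under every model; pooled across sessions.

    ``choices`` is a cohort ChoiceTable (columns subject, session, trial,
    chose_sbs).  Subjects missing a session present in the design are skipped
    and listed in the returned skip report.  Per-(subject, model) fits use
    seeds derived deterministically from ``seed``.

    Returns (fit table, AIC matrix with subjects as rows and models as
    columns, skip report).
    """
    design_df = design.to_frame()
    expected_sessions = set(design_df["session"].unique())
    exp_mask = design_df["is_control"] == 0

    rows, aic_rows, skipped = [], {}, []
    for si, (subj, grp) in enumerate(choices.groupby("subject", sort=True)):
        have = set(grp["session"].unique())
        if have != expected_sessions:
            skipped.append(f"subject {subj}: sessions {sorted(have)} != "
                           f"expected {sorted(expected_sessions)}")
            continue
        merged = design_df.merge(grp, on=["session", "trial"], how="left", validate="1:1")
        sub_trials = merged[exp_mask.to_numpy()]
        y = sub_trials["chose_sbs"].to_numpy()
        if np.any(pd.isna(y)) or np.any(y < 0):
            skipped.append(f"subject {subj}: missing choices on non-control trials")
            continue
        aic_rows[subj] = {}
        for mi, model in enumerate(models):
            fit = fit_subject(sub_trials, y, model_id=model, n_starts=n_starts,
                              seed=int(np.random.SeedSequence([seed, si, mi])
                                       .generate_state(1)[0]) % 2**31,
                              bounds=bounds)
            rows.append({
                "subject": subj, "model": model, "K": fit.params.K,
                "r": fit.params.r if model == "du" else np.nan,
                "beta": fit.params.beta, "nll": fit.nll, "aic": fit.aic,
                "boundary_flag": fit.boundary_flag,
                "n_starts_agreeing": fit.n_starts_agreeing,
            })
            aic_rows[subj][model] = fit.aic

    fit_table = pd.DataFrame(rows)
    aic_matrix = pd.DataFrame.from_dict(aic_rows, orient="index")[list(models)]
    aic_matrix.index.name = "subject"
    return fit_table, aic_matrix, skipped
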