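"""Valuation models and the softmax choice rule for intertemporal choice.

Two per-subject valuation models are implemented:

* discounted utility ("du"): V = (1 - exp(-r*M)) / (r * (1 + K*d)) -- a
  nonlinear utility of amount M (concave for r > 0, convex for r < 0)
  discounted hyperbolically over the delay d,
* standard hyperbolic ("hyp"): V = M / (1 + K*d).

The du model reduces to the hyperbolic one in the r -> 0 limit.  Choice
probabilities come from a binary softmax on the value difference with inverse
temperature beta: P(SbS) = 1 / (1 + exp(-beta * (V_SbS - V_LL))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_design import StudyDesign

__all__ = [
    "SubjectParams",
    "MODEL_IDS",
    "du_value",
    "hyp_value",
    "choice_prob",
    "simulate_choices",
    "PROB_FLOOR",
]

MODEL_IDS = ("du", "hyp")

#: probabilities are clamped to [PROB_FLOOR, 1 - PROB_FLOOR] before any log
PROB_FLOOR = 1e-12

# below this |r| the utility switches to its series expansion M - r M^2/2,
# which is accurate to ~(rM)^2/6 relative error
_R_SERIES_THRESHOLD = 1e-12


@dataclass(frozen=True)
class SubjectParams:
    """Free parameters of one subject under one valuation model.

    K is the discount rate per day (K >= 0), beta the softmax inverse
    temperature (> 0), and r the utility curvature per euro -- present only
    for the discounted-utility model (may be negative).
    """

    K: float
    beta: float
    r: float = 0.0
    model_id: str = "du"

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def _check_domain(amount, delay, K) -> None:
    if np.any(np.asarray(amount) < 0):
        raise ValueError("amount must be non-negative")
    if np.any(np.asarray(delay) < 0):
        raise ValueError("delay must be non-negative")
    if np.any(np.asarray(K) < 0):
        raise ValueError("K must be non-negative")


def du_value(amount, delay, K, r):
    """Discounted-utility value of an option.

    Continuous in r at r = 0, where it equals the hyperbolic value: the
    utility term (1 - e^(-rM))/r is evaluated with expm1 and falls back to the
    two-term series M - r*M^2/2 for |r| below 1e-12.
    """
    _check_domain(amount, delay, K)
    amount = np.asarray(amount, dtype=float)
    r = float(r)
    if abs(r) < _R_SERIES_THRESHOLD:
        utility = amount - r * amount**2 / 2.0
    else:
        utility = -np.expm1(-r * amount) / r
    out = utility / (1.0 + np.asarray(K, dtype=float) * np.asarray(delay, dtype=float))
    return out if out.ndim else float(out)


def hyp_value(amount, delay, K):
    """Standard hyperbolic value M / (1 + K*d)."""
    _check_domain(amount, delay, K)
    out = np.asarray(amount, dtype=float) / (
        1.0 + np.asarray(K, dtype=float) * np.asarray(delay, dtype=float)
    )
    return out if out.ndim else float(out)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # computed on |x| so that sigmoid(x) + sigmoid(-x) == 1 to the last bit
    x = np.asarray(x, dtype=float)
    p_hi = 1.0 / (1.0 + np.exp(-np.abs(x)))
    return np.where(x >= 0, p_hi, 1.0 - p_hi)


def choice_prob(v_sbs, v_ll, beta, clamp: bool = True):
    """Softmax probability of choosing the SbS option.

    Exactly 0.5 at a value tie; complements sum to 1 exactly (also after
    clamping, which is symmetric at PROB_FLOOR).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    p = _sigmoid(beta * (np.asarray(v_sbs, dtype=float) - np.asarray(v_ll, dtype=float)))
    if clamp:
        p = np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)
    return p if p.ndim else float(p)


def option_values(params: SubjectParams, small_amount, small_delay, large_amount, large_delay):
    """Vectorized (V_SbS, V_LL) under the parameter set's model."""
    if params.model_id == "du":
        v_s = du_value(small_amount, small_delay, params.K, params.r)
        v_l = du_value(large_amount, large_delay, params.K, params.r)
    else:
        v_s = hyp_value(small_amount, small_delay, params.K)
        v_l = hyp_value(large_amount, large_delay, params.K)
    return v_s, v_l


def simulate_choices(params: SubjectParams, design: StudyDesign, seed: int = 0) -> pd.DataFrame:
    """Simulate one agent's choices on every trial of a design.

    Non-control trials draw a Bernoulli choice with the softmax probability;
    control trials (identical options) draw the responded side 50/50 and have
    ``chose_sbs`` = -1 (no SbS option exists).  Deterministic given the seed.

    Returns a ChoiceTable with columns session, trial, chose_sbs, chose_side.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for sess in design.sessions:
        df = pd.DataFrame([t.__dict__ for t in sess.trials])
        is_ctrl = df["is_control"].to_numpy(dtype=bool)
        chose_sbs = np.full(len(df), -1, dtype=int)
        chose_side = np.empty(len(df), dtype=object)

        exp = df[~is_ctrl]
        v_s, v_l = option_values(
            params,
            exp["small_amount"].to_numpy(), exp["small_delay"].to_numpy(),
            exp["large_amount"].to_numpy(), exp["large_delay"].to_numpy(),
        )
        p = choice_prob(v_s, v_l, params.beta)
        took_sbs = rng.random(len(exp)) < p
        chose_sbs[~is_ctrl] = took_sbs.astype(int)
        sbs_side = exp["sbs_side"].to_numpy()
        other = np.where(sbs_side == "left", "right", "left")
        chose_side[~is_ctrl] = np.where(took_sbs, sbs_side, other)

        chose_side[is_ctrl] = np.where(rng.random(int(is_ctrl.sum())) < 0.5, "left", "right")

        frames.append(pd.DataFrame({
            "session": sess.session_index,
            "trial": np.arange(1, len(df) + 1),
            "chose_sbs": chose_sbs,
            "chose_side": chose_side,
        }))
    return pd.concat(frames, ignore_index=True)
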