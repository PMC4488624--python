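"""Random-effects Bayesian model selection (BMS) over per-subject evidences.

Treats the identity of the data-generating model as a random effect across
subjects: model frequencies in the population carry a Dirichlet prior
Dir(alpha0), and a variational-Bayes fixed point yields the Dirichlet
posterior Dir(alpha).  The posterior model probability phi_k = alpha_k /
sum(alpha) is the expected population frequency of model k; the exceedance
probability is the posterior probability that model k is the most frequent.

Per-subject log-evidences are approximated from AIC scores as -AIC/2 (the
usual information-criterion evidence convention).

Variational update, iterated to convergence:

    u_nk  ∝  exp(L_nk + psi(alpha_k) - psi(sum alpha))   (row-normalized)
    alpha = alpha0 + sum_n u_n
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma
from scipy.stats import beta as beta_dist

__all__ = ["BMSResult", "aic_to_log_evidence", "rfx_bms", "exceedance_prob"]


@dataclass(frozen=True)
class BMSResult:
    models: tuple[str, ...]
    alpha: np.ndarray          # Dirichlet concentration per model
    phi: np.ndarray            # posterior model probability alpha / sum(alpha)
    exceedance: np.ndarray     # P(model k most frequent in the population)
    n_iterations: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "alpha": [float(a) for a in self.alpha],
            "phi": [float(p) for p in self.phi],
            "exceedance": [float(e) for e in self.exceedance],
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


def aic_to_log_evidence(aic_matrix: pd.DataFrame | np.ndarray):
    """Element-wise -AIC/2; raises on NaN, naming the offending cell."""
    if isinstance(aic_matrix, pd.DataFrame):
        if aic_matrix.isna().any().any():
            sub = aic_matrix.stack(future_stack=True)
            subj, model = sub.index[sub.isna()][0]
            raise ValueError(f"AIC matrix has NaN for subject {subj}, model {model}")
        return -aic_matrix / 2.0
    arr = np.asarray(aic_matrix, dtype=float)
    if np.isnan(arr).any():
        n, m = np.argwhere(np.isnan(arr))[0]
        raise ValueError(f"AIC matrix has NaN at subject index {n}, model index {m}")
    return -arr / 2.0


def rfx_bms(log_evidence, alpha0=1.0, tol: float = 1e-6, max_iter: int = 1000,
            exceedance_samples: int = 1_000_000, seed: int = 0) -> BMSResult:
    """Variational random-effects BMS on a subjects x models log-evidence matrix.

    ``alpha0`` is the Dirichlet prior concentration (scalar broadcast or one
    per model; default uniform 1).  Iterates the fixed point until
    max|delta alpha| < tol; if ``max_iter`` is reached the result is returned
    with ``converged=False``.  Per-subject weights are row-shift invariant:
    adding a constant to one subject's log-evidence row changes nothing.
    """
    if isinstance(log_evidence, pd.DataFrame):
        models = tuple(str(c) for c in log_evidence.columns)
        L = log_evidence.to_numpy(dtype=float)
    else:
        L = np.asarray(log_evidence, dtype=float)
        models = tuple(f"m{k}" for k in range(L.shape[1]))
    if L.ndim != 2 or L.shape[0] < 1 or L.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 1 subject and >= 2 models")

    n, K = L.shape
    alpha0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (K,)).copy()
    if np.any(alpha0 <= 0):
        raise ValueError("alpha0 must be positive")

    alpha = alpha0.copy()
    converged = False
    for it in range(1, max_iter + 1):
        log_u = L + digamma(alpha) - digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new

    phi = alpha / alpha.sum()
    xp = exceedance_prob(alpha, n_samples=exceedance_samples, seed=seed)
    return BMSResult(models=models, alpha=alpha, phi=phi, exceedance=xp,
                     n_iterations=it, converged=converged)


def exceedance_prob(alpha, n_samples: int = 1_000_000, seed: int = 0) -> np.ndarray:
    """P(model k has the largest population frequency) under Dir(alpha).

    For two models this is exact via the Beta CDF at 1/2; for three or more it
    is a Monte-Carlo estimate over Dirichlet samples (``n_samples`` >= 1000).
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    if alpha.size == 2:
        p1 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        return np.array([p1, 1.0 - p1])
    if n_samples < 1000:
        raise ValueError("Monte-Carlo exceedance needs n_samples >= 1000")
    rng = np.random.default_rng(seed)
    # sample Dirichlet via normalized gammas, count arg-max wins per model
    g = rng.gamma(alpha, size=(int(n_samples), alpha.size))
    wins = np.bincount(np.argmax(g, axis=1), minlength=alpha.size)
    return wins / wins.sum()
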