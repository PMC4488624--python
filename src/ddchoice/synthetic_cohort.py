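"""Ground-truth agent cohorts and matched region-volume tables.

The behavioral/MRI dataset this pipeline targets is not publicly deposited,
so this module generates a synthetic stand-in cohort whose marginals match
the reported descriptives: 70 subjects (51 women, 19 men, ages 19-44),
discount rates K log-normal around a median of 0.03/day (heavy right tail),
utility curvature r ~ N(0.03, 0.10) truncated to [-0.25, 0.5], and softmax
inverse temperatures beta gamma-distributed with mean 7.04 and SD 8.28.

Volume tables mimic Freesurfer subcortical segmentations: every region scales
with whole-brain volume plus noise, and a configurable association between
bilateral caudate volume and the SbS score can be planted with a chosen
expected partial correlation (given whole-brain volume, gender and age).

All CSVs written from here carry a ground-truth banner column; the truth
table is never an input to fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .choice_models import SubjectParams, simulate_choices
from .task_design import StudyDesign

__all__ = [
    "CohortConfig",
    "sample_cohort",
    "generate_cohort_choices",
    "generate_volumes",
    "child_seed",
]

# per-hemisphere mean gray-matter volumes (mm^3), typical adult aseg magnitudes
REGION_MEAN_MM3 = {
    "caudate": 3700.0,
    "putamen": 5500.0,
    "pallidum": 1800.0,
    "hippocampus": 4200.0,
    "amygdala": 1700.0,
    "accumbens": 600.0,
}
WBV_MEAN_MM3 = 1.15e6
WBV_SD_MM3 = 1.1e5


def child_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-component seed fan-out from one master seed."""
    return int(np.random.SeedSequence([master_seed, *key]).generate_state(1)[0]) % 2**31


@dataclass
class CohortConfig:
    """Population parameters of the synthetic cohort (defaults match the
    reported study descriptives)."""

    n_subjects: int = 70
    n_female: int | None = None          # default: 51/70 of the cohort
    log_k_loc: float = float(np.log(0.03))   # log-normal median 0.03 per day
    log_k_scale: float = 1.5
    r_mean: float = 0.03                 # per euro
    r_sd: float = 0.10
    r_bounds: tuple[float, float] = (-0.25, 0.5)
    beta_mean: float = 7.04
    beta_sd: float = 8.28
    age_range: tuple[float, float] = (19.0, 44.0)
    volume_noise_frac: float = 0.06      # region noise SD as fraction of mean
    planted_effect_r: float = 0.3        # caudate-SbS partial correlation
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.log_k_scale <= 0 or self.r_sd <= 0 or self.beta_sd <= 0:
            raise ValueError("distribution scales must be positive")
        if not abs(self.planted_effect_r) < 1.0:
            raise ValueError("planted effect |r| must be < 1")


def sample_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Draw ground-truth (K, r, beta, age, gender) for every subject.

    K is log-normal, r truncated-normal, beta gamma with moment-matched
    shape/scale.  Gender is coded 0 = female, 1 = male with a fixed 51:19
    split (scaled for other cohort sizes).  Deterministic given config.seed.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    K = np.exp(rng.normal(cfg.log_k_loc, cfg.log_k_scale, n))
    lo, hi = cfg.r_bounds
    a, b = (lo - cfg.r_mean) / cfg.r_sd, (hi - cfg.r_mean) / cfg.r_sd
    r = stats.truncnorm.rvs(a, b, loc=cfg.r_mean, scale=cfg.r_sd, size=n, random_state=rng)
    shape = (cfg.beta_mean / cfg.beta_sd) ** 2
    scale = cfg.beta_sd**2 / cfg.beta_mean
    beta = np.maximum(rng.gamma(shape, scale, n), 1e-3)
    age = rng.uniform(*cfg.age_range, n)
    n_female = cfg.n_female if cfg.n_female is not None else int(round(n * 51 / 70))
    gender = rng.permutation(np.repeat([0, 1], [n_female, n - n_female]))

    return pd.DataFrame({
        "subject": [f"s{i:03d}" for i in range(1, n + 1)],
        "K": K, "r": r, "beta": beta,
        "age": age, "gender": gender,
        "ground_truth": "yes — not an input to fitting",
    })


def generate_cohort_choices(truth: pd.DataFrame, design: StudyDesign,
                            generating_model: str = "du", seed: int = 0) -> pd.DataFrame:
    """Forward-simulate the whole cohort's ChoiceTable under one model.

    The du model uses each subject's true r; the hyperbolic model ignores it.
    Per-subject seeds fan out deterministically from ``seed``.
    """
    if generating_model not in ("du", "hyp"):
        raise ValueError(f"unknown generating model {generating_model!r}")
    frames = []
    for i, row in enumerate(truth.itertuples(index=False)):
        params = SubjectParams(
            K=float(row.K), beta=float(row.beta),
            r=float(row.r) if generating_model == "du" else 0.0,
            model_id=generating_model,
        )
        tbl = simulate_choices(params, design, seed=child_seed(seed, i))
        tbl.insert(0, "subject", row.subject)
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)


def generate_volumes(scores: pd.DataFrame, effect_target_r: float | None = None,
                     seed: int = 0, noise_frac: float = 0.06,
                     effect_parameter: str = "sbs_mean") -> pd.DataFrame:
    """Synthetic Freesurfer-style volume table with a planted caudate effect.

    ``scores`` needs columns subject, ``effect_parameter``, age, gender.
    Whole-brain volume is drawn first; each region-hemisphere volume is the
    region's population mean scaled by relative brain size plus Gaussian
    noise.  Bilateral caudate volumes additionally receive a component along
    the covariate-residualized (whole-brain volume, gender, age) and
    standardized score, with slope c = sigma * rho / sqrt(1 - rho^2) so the
    expected partial correlation equals ``effect_target_r``.
    """
    rho = 0.0 if effect_target_r is None else float(effect_target_r)
    if not abs(rho) < 1.0:
        raise ValueError("effect_target_r must satisfy |r| < 1")
    rng = np.random.default_rng(seed)
    n = len(scores)

    wbv = rng.normal(WBV_MEAN_MM3, WBV_SD_MM3, n)
    wbv = np.maximum(wbv, 0.5 * WBV_MEAN_MM3)

    X = np.column_stack([np.ones(n), wbv, scores["gender"].to_numpy(dtype=float),
                         scores["age"].to_numpy(dtype=float)])
    s = scores[effect_parameter].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, s, rcond=None)
    z = s - X @ coef
    sd_z = z.std()
    if sd_z == 0:
        raise ValueError(f"{effect_parameter} has no variance beyond the covariates; "
                         "cannot plant an effect")
    z = z / sd_z

    out = {"subject": scores["subject"].to_numpy(), "whole_brain_volume": wbv,
           "age": scores["age"].to_numpy(), "gender": scores["gender"].to_numpy()}
    rel = wbv / WBV_MEAN_MM3
    for region, mean in REGION_MEAN_MM3.items():
        sigma = noise_frac * mean
        slope = sigma * rho / np.sqrt(1.0 - rho * rho) if region == "caudate" else 0.0
        for hemi in ("left", "right"):
            vol = mean * rel + slope * z + rng.normal(0.0, sigma, n)
            out[f"{hemi}_{region}"] = np.maximum(vol, 1.0)
    return pd.DataFrame(out)
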