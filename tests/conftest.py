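import numpy as np
import pandas as pd
import pytest

import ddchoice as dc


@pytest.fixture(scope="session")
def default_design():
    """Default 3-session design, seed 0."""
    return dc.generate_study(seed=0)


@pytest.fixture(scope="session")
def design_frame(default_design):
    return default_design.to_frame()


@pytest.fixture(scope="session")
def exp_trials(design_frame):
    """Non-control trials of the default design, in table order."""
    return design_frame[design_frame["is_control"] == 0]


def aligned_choices(choices: pd.DataFrame, exp_trials: pd.DataFrame) -> np.ndarray:
    """Choice vector aligned with the non-control trial rows."""
    merged = exp_trials.merge(choices, on=["session", "trial"], how="left")
    return merged["chose_sbs"].to_numpy()


@pytest.fixture(scope="session")
def default_cohort():
    """Ground truth and simulated choices of the all-defaults cohort
    (70 du agents on the default design, every seed at its default 0)."""
    design = dc.generate_study(seed=0)
    truth = dc.sample_cohort(dc.CohortConfig())
    choices = dc.generate_cohort_choices(truth, design, "du", seed=0)
    return design, truth, choices


@pytest.fixture(scope="session")
def default_cohort_fit(default_cohort):
    """Both-model ML fits and the AIC matrix of the default cohort.

    Shared session-wide: this is the expensive fixture (70 subjects x 2
    models x 10 starts)."""
    design, truth, choices = default_cohort
    fit_table, aic_matrix, skipped = dc.fit_cohort(choices, design, seed=0)
    assert not skipped
    return design, truth, choices, fit_table, aic_matrix


@pytest.fixture()
def surrogate_scores():
    """Factory for score tables with realistic marginals and no built-in
    score-volume link (for volume-generator calibration)."""
    def make(n: int, rng: np.random.Generator) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": [f"s{i:03d}" for i in range(n)],
            "sbs_mean": np.clip(rng.normal(38.17, 19.08, n), 0, 100),
            "log_k": rng.normal(np.log(0.03), 1.5, n),
            "age": rng.uniform(19, 44, n),
            "gender": (rng.random(n) < 19 / 70).astype(int),
        })
    return make
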