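"""Construction and validation of the three-session delay-discounting task.

Each session presents binary choices between a smaller-but-sooner (SbS)
monetary option (delay at most two weeks) and a larger-but-later (LL) option
(delay at most one year).  A session holds 110 trials, of which 10 are control
trials showing the same option on both sides of the screen (a probe for
left/right response bias).  The mean SbS/LL amount and delay of the
experimental trials are matched across the three sessions so that sessions are
interchangeable stimulus sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "Session",
    "StudyDesign",
    "DesignConfig",
    "ValidationReport",
    "generate_study",
    "validate_design",
    "read_trials",
    "write_trials",
]

SBS_DELAY_MAX = 14  # days; "maximum time delay of 2 weeks"
LL_DELAY_MAX = 365  # days; "maximum time delay of 1 year"

TRIAL_COLUMNS = [
    "subject",
    "session",
    "trial",
    "small_amount",
    "small_delay",
    "large_amount",
    "large_delay",
    "is_control",
    "sbs_side",
]


@dataclass(frozen=True)
class Trial:
    """One intertemporal choice: amounts in euro, delays in days.

    Control trials display the identical option on both sides, so
    ``small_* == large_*``.  ``sbs_side`` records which side of the screen the
    SbS option occupied ('left' or 'right').
    """

    small_amount: float
    small_delay: float
    large_amount: float
    large_delay: float
    is_control: bool = False
    sbs_side: str = "left"


@dataclass
class Session:
    trials: list[Trial]
    session_index: int

    @property
    def experimental(self) -> list[Trial]:
        return [t for t in self.trials if not t.is_control]

    @property
    def controls(self) -> list[Trial]:
        return [t for t in self.trials if t.is_control]


@dataclass
class StudyDesign:
    sessions: list[Session]
    matching_report: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sessions:
            for i, t in enumerate(s.trials, start=1):
                rows.append(
                    (0, s.session_index, i, t.small_amount, t.small_delay,
                     t.large_amount, t.large_delay, int(t.is_control), t.sbs_side)
                )
        return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@dataclass
class DesignConfig:
    """Tunable task-structure parameters.

    Amount/delay defaults span the canonical stimuli of this task family
    ("3 EUR now or 10 EUR in 5 days", "5 EUR in 2 weeks or 15 EUR in 7
    months"): SbS amounts are whole euro in [1, 15], LL amounts multiply the
    SbS amount by 1.5-5x (rounded to whole euro), SbS delays cover 0-14 days
    (0 = immediately) and LL delays 15-365 days.
    """

    n_sessions: int = 3
    n_trials: int = 110
    n_control: int = 10
    sbs_amount_min: int = 1
    sbs_amount_max: int = 15
    ll_mult_min: float = 1.5
    ll_mult_max: float = 5.0
    sbs_delay_min: int = 0
    sbs_delay_max: int = SBS_DELAY_MAX
    ll_delay_min: int = 15
    ll_delay_max: int = LL_DELAY_MAX
    amount_tolerance: float = 0.5   # EUR, cross-session matching of mean amounts
    delay_tolerance: float = 2.0    # days, cross-session matching of mean delays
    max_attempts: int = 1000

    def validate(self) -> None:
        if self.n_control > self.n_trials:
            raise ValueError("n_control must not exceed n_trials")
        if self.sbs_amount_min <= 0 or self.ll_mult_min <= 1.0:
            raise ValueError("amounts must be positive and LL multiplier > 1")
        if self.sbs_delay_min < 0 or self.ll_delay_min <= self.sbs_delay_max:
            raise ValueError("LL delays must strictly exceed all SbS delays")
        if self.n_sessions < 1 or self.n_trials < 1:
            raise ValueError("need at least one session and one trial")


class MatchingError(RuntimeError):
    """Raised when cross-session matching cannot be achieved."""


def _balanced_sides(n: int, rng: np.random.Generator) -> np.ndarray:
    sides = np.array(["left", "right"]).repeat([(n + 1) // 2, n // 2])
    rng.shuffle(sides)
    return sides


def _sample_experimental(cfg: DesignConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_trials - cfg.n_control
    sa = rng.integers(cfg.sbs_amount_min, cfg.sbs_amount_max + 1, size=n)
    mult = rng.uniform(cfg.ll_mult_min, cfg.ll_mult_max, size=n)
    la = np.maximum(sa + 1, np.rint(sa * mult)).astype(int)
    sd = rng.integers(cfg.sbs_delay_min, cfg.sbs_delay_max + 1, size=n)
    ld = rng.integers(cfg.ll_delay_min, cfg.ll_delay_max + 1, size=n)
    return pd.DataFrame(
        {"small_amount": sa, "small_delay": sd, "large_amount": la, "large_delay": ld}
    )


def _means(df: pd.DataFrame) -> np.ndarray:
    return df[["small_amount", "large_amount", "small_delay", "large_delay"]].mean().to_numpy()


_MEAN_NAMES = ("mean SbS amount", "mean LL amount", "mean SbS delay", "mean LL delay")


def generate_study(config: DesignConfig | None = None, seed: int = 0) -> StudyDesign:
    """Generate a matched multi-session design, deterministically for a seed.

    Matching is enforced by rejection sampling: a candidate session's four
    experimental-trial means (SbS/LL amount and delay) must lie within the
    configured tolerances of every previously accepted session.  Raises
    :class:`MatchingError` naming the worst-violating mean if ``max_attempts``
    candidates are exhausted.
    """
    cfg = config or DesignConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    tol = np.array([cfg.amount_tolerance, cfg.amount_tolerance,
                    cfg.delay_tolerance, cfg.delay_tolerance])

    accepted: list[pd.DataFrame] = []
    for _ in range(cfg.n_sessions):
        for attempt in range(cfg.max_attempts):
            cand = _sample_experimental(cfg, rng)
            diffs = np.array([np.abs(_means(cand) - _means(prev)) for prev in accepted])
            if not accepted or np.all(diffs < tol):
                accepted.append(cand)
                break
        else:
            worst = int(np.argmax((diffs / tol).max(axis=0)))
            raise MatchingError(
                f"could not match {_MEAN_NAMES[worst]} across sessions within "
                f"tolerance after {cfg.max_attempts} attempts"
            )

    sessions = []
    for idx, exp in enumerate(accepted, start=1):
        sides = _balanced_sides(len(exp), rng)
        trials = [
            Trial(float(r.small_amount), float(r.small_delay),
                  float(r.large_amount), float(r.large_delay), False, side)
            for r, side in zip(exp.itertuples(index=False), sides)
        ]
        # control trials duplicate a random experimental trial's SbS option
        ctrl_src = rng.integers(0, len(trials), size=cfg.n_control)
        ctrl_sides = _balanced_sides(cfg.n_control, rng)
        for j, side in zip(ctrl_src, ctrl_sides):
            src = trials[j]
            trials.append(Trial(src.small_amount, src.small_delay,
                                src.small_amount, src.small_delay, True, str(side)))
        order = rng.permutation(len(trials))
        trials = [trials[i] for i in order]
        sessions.append(Session(trials=trials, session_index=idx))

    report = pd.DataFrame(
        [_means(exp) for exp in accepted],
        columns=list(_MEAN_NAMES),
        index=pd.Index(range(1, cfg.n_sessions + 1), name="session"),
    )
    return StudyDesign(sessions=sessions, matching_report=report)


@dataclass
class ValidationReport:
    checks: pd.DataFrame  # columns: check, session, passed, measured

    @property
    def all_passed(self) -> bool:
        return bool(self.checks["passed"].all())

    def failed(self) -> pd.DataFrame:
        return self.checks[~self.checks["passed"]]


def validate_design(
    design: StudyDesign,
    amount_tolerance: float = 0.5,
    delay_tolerance: float = 2.0,
    expected_trials: int | None = None,
    expected_control: int | None = None,
    side_balance_tolerance: int = 10,
) -> ValidationReport:
    """Check every structural invariant and return a per-check report.

    Expected per-session counts default to those of the first session, so a
    design that is merely internally inconsistent is still caught.
    """
    if not design.sessions:
        raise ValueError("design has no sessions")
    n_expected = expected_trials if expected_trials is not None else len(design.sessions[0].trials)
    c_expected = expected_control if expected_control is not None else len(design.sessions[0].controls)

    rows: list[tuple] = []
    for s in design.sessions:
        rows.append(("trial_count", s.session_index,
                     len(s.trials) == n_expected, float(len(s.trials))))
        rows.append(("control_count", s.session_index,
                     len(s.controls) == c_expected, float(len(s.controls))))
        exp = s.experimental
        dominance = all(t.large_amount > t.small_amount and t.large_delay > t.small_delay
                        for t in exp)
        rows.append(("ll_dominates_sbs", s.session_index, dominance, float(dominance)))
        ctrl_identical = all(t.small_amount == t.large_amount and t.small_delay == t.large_delay
                             for t in s.controls)
        rows.append(("control_options_identical", s.session_index,
                     ctrl_identical, float(ctrl_identical)))
        bounds_ok = all(t.small_delay <= SBS_DELAY_MAX and t.large_delay <= LL_DELAY_MAX
                        for t in s.trials)
        rows.append(("delay_bounds", s.session_index, bounds_ok, float(bounds_ok)))
        n_left = sum(t.sbs_side == "left" for t in exp)
        rows.append(("side_balance", s.session_index,
                     abs(n_left - len(exp) / 2) <= side_balance_tolerance, float(n_left)))

    mean_frames = [
        _means(pd.DataFrame([t.__dict__ for t in s.experimental]))
        for s in design.sessions
    ]
    tol = np.array([amount_tolerance, amount_tolerance, delay_tolerance, delay_tolerance])
    for (i, a), (j, b) in combinations(enumerate(mean_frames), 2):
        diff = np.abs(np.asarray(a) - np.asarray(b))
        for k, name in enumerate(_MEAN_NAMES):
            rows.append((f"matching: {name} (s{i + 1} vs s{j + 1})", 0,
                         bool(diff[k] < tol[k]), float(diff[k])))

    return ValidationReport(
        checks=pd.DataFrame(rows, columns=["check", "session", "passed", "measured"])
    )


def write_trials(design: StudyDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_trials(path: str | Path) -> StudyDesign:
    """Read a trial table CSV back into a :class:`StudyDesign`.

    Raises on missing columns, non-numeric amounts/delays or negative delays
    (naming the offending row); out-of-range delays are recorded as warnings
    on the returned design rather than rejected.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing column(s): {', '.join(missing)}")

    numeric = ["small_amount", "small_delay", "large_amount", "large_delay"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(f"non-numeric {col} at row {int(bad[0])}")
        df[col] = vals
    for col in ("small_delay", "large_delay"):
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValueError(f"negative {col} at row {int(neg[0])}")

    warnings = []
    over_sbs = df.index[(df["small_delay"] > SBS_DELAY_MAX) & (df["is_control"] == 0)]
    for i in over_sbs:
        warnings.append(f"row {int(i)}: small_delay {df.loc[i, 'small_delay']} "
                        f"exceeds {SBS_DELAY_MAX}-day SbS bound")
    over_ll = df.index[df["large_delay"] > LL_DELAY_MAX]
    for i in over_ll:
        warnings.append(f"row {int(i)}: large_delay {df.loc[i, 'large_delay']} "
                        f"exceeds {LL_DELAY_MAX}-day bound")

    sessions = []
    for sidx, grp in df.groupby("session", sort=True):
        grp = grp.sort_values("trial")
        trials = [
            Trial(float(r.small_amount), float(r.small_delay), float(r.large_amount),
                  float(r.large_delay), bool(r.is_control), str(r.sbs_side))
            for r in grp.itertuples(index=False)
        ]
        sessions.append(Session(trials=trials, session_index=int(sidx)))
    return StudyDesign(sessions=sessions, warnings=warnings)
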