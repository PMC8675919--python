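"""Synthetic generator for the two-alternative odor-detection task.

Emulates the behavioral experiment end to end: head-fixed mice report
whether a pseudorandom odorant mixture contains one of two learned
target odorants.  Mixture size is drawn from a truncated geometric
distribution p(x) proportional to b^x over x = 1..6 (smaller b means
easier sessions); the chance that the next trial is target-on is one
minus the fraction of "report present" choices in the animal's last
five responses (a negative-feedback rule that counteracts side biases);
choices and reaction times come from the drift-diffusion process of the
condition's ground-truth parameters, with uniform outlier contamination
and a response-window cutoff.

The defaults reproduce the study's structure: ~250 +/- 20 trials per
session, session difficulty b in {0.5, 0.75, 1}, a 2.8 s response
window measured from odor onset with a 200 ms odor-arrival delay
(already subtracted from all stored reaction times), and an 18-cell
condition grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import TARGET_OFF, TARGET_ON, Condition, DDMParameters, condition_grid
from .simulate import simulate_first_passage_batch

logger = logging.getLogger(__name__)

__all__ = [
    "TaskConfig",
    "complexity_pmf",
    "next_target_probability",
    "generate_mouse_dataset",
    "generate_cohort",
    "combined_ground_truth",
    "mechanism_ground_truth",
    "flat_ground_truth",
    "write_trials",
    "read_trials",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "mouse_id",
    "session_id",
    "session_b",
    "trial_index",
    "trial_type",
    "target",
    "n_background",
    "choice",
    "correct",
    "rt_raw",
    "rt_normalized",
    "is_outlier",
]

REPORT_PRESENT = "report_present"
REPORT_ABSENT = "report_absent"


def complexity_pmf(b: float) -> np.ndarray:
    """Mixture-size distribution p(x) proportional to b^x, x = 1..6."""
    if not 0.0 < b <= 1.0:
        raise ValueError(f"complexity parameter b must lie in (0, 1], got {b}")
    w = b ** np.arange(1, 7, dtype=float)
    return w / w.sum()


def next_target_probability(recent_choices) -> float:
    """1 - fraction of "report present" among the last <= 5 choices.

    An empty history (session start) yields 0.5.  The rule feeds back on
    the animal's own licks, not the trial labels, so a side-biased agent
    receives compensating trial statistics.
    """
    choices = list(recent_choices)
    if len(choices) > 5:
        raise ValueError("at most the last 5 choices enter the adaptive rule")
    if not choices:
        return 0.5
    frac_present = sum(c == REPORT_PRESENT for c in choices) / len(choices)
    return 1.0 - frac_present


def combined_ground_truth(
    threshold: float = 0.5,
    start_bias: float = -0.1,
    non_decision_time: float = 0.35,
    drift_on_a: float = 1.25,
    drift_on_b: float = 1.15,
    drift_off: float = -1.4,
    diffusion0: float = 0.65,
    drift_decrement: float = 0.06,
    noise_increment: float = 0.15,
) -> dict[Condition, DDMParameters]:
    """Combined signal-reduction + noise-boost ground truth.

    Every background odorant shrinks the drift magnitude by
    ``drift_decrement`` (toward zero from either side) and adds
    ``noise_increment`` to the diffusion variance.  Parameters live in
    the theta = 1/2 gauge used by the fitting procedure so recovered and
    generating values are directly comparable.  The two target odorants
    get slightly different baseline drifts, as real odorant pairs do.
    """
    truth: dict[Condition, DDMParameters] = {}
    for cond in condition_grid():
        n = cond.n_background
        if cond.target == "A":
            drift = drift_on_a - drift_decrement * n
        elif cond.target == "B":
            drift = drift_on_b - drift_decrement * n
        else:
            drift = drift_off + drift_decrement * n
        truth[cond] = DDMParameters(
            threshold=threshold,
            start_bias=start_bias,
            drift=drift,
            diffusion_var=diffusion0 + noise_increment * n,
            non_decision_time=non_decision_time,
        )
    return truth


def mechanism_ground_truth(
    mechanism: str,
    gain: float = 0.06,
    **baseline_kwargs,
) -> dict[Condition, DDMParameters]:
    """Ground truth driven by a single pure interference mechanism."""
    if mechanism == "signal_reduction":
        return combined_ground_truth(
            drift_decrement=gain, noise_increment=0.0, **baseline_kwargs
        )
    if mechanism == "noise_boost":
        return combined_ground_truth(
            drift_decrement=0.0, noise_increment=gain, **baseline_kwargs
        )
    if mechanism == "false_signal":
        return combined_ground_truth(
            drift_decrement=-gain, noise_increment=0.0, **baseline_kwargs
        )
    raise ValueError(f"unknown mechanism {mechanism!r}")


def flat_ground_truth(params: DDMParameters | None = None) -> dict[Condition, DDMParameters]:
    """Identical parameters in every condition (negative control)."""
    if params is None:
        params = DDMParameters(0.5, -0.1, 1.0, 0.9, 0.35)
    return {cond: params for cond in condition_grid()}


@dataclass
class TaskConfig:
    """Everything needed to generate one synthetic mouse.

    ``complexity_b`` fixes a single difficulty for all sessions; when
    None (default) each session draws b from ``session_b_choices``,
    matching that analyzed sessions were collected at b >= 0.5.
    ``n_training_sessions`` prepends easy b = 0.25 sessions so the
    session filter has something to reject.
    """

    ground_truth: dict[Condition, DDMParameters] = field(
        default_factory=combined_ground_truth
    )
    n_sessions: int = 70
    trials_per_session_mean: float = 250.0
    trials_per_session_sd: float = 20.0
    complexity_b: float | None = None
    session_b_choices: tuple = (0.5, 0.75, 1.0)
    n_training_sessions: int = 0
    training_b: float = 0.25
    adaptive_window: int = 5
    response_window: float = 2.8
    odor_delay: float = 0.2
    outlier_rate: float = 0.05
    step: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in condition_grid() if c not in self.ground_truth]
        if missing:
            raise ValueError(
                f"ground_truth must cover all 18 conditions; missing {missing[:3]}..."
            )
        if self.complexity_b is not None:
            complexity_pmf(self.complexity_b)  # validate range

    @property
    def effective_window(self) -> float:
        """Response window on the delay-corrected RT scale."""
        return self.response_window - self.odor_delay


def _draw_condition(
    trial_on: bool, b: float, rng: np.random.Generator
) -> Condition:
    x = int(rng.choice(np.arange(1, 7), p=complexity_pmf(b)))
    if trial_on:
        target = "A" if rng.random() < 0.5 else "B"
        return Condition(target, x - 1)
    return Condition("none", x)


def generate_mouse_dataset(config: TaskConfig, mouse_id: str = "m1") -> pd.DataFrame:
    """Simulate all sessions of one mouse; returns a trial table.

    Trials run sequentially within a session: the adaptive rule sees the
    agent's own recent responded choices, the condition is drawn, and
    the response comes from the condition's diffusion parameters (or the
    outlier process).  Trials whose RT exceeds the response window are
    omissions: they consume a trial slot but appear neither in the table
    nor in the choice history.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    n_omitted = 0

    session_bs: list[float] = [config.training_b] * config.n_training_sessions
    for _ in range(config.n_sessions):
        if config.complexity_b is not None:
            session_bs.append(config.complexity_b)
        else:
            session_bs.append(float(rng.choice(config.session_b_choices)))

    for s_idx, b in enumerate(session_bs):
        n_trials = max(
            50,
            int(
                round(
                    rng.normal(
                        config.trials_per_session_mean, config.trials_per_session_sd
                    )
                )
            ),
        )
        history: list[str] = []
        for t_idx in range(n_trials):
            p_on = next_target_probability(history[-config.adaptive_window :])
            trial_on = rng.random() < p_on
            cond = _draw_condition(trial_on, b, rng)
            pars = config.ground_truth[cond]
            ter = pars.non_decision_time

            if rng.random() < config.outlier_rate:
                rt = float(rng.uniform(ter, config.effective_window))
                choice = REPORT_PRESENT if rng.random() < 0.5 else REPORT_ABSENT
                outlier = True
            else:
                up, dt = simulate_first_passage_batch(
                    pars,
                    1,
                    rng,
                    step=config.step,
                    max_time=config.effective_window - ter + config.step,
                )
                rt = float(dt[0]) + ter
                if rt > config.effective_window:
                    n_omitted += 1
                    continue  # omission: no lick, no record, no history
                choice = REPORT_PRESENT if up[0] else REPORT_ABSENT
                outlier = False

            history.append(choice)
            rows.append(
                {
                    "mouse_id": mouse_id,
                    "session_id": f"{mouse_id}_s{s_idx:03d}",
                    "session_b": b,
                    "trial_index": t_idx,
                    "trial_type": cond.trial_type,
                    "target": cond.target,
                    "n_background": cond.n_background,
                    "choice": choice,
                    "correct": (choice == REPORT_PRESENT)
                    == (cond.trial_type == TARGET_ON),
                    "rt_raw": rt,
                    "rt_normalized": np.nan,
                    "is_outlier": outlier,
                }
            )
    if n_omitted:
        logger.info("mouse %s: %d omitted (no-response) trials", mouse_id, n_omitted)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_cohort(
    configs: dict[str, TaskConfig],
) -> pd.DataFrame:
    """Concatenate per-mouse datasets (keys become mouse ids)."""
    frames = [generate_mouse_dataset(cfg, mouse_id) for mouse_id, cfg in configs.items()]
    return pd.concat(frames, ignore_index=True)


def condition_of_row(row) -> Condition:
    return Condition(row["target"], int(row["n_background"]))


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as tab-separated text with a header row."""
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df
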