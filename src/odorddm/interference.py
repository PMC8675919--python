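"""Background-interference hypotheses and their behavioral predictions.

Three candidate mechanisms map the number of background odorants in the
mixture onto the decision-process parameters:

* ``false_signal``    -- backgrounds add target-like evidence: both
  drifts increase by the background offset.
* ``signal_reduction``-- backgrounds suppress the target signal: both
  drifts decrease by the offset.
* ``noise_boost``     -- backgrounds add diffusion variance and leave
  the drifts untouched.

The qualitative predictions (how the probability of reporting "present"
and the mean decision time move with background count) are generic: they
hold for any valid baseline with A-0 < 0 < A+0 and any nondecreasing
background function, not just the linear default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import pandas as pd

from . import ddm
from .params import TARGET_OFF, TARGET_ON, DDMParameters

MECHANISMS = ("false_signal", "signal_reduction", "noise_boost")

__all__ = ["HypothesisSpec", "apply_mechanism", "prediction_table", "MECHANISMS"]


def _linear_background(gain: float) -> Callable[[int], float]:
    def fn(n_background: int) -> float:
        return gain * n_background

    return fn


@dataclass(frozen=True)
class HypothesisSpec:
    """One interference mechanism with its baseline parameters.

    ``background_function`` maps the background count to a nonnegative
    offset added to (or subtracted from) the affected parameter; it
    defaults to the linear schedule ``k * n_background`` with gain
    ``background_gain``.
    """

    mechanism: str
    baseline_on: DDMParameters  # uses the target-present drift A+0 > 0
    baseline_off: DDMParameters  # uses the target-absent drift A-0 < 0
    background_gain: float = 1.0
    background_function: Callable[[int], float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}"
            )
        if not self.baseline_off.drift < 0.0 < self.baseline_on.drift:
            raise ValueError(
                "baseline drifts must satisfy A-0 < 0 < A+0; got "
                f"A+0={self.baseline_on.drift}, A-0={self.baseline_off.drift}"
            )
        if self.background_function is None and not self.background_gain > 0:
            raise ValueError("background_gain must be > 0")

    def offset(self, n_background: int) -> float:
        fn = self.background_function or _linear_background(self.background_gain)
        value = fn(n_background)
        if n_background == 0 and value != 0.0:
            raise ValueError("background_function(0) must be 0")
        if value < 0.0:
            raise ValueError("background_function must be nonnegative")
        return value


def apply_mechanism(
    spec: HypothesisSpec, n_background: int, trial_type: str
) -> DDMParameters:
    """Parameters of the (trial type, background count) condition.

    Threshold and start bias are untouched by every mechanism; the
    offset moves the drift up (false signal), down (signal reduction),
    or the diffusion variance up (noise boost).  Signal reduction may
    legitimately drive the target-present drift negative at high
    background counts, in which case p falls below (1 + m) / 2.
    """
    if n_background < 0:
        raise ValueError(f"n_background must be >= 0, got {n_background}")
    if trial_type not in (TARGET_ON, TARGET_OFF):
        raise ValueError(f"unknown trial_type {trial_type!r}")
    base = spec.baseline_on if trial_type == TARGET_ON else spec.baseline_off
    off = spec.offset(n_background)
    if spec.mechanism == "false_signal":
        return base.replace(drift=base.drift + off)
    if spec.mechanism == "signal_reduction":
        return base.replace(drift=base.drift - off)
    return base.replace(diffusion_var=base.diffusion_var + off)


def prediction_table(
    spec: HypothesisSpec, n_background_list=range(7)
) -> pd.DataFrame:
    """Choice probability and mean decision time per condition.

    One row per (background count, trial type) with columns
    ``mechanism, n_background, trial_type, p, mean_dt``.
    """
    rows = []
    for n in n_background_list:
        for trial_type in (TARGET_ON, TARGET_OFF):
            params = apply_mechanism(spec, int(n), trial_type)
            rows.append(
                {
                    "mechanism": spec.mechanism,
                    "n_background": int(n),
                    "trial_type": trial_type,
                    "p": ddm.choice_probability(params),
                    "mean_dt": ddm.mean_decision_time(params),
                }
            )
    return pd.DataFrame(rows)
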