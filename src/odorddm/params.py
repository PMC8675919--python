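"""Parameter containers and the experimental condition grid.

The decision process is a one-dimensional drift-diffusion: a decision
variable x accumulates evidence at mean rate A (the drift) corrupted by
white noise of variance c^2 per unit time, starting from m*theta and
terminating when it first reaches +theta ("report target present") or
-theta ("report target absent").  A non-decision time Ter accounts for
the sensory and motor latencies outside the accumulation process.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator


class ParameterDomainError(ValueError):
    """A DDM parameter lies outside its mathematical domain."""


@dataclass(frozen=True)
class DDMParameters:
    """One condition's decision-process parameters.

    Attributes
    ----------
    threshold : float
        Evidence bound theta > 0; decisions are made at +/-theta.
    start_bias : float
        Dimensionless start point m in (-1, 1); the decision variable
        starts at m*theta.  m > 0 favors "report present".
    drift : float
        Mean evidence accumulation rate A (evidence / s).  May be any
        sign; positive drifts push toward the "present" bound.
    diffusion_var : float
        Noise variance c^2 > 0 (evidence^2 / s).
    non_decision_time : float
        Ter >= 0 (s), added to the decision time to give reaction time.
    """

    threshold: float
    start_bias: float = 0.0
    drift: float = 0.0
    diffusion_var: float = 1.0
    non_decision_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ParameterDomainError(f"threshold must be > 0, got {self.threshold}")
        if not -1.0 < self.start_bias < 1.0:
            raise ParameterDomainError(
                f"start_bias must lie in (-1, 1), got {self.start_bias}"
            )
        if not self.diffusion_var > 0:
            raise ParameterDomainError(
                f"diffusion_var must be > 0, got {self.diffusion_var}"
            )
        if self.non_decision_time < 0:
            raise ParameterDomainError(
                f"non_decision_time must be >= 0, got {self.non_decision_time}"
            )

    def replace(self, **changes) -> "DDMParameters":
        return replace(self, **changes)


TARGET_ON = "target_on"
TARGET_OFF = "target_off"
TARGET_IDENTITIES = ("A", "B", "none")


@dataclass(frozen=True, order=True)
class Condition:
    """A cell of the 18-condition design grid.

    ``target`` is "A" or "B" on target-on trials and "none" on
    target-off trials.  ``n_background`` counts the non-target mixture
    components: 0-5 when a target is present (mixture size 1-6 includes
    the target) and 1-6 when it is absent.
    """

    target: str
    n_background: int

    def __post_init__(self) -> None:
        if self.target not in TARGET_IDENTITIES:
            raise ValueError(f"unknown target identity {self.target!r}")
        lo, hi = (1, 6) if self.target == "none" else (0, 5)
        if not lo <= self.n_background <= hi:
            raise ValueError(
                f"n_background={self.n_background} out of range "
                f"[{lo}, {hi}] for target={self.target!r}"
            )

    @property
    def trial_type(self) -> str:
        return TARGET_OFF if self.target == "none" else TARGET_ON


def condition_grid() -> list[Condition]:
    """The full 18-cell design: {A, B} x 0-5 backgrounds, none x 1-6."""
    grid: list[Condition] = []
    for target in ("A", "B"):
        grid.extend(Condition(target, n) for n in range(6))
    grid.extend(Condition("none", n) for n in range(1, 7))
    return grid


def iter_conditions() -> Iterator[Condition]:
    yield from condition_grid()
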