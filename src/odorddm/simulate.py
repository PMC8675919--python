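"""Stochastic single-trial simulation of the decision process.

The decision variable follows the Euler-Maruyama discretization of
``dx/dt = A + xi`` from ``x(0) = m*theta`` until it first leaves
``(-theta, +theta)``.  By default a Brownian-bridge test is applied
within each step: given the step endpoints both inside the bounds, the
probability that the continuous path crossed a bound in between is
``exp(-2 d_i d_{i+1} / (c^2 dt))`` (d = distance to that bound), and a
uniform draw decides whether the trial is absorbed there.  This removes
the O(sqrt(dt)) first-passage bias of the plain scheme; pass
``bridge=False`` for the uncorrected discretization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .params import DDMParameters

logger = logging.getLogger(__name__)

__all__ = [
    "SimulatedTrial",
    "simulate_first_passage",
    "simulate_first_passage_batch",
    "simulate_trials",
]


@dataclass(frozen=True)
class SimulatedTrial:
    """One simulated response: boundary, timing, and outlier flag."""

    boundary: str  # "upper" (report present) or "lower" (report absent)
    decision_time: float
    reaction_time: float
    is_outlier: bool = False


def simulate_first_passage_batch(
    params: DDMParameters,
    n: int,
    rng: np.random.Generator,
    step: float = 1e-4,
    bridge: bool = True,
    max_time: float = 50.0,
):
    """Simulate ``n`` independent first passages.

    Returns ``(upper, decision_time)``: a boolean array (True where the
    +theta bound was hit first) and the absorption times in seconds.
    Trials still unabsorbed at ``max_time`` (probability decays
    exponentially; negligible for sane parameters) are assigned the
    bound nearest to their final position and time ``max_time``.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    theta = params.threshold
    drift_inc = params.drift * step
    noise_sd = math.sqrt(params.diffusion_var * step)
    c2dt = params.diffusion_var * step

    x = np.full(n, params.start_bias * theta)
    alive = np.arange(n)
    upper = np.zeros(n, dtype=bool)
    times = np.full(n, max_time)
    t_offset = 0.0
    max_steps = int(math.ceil(max_time / step))
    steps_done = 0

    while alive.size and steps_done < max_steps:
        na = alive.size
        block = max(64, min(4096, int(4e6 / na)))
        block = min(block, max_steps - steps_done)
        incr = rng.standard_normal((na, block)) * noise_sd + drift_inc
        np.cumsum(incr, axis=1, out=incr)
        path = incr + x[:, None]

        hit_up = path >= theta
        hit_lo = path <= -theta
        event = hit_up | hit_lo
        if bridge:
            # distances to each bound at consecutive interior points
            prev = np.concatenate([x[:, None], path[:, :-1]], axis=1)
            with np.errstate(over="ignore"):
                p_up = np.exp(-2.0 * (theta - prev) * (theta - path) / c2dt)
                p_lo = np.exp(-2.0 * (theta + prev) * (theta + path) / c2dt)
            u = rng.random((na, block))
            bridged_up = (u < p_up) & ~event
            # a second draw keeps the two bound tests conditionally
            # independent; crossing both in one step is O(exp(-8 theta^2/c2dt))
            bridged_lo = (rng.random((na, block)) < p_lo) & ~event & ~bridged_up
            hit_up = hit_up | bridged_up
            event = event | bridged_up | bridged_lo

        any_event = event.any(axis=1)
        if np.any(any_event):
            rows = np.nonzero(any_event)[0]
            first = np.argmax(event[rows], axis=1)
            idx = alive[rows]
            upper[idx] = hit_up[rows, first]
            times[idx] = t_offset + (first + 1) * step
        keep = ~any_event
        x = path[keep, -1]
        alive = alive[keep]
        t_offset += block * step
        steps_done += block

    if alive.size:  # censored stragglers: nearest bound, capped time
        upper[alive] = x > 0
        logger.debug("%d trials unabsorbed at max_time=%.1f s", alive.size, max_time)
    return upper, times


def simulate_first_passage(
    params: DDMParameters,
    rng: np.random.Generator,
    step: float = 1e-4,
    bridge: bool = True,
    max_time: float = 50.0,
) -> tuple[str, float]:
    """One first passage; returns (boundary, decision_time)."""
    up, t = simulate_first_passage_batch(
        params, 1, rng, step=step, bridge=bridge, max_time=max_time
    )
    return ("upper" if up[0] else "lower"), float(t[0])


def simulate_trials(
    params: DDMParameters,
    n: int,
    outlier_rate: float,
    response_window: float,
    rng: np.random.Generator,
    step: float = 1e-4,
    bridge: bool = True,
) -> list[SimulatedTrial]:
    """Simulate ``n`` responses with outlier contamination.

    Each trial is, with probability ``outlier_rate``, an outlier whose
    reaction time is uniform on [Ter, response_window] and whose choice
    is a fair coin; otherwise choice and decision time come from the
    diffusion process and RT = DT + Ter.  Trials whose RT exceeds the
    response window are omitted from the returned list (the count is
    logged), mirroring that only responded trials enter the analysis.
    """
    if not 0.0 <= outlier_rate < 1.0:
        raise ValueError(f"outlier_rate must lie in [0, 1), got {outlier_rate}")
    ter = params.non_decision_time
    if response_window <= ter:
        raise ValueError("response_window must exceed the non-decision time")

    is_outlier = rng.random(n) < outlier_rate
    n_ddm = int(np.sum(~is_outlier))
    up, dt_times = simulate_first_passage_batch(
        params, n_ddm, rng, step=step, bridge=bridge
    )

    trials: list[SimulatedTrial] = []
    n_omitted = 0
    i_ddm = 0
    for flag in is_outlier:
        if flag:
            rt = float(rng.uniform(ter, response_window))
            boundary = "upper" if rng.random() < 0.5 else "lower"
            trials.append(SimulatedTrial(boundary, rt - ter, rt, True))
        else:
            t = float(dt_times[i_ddm])
            boundary = "upper" if up[i_ddm] else "lower"
            i_ddm += 1
            rt = t + ter
            if rt > response_window:
                n_omitted += 1
                continue
            trials.append(SimulatedTrial(boundary, t, rt, False))
    if n_omitted:
        logger.info(
            "omitted %d of %d trials exceeding the %.2f s response window",
            n_omitted,
            n,
            response_window,
        )
    return trials
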