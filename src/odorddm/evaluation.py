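"""Model checking and headline summaries.

Three layers sit on top of the fit: a posterior-predictive check
(simulate responses at the fitted parameters and compare choice
fractions and RT medians to the data), across-mouse drift/diffusion
trends versus background count, and a parameter-recovery report that
scores the whole pipeline on data generated from known parameters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import FitResult
from .params import TARGET_ON, Condition, DDMParameters
from .simulate import simulate_first_passage_batch
from .task import REPORT_PRESENT

__all__ = [
    "posterior_predictive_check",
    "parameter_trends",
    "parameter_recovery_report",
    "rescale_to_gauge",
]

N_PREDICTIVE_SIMULATIONS = 1000


def _mad(x: np.ndarray) -> float:
    """Median absolute deviation, unscaled."""
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def posterior_predictive_check(
    fit: FitResult,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    n_sim: int = N_PREDICTIVE_SIMULATIONS,
    step: float = 1e-3,
) -> pd.DataFrame:
    """Simulate ``n_sim`` responses per condition at the fitted
    parameters and compare with the observed data.

    Returns one row per condition with observed vs predicted fraction
    "report present" and median RT +/- MAD (normalized RTs when
    available).  Deterministic given ``rng``'s state.
    """
    rt_col = (
        "rt_normalized"
        if "rt_normalized" in trials and trials["rt_normalized"].notna().all()
        else "rt_raw"
    )
    rows = []
    for (target, n_bg), sub in trials.groupby(["target", "n_background"]):
        cond = Condition(target, int(n_bg))
        if cond not in fit.drift:
            raise ValueError(f"fit does not cover condition {cond}")
        params = fit.params_for(cond)
        up, dt = simulate_first_passage_batch(params, n_sim, rng, step=step)
        rt_sim = dt + params.non_decision_time
        rt_obs = sub[rt_col].to_numpy()
        observed_present = (sub["choice"] == REPORT_PRESENT).to_numpy()
        rows.append(
            {
                "target": cond.target,
                "trial_type": cond.trial_type,
                "n_background": cond.n_background,
                "observed_p": float(observed_present.mean()),
                "predicted_p": float(up.mean()),
                "observed_median_rt": float(np.median(rt_obs)),
                "observed_mad_rt": _mad(rt_obs),
                "predicted_median_rt": float(np.median(rt_sim)),
                "predicted_mad_rt": _mad(rt_sim),
                "n_observed": int(len(sub)),
                "n_simulated": int(n_sim),
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["trial_type", "target", "n_background"], ignore_index=True
    )


def _per_mouse_frame(fits: list[FitResult], by_target: bool) -> pd.DataFrame:
    rows = []
    for i, fit in enumerate(fits):
        for c in fit.conditions:
            rows.append(
                {
                    "mouse": i,
                    "target": c.target,
                    "trial_type": c.trial_type,
                    "n_background": c.n_background,
                    "drift": fit.drift[c],
                    "diffusion_var": fit.diffusion_var[c],
                }
            )
    df = pd.DataFrame(rows)
    if by_target:
        return df
    # pool targets A and B by simple average within mouse
    return (
        df.groupby(["mouse", "trial_type", "n_background"], as_index=False)
        .agg(drift=("drift", "mean"), diffusion_var=("diffusion_var", "mean"))
    )


def parameter_trends(
    fits: list[FitResult], by_target: bool = False
) -> pd.DataFrame:
    """Across-mouse mean +/- SE of drift and diffusion per condition.

    Target-on conditions pool targets A and B by simple average unless
    ``by_target`` keeps them separate.  With a single mouse the SEs are
    reported as NaN.
    """
    df = _per_mouse_frame(fits, by_target)
    keys = ["target", "n_background"] if by_target else ["trial_type", "n_background"]

    def se(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    out = df.groupby(keys, as_index=False).agg(
        mean_drift=("drift", "mean"),
        se_drift=("drift", se),
        mean_diffusion=("diffusion_var", "mean"),
        se_diffusion=("diffusion_var", se),
        n_mice=("drift", "size"),
    )
    if by_target:
        out["trial_type"] = np.where(out["target"] == "none", "target_off", TARGET_ON)
    return out


def rescale_to_gauge(
    params: DDMParameters, threshold: float = 0.5
) -> DDMParameters:
    """Express parameters in the gauge with the given threshold.

    The diffusion process is invariant under (theta, A, c^2) ->
    (lam*theta, lam*A, lam^2*c^2); this maps a parameter set onto the
    reporting gauge so generating and fitted values are comparable.
    """
    lam = threshold / params.threshold
    return DDMParameters(
        threshold=threshold,
        start_bias=params.start_bias,
        drift=lam * params.drift,
        diffusion_var=lam * lam * params.diffusion_var,
        non_decision_time=params.non_decision_time,
    )


def _trend_slope(values: dict[Condition, float], transform=lambda x: x) -> float:
    n = np.array([c.n_background for c in values])
    v = np.array([transform(values[c]) for c in values])
    return float(np.polyfit(n, v, 1)[0])


def parameter_recovery_report(
    ground_truth: dict[Condition, DDMParameters],
    fit: FitResult,
) -> pd.DataFrame:
    """Score a fit against the parameters that generated its data.

    One row per parameter class (drift, diffusion_var) with bias, RMSE,
    truth-estimate Pearson correlation, and the fitted-vs-true sign of
    the background trend (|drift| should fall, diffusion rise, with
    background count under the combined mechanism).  Ground truth is
    first mapped onto the fit's theta = 1/2 gauge.
    """
    conds = fit.conditions
    if set(conds) != set(ground_truth):
        raise ValueError("ground truth and fit cover different condition sets")
    truth = {c: rescale_to_gauge(ground_truth[c], fit.threshold) for c in conds}

    rows = []
    for name, attr, transform in (
        ("drift", "drift", abs),
        ("diffusion_var", "diffusion_var", lambda x: x),
    ):
        tv = {c: getattr(truth[c], attr) for c in conds}
        ev = getattr(fit, attr)
        t = np.array([tv[c] for c in conds])
        e = np.array([ev[c] for c in conds])
        truth_slope = _trend_slope(tv, transform)
        est_slope = _trend_slope(ev, transform)
        rows.append(
            {
                "parameter": name,
                "bias": float(np.mean(e - t)),
                "rmse": float(np.sqrt(np.mean((e - t) ** 2))),
                "correlation": float(np.corrcoef(t, e)[0, 1]),
                "truth_trend_slope": truth_slope,
                "estimate_trend_slope": est_slope,
                "trend_sign_agrees": bool(np.sign(truth_slope) == np.sign(est_slope)),
            }
        )
    return pd.DataFrame(rows)
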