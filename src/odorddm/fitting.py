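"""Chi-square quantile fitting of the drift-diffusion model.

Per mouse, the empirical correct and error reaction times of each of
the 18 conditions are split into 6 bins at the 0.1/0.3/0.5/0.7/0.9
quantiles (12 summary statistics per condition, 216 in all).  Model
expected frequencies come from the theoretical defective first-passage
CDF evaluated at the empirical quantiles, mixed with a 5% uniform
outlier component, and the objective sum((O - E)^2 / E) is minimized
over 38 free parameters: a (threshold, drift) pair per condition plus
one shared start fraction m' and one shared non-decision time Ter.

The fitting frame fixes the diffusion variance at 1 with bounds at 0
and theta_fit and start m' * theta_fit.  Because the diffusion is a
scale parameter, the fitted values are afterwards rescaled to the
theta' = 1 (theta = 1/2) gauge the analysis reports:

    A = A_fit / theta_fit,   c^2 = 1 / theta_fit^2,   m = 2 m' - 1.

The optimizer exploits that, given (m', Ter), conditions decouple:
nested per-condition 2-parameter simplex fits run inside an outer
simplex over (m', Ter), and a bounded quasi-Newton pass polishes the
full 38-vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import ddm
from .params import TARGET_ON, Condition, DDMParameters, condition_grid

logger = logging.getLogger(__name__)

__all__ = [
    "QUANTILE_FRACTIONS",
    "QuantileSummary",
    "FitResultRaw",
    "FitResult",
    "quantile_summary",
    "summarize_trials",
    "expected_frequencies",
    "chi_square_objective",
    "QuantileDDMFitter",
    "fit_mouse",
    "rescale_parameters",
]

QUANTILE_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 0.9)

#: conditions with fewer responses of a type than this collapse that
#: type's 6 bins to 2 (below/above the median)
SPARSE_MIN = 12

E_FLOOR = 1e-3
PENALTY = 1e10

BOUNDS = {
    "theta_fit": (0.05, 10.0),
    "drift_fit": (-20.0, 20.0),
    "start_fraction": (0.05, 0.95),
}


@dataclass(frozen=True)
class QuantileSummary:
    """Observed RT-quantile bin counts for one condition.

    ``correct_quantile_rts`` has 5 entries for a full cell, 1 (the
    median) for a sparse cell, and 0 for an empty response type; the
    bin counts always have one more entry than the quantiles.
    """

    condition: Condition
    n_correct: int
    n_error: int
    correct_quantile_rts: np.ndarray
    error_quantile_rts: np.ndarray
    correct_bin_counts: np.ndarray
    error_bin_counts: np.ndarray

    @property
    def n_total(self) -> int:
        return self.n_correct + self.n_error

    @property
    def observed_bin_counts(self) -> np.ndarray:
        """Correct bins then error bins (12 values for a full cell)."""
        return np.concatenate([self.correct_bin_counts, self.error_bin_counts])

    @property
    def n_statistics(self) -> int:
        return len(self.correct_bin_counts) + len(self.error_bin_counts)


def _type_quantiles(rts: np.ndarray) -> np.ndarray:
    if rts.size == 0:
        return np.empty(0)
    if rts.size < SPARSE_MIN:
        return np.quantile(rts, [0.5])
    return np.quantile(rts, QUANTILE_FRACTIONS)


def _bin_counts(rts: np.ndarray, quantiles: np.ndarray) -> np.ndarray:
    edges = np.concatenate([[-np.inf], quantiles, [np.inf]])
    counts, _ = np.histogram(rts, bins=edges)
    # np.histogram bins are left-closed; shift ties at the quantile into
    # the lower bin to match right-closed (-inf, q1], (q1, q2], ...
    for i, q in enumerate(quantiles):
        ties = int(np.sum(rts == q))
        if ties:
            counts[i] += ties
            counts[i + 1] -= ties
    return counts.astype(float)


def quantile_summary(
    correct_rts: np.ndarray, error_rts: np.ndarray, condition: Condition
) -> QuantileSummary:
    """Summarize one condition's RTs into quantile bin counts.

    Quantiles use linear interpolation of the empirical CDF; bin counts
    are actual tallies (right-closed bins), so duplicated RT values
    straddling a quantile still sum to the response count.
    """
    correct_rts = np.asarray(correct_rts, dtype=float)
    error_rts = np.asarray(error_rts, dtype=float)
    if correct_rts.size + error_rts.size < 1:
        raise ValueError(f"condition {condition} has no trials")
    qc = _type_quantiles(correct_rts)
    qe = _type_quantiles(error_rts)
    return QuantileSummary(
        condition=condition,
        n_correct=int(correct_rts.size),
        n_error=int(error_rts.size),
        correct_quantile_rts=qc,
        error_quantile_rts=qe,
        correct_bin_counts=_bin_counts(correct_rts, qc),
        error_bin_counts=_bin_counts(error_rts, qe),
    )


def summarize_trials(
    trials: pd.DataFrame, rt_column: str | None = None
) -> dict[Condition, QuantileSummary]:
    """Quantile summaries for every condition present in a trial table."""
    if rt_column is None:
        rt_column = (
            "rt_normalized"
            if "rt_normalized" in trials and trials["rt_normalized"].notna().all()
            else "rt_raw"
        )
    out: dict[Condition, QuantileSummary] = {}
    for (target, n_bg), sub in trials.groupby(["target", "n_background"]):
        cond = Condition(target, int(n_bg))
        rts = sub[rt_column].to_numpy()
        correct = sub["correct"].to_numpy(dtype=bool)
        out[cond] = quantile_summary(rts[correct], rts[~correct], cond)
    return out


# ---------------------------------------------------------------------------
# Expected frequencies and the objective
# ---------------------------------------------------------------------------


def _mixed_cum(
    params: DDMParameters,
    rt_quantiles: np.ndarray,
    boundary: str,
    outlier_rate: float,
    outlier_window: float,
) -> tuple[np.ndarray, float]:
    """Cumulative defective probability (with outlier mixture) at the
    empirical quantile RTs, plus the boundary's total mixed mass."""
    ter = params.non_decision_time
    tau = np.maximum(np.asarray(rt_quantiles, dtype=float) - ter, 0.0)
    cum_ddm = ddm.fpt_defective_cdf(params, tau, boundary)
    mass_ddm = ddm.boundary_mass(params, boundary)
    w = max(outlier_window - ter, 1e-9)
    cum_out = 0.5 * np.clip(tau / w, 0.0, 1.0)
    cum = (1.0 - outlier_rate) * cum_ddm + outlier_rate * cum_out
    mass = (1.0 - outlier_rate) * mass_ddm + 0.5 * outlier_rate
    return np.atleast_1d(cum), mass


def expected_frequencies(
    params: DDMParameters,
    summary: QuantileSummary,
    outlier_rate: float = 0.05,
    outlier_window: float = 2.6,
    normalization: str = "total",
) -> np.ndarray:
    """Model-expected counts for the observed quantile bins.

    For each response type the defective CDF (on the decision-time
    scale, quantile RTs minus Ter, floored at zero) is evaluated at the
    empirical quantiles; successive differences with end caps 0 and the
    boundary's total mass give bin probabilities, mixed with a uniform
    outlier component of weight ``outlier_rate``.

    normalization="total" (default) multiplies the defective bin
    probabilities by the condition's total trial count, so choice
    probability and RT shape are both constrained.
    normalization="within_type" renormalizes each response type's bins
    to its own trial count, constraining conditional RT shape only.
    """
    if normalization not in ("total", "within_type"):
        raise ValueError("normalization must be 'total' or 'within_type'")
    correct_boundary = (
        "upper" if summary.condition.trial_type == TARGET_ON else "lower"
    )
    error_boundary = "lower" if correct_boundary == "upper" else "upper"
    pieces = []
    for boundary, quantiles, n_type in (
        (correct_boundary, summary.correct_quantile_rts, summary.n_correct),
        (error_boundary, summary.error_quantile_rts, summary.n_error),
    ):
        cum, mass = _mixed_cum(params, quantiles, boundary, outlier_rate, outlier_window)
        probs = np.diff(np.concatenate([[0.0], cum, [max(mass, float(np.max(cum, initial=0.0)))]]))
        probs = np.maximum(probs, 0.0)
        if normalization == "total":
            pieces.append(summary.n_total * probs)
        else:
            total = probs.sum()
            pieces.append(n_type * probs / total if total > 0 else probs * 0.0)
    return np.concatenate(pieces)


def _decode(vector: np.ndarray, conditions: list[Condition]):
    n = len(conditions)
    theta_fit = vector[0 : 2 * n : 2]
    drift_fit = vector[1 : 2 * n : 2]
    m_prime = vector[2 * n]
    ter = vector[2 * n + 1]
    return theta_fit, drift_fit, m_prime, ter


def _fit_frame_params(theta_fit: float, drift_fit: float, m_prime: float, ter: float) -> DDMParameters:
    """Fitting-frame condition parameters (unit diffusion variance)."""
    return DDMParameters(
        threshold=theta_fit / 2.0,
        start_bias=2.0 * m_prime - 1.0,
        drift=drift_fit,
        diffusion_var=1.0,
        non_decision_time=ter,
    )


def _condition_chisq(
    theta_fit: float,
    drift_fit: float,
    m_prime: float,
    ter: float,
    summary: QuantileSummary,
    outlier_rate: float,
    outlier_window: float,
    normalization: str,
) -> float:
    params = _fit_frame_params(theta_fit, drift_fit, m_prime, ter)
    expected = expected_frequencies(
        params, summary, outlier_rate, outlier_window, normalization
    )
    observed = summary.observed_bin_counts
    return float(np.sum((observed - expected) ** 2 / np.maximum(expected, E_FLOOR)))


def _bounds_violation(
    theta_fit, drift_fit, m_prime, ter, ter_max
) -> float:
    v = 0.0
    lo, hi = BOUNDS["theta_fit"]
    v += float(np.sum(np.maximum(lo - theta_fit, 0) + np.maximum(theta_fit - hi, 0)))
    lo, hi = BOUNDS["drift_fit"]
    v += float(np.sum(np.maximum(lo - drift_fit, 0) + np.maximum(drift_fit - hi, 0)))
    lo, hi = BOUNDS["start_fraction"]
    v += max(lo - m_prime, 0) + max(m_prime - hi, 0)
    v += max(-ter, 0) + max(ter - ter_max, 0)
    return v


def chi_square_objective(
    vector: np.ndarray,
    summaries: dict[Condition, QuantileSummary],
    outlier_rate: float = 0.05,
    outlier_window: float = 2.6,
    normalization: str = "total",
    ter_max: float = np.inf,
) -> float:
    """Full-mouse objective over the 38-vector.

    Layout: [theta_fit_1, A_fit_1, ..., theta_fit_18, A_fit_18, m',
    Ter] with conditions in canonical grid order.  Out-of-bounds
    vectors return a large, violation-graded penalty so derivative-free
    optimizers can recover.
    """
    conditions = sorted(summaries)
    vector = np.asarray(vector, dtype=float)
    if vector.size != 2 * len(conditions) + 2:
        raise ValueError(
            f"expected {2 * len(conditions) + 2} parameters, got {vector.size}"
        )
    theta_fit, drift_fit, m_prime, ter = _decode(vector, conditions)
    violation = _bounds_violation(theta_fit, drift_fit, m_prime, ter, ter_max)
    if violation > 0:
        return PENALTY * (1.0 + violation)
    return sum(
        _condition_chisq(
            tf, af, m_prime, ter, summaries[c], outlier_rate, outlier_window, normalization
        )
        for tf, af, c in zip(theta_fit, drift_fit, conditions)
    )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class FitResultRaw:
    """Fitting-frame parameters: unit diffusion, per-condition bounds."""

    conditions: list[Condition]
    threshold_fit: dict[Condition, float]
    drift_fit: dict[Condition, float]
    start_fraction: float
    non_decision: float
    objective: float
    n_evaluations: int
    converged: bool

    @property
    def n_free_parameters(self) -> int:
        return 2 * len(self.conditions) + 2


@dataclass
class FitResult:
    """Reported-gauge parameters: theta' = 1 (theta = 1/2)."""

    conditions: list[Condition]
    drift: dict[Condition, float]
    diffusion_var: dict[Condition, float]
    start_bias: float
    non_decision: float
    threshold: float = 0.5
    objective: float = np.nan

    def params_for(self, condition: Condition) -> DDMParameters:
        return DDMParameters(
            threshold=self.threshold,
            start_bias=self.start_bias,
            drift=self.drift[condition],
            diffusion_var=self.diffusion_var[condition],
            non_decision_time=self.non_decision,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target": c.target,
                "trial_type": c.trial_type,
                "n_background": c.n_background,
                "drift": self.drift[c],
                "diffusion_var": self.diffusion_var[c],
                "start_bias": self.start_bias,
                "non_decision": self.non_decision,
                "threshold": self.threshold,
            }
            for c in self.conditions
        ]
        return pd.DataFrame(rows)


def rescale_parameters(raw: FitResultRaw) -> FitResult:
    """Exact gauge change A = A_fit/theta_fit, c^2 = 1/theta_fit^2.

    The start bias m = 2 m' - 1 and Ter are scale-free.  The identities
    are exactly invertible: theta_fit = 1/c, A_fit = A/c.
    """
    drift = {}
    diffusion = {}
    for c in raw.conditions:
        tf = raw.threshold_fit[c]
        if tf <= 0:
            raise ValueError(f"threshold_fit must be > 0, got {tf} for {c}")
        drift[c] = raw.drift_fit[c] / tf
        diffusion[c] = 1.0 / tf**2
    return FitResult(
        conditions=list(raw.conditions),
        drift=drift,
        diffusion_var=diffusion,
        start_bias=2.0 * raw.start_fraction - 1.0,
        non_decision=raw.non_decision,
        objective=raw.objective,
    )


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------


def _moment_init(summary: QuantileSummary, ter: float) -> tuple[float, float]:
    """Method-of-moments (theta_fit, A_fit) start values.

    Inverts p = logistic(r) for the scaled drift and the m = 0 mean
    decision time E[DT] = (theta/A) tanh(r/2) for the scale.
    """
    n = summary.n_total
    if summary.condition.trial_type == TARGET_ON:
        n_up = summary.n_correct
    else:
        n_up = summary.n_error
    p_hat = np.clip((n_up + 1.0) / (n + 2.0), 0.02, 0.98)
    all_q = np.concatenate([summary.correct_quantile_rts, summary.error_quantile_rts])
    t_bar = max(float(np.mean(all_q)) - ter, 5e-3)
    r0 = float(np.log(p_hat / (1.0 - p_hat)))
    if abs(r0) < 1e-3:
        theta_fit = 2.0 * np.sqrt(t_bar)
    else:
        theta_fit = float(np.sqrt(2.0 * t_bar * r0 / np.tanh(r0 / 2.0)))
    theta_fit = float(np.clip(theta_fit, *BOUNDS["theta_fit"]))
    drift_fit = float(np.clip(r0 / theta_fit, *BOUNDS["drift_fit"]))
    return theta_fit, drift_fit


class QuantileDDMFitter(BaseEstimator):
    """Chi-square quantile estimator of per-condition DDM parameters.

    Fits one mouse's trial table: 18 (threshold, drift) pairs plus a
    shared start fraction and non-decision time (38 free parameters),
    then rescales to the theta = 1/2 gauge.

    Parameters
    ----------
    outlier_rate : float
        Weight of the uniform outlier mixture in the expected
        frequencies (the analysis allows 5% of responses to be
        discarded as lapses).
    normalization : {"total", "within_type"}
        How expected bin probabilities become expected counts; see
        :func:`expected_frequencies`.
    outlier_window : float or None
        Upper end of the uniform outlier RT support; None uses the
        largest observed RT.
    outer_maxiter, inner_maxiter, warm_maxiter, polish_maxiter, n_restarts
        Budgets of the nested optimizer stages.
    seed : int
        Seeds the restart perturbations; the fit is deterministic.

    Attributes (after ``fit``)
    --------------------------
    raw_result_ : FitResultRaw;  result_ : FitResult
    drift_, diffusion_ : dict Condition -> float (rescaled gauge)
    start_bias_, non_decision_, objective_ : float
    n_evaluations_ : int;  converged_ : bool
    summaries_ : dict Condition -> QuantileSummary
    """

    def __init__(
        self,
        outlier_rate: float = 0.05,
        normalization: str = "total",
        outlier_window: float | None = None,
        rt_column: str | None = None,
        outer_maxiter: int = 40,
        inner_maxiter: int = 200,
        warm_maxiter: int = 40,
        polish_maxiter: int = 60,
        n_restarts: int = 2,
        seed: int = 0,
    ):
        self.outlier_rate = outlier_rate
        self.normalization = normalization
        self.outlier_window = outlier_window
        self.rt_column = rt_column
        self.outer_maxiter = outer_maxiter
        self.inner_maxiter = inner_maxiter
        self.warm_maxiter = warm_maxiter
        self.polish_maxiter = polish_maxiter
        self.n_restarts = n_restarts
        self.seed = seed

    # -- internals ---------------------------------------------------

    def _cond_obj(self, x, m_prime, ter, summary):
        self._n_eval += 1
        tf, af = x
        lo, hi = BOUNDS["theta_fit"]
        v = max(lo - tf, 0) + max(tf - hi, 0)
        lo, hi = BOUNDS["drift_fit"]
        v += max(lo - af, 0) + max(af - hi, 0)
        if v > 0:
            return PENALTY * (1.0 + v)
        return _condition_chisq(
            tf,
            af,
            m_prime,
            ter,
            summary,
            self.outlier_rate,
            self._window,
            self.normalization,
        )

    def _fit_condition(self, summary, m_prime, ter, x0, maxiter, rng=None):
        best = None
        starts = [np.asarray(x0, dtype=float)]
        if rng is not None:
            for _ in range(self.n_restarts):
                starts.append(
                    np.asarray(x0) * rng.uniform(0.6, 1.6, 2)
                    + np.array([0.0, rng.normal(0.0, 0.5)])
                )
        for s in starts:
            res = minimize(
                self._cond_obj,
                s,
                args=(m_prime, ter, summary),
                method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-4},
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    # -- sklearn API -------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        if X["mouse_id"].nunique() > 1:
            raise ValueError("fit one mouse at a time (multiple mouse_id present)")
        summaries = summarize_trials(X, rt_column=self.rt_column)
        expected_conditions = set(condition_grid())
        missing = expected_conditions - set(summaries)
        if missing:
            raise ValueError(
                f"all 18 conditions must be present; missing {sorted(missing)[:3]}"
            )
        self.summaries_ = summaries
        conditions = sorted(summaries)

        rt_col = self.rt_column or (
            "rt_normalized"
            if "rt_normalized" in X and X["rt_normalized"].notna().all()
            else "rt_raw"
        )
        rts = X[rt_col].to_numpy()
        t_min = float(np.min(rts))
        self._window = (
            float(np.max(rts)) if self.outlier_window is None else self.outlier_window
        )
        ter_max = t_min - 1e-4
        self._n_eval = 0
        rng = np.random.default_rng(self.seed)

        ter0 = min(0.95 * t_min, ter_max)
        m0 = 0.5

        # stage 1: independent condition fits at the initial (m', Ter)
        cond_x = {}
        for c in conditions:
            x0 = _moment_init(summaries[c], ter0)
            res = self._fit_condition(
                summaries[c], m0, ter0, x0, self.inner_maxiter, rng=rng
            )
            cond_x[c] = res.x

        # stage 2: outer simplex over the shared (m', Ter) with
        # warm-started per-condition refits
        def outer_obj(shared):
            m_prime, ter = shared
            v = _bounds_violation(
                np.array([1.0]), np.array([0.0]), m_prime, ter, ter_max
            )
            if v > 0:
                return PENALTY * (1.0 + v)
            total = 0.0
            for c in conditions:
                res = self._fit_condition(
                    summaries[c], m_prime, ter, cond_x[c], self.warm_maxiter
                )
                cond_x[c] = res.x
                total += res.fun
            return total

        outer = minimize(
            outer_obj,
            np.array([m0, ter0]),
            method="Nelder-Mead",
            options={
                "maxiter": self.outer_maxiter,
                "xatol": 1e-3,
                "fatol": 1e-2,
            },
        )
        m_best, ter_best = outer.x

        # stage 3: bounded quasi-Newton polish of the full vector
        vec0 = np.empty(2 * len(conditions) + 2)
        for i, c in enumerate(conditions):
            vec0[2 * i : 2 * i + 2] = cond_x[c]
        vec0[-2], vec0[-1] = m_best, ter_best

        def full_obj(vec):
            self._n_eval += 1
            return chi_square_objective(
                vec,
                summaries,
                self.outlier_rate,
                self._window,
                self.normalization,
                ter_max,
            )

        bounds = []
        for _ in conditions:
            bounds.append(BOUNDS["theta_fit"])
            bounds.append(BOUNDS["drift_fit"])
        bounds.append(BOUNDS["start_fraction"])
        bounds.append((0.0, ter_max))
        polish = minimize(
            full_obj,
            vec0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.polish_maxiter, "maxfun": 20000},
        )
        vec_best = polish.x if polish.fun <= full_obj(vec0) else vec0
        obj_best = min(float(polish.fun), float(full_obj(vec0)))

        theta_fit, drift_fit, m_prime, ter = _decode(vec_best, conditions)
        self.raw_result_ = FitResultRaw(
            conditions=conditions,
            threshold_fit={c: float(t) for c, t in zip(conditions, theta_fit)},
            drift_fit={c: float(a) for c, a in zip(conditions, drift_fit)},
            start_fraction=float(m_prime),
            non_decision=float(ter),
            objective=obj_best,
            n_evaluations=self._n_eval,
            converged=bool(polish.success or outer.success),
        )
        self.result_ = rescale_parameters(self.raw_result_)
        self.drift_ = self.result_.drift
        self.diffusion_ = self.result_.diffusion_var
        self.start_bias_ = self.result_.start_bias
        self.non_decision_ = self.result_.non_decision
        self.objective_ = obj_best
        self.n_evaluations_ = self._n_eval
        self.converged_ = self.raw_result_.converged
        logger.info(
            "fit: objective %.2f after %d evaluations (converged=%s)",
            obj_best,
            self._n_eval,
            self.converged_,
        )
        return self

    def predict_params(self, condition: Condition) -> DDMParameters:
        """Rescaled-gauge parameters of one condition."""
        return self.result_.params_for(condition)


def fit_mouse(trials: pd.DataFrame, **fitter_kwargs) -> tuple[FitResultRaw, FitResult]:
    """Fit one mouse's preprocessed trials; returns (raw, rescaled)."""
    fitter = QuantileDDMFitter(**fitter_kwargs).fit(trials)
    return fitter.raw_result_, fitter.result_
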