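"""Quantile summaries, expected frequencies, the chi-square objective,
rescaling identities, and the 38-parameter fit."""

import numpy as np
import pytest

from odorddm import ddm, fitting, task
from odorddm.fitting import (
    QuantileDDMFitter,
    QuantileSummary,
    chi_square_objective,
    expected_frequencies,
    fit_mouse,
    quantile_summary,
    rescale_parameters,
    summarize_trials,
)
from odorddm.params import Condition, DDMParameters, condition_grid
from odorddm.simulate import simulate_first_passage_batch

COND_ON = Condition("A", 2)
COND_OFF = Condition("none", 3)

FAST_FIT = dict(
    outer_maxiter=8, inner_maxiter=120, warm_maxiter=25, polish_maxiter=25, n_restarts=1
)


class TestQuantileSummary:
    def test_forced_bin_fractions(self, rng):
        rts = rng.uniform(0.3, 1.5, 100)
        s = quantile_summary(rts, rng.uniform(0.3, 1.5, 50), COND_ON)
        assert s.correct_bin_counts == pytest.approx([10, 20, 20, 20, 20, 10])
        assert s.error_bin_counts == pytest.approx([5, 10, 10, 10, 10, 5])

    def test_twelve_statistics(self, rng):
        s = quantile_summary(rng.uniform(0, 1, 60), rng.uniform(0, 1, 40), COND_ON)
        assert s.n_statistics == 12
        assert len(s.observed_bin_counts) == 12

    def test_bins_sum_to_counts_with_ties(self):
        # duplicates straddling a quantile: brute-force recount with
        # right-closed bins must equal the reported counts
        rts = np.array([0.5] * 30 + [0.7] * 40 + [0.9] * 30)
        s = quantile_summary(rts, np.array([0.6] * 20), COND_ON)
        assert s.correct_bin_counts.sum() == 100
        assert s.error_bin_counts.sum() == 20
        edges = np.concatenate([[-np.inf], s.correct_quantile_rts, [np.inf]])
        brute = [
            np.sum((rts > lo) & (rts <= hi)) for lo, hi in zip(edges[:-1], edges[1:])
        ]
        assert s.correct_bin_counts == pytest.approx(brute)

    def test_quantiles_nondecreasing(self, rng):
        s = quantile_summary(rng.exponential(0.5, 500), rng.exponential(0.5, 200), COND_ON)
        assert np.all(np.diff(s.correct_quantile_rts) >= 0)
        assert np.all(np.diff(s.error_quantile_rts) >= 0)

    def test_sparse_type_collapses_to_median_split(self, rng):
        s = quantile_summary(rng.uniform(0, 1, 100), rng.uniform(0, 1, 7), COND_ON)
        assert len(s.error_quantile_rts) == 1
        assert s.error_bin_counts.sum() == 7
        assert s.n_statistics == 8

    def test_empty_type_yields_single_empty_bin(self, rng):
        s = quantile_summary(rng.uniform(0, 1, 50), np.array([]), COND_ON)
        assert len(s.error_quantile_rts) == 0
        assert s.error_bin_counts == pytest.approx([0.0])

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            quantile_summary(np.array([]), np.array([]), COND_ON)


def _model_summary(params, cond, n_total, outlier_window=2.6):
    """Summary whose observed counts equal the model expectation."""
    ter = params.non_decision_time
    up_mass = ddm.choice_probability(params)
    correct_boundary = "upper" if cond.trial_type == "target_on" else "lower"
    masses = {"upper": up_mass, "lower": 1 - up_mass}
    qs = {}
    for boundary in ("upper", "lower"):
        qs[boundary] = np.array(
            [
                ddm.fpt_quantile(params, f * masses[boundary], boundary) + ter
                for f in fitting.QUANTILE_FRACTIONS
            ]
        )
    err_boundary = "lower" if correct_boundary == "upper" else "upper"
    frac = np.array([0.1, 0.2, 0.2, 0.2, 0.2, 0.1])
    n_c = n_total * masses[correct_boundary]
    n_e = n_total * masses[err_boundary]
    return QuantileSummary(
        condition=cond,
        n_correct=int(round(n_c)),
        n_error=int(round(n_e)),
        correct_quantile_rts=qs[correct_boundary],
        error_quantile_rts=qs[err_boundary],
        correct_bin_counts=n_c * frac,
        error_bin_counts=n_e * frac,
    )


class TestExpectedFrequencies:
    def test_self_consistency(self):
        # a summary built from the model's own defective quantiles must
        # reproduce itself (zero chi-square contribution up to rounding)
        params = DDMParameters(0.6, -0.1, 1.1, 1.0, 0.35)
        s = _model_summary(params, COND_ON, 1000)
        e = expected_frequencies(params, s, outlier_rate=0.0)
        assert e == pytest.approx(s.observed_bin_counts, abs=1e-3)
        chisq = np.sum((s.observed_bin_counts - e) ** 2 / np.maximum(e, 1e-3))
        assert chisq < 1e-4

    def test_total_normalization_sums_to_n(self, rng):
        params = DDMParameters(0.5, 0.0, 1.0, 1.0, 0.3)
        s = quantile_summary(
            rng.uniform(0.4, 1.5, 80), rng.uniform(0.4, 1.5, 20), COND_ON
        )
        e = expected_frequencies(params, s, outlier_rate=0.05)
        assert e.sum() == pytest.approx(s.n_total, abs=1e-6)

    def test_within_type_sums_to_type_counts(self, rng):
        params = DDMParameters(0.5, 0.0, 1.0, 1.0, 0.3)
        s = quantile_summary(
            rng.uniform(0.4, 1.5, 80), rng.uniform(0.4, 1.5, 20), COND_ON
        )
        e = expected_frequencies(params, s, normalization="within_type")
        assert e[:6].sum() == pytest.approx(80, abs=1e-6)
        assert e[6:].sum() == pytest.approx(20, abs=1e-6)

    def test_matches_large_simulation(self):
        # expected bin fractions agree with Monte Carlo at the
        # generating parameters
        params = DDMParameters(0.5, -0.1, 1.0, 0.9, 0.35)
        n = 100_000
        up, dt = simulate_first_passage_batch(
            params, n, np.random.default_rng(21), step=5e-4
        )
        rts = dt + params.non_decision_time
        s = quantile_summary(rts[up], rts[~up], COND_ON)
        e = expected_frequencies(params, s, outlier_rate=0.0)
        o = s.observed_bin_counts
        # multinomial SE per bin
        se = np.sqrt(np.maximum(e * (1 - e / n), 1.0))
        assert np.all(np.abs(o - e) < 3.5 * se)

    def test_gauge_invariance(self, rng):
        # (theta, A, c^2) -> (lam theta, lam A, lam^2 c^2) leaves the
        # predicted frequencies untouched
        params = DDMParameters(0.5, 0.2, -1.0, 0.8, 0.3)
        lam = 3.0
        scaled = DDMParameters(0.5 * lam, 0.2, -1.0 * lam, 0.8 * lam * lam, 0.3)
        s = quantile_summary(
            rng.uniform(0.4, 1.5, 60), rng.uniform(0.4, 1.5, 40), COND_OFF
        )
        a = expected_frequencies(params, s)
        b = expected_frequencies(scaled, s)
        assert a == pytest.approx(b, rel=1e-8)

    def test_quantile_below_ter_floors_to_zero(self):
        params = DDMParameters(0.5, 0.0, 1.0, 1.0, 0.5)
        s = QuantileSummary(
            COND_ON,
            10,
            0,
            np.array([0.1, 0.2, 0.3, 0.4, 0.45]),  # all below Ter
            np.empty(0),
            np.array([1.0, 2, 2, 2, 2, 1]),
            np.array([0.0]),
        )
        e = expected_frequencies(params, s, outlier_rate=0.0)
        assert e[:5] == pytest.approx(0.0)


def _truth_vector(truth, m_prime, ter):
    conds = sorted(condition_grid())
    vec = np.empty(2 * len(conds) + 2)
    for i, c in enumerate(conds):
        p = truth[c]
        cc = np.sqrt(p.diffusion_var)
        vec[2 * i] = 1.0 / cc * (2 * p.threshold / 1.0)  # theta_fit = 2 theta / c
        vec[2 * i + 1] = p.drift / cc
    vec[-2], vec[-1] = m_prime, ter
    return vec


class TestChiSquareObjective:
    def test_nonnegative_and_length_checked(self, small_preprocessed):
        summaries = summarize_trials(small_preprocessed)
        truth = task.combined_ground_truth()
        vec = _truth_vector(truth, 0.45, 0.35)
        assert chi_square_objective(vec, summaries) >= 0
        with pytest.raises(ValueError):
            chi_square_objective(vec[:-1], summaries)

    def test_out_of_bounds_penalized(self, small_preprocessed):
        summaries = summarize_trials(small_preprocessed)
        vec = _truth_vector(task.combined_ground_truth(), 0.45, 0.35)
        bad = vec.copy()
        bad[0] = -1.0
        assert chi_square_objective(bad, summaries) >= fitting.PENALTY

    def test_perturbing_drift_increases_objective(self, small_preprocessed):
        summaries = summarize_trials(small_preprocessed)
        vec = _truth_vector(task.combined_ground_truth(), 0.45, 0.35)
        base = chi_square_objective(vec, summaries)
        for delta in (-0.8, 0.8):
            pert = vec.copy()
            pert[1] += delta  # first condition's drift
            assert chi_square_objective(pert, summaries) > base


class TestRescaling:
    def test_printed_identities(self):
        raw = fitting.FitResultRaw(
            conditions=[COND_ON],
            threshold_fit={COND_ON: 2.0},
            drift_fit={COND_ON: 1.0},
            start_fraction=0.5,
            non_decision=0.3,
            objective=1.0,
            n_evaluations=10,
            converged=True,
        )
        res = rescale_parameters(raw)
        assert res.drift[COND_ON] == pytest.approx(0.5)
        assert res.diffusion_var[COND_ON] == pytest.approx(0.25)
        assert res.start_bias == pytest.approx(0.0)
        assert res.threshold == 0.5

    def test_unit_threshold_gives_unit_diffusion(self):
        raw = fitting.FitResultRaw(
            [COND_ON], {COND_ON: 1.0}, {COND_ON: 0.7}, 0.6, 0.2, 0.0, 1, True
        )
        assert rescale_parameters(raw).diffusion_var[COND_ON] == pytest.approx(1.0)

    def test_round_trip_exact(self):
        raw = fitting.FitResultRaw(
            [COND_ON], {COND_ON: 1.7}, {COND_ON: -2.3}, 0.41, 0.33, 5.0, 1, True
        )
        res = rescale_parameters(raw)
        c = np.sqrt(res.diffusion_var[COND_ON])
        assert 1.0 / c == pytest.approx(1.7, abs=1e-12)
        assert res.drift[COND_ON] / c == pytest.approx(-2.3, abs=1e-12)

    def test_choice_probability_gauge_invariant(self):
        theta_fit, a_fit, m_prime = 1.6, 1.3, 0.42
        fit_frame = DDMParameters(theta_fit / 2, 2 * m_prime - 1, a_fit, 1.0)
        rescaled = DDMParameters(
            0.5, 2 * m_prime - 1, a_fit / theta_fit, 1.0 / theta_fit**2
        )
        assert ddm.choice_probability(fit_frame) == pytest.approx(
            ddm.choice_probability(rescaled), abs=1e-10
        )

    def test_nonpositive_threshold_rejected(self):
        raw = fitting.FitResultRaw(
            [COND_ON], {COND_ON: 0.0}, {COND_ON: 1.0}, 0.5, 0.3, 0.0, 1, True
        )
        with pytest.raises(ValueError):
            rescale_parameters(raw)


@pytest.fixture(scope="module")
def fitted(small_preprocessed):
    return QuantileDDMFitter(seed=0, **FAST_FIT).fit(small_preprocessed)


class TestFitMouse:
    def test_thirty_eight_parameters(self, fitted):
        assert fitted.raw_result_.n_free_parameters == 38
        assert sum(s.n_statistics for s in fitted.summaries_.values()) <= 216

    def test_objective_not_worse_than_heuristic_start(self, fitted, small_preprocessed):
        summaries = fitted.summaries_
        conds = sorted(summaries)
        rts = small_preprocessed["rt_normalized"].to_numpy()
        ter0 = min(0.95 * rts.min(), rts.min() - 1e-4)
        vec = np.empty(38)
        for i, c in enumerate(conds):
            vec[2 * i : 2 * i + 2] = fitting._moment_init(summaries[c], ter0)
        vec[-2], vec[-1] = 0.5, ter0
        init_obj = chi_square_objective(
            vec, summaries, outlier_window=fitted._window, ter_max=rts.min()
        )
        assert fitted.objective_ <= init_obj + 1e-9

    def test_recovers_generating_trends(self, fitted, small_config):
        truth = small_config.ground_truth
        drifts_true = np.array([truth[c].drift for c in fitted.result_.conditions])
        # rescale truth to the fit gauge (already theta = 1/2)
        drifts_est = np.array([fitted.drift_[c] for c in fitted.result_.conditions])
        r = np.corrcoef(drifts_true, drifts_est)[0, 1]
        assert r > 0.9

    def test_deterministic(self, small_preprocessed, fitted):
        again = QuantileDDMFitter(seed=0, **FAST_FIT).fit(small_preprocessed)
        assert again.drift_ == fitted.drift_
        assert again.objective_ == fitted.objective_

    def test_missing_condition_rejected(self, small_preprocessed):
        subset = small_preprocessed[
            ~(
                (small_preprocessed["target"] == "A")
                & (small_preprocessed["n_background"] == 5)
            )
        ]
        with pytest.raises(ValueError):
            QuantileDDMFitter(**FAST_FIT).fit(subset)

    def test_multiple_mice_rejected(self, small_preprocessed):
        doubled = small_preprocessed.copy()
        other = small_preprocessed.copy()
        other["mouse_id"] = "m2"
        import pandas as pd

        with pytest.raises(ValueError):
            QuantileDDMFitter(**FAST_FIT).fit(pd.concat([doubled, other]))


class TestRecoveryDegradesGracefully:
    def test_trend_signs_survive_small_samples(self):
        # ~100 trials per condition: point estimates get noisy but the
        # direction of both background trends should almost always hold
        wins = 0
        n_rep = 6
        for rep in range(n_rep):
            cfg = task.TaskConfig(n_sessions=8, complexity_b=1.0, seed=100 + rep)
            trials = task.generate_mouse_dataset(cfg)
            from odorddm import preprocessing

            kept, _ = preprocessing.filter_sessions(trials)
            kept = preprocessing.normalize_reaction_times(kept)
            _, res = fit_mouse(kept, seed=rep, **FAST_FIT)
            conds = res.conditions
            n_bg = np.array([c.n_background for c in conds])
            drift_slope = np.polyfit(n_bg, [abs(res.drift[c]) for c in conds], 1)[0]
            diff_slope = np.polyfit(n_bg, [res.diffusion_var[c] for c in conds], 1)[0]
            if drift_slope < 0 and diff_slope > 0:
                wins += 1
        assert wins >= n_rep - 1
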