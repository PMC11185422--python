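import numpy as np
import pytest

from vernier2ifc.data import collapse_to_level_summaries
from vernier2ifc.design import Task
from vernier2ifc.fitting import (
    ParticipantData,
    SubsetEligibilityError,
    bic,
    cv_logl,
    effective_counts,
    fit_evidence_strengths,
    fit_observer,
    fit_sigma_d,
    fit_subset,
    joint_log_likelihood,
    parametric_percent_correct,
    _fold_counts,
)
from vernier2ifc.observers import ObserverSpec, PredictionTable, simulate_prediction_table
from vernier2ifc.synth import GroundTruth, default_ground_truth, generate_dataset

from _oracles import enumerate_monotone_fit


def _analytic_table(p_by_c, sigma_values=(0.0,), p_int=0.7):
    """A deterministic toy prediction table with independent outcomes."""
    c_values = np.arange(len(p_by_c), dtype=float)
    probs = np.empty((len(p_by_c), len(sigma_values), 4))
    for i, po in enumerate(p_by_c):
        for j, _ in enumerate(sigma_values):
            probs[i, j] = [po * p_int, po * (1 - p_int),
                           (1 - po) * p_int, (1 - po) * (1 - p_int)]
    return PredictionTable(1, c_values, np.asarray(sigma_values, float),
                           probs, n_sim=1, seed=0)


class TestPercentCorrect:
    def test_monotone_fit_close_to_raw(self):
        rng = np.random.default_rng(0)
        x = np.linspace(16.7, 100, 6) / 100
        true = np.array([0.55, 0.63, 0.71, 0.8, 0.88, 0.95])
        k = rng.binomial(137, true)
        p = parametric_percent_correct(x, k, np.full(6, 137))
        assert np.all(np.diff(p) >= 0)
        assert np.max(np.abs(p - true)) < 0.05

    def test_floor_at_chance(self):
        x = np.linspace(16.7, 100, 6) / 100
        k = np.round(np.array([0.45, 0.5, 0.6, 0.7, 0.8, 0.9]) * 137).astype(int)
        p = parametric_percent_correct(x, k, np.full(6, 137))
        assert np.all(p >= 0.5)

    def test_flat_chance_stays_at_chance(self):
        x = np.linspace(16.7, 100, 6) / 100
        p = parametric_percent_correct(x, np.full(6, 68), np.full(6, 137))
        np.testing.assert_allclose(p, 0.5, atol=0.02)


class TestEvidenceStrengths:
    def test_matches_exhaustive_enumeration(self):
        """Constrained DP equals brute force on small grids."""
        rng = np.random.default_rng(1)
        c_grid = np.linspace(0, 5, 11)
        for trial in range(5):
            p_grid = np.sort(rng.uniform(0.5, 1.0, 11))
            n_corr = rng.integers(40, 100, 3)
            n_inc = rng.integers(5, 60, 3)
            got = fit_evidence_strengths(p_grid, n_corr, n_inc, c_grid)
            want, _ = enumerate_monotone_fit(p_grid, n_corr, n_inc, c_grid)
            np.testing.assert_allclose(got, want)

    def test_chance_targets_map_to_zero_strength(self):
        p_grid = np.linspace(0.5, 0.99, 51)
        c_grid = np.linspace(0, 5, 51)
        got = fit_evidence_strengths(p_grid, np.full(6, 68), np.full(6, 69), c_grid)
        np.testing.assert_allclose(got, 0.0)

    def test_output_monotone_even_for_inverted_targets(self):
        p_grid = np.linspace(0.5, 0.99, 51)
        c_grid = np.linspace(0, 5, 51)
        n = np.full(4, 137)
        acc = np.array([0.6, 0.7, 0.85, 0.75])  # level 3 easier than level 4
        got = fit_evidence_strengths(p_grid, np.round(acc * 137).astype(int),
                                     n - np.round(acc * 137).astype(int), c_grid)
        assert np.all(np.diff(got) >= 0)

    def test_known_strengths_recovered(self, table_m3):
        truth = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        p_true = np.array([table_m3.p_orientation_correct()[table_m3.c_index(c)]
                           for c in truth])
        n_corr, n_inc = effective_counts(np.full(6, 137), p_true)
        got = fit_evidence_strengths(table_m3.p_orientation_correct(),
                                     n_corr, n_inc, table_m3.c_values)
        assert np.max(np.abs(got - truth)) <= 0.2


class TestLikelihoodAndBIC:
    def test_single_level_arithmetic(self):
        table = _analytic_table([0.9], p_int=1.0)
        ll = joint_log_likelihood(table, np.array([0.0]), 0.0,
                                  np.array([[10, 0, 0, 0]]))
        assert ll == pytest.approx(10 * np.log(0.9))

    def test_equals_trial_by_trial_sum(self):
        table = _analytic_table([0.7, 0.9], p_int=0.6)
        counts = np.array([[5, 2, 1, 3], [7, 1, 2, 0]])
        ll = joint_log_likelihood(table, np.array([0.0, 1.0]), 0.0, counts)
        brute = 0.0
        for lev, c in enumerate([0.0, 1.0]):
            p = table.joint(c, 0.0)
            for cell in range(4):
                brute += counts[lev, cell] * np.log(p[cell])
        assert ll == pytest.approx(brute, abs=1e-12)

    def test_level_permutation_invariance(self):
        table = _analytic_table([0.6, 0.8, 0.95])
        counts = np.array([[5, 2, 1, 3], [7, 1, 2, 0], [9, 3, 1, 1]])
        a = joint_log_likelihood(table, np.array([0.0, 1.0, 2.0]), 0.0, counts)
        b = joint_log_likelihood(table, np.array([2.0, 0.0, 1.0]), 0.0,
                                 counts[[2, 0, 1]])
        assert a == pytest.approx(b, abs=1e-12)

    def test_bic_formula(self):
        assert bic(-100.0, 6, 822) == pytest.approx(200 + 6 * np.log(822))
        assert bic(-50.0, 0, 10) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            bic(-1.0, 1, 0)

    def test_ideal_noisy_bic_identity(self):
        # same logL, k differing by one: BIC difference is exactly ln(n)
        n = 822
        assert (bic(-100.0, 7, n) - bic(-100.0, 6, n)) == pytest.approx(np.log(n))


class TestSigmaFitting:
    def test_argmax_dominates_zero(self, table_m3):
        counts = np.array([[40, 30, 35, 32]] * 6)
        c_hat = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        s_hat, ll = fit_sigma_d(table_m3, c_hat, counts)
        ll0 = joint_log_likelihood(table_m3, c_hat, 0.0, counts)
        assert ll >= ll0
        assert s_hat in table_m3.sigma_values


class TestCrossValidation:
    def test_ideal_score_equals_full_likelihood(self, table_m3):
        counts = np.array([[50, 30, 30, 27]] * 6)
        c_hat = np.array([0.5, 0.5, 1.0, 1.5, 2.0, 2.0])
        mean, scores = cv_logl(table_m3, c_hat, counts, variant="ideal")
        assert mean == joint_log_likelihood(table_m3, c_hat, 0.0, counts)
        assert scores.size == 1

    def test_same_seed_bitwise_identical(self, table_m3):
        counts = np.array([[50, 30, 30, 27]] * 6)
        c_hat = np.array([0.5, 0.5, 1.0, 1.5, 2.0, 2.0])
        m1, s1 = cv_logl(table_m3, c_hat, counts, folds=5, resamples=3, seed=8)
        m2, s2 = cv_logl(table_m3, c_hat, counts, folds=5, resamples=3, seed=8)
        assert m1 == m2
        np.testing.assert_array_equal(s1, s2)

    def test_fold_balance_within_one_trial(self):
        rng = np.random.default_rng(2)
        counts = np.array([[50, 30, 30, 27], [61, 20, 35, 21]])
        folds = _fold_counts(counts, 10, rng)
        np.testing.assert_array_equal(folds.sum(axis=0), counts)
        per_level_totals = folds.sum(axis=2)  # (folds, levels)
        assert np.all(per_level_totals.max(axis=0)
                      - per_level_totals.min(axis=0) <= 1)


class TestSubsets:
    def test_incorrect_only_empty_subset_rejected(self, table_m3):
        pdata = ParticipantData(
            "P01", Task.MASKED, np.arange(1, 7),
            np.column_stack([np.full(6, 80), np.full(6, 57),
                             np.zeros(6, int), np.zeros(6, int)]))
        with pytest.raises(ValueError, match="no incorrect"):
            fit_subset(table_m3, pdata, "incorrect_only")

    def test_easy_subset_screens_low_performers(self, table_m3):
        # pooled orientation accuracy ~55% at the easiest levels: ineligible
        low = ParticipantData(
            "P01", Task.MASKED, np.arange(1, 7),
            np.tile([40, 35, 30, 32], (6, 1)))
        with pytest.raises(SubsetEligibilityError, match="below"):
            fit_subset(table_m3, low, "easy")

    def test_hard_subset_screens_high_performers(self, table_m3):
        high = ParticipantData(
            "P01", Task.MASKED, np.arange(1, 7),
            np.tile([80, 50, 4, 3], (6, 1)))
        with pytest.raises(SubsetEligibilityError, match="at or above"):
            fit_subset(table_m3, high, "hard")


class TestFullRecovery:
    def test_generate_and_fit_recovers_noise_contrast(self, table_m3):
        """Noise concentrated in the hard conditions is recovered as
        sigma(hard) > sigma(easy) by the subset refits."""
        sigma_by_level = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        truth = GroundTruth(
            task=Task.MASKED, observer=ObserverSpec(3),
            c_per_participant=[np.array([0.3, 0.6, 1.2, 1.7, 2.2, 2.6])] * 6,
            sigma_d_per_participant=[sigma_by_level] * 6,
            trials_per_level=[137] * 6,
        )
        trials = generate_dataset(truth, seed=21)
        summaries = collapse_to_level_summaries(trials)
        by_part = {}
        for s in summaries:
            by_part.setdefault(s.participant_id, []).append(s)
        easy_sigmas, hard_sigmas = [], []
        for pid, rows in sorted(by_part.items()):
            pdata = ParticipantData.from_summaries(rows)
            easy_sigmas.append(
                fit_subset(table_m3, pdata, "easy", run_cv=False).sigma_d_hat)
            hard_sigmas.append(
                fit_subset(table_m3, pdata, "hard", run_cv=False).sigma_d_hat)
        assert np.median(hard_sigmas) > np.median(easy_sigmas)

    def test_noisy_fit_recovers_sigma(self, table_m3):
        truth = default_ground_truth(Task.MASKED, model_id=3, sigma_d=0.5,
                                     n_participants=4, seed=30)
        truth.trials_per_level = [137] * 4
        trials = generate_dataset(truth, seed=31)
        summaries = collapse_to_level_summaries(trials)
        by_part = {}
        for s in summaries:
            by_part.setdefault(s.participant_id, []).append(s)
        errs = []
        for pid, rows in sorted(by_part.items()):
            res = fit_observer(table_m3, ParticipantData.from_summaries(rows),
                               "noisy", run_cv=False)
            errs.append(abs(res.sigma_d_hat - 0.5))
        assert np.median(errs) <= 0.15
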