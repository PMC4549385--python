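"""Response-feature analysis: z-scoring, model fits, selection, PCA, ranking."""

import numpy as np
import pandas as pd
import pytest

from gmvrec.recovery import (
    DEFAULT_VISIT_DAYS,
    ModelFit,
    NormTable,
    TrajectorySeries,
    aicc,
    classify_recovery,
    classify_series,
    fit_recovery_models,
    interpolate_missing,
    pc_recovery_scores,
    rank_subtests,
    select_model,
    zscore_series,
)
from gmvrec.synthcohort import (
    DEFAULT_MODEL_PARAMS,
    DEFAULT_NORMS,
    CohortSpec,
    evaluate_model,
    generate_cohort_trajectories,
)

DAYS = np.asarray(DEFAULT_VISIT_DAYS, dtype=float)


def _series(z, days=DAYS):
    return TrajectorySeries("s", "pso", days, z=np.asarray(z, float))


class TestZScoring:
    def test_control_mean_maps_to_zero(self):
        s = TrajectorySeries("s", "pso", [7.0], scores=[5.7])
        assert zscore_series(s, DEFAULT_NORMS).z[0] == pytest.approx(0.0)

    def test_normal_band_boundary(self):
        # score = mu + 2.5 sigma sits exactly at the impairment boundary
        s = TrajectorySeries("s", "pso", [7.0], scores=[5.7 + 2.5 * 0.7])
        assert zscore_series(s, DEFAULT_NORMS).z[0] == pytest.approx(-2.5)

    def test_arithmetic_example(self):
        s = TrajectorySeries("s", "pso", [7.0], scores=[7.45])
        assert zscore_series(s, DEFAULT_NORMS).z[0] == pytest.approx(-2.5)

    def test_unknown_task_raises(self):
        s = TrajectorySeries("s", "nonexistent", [7.0], scores=[5.0])
        with pytest.raises(KeyError):
            zscore_series(s, DEFAULT_NORMS)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            NormTable({"pso": (5.7, 0.0)})


class TestModelFits:
    def test_linear_fit_recovers_noiseless_parameters(self):
        z = -0.9 + 0.005 * DAYS
        fits = fit_recovery_models(_series(z))
        lin = fits[0]
        assert abs(lin.I - (-0.9)) / 0.9 < 1e-6
        assert abs(lin.beta - 0.005) / 0.005 < 1e-6

    def test_exponential_fit_recovers_slow_rate(self):
        z = evaluate_model(DEFAULT_MODEL_PARAMS["slow"], DAYS, "slow")
        exp_fit = fit_recovery_models(_series(z))[1]
        assert round(exp_fit.beta, 3) == 0.023
        assert exp_fit.I == pytest.approx(-5.9, rel=1e-5)

    def test_constant_series_degenerate_offset_solution(self):
        # z = -3 is fitted exactly by I = 0, c = -3 with beta free
        fits = fit_recovery_models(_series(np.full(10, -3.0)))
        off = fits[2]
        assert off.rss < 1e-18
        assert off.c == pytest.approx(-3.0, abs=1e-6)
        assert abs(off.I) < 1e-6

    def test_aicc_matches_independent_formula(self):
        rng = np.random.default_rng(5)
        z = evaluate_model(DEFAULT_MODEL_PARAMS["poor"], DAYS, "poor") + rng.normal(
            0, 0.3, DAYS.size
        )
        for f in fit_recovery_models(_series(z)):
            n, k = f.n_obs, f.k_params
            expected = (
                n * np.log(max(f.rss, 1e-30) / n)
                + 2 * k
                + 2 * k * (k + 1) / (n - k - 1)
            )
            assert f.aicc == pytest.approx(expected, rel=1e-12)

    def test_too_few_visits_rejected(self):
        with pytest.raises(ValueError, match="5 visits"):
            fit_recovery_models(_series([1, 2, 3, 4], days=DAYS[:4]))


def _fit(kind, aicc_val, k):
    return ModelFit(kind, -1.0, 0.01, None, 1.0, 10, k, aicc_val)


class TestModelSelection:
    def test_equal_fit_prefers_fewer_parameters(self):
        fits = [_fit("exp", 10.0, 3), _fit("exp_offset", 10.0, 4)]
        assert select_model(fits).kind == "exp"

    def test_two_unit_band_parsimony_rule(self):
        fits = [
            _fit("linear", 10.0, 3),
            _fit("exp", 10.5, 4),
            _fit("exp_offset", 14.0, 4),
        ]
        assert select_model(fits).kind == "linear"

    def test_clear_winner_outside_band(self):
        fits = [_fit("linear", 20.0, 3), _fit("exp", 10.0, 3)]
        assert select_model(fits).kind == "exp"

    def test_all_infinite_aicc_rejected(self):
        fits = [_fit("linear", np.inf, 3), _fit("exp", np.inf, 3)]
        with pytest.raises(ValueError):
            select_model(fits)

    def test_time_unit_rescaling_leaves_selection_invariant(self):
        rng = np.random.default_rng(11)
        for label in ("fast", "slow", "poor"):
            z = evaluate_model(DEFAULT_MODEL_PARAMS[label], DAYS, label) + rng.normal(
                0, 0.3, DAYS.size
            )
            a = select_model(fit_recovery_models(_series(z)))
            b = select_model(fit_recovery_models(_series(z, days=DAYS / 10.0)))
            assert a.kind == b.kind
            if a.kind != "linear":
                assert b.beta == pytest.approx(10 * a.beta, rel=1e-3)


class TestClassification:
    def test_linear_labelled_fast(self):
        best = ModelFit("linear", -0.9, 0.005, None, 0.1, 10, 3, -10.0)
        assert classify_recovery(best).label == "fast"

    def test_chronic_offset_below_cutoff_labelled_poor(self):
        best = ModelFit("exp_offset", -23.4, 0.031, -5.5, 0.1, 10, 4, -10.0)
        cls = classify_recovery(best)
        assert cls.label == "poor"
        assert cls.asymptote == -5.5

    def test_offset_above_cutoff_labelled_slow(self):
        best = ModelFit("exp_offset", -5.0, 0.02, -1.0, 0.1, 10, 4, -10.0)
        assert classify_recovery(best).label == "slow"

    def test_pure_exponential_labelled_slow(self):
        best = ModelFit("exp", -5.9, 0.023, None, 0.1, 10, 3, -10.0)
        cls = classify_recovery(best)
        assert cls.label == "slow" and cls.asymptote == 0.0

    def test_negative_slope_linear_warns_but_stays_fast(self):
        best = ModelFit("linear", -0.9, -0.002, None, 0.1, 10, 3, -10.0)
        with pytest.warns(UserWarning, match="negative slope"):
            assert classify_recovery(best).label == "fast"


class TestPCScores:
    def test_rank_one_matrix_explains_all_variance(self):
        traj = np.linspace(-5, 0, 10)
        Z = np.outer([1.0, 2.0, 3.0, 0.5], traj)
        pc = pc_recovery_scores(Z)
        assert pc.explained_variance_fraction == pytest.approx(1.0)

    def test_toy_matrix_matches_brute_force_eigendecomposition(self):
        Z = np.array([[1.0, 2.0], [3.0, 5.0], [-1.0, 0.0]])
        C = Z - Z.mean(0)
        evals, evecs = np.linalg.eigh(C.T @ C)  # 2x2, ascending
        v = evecs[:, -1]
        pc = pc_recovery_scores(Z)
        assert abs(abs(pc.loadings @ v) - 1.0) < 1e-10
        expected_scores = C @ v
        got = pc.scores
        if np.sign(got[0]) != np.sign(expected_scores[0]):
            expected_scores = -expected_scores
        np.testing.assert_allclose(got, expected_scores, atol=1e-10)
        assert pc.explained_variance_fraction == pytest.approx(
            evals[-1] / evals.sum()
        )

    def test_scores_order_subgroups_by_impairment(self):
        spec = CohortSpec(n_fast=5, n_slow=15, n_poor=8, noise_sd=0.3, seed=21)
        cohort = generate_cohort_trajectories(spec)
        pc = pc_recovery_scores(cohort.z_matrix("pso"))
        med = {
            lab: np.median(pc.scores[cohort.subjects.true_label.to_numpy() == lab])
            for lab in ("fast", "slow", "poor")
        }
        assert med["fast"] < med["slow"] < med["poor"]

    def test_scores_invariant_to_subject_order(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(8, 10))
        pc = pc_recovery_scores(Z)
        perm = rng.permutation(8)
        pc2 = pc_recovery_scores(Z[perm])
        np.testing.assert_allclose(pc2.scores, pc.scores[perm], atol=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pc_recovery_scores(np.ones((4, 10)))


class TestRanking:
    @staticmethod
    def _table(task_z: dict):
        rows = []
        for task, Z in task_z.items():
            for i, row in enumerate(Z):
                for d, z in zip(DAYS, row):
                    rows.append((f"s{i}", task, d, z))
        return pd.DataFrame(rows, columns=["subject_id", "task_id", "visit_day", "z"])

    def test_constant_task_ranked_last(self):
        rng = np.random.default_rng(2)
        recovering = np.array(
            [evaluate_model(DEFAULT_MODEL_PARAMS["slow"], DAYS, "slow") for _ in range(6)]
        ) + rng.normal(0, 0.3, (6, 10))
        flat = np.tile(np.full(10, -1.0), (6, 1))
        crits = rank_subtests(self._table({"recover": recovering, "flat": flat}))
        assert crits[-1].task_id == "flat"
        assert crits[-1].longitudinal_effect_p > 0.9

    def test_stronger_criteria_rank_first(self):
        rng = np.random.default_rng(4)
        base = evaluate_model(DEFAULT_MODEL_PARAMS["poor"], DAYS, "poor")
        task_a = np.array([base for _ in range(8)]) + rng.normal(0, 0.9, (8, 10))
        task_b = 0.3 * np.array([base for _ in range(8)]) + rng.normal(0, 0.3, (8, 10))
        crits = rank_subtests(self._table({"b_task": task_b, "a_task": task_a}))
        assert crits[0].task_id == "a_task"
        assert crits[0].within_subject_variance > crits[1].within_subject_variance
        assert crits[0].prop_impaired_final >= crits[1].prop_impaired_final

    def test_identical_tasks_tie_broken_by_task_id(self):
        rng = np.random.default_rng(6)
        Z = np.array(
            [evaluate_model(DEFAULT_MODEL_PARAMS["slow"], DAYS, "slow") for _ in range(5)]
        ) + rng.normal(0, 0.3, (5, 10))
        crits = rank_subtests(self._table({"b": Z, "a": Z}))
        assert [c.task_id for c in crits] == ["a", "b"]
        assert crits[0].composite_rank == crits[1].composite_rank


class TestInterpolation:
    def test_interior_gaps_filled_linearly(self):
        z = np.array([0.0, np.nan, 2.0, np.nan, 4.0])
        t = np.array([0.0, 1, 2, 3, 4])
        np.testing.assert_allclose(interpolate_missing(t, z), [0, 1, 2, 3, 4])

    def test_edge_gap_rejected(self):
        with pytest.raises(ValueError, match="first or last"):
            interpolate_missing(np.arange(5.0), np.array([np.nan, 1, 2, 3, 4.0]))

    def test_too_many_gaps_rejected(self):
        z = np.array([0.0, np.nan, np.nan, np.nan, 4.0])
        with pytest.raises(ValueError, match="exceeds"):
            interpolate_missing(np.arange(5.0), z)


def test_classify_series_end_to_end(subgroup_model):
    z = subgroup_model("poor", DAYS)
    cls = classify_series(_series(z))
    assert cls.label == "poor"
    assert cls.asymptote == pytest.approx(-5.5, abs=0.05)
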