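"""Sliding-window FNC estimation: taper, covariance, glasso, Fisher z, covariates."""
import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conftest import make_wfnc

from dfncstates import (
    ComponentTimecourse,
    FNCConfig,
    GlassoConfig,
    estimate_run_fnc,
    fisher_z,
    gaussian_tapered_window,
    glasso_precision,
    make_state_covariances,
    precision_to_fc,
    regress_covariates,
    select_lambda_cv,
    simulate_run,
    simulate_state_sequence,
    sliding_window_offsets,
    sticky_transition_model,
    vec_upper,
    weighted_window_covariance,
)
from dfncstates.connectivity import TaperedWindow, _all_window_covariances


class TestTaper:
    def test_study_taper_is_symmetric_and_center_heavy(self):
        taper = gaussian_tapered_window(22, 3.0)
        w = taper.weights
        assert len(w) == 22
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)
        assert set(np.argsort(w)[-2:]) == {10, 11}  # the two central samples
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_vanishing_sigma_recovers_uniform_window(self):
        taper = gaussian_tapered_window(22, 1e-9)
        np.testing.assert_allclose(taper.weights, 1 / 22, atol=1e-9)

    def test_rejects_degenerate_windows(self):
        with pytest.raises(ValueError):
            gaussian_tapered_window(1, 3.0)
        with pytest.raises(ValueError):
            gaussian_tapered_window(22, 0.0)


class TestOffsets:
    @pytest.mark.parametrize(
        "t_len,width,step,expected",
        [(200, 22, 1, 178), (23, 22, 1, 1), (100, 20, 5, 16)],
    )
    def test_window_count_convention(self, t_len, width, step, expected):
        offsets = sliding_window_offsets(t_len, width, step)
        assert len(offsets) == expected
        assert offsets[0] == 0
        assert np.all(np.diff(offsets) == step)

    def test_run_no_longer_than_window_raises(self):
        with pytest.raises(ValueError):
            sliding_window_offsets(22, 22)


class TestWindowCovariance:
    def test_identical_columns_have_unit_correlation(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(10)
        data = np.column_stack([col, col])
        taper = TaperedWindow(np.full(10, 0.1), 10, 1.0)
        cov = weighted_window_covariance(data, 0, taper)
        r = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_uniform_weights_match_textbook_covariance(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((5, 3))
        taper = TaperedWindow(np.full(5, 0.2), 5, 1.0)
        cov = weighted_window_covariance(data, 0, taper)
        np.testing.assert_allclose(cov, np.cov(data.T, bias=True), atol=1e-12)

    def test_half_support_weights_recover_first_half_covariance(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((20, 3))
        w = np.concatenate([np.full(10, 0.1), np.full(10, 1e-15)])
        taper = TaperedWindow(w / w.sum(), 20, 1.0)
        cov = weighted_window_covariance(data, 0, taper)
        np.testing.assert_allclose(cov, np.cov(data[:10].T, bias=True), atol=1e-10)

    def test_vectorized_covariances_match_single_window_path(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((40, 4))
        taper = gaussian_tapered_window(10, 2.0)
        offsets = sliding_window_offsets(40, 10)
        stack = _all_window_covariances(data, offsets, taper)
        for i, off in enumerate(offsets):
            np.testing.assert_allclose(
                stack[i], weighted_window_covariance(data, off, taper), atol=1e-12
            )


class TestGlasso:
    def test_unpenalized_solution_is_the_inverse(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((60, 4))
        s = np.cov(a.T)
        theta = glasso_precision(s, 0.0)
        np.testing.assert_allclose(theta, np.linalg.inv(s), atol=1e-6)

    def test_heavy_penalty_zeroes_all_off_diagonals(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((60, 4))
        s = np.cov(a.T)
        theta = glasso_precision(s, 50.0)
        off = theta - np.diag(np.diag(theta))
        assert np.abs(off).max() == 0.0
        np.testing.assert_allclose(np.diag(theta), 1 / np.diag(s), atol=1e-8)

    def test_matches_independent_coordinate_descent_oracle(self):
        from sklearn.covariance import graphical_lasso

        rng = np.random.default_rng(2)
        a = rng.standard_normal((50, 4))
        s = np.cov(a.T)
        for lam in (0.05, 0.1, 0.3):
            theta = glasso_precision(s, lam, GlassoConfig(tol=1e-8))
            _, oracle = graphical_lasso(s, alpha=lam, tol=1e-10, mode="lars")
            assert np.abs(theta - oracle).max() < 1e-5

    def test_objective_trace_is_non_increasing(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((30, 6))
        s = np.cov(a.T)
        _, info = glasso_precision(s, 0.1, return_info=True)
        assert np.all(np.diff(info["trace"]) <= 1e-10)
        assert abs(info["gap"]) < GlassoConfig().tol * 6

    def test_handles_rank_deficient_covariance(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((6, 10))  # fewer samples than variables
        s = np.cov(a.T, bias=True) + 0.0
        np.fill_diagonal(s, np.diag(s) + 1e-10)
        theta = glasso_precision(s, 0.1)
        assert np.linalg.eigvalsh(theta)[0] > 0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            glasso_precision(np.array([[1.0, 0.5], [0.4, 1.0]]), 0.1)
        with pytest.raises(ValueError):
            glasso_precision(np.eye(3), -0.1)
        singular = np.ones((3, 3))
        with pytest.raises(ValueError):
            glasso_precision(singular, 0.0)


class TestPrecisionToFC:
    def test_identity_precision_gives_identity_correlation(self):
        np.testing.assert_allclose(precision_to_fc(np.eye(4)), np.eye(4))

    def test_diagonal_precision_gives_zero_off_diagonals(self):
        fc = precision_to_fc(np.diag([2.0, 5.0, 0.5]))
        np.testing.assert_allclose(fc, np.eye(3), atol=1e-12)

    def test_matches_direct_linear_algebra(self):
        rng = np.random.default_rng(5)
        m = rng.standard_normal((4, 4))
        theta = m @ m.T + 4 * np.eye(4)
        fc = precision_to_fc(theta)
        cov = np.linalg.inv(theta)
        d = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(fc, cov / np.outer(d, d), atol=1e-10)
        assert np.abs(fc[np.triu_indices(4, 1)]).max() < 1

    def test_indefinite_precision_raises(self):
        with pytest.raises(ValueError):
            precision_to_fc(np.diag([1.0, -1.0]))


class TestLambdaSelection:
    def test_single_value_grid_is_returned(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((60, 4))
        taper = gaussian_tapered_window(10, 2.0)
        offsets = sliding_window_offsets(60, 10)
        config = GlassoConfig(lambda_grid=np.array([0.2]))
        assert select_lambda_cv(data, offsets, taper, config) == 0.2

    def test_selected_lambda_beats_grid_endpoints_on_sparse_data(self):
        covs = make_state_covariances(6, 1, block_spec=[3, 3],
                                      within_block_r=0.5, cross_block_r=0.0)
        labels = np.ones(150, dtype=int)
        tc, _ = simulate_run(covs, labels, seed=11)
        taper = gaussian_tapered_window(22, 3.0)
        offsets = sliding_window_offsets(150, 22)
        config = GlassoConfig()
        lam, scores = select_lambda_cv(tc, offsets, taper, config, return_scores=True)
        chosen = int(np.flatnonzero(config.lambda_grid == lam)[0])
        assert scores[chosen] >= scores[0]
        assert scores[chosen] >= scores[-1]

    def test_independent_components_favor_strong_penalties(self):
        taper = gaussian_tapered_window(22, 3.0)
        config = GlassoConfig()
        top = 0
        n_reps = 50
        for rep in range(n_reps):
            rng = np.random.default_rng(300 + rep)
            data = rng.standard_normal((500, 5))
            offsets = sliding_window_offsets(500, 22)
            lam = select_lambda_cv(data, offsets, taper, config)
            top += lam >= config.lambda_grid[-3]
        assert top >= 0.8 * n_reps

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            GlassoConfig(lambda_grid=np.array([]))


class TestFisherZ:
    def test_known_values(self):
        fc = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = fisher_z(fc)
        assert z[0, 1] == pytest.approx(0.549306, abs=1e-6)
        assert z[0, 0] == 0.0
        np.testing.assert_allclose(fisher_z(-fc + 2 * np.eye(2)), -z, atol=1e-12)
        np.testing.assert_allclose(fisher_z(np.eye(3)), np.zeros((3, 3)))

    def test_perfect_correlation_rejected(self):
        fc = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            fisher_z(fc)


def _toy_subject_wfncs(n_subjects, n_windows=6, c=4, seed=0, effect=None):
    """Synthetic per-subject z stacks, optionally with an age effect on edge (0,1)."""
    rng = np.random.default_rng(seed)
    ages = np.linspace(20, 60, n_subjects)
    wfncs = []
    for i in range(n_subjects):
        z = 0.2 * rng.standard_normal((n_windows, c, c))
        z = (z + z.transpose(0, 2, 1)) / 2
        ii = np.arange(c)
        z[:, ii, ii] = 0.0
        if effect is not None:
            z[:, 0, 1] += effect * ages[i]
            z[:, 1, 0] += effect * ages[i]
        wfncs.append(make_wfnc(z, subject=f"sub-{i:03d}"))
    import pandas as pd

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n_subjects)],
            "age": ages,
            "sex": rng.choice(["F", "M"], n_subjects),
            "mean_fd": np.abs(rng.normal(0.12, 0.05, n_subjects)),
        }
    )
    return wfncs, table


class TestCovariateRegression:
    def test_identical_covariates_change_nothing(self):
        wfncs, table = _toy_subject_wfncs(8, seed=1)
        table["age"] = 30.0
        table["sex"] = "F"
        table["mean_fd"] = 0.1
        out = regress_covariates(wfncs, table)
        for w_in, w_out in zip(wfncs, out):
            np.testing.assert_allclose(w_in.z, w_out.z, atol=1e-10)

    def test_planted_age_effect_is_removed(self):
        wfncs, table = _toy_subject_wfncs(20, seed=2, effect=0.05)
        out = regress_covariates(wfncs, table)
        means = np.array([w.z[:, 0, 1].mean() for w in out])
        r = np.corrcoef(means, table["age"])[0, 1]
        assert abs(r) < 0.05

    def test_null_adjustment_is_small(self):
        wfncs, table = _toy_subject_wfncs(20, seed=3)
        out = regress_covariates(wfncs, table)
        change = np.mean([np.abs(a.z - b.z).mean() for a, b in zip(wfncs, out)])
        # Null fitted effects scale like sigma * sqrt(p / n).
        assert change < 3 * 0.2 * np.sqrt(3 / 20)

    def test_too_few_subjects_rejected(self):
        wfncs, table = _toy_subject_wfncs(4, seed=4)
        with pytest.raises(ValueError):
            regress_covariates(wfncs, table)

    def test_missing_subject_rejected(self):
        wfncs, table = _toy_subject_wfncs(8, seed=5)
        with pytest.raises(ValueError):
            regress_covariates(wfncs, table.iloc[:-1])


class TestEndToEnd:
    def test_windows_sit_closest_to_their_own_state(self):
        """High-SNR planted states: windows away from transitions match their state."""
        covs = make_state_covariances(10, 4, within_block_r=0.7, cross_block_r=0.6)
        model = sticky_transition_model(4, 0.975)
        rng = np.random.default_rng(42)
        true_vecs = []
        for cov in covs.covariances:
            z = np.arctanh(np.clip(cov - np.eye(10) * cov, -0.999, 0.999))
            np.fill_diagonal(z, 0.0)
            true_vecs.append(vec_upper(z))
        true_vecs = np.stack(true_vecs)
        hits = total = 0
        for rep in range(3):
            labels = simulate_state_sequence(200, model, seed=rng)
            tc, _ = simulate_run(covs, labels, seed=rng)
            wfnc = estimate_run_fnc(tc, FNCConfig())
            vecs = vec_upper(wfnc.z)
            for i, off in enumerate(wfnc.offsets):
                seg = labels[off : off + 22]
                if np.all(seg == seg[0]):
                    d = cdist(vecs[i : i + 1], true_vecs, "cityblock")[0]
                    hits += int(np.argmin(d) + 1 == seg[0])
                    total += 1
        assert total > 100
        assert hits / total >= 0.9

    def test_z_matrices_symmetric_and_finite(self):
        covs = make_state_covariances(8, 2)
        labels = simulate_state_sequence(60, sticky_transition_model(2, 0.9), seed=1)
        tc, _ = simulate_run(covs, labels, seed=2)
        wfnc = estimate_run_fnc(tc, FNCConfig(width=10, sigma=1.5))
        assert wfnc.n_windows == 50
        assert np.isfinite(wfnc.z).all()
        assert np.abs(wfnc.z - wfnc.z.transpose(0, 2, 1)).max() < 1e-10
        assert np.abs(np.einsum("nii->ni", wfnc.z)).max() == 0.0
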