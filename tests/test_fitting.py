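"""OLS beta estimation, bounded optimization, and cross-validation."""

import numpy as np
import pytest

from temporal_channels import (
    ModelParams,
    cross_validate,
    fit_betas,
    optimize_params,
)
from temporal_channels.channels import PARAM_BOUNDS
from temporal_channels.fitting import RunData, make_folds
from temporal_channels.forward import ForwardModel
from temporal_channels.synthetic import (
    default_designs,
    generate_dataset,
    lateral_like,
    noise_sd_for_snr,
    ventral_like,
)


@pytest.fixture(scope="module")
def small_designs():
    return default_designs(runs_per_experiment=2, seed=3)


@pytest.fixture(scope="module")
def design_matrix(small_designs, ventral_params):
    fm = ForwardModel([d for _, d in small_designs[:2]])
    return fm.design_matrix("A+S", ventral_params)


class TestFitBetas:
    def test_noiseless_exact_recovery(self, design_matrix, rng):
        beta_true = rng.uniform(-1, 2, design_matrix.X.shape[1])
        y = design_matrix.X @ beta_true
        fit = fit_betas(design_matrix, y)
        np.testing.assert_allclose(fit.coef, beta_true, atol=1e-9)

    def test_matches_normal_equations_oracle(self, design_matrix, rng):
        y = design_matrix.X @ rng.uniform(0, 1, design_matrix.X.shape[1])
        y = y + rng.normal(0, 0.3, y.size)
        fit = fit_betas(design_matrix, y)
        A = design_matrix.X
        oracle = np.linalg.solve(A.T @ A, A.T @ y)  # independent normal equations
        np.testing.assert_allclose(fit.coef, oracle, atol=1e-8)
        # residuals orthogonal to the design
        resid = y - A @ fit.coef
        assert np.abs(A.T @ resid).max() < 1e-8

    def test_orthogonalized_noise_gives_zero_betas(self, design_matrix, rng):
        A = design_matrix.X
        noise = rng.normal(size=A.shape[0])
        proj = A @ np.linalg.lstsq(A, noise, rcond=None)[0]
        fit = fit_betas(design_matrix, noise - proj)
        np.testing.assert_allclose(fit.coef, 0.0, atol=1e-9)

    def test_rank_deficiency_names_columns(self, design_matrix):
        X = design_matrix
        X2 = type(X)(
            X=np.column_stack([X.X, X.X[:, 0]]),
            columns=X.columns + ["sustained.face.copy"],
            n_predictors=X.n_predictors,
            run_slices=X.run_slices,
            channel_blocks=X.channel_blocks,
            normalization=X.normalization,
            variant=X.variant,
        )
        with pytest.raises(ValueError, match="rank deficient"):
            fit_betas(X2, np.zeros(X2.X.shape[0]))


class TestOptimizeParams:
    @pytest.fixture(scope="class")
    def cts_fit(self):
        truth = ventral_like(noise_sd=0.1, seed=5)
        runs, _ = generate_dataset(truth, default_designs(1, seed=5))
        return optimize_params("CTS", runs, maxiter=8)

    def test_objective_never_worse_than_init(self, cts_fit):
        assert cts_fit.objective <= cts_fit.objective_init

    def test_params_within_bounds(self, cts_fit):
        for name in cts_fit.free_names:
            lo, hi = PARAM_BOUNDS[name]
            assert lo <= getattr(cts_fit.params, name) <= hi

    def test_glm_has_no_free_parameters(self):
        truth = ventral_like(noise_sd=0.1, seed=5)
        runs, _ = generate_dataset(truth, default_designs(1, seed=5))
        out = optimize_params("GLM", runs)
        assert out.free_names == ()
        assert out.converged

    def test_beta_recovery_under_noise(self):
        """At SNR 5, recovered channel x category betas track the ground
        truth closely across seeded datasets."""
        base = ventral_like()
        true_b, fit_b = [], []
        for seed in range(20):
            designs = default_designs(1, seed=seed)
            sd = noise_sd_for_snr(base, designs, 5.0)
            truth = ventral_like(noise_sd=sd, seed=seed)
            runs, _ = generate_dataset(truth, designs)
            opt = optimize_params("A+S", runs, maxiter=10)
            fm = ForwardModel([r.design for r in runs])
            X = fm.design_matrix("A+S", opt.params)
            fit = fit_betas(X, np.concatenate([r.series for r in runs]))
            true_b.append(truth.beta_vector())
            fit_b.append(fit.predictor_coef)
        r = np.corrcoef(np.concatenate(true_b), np.concatenate(fit_b))[0, 1]
        assert r > 0.95


class TestCrossValidate:
    def test_fold_symmetry(self, small_designs):
        truth = ventral_like(noise_sd=0.3, seed=9)
        runs, _ = generate_dataset(truth, small_designs)
        folds = make_folds(runs, 2)
        a = cross_validate("GLM", runs, folds=folds)
        b = cross_validate("GLM", runs, folds=folds[::-1])
        assert a.x_r2 == b.x_r2
        assert a.params == b.params

    def test_rejects_too_few_runs(self):
        truth = ventral_like(noise_sd=0.1, seed=2)
        runs, _ = generate_dataset(truth, default_designs(1, seed=2))
        with pytest.raises(ValueError, match="need at least"):
            cross_validate("GLM", runs, n_folds=2)

    def test_shuffled_series_scores_at_or_below_zero(self, small_designs, rng):
        """Permuting samples within each run destroys the stimulus-response
        alignment; average held-out x-R^2 is non-positive."""
        truth = ventral_like(noise_sd=0.3, seed=4)
        runs, _ = generate_dataset(truth, small_designs)
        vals = []
        for _ in range(100):
            shuffled = [
                RunData(r.experiment, r.design, rng.permutation(r.series), r.run_id)
                for r in runs
            ]
            vals.append(cross_validate("GLM", shuffled).x_r2_mean)
        assert np.mean(vals) <= 0.0
        assert min(vals) < 0.0  # x-R^2 is reported as negative when it is

    def test_transient_only_data_favors_s_over_dual(self, small_designs):
        """With no sustained signal, dropping the sustained channel costs
        nothing (the lateral-region signature at synthetic scale)."""
        designs = default_designs(2, seed=21)
        base = lateral_like()
        sd = noise_sd_for_snr(base, designs, 5.0)
        truth = lateral_like(noise_sd=sd, seed=21)
        runs, _ = generate_dataset(truth, designs)
        folds = make_folds(runs, 2)
        s = cross_validate("S", runs, folds=folds, maxiter=10)
        dual = cross_validate("A+S", runs, folds=folds, maxiter=10)
        assert s.x_r2_mean >= dual.x_r2_mean - 0.01

    def test_linear_and_adaptation_nearly_equivalent_on_linear_data(self):
        """On data generated without adaptation, the A model (alpha at its
        upper bound) performs within 0.02 x-R^2 of the L model."""
        from temporal_channels.synthetic import GroundTruth

        designs = default_designs(2, seed=31)
        truth = GroundTruth(
            variant="L",
            params=ModelParams(tau_ms=6.0),
            betas={"sustained": {"face": 0.5, "body": 1.0, "word": 0.3}},
            noise_sd=0.0,
            seed=31,
        )
        sd = noise_sd_for_snr(truth, designs, 5.0)
        truth = GroundTruth(
            variant="L",
            params=ModelParams(tau_ms=6.0),
            betas={"sustained": {"face": 0.5, "body": 1.0, "word": 0.3}},
            noise_sd=sd,
            seed=31,
        )
        runs, _ = generate_dataset(truth, designs)
        folds = make_folds(runs, 2)
        l_fit = cross_validate("L", runs, folds=folds, maxiter=10)
        a_fit = cross_validate("A", runs, folds=folds, maxiter=10)
        assert abs(l_fit.x_r2_mean - a_fit.x_r2_mean) < 0.02

    def test_result_serializes_to_json(self, tmp_path, small_designs):
        import json

        truth = ventral_like(noise_sd=0.3, seed=9)
        runs, _ = generate_dataset(truth, small_designs)
        fit = cross_validate("GLM", runs)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["variant"] == "GLM"
        assert set(payload["x_r2"]) == {"experiment_1", "experiment_2", "experiment_3"}
        assert "transient_irf_normalization" in payload["conventions"]
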