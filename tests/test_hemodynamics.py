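"""HRF, BOLD prediction, and design-matrix assembly."""

import numpy as np
import pytest

from temporal_channels import (
    HemodynamicModel,
    ModelParams,
    build_design_matrix,
    build_run,
    build_trial,
    canonical_hrf,
    predict_bold,
    render_step_function,
)
from temporal_channels.forward import ForwardModel


class TestCanonicalHRF:
    def test_shape(self):
        h = canonical_hrf()
        assert h[0] == 0.0
        assert np.argmax(h) / 1000 == pytest.approx(5.0, abs=0.05)
        assert h.max() == 1.0
        assert np.abs(h[30000:]).max() < 1e-3  # late tail is negligible

    def test_undershoot(self):
        h = canonical_hrf()
        assert h.min() < 0
        assert np.argmin(h) / 1000 == pytest.approx(15.0, abs=1.0)


class TestPredictBold:
    def test_zero_input(self):
        hemo = HemodynamicModel.canonical()
        assert not predict_bold(np.zeros(5000), hemo).any()

    def test_matches_dense_brute_force_oracle(self, rng):
        """TR sampling of the package convolution equals a direct dense
        convolution evaluated at the TR points."""
        hemo = HemodynamicModel.canonical()
        neural = np.zeros(27000)
        neural[12000:12990] = rng.uniform(0.5, 1.0, 990)
        oracle = np.convolve(neural, hemo.kernel)[:27000][::1000]
        np.testing.assert_allclose(predict_bold(neural, hemo), oracle, atol=1e-9)

    def test_flash_reproduces_hrf_shape(self):
        hemo = HemodynamicModel.canonical()
        neural = np.zeros(40000)
        neural[1000:1033] = 1.0
        pred = predict_bold(neural, hemo)
        r = np.corrcoef(pred[1:33], hemo.kernel[::1000][:32])[0, 1]
        assert r > 0.999

    def test_rejects_partial_tr(self):
        hemo = HemodynamicModel.canonical()
        with pytest.raises(ValueError, match="integer multiple"):
            predict_bold(np.zeros(4500), hemo)


class TestDesignMatrix:
    def test_column_layout_dual_channel(self, standard_steps):
        X = build_design_matrix([standard_steps[1]], "A+S", ModelParams())
        assert X.n_predictors == 6
        assert X.X.shape == (270, 7)
        assert X.columns[:3] == ["sustained.face", "sustained.body", "sustained.word"]
        assert X.columns[-1] == "intercept.run0"

    def test_channel_blocks_height_matched(self, standard_steps, ventral_params):
        X = build_design_matrix(list(standard_steps.values()), "A+S", ventral_params)
        s = X.X[:, X.channel_blocks["sustained"]]
        t = X.X[:, X.channel_blocks["transient"]]
        assert s.max() == pytest.approx(t.max(), abs=1e-12) == pytest.approx(1.0)

    def test_linear_is_adaptation_limit(self, standard_steps):
        """Forcing the adaptation multiplier to 1 (alpha -> inf) gives the L model."""
        steps = [standard_steps[1]]
        X_l = build_design_matrix(steps, "L", ModelParams())
        X_a = build_design_matrix(steps, "A", ModelParams(alpha_s=np.inf))
        np.testing.assert_allclose(X_l.X, X_a.X, atol=1e-12)

    def test_adaptation_near_linear_for_short_trials(self):
        """At the upper alpha bound, 3-s trials decay little: A and L peaks
        agree within 15%."""
        run = build_run([build_trial(1, 3, "face")])
        step = render_step_function(run)
        peak_l = build_design_matrix([step], "L", normalization={"sustained": 1.0}).X[:, 0].max()
        peak_a = build_design_matrix(
            [step], "A", ModelParams(alpha_s=40.0), normalization={"sustained": 1.0}
        ).X[:, 0].max()
        assert abs(peak_a - peak_l) / peak_l < 0.15

    def test_nonnegative_neural_responses(self, standard_steps, ventral_params):
        """Every rectified/compressed neural output is non-negative (the BOLD
        predictors themselves are signed via the HRF undershoot)."""
        from temporal_channels.hemodynamics import _neural_responses
        from temporal_channels.variants import get_variant

        for variant in ("GLM", "CTS", "A", "S", "A+Q", "A+S"):
            neural = _neural_responses(
                standard_steps[2], get_variant(variant), ventral_params
            )
            for chan, resp in neural.items():
                assert resp.min() >= -1e-12, (variant, chan)

    def test_neural_response_export(self, tmp_path):
        from temporal_channels.hemodynamics import neural_responses_to_tsv

        run = build_run([build_trial(1, 3, "face")])
        step = render_step_function(run)
        out = tmp_path / "neural.tsv"
        frame = neural_responses_to_tsv(step, "A+S", ModelParams(), path=out)
        assert list(frame.columns) == ["time_ms", "channel", "category", "value"]
        assert set(frame.channel) == {"sustained", "transient"}
        assert len(frame) == 2 * 3 * step.n_samples
        assert out.exists()

    def test_unknown_variant_rejected(self, standard_steps):
        with pytest.raises(ValueError, match="unknown model variant"):
            build_design_matrix([standard_steps[1]], "Z+Q")

    def test_low_pass_downsampling_distortion(self):
        """Predictors built at 1-ms vs 2-ms working resolution agree to
        <0.1% RMS (grid-aligned continuous trials)."""
        run = build_run([build_trial(1, d, c) for d, c in [(3, "face"), (10, "body")]])
        mats = {}
        for res in (1, 2):
            step = render_step_function(run, resolution_ms=res)
            hemo = HemodynamicModel.canonical(resolution_ms=res)
            mats[res] = build_design_matrix([step], "A+S", ModelParams(), hemo=hemo)
        diff = mats[1].predictors - mats[2].predictors
        rms = np.sqrt((diff**2).mean())
        assert rms < 1e-3 * np.abs(mats[1].predictors).max()


class TestForwardModelEquivalence:
    @pytest.mark.parametrize("variant", ["GLM", "L", "A", "A+Q", "L+Q"])
    def test_fast_path_matches_reference_exactly(
        self, variant, standard_runs, standard_steps, ventral_params
    ):
        fm = ForwardModel(list(standard_runs.values()), fixed_irf_support=False)
        X_fast = fm.design_matrix(variant, ventral_params)
        X_ref = build_design_matrix(list(standard_steps.values()), variant, ventral_params)
        assert np.abs(X_fast.X - X_ref.X).max() <= 1e-9
        assert X_fast.columns == X_ref.columns

    @pytest.mark.parametrize("variant", ["CTS", "S", "C+Q", "A+S"])
    def test_fast_path_matches_reference_compressive(
        self, variant, standard_runs, standard_steps, ventral_params
    ):
        # compressive powers (exponent < 1) amplify float rounding near zero,
        # so the agreement tolerance is wider than for the linear variants
        fm = ForwardModel(list(standard_runs.values()), fixed_irf_support=False)
        X_fast = fm.design_matrix(variant, ventral_params)
        X_ref = build_design_matrix(list(standard_steps.values()), variant, ventral_params)
        assert np.abs(X_fast.X - X_ref.X).max() <= 1e-6
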