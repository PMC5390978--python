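import numpy as np
import pandas as pd
import pytest

from dispersalkit.diffusion import (
    DiffusionParams,
    DiffusionTrapCatchModel,
    compare_models,
    eval_model,
    fit_diffusion,
)


class TestEvalModel:
    def test_simple_curve_at_study_scale(self):
        p = DiffusionParams(kind="simple", A_prime=2.5, B=26.1)
        # percent-per-trap scale: same order as the observed 0.067 % at 40 m
        assert eval_model(p, 40.0) == pytest.approx(
            2.5 * 40**-0.5 * np.exp(-40 / 26.1), rel=1e-12
        )
        assert eval_model(p, 40.0) == pytest.approx(0.0854, abs=5e-4)

    def test_degenerate_mixture_equals_simple(self):
        simple = DiffusionParams(kind="simple", A_prime=1.7, B=50.0)
        degen = DiffusionParams(
            kind="heterogeneous", A1_prime=1.7, B1=50.0, A2_prime=0.0, B2=500.0
        )
        r = np.geomspace(1, 2000, 50)
        np.testing.assert_allclose(eval_model(degen, r), eval_model(simple, r), rtol=1e-14)

    def test_flat_tail_limit(self):
        p = DiffusionParams(kind="mixed_equal", A_prime=0.0, B=10.0, C_prime=0.001)
        assert eval_model(p, 5.0) == pytest.approx(0.001)
        assert eval_model(p, 1e6) == pytest.approx(0.001)

    def test_nonpositive_distance_rejected(self):
        p = DiffusionParams(kind="simple", A_prime=1.0, B=10.0)
        with pytest.raises(ValueError):
            eval_model(p, 0.0)


class TestFitting:
    def test_noiseless_self_consistency(self, rings):
        truth = DiffusionParams(kind="simple", A_prime=2.5, B=26.1)
        y = eval_model(truth, rings)
        res = DiffusionTrapCatchModel(rings, y, "simple", "none").fit()
        assert res.params.A_prime == pytest.approx(2.5, rel=1e-4)
        assert res.params.B == pytest.approx(26.1, rel=1e-4)

    def test_stationarity_and_aic_identity(self, mixture_dataset):
        r, y = mixture_dataset
        for kind, variance in [
            ("simple", "exponential"), ("heterogeneous", "power"), ("mixed_equal", "power"),
        ]:
            res = DiffusionTrapCatchModel(r, y, kind, variance).fit()
            assert res.score_sup < 1e-5
            assert res.aic == pytest.approx(-2 * res.loglik + 2 * res.k_params, abs=1e-9)

    def test_mixture_component_ordering(self, mixture_dataset):
        r, y = mixture_dataset
        res = DiffusionTrapCatchModel(r, y, "heterogeneous", "power").fit()
        assert res.params.B1 < res.params.B2

    def test_heterogeneous_never_loses_to_nested_simple(self, mixture_dataset):
        # 2 extra parameters cost at most +4 AIC because the mixture nests
        # the one-component model
        r, y = mixture_dataset
        for variance in ("none", "power"):
            simple = DiffusionTrapCatchModel(r, y, "simple", variance).fit()
            het = DiffusionTrapCatchModel(r, y, "heterogeneous", variance).fit()
            assert het.aic <= simple.aic + 4.0 + 1e-6

    def test_covariance_psd_and_wald_symmetry(self, mixture_dataset):
        r, y = mixture_dataset
        res = DiffusionTrapCatchModel(r, y, "heterogeneous", "power").fit()
        eigs = np.linalg.eigvalsh(res.covariance)
        assert eigs.min() > -1e-8 * max(1.0, eigs.max())
        ci = res.conf_int()
        np.testing.assert_allclose(
            ci[:, 1] - res.estimates, res.estimates - ci[:, 0], rtol=1e-10
        )

    def test_preconditions(self, rings):
        with pytest.raises(ValueError, match="observations"):
            DiffusionTrapCatchModel([40.0], [0.1], "simple", "none")
        with pytest.raises(ValueError, match="all-zero"):
            DiffusionTrapCatchModel(rings, np.zeros(6), "simple", "none")

    def test_fit_diffusion_accepts_frame(self, mixture_dataset):
        r, y = mixture_dataset
        df = pd.DataFrame({"ring_m": r, "pr_percent": y})
        res = fit_diffusion(df, "simple", "none")
        assert res.kind == "simple"
        assert np.isfinite(res.aic)


class TestCompare:
    def test_akaike_weights_two_models(self, mixture_dataset):
        r, y = mixture_dataset
        f1 = fit_diffusion(pd.DataFrame({"ring_m": r, "pr_percent": y}), "simple", "none")
        f2 = fit_diffusion(pd.DataFrame({"ring_m": r, "pr_percent": y}), "heterogeneous", "none")
        # impose an AIC gap of exactly 2 to check the weight formula
        f2.aic = f1.aic + 2.0
        table = compare_models([f1, f2])
        w = dict(zip(table["kind"], table["akaike_weight"]))
        assert w["simple"] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)
        assert w["heterogeneous"] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)), abs=1e-12)
        assert table["akaike_weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_lrt_identical_fits(self, mixture_dataset):
        r, y = mixture_dataset
        df = pd.DataFrame({"ring_m": r, "pr_percent": y})
        simple = fit_diffusion(df, "simple", "power")
        het = fit_diffusion(df, "heterogeneous", "power")
        table = compare_models([simple, het])
        row = table[table.kind == "heterogeneous"].iloc[0]
        assert row.lrt_stat >= -1e-8
        assert 0.0 <= row.lrt_p <= 1.0
        # degenerate check: a model compared against itself has stat 0, p 1
        het2 = fit_diffusion(df, "heterogeneous", "power")
        het2.loglik = het.loglik
        stat = 2 * (het2.loglik - het.loglik)
        assert stat == 0.0

    def test_mismatched_data_rejected(self, mixture_dataset, rings):
        r, y = mixture_dataset
        f1 = fit_diffusion(pd.DataFrame({"ring_m": r, "pr_percent": y}), "simple", "none")
        other = pd.DataFrame({"ring_m": rings, "pr_percent": np.linspace(0.1, 0.6, 6)[::-1]})
        f2 = fit_diffusion(other, "simple", "none")
        with pytest.raises(ValueError, match="identical data"):
            compare_models([f1, f2])


class TestPredictionBand:
    def test_zero_covariance_collapses_to_mean(self, mixture_dataset):
        r, y = mixture_dataset
        res = DiffusionTrapCatchModel(r, y, "simple", "none").fit()
        res.covariance = np.zeros_like(res.covariance)
        band = res.predict_band(np.array([50.0, 500.0]))
        np.testing.assert_allclose(band["lower"], band["mean"])
        np.testing.assert_allclose(band["upper"], band["mean"])

    def test_half_width_formula_with_scale_uncertainty_only(self, mixture_dataset):
        # when only A' is uncertain the delta-method gradient is the basis
        # function, so the half-width is 1.96 * se(A') * r^{-1/2} e^{-r/B}
        r, y = mixture_dataset
        res = DiffusionTrapCatchModel(r, y, "simple", "none").fit()
        s = 0.3
        cov = np.zeros_like(res.covariance)
        cov[0, 0] = s**2
        res.covariance = cov
        grid = np.array([40.0, 320.0, 960.0])
        band = res.predict_band(grid)
        expected = 1.96 * s * grid**-0.5 * np.exp(-grid / res.params.B)
        np.testing.assert_allclose(band["upper"] - band["mean"], expected, rtol=1e-10)

    def test_band_vanishes_at_infinity(self, mixture_dataset):
        r, y = mixture_dataset
        res = DiffusionTrapCatchModel(r, y, "heterogeneous", "power").fit()
        band = res.predict_band(np.array([1e2, 1e4, 1e6]))
        widths = (band["upper"] - band["lower"]).to_numpy()
        assert widths[-1] < 1e-6
        assert widths[-1] < widths[0]
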