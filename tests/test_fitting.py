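"""Segmented and nonlinear IVIM estimators against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from ivimkit import FitOptions, IVIMParams, fit_loglinear_wlls, full_nlls_fit, ivim_signal, segmented_fit


def biexp(f, D, Dstar, S0, b):
    b = np.asarray(b, float)
    return S0 * (f * np.exp(-b * Dstar) + (1 - f) * np.exp(-b * D))


class TestWLLS:
    def test_exact_two_point_log_line(self):
        D, icpt = fit_loglinear_wlls([200, 800], [np.exp(-0.2), np.exp(-0.8)])
        assert D == pytest.approx(1.0e-3, rel=1e-12)
        assert icpt == pytest.approx(1.0, rel=1e-12)

    def test_constant_signal_gives_zero_decay(self):
        D, icpt = fit_loglinear_wlls([0, 300, 700], [0.85, 0.85, 0.85])
        assert D == pytest.approx(0.0, abs=1e-15)
        assert icpt == pytest.approx(0.85)

    def test_noiseless_monoexponential_recovery(self):
        b = np.array([200.0, 500.0, 800.0])
        s = 0.85 * np.exp(-b * 2.0e-3)
        D, icpt = fit_loglinear_wlls(b, s)
        assert D == pytest.approx(2.0e-3, rel=1e-10)
        assert icpt == pytest.approx(0.85, rel=1e-10)

    def test_single_iteration_equal_weights_equals_ols(self):
        rng = np.random.default_rng(0)
        b = np.array([200.0, 400.0, 600.0, 800.0])
        s = np.exp(-b * 1.2e-3) * np.exp(rng.normal(0, 0.05, b.size))
        D, icpt = fit_loglinear_wlls(b, s, iterations=1, initial_weights=np.ones_like(b))
        slope, const = np.polyfit(b, np.log(s), 1)
        assert D == pytest.approx(-slope, rel=1e-10)
        assert icpt == pytest.approx(np.exp(const), rel=1e-10)

    def test_nonpositive_samples_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="non-positive"):
            D, _ = fit_loglinear_wlls([200, 500, 800], [0.7, -0.1, 0.3])
        assert D > 0

    def test_too_few_usable_samples_fails(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_loglinear_wlls([500, 500], [0.5, 0.5])


class TestSegmentedFit:
    def test_monoexponential_input_clips_f_and_flags(self, kidney):
        b = np.array(kidney.minimal_b, float)
        s = np.exp(-b * 1.5e-3)  # f = 0: no perfusion compartment
        res = segmented_fit(b, s, FitOptions(b_threshold=200))
        assert "f_clipped_to_zero" in res.flags or res.params.f == pytest.approx(0.0, abs=1e-9)
        assert res.params.D == pytest.approx(1.5e-3, rel=1e-6)
        if "f_clipped_to_zero" in res.flags:
            assert not res.dstar_defined

    def test_step1_matches_two_point_oracle(self, kidney, kidney_params):
        # only b = 200 and 800 lie at/above the kidney threshold, so step 1
        # must equal the closed-form two-point log-line through them
        p = kidney_params
        b = np.array(kidney.minimal_b, float)
        s = ivim_signal(p, b)
        s200, s800 = s[b == 200][0], s[b == 800][0]
        D_oracle = np.log(s200 / s800) / 600.0
        icpt_oracle = s200 * np.exp(200 * D_oracle)
        res = segmented_fit(b, s, FitOptions(b_threshold=200))
        assert res.params.D == pytest.approx(D_oracle, rel=1e-9)
        assert res.intercept == pytest.approx(icpt_oracle, rel=1e-9)
        # documented segmentation bias signs, but tiny for Dstar*bt = 10
        assert res.params.D >= p.D
        assert res.params.f <= p.f
        assert res.params.D == pytest.approx(p.D, rel=5e-3)
        assert res.params.f == pytest.approx(p.f, rel=5e-3)

    def test_dstar_matches_golden_section_oracle(self, kidney, kidney_params):
        p = kidney_params
        b = np.array(kidney.minimal_b, float)
        s = ivim_signal(p, b)
        res = segmented_fit(b, s, FitOptions(b_threshold=200))
        # brute-force 1-D scan over Dstar with D, f, S0 frozen as in step 2
        Dh, fh, s0 = res.params.D, res.params.f, float(s[b == 0].mean())

        def sse(dstar):
            return np.sum((biexp(fh, Dh, dstar, s0, b) - s) ** 2)

        oracle = minimize_scalar(sse, bounds=(Dh, 0.5), method="bounded",
                                 options={"xatol": 1e-10}).x
        assert res.params.Dstar == pytest.approx(oracle, rel=1e-4)
        assert res.params.Dstar == pytest.approx(50e-3, rel=0.05)

    def test_bias_signs_hold_across_organs(self, presets):
        for preset in presets.values():
            m = preset.prior_means()
            p = IVIMParams(f=m["f"], D=m["D"], Dstar=m["Dstar"])
            b = np.array(preset.minimal_b, float)
            res = segmented_fit(b, ivim_signal(p, b),
                                FitOptions(b_threshold=preset.b_threshold))
            assert res.params.D >= p.D, preset.organ
            assert res.params.f <= p.f, preset.organ

    def test_bias_magnitude_shrinks_with_dstar(self):
        b = np.array([0.0, 30, 70, 100, 200, 800])
        biases = []
        for dstar in (20e-3, 50e-3, 100e-3):
            p = IVIMParams(f=0.15, D=1.5e-3, Dstar=dstar)
            res = segmented_fit(b, ivim_signal(p, b), FitOptions(b_threshold=200))
            biases.append(res.params.D - p.D)
        assert biases[0] > biases[1] > biases[2] >= 0

    def test_missing_low_b_precondition(self):
        with pytest.raises(ValueError, match=r"\(0, 200"):
            segmented_fit([0, 200, 800], biexp(0.1, 1e-3, 2e-2, 1, [0, 200, 800]),
                          FitOptions(b_threshold=200))


class TestFullNLLS:
    def test_noiseless_roundtrip_six_bvalues(self):
        p = IVIMParams(f=0.22, D=1.1e-3, Dstar=60e-3, S0=500.0)
        b = np.array([0, 10, 50, 150, 400, 800], float)
        est = full_nlls_fit(b, ivim_signal(p, b)).params
        for name in ("f", "D", "Dstar", "S0"):
            assert getattr(est, name) == pytest.approx(getattr(p, name), rel=1e-3)

    def test_three_bvalues_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            full_nlls_fit([0, 200, 800], [1.0, 0.7, 0.4])

    def test_init_at_truth_noiseless_immediate_convergence(self, kidney_params):
        p = kidney_params
        b = np.array([0, 30, 70, 100, 200, 800], float)
        res = full_nlls_fit(b, ivim_signal(p, b), init=p)
        assert all(res.converged.values())
        assert res.rss == pytest.approx(0.0, abs=1e-20)

    def test_matches_coarse_grid_search_oracle(self):
        # independent 4-D grid enumeration on a small noiseless instance
        p = IVIMParams(f=0.2, D=1.0e-3, Dstar=40e-3, S0=1.0)
        b = np.array([0, 50, 100, 200, 500, 800], float)
        s = ivim_signal(p, b)
        fs = np.linspace(0.05, 0.4, 15)
        Ds = np.linspace(0.5e-3, 2e-3, 16)
        Dss = np.linspace(10e-3, 80e-3, 15)
        S0s = np.linspace(0.9, 1.1, 9)
        best, best_sse = None, np.inf
        for fv in fs:
            for dv in Ds:
                for sv in Dss:
                    pred = fv * np.exp(-b * sv) + (1 - fv) * np.exp(-b * dv)
                    for s0 in S0s:
                        sse = np.sum((s0 * pred - s) ** 2)
                        if sse < best_sse:
                            best, best_sse = (fv, dv, sv, s0), sse
        est = full_nlls_fit(b, s).params
        # NLLS must agree with the grid optimum to within the grid resolution
        assert abs(est.f - best[0]) <= (fs[1] - fs[0])
        assert abs(est.D - best[1]) <= (Ds[1] - Ds[0])
        assert abs(est.Dstar - best[2]) <= (Dss[1] - Dss[0])
        assert abs(est.S0 - best[3]) <= (S0s[1] - S0s[0])
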