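"""SEM engine: RAM algebra, ML discrepancy, fitting, standardization."""

from dataclasses import replace

import numpy as np
import pytest

from aerodyn.sem import (SemSpec, build_true_theta, default_spec, fit_indices,
                         fit_sem, fml, implied_covariance, simulate,
                         standardize)

# disturbance variance completing a unit-variance outcome latent:
# 1 - (g1^2 + g2^2 + 2 g1 g2 phi) for paths (0.51, 0.35) and phi = 0.64
LA_PSI = 1.0 - (0.51 ** 2 + 0.35 ** 2 + 2 * 0.51 * 0.35 * 0.64)


def single_factor_spec(k=3):
    return SemSpec(loadings={"F": [f"x{i}" for i in range(k)]})


def aerosol_truth_theta(spec):
    """Standardized truth: strong negative humidity loading on local
    generation, near-unit dust-immigration loadings on regional dispersal,
    moderate outcome loadings, and dominant local-generation path."""
    loadings = dict(zip(spec.observed,
                        [-0.99, 0.59, -0.55, 0.92, 0.93, 0.95, 0.45, 0.43]))
    paths = {("LA", "LG"): 0.51, ("LA", "RD"): 0.35}
    covs = {("LG", "RD"): 0.64}
    return build_true_theta(spec, loadings, paths, covs)


class TestImpliedCovariance:
    def test_zero_loadings_diagonal(self):
        spec = single_factor_spec()
        theta = np.array([0.0, 0, 0, 1.0, 2.0, 3.0])
        sigma = implied_covariance(theta, spec)
        assert np.allclose(sigma, np.diag([1.0, 2.0, 3.0]))

    def test_unit_loading_zero_residual(self):
        spec = SemSpec(loadings={"F": ["x"]})
        sigma = implied_covariance(np.array([1.0, 1e-12]), spec)
        assert sigma[0, 0] == pytest.approx(1.0)  # the latent variance

    def test_matches_hand_expansion(self):
        """3-indicator factor: Sigma_ij = l_i l_j phi + delta_ij theta_i."""
        spec = single_factor_spec()
        lam = np.array([0.8, -0.5, 1.2])
        res = np.array([0.4, 0.7, 0.3])
        sigma = implied_covariance(np.concatenate([lam, res]), spec)
        expected = np.outer(lam, lam) + np.diag(res)
        assert np.allclose(sigma, expected, atol=1e-12)

    def test_structural_paths_propagate(self):
        spec = default_spec()
        theta = aerosol_truth_theta(spec)
        sim_spec = replace(spec, psi_fixed=LA_PSI)
        sigma = implied_covariance(theta, sim_spec)
        # all variables unit variance under the standardized truth
        assert np.allclose(np.diag(sigma), 1.0, atol=1e-9)
        # humidity (on LG) vs abundance (on LA): lambda_h * lambda_a *
        # (gamma_lg + gamma_rd * phi)
        expected = -0.99 * 0.45 * (0.51 + 0.35 * 0.64)
        assert sigma[0, 6] == pytest.approx(expected, abs=1e-9)


class TestFml:
    def test_zero_iff_equal(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert fml(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_positive_otherwise(self):
        S = np.eye(3)
        sigma = np.diag([1.5, 0.8, 1.0])
        assert fml(S, sigma) > 0

    def test_two_by_two_closed_form(self):
        S = np.array([[1.0, 0.5], [0.5, 2.0]])
        sigma = np.array([[1.2, 0.1], [0.1, 1.8]])
        det_s = 1.0 * 2.0 - 0.25
        det_m = 1.2 * 1.8 - 0.01
        inv_m = np.array([[1.8, -0.1], [-0.1, 1.2]]) / det_m
        expected = (np.log(det_m) + np.trace(S @ inv_m) - np.log(det_s) - 2)
        assert fml(S, sigma) == pytest.approx(expected, abs=1e-12)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            fml(np.array([[1.0, 2.0], [2.0, 1.0]]), np.eye(2))


class TestFitSem:
    def test_single_factor_closed_form(self):
        """Equal-loading saturated toy: lambda = sqrt(common covariance)."""
        c = 0.36
        S = np.full((3, 3), c) + np.diag(np.full(3, 1 - c))
        fit = fit_sem(S=S, n=500, spec=single_factor_spec(), seed=0)
        lam = np.array(list(fit.loadings.values()))
        assert np.allclose(np.abs(lam), np.sqrt(c), atol=1e-4)
        assert fit.fmin < 1e-8  # saturated: perfect fit

    def test_parameter_recovery_moderate_n(self):
        spec = default_spec()
        theta = aerosol_truth_theta(spec)
        data = simulate(theta, replace(spec, psi_fixed=LA_PSI), 2000,
                        np.random.default_rng(42))
        fit = fit_sem(data, spec, seed=0)
        std = standardize(fit)
        assert std.paths["LA<-LG"] == pytest.approx(0.51, abs=0.08)
        assert std.paths["LA<-RD"] == pytest.approx(0.35, abs=0.08)
        assert std.latent_covariances["LG~~RD"] == pytest.approx(0.64,
                                                                 abs=0.08)
        assert std.loadings["humidity"] == pytest.approx(-0.99, abs=0.05)

    def test_objective_non_increasing(self):
        spec = single_factor_spec()
        S = np.full((3, 3), 0.5) + np.diag(np.full(3, 0.5))
        fit = fit_sem(S=S, n=200, spec=spec, seed=0, n_starts=1,
                      track_trace=True)
        trace = np.array(fit.objective_trace)
        assert len(trace) > 1
        assert (np.diff(trace) <= 1e-10).all()

    def test_listwise_deletion(self):
        spec = single_factor_spec()
        theta = np.array([0.8, 0.8, 0.8, 0.36, 0.36, 0.36])
        data = simulate(theta, spec, 400, np.random.default_rng(0))
        data.iloc[:50, 0] = np.nan
        fit = fit_sem(data, spec, seed=0)
        assert fit.n == 350

    def test_rescaling_invariance_of_standardized_solution(self):
        spec = default_spec()
        theta = aerosol_truth_theta(spec)
        data = simulate(theta, replace(spec, psi_fixed=LA_PSI), 1500,
                        np.random.default_rng(3))
        fit1 = fit_sem(data, spec, seed=0)
        scaled = data.copy()
        scaled["humidity"] *= 15.0
        scaled["abundance"] *= 0.8
        fit2 = fit_sem(scaled, spec, seed=0)
        s1, s2 = standardize(fit1), standardize(fit2)
        assert fit1.chi2 == pytest.approx(fit2.chi2, rel=1e-4, abs=1e-6)
        for key in s1.loadings:
            assert s1.loadings[key] == pytest.approx(s2.loadings[key],
                                                     abs=1e-4)
        i1, i2 = fit_indices(fit1), fit_indices(fit2)
        assert i1["srmr"] == pytest.approx(i2["srmr"], abs=1e-6)


class TestStandardize:
    def test_already_standardized_unchanged(self):
        spec = single_factor_spec()
        lam = np.array([0.7, 0.6, 0.5])
        S = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        fit = fit_sem(S=S, n=1000, spec=spec, seed=0)
        std = standardize(fit)
        for name, value in zip(spec.observed, lam):
            assert std.loadings[name] == pytest.approx(value, abs=1e-4)
            assert std.explained_variance[name] == pytest.approx(value ** 2,
                                                                 abs=1e-3)

    def test_sign_flip_symmetry(self):
        spec = single_factor_spec()
        lam = np.array([0.7, 0.6, 0.5])
        S = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        flipped = replace(spec, start_signs={"x0": -1.0, "x1": -1.0,
                                             "x2": -1.0})
        f1 = fit_sem(S=S, n=1000, spec=spec, seed=0)
        f2 = fit_sem(S=S, n=1000, spec=flipped, seed=0)
        s1, s2 = standardize(f1), standardize(f2)
        for name in spec.observed:
            assert abs(s1.loadings[name]) == pytest.approx(
                abs(s2.loadings[name]), abs=1e-4)

    def test_high_loading_explained_variance(self):
        """A -0.99 standardized loading explains 98% of its indicator."""
        spec = single_factor_spec()
        lam = np.array([-0.99, 0.59, -0.55])
        S = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        std = standardize(fit_sem(S=S, n=2000, spec=spec, seed=0))
        assert std.explained_variance["x0"] == pytest.approx(0.98, abs=0.01)


class TestFitIndices:
    def test_perfect_fit_limits(self):
        spec = single_factor_spec(4)  # df = 10 - 8 = 2 > 0
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        S = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        fit = fit_sem(S=S, n=500, spec=spec, seed=0)
        idx = fit_indices(fit)
        assert idx["rmsea"] == pytest.approx(0.0, abs=1e-4)
        assert idx["srmr"] == pytest.approx(0.0, abs=1e-4)
        # the TLI = 1 limit holds where chi-square equals its df exactly
        at_limit = replace(fit, fmin=fit.df / (fit.n - 1),
                           chi2=float(fit.df))
        idx_limit = fit_indices(at_limit)
        assert idx_limit["tli"] == pytest.approx(1.0, abs=1e-9)
        assert idx_limit["rmsea"] == pytest.approx(0.0, abs=1e-12)

    def test_srmr_matches_hand_computation(self):
        from aerodyn.sem import _srmr
        S = np.array([[1.0, 0.5, 0.2],
                      [0.5, 2.0, 0.1],
                      [0.2, 0.1, 1.5]])
        sigma = np.array([[1.1, 0.4, 0.25],
                          [0.4, 1.9, 0.15],
                          [0.25, 0.15, 1.4]])
        d = 1 / np.sqrt(np.diag(S))
        rs = S * np.outer(d, d)
        rm = sigma * np.outer(d, d)
        acc = []
        for i in range(3):
            for j in range(i, 3):
                acc.append((rs[i, j] - rm[i, j]) ** 2)
        assert _srmr(S, sigma) == pytest.approx(np.sqrt(np.mean(acc)),
                                                abs=1e-10)


class TestSpecValidation:
    def test_cross_loading_rejected(self):
        with pytest.raises(ValueError):
            SemSpec(loadings={"A": ["x"], "B": ["x"]})

    def test_unknown_latent_in_path_rejected(self):
        with pytest.raises(ValueError):
            SemSpec(loadings={"A": ["x"]}, paths=[("A", "Z")])

    def test_default_spec_df(self):
        spec = default_spec()
        assert spec.df == 17
        assert len(spec.observed) == 8

    def test_yaml_round_trip(self, tmp_path):
        spec = default_spec()
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = SemSpec.from_yaml(path)
        assert back.loadings == spec.loadings
        assert back.paths == spec.paths
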