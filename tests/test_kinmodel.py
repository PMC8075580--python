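import numpy as np
import pytest
from scipy.integrate import quad

from sptkin.errors import IncomparableFitsError, ModelValidationError
from sptkin.jumplens import compute_jump_dataset
from sptkin.kinmodel import (
    DiffusionModel,
    FitResult,
    f_bound,
    fit_model,
    jump_cdf_single,
    jump_pdf_single,
    model_cdf,
    select_by_aic,
    z_survival,
)
from sptkin.simulate import SimulationConfig, make_fixture, simulate_spt
from sptkin.trajectories import filter_localizations, link_trajectories

from conftest import mc_slab_survival


def _pipeline_dataset(cfg):
    locs, _ = simulate_spt(cfg)
    trajs = link_trajectories(filter_localizations(locs))
    return compute_jump_dataset(trajs)


class TestJumpCdfSingle:
    def test_limits(self):
        assert jump_cdf_single(0.0, 1.0, 0.02, 0.035) == 0.0
        assert jump_cdf_single(1e3, 1.0, 0.02, 0.035) == pytest.approx(1.0)

    def test_rayleigh_mode(self):
        # D=0: density peaks at sqrt(2)*sigma
        sigma = 0.035
        r = np.linspace(0.0, 0.3, 30001)
        pdf = jump_pdf_single(r, 0.0, 0.02, sigma)
        assert r[np.argmax(pdf)] == pytest.approx(np.sqrt(2) * sigma, abs=1e-4)

    def test_known_value(self):
        D, dt, sigma = 0.5, 0.02, 0.035
        r = np.sqrt(4 * (D * dt + sigma**2))
        assert jump_cdf_single(r, D, dt, sigma) == pytest.approx(1 - np.exp(-1))

    def test_cdf_is_integral_of_pdf(self):
        D, dt, sigma = 0.3, 0.02, 0.02
        for r in [0.05, 0.2, 0.5]:
            num, _ = quad(lambda x: jump_pdf_single(x, D, dt, sigma), 0, r)
            assert jump_cdf_single(r, D, dt, sigma) == pytest.approx(num, rel=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            jump_cdf_single(0.1, -1.0, 0.02, 0.035)
        with pytest.raises(ValueError):
            jump_cdf_single(0.1, 1.0, 0.02, -0.01)


class TestZSurvival:
    def test_immobile(self):
        assert z_survival(0.0, 0.02, 0.9) == 1.0

    def test_infinite_slab_limit(self):
        # short-time loss scales as sqrt(D*dt)/dZ, so push dZ far out
        assert z_survival(1.0, 0.02, 1e3) == pytest.approx(1.0, abs=1e-3)
        assert z_survival(1.0, 0.02, 1e7) == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_oracle(self, rng):
        p_mc, se = mc_slab_survival(1.0, 0.02, 0.9, 100_000, rng)
        assert abs(z_survival(1.0, 0.02, 0.9) - p_mc) < 3 * se

    def test_monotone_in_d_dt_dz(self):
        ds = [0.1, 0.5, 1.0, 3.0]
        vals = [z_survival(D, 0.02, 0.9) for D in ds]
        assert all(np.diff(vals) < 0)
        dts = [0.02, 0.04, 0.08]
        vals = [z_survival(1.0, dt, 0.9) for dt in dts]
        assert all(np.diff(vals) < 0)
        dzs = [0.5, 0.9, 1.5]
        vals = [z_survival(1.0, 0.02, dz) for dz in dzs]
        assert all(np.diff(vals) > 0)
        assert all(0 < z_survival(D, 0.02, 0.9) <= 1 for D in ds)

    def test_images_matches_eigenseries_in_overlap(self):
        from sptkin.kinmodel import _z_survival_images

        for alpha in [0.02, 0.05, 0.2]:
            assert _z_survival_images(alpha) == pytest.approx(
                z_survival(alpha, 1.0, 1.0), abs=1e-12
            )

    def test_truncation_warning(self):
        with pytest.warns(RuntimeWarning, match="error bound"):
            z_survival(1e-4, 0.02, 0.9, n_terms=3)


class TestModelCdf:
    def _model(self, fractions, diffusion, sigma=0.035, dz=0.9):
        return DiffusionModel(
            fractions=fractions, diffusion=diffusion, sigma=sigma, dz=dz
        )

    def test_single_state_degenerate(self):
        m = self._model((1.0,), (0.5,))
        r = np.linspace(0, 2, 50)
        np.testing.assert_allclose(
            model_cdf(m, 0.02, r), jump_cdf_single(r, 0.5, 0.02, 0.035)
        )

    def test_equal_d_collapses(self):
        r = np.linspace(0, 2, 50)
        m = self._model((0.3, 0.7), (0.5, 0.5))
        np.testing.assert_allclose(
            model_cdf(m, 0.02, r), jump_cdf_single(r, 0.5, 0.02, 0.035), atol=1e-12
        )

    def test_bound_weight_grows_with_lag(self):
        from sptkin.kinmodel import _lag_weights

        m = self._model((0.5, 0.5), (0.005, 1.0))
        w1 = _lag_weights(m, 0.02)
        w2 = _lag_weights(m, 0.04)
        assert w2[0] > w1[0]
        # derived directly from the survival ratio
        z1, z2 = z_survival(1.0, 0.02, 0.9), z_survival(1.0, 0.04, 0.9)
        assert w1[0] == pytest.approx(0.5 / (0.5 + 0.5 * z1))
        assert w2[0] == pytest.approx(0.5 / (0.5 + 0.5 * z2))

    def test_monotone_and_saturates(self):
        m = self._model((0.4, 0.2, 0.4), (0.01, 0.15, 1.0))
        for dt in [0.02, 0.04, 0.08]:
            r = np.linspace(0, 30, 4000)
            cdf = model_cdf(m, dt, r)
            assert np.all(np.diff(cdf) >= -1e-12)
            assert cdf[-1] == pytest.approx(1.0, abs=1e-6)

    def test_validation_errors(self):
        with pytest.raises(ModelValidationError):
            self._model((0.5, 0.4), (0.01, 1.0))  # fractions don't sum to 1
        with pytest.raises(ModelValidationError):
            self._model((0.5, 0.5), (1.0, 0.01))  # not ascending
        with pytest.raises(ModelValidationError):
            self._model((0.5, 0.5), (0.01, 1.0), sigma=0.5)


class TestFit:
    def test_two_state_recovery(self):
        cfg = SimulationConfig(
            n_molecules=3500,
            state_fractions=(0.5, 0.5),
            state_d=(0.005, 1.0),
            seed=1,
            nucleus_radius=None,
            sigma_loc=0.035,
            dz=0.9,
            bleach_mean_frames=20.0,
            n_frames=20000,
        )
        ds = _pipeline_dataset(cfg)
        assert ds.total_jumps >= 10_000
        fit = fit_model(ds, n_states=2, seed=3)
        assert f_bound(fit) == pytest.approx(0.5, abs=0.03)

    def test_all_bound_recovery(self):
        cfg = SimulationConfig(
            n_molecules=2000,
            state_fractions=(1.0,),
            state_d=(0.005,),
            seed=4,
            nucleus_radius=1.0,
            sigma_loc=0.035,
            dz=0.9,
            bleach_mean_frames=20.0,
            n_frames=20000,
        )
        ds = _pipeline_dataset(cfg)
        fit = fit_model(ds, n_states=2, seed=0)
        assert f_bound(fit) >= 0.95

    def test_three_state_respects_d_slow_min(self):
        cfg = make_fixture("nse4-like", n_molecules=800, seed=2)
        ds = _pipeline_dataset(cfg)
        fit = fit_model(ds, n_states=3, d_slow_min=0.08, seed=0)
        d_sorted = sorted(fit.model.diffusion)
        assert d_sorted[1] >= 0.08

    def test_deterministic_given_seed(self):
        cfg = make_fixture("cohesin-like", n_molecules=400, seed=8)
        ds = _pipeline_dataset(cfg)
        f1 = fit_model(ds, n_states=2, seed=11)
        f2 = fit_model(ds, n_states=2, seed=11)
        assert f1.model == f2.model
        assert f1.rss == f2.rss

    def test_aic_formula(self):
        cfg = make_fixture("cohesin-like", n_molecules=400, seed=8)
        ds = _pipeline_dataset(cfg)
        fit = fit_model(ds, n_states=2, seed=0)
        assert fit.k_params == 4
        assert fit.aic == pytest.approx(
            fit.n_points * np.log(fit.rss / fit.n_points) + 2 * fit.k_params
        )

    def test_low_jump_warning(self):
        cfg = make_fixture("cohesin-like", n_molecules=6, seed=3)
        ds = _pipeline_dataset(cfg)
        assert ds.total_jumps < 100
        with pytest.warns(RuntimeWarning, match="jumps"):
            fit_model(ds, n_states=2, seed=0)


class TestSelection:
    def _fit(self, aic, n_states, n_points=100):
        model = DiffusionModel(
            fractions=(0.5, 0.5) if n_states == 2 else (0.4, 0.3, 0.3),
            diffusion=(0.01, 1.0) if n_states == 2 else (0.01, 0.2, 1.0),
            sigma=0.035,
            dz=0.9,
        )
        return FitResult(
            model=model,
            rss=1.0,
            n_points=n_points,
            k_params=2 * n_states,
            aic=aic,
            n_states=n_states,
            converged=True,
            seed=0,
        )

    def test_equal_rss_prefers_two_states(self):
        n = 100
        rss = 1.0
        aic2 = n * np.log(rss / n) + 4
        aic3 = n * np.log(rss / n) + 6
        best = select_by_aic(self._fit(aic2, 2), self._fit(aic3, 3))
        assert best.n_states == 2
        assert best.delta_aic == pytest.approx(2.0)

    def test_lower_aic_wins(self):
        best = select_by_aic(self._fit(-500.0, 2), self._fit(-700.0, 3))
        assert best.n_states == 3

    def test_incomparable(self):
        with pytest.raises(IncomparableFitsError):
            select_by_aic(self._fit(-500.0, 2), self._fit(-700.0, 3, n_points=99))


class TestFBound:
    def test_three_state_lookup(self):
        model = DiffusionModel(
            fractions=(0.4, 0.2, 0.4),
            diffusion=(0.005, 0.2, 1.5),
            sigma=0.035,
            dz=0.9,
        )
        fit = FitResult(
            model=model, rss=0.1, n_points=10, k_params=6, aic=0.0,
            n_states=3, converged=True, seed=0,
        )
        assert f_bound(fit) == 0.4

    def test_two_state_lookup(self):
        model = DiffusionModel(
            fractions=(0.7, 0.3), diffusion=(0.01, 1.0), sigma=0.035, dz=0.9
        )
        fit = FitResult(
            model=model, rss=0.1, n_points=10, k_params=4, aic=0.0,
            n_states=2, converged=True, seed=0,
        )
        assert f_bound(fit) == 0.7
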