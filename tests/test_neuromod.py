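"""Closed-loop demo: synthetic plant, GPR surrogate, UCB acquisition."""

import numpy as np
import pytest

import cycleflow.neuromod as nm

CFG = nm.PlantConfig()


class TestPlant:
    def test_peak_at_configured_optimum(self):
        obs = nm.plant_evaluate(
            nm.StimulationParams(CFG.optimum_amplitude, CFG.optimum_frequency), CFG
        )
        assert obs.objective == pytest.approx(CFG.peak)

    def test_symmetry_around_the_optimum(self):
        for delta in (0.5, 1.7, 3.0):
            lo = nm.plant_evaluate(
                nm.StimulationParams(CFG.optimum_amplitude - delta, CFG.optimum_frequency), CFG
            ).objective
            hi = nm.plant_evaluate(
                nm.StimulationParams(CFG.optimum_amplitude + delta, CFG.optimum_frequency), CFG
            ).objective
            assert lo == pytest.approx(hi)

    def test_grid_argmax_recovers_optimum(self):
        aa = np.linspace(*CFG.amplitude_bounds, 200)
        ff = np.linspace(*CFG.frequency_bounds, 200)
        best, best_val = None, -1.0
        for a in aa:
            for f in ff:
                v = nm.plant_evaluate(nm.StimulationParams(a, f), CFG).objective
                if v > best_val:
                    best, best_val = (a, f), v
        cell_a = (CFG.amplitude_bounds[1] - CFG.amplitude_bounds[0]) / 199
        cell_f = (CFG.frequency_bounds[1] - CFG.frequency_bounds[0]) / 199
        assert abs(best[0] - CFG.optimum_amplitude) <= cell_a
        assert abs(best[1] - CFG.optimum_frequency) <= cell_f

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            nm.plant_evaluate(nm.StimulationParams(-1.0, 50.0), CFG)

    def test_deterministic_given_seed_even_with_noise(self):
        noisy = nm.PlantConfig(noise_sd=0.05, seed=11)
        p = nm.StimulationParams(4.0, 55.0)
        assert nm.plant_evaluate(p, noisy).objective == nm.plant_evaluate(p, noisy).objective


def _observations(points, fn):
    return [
        nm.Observation(nm.StimulationParams(a, f), fn(a, f)) for a, f in points
    ]


class TestSurrogate:
    def test_interpolates_noiseless_linear_function(self):
        pts = [(1.0, 40.0), (3.0, 50.0), (5.0, 60.0), (7.0, 80.0), (9.0, 95.0), (2.0, 90.0)]
        obs = _observations(pts, lambda a, f: 0.1 * a + 0.01 * f)
        model = nm.fit_surrogate(obs, CFG.bounds, seed=0)
        mu, _sd = model.predict(np.array(pts))
        targets = np.array([o.objective for o in obs])
        assert np.allclose(mu, targets, atol=1e-6)

    def test_variance_shrinks_at_training_points(self):
        pts = [(2.0, 40.0), (3.0, 45.0), (4.0, 55.0)]
        obs = _observations(pts, lambda a, f: np.sin(a) + 0.01 * f)
        model = nm.fit_surrogate(obs, CFG.bounds, seed=0)
        _mu, sd_train = model.predict(np.array(pts))
        corners = np.array([[10.0, 100.0], [0.0, 100.0], [10.0, 30.0]])
        _mu2, sd_far = model.predict(corners)
        assert sd_train.max() <= sd_far.max()

    def test_posterior_matches_closed_form_solve(self):
        """Hand-rolled GPR algebra with the fitted hyperparameters must
        reproduce the model's posterior mean (1-D slice, 5 points)."""
        pts = [(1.0, 60.0), (3.0, 60.0), (5.0, 60.0), (7.0, 60.0), (9.0, 60.0)]
        obs = _observations(pts, lambda a, f: np.cos(a / 2.0))
        model = nm.fit_surrogate(obs, CFG.bounds, seed=0)

        # extract fitted kernel: c * RBF(ls) + white noise, on unit-box inputs
        k = model.gpr.kernel_
        c = k.k1.k1.constant_value
        ls = np.asarray(k.k1.k2.length_scale, float)
        noise = k.k2.noise_level
        X = model._standardize(np.array(pts))
        y = np.array([o.objective for o in obs])
        y_mean, y_std = y.mean(), y.std()
        yn = (y - y_mean) / y_std

        def rbf(A, B):
            d2 = ((A[:, None, :] - B[None, :, :]) / ls) ** 2
            return c * np.exp(-0.5 * d2.sum(-1))

        K = rbf(X, X) + noise * np.eye(len(X))
        query = np.array([(2.0, 60.0), (4.5, 60.0), (8.0, 60.0)])
        Xq = model._standardize(query)
        mu_closed = y_mean + y_std * (rbf(Xq, X) @ np.linalg.solve(K, yn))
        mu_model, _ = model.predict(query)
        assert np.allclose(mu_model, mu_closed, atol=1e-8)

    def test_duplicate_only_data_flagged_degenerate(self):
        obs = _observations([(5.0, 60.0)] * 4, lambda a, f: 0.5)
        model = nm.fit_surrogate(obs, CFG.bounds, seed=0)
        assert model.degenerate

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            nm.fit_surrogate(_observations([(5.0, 60.0)], lambda a, f: 1.0), CFG.bounds)


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(5)
    pts = [(float(rng.uniform(0, 10)), float(rng.uniform(30, 100))) for _ in range(8)]
    obs = _observations(
        pts, lambda a, f: nm.plant_evaluate(nm.StimulationParams(a, f), CFG).objective
    )
    return nm.fit_surrogate(obs, CFG.bounds, seed=0)


class TestAcquisition:
    def test_kappa_zero_returns_posterior_mean_maximizer(self, model):
        p = nm.acquire_next(model, CFG.bounds, kappa=0.0)
        aa = np.linspace(*CFG.amplitude_bounds, 500)
        ff = np.linspace(*CFG.frequency_bounds, 500)
        A, F = np.meshgrid(aa, ff, indexing="ij")
        mu, _ = model.predict(np.column_stack([A.ravel(), F.ravel()]))
        mu_at_p, _ = model.predict(np.array([[p.amplitude, p.frequency]]))
        assert mu_at_p[0] >= mu.max() - 1e-6

    def test_constant_variance_makes_kappa_irrelevant(self, model):
        class FlatSigma:
            bounds = CFG.bounds

            def predict(self, X):
                mu, _sd = model.predict(X)
                return mu, np.ones_like(mu) * 0.3

        flat = FlatSigma()
        p0 = nm.acquire_next(flat, CFG.bounds, kappa=0.0)
        p5 = nm.acquire_next(flat, CFG.bounds, kappa=5.0)
        assert p0.amplitude == pytest.approx(p5.amplitude, abs=1e-3)
        assert p0.frequency == pytest.approx(p5.frequency, abs=1e-3)

    def test_matches_exhaustive_grid_within_one_cell(self, model):
        kappa = 2.0
        p = nm.acquire_next(model, CFG.bounds, kappa=kappa)
        aa = np.linspace(*CFG.amplitude_bounds, 500)
        ff = np.linspace(*CFG.frequency_bounds, 500)
        A, F = np.meshgrid(aa, ff, indexing="ij")
        mu, sd = model.predict(np.column_stack([A.ravel(), F.ravel()]))
        acq = mu + kappa * sd
        best = acq.max()
        got = model.predict(np.array([[p.amplitude, p.frequency]]))
        got_acq = got[0][0] + kappa * got[1][0]
        assert got_acq >= best - 1e-6


class TestClosedLoop:
    def test_budget_and_phase_labels(self):
        trace = nm.run_closed_loop(budget=20, burn_in=5, seed=1, engine="monolithic")
        assert len(trace.observations) == 20
        assert trace.phases[:5] == ["burn-in"] * 5
        assert set(trace.phases[5:]) == {"model-guided"}

    def test_boundary_budget_one_guided_step(self, monkeypatch):
        fits = []
        original = nm.fit_surrogate

        def counting(*args, **kwargs):
            fits.append(1)
            return original(*args, **kwargs)

        monkeypatch.setattr(nm, "fit_surrogate", counting)
        trace = nm.run_closed_loop(budget=6, burn_in=5, seed=1, engine="monolithic")
        assert len(trace.observations) == 6
        assert len(fits) == 1  # burn-in never touches the surrogate

    def test_invalid_budget_rejected(self):
        with pytest.raises(ValueError):
            nm.run_closed_loop(budget=5, burn_in=5)

    def test_best_so_far_monotone(self):
        trace = nm.run_closed_loop(budget=12, burn_in=4, seed=2, engine="monolithic")
        assert all(b2 >= b1 for b1, b2 in zip(trace.best_so_far, trace.best_so_far[1:]))

    def test_orchestrated_equals_monolithic(self):
        a = nm.run_closed_loop(budget=10, burn_in=4, seed=7, engine="workflow")
        b = nm.run_closed_loop(budget=10, burn_in=4, seed=7, engine="monolithic")
        assert [(o.params, o.objective) for o in a.observations] == [
            (o.params, o.objective) for o in b.observations
        ]

    def test_random_search_baseline_shape(self):
        tr = nm.random_search(10, seed=3)
        assert len(tr.observations) == 10
        assert tr.phases == ["random"] * 10
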