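"""Proofreading chain probability, saturable response fit, gated analyses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from proofkin import (
    KineticProofreadingRegressor,
    SimulationConfig,
    StepParams,
    amplification_factor,
    completion_probability,
    dag_response,
    fit_proofreading_model,
    generate_cell_table,
    kernel_smooth,
    occupancy_gated_correlation,
    simulate_binding_events,
)
from proofkin.synthetic import GillespieRates


class TestCompletionProbability:
    @pytest.mark.parametrize(
        "tau_off, tau_p, n, expected",
        [
            (3.0, 5.0, 0, 1.0),       # no steps: every binding signals
            (2.0, 2.0, 1, 0.5),       # symmetric race
            (2.0, 2.0, 3, 0.125),
            (2.0, 6.0, 1, 0.25),      # alpha = 2 / (2 + 6)
        ],
    )
    def test_known_values(self, tau_off, tau_p, n, expected):
        p = completion_probability(tau_off, StepParams(tau_p=tau_p, n_steps=n))
        assert p == pytest.approx(expected, rel=1e-12)

    @given(
        tau1=st.floats(0.01, 100.0),
        tau2=st.floats(0.01, 100.0),
        tau_p=st.floats(0.01, 100.0),
        n=st.integers(0, 8),
    )
    def test_monotone_in_halflife_and_bounded(self, tau1, tau2, tau_p, n):
        step = StepParams(tau_p=tau_p, n_steps=n)
        lo, hi = sorted([tau1, tau2])
        p_lo, p_hi = completion_probability(lo, step), completion_probability(hi, step)
        assert 0 < p_lo <= p_hi <= 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            completion_probability(0.0, StepParams(1.0, 1))
        with pytest.raises(ValueError):
            StepParams(tau_p=-1.0, n_steps=1)

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.9])
    @pytest.mark.parametrize("n_steps", [1, 2, 3, 4, 5])
    def test_stochastic_oracle_equivalence(self, alpha, n_steps):
        """Event-simulation completion frequency matches alpha**n within 3 SE."""
        koff = 1.0
        kp = alpha / (1 - alpha) * koff
        tau_off, tau_p = np.log(2) / koff, np.log(2) / kp
        p = completion_probability(tau_off, StepParams(tau_p=tau_p, n_steps=n_steps))
        assert p == pytest.approx(alpha**n_steps, rel=1e-12)
        n_events = 10_000
        ev = simulate_binding_events(
            GillespieRates(kon=1.0, koff=koff, kp=kp, n_steps=n_steps), n_events,
            seed=1000 + 17 * n_steps + int(100 * alpha),
        )
        freq = np.mean([e.completed for e in ev])
        se = np.sqrt(p * (1 - p) / n_events)
        assert abs(freq - p) <= 3 * se


class TestDagResponse:
    def test_null_occupancy_gives_basal(self):
        assert dag_response(0.0, 3.0, 2.7, 1e6, 5.0, 100.0) == pytest.approx(5.0)

    def test_half_saturation_by_definition_of_K(self):
        # R * tau**n == K -> half-maximal response above basal
        assert dag_response(10.0, 2.0, 2.0, 40.0, 1.0, 6.0) == pytest.approx(4.0)

    def test_arithmetic_example(self):
        for n in (0.0, 1.0, 2.7):
            assert dag_response(2.0, 1.0, n, 1.0, 0.0, 1.0) == pytest.approx(2.0 / 3.0)

    def test_independent_of_tau_when_n_zero(self):
        vals = [dag_response(5.0, tau, 0.0, 10.0, 1.0, 3.0) for tau in (0.1, 1.0, 10.0)]
        assert np.ptp(vals) == 0.0

    def test_saturates_to_amplitude_plus_basal(self):
        assert dag_response(1e12, 10.0, 2.0, 1.0, 5.0, 100.0) == pytest.approx(105.0, rel=1e-6)

    def test_invalid_K_rejected(self):
        with pytest.raises(ValueError):
            dag_response(1.0, 1.0, 2.0, 0.0, 0.0, 1.0)


class TestAmplification:
    @pytest.mark.parametrize("n, fold, expected", [(0.0, 7.0, 1.0), (1.0, 10.0, 10.0)])
    def test_trivial_exponents(self, n, fold, expected):
        assert amplification_factor(n, fold) == pytest.approx(expected)

    def test_matches_unsaturated_response_ratio(self):
        """fold**n equals the ratio of far-from-saturation responses at fixed R."""
        n, fold, K = 2.7, 10.0, 1e16
        lo = dag_response(1.0, 1.0, n, K, 0.0, 1.0)
        hi = dag_response(1.0, fold, n, K, 0.0, 1.0)
        assert amplification_factor(n, fold) == pytest.approx(hi / lo, rel=1e-12)

    def test_occupancy_coupled_ratio(self):
        """With occupancy scaling with tau, the ratio gains one power of the fold."""
        n, fold, K = 2.7, 10.0, 1e16
        lo = dag_response(1.0, 1.0, n, K, 0.0, 1.0)
        hi = dag_response(fold, fold, n, K, 0.0, 1.0)
        assert amplification_factor(n, fold, include_occupancy=True) == pytest.approx(
            hi / lo, rel=1e-12
        )

    def test_invalid_fold_rejected(self):
        with pytest.raises(ValueError):
            amplification_factor(2.0, 0.0)


class TestProofreadingFit:
    def test_noiseless_exact_recovery(self, noiseless_config):
        t = generate_cell_table(noiseless_config)
        fits = fit_proofreading_model(t, normalization="none", ci_method="linear")
        c = noiseless_config
        for fit in fits.values():
            assert fit.n == pytest.approx(c.true_n, rel=1e-6)
            assert fit.K == pytest.approx(c.true_K, rel=1e-5)
            assert fit.beta == pytest.approx(c.true_beta, rel=1e-5)
            assert fit.amplitude == pytest.approx(c.true_A, rel=1e-5)

    def test_recovery_against_estimator_interface(self, noiseless_config):
        t = generate_cell_table(noiseless_config)
        X = t[["occupancy_au", "half_life_s"]].to_numpy()
        est = KineticProofreadingRegressor(ci_method="linear").fit(X, t["dag_au"].to_numpy())
        assert est.n_ == pytest.approx(noiseless_config.true_n, rel=1e-6)
        assert np.allclose(est.predict(X), t["dag_au"].to_numpy(), rtol=1e-8)
        assert est.dof_ == len(t) // noiseless_config.n_days * noiseless_config.n_days - 4

    def test_pooling_across_days_refused(self, default_config):
        t = generate_cell_table(default_config)
        with pytest.raises(ValueError, match="pool"):
            fit_proofreading_model(t, group_by_day=False)
        pooled = fit_proofreading_model(
            t, group_by_day=False, allow_pooling=True, ci_method="linear"
        )
        assert set(pooled) == {"pooled"}

    def test_occupancy_unit_rescale_leaves_n_invariant(self):
        t = generate_cell_table(SimulationConfig(seed=5, n_days=1))
        f1 = next(iter(fit_proofreading_model(t, ci_method="linear").values()))
        t2 = t.assign(
            occupancy_au=t["occupancy_au"] * 37.0, dataset_id="x" + t["dataset_id"]
        )
        f2 = next(iter(fit_proofreading_model(t2, ci_method="linear").values()))
        assert f2.n == pytest.approx(f1.n, abs=1e-5)
        assert f2.K == pytest.approx(37.0 * f1.K, rel=1e-4)
        assert f2.beta == pytest.approx(f1.beta, abs=1e-5)

    def test_normalization_does_not_change_n(self):
        t = generate_cell_table(SimulationConfig(seed=9, n_days=1))
        n_by_scheme = {
            scheme: next(iter(fit_proofreading_model(t, normalization=scheme,
                                                     ci_method="linear").values())).n
            for scheme in ("none", "saturation")
        }
        assert n_by_scheme["none"] == pytest.approx(n_by_scheme["saturation"], abs=1e-6)

    def test_too_few_cells_rejected(self):
        t = generate_cell_table(SimulationConfig(seed=0, n_days=1)).head(8)
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_proofreading_model(t)

    def test_missing_columns_rejected(self):
        t = generate_cell_table(SimulationConfig(seed=0, n_days=1)).drop(columns=["dag_au"])
        with pytest.raises(ValueError, match="dag_au"):
            fit_proofreading_model(t)


class TestGatedCorrelation:
    def test_perfect_monotone_gives_plus_minus_one(self):
        import pandas as pd

        tau = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        up = pd.DataFrame(
            {"occupancy_au": np.ones(5), "half_life_s": tau, "dag_au": tau**2}
        )
        rho, n = occupancy_gated_correlation(up, occupancy_band=(0.0, 2.0))
        assert rho == pytest.approx(1.0, rel=1e-12) and n == 5
        down = up.assign(dag_au=-(tau**2))
        rho, _ = occupancy_gated_correlation(down, occupancy_band=(0.0, 2.0))
        assert rho == pytest.approx(-1.0, rel=1e-12)

    def test_positive_association_under_proofreading(self):
        hits = 0
        for seed in range(100):
            t = generate_cell_table(SimulationConfig(seed=seed))
            rho, _ = occupancy_gated_correlation(t)
            hits += rho > 0
        assert hits >= 95

    def test_empty_gate_rejected(self, default_config):
        t = generate_cell_table(default_config)
        with pytest.raises(ValueError, match="no cells"):
            occupancy_gated_correlation(t, occupancy_band=(-10.0, -5.0))


class TestKernelSmoothing:
    def test_constant_y_gives_constant_fit(self):
        x = np.linspace(0, 1, 30)
        _, f = kernel_smooth(x, np.full(30, 4.2), bandwidth=0.1)
        assert np.allclose(f, 4.2)

    def test_huge_bandwidth_gives_global_mean(self):
        x = np.linspace(0, 1, 30)
        y = np.sin(6 * x)
        _, f = kernel_smooth(x, y, bandwidth=1e6)
        assert np.allclose(f, y.mean(), atol=1e-6)

    def test_linear_signal_recovered(self, rng):
        x = np.linspace(0, 1, 200)
        y = 2 * x + rng.normal(0, 0.1, 200)
        g, f = kernel_smooth(x, y, bandwidth=0.05)
        interior = (g > 0.1) & (g < 0.9)
        assert np.max(np.abs(f[interior] - 2 * g[interior])) <= 0.2

    def test_convex_combination_bounds(self, rng):
        x = rng.uniform(0, 1, 50)
        y = rng.normal(0, 1, 50)
        _, f = kernel_smooth(x, y, bandwidth=0.2)
        assert np.nanmin(f) >= y.min() - 1e-12 and np.nanmax(f) <= y.max() + 1e-12

    def test_unsupported_grid_points_are_nan(self):
        x = np.zeros(5)
        g, f = kernel_smooth(x, np.ones(5), bandwidth=0.01, grid=[0.0, 1.0])
        assert f[0] == pytest.approx(1.0) and np.isnan(f[1])

    def test_matches_local_constant_kernel_regression(self):
        """Cross-check against the statsmodels local-constant estimator."""
        from statsmodels.nonparametric.kernel_regression import KernelReg

        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 1, 80))
        y = np.cos(3 * x) + rng.normal(0, 0.05, 80)
        bw = 0.08
        grid = np.linspace(0.1, 0.9, 15)
        _, ours = kernel_smooth(x, y, bandwidth=bw, grid=grid)
        theirs = KernelReg(y, x, var_type="c", reg_type="lc", bw=[bw]).fit(grid)[0]
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            kernel_smooth([1.0, 2.0], [1.0, 2.0], bandwidth=0.0)


class TestNullModel:
    def test_occupancy_only_data_yield_small_n(self):
        cfg = SimulationConfig(seed=3, n_days=1, true_n=0.0, true_K=5e4)
        fit = next(iter(fit_proofreading_model(generate_cell_table(cfg)).values()))
        assert fit.ci95_n[0] <= 0.0 <= fit.ci95_n[1]
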