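import numpy as np
import pytest

import graftnet as gn
from graftnet.calibration import (
    calibrate_cn,
    calibrate_scaling,
    calibrate_weights,
    cn_default_bounds,
    ga_minimize,
)
from graftnet.core import (
    CellEventSeries,
    ClusterExpressionSeries,
    GAConfig,
    ScalingFactors,
)
from graftnet.hybrid import HybridParameters


def small_cfg(**kw):
    base = dict(pop_multiplier=20, generations=25, n_restarts=2, n_runs=1, seed=42)
    base.update(kw)
    return GAConfig(**base)


class TestGAEngine:
    def test_sphere_benchmark(self):
        obj = lambda X: np.sum(np.atleast_2d(X) ** 2, axis=1)
        x, f, trace = ga_minimize(
            obj, 5, (np.full(5, -1.0), np.full(5, 1.0)), small_cfg(), vectorized=True
        )
        assert f < 1e-3
        assert np.all(np.abs(x) < 0.1)

    def test_deterministic_under_seed(self):
        obj = lambda X: np.sum((np.atleast_2d(X) - 0.3) ** 2, axis=1)
        runs = [
            ga_minimize(obj, 3, (np.full(3, -1.0), np.full(3, 1.0)),
                        small_cfg(seed=7), vectorized=True)
            for _ in range(2)
        ]
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]
        assert runs[0][2]["runs"] == runs[1][2]["runs"]

    def test_restarts_never_degrade(self):
        obj = lambda X: np.sum(np.sin(3 * np.atleast_2d(X)) ** 2 + 0.1 * np.atleast_2d(X) ** 2,
                               axis=1)
        _, _, trace = ga_minimize(
            obj, 4, (np.full(4, -2.0), np.full(4, 2.0)), small_cfg(n_runs=2),
            vectorized=True,
        )
        for stage_bests in trace["runs"]:
            assert all(b2 <= b1 + 1e-15 for b1, b2 in zip(stage_bests, stage_bests[1:]))

    def test_screen_excludes_forbidden_optimum(self):
        # global optimum at the origin is vetoed; the returned best must
        # satisfy the screen
        obj = lambda X: np.sum(np.atleast_2d(X) ** 2, axis=1)
        screen = lambda x: x[0] >= 0.25
        x, f, _ = ga_minimize(
            obj, 2, (np.full(2, -1.0), np.full(2, 1.0)), small_cfg(),
            screen=screen, vectorized=True,
        )
        assert screen(x)
        assert f >= 0.25**2 - 1e-9

    def test_all_nonfinite_population_raises(self):
        obj = lambda X: np.full(np.atleast_2d(X).shape[0], np.nan)
        with pytest.raises(RuntimeError):
            ga_minimize(obj, 2, (np.full(2, -1.0), np.full(2, 1.0)),
                        small_cfg(generations=2), vectorized=True)


@pytest.fixture(scope="module")
def independent_curves(grid=gn.TimeGrid()):
    """Five deliberately independent cluster curves on the study grid."""
    t = grid.times
    values = np.vstack([
        np.exp(-t / 3.0),
        t / 28.0,
        np.cos(0.3 * t),
        np.exp(-((t - 7.0) ** 2) / 20.0),
        np.full_like(t, 0.8),
    ])
    return ClusterExpressionSeries(network_id="MIT", values=values, grid=grid)


class TestWeightCalibration:
    def test_recovers_constructed_combination(self, independent_curves):
        grid = independent_curves.grid
        truth_w = np.array([0.4, -0.6, 0.0, 0.0, 0.0])
        phi = truth_w @ independent_curves.values
        events = CellEventSeries(mitosis=phi, apoptosis=phi, ecm=phi, grid=grid)
        curves = {net: ClusterExpressionSeries(network_id=net,
                                               values=independent_curves.values,
                                               grid=grid)
                  for net in gn.NETWORK_IDS}
        res = calibrate_weights(curves, events, small_cfg(pop_multiplier=60,
                                                          generations=80, n_runs=2))
        for net in gn.NETWORK_IDS:
            w = res.params[net].w
            assert np.max(np.abs(w - truth_w)) < 0.05
            assert abs(np.sum(np.abs(w)) - 1.0) < 1e-9

    def test_single_cluster_event_recovers_unit_vector(self, independent_curves):
        grid = independent_curves.grid
        phi = independent_curves.values[2]  # event identical to cluster C
        events = CellEventSeries(mitosis=phi, apoptosis=phi, ecm=phi, grid=grid)
        curves = {net: independent_curves for net in gn.NETWORK_IDS}
        res = calibrate_weights(curves, events, small_cfg(pop_multiplier=60,
                                                          generations=80, n_runs=2))
        w = res.params["MIT"].w
        assert w[2] > 0.9
        assert res.extras["per_network"]["MIT"] < 1e-3

    def test_degenerate_curves_rejected(self, grid):
        zero = ClusterExpressionSeries(network_id="MIT",
                                       values=np.zeros((5, 7)), grid=grid)
        events = CellEventSeries(mitosis=np.ones(7), apoptosis=np.ones(7),
                                 ecm=np.ones(7), grid=grid)
        with pytest.raises(ValueError):
            calibrate_weights({net: zero for net in gn.NETWORK_IDS}, events, small_cfg())


class TestCNCalibration:
    def test_equilibrium_reference_fit(self, grid):
        # constant reference at its own asymptote: the zero-coupling family
        # fits exactly, so the GA must reach a near-zero objective
        level = np.array([1.0, 1.2, 0.8, 1.5, 0.9])
        ref = ClusterExpressionSeries(
            network_id="MIT", values=np.tile(level[:, None], (1, 7)), grid=grid
        )
        res = calibrate_cn(ref, small_cfg(pop_multiplier=15, generations=25))
        assert res.objective < 1e-2
        assert all(stable for stable, _ in res.stability_report.values())

    def test_bounds_span_data_range(self, dataset):
        lo, hi = cn_default_bounds(dataset.expression["MIT"])
        v = dataset.expression["MIT"].values
        assert np.all(lo[25:30] < v.min(axis=1))
        assert np.all(hi[25:30] > v.max(axis=1))

    def test_calibrated_model_passes_all_knockdowns(self, dataset):
        res = calibrate_cn(dataset.expression["APOP"],
                           small_cfg(pop_multiplier=30, generations=35))
        assert res.stability_report is not None
        assert all(stable for stable, _ in res.stability_report.values())


class TestScalingCalibration:
    def test_recovers_thickness_curve(self, clean_dataset):
        truth = clean_dataset.truth
        partial = HybridParameters(
            cn=truth.cn, g0=truth.g0, weights=truth.weights,
            scaling=ScalingFactors(np.ones(5), np.ones(5), np.ones(5)),
            scenario=truth.scenario,
        )
        res = calibrate_scaling(
            partial,
            clean_dataset.morphology["time_days"].to_numpy(),
            clean_dataset.morphology["intimal_thickness_mm"].to_numpy(),
            small_cfg(pop_multiplier=30, generations=50, n_restarts=3,
                      restart_shrink=0.08),
        )
        assert res.extras["prms_percent"] < 1.0

    def test_flow_velocity_scale_degeneracy(self, truth, grid):
        # doubling the centerline velocity doubles every shear quantity;
        # halving all scaling factors restores the identical trajectory
        import dataclasses

        fast = dataclasses.replace(truth.scenario, u=2.0, tau0=None)
        halved = ScalingFactors(
            beta_mit=truth.scaling.beta_mit / 2,
            beta_apop=truth.scaling.beta_apop / 2,
            beta_ecm=truth.scaling.beta_ecm / 2,
        )
        base = gn.simulate_hybrid(truth.hybrid, None, grid)
        rescaled = gn.simulate_hybrid(
            HybridParameters(cn=truth.cn, g0=truth.g0, weights=truth.weights,
                             scaling=halved, scenario=fast),
            None, grid,
        )
        assert np.allclose(base.morphology.intimal_thickness,
                           rescaled.morphology.intimal_thickness, atol=1e-12)
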