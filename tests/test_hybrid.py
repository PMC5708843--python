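import numpy as np
import pytest

import graftnet as gn
from graftnet.core import CNParameters, ScalingFactors, TherapySpec, VesselState
from graftnet.hybrid import HybridParameters, alpha1, alpha2, phi, prms, simulate_cn_networks
from graftnet.vessel import simulate_ds


def constant_model(g0_value=1.0, beta=(1.0, 1.0, 1.0), weights=None, scenario=None):
    """Hybrid model with zero couplings: every cluster stays at its initial value."""
    cn = {net: CNParameters(A=np.zeros((5, 5)), B=np.zeros(5), C=np.zeros(3))
          for net in gn.NETWORK_IDS}
    g0 = {net: np.full(5, g0_value) for net in gn.NETWORK_IDS}
    if weights is None:
        weights = {net: gn.validate_weights(np.full(5, 0.2), network_id=net)
                   for net in gn.NETWORK_IDS}
    scaling = ScalingFactors(
        beta_mit=np.full(5, beta[0]),
        beta_apop=np.full(5, beta[1]),
        beta_ecm=np.full(5, beta[2]),
    )
    return HybridParameters(cn=cn, g0=g0, weights=weights,
                            scaling=scaling, scenario=scenario or VesselState())


class TestAlpha:
    def test_zero_scaling_gives_zero(self, truth, grid):
        params = HybridParameters(
            cn=truth.cn, g0=truth.g0, weights=truth.weights,
            scaling=ScalingFactors(np.zeros(5), np.zeros(5), np.zeros(5)),
            scenario=truth.scenario,
        )
        res = simulate_cn_networks(params, grid)
        t = np.linspace(0, 28, 10)
        assert np.allclose(alpha1(t, params, res), 0.0)
        assert np.allclose(alpha2(t, params, res), 0.0)

    def test_single_term_reduction(self, grid):
        w = {net: gn.WeightVector(network_id=net, w=np.array([1.0, 0, 0, 0, 0]))
             for net in gn.NETWORK_IDS}
        model = constant_model(weights=w, beta=(5.0, 0.0, 0.0))
        model.g0["MIT"] = np.array([1.7, 1, 1, 1, 1])
        res = simulate_cn_networks(model, gn.TimeGrid())
        t = np.array([0.0, 5.0, 28.0])
        # beta1 = (5,0,0,0,0)-equivalent via uniform 5 and w = e_A
        assert np.allclose(alpha1(t, model, res), 1.7)

    def test_balanced_proliferation_cancels(self, grid):
        model = constant_model(beta=(2.0, 2.0, 0.0))
        res = simulate_cn_networks(model, grid)
        t = np.array([0.0, 10.0])
        assert np.allclose(alpha1(t, model, res), 0.0)

    def test_alpha2_sign_flips_with_weights(self, truth, grid):
        res = simulate_cn_networks(truth.hybrid, grid)
        t = np.linspace(0, 28, 7)
        base = alpha2(t, truth.hybrid, res)
        flipped = HybridParameters(
            cn=truth.cn, g0=truth.g0,
            weights={**truth.weights,
                     "ECM": gn.WeightVector(network_id="ECM", w=-truth.weights["ECM"].w)},
            scaling=truth.scaling, scenario=truth.scenario,
        )
        assert np.allclose(alpha2(t, flipped, res), -base)

    def test_linear_in_scaling(self, truth, grid):
        res = simulate_cn_networks(truth.hybrid, grid)
        t = np.linspace(0, 28, 7)
        scaled = HybridParameters(
            cn=truth.cn, g0=truth.g0, weights=truth.weights,
            scaling=ScalingFactors(*(3.0 * v for v in (
                truth.scaling.beta_mit, truth.scaling.beta_apop, truth.scaling.beta_ecm))),
            scenario=truth.scenario,
        )
        assert np.allclose(alpha1(t, scaled, res), 3.0 * alpha1(t, truth.hybrid, res))
        assert np.allclose(alpha2(t, scaled, res), 3.0 * alpha2(t, truth.hybrid, res))

    def test_out_of_range_time_rejected(self, truth, grid):
        res = simulate_cn_networks(truth.hybrid, grid)
        with pytest.raises(ValueError):
            alpha1(np.array([29.0]), truth.hybrid, res)


class TestPRMS:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0])
        assert prms(x, x) == 0.0

    def test_proportional_series(self):
        x = np.array([0.5, 1.0, 2.0])
        assert prms(x, 1.01 * x) == pytest.approx(1.0)

    def test_zero_model(self):
        x = np.array([0.5, 1.0, 2.0])
        assert prms(x, np.zeros(3)) == pytest.approx(100.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            prms(np.zeros(3), np.ones(3))


class TestSimulateHybrid:
    def test_therapy_neutrality(self, truth, grid):
        a = gn.simulate_hybrid(truth.hybrid, None, grid)
        b = gn.simulate_hybrid(truth.hybrid, TherapySpec(), grid)
        assert np.array_equal(a.morphology.a_smc, b.morphology.a_smc)
        assert np.array_equal(a.morphology.a_ecm, b.morphology.a_ecm)

    def test_full_flow_blocks_growth(self, truth, grid):
        import dataclasses

        model = HybridParameters(
            cn=truth.cn, g0=truth.g0, weights=truth.weights, scaling=truth.scaling,
            scenario=dataclasses.replace(truth.scenario, flow_factor=1.0),
        )
        run = gn.simulate_hybrid(model, None, grid)
        assert np.allclose(run.morphology.intimal_area, model.scenario.intimal_area)

    def test_constant_expression_reduces_to_constant_gain_ds(self, grid):
        # zero couplings freeze every cluster at G0, so the coupled model
        # must coincide with the wall system under constant gains
        model = constant_model(g0_value=1.3, beta=(0.4, 0.1, 0.3))
        run = gn.simulate_hybrid(model, None, grid)
        a1 = (np.sum(model.scaling.beta_mit * model.weights["MIT"].w * 1.3)
              - np.sum(model.scaling.beta_apop * model.weights["APOP"].w * 1.3)) / 5.0
        a2 = np.sum(model.scaling.beta_ecm * model.weights["ECM"].w * 1.3) / 5.0
        direct = simulate_ds(lambda t: a1, lambda t: a2, model.scenario, grid)
        assert np.allclose(run.morphology.a_smc, direct.a_smc, rtol=1e-9)
        assert np.allclose(run.morphology.a_ecm, direct.a_ecm, rtol=1e-9)

    def test_time_varying_gain_departs_from_constant_gain(self, truth, grid):
        # the coupled model's thickness is not proportional to the
        # constant-gain exponential course
        run = gn.simulate_hybrid(truth.hybrid, None, grid)
        res = run.cn_results
        a1_0 = float(alpha1(np.array([0.0]), truth.hybrid, res)[0])
        a2_0 = float(alpha2(np.array([0.0]), truth.hybrid, res)[0])
        const = simulate_ds(lambda t: a1_0, lambda t: a2_0, truth.scenario, grid)
        mask = run.morphology.times > 1.0
        ratio = run.morphology.intimal_thickness[mask] / const.intimal_thickness[mask]
        assert np.ptp(ratio) / np.mean(ratio) > 0.05

    def test_self_consistency_with_generator(self, clean_dataset, grid):
        run = gn.simulate_hybrid(clean_dataset.truth.hybrid, None, grid)
        model_thick = run.morphology.sample(grid.times, "intimal_thickness")
        assert np.allclose(
            model_thick, clean_dataset.morphology["intimal_thickness_mm"], atol=1e-12
        )

    def test_phi_matches_weighted_combination(self, truth, grid):
        run = gn.simulate_hybrid(truth.hybrid, None, grid)
        t = np.linspace(0, 28, 5)
        manual = truth.weights["MIT"].w @ run.cn_results["MIT"].sample(t)
        assert np.allclose(phi("MIT", truth.hybrid, run.cn_results, t), manual)
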