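import numpy as np
import pytest

import graftnet as gn
from graftnet.core import CNParameters, ScalingFactors, TherapySpec, VesselState
from graftnet.hybrid import HybridParameters
from graftnet.therapy import (
    evaluate_therapy,
    optimize_pair,
    optimize_single,
    sensitivity,
)


@pytest.fixture(scope="module")
def model(truth):
    return truth.hybrid


@pytest.fixture(scope="module")
def inert_e_model(truth):
    """Truth model with cluster E fully decoupled and weightless: freezing E
    at any delta cannot change the outcome."""
    cn = {}
    for net, p in truth.cn.items():
        A = p.A.copy()
        A[4, :] = 0.0
        A[:, 4] = 0.0
        cn[net] = CNParameters(A=A, B=p.B, C=p.C)
    weights = {}
    for net, wv in truth.weights.items():
        w = wv.w.copy()
        w[4] = 0.0
        weights[net] = gn.validate_weights(w, network_id=net)
    return HybridParameters(cn=cn, g0=truth.g0, weights=weights,
                            scaling=truth.scaling, scenario=truth.scenario)


class TestEvaluateTherapy:
    def test_empty_spec_zero_gain(self, model):
        out = evaluate_therapy(model, TherapySpec())
        assert out.viable
        assert out.gain_percent == pytest.approx(0.0, abs=1e-12)
        assert out.a_pre == out.a_post

    def test_gain_identity(self, model):
        out = evaluate_therapy(model, TherapySpec({"C": 0.5}))
        assert out.viable
        assert out.gain_percent == pytest.approx(
            100.0 * (out.a_pre - out.a_post) / out.a_pre
        )

    def test_nonviable_when_event_rate_goes_negative(self, grid):
        # over-expressing a strongly inhibitory cluster drives the weighted
        # mitosis combination negative -> therapy discarded as non-viable
        cn = {net: CNParameters(A=np.zeros((5, 5)), B=np.zeros(5), C=np.zeros(3))
              for net in gn.NETWORK_IDS}
        g0 = {net: np.ones(5) for net in gn.NETWORK_IDS}
        w = np.array([0.3, -0.4, 0.3, 0.0, 0.0])
        weights = {net: gn.WeightVector(network_id=net, w=w) for net in gn.NETWORK_IDS}
        m = HybridParameters(
            cn=cn, g0=g0, weights=weights,
            scaling=ScalingFactors(np.full(5, 0.3), np.zeros(5), np.full(5, 0.1)),
            scenario=VesselState(),
        )
        untreated = evaluate_therapy(m, TherapySpec())
        assert untreated.viable  # phi = 0.2 > 0 without treatment
        out = evaluate_therapy(m, TherapySpec({"B": 3.0}))
        # phi_Mit = 0.3 + 0.3 - 0.4*3 = -0.6 < 0
        assert not out.viable
        assert out.gain_percent is None


class TestOptimizeSingle:
    def test_inert_cluster_flat_response_boundary_tie(self, inert_e_model):
        d, out = optimize_single(inert_e_model, "E", step=0.25)
        assert d == 0.0  # flat response resolves to the smallest delta
        assert out.gain_percent == pytest.approx(0.0, abs=1e-6)

    def test_beneficial_inhibition_found(self, model):
        d, out = optimize_single(model, "C", step=0.05)
        assert d < 1.0
        assert out.viable
        assert out.gain_percent > 50.0

    def test_grid_matches_direct_evaluation(self, model):
        # the batched affine path must agree with the one-at-a-time
        # adaptive-integrator route
        from graftnet.therapy import _GridEvaluator

        ev = _GridEvaluator(model, ("D",))
        deltas = np.array([0.0, 0.5, 1.0, 2.0, 3.0])
        areas, viable, _ = ev.evaluate(deltas[:, None])
        for d, a, v in zip(deltas, areas, viable):
            out = evaluate_therapy(model, TherapySpec({"D": d}))
            assert a == pytest.approx(out.a_post, rel=1e-5)
            assert v == out.viable

    def test_refinement_consistency(self, model):
        d_coarse, _ = optimize_single(model, "D", step=0.1)
        d_fine, _ = optimize_single(model, "D", step=0.01)
        assert abs(d_coarse - d_fine) <= 0.1 + 1e-9

    def test_deterministic(self, model):
        r1 = optimize_single(model, "B", step=0.1)
        r2 = optimize_single(model, "B", step=0.1)
        assert r1[0] == r2[0]
        assert r1[1].a_post == r2[1].a_post


class TestOptimizePair:
    def test_pair_with_inert_partner_marginalizes(self, inert_e_model):
        d_single, out_single = optimize_single(inert_e_model, "C", step=0.05)
        pair, out_pair = optimize_pair(inert_e_model, ("C", "E"),
                                       coarse=0.05, fine=0.05)
        assert pair[0] == pytest.approx(d_single, abs=0.05)
        assert out_pair.gain_percent == pytest.approx(out_single.gain_percent,
                                                      abs=0.5)

    def test_identical_clusters_rejected(self, model):
        with pytest.raises(ValueError):
            optimize_pair(model, ("C", "C"))

    def test_pair_beats_or_matches_worse_single(self, model):
        # coupling the two best targets must not underperform the weaker one
        pair, out = optimize_pair(model, ("C", "D"), coarse=0.25, fine=0.25)
        _, out_d = optimize_single(model, "D", step=0.25)
        assert out.gain_percent >= out_d.gain_percent - 0.5


class TestSensitivity:
    def test_grid_contains_center_and_is_symmetric(self, model):
        spec = TherapySpec({"D": 2.0})
        rep = sensitivity(model, spec, n_points=11)
        g = rep.grids[0]
        assert g.size == 11
        assert np.isclose(g[5], 2.0)  # center in the middle
        assert np.allclose(g + g[::-1], 2 * 2.0)  # symmetric before clipping
        assert rep.gains.shape == (11,)

    def test_clipping_at_delta_cap(self, model):
        rep = sensitivity(model, TherapySpec({"D": 3.0}), n_points=5)
        assert np.all(rep.grids[0] <= 3.0)
        assert np.isclose(rep.grids[0][-1], 3.0)

    def test_flat_model_uniform_gains(self, inert_e_model):
        rep = sensitivity(inert_e_model, TherapySpec({"E": 2.0}), n_points=5)
        assert np.all(rep.viable)
        assert np.ptp(rep.gains) < 1e-6
        assert rep.robustness == 1.0  # a flat response is trivially robust

    def test_pair_report_shape(self, model):
        rep = sensitivity(model, TherapySpec({"C": 1.0, "D": 2.0}), n_points=5)
        assert rep.gains.shape == (5, 5)
        assert rep.clusters == ("C", "D")
        assert 0.0 <= rep.robustness <= 1.0

    def test_empty_center_rejected(self, model):
        with pytest.raises(ValueError):
            sensitivity(model, TherapySpec())
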