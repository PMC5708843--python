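"""Coupling of the three cluster networks to the wall-growth system.

The constant growth gains of the bare dynamical system are replaced by
weighted, scaled network output:

    alpha1(t) = sum_i beta1_i w1_i G_i^Mit(t)/5 - sum_i beta2_i w2_i G_i^Apop(t)/5
    alpha2(t) = sum_i beta3_i w3_i G_i^ECM(t)/5

so proliferation is mitosis net of apoptosis and matrix deposition follows the
ECM network. A therapy freezes the treated cluster at ``delta * G(0)``
simultaneously in all three networks (one gene set, three biologic mappings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    NETWORK_IDS,
    CNParameters,
    ScalingFactors,
    TherapySpec,
    TimeGrid,
    VesselState,
    WeightVector,
    cluster_index,
)
from .network import CNSimResult, simulate_network
from .vessel import MorphologyTrajectory, simulate_ds


@dataclass(eq=False)
class HybridParameters:
    """Everything needed to run the coupled model.

    ``cn``/``g0``/``weights`` are keyed by network id ("MIT", "APOP", "ECM");
    ``g0`` holds the initial (2 h) cluster expression of each network.
    """

    cn: dict[str, CNParameters]
    g0: dict[str, np.ndarray]
    weights: dict[str, WeightVector]
    scaling: ScalingFactors
    scenario: VesselState
    divergence_bound: float | None = field(default=None)

    def __post_init__(self) -> None:
        for mapping, what in ((self.cn, "cn"), (self.g0, "g0"), (self.weights, "weights")):
            missing = set(NETWORK_IDS) - set(mapping)
            if missing:
                raise ValueError(f"{what} missing networks {sorted(missing)}")
        self.g0 = {k: np.asarray(v, dtype=float) for k, v in self.g0.items()}
        for k, v in self.g0.items():
            if v.shape != (5,):
                raise ValueError(f"g0[{k}] must be a 5-vector")
        for k, wv in self.weights.items():
            if wv.network_id != k:
                raise ValueError(f"weights[{k}] is labeled {wv.network_id}")

    def beta(self, network_id: str) -> np.ndarray:
        return {
            "MIT": self.scaling.beta_mit,
            "APOP": self.scaling.beta_apop,
            "ECM": self.scaling.beta_ecm,
        }[network_id]

    def default_bound(self) -> float:
        if self.divergence_bound is not None:
            return self.divergence_bound
        scale = max(
            max(np.max(np.abs(v)) for v in self.g0.values()),
            max(np.max(np.abs(p.B)) for p in self.cn.values()),
        )
        return 50.0 * float(scale)


def simulate_cn_networks(
    params: HybridParameters,
    grid: TimeGrid,
    therapy: TherapySpec | None = None,
) -> dict[str, CNSimResult]:
    """Run the three networks, applying the therapy's freeze rule to each."""
    therapy = therapy or TherapySpec()
    frozen = set(therapy.treated)
    bound = params.default_bound()
    results = {}
    for net in NETWORK_IDS:
        g0 = params.g0[net].copy()
        for label, delta in therapy.deltas.items():
            g0[cluster_index(label)] *= delta
        results[net] = simulate_network(
            params.cn[net], g0, grid, frozen=frozen, divergence_bound=bound
        )
    return results


def _combo(params: HybridParameters, network_id: str, cn_results, t) -> np.ndarray:
    coeff = params.beta(network_id) * params.weights[network_id].w
    g = cn_results[network_id].sample(t)
    return coeff @ g / 5.0


def alpha1(t, params: HybridParameters, cn_results) -> np.ndarray:
    """Net proliferation gain: mitosis minus apoptosis network output."""
    t = np.asarray(t, dtype=float)
    _check_range(t, cn_results)
    return _combo(params, "MIT", cn_results, t) - _combo(params, "APOP", cn_results, t)


def alpha2(t, params: HybridParameters, cn_results) -> np.ndarray:
    """Matrix-deposition gain from the ECM network."""
    t = np.asarray(t, dtype=float)
    _check_range(t, cn_results)
    return _combo(params, "ECM", cn_results, t)


def _check_range(t, cn_results) -> None:
    tmax = min(res.times[-1] for res in cn_results.values())
    if np.any(np.asarray(t) > tmax + 1e-9) or np.any(np.asarray(t) < -1e-9):
        raise ValueError("time outside the simulated range")


def phi(network_id: str, params: HybridParameters, cn_results, t) -> np.ndarray:
    """Weighted cluster combination for one biologic event (rate surrogate)."""
    g = cn_results[network_id].sample(np.asarray(t, dtype=float))
    return params.weights[network_id].w @ g


@dataclass(eq=False)
class HybridRun:
    morphology: MorphologyTrajectory
    cn_results: dict[str, CNSimResult]
    therapy: TherapySpec

    @property
    def diverged(self) -> bool:
        return self.morphology.diverged or any(r.diverged for r in self.cn_results.values())


def simulate_hybrid(
    params: HybridParameters,
    therapy: TherapySpec | None = None,
    grid: TimeGrid | None = None,
) -> HybridRun:
    """Run the full coupled model: three networks, then the wall system."""
    grid = grid or TimeGrid()
    therapy = therapy or TherapySpec()
    cn_results = simulate_cn_networks(params, grid, therapy)

    t_nodes = cn_results["MIT"].times
    a1_nodes = alpha1(t_nodes, params, cn_results)
    a2_nodes = alpha2(t_nodes, params, cn_results)

    def a1(t):
        return np.interp(t, t_nodes, a1_nodes)

    def a2(t):
        return np.interp(t, t_nodes, a2_nodes)

    morph = simulate_ds(a1, a2, params.scenario, grid)
    if any(r.diverged for r in cn_results.values()):
        morph.diverged = True
    return HybridRun(morphology=morph, cn_results=cn_results, therapy=therapy)


def prms(reference, model) -> float:
    """Normalized root-mean-square deviation, in percent:
    100 * ||ref - mod|| / ||ref||."""
    ref = np.asarray(reference, dtype=float)
    mod = np.asarray(model, dtype=float)
    if ref.shape != mod.shape:
        raise ValueError("series must be aligned")
    norm = np.sqrt(np.sum(ref * ref))
    if norm == 0.0:
        raise ValueError("reference series has zero norm")
    return float(100.0 * np.sqrt(np.sum((ref - mod) ** 2)) / norm)
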