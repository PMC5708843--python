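"""Shear-driven wall growth: the dynamical-system half of the model.

The graft is a straight cylinder; Poiseuille flow gives the wall shear

    tau = 2 * mu * U_eff / R1,      U_eff = flow_factor * U,

and only a shear *deficit* relative to the arterial baseline drives growth,
Delta-tau^- = min(tau - tau0, 0):

    dA_SMC/dt = -alpha1(t) * Delta-tau^- * A_SMC
    dA_ECM/dt = -alpha2(t) * Delta-tau^- * A_SMC   (floored at A_ECM = 0).

Intimal growth encroaches on the lumen (fixed outer boundary), which raises
tau back toward tau0 — the homeostatic feedback loop that lets the graft find
a new set point or, if unbalanced, occlude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import TimeGrid, VesselState

#: Hard floor on the lumen radius (mm); reaching it means the simulated graft
#: is effectively occluded and the trajectory is flagged.
R1_FLOOR = 0.05


def shear_stress(state: VesselState, r1: float | None = None) -> float:
    """Wall shear (Pa) at lumen radius ``r1`` (defaults to the current state's).

    With mu in cP and R1 in mm the unit conversions cancel:
    tau[Pa] = 2 * mu[cP] * U_eff[m/s] / R1[mm].
    """
    r1 = state.r1 if r1 is None else r1
    if r1 <= 0:
        raise ValueError("lumen radius must be positive")
    return 2.0 * state.mu * (state.flow_factor * state.u) / r1


def delta_tau_minus(tau: float, tau0: float) -> float:
    """Negative part of the shear deviation from baseline: min(tau - tau0, 0)."""
    return min(tau - tau0, 0.0)


def lumen_radius(r1_baseline: float, intimal_area_growth: float,
                 floor: float = R1_FLOOR) -> float:
    """Lumen radius once ``intimal_area_growth`` mm^2 of new intima has been
    deposited against a fixed outer boundary; floored at ``floor`` mm."""
    if intimal_area_growth < 0:
        raise ValueError("intimal area growth must be non-negative")
    r_sq = r1_baseline**2 - intimal_area_growth / np.pi
    return float(np.sqrt(max(floor**2, r_sq)))


@dataclass(eq=False)
class MorphologyTrajectory:
    """Dense time course of wall composition, geometry and shear."""

    times: np.ndarray
    a_smc: np.ndarray
    a_ecm: np.ndarray
    r1: np.ndarray
    tau: np.ndarray
    r1_baseline: float
    occluded: bool = False
    diverged: bool = False

    @property
    def intimal_area(self) -> np.ndarray:
        return self.a_smc + self.a_ecm

    @property
    def intimal_thickness(self) -> np.ndarray:
        return self.r1_baseline - self.r1

    def sample(self, t, what: str = "intimal_thickness") -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.interp(t, self.times, getattr(self, what))

    def final_intimal_area(self) -> float:
        return float(self.intimal_area[-1])


def simulate_ds(
    alpha1: Callable[[float], float],
    alpha2: Callable[[float], float],
    state0: VesselState,
    grid: TimeGrid,
) -> MorphologyTrajectory:
    """Integrate the wall-growth system with time-dependent growth gains.

    ``alpha1``/``alpha2`` are callables of time (days) in Pa^-1 day^-1; shear
    is recomputed from the encroached lumen at every step, closing the
    feedback loop. Integration is classical RK4 on the dense step grid (the
    floor on A_ECM makes the vector field discontinuous there, which defeats
    adaptive stiff steppers; the fixed-step path handles it by clipping and
    resolves these smooth dynamics to ~1e-8 relative — see docs/methods.md).
    """
    intimal0 = state0.intimal_area
    t_dense = grid.dense_times()

    nodes = ds_node_times(grid)
    a1_nodes = np.asarray([float(alpha1(t)) for t in nodes])[None, :]
    a2_nodes = np.asarray([float(alpha2(t)) for t in nodes])[None, :]
    step_times, smc, ecm = integrate_ds_batch(a1_nodes, a2_nodes, state0, grid)
    diverged = not (np.all(np.isfinite(smc)) and np.all(np.isfinite(ecm)))
    if diverged:
        keep = np.all(np.isfinite(smc), axis=0) & np.all(np.isfinite(ecm), axis=0)
        last = max(int(np.argmin(keep)) - 1, 0) if not keep.all() else len(step_times) - 1
        smc[:, last + 1:] = smc[:, last:last + 1]
        ecm[:, last + 1:] = ecm[:, last:last + 1]
    a_smc = np.interp(t_dense, step_times, smc[0])
    a_ecm = np.maximum(np.interp(t_dense, step_times, ecm[0]), 0.0)

    growth = np.maximum(a_smc + a_ecm - intimal0, 0.0)
    r1 = np.array([lumen_radius(state0.r1_baseline, g) for g in growth])
    tau = np.array([shear_stress(state0, r) for r in r1])
    occluded = bool(np.any(r1 <= R1_FLOOR * (1 + 1e-9)))
    return MorphologyTrajectory(
        times=t_dense, a_smc=a_smc, a_ecm=a_ecm, r1=r1, tau=tau,
        r1_baseline=state0.r1_baseline, occluded=occluded, diverged=diverged,
    )


# ---------------------------------------------------------------------------
# Vectorized fixed-step path used by calibration and therapy grids


def ds_node_times(grid: TimeGrid, n_steps: int | None = None) -> np.ndarray:
    """Half-step node times for the batch RK4 integrator (step = dense_step)."""
    if n_steps is None:
        n_steps = int(round(grid.t_end / grid.dense_step))
    return np.linspace(0.0, grid.t_end, 2 * n_steps + 1)


def integrate_ds_batch(
    alpha1_nodes: np.ndarray,
    alpha2_nodes: np.ndarray,
    state0: VesselState,
    grid: TimeGrid,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classical RK4 on the wall system for a whole population at once.

    ``alpha*_nodes`` have shape (P, 2*n_steps+1): gain values on the half-step
    node grid of :func:`ds_node_times`. Returns ``(step_times, a_smc, a_ecm)``
    where the state arrays have shape (P, n_steps+1). Matches the adaptive
    integrator to ~1e-8 relative on these smooth dynamics.
    """
    a1 = np.atleast_2d(np.asarray(alpha1_nodes, dtype=float))
    a2 = np.atleast_2d(np.asarray(alpha2_nodes, dtype=float))
    n_nodes = a1.shape[1]
    if n_nodes % 2 == 0:
        raise ValueError("alpha node arrays must cover half steps (odd length)")
    n_steps = (n_nodes - 1) // 2
    h = grid.t_end / n_steps
    P = a1.shape[0]

    intimal0 = state0.intimal_area
    r1b2 = state0.r1_baseline**2
    tau_num = 2.0 * state0.mu * state0.flow_factor * state0.u
    tau0 = state0.tau0

    def dtm(a_total):
        growth = np.maximum(a_total - intimal0, 0.0)
        r1 = np.sqrt(np.maximum(R1_FLOOR**2, r1b2 - growth / np.pi))
        return np.minimum(tau_num / r1 - tau0, 0.0)

    def deriv(a1v, a2v, smc, ecm):
        d = dtm(smc + np.maximum(ecm, 0.0))
        d_smc = -a1v * d * smc
        d_ecm = np.where((ecm <= 0.0) & (-a2v * d * smc < 0.0), 0.0, -a2v * d * smc)
        return d_smc, d_ecm

    smc = np.full(P, state0.a_smc)
    ecm = np.full(P, state0.a_ecm)
    out_smc = np.empty((P, n_steps + 1))
    out_ecm = np.empty((P, n_steps + 1))
    out_smc[:, 0] = smc
    out_ecm[:, 0] = ecm
    for k in range(n_steps):
        aL1, aM1, aR1 = a1[:, 2 * k], a1[:, 2 * k + 1], a1[:, 2 * k + 2]
        aL2, aM2, aR2 = a2[:, 2 * k], a2[:, 2 * k + 1], a2[:, 2 * k + 2]
        k1s, k1e = deriv(aL1, aL2, smc, ecm)
        k2s, k2e = deriv(aM1, aM2, smc + 0.5 * h * k1s, ecm + 0.5 * h * k1e)
        k3s, k3e = deriv(aM1, aM2, smc + 0.5 * h * k2s, ecm + 0.5 * h * k2e)
        k4s, k4e = deriv(aR1, aR2, smc + h * k3s, ecm + h * k3e)
        smc = smc + h / 6.0 * (k1s + 2 * k2s + 2 * k3s + k4s)
        ecm = np.maximum(ecm + h / 6.0 * (k1e + 2 * k2e + 2 * k3e + k4e), 0.0)
        out_smc[:, k + 1] = smc
        out_ecm[:, k + 1] = ecm
    step_times = np.linspace(0.0, grid.t_end, n_steps + 1)
    return step_times, out_smc, out_ecm
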