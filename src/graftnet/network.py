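"""The five-cluster interconnected gene network.

Each cluster's mean expression G_i(t) obeys

    dG_k/dt = lambda(t) * sum_j A[j, k] * (G_j - B_j),

a linear system toward the asymptote vector B whose direction of flow is
modulated by the scalar cubic mask lambda(t) = C1 t^3 + C2 t^2 + C3 t + 1.
Because lambda is scalar the exact solution is

    G(t) = B + expm(A^T * Lambda(t)) (G(0) - B),   Lambda(t) = int_0^t lambda,

which this module exposes both as an adaptive ODE integration
(:func:`simulate_network`, the public simulator, able to freeze clusters for
therapy and knockdown variants) and as a batched eigendecomposition evaluator
used by the calibration stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import CLUSTER_LABELS, CNParameters, ClusterExpressionSeries, TimeGrid, cluster_index


def eval_modulation(C, t):
    """Cubic time-modulation mask lambda(t) = C1 t^3 + C2 t^2 + C3 t + 1."""
    C = np.asarray(C, dtype=float)
    t = np.asarray(t, dtype=float)
    return ((C[..., 0] * t + C[..., 1]) * t + C[..., 2]) * t + 1.0


def modulation_integral(C, t):
    """Lambda(t) = int_0^t lambda(s) ds for the cubic mask."""
    C = np.asarray(C, dtype=float)
    t = np.asarray(t, dtype=float)
    return (((C[..., 0] / 4.0 * t + C[..., 1] / 3.0) * t + C[..., 2] / 2.0) * t + 1.0) * t


@dataclass(eq=False)
class CNSimResult:
    """Dense cluster trajectories plus divergence diagnostics."""

    times: np.ndarray
    trajectories: np.ndarray  # (5, len(times))
    diverged: bool
    max_abs: float

    def sample(self, t) -> np.ndarray:
        """Linear interpolation of all five trajectories at times ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((self.trajectories.shape[0], t.size))
        for i, row in enumerate(self.trajectories):
            out[i] = np.interp(t, self.times, row)
        return out

    def cluster(self, label: str) -> np.ndarray:
        return self.trajectories[cluster_index(label)]


def simulate_network(
    params: CNParameters,
    g0,
    grid: TimeGrid,
    frozen=(),
    divergence_bound: float | None = None,
    rtol: float = 1e-8,
) -> CNSimResult:
    """Integrate the network on the dense grid.

    Clusters named in ``frozen`` keep their initial value (zero derivative) but
    still drive the others through the coupling sum. Integration failures and
    trajectories exceeding ``divergence_bound`` are reported through the
    ``diverged`` flag, never raised.
    """
    g0 = np.asarray(g0, dtype=float).copy()
    if g0.shape != (5,):
        raise ValueError("G0 must be a 5-vector")
    frozen = frozenset(frozen)
    unknown = frozen - set(CLUSTER_LABELS)
    if unknown:
        raise ValueError(f"unknown frozen cluster labels {sorted(unknown)}")
    free = np.array([lab not in frozen for lab in CLUSTER_LABELS])

    M = params.A.T
    B = params.B
    C = params.C
    bound = np.inf if divergence_bound is None else float(divergence_bound)
    t_dense = grid.dense_times()

    def rhs(t, g):
        dg = eval_modulation(C, t) * (M @ (g - B))
        return np.where(free, dg, 0.0)

    def blowup(t, g):
        return np.max(np.abs(g)) - bound

    blowup.terminal = True

    try:
        sol = solve_ivp(
            rhs,
            (0.0, grid.t_end),
            g0,
            method="LSODA",
            t_eval=t_dense,
            rtol=rtol,
            atol=1e-10,
            events=blowup if np.isfinite(bound) else None,
        )
    except Exception:
        traj = np.tile(g0[:, None], (1, t_dense.size))
        return CNSimResult(times=t_dense, trajectories=traj, diverged=True, max_abs=np.inf)

    n_ok = sol.y.shape[1] if sol.success or sol.y.size else 0
    diverged = (not sol.success) or (n_ok < t_dense.size)
    traj = np.empty((5, t_dense.size))
    if n_ok:
        traj[:, :n_ok] = sol.y
        traj[:, n_ok:] = sol.y[:, -1:]
    else:
        traj[:] = g0[:, None]
    finite = traj[np.isfinite(traj)]
    max_abs = float(np.max(np.abs(finite))) if finite.size else np.inf
    if not np.all(np.isfinite(traj)) or max_abs > bound:
        diverged = True
    return CNSimResult(times=t_dense, trajectories=traj, diverged=diverged, max_abs=max_abs)


def fit_residual(sim: CNSimResult, reference: ClusterExpressionSeries,
                 clusters=None) -> float:
    """Sum of squared deviations model-vs-reference at the post-implant times.

    This is the calibration objective as used throughout: the squared distance
    summed over clusters (all five, or the subset given) and the M harvest
    times after implantation.
    """
    times = reference.grid.post_times
    model = sim.sample(times)
    ref = reference.post_values
    idx = (
        np.arange(5)
        if clusters is None
        else np.array([cluster_index(c) for c in clusters])
    )
    diff = model[idx] - ref[idx]
    return float(np.sum(diff * diff))


def knockdown_response(
    params: CNParameters,
    g0,
    cluster: str,
    reference: ClusterExpressionSeries,
    tol: float = 10.0,
    divergence_bound: float | None = None,
    rtol: float = 1e-8,
) -> tuple[bool, float]:
    """Silence one cluster (clamped to zero, value and derivative) and score
    the remaining four against the reference.

    Returns ``(stable, rms)`` where ``rms`` is the sum-of-squares misfit of
    the four free clusters and ``stable`` requires no divergence and
    ``rms <= tol``.
    """
    if divergence_bound is None:
        divergence_bound = 50.0 * float(np.max(np.abs(reference.values)))
    g0 = np.asarray(g0, dtype=float).copy()
    g0[cluster_index(cluster)] = 0.0
    sim = simulate_network(
        params, g0, reference.grid, frozen={cluster},
        divergence_bound=divergence_bound, rtol=rtol,
    )
    others = [lab for lab in CLUSTER_LABELS if lab != cluster]
    if sim.diverged:
        return False, np.inf
    rms = fit_residual(sim, reference, clusters=others)
    return (rms <= tol), rms


# ---------------------------------------------------------------------------
# Exact solution paths (linear-in-G structure)


def closed_form(params: CNParameters, g0, times) -> np.ndarray:
    """Exact trajectories at ``times`` via the matrix exponential solution."""
    from scipy.linalg import expm

    g0 = np.asarray(g0, dtype=float)
    times = np.asarray(times, dtype=float)
    M = params.A.T
    lam = modulation_integral(params.C, times)
    d0 = g0 - params.B
    out = np.empty((5, times.size))
    for k, L in enumerate(lam):
        out[:, k] = params.B + expm(M * L) @ d0
    return out


def closed_form_batch(A_batch, B_batch, C_batch, g0, times) -> np.ndarray:
    """Vectorized exact solution for a population of parameter candidates.

    Returns an array of shape ``(P, 5, T)``. Candidates whose eigenbasis is
    numerically singular or whose trajectories overflow come back non-finite;
    callers penalize those.
    """
    A_batch = np.asarray(A_batch, dtype=float)
    B_batch = np.asarray(B_batch, dtype=float)
    C_batch = np.asarray(C_batch, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    times = np.asarray(times, dtype=float)

    M = np.swapaxes(A_batch, -1, -2)  # (P, 5, 5)
    lam = modulation_integral(C_batch[:, None, :], times[None, :])  # (P, T)
    d0 = g0[None, :] - B_batch  # (P, 5)

    with np.errstate(all="ignore"):
        w, V = np.linalg.eig(M)  # complex (P,5), (P,5,5)
        try:
            y0 = np.linalg.solve(V, d0[..., None])[..., 0]  # (P, 5)
        except np.linalg.LinAlgError:
            y0 = (np.linalg.pinv(V) @ d0[..., None])[..., 0]
        # exp(w_i * Lambda(t)) for every candidate/mode/time
        expwl = np.exp(w[:, :, None] * lam[:, None, :])  # (P, 5, T)
        modes = expwl * y0[:, :, None]
        G = B_batch[:, :, None] + np.einsum("pij,pjt->pit", V, modes).real
    return G
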