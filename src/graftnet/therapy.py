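"""In-silico gene-therapy screening.

A therapy fixes one or two clusters at ``delta`` times their initial
expression for the whole 28-day follow-up (in all three networks at once) and
is scored by the relative reduction of the 28-day intimal cross-sectional
area:

    gain% = 100 * (A_pre - A_post) / A_pre.

A therapy is viable only if the weighted mitosis and apoptosis combinations
stay non-negative throughout the simulation (cell birth/death rates cannot be
negative); non-viable settings are excluded from optimization.

Optimization over delta is an exhaustive, deterministic grid search. Because a
frozen cluster enters the remaining linear dynamics as a constant input, every
trajectory — and hence every alpha and every event-rate combination — is
affine in the treated deltas; three base simulations per network therefore
suffice to evaluate an entire delta grid, with the wall ODE batched over the
grid. Returned optima are re-evaluated through the adaptive-integrator path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import CLUSTER_LABELS, DELTA_MAX, NETWORK_IDS, TherapySpec, TimeGrid, cluster_index
from .hybrid import HybridParameters, HybridRun, phi, simulate_hybrid
from .network import simulate_network
from .vessel import ds_node_times, integrate_ds_batch

VIABILITY_TOL = -1e-9


@dataclass(eq=False)
class TherapyOutcome:
    spec: TherapySpec
    a_pre: float
    a_post: float
    viable: bool
    gain_percent: float | None
    diverged: bool
    pre: HybridRun
    post: HybridRun


def _viable(params: HybridParameters, run: HybridRun) -> bool:
    t = run.cn_results["MIT"].times
    return bool(
        np.min(phi("MIT", params, run.cn_results, t)) >= VIABILITY_TOL
        and np.min(phi("APOP", params, run.cn_results, t)) >= VIABILITY_TOL
    )


def evaluate_therapy(
    model: HybridParameters,
    spec: TherapySpec,
    grid: TimeGrid | None = None,
    pre: HybridRun | None = None,
) -> TherapyOutcome:
    """Simulate pre- and post-therapy and score the 28-day area reduction."""
    grid = grid or TimeGrid()
    if pre is None:
        pre = simulate_hybrid(model, None, grid)
    post = simulate_hybrid(model, spec, grid)
    a_pre = pre.morphology.final_intimal_area()
    a_post = post.morphology.final_intimal_area()
    diverged = pre.diverged or post.diverged
    viable = (not diverged) and _viable(model, post)
    gain = 100.0 * (a_pre - a_post) / a_pre if viable else None
    return TherapyOutcome(
        spec=spec, a_pre=a_pre, a_post=a_post, viable=viable,
        gain_percent=gain, diverged=diverged, pre=pre, post=post,
    )


# ---------------------------------------------------------------------------
# Batched grid evaluation (affine-in-delta fast path)


class _GridEvaluator:
    """Evaluates final intimal area and viability over a grid of deltas for a
    fixed set of treated clusters."""

    def __init__(self, model: HybridParameters, clusters: tuple[str, ...],
                 grid: TimeGrid | None = None):
        self.model = model
        self.clusters = clusters
        self.grid = grid or TimeGrid()
        self.nodes = ds_node_times(self.grid)
        self.bound = model.default_bound()
        self._build_bases()

    def _base_sim(self, net: str, values: dict[str, float]):
        g0 = self.model.g0[net].copy()
        for lab in self.clusters:
            g0[cluster_index(lab)] = values.get(lab, 0.0) * self.model.g0[net][cluster_index(lab)]
        return simulate_network(
            self.model.cn[net], g0, self.grid,
            frozen=set(self.clusters), divergence_bound=self.bound,
        )

    def _build_bases(self) -> None:
        self.ok = True
        # trajectories sampled on the RK4 half-step node grid, per network:
        # base (all treated at 0) and one difference column per treated cluster
        self.G0: dict[str, np.ndarray] = {}
        self.dG: dict[str, list[np.ndarray]] = {}
        for net in NETWORK_IDS:
            sim0 = self._base_sim(net, {})
            if sim0.diverged:
                self.ok = False
                return
            g_base = sim0.sample(self.nodes)
            self.G0[net] = g_base
            diffs = []
            for lab in self.clusters:
                sim1 = self._base_sim(net, {lab: 1.0})
                if sim1.diverged:
                    self.ok = False
                    return
                diffs.append(sim1.sample(self.nodes) - g_base)
            self.dG[net] = diffs

    def _combined(self, net: str, deltas: np.ndarray) -> np.ndarray:
        """Trajectories (P, 5, nodes) for a (P, k) delta matrix."""
        G = np.broadcast_to(self.G0[net], (deltas.shape[0],) + self.G0[net].shape).copy()
        for j, d in enumerate(self.dG[net]):
            G += deltas[:, j, None, None] * d
        return G

    def evaluate(self, deltas: np.ndarray):
        """Return (final_area, viable, diverged) arrays for (P, k) deltas."""
        deltas = np.atleast_2d(np.asarray(deltas, dtype=float))
        P = deltas.shape[0]
        if not self.ok:
            return self._evaluate_direct(deltas)
        areas = np.empty(P)
        viable = np.ones(P, dtype=bool)
        diverged = np.zeros(P, dtype=bool)
        w = self.model.weights
        chunk = max(1, int(2e7 // (5 * self.nodes.size)))
        a1 = np.empty((P, self.nodes.size))
        a2 = np.empty((P, self.nodes.size))
        for s in range(0, P, chunk):
            sl = slice(s, min(s + chunk, P))
            Gm = self._combined("MIT", deltas[sl])
            Ga = self._combined("APOP", deltas[sl])
            Ge = self._combined("ECM", deltas[sl])
            for Gx in (Gm, Ga, Ge):
                diverged[sl] |= np.max(np.abs(Gx), axis=(1, 2)) > self.bound
            cm = self.model.beta("MIT") * w["MIT"].w
            ca = self.model.beta("APOP") * w["APOP"].w
            ce = self.model.beta("ECM") * w["ECM"].w
            a1[sl] = (np.einsum("i,pit->pt", cm, Gm) - np.einsum("i,pit->pt", ca, Ga)) / 5.0
            a2[sl] = np.einsum("i,pit->pt", ce, Ge) / 5.0
            phi_m = np.einsum("i,pit->pt", w["MIT"].w, Gm)
            phi_a = np.einsum("i,pit->pt", w["APOP"].w, Ga)
            viable[sl] = (
                (np.min(phi_m, axis=1) >= VIABILITY_TOL)
                & (np.min(phi_a, axis=1) >= VIABILITY_TOL)
            )
        _, smc, ecm = integrate_ds_batch(a1, a2, self.model.scenario, self.grid)
        areas[:] = smc[:, -1] + ecm[:, -1]
        viable &= ~diverged
        return areas, viable, diverged

    def _evaluate_direct(self, deltas: np.ndarray):
        """Slow fallback when a base simulation diverges."""
        P = deltas.shape[0]
        areas = np.empty(P)
        viable = np.zeros(P, dtype=bool)
        diverged = np.zeros(P, dtype=bool)
        pre = simulate_hybrid(self.model, None, self.grid)
        for i, row in enumerate(deltas):
            spec = TherapySpec(dict(zip(self.clusters, row)))
            out = evaluate_therapy(self.model, spec, self.grid, pre=pre)
            areas[i] = out.a_post
            viable[i] = out.viable
            diverged[i] = out.diverged
        return areas, viable, diverged


def _delta_grid(step: float) -> np.ndarray:
    n = int(round(DELTA_MAX / step))
    return np.round(np.linspace(0.0, DELTA_MAX, n + 1), 10)


def optimize_single(
    model: HybridParameters,
    cluster: str,
    step: float = 0.01,
    grid: TimeGrid | None = None,
) -> tuple[float | None, TherapyOutcome | None]:
    """Exhaustive search of delta in [0, 3] minimizing the viable 28-day area.

    Ties resolve to the smaller delta (first grid hit). Returns
    ``(None, None)`` when no viable delta exists.
    """
    deltas = _delta_grid(step)
    ev = _GridEvaluator(model, (cluster,), grid)
    areas, viable, _ = ev.evaluate(deltas[:, None])
    if not np.any(viable):
        return None, None
    masked = np.where(viable, areas, np.inf)
    best = int(np.argmin(masked))
    d = float(deltas[best])
    outcome = evaluate_therapy(model, TherapySpec({cluster: d}), grid)
    return d, outcome


def optimize_pair(
    model: HybridParameters,
    clusters: tuple[str, str],
    coarse: float = 0.05,
    fine: float = 0.01,
    grid: TimeGrid | None = None,
) -> tuple[tuple[float, float] | None, TherapyOutcome | None]:
    """Coarse grid over [0, 3]^2 then local refinement around the optimum."""
    a, b = clusters
    if a == b:
        raise ValueError("pair must name two distinct clusters")
    ev = _GridEvaluator(model, (a, b), grid)

    def search(da: np.ndarray, db: np.ndarray):
        DA, DB = np.meshgrid(da, db, indexing="ij")
        pts = np.column_stack([DA.ravel(), DB.ravel()])
        areas, viable, _ = ev.evaluate(pts)
        if not np.any(viable):
            return None, None
        masked = np.where(viable, areas, np.inf)
        i = int(np.argmin(masked))
        return pts[i], areas[i]

    hit, _ = search(_delta_grid(coarse), _delta_grid(coarse))
    if hit is None:
        return None, None
    n_fine = int(round(coarse / fine))
    local = [
        np.clip(hit[j] + fine * np.arange(-n_fine, n_fine + 1), 0.0, DELTA_MAX)
        for j in range(2)
    ]
    hit2, _ = search(np.unique(np.round(local[0], 10)), np.unique(np.round(local[1], 10)))
    best = hit2 if hit2 is not None else hit
    pair = (float(best[0]), float(best[1]))
    outcome = evaluate_therapy(model, TherapySpec({a: pair[0], b: pair[1]}), grid)
    return pair, outcome


@dataclass(eq=False)
class SensitivityReport:
    """Gain response probed through a +/-50% neighborhood of the optimum."""

    clusters: tuple[str, ...]
    center: tuple[float, ...]
    grids: tuple[np.ndarray, ...]
    gains: np.ndarray  # (n,) for singles, (n, n) for pairs; NaN where non-viable
    viable: np.ndarray
    robustness: float = field(init=False)

    def __post_init__(self) -> None:
        finite = self.gains[self.viable] if np.any(self.viable) else np.array([])
        if finite.size == 0:
            self.robustness = 0.0
            return
        peak = float(np.max(finite))
        retained = (np.where(self.viable, self.gains, -np.inf) >= 0.5 * peak - 1e-12).mean()
        self.robustness = float(retained)


def sensitivity(
    model: HybridParameters,
    center_spec: TherapySpec,
    n_points: int = 11,
    grid: TimeGrid | None = None,
) -> SensitivityReport:
    """Probe delta values spanning +/-50% of the optimum, clipped to [0, 3]."""
    clusters = center_spec.treated
    if not clusters:
        raise ValueError("sensitivity needs a non-empty therapy")
    center = tuple(center_spec.deltas[c] for c in clusters)
    grids = tuple(
        np.clip(np.linspace(0.5 * d, 1.5 * d, n_points), 0.0, DELTA_MAX) for d in center
    )
    ev = _GridEvaluator(model, clusters, grid)
    if len(clusters) == 1:
        pts = grids[0][:, None]
        shape: tuple[int, ...] = (n_points,)
    else:
        DA, DB = np.meshgrid(grids[0], grids[1], indexing="ij")
        pts = np.column_stack([DA.ravel(), DB.ravel()])
        shape = (n_points, n_points)
    areas, viable, _ = ev.evaluate(pts)
    pre = simulate_hybrid(model, None, grid or TimeGrid())
    a_pre = pre.morphology.final_intimal_area()
    gains = 100.0 * (a_pre - areas) / a_pre
    gains = np.where(viable, gains, np.nan)
    return SensitivityReport(
        clusters=clusters,
        center=center,
        grids=grids,
        gains=gains.reshape(shape),
        viable=viable.reshape(shape),
    )


def screen_all(
    model: HybridParameters,
    single_step: float = 0.01,
    pair_coarse: float = 0.05,
    pair_fine: float = 0.01,
    grid: TimeGrid | None = None,
    with_sensitivity: bool = False,
) -> list[dict]:
    """Rank all 5 single and 10 coupled therapies by gain%."""
    records = []
    for c in CLUSTER_LABELS:
        d, out = optimize_single(model, c, step=single_step, grid=grid)
        rec = {"therapy": c, "deltas": None if d is None else (d,),
               "viable": out.viable if out else False,
               "gain_percent": out.gain_percent if out else None}
        if with_sensitivity and d is not None:
            rec["robustness"] = sensitivity(model, out.spec, grid=grid).robustness
        records.append(rec)
    for a, b in itertools.combinations(CLUSTER_LABELS, 2):
        pair, out = optimize_pair(model, (a, b), coarse=pair_coarse, fine=pair_fine, grid=grid)
        rec = {"therapy": f"{a}+{b}", "deltas": pair,
               "viable": out.viable if out else False,
               "gain_percent": out.gain_percent if out else None}
        if with_sensitivity and pair is not None:
            rec["robustness"] = sensitivity(model, out.spec, grid=grid).robustness
        records.append(rec)
    records.sort(key=lambda r: -1e18 if r["gain_percent"] is None else r["gain_percent"],
                 reverse=True)
    return records
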