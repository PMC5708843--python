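"""Shared domain types and unit conventions.

The package models the first 28 days of vein-graft arterialization. Time is
measured in days everywhere (the 2-hour harvest is 1/12 day); gene-cluster
expression is in relative [mRNA] units; wall cross-sectional areas are in mm^2,
radii in mm, shear stress in Pa, and blood viscosity is configured in cP
(1 cP = 1e-3 Pa s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Gene-cluster labels; they map to indices 0..4 (equations index them 1..5).
CLUSTER_LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E")

#: The three biologic networks a cluster participates in: cell mitosis,
#: cell apoptosis and extracellular-matrix synthesis.
NETWORK_IDS: tuple[str, ...] = ("MIT", "APOP", "ECM")

#: Graft harvest times of the underlying rabbit study, in days:
#: implantation, 2 hours, then 1, 3, 7, 14 and 28 days.
STUDY_TIMES_DAYS: tuple[float, ...] = (0.0, 1.0 / 12.0, 1.0, 3.0, 7.0, 14.0, 28.0)

CP_TO_PA_S = 1e-3

N_CLUSTERS = 5
N_CN_UNKNOWNS = 33  # 25 couplings + 5 asymptotes + 3 modulation coefficients


def cluster_index(label: str) -> int:
    try:
        return CLUSTER_LABELS.index(label)
    except ValueError:
        raise KeyError(f"unknown cluster label {label!r}; expected one of {CLUSTER_LABELS}")


@dataclass(frozen=True, eq=False)
class TimeGrid:
    """Sampling times (days) plus the dense integration output step."""

    times: np.ndarray = field(default_factory=lambda: np.asarray(STUDY_TIMES_DAYS))
    dense_step: float = 1.0 / 24.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("TimeGrid needs at least two sampling times")
        if t[0] != 0.0:
            raise ValueError("first sampling time must be 0")
        if np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ValueError("sampling times must be strictly increasing and non-negative")
        if self.dense_step <= 0:
            raise ValueError("dense_step must be positive")

    @property
    def post_times(self) -> np.ndarray:
        """The M post-implantation harvest times (t > 0) used for fitting."""
        return self.times[self.times > 0]

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def dense_times(self) -> np.ndarray:
        """Dense output grid: regular steps plus the sampling times."""
        n = int(round(self.t_end / self.dense_step))
        regular = np.linspace(0.0, n * self.dense_step, n + 1)
        return np.union1d(np.round(regular, 12), np.round(self.times, 12))


@dataclass(eq=False)
class ClusterExpressionSeries:
    """Mean expression of the five clusters of one biologic network.

    ``values[i, k]`` is the expression of cluster ``CLUSTER_LABELS[i]`` at
    ``grid.times[k]``, in relative [mRNA] units.
    """

    network_id: str
    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        if self.network_id not in NETWORK_IDS:
            raise ValueError(f"network_id must be one of {NETWORK_IDS}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_CLUSTERS, self.grid.times.size):
            raise ValueError(
                f"expected values of shape {(N_CLUSTERS, self.grid.times.size)}, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values must be finite")
        self.values = v

    def cluster(self, label: str) -> np.ndarray:
        return self.values[cluster_index(label)]

    @property
    def post_values(self) -> np.ndarray:
        """Values at the post-implantation harvest times only."""
        return self.values[:, self.grid.times > 0]

    def initial_state(self) -> np.ndarray:
        """Expression at the earliest post-implant sample (2 h), used as G0."""
        return self.values[:, np.argmax(self.grid.times > 0)].copy()


@dataclass(eq=False)
class CellEventSeries:
    """Cellular-event rates at the harvest times.

    Mitosis and apoptosis rates are in relative cells/mm^2/day units, matrix
    deposition in relative mm^2/day units; the model only ever uses them as
    weighted combinations of cluster expression, so the relative scale is what
    matters.
    """

    mitosis: np.ndarray
    apoptosis: np.ndarray
    ecm: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        for name in ("mitosis", "apoptosis", "ecm"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != self.grid.times.shape:
                raise ValueError(f"{name} must have one value per sampling time")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} rates must be finite")
            setattr(self, name, v)

    def rate(self, network_id: str) -> np.ndarray:
        return {"MIT": self.mitosis, "APOP": self.apoptosis, "ECM": self.ecm}[network_id]


@dataclass(eq=False)
class CNParameters:
    """The 33 unknowns of one cluster network.

    ``A[j, k]`` is the impact of cluster j on cluster k (row -> column), ``B``
    the per-cluster asymptote levels and ``C = (C1, C2, C3)`` the cubic
    time-modulation coefficients (units day^-3, day^-2, day^-1).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        C = np.asarray(self.C, dtype=float)
        if A.shape != (N_CLUSTERS, N_CLUSTERS) or B.shape != (N_CLUSTERS,) or C.shape != (3,):
            raise ValueError("CNParameters needs A (5,5), B (5,), C (3,)")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B)) and np.all(np.isfinite(C))):
            raise ValueError("CNParameters entries must be finite")
        self.A, self.B, self.C = A, B, C

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.A.ravel(), self.B, self.C])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "CNParameters":
        x = np.asarray(x, dtype=float)
        if x.shape != (N_CN_UNKNOWNS,):
            raise ValueError(f"expected {N_CN_UNKNOWNS} entries, got {x.shape}")
        return cls(A=x[:25].reshape(5, 5), B=x[25:30], C=x[30:33])


def validate_weights(w, network_id: str = "MIT") -> "WeightVector":
    """Project a raw 5-vector onto the weight constraint set.

    Entries are clipped into [-1, 1] and then rescaled so the absolute values
    sum to one. Raises ``ValueError`` for a wrong length, non-finite entries or
    an all-zero vector (the normalization is undefined there).
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (N_CLUSTERS,):
        raise ValueError(f"expected a 5-vector of weights, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    w = np.clip(w, -1.0, 1.0)
    total = np.sum(np.abs(w))
    if total == 0.0:
        raise ValueError("cannot normalize an all-zero weight vector")
    return WeightVector(network_id=network_id, w=w / total)


@dataclass(eq=False)
class WeightVector:
    """Signed relative impact of each cluster on one biologic event."""

    network_id: str
    w: np.ndarray

    def __post_init__(self) -> None:
        if self.network_id not in NETWORK_IDS:
            raise ValueError(f"network_id must be one of {NETWORK_IDS}")
        w = np.asarray(self.w, dtype=float)
        if w.shape != (N_CLUSTERS,):
            raise ValueError("weight vector must have 5 entries")
        if np.any(np.abs(w) > 1.0 + 1e-12):
            raise ValueError("each weight must lie in [-1, 1]")
        if abs(np.sum(np.abs(w)) - 1.0) > 1e-9:
            raise ValueError("absolute weights must sum to 1 (within 1e-9)")
        self.w = w


@dataclass(eq=False)
class ScalingFactors:
    """Per-cluster factors converting [mRNA] to wall-growth-rate units (Pa^-1 day^-1)."""

    beta_mit: np.ndarray
    beta_apop: np.ndarray
    beta_ecm: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beta_mit", "beta_apop", "beta_ecm"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_CLUSTERS,):
                raise ValueError(f"{name} must have 5 entries")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, v)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.beta_mit, self.beta_apop, self.beta_ecm])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "ScalingFactors":
        x = np.asarray(x, dtype=float)
        if x.shape != (15,):
            raise ValueError("expected 15 scaling factors")
        return cls(beta_mit=x[:5], beta_apop=x[5:10], beta_ecm=x[10:15])


@dataclass(frozen=True)
class VesselState:
    """Initial wall composition and hemodynamic configuration of one graft.

    The graft is a straight cylinder with lumen radius ``r1`` (= ``r1_baseline``
    at implantation). Poiseuille flow with centerline velocity ``flow_factor*u``
    gives the wall shear ``tau = 2*mu*flow_factor*u / r1``; ``flow_factor`` is
    1.0 for the high-flow graft and 0.1 for the ligated (low-flow) one. The
    baseline (arterial) shear ``tau0`` defaults to the full-flow value.
    """

    a_smc: float = 0.013  # mm^2, cellular component of the initial intima
    a_ecm: float = 0.007  # mm^2, matrix component of the initial intima
    r1_baseline: float = 1.0  # mm
    u: float = 1.0  # m/s centerline velocity at full flow
    mu: float = 3.2  # cP
    flow_factor: float = 0.1
    tau0: float | None = None  # Pa; default: arterial shear at baseline geometry

    def __post_init__(self) -> None:
        if self.a_smc < 0 or self.a_ecm < 0:
            raise ValueError("wall areas must be non-negative")
        if self.r1_baseline <= 0:
            raise ValueError("baseline radius must be positive")
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")
        if self.tau0 is None:
            # mu[cP]*1e-3 [Pa s] * 2*U[m/s] / (R1[mm]*1e-3 [m]) == 2*mu*U/R1
            object.__setattr__(self, "tau0", 2.0 * self.mu * self.u / self.r1_baseline)

    @property
    def r1(self) -> float:
        """Lumen radius at implantation (mm)."""
        return self.r1_baseline

    @property
    def intimal_area(self) -> float:
        return self.a_smc + self.a_ecm

    def with_flow(self, flow_factor: float) -> "VesselState":
        return replace(self, flow_factor=flow_factor)


DELTA_MAX = 3.0  # enforced cap on over-expression (3-fold above baseline)


@dataclass(frozen=True)
class TherapySpec:
    """Constant cluster modulation: each treated cluster starts at
    ``delta * G(0)`` and is held there for the whole follow-up.

    ``delta < 1`` is inhibition, ``delta = 1`` freezes the baseline level,
    ``delta > 1`` (up to 3) is over-expression. At most two clusters may be
    treated (single or coupled therapy).
    """

    deltas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = dict(self.deltas)
        if len(d) > 2:
            raise ValueError("at most two clusters may be treated simultaneously")
        for label, delta in d.items():
            cluster_index(label)
            if not (0.0 <= delta <= DELTA_MAX):
                raise ValueError(f"delta for cluster {label} must lie in [0, {DELTA_MAX}]")
        object.__setattr__(self, "deltas", d)

    @property
    def treated(self) -> tuple[str, ...]:
        return tuple(sorted(self.deltas))

    def __bool__(self) -> bool:
        return bool(self.deltas)


@dataclass
class GAConfig:
    """Genetic-algorithm settings shared by all calibration stages.

    The population is ``pop_multiplier`` times the number of unknowns; after
    the first run the algorithm restarts ``n_restarts`` times with bounds
    shrunk to ``restart_shrink`` of the original range around the incumbent
    best. ``tolerance`` is the knockdown-stability threshold (Tol) applied to
    the sum-of-squares misfit of the four free clusters. ``n_runs`` independent
    seeded runs are performed and the best kept.
    """

    pop_multiplier: float = 100.0
    generations: int = 100
    n_restarts: int = 2
    restart_shrink: float = 0.1
    tolerance: float = 10.0
    seed: int | None = None
    n_runs: int = 3
    # generic real-coded GA operators
    crossover_rate: float = 0.9
    blend_alpha: float = 0.3
    mutation_rate: float = 0.15
    mutation_sigma: float = 0.08
    tournament_size: int = 3
    elite: int = 2

    def __post_init__(self) -> None:
        if self.pop_multiplier < 1:
            raise ValueError("pop_multiplier must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.generations < 1 or self.n_restarts < 0 or self.n_runs < 1:
            raise ValueError("invalid GA budget")
        if not (0 < self.restart_shrink <= 1):
            raise ValueError("restart_shrink must lie in (0, 1]")
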