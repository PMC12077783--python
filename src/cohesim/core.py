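"""Domain types and the simulation loop.

The cluster is a 1D chain of N equal spheres (radius ``r = 1``, mass
``m = 1``) on the gradient axis, initialized just touching.  Neighboring
agents are coupled by viscoelastic bonds (:mod:`cohesim.rheology`) whose
tensile stiffness increases linearly from the trailing bond (``K_min``) to the
leading bond (``K_max = gradient_strength * K_min``) -- the internal cohesion
gradient.  Each timestep (``dt = 1``) advances the passive dynamics with one
classical RK4 step of the coupled system and then applies environmental
damping, multiplying every velocity (and, for SLS, every bond acceleration
memory) by the retention factor ``eta_env``.  ``eta_env = 0`` is the
overdamped Stokes limit used for Kelvin-Voigt runs; SLS runs retain 75% of the
velocity per step.  Every ``period``-th step a protrusion event
(:mod:`cohesim.protrusion`) instantaneously displaces the selected agents
before that step's relaxation.

All internal forces come in equal and opposite pairs, so relaxation never
moves the center of mass: net cluster motion can only be produced by the
protrusion events themselves.

Ensembles of replicates are integrated as a single vectorized system (one
row per replicate); replicate ``i`` uses an independent PCG64 generator seeded
``seed + i``, and a single run is exactly row 0 of the corresponding ensemble,
so trajectories are bit-reproducible either way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import protrusion as prot
from .rheology import KV, SLS, BondParams, RheologyParams

__all__ = [
    "AgentState",
    "ClusterConfig",
    "SimulationConfig",
    "Trajectory",
    "Ensemble",
    "SimulationError",
    "initialize_cluster",
    "bond_stiffnesses",
    "step",
    "run_simulation",
    "simulate_ensemble",
]

_EVENT_COLUMNS = ["replicate", "timestep", "agent_index", "proposal", "accepted"]


class SimulationError(RuntimeError):
    """Numerical blow-up (non-finite state), reported with the offending step."""


@dataclass
class AgentState:
    """One cell on the gradient axis.

    ``index`` is 1-based: 1 is the trailing agent, N the leading agent
    (the gradient increases toward larger ``x``).  Positions are in cell
    radii; velocities in radii per timestep.
    """

    index: int
    x: float
    v: float = 0.0
    a: float = 0.0
    r: float = 1.0
    m: float = 1.0


@dataclass(frozen=True)
class ClusterConfig:
    """Geometry and stiffness layout of the cluster.

    Parameters
    ----------
    N:
        Number of agents (>= 2).
    gradient_strength:
        Ratio of the strongest to the weakest tensile stiffness (>= 1).
    K_min:
        Tensile stiffness of the trailing bond; the leading bond has
        ``K_max = gradient_strength * K_min``.
    Kr:
        Compressive (repulsive) stiffness, constant across the cluster.
    zone_max:
        Neighbor-detection distance: a bond whose gap exceeds this exerts no
        force.
    stiffness_assignment:
        ``"bond"`` (default): the N-1 bond stiffnesses are linearly spaced
        ``K_min..K_max``.  ``"agent"``: stiffness is assigned per agent
        (linearly spaced over the N agents) and each bond takes its leading
        member's value.
    r:
        Agent radius (1 by convention; all reported lengths are in radii).
    """

    N: int = 5
    gradient_strength: float = 10.0
    K_min: float = 0.0022
    Kr: float = 1.0
    zone_max: float = 4.0
    stiffness_assignment: str = "bond"
    r: float = 1.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("a cluster needs N >= 2 agents")
        if self.gradient_strength < 1:
            raise ValueError("gradient_strength must be >= 1")
        if self.K_min <= 0 or self.Kr <= 0:
            raise ValueError("stiffnesses must be > 0")
        if self.zone_max <= 2 * self.r:
            raise ValueError("zone_max must exceed one diameter")
        if self.stiffness_assignment not in ("bond", "agent"):
            raise ValueError("stiffness_assignment must be 'bond' or 'agent'")

    @property
    def K_max(self) -> float:
        return self.gradient_strength * self.K_min


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one run.

    ``eta_env`` is the fraction of velocity *retained* per timestep (0 =
    velocities zeroed every step, the purely viscous limit; 1 = no
    environmental damping).  ``None`` selects the model default: 0.0 for KV,
    0.75 for SLS.
    """

    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    rheology: RheologyParams = field(default_factory=RheologyParams)
    protrusion: prot.ProtrusionConfig = field(default_factory=prot.ProtrusionConfig)
    eta_env: Optional[float] = None
    n_steps: int = 2000
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta_env is not None and not 0.0 <= self.eta_env <= 1.0:
            raise ValueError("eta_env must lie in [0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def damping_retention(self) -> float:
        """Resolved eta_env (model default when unset)."""
        if self.eta_env is not None:
            return self.eta_env
        return 0.0 if self.rheology.model == KV else 0.75


def bond_stiffnesses(config: ClusterConfig) -> np.ndarray:
    """Tensile stiffness of each of the N-1 bonds, trailing to leading."""
    if config.stiffness_assignment == "agent":
        per_agent = np.linspace(config.K_min, config.K_max, config.N)
        return per_agent[1:].copy()
    return np.linspace(config.K_min, config.K_max, config.N - 1)


def initial_positions(config: ClusterConfig) -> np.ndarray:
    """Just-touching lattice: agent i at ``x = 2r*(i-1)``."""
    return 2.0 * config.r * np.arange(config.N, dtype=float)


def initialize_cluster(config: ClusterConfig, rheology: RheologyParams | None = None):
    """Build the initial agents and bonds.

    Returns ``(agents, bonds)``: N :class:`AgentState` at rest on the
    just-touching lattice and N-1 :class:`BondParams` with tensile stiffness
    linearly spaced from ``K_min`` to ``K_max``.
    """
    rheology = rheology or RheologyParams()
    xs = initial_positions(config)
    agents = [AgentState(index=i + 1, x=float(x), r=config.r) for i, x in enumerate(xs)]
    bonds = [
        BondParams(Ka=float(k), Kr=config.Kr, rheology=rheology)
        for k in bond_stiffnesses(config)
    ]
    return agents, bonds


# ---------------------------------------------------------------------------
# vectorized force kernels (one row per replicate)
# ---------------------------------------------------------------------------


def _kv_accel(x, v, Ka, Kr, eta_i, zone_max, diam):
    g = x[:, 1:] - x[:, :-1] - diam
    gr = v[:, 1:] - v[:, :-1]
    s = np.where(g > 0, Ka, Kr) * g + eta_i * gr
    s = np.where(g > zone_max, 0.0, s)
    a = np.zeros_like(x)
    a[:, :-1] += s
    a[:, 1:] -= s
    return a


def _sls_deriv(x, v, A, Ka, Kr, K2, tau, zone_max, diam):
    """Time derivatives (dx, dv, dA) of the SLS chain.

    ``A`` is the per-bond acceleration memory (stress = -A); each attached
    bond applies its full stress, signed, to both members (the per-agent
    force is the sum of its rearward and forward bond terms), so the tau -> 0
    limit of a bond reproduces the KV dynamics at the same moduli.
    """
    g = x[:, 1:] - x[:, :-1] - diam
    gr = v[:, 1:] - v[:, :-1]
    attached = g <= zone_max
    K1 = np.where(g > 0, Ka, Kr)
    jerk = np.where(
        attached,
        -(K1 / tau) * g - (K1 + K2) * gr - A / tau,
        -A / tau,
    )
    s = np.where(attached, -A, 0.0)
    a = np.zeros_like(x)
    a[:, :-1] += s
    a[:, 1:] -= s
    return v, a, jerk


def _rk4_kv(x, v, dt, Ka, Kr, eta_i, zone_max, diam):
    a1 = _kv_accel(x, v, Ka, Kr, eta_i, zone_max, diam)
    x2 = x + 0.5 * dt * v
    v2 = v + 0.5 * dt * a1
    a2 = _kv_accel(x2, v2, Ka, Kr, eta_i, zone_max, diam)
    x3 = x + 0.5 * dt * v2
    v3 = v + 0.5 * dt * a2
    a3 = _kv_accel(x3, v3, Ka, Kr, eta_i, zone_max, diam)
    x4 = x + dt * v3
    v4 = v + dt * a3
    a4 = _kv_accel(x4, v4, Ka, Kr, eta_i, zone_max, diam)
    xn = x + dt * (v + 2.0 * v2 + 2.0 * v3 + v4) / 6.0
    vn = v + dt * (a1 + 2.0 * a2 + 2.0 * a3 + a4) / 6.0
    return xn, vn


def _rk4_sls(x, v, A, dt, Ka, Kr, K2, tau, zone_max, diam):
    dx1, dv1, dA1 = _sls_deriv(x, v, A, Ka, Kr, K2, tau, zone_max, diam)
    dx2, dv2, dA2 = _sls_deriv(
        x + 0.5 * dt * dx1, v + 0.5 * dt * dv1, A + 0.5 * dt * dA1,
        Ka, Kr, K2, tau, zone_max, diam,
    )
    dx3, dv3, dA3 = _sls_deriv(
        x + 0.5 * dt * dx2, v + 0.5 * dt * dv2, A + 0.5 * dt * dA2,
        Ka, Kr, K2, tau, zone_max, diam,
    )
    dx4, dv4, dA4 = _sls_deriv(
        x + dt * dx3, v + dt * dv3, A + dt * dA3,
        Ka, Kr, K2, tau, zone_max, diam,
    )
    xn = x + dt * (dx1 + 2.0 * dx2 + 2.0 * dx3 + dx4) / 6.0
    vn = v + dt * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4) / 6.0
    An = A + dt * (dA1 + 2.0 * dA2 + 2.0 * dA3 + dA4) / 6.0
    return xn, vn, An


class _Engine:
    """Vectorized integrator state for an ensemble of replicates."""

    def __init__(self, config: SimulationConfig, n_replicates: int):
        cl = config.cluster
        self.config = config
        self.diam = 2.0 * cl.r
        self.Ka = bond_stiffnesses(cl)[None, :]
        self.Kr = cl.Kr
        self.zone_max = cl.zone_max
        self.eta_env = config.damping_retention
        self.dt = config.dt
        self.model = config.rheology.model
        self.eta_i = config.rheology.eta_i
        self.K2 = config.rheology.K2
        self.tau = config.rheology.tau
        self.x = np.tile(initial_positions(cl), (n_replicates, 1))
        self.v = np.zeros_like(self.x)
        self.A = np.zeros((n_replicates, cl.N - 1))  # SLS bond accel memory

    def relax(self, step_index: int) -> None:
        # overflow of a diverging trajectory is reported via the finiteness
        # check below, not as a numpy warning
        with np.errstate(over="ignore", invalid="ignore"):
            if self.model == KV:
                self.x, self.v = _rk4_kv(
                    self.x, self.v, self.dt, self.Ka, self.Kr,
                    self.eta_i, self.zone_max, self.diam,
                )
            else:
                self.x, self.v, self.A = _rk4_sls(
                    self.x, self.v, self.A, self.dt, self.Ka, self.Kr,
                    self.K2, self.tau, self.zone_max, self.diam,
                )
                self.A *= self.eta_env
            self.v *= self.eta_env
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.v))):
            raise SimulationError(
                f"non-finite position/velocity at timestep {step_index}"
            )

    def jump(self, rep: int, agent: int, displacement: float) -> None:
        """Instantaneously displace one agent (0-based index) in one replicate.

        The jump is kinematic: the agent's velocity is reset.  For SLS the
        adjacent bonds receive the unrelaxed elastic stress increment
        ``(K1 + K2) * dgap`` of a sudden strain step.
        """
        x = self.x[rep]
        old = x[agent]
        x[agent] = old + displacement
        self.v[rep, agent] = 0.0
        if self.model == SLS:
            for b, sign in ((agent - 1, +1.0), (agent, -1.0)):
                if 0 <= b < x.shape[0] - 1:
                    g_new = x[b + 1] - x[b] - self.diam
                    if g_new > self.zone_max:
                        self.A[rep, b] = 0.0
                        continue
                    g_old = g_new - sign * displacement
                    if g_old > self.zone_max:
                        # reattachment: fresh bond, no stored stress
                        self.A[rep, b] = 0.0
                        continue
                    K1 = self.Ka[0, b] if g_new > 0 else self.Kr
                    self.A[rep, b] -= (K1 + self.K2) * sign * displacement


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Positions of every agent at every recorded timestep for one run."""

    positions: np.ndarray  # (n_steps + 1, N)
    events: pd.DataFrame
    config: SimulationConfig
    seed: int

    @property
    def com(self) -> np.ndarray:
        """Center of mass (equal masses: arithmetic mean) at each timestep."""
        return self.positions.mean(axis=1)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.positions.shape[0], dtype=float) * self.config.dt

    def positions_frame(self) -> pd.DataFrame:
        n_t, n_a = self.positions.shape
        return pd.DataFrame(
            {
                "timestep": np.repeat(np.arange(n_t), n_a),
                "agent_index": np.tile(np.arange(1, n_a + 1), n_t),
                "x": self.positions.ravel(),
            }
        )

    def validate(self, tol: float = 1e-9) -> None:
        """Assert the non-overlap invariant at every recorded step."""
        gaps = np.diff(self.positions, axis=1) - 2.0 * self.config.cluster.r
        if gaps.min(initial=0.0) < -tol:
            t, b = np.unravel_index(np.argmin(gaps), gaps.shape)
            raise AssertionError(
                f"overlap at timestep {t}, bond {b + 1}: gap {gaps[t, b]:.3e}"
            )


@dataclass
class Ensemble:
    """A set of seeded replicates of one configuration."""

    positions: np.ndarray  # (n_replicates, n_steps + 1, N)
    events: pd.DataFrame
    config: SimulationConfig
    seeds: list[int]

    @property
    def n_replicates(self) -> int:
        return self.positions.shape[0]

    @property
    def com(self) -> np.ndarray:
        """(n_replicates, n_steps + 1) center-of-mass series."""
        return self.positions.mean(axis=2)

    def replicate(self, i: int) -> Trajectory:
        ev = self.events[self.events["replicate"] == i].drop(columns="replicate")
        cfg = replace(self.config, seed=self.seeds[i])
        return Trajectory(
            positions=self.positions[i].copy(),
            events=ev.reset_index(drop=True),
            config=cfg,
            seed=self.seeds[i],
        )


# ---------------------------------------------------------------------------
# the loop: relax -> protrude -> relax
# ---------------------------------------------------------------------------


def step(engine: _Engine, step_index: int, phase: str = "relax", rngs=None,
         events=None) -> None:
    """Advance the engine by one dt.

    A ``protrude`` phase first applies the configured displacement events,
    then runs the same relaxation dynamics as a plain ``relax`` step.
    """
    if phase == "protrude":
        _apply_events(engine, step_index, rngs, events)
    engine.relax(step_index)


def _apply_events(engine: _Engine, step_index: int, rngs, events: list) -> None:
    cfg = engine.config
    pc = cfg.protrusion
    # A protrusion event kinematically repositions the overdamped cluster:
    # all velocities reset, so total momentum stays exactly zero and the COM
    # can move only through the accepted displacements themselves.
    engine.v.fill(0.0)
    n = cfg.cluster.N
    r = cfg.cluster.r
    n_rep = engine.x.shape[0]
    if pc.mode == "deterministic":
        event_index = step_index // pc.period - 1
        for rep in range(n_rep):
            moves = prot.deterministic_displacements(
                pc.deterministic_submode, pc.deterministic_amplitude, event_index, n
            )
            for idx in sorted(moves):
                accepted = _try_jump(engine, rep, idx - 1, moves[idx], r)
                events.append((rep, step_index, idx, moves[idx], accepted))
    else:
        protruders = prot.select_protruders(pc.mode, n, pc.amplitude, pc.interior_scale)
        for rep in range(n_rep):
            rng = rngs[rep]
            for idx, sigma in protruders:
                d = prot.propose_stochastic(rng, sigma)
                accepted = _try_jump(engine, rep, idx - 1, d, r)
                events.append((rep, step_index, idx, d, accepted))


def _try_jump(engine: _Engine, rep: int, i: int, d: float, r: float) -> bool:
    x = engine.x[rep]
    left = x[i - 1] if i > 0 else None
    right = x[i + 1] if i < x.shape[0] - 1 else None
    accepted, _ = prot.validate_and_apply(x[i], left, right, d, r=r)
    if accepted:
        engine.jump(rep, i, d)
    return accepted


def simulate_ensemble(config: SimulationConfig, n_replicates: int = 1) -> Ensemble:
    """Run ``n_replicates`` seeded replicates of one configuration.

    Replicate ``i`` draws its protrusions from an independent generator
    seeded ``config.seed + i``.  Identical config and seed give bit-identical
    trajectories.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    pc = config.protrusion
    if pc.period >= config.n_steps:
        warnings.warn(
            f"protrusion period {pc.period} >= n_steps {config.n_steps}: "
            "no protrusion events will occur",
            stacklevel=2,
        )
    seeds = [config.seed + i for i in range(n_replicates)]
    rngs = [np.random.default_rng(s) for s in seeds]
    engine = _Engine(config, n_replicates)
    positions = np.empty((n_replicates, config.n_steps + 1, config.cluster.N))
    positions[:, 0] = engine.x
    events: list = []
    for k in range(1, config.n_steps + 1):
        phase = "protrude" if k % pc.period == 0 else "relax"
        step(engine, k, phase, rngs=rngs, events=events)
        positions[:, k] = engine.x
    events_df = pd.DataFrame(events, columns=_EVENT_COLUMNS)
    return Ensemble(positions=positions, events=events_df, config=config, seeds=seeds)


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run one simulation and return its trajectory."""
    return simulate_ensemble(config, n_replicates=1).replicate(0)
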