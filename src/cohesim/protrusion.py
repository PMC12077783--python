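"""Protrusion protocols: the active displacements that drive the cluster.

Every ``period`` timesteps the selected agents attempt an instantaneous
displacement ("protrusion"), after which the passive spring-damper dynamics
relax the cluster until the next event.  Stochastic protrusions are drawn from
a zero-mean Gaussian whose standard deviation (the protrusion amplitude) sets
the characteristic step length; the sign of the draw is the direction along
the gradient axis.  A proposal that would bring the agent within one diameter
of a neighbor is rejected outright -- the agent does not move at all -- which
is what truncates the effective inward step distribution of a crowded agent
and, combined with the cohesion gradient, rectifies the noise into directed
cluster motion.

Deterministic protocols displace the two outermost agents by a fixed length in
prescribed patterns; they serve as control experiments in which the center of
mass provably stays put.  Overlap-producing deterministic displacements are
rejected by the same rule as stochastic ones, which keeps the rejection
pattern symmetric between the two ends in steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STOCHASTIC_MODES",
    "DETERMINISTIC_SUBMODES",
    "ProtrusionConfig",
    "propose_stochastic",
    "select_protruders",
    "validate_and_apply",
    "deterministic_displacements",
    "apply_deterministic",
]

STOCHASTIC_MODES = ("ends_only", "all_cells", "hybrid")
DETERMINISTIC_SUBMODES = ("outward_step", "inphase_oscillation", "antiphase_oscillation")

#: accept proposals that land exactly at the just-touching position
_TOUCH_TOL = 1e-12


@dataclass(frozen=True)
class ProtrusionConfig:
    """Parameters of the protrusion protocol.

    amplitude:
        Gaussian standard deviation sigma of proposed displacements (radii).
    period:
        Timesteps between protrusion events; intervening steps are pure
        relaxation.
    mode:
        ``ends_only`` (only the outermost agents protrude), ``all_cells``,
        ``hybrid`` (ends at full sigma, interior at ``interior_scale*sigma``)
        or ``deterministic``.
    interior_scale:
        Multiplier on sigma for interior agents in hybrid mode (default 0.25,
        i.e. interior wandering suppressed by 75%).
    deterministic_submode, deterministic_amplitude:
        Pattern and fixed step length for the deterministic protocols.
    """

    amplitude: float = 0.5
    period: int = 15
    mode: str = "ends_only"
    interior_scale: float = 0.25
    deterministic_submode: str = "outward_step"
    deterministic_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in STOCHASTIC_MODES + ("deterministic",):
            raise ValueError(f"unknown protrusion mode {self.mode!r}")
        if self.mode != "deterministic" and self.amplitude <= 0:
            raise ValueError("stochastic modes require amplitude > 0")
        if self.period < 1:
            raise ValueError("period must be >= 1")
        if not 0.0 <= self.interior_scale <= 1.0:
            raise ValueError("interior_scale must lie in [0, 1]")
        if self.deterministic_submode not in DETERMINISTIC_SUBMODES:
            raise ValueError(
                f"unknown deterministic submode {self.deterministic_submode!r}"
            )


def propose_stochastic(rng: np.random.Generator, sigma: float) -> float:
    """Draw one signed displacement from N(0, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return float(rng.normal(0.0, sigma))


def select_protruders(mode, n_agents, sigma, interior_scale=0.25):
    """Which agents protrude, and with what amplitude.

    Returns a list of ``(index, sigma)`` pairs with 1-based indices in
    trailing-to-leading order (the order in which simultaneous proposals are
    validated).
    """
    if mode == "ends_only":
        return [(1, sigma), (n_agents, sigma)]
    if mode == "all_cells":
        return [(i, sigma) for i in range(1, n_agents + 1)]
    if mode == "hybrid":
        out = [(1, sigma)]
        out.extend((i, interior_scale * sigma) for i in range(2, n_agents))
        out.append((n_agents, sigma))
        return out
    raise ValueError(f"unknown stochastic mode {mode!r}")


def validate_and_apply(position, left_neighbor, right_neighbor, proposal, r=1.0):
    """Apply a proposed displacement if it keeps the agent clear of neighbors.

    Parameters
    ----------
    position:
        Current position of the protruding agent.
    left_neighbor, right_neighbor:
        Positions of the adjacent agents (``None`` for the free side of an
        outermost agent).
    proposal:
        Signed displacement.
    r:
        Agent radius; centers may not come closer than ``2r``.

    Returns ``(accepted, new_position)``; on rejection the position is
    unchanged.  A proposal that lands the pair exactly just-touching is
    accepted (tie goes to accept).
    """
    new = position + proposal
    if left_neighbor is not None and new - left_neighbor < 2.0 * r - _TOUCH_TOL:
        return False, position
    if right_neighbor is not None and right_neighbor - new < 2.0 * r - _TOUCH_TOL:
        return False, position
    return True, new


def deterministic_displacements(submode, amplitude, event_index, n_agents):
    """Proposed displacements of the two end agents for one deterministic event.

    Returns ``{agent_index: displacement}`` (1-based).  ``outward_step`` moves
    both ends away from the center every event; ``inphase_oscillation`` moves
    both ends in the same axial direction, alternating sign between events;
    ``antiphase_oscillation`` alternates between both ends moving outward and
    both moving inward.
    """
    a = float(amplitude)
    if submode == "outward_step":
        return {1: -a, n_agents: +a}
    if submode == "inphase_oscillation":
        s = a if event_index % 2 == 0 else -a
        return {1: s, n_agents: s}
    if submode == "antiphase_oscillation":
        if event_index % 2 == 0:
            return {1: -a, n_agents: +a}
        return {1: +a, n_agents: -a}
    raise ValueError(f"unknown deterministic submode {submode!r}")


def apply_deterministic(positions, submode, amplitude, event_index, r=1.0):
    """Apply one deterministic event to an array of agent positions.

    Proposals are validated trailing-to-leading against already-updated
    positions with the same non-overlap rejection rule as stochastic
    protrusions.  Returns ``(new_positions, events)`` where ``events`` is a
    list of ``(agent_index, proposal, accepted)``.
    """
    x = np.array(positions, dtype=float)
    n = x.shape[0]
    moves = deterministic_displacements(submode, amplitude, event_index, n)
    events = []
    for idx in sorted(moves):
        i = idx - 1
        left = x[i - 1] if i > 0 else None
        right = x[i + 1] if i < n - 1 else None
        accepted, new = validate_and_apply(x[i], left, right, moves[idx], r=r)
        if accepted:
            x[i] = new
        events.append((idx, moves[idx], accepted))
    return x, events
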