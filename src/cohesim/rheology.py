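"""Viscoelastic constitutive laws for intercellular bonds.

Neighboring cells in the cluster are coupled by damped springs in one of two
standard rheological configurations:

* Kelvin-Voigt (KV): a spring and a dashpot in parallel,
  ``sigma = K*eps + eta_i*deps/dt``.  The element responds elastically with no
  creep; all stress vanishes instantaneously when the strain does.
* Standard Linear Solid (SLS): KV extended with a second spring (modulus
  ``K2``) in series with the dashpot.  In Maxwell form,
  ``sigma + tau*dsigma/dt = K1*eps + tau*(K1 + K2)*deps/dt`` with relaxation
  time ``tau = eta/K2``.  A step strain produces an unrelaxed stress
  ``(K1 + K2)*eps`` that decays to the equilibrium plateau ``K1*eps``.

Strain is measured per bond as the surface-to-surface gap
``g = x_lead - x_trail - 2r``: the just-touching configuration (``g = 0``) is
the zero-stress rest state.  The elastic modulus switches with the sign of the
gap -- the tensile (cohesive) stiffness ``Ka`` acts only under separation
(``g > 0``), the compressive stiffness ``Kr`` only under overlap (``g < 0``) --
and a bond whose gap exceeds the detection distance ``zone_max`` is detached
and exerts no force.

Sign convention: a positive bond stress is a tension that pulls the pair back
together (force ``+stress`` on the trailing member, ``-stress`` on the leading
member; in the SLS bond-acceleration form the stress is carried by the
integrated state, ``stress = -gap_accel``).  All functions are pure and
accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KV",
    "SLS",
    "RheologyParams",
    "BondParams",
    "BondState",
    "active_stiffness",
    "kv_stress",
    "kv_acceleration",
    "sls_jerk",
    "sls_stress",
]

KV = "kv"
SLS = "sls"


@dataclass(frozen=True)
class RheologyParams:
    """Constitutive parameters shared by every bond in a cluster.

    Parameters
    ----------
    model:
        ``"kv"`` or ``"sls"``.
    eta_i:
        Intracellular (bond) viscosity: stress per unit strain rate between
        neighboring cells.  Used directly by the KV element; for SLS the
        viscosity enters only through ``tau = eta_i / K2``.
    K2:
        SLS series spring modulus (ignored by KV).
    tau:
        SLS stress-relaxation time (ignored by KV).
    """

    model: str = KV
    eta_i: float = 0.1
    K2: float = 0.01
    tau: float = 10.0

    def __post_init__(self) -> None:
        if self.model not in (KV, SLS):
            raise ValueError(f"unknown rheology model {self.model!r}")
        if self.eta_i < 0:
            raise ValueError("eta_i must be >= 0")
        if self.model == SLS:
            if self.K2 <= 0:
                raise ValueError("SLS requires K2 > 0")
            if self.tau <= 0:
                raise ValueError("SLS requires tau > 0")


@dataclass(frozen=True)
class BondParams:
    """Stiffness of one bond: its position on the cohesion gradient (``Ka``),
    the cluster-wide compressive stiffness ``Kr``, and the shared rheology."""

    Ka: float
    Kr: float
    rheology: RheologyParams = field(default_factory=RheologyParams)

    def __post_init__(self) -> None:
        if self.Ka <= 0 or self.Kr <= 0:
            raise ValueError("bond stiffnesses Ka and Kr must be > 0")


@dataclass
class BondState:
    """Kinematic state of one bond.

    ``gap`` is the strain proxy, ``gap_rate`` its time derivative, and
    ``gap_accel`` the second derivative, which for SLS is an independent
    dynamical variable carrying the stress memory (``stress = -gap_accel``).
    """

    gap: float
    gap_rate: float = 0.0
    gap_accel: float = 0.0


def active_stiffness(gap, Ka, Kr):
    """Select the modulus acting at the current strain.

    Exactly one of the tensile/compressive moduli is active at any instant:
    ``Ka`` under separation (``gap > 0``), ``Kr`` under compression.  At the
    rest point ``gap == 0`` the choice is immaterial (zero elastic stress);
    ``Kr`` is returned for definiteness.
    """
    return np.where(np.asarray(gap) > 0, Ka, Kr)


def kv_stress(gap, gap_rate, Ka, Kr, eta_i, zone_max):
    """Kelvin-Voigt bond stress (tension positive).

    ``stress = K_active * gap + eta_i * gap_rate`` for attached bonds; zero
    for detached bonds (``gap > zone_max``).
    """
    gap = np.asarray(gap, dtype=float)
    s = active_stiffness(gap, Ka, Kr) * gap + eta_i * np.asarray(gap_rate, dtype=float)
    return np.where(gap > zone_max, 0.0, s)


def kv_acceleration(bond_states, bond_params, zone_max):
    """Net KV acceleration on one agent from its (up to two) bonds.

    Parameters
    ----------
    bond_states, bond_params:
        Two-element sequences ``[left, right]`` giving the agent's rearward
        and forward bonds; either entry may be ``None`` for an outermost
        agent.  ``left`` is the bond in which this agent is the leading
        member, ``right`` the one in which it trails.
    zone_max:
        Detachment gap; bonds stretched beyond it exert no force.

    Unit mass is assumed, so force and acceleration coincide.  The signs are
    arranged so the two members of a bond receive equal and opposite forces:
    the trailing member feels ``+stress``, the leading member ``-stress``.
    """
    accel = 0.0
    left_state, right_state = bond_states
    left_params, right_params = bond_params
    if left_state is not None:
        s = kv_stress(
            left_state.gap,
            left_state.gap_rate,
            left_params.Ka,
            left_params.Kr,
            left_params.rheology.eta_i,
            zone_max,
        )
        accel -= float(s)
    if right_state is not None:
        s = kv_stress(
            right_state.gap,
            right_state.gap_rate,
            right_params.Ka,
            right_params.Kr,
            right_params.rheology.eta_i,
            zone_max,
        )
        accel += float(s)
    return accel


def sls_jerk(state: BondState, params: BondParams):
    """Third time derivative of the SLS bond displacement.

    ``d(gap_accel)/dt = -(K1/tau)*gap - (K1 + K2)*gap_rate - gap_accel/tau``
    with ``K1`` the gap-sign-selected modulus.  With the stress read-out
    ``sigma = -gap_accel`` this is exactly the Maxwell form
    ``dsigma/dt = (K1*gap - sigma)/tau + (K1 + K2)*gap_rate``, so a bond held
    at fixed strain ``g0`` relaxes as ``sigma(t) = g0*(K1 + K2*exp(-t/tau))``
    and the rest state is attracting.
    """
    rh = params.rheology
    if rh.tau <= 0:
        raise ValueError("SLS requires tau > 0")
    K1 = active_stiffness(state.gap, params.Ka, params.Kr)
    return (
        -(K1 / rh.tau) * np.asarray(state.gap, dtype=float)
        - (K1 + rh.K2) * np.asarray(state.gap_rate, dtype=float)
        - np.asarray(state.gap_accel, dtype=float) / rh.tau
    )


def sls_stress(gap_accel, gap, zone_max):
    """Bond tension carried by the SLS acceleration memory (zero if detached)."""
    gap = np.asarray(gap, dtype=float)
    return np.where(gap > zone_max, 0.0, -np.asarray(gap_accel, dtype=float))
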