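"""The ternary pulse: phase field, soliton energy bookkeeping, collision algebra.

A computational action potential (CAP) decomposes the spike into three
phases read as a ternary digit along the membrane: resting potential is 0,
the threshold front is +1, and the trailing analog refractory tail is -1.
Computation happens when pulses interact: a head-on meeting annihilates
both (the +1 of each runs into the -1 of the other), an arrival at a node
inside the refractory window left by an earlier passage is annulled
(occlusion), and in-phase arrivals merge into one pulse.

The soliton carries a scalar energy budget that dissipates linearly with
distance; a pulse whose residual energy falls below the next segment's
activation threshold fails to propagate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .graph_model import StimulusLabel

__all__ = [
    "CAPPulse",
    "CollisionKind",
    "CollisionOutcome",
    "ternary_state",
    "residual_energy",
    "can_activate",
    "in_phase",
    "resolve_node_arrival",
    "resolve_head_on",
]


class CollisionKind(str, Enum):
    MUTUAL_ANNIHILATION = "MUTUAL_ANNIHILATION"
    ANNUL_SECOND = "ANNUL_SECOND"
    MERGE = "MERGE"
    PASS = "PASS"


@dataclass(frozen=True)
class CAPPulse:
    """A travelling ternary pulse on one segment.

    ``position_um`` is the front position *at* ``birth_time_s`` (birth here
    meaning entry onto the current segment); the front then moves at
    ``velocity_m_per_s`` in ``direction`` (+1 toward the segment target,
    -1 toward the source).
    """

    id: int
    birth_time_s: float
    segment_id: str
    position_um: float
    direction: int
    velocity_m_per_s: float
    energy: float = 0.0
    refractory_s: float = 2e-3
    label: StimulusLabel = StimulusLabel.SIGNAL

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.velocity_m_per_s <= 0:
            raise ValueError("velocity must be > 0")
        if self.energy < 0:
            raise ValueError("energy must be >= 0")
        if self.refractory_s < 0:
            raise ValueError("refractory duration must be >= 0")

    @property
    def velocity_um_per_s(self) -> float:
        return self.velocity_m_per_s * 1e6

    def front_position_um(self, t_s: float) -> float:
        """Front position at time t (unclamped; caller checks segment bounds)."""
        return self.position_um + self.direction * self.velocity_um_per_s * (
            t_s - self.birth_time_s
        )


def ternary_state(
    p: CAPPulse,
    x_um: float,
    t_s: float,
    segment_length_um: Optional[float] = None,
    front_tol_um: float = 1e-6,
) -> int:
    """Ternary digit the pulse imposes at position ``x_um`` at time ``t_s``.

    +1 at the threshold front (within ``front_tol_um``), -1 at points the
    front passed within the preceding refractory duration, 0 elsewhere —
    including everywhere before the pulse was born (no acausal phase).
    """
    if segment_length_um is not None and not (0.0 <= x_um <= segment_length_um):
        raise ValueError(
            f"position {x_um} um lies off the segment [0, {segment_length_um}]"
        )
    if x_um < 0:
        raise ValueError("position must be >= 0")
    if t_s < p.birth_time_s:
        return 0
    front = p.front_position_um(t_s)
    if abs(x_um - front) <= front_tol_um:
        return 1
    # has the front already passed x?
    if (front - x_um) * p.direction > 0:
        t_pass = p.birth_time_s + (x_um - p.position_um) / (
            p.direction * p.velocity_um_per_s
        )
        if t_pass >= p.birth_time_s and (t_s - t_pass) < p.refractory_s:
            return -1
    return 0


def residual_energy(e0: float, rate_per_um: float, distance_um: float) -> float:
    """Residual soliton energy after linear dissipation, floored at zero.

    Energy drops by ``rate * distance`` along the path (Ed = E - e); a
    pulse whose budget is exhausted is dead.
    """
    if e0 < 0 or rate_per_um < 0 or distance_um < 0:
        raise ValueError("energy, rate and distance must all be >= 0")
    return max(e0 - rate_per_um * distance_um, 0.0)


def can_activate(residual: float, threshold: float) -> bool:
    """True iff the residual energy reaches the activation threshold.

    The boundary is inclusive: energy exactly at threshold activates.
    """
    return residual >= threshold


def in_phase(t1_s: float, t2_s: float, tolerance_s: float) -> bool:
    """Two firing times are in phase when they differ by at most the
    temporal-accuracy tolerance (channel spacing / velocity by default)."""
    if tolerance_s < 0:
        raise ValueError("tolerance must be >= 0")
    return abs(t1_s - t2_s) <= tolerance_s


def resolve_node_arrival(
    node_last_passage_s: Optional[float],
    arrival_s: float,
    tau_s: float,
    merge_tolerance_s: float,
) -> CollisionKind:
    """Timing rule for a pulse arriving at a node with refractory memory.

    With Δ = arrival - last passage:

    * no prior passage           → PASS
    * Δ ≤ merge tolerance        → MERGE  (in-phase arrivals map together)
    * merge tolerance < Δ < τ    → ANNUL_SECOND  (occlusion by the
      refractory tail left at the node)
    * Δ ≥ τ                      → PASS  (half-open window [0, τ))
    """
    if merge_tolerance_s < 0:
        raise ValueError("merge tolerance must be >= 0")
    if node_last_passage_s is None:
        return CollisionKind.PASS
    delta = arrival_s - node_last_passage_s
    if delta < 0:
        raise ValueError(
            "arrival precedes recorded passage (event-ordering bug)"
        )
    if delta <= merge_tolerance_s:
        return CollisionKind.MERGE
    if delta < tau_s:
        return CollisionKind.ANNUL_SECOND
    return CollisionKind.PASS


@dataclass(frozen=True)
class CollisionOutcome:
    kind: CollisionKind
    survivor_ids: tuple[int, ...]
    time_s: float
    segment_id: Optional[str] = None
    position_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind is CollisionKind.MUTUAL_ANNIHILATION and self.survivor_ids:
            raise ValueError("mutual annihilation leaves no survivors")
        if self.kind in (CollisionKind.ANNUL_SECOND, CollisionKind.MERGE) and len(
            self.survivor_ids
        ) != 1:
            raise ValueError(f"{self.kind.value} must leave exactly one survivor")


def resolve_head_on(a: CAPPulse, b: CAPPulse) -> CollisionOutcome:
    """Meeting point and time of two opposing pulses on one segment.

    Head-on collision annihilates both: neither front can cross the other's
    refractory zone.  Symmetric in argument order.  Fronts are linear in
    time, so the meeting is the solution of ``x_a(t) == x_b(t)``.
    """
    if a.segment_id != b.segment_id:
        raise ValueError("pulses are on different segments")
    if a.direction == b.direction:
        raise ValueError(
            "same-direction pulses do not collide head-on (chase, not collision)"
        )
    va = a.direction * a.velocity_um_per_s
    vb = b.direction * b.velocity_um_per_s
    # pa + va (t - ta) = pb + vb (t - tb)
    t_meet = (b.position_um - vb * b.birth_time_s
              - a.position_um + va * a.birth_time_s) / (va - vb)
    if t_meet < max(a.birth_time_s, b.birth_time_s) - 1e-15:
        raise ValueError("pulses are receding; no meeting after both exist")
    x_meet = a.front_position_um(t_meet)
    return CollisionOutcome(
        kind=CollisionKind.MUTUAL_ANNIHILATION,
        survivor_ids=(),
        time_s=t_meet,
        segment_id=a.segment_id,
        position_um=x_meet,
    )
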