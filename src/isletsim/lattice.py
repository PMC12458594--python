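"""Voxel-state lattice, Ising energy and event propensities.

The tissue is discretised on a uniform 3-D grid with isotropic spacing
``dx``.  Every voxel is in one of three states: HEALTHY (non-tumorous
tissue inside the organ), TUMOR (at least one tumor cell present) or
BOUNDARY (outside the organ; inert).  Tumor voxels evolve through three
elementary events:

* ``JUMP`` -- the tumor voxel moves to a face-adjacent healthy voxel,
* ``DUP``  -- the tumor voxel duplicates into a face-adjacent healthy voxel,
* ``DIE``  -- the tumor voxel reverts to healthy.

The propensity (probability per unit time) of an event of class ``a`` is

    rate = (1 / tau_a) * exp(-dE / kBT),

where ``dE`` is the change of a nearest-neighbour Ising energy

    E = -(1/2) * sum_i sum_<j,i> J * s_i * s_j,       s_i = +1 for TUMOR,
                                                      s_i = -1 otherwise.

The energy acts as a surface tension: events that detach tumor voxels from
a cluster raise E and are exponentially suppressed, which is what produces
compact, spheroidal islets.

Conventions
-----------
* Connectivity is strictly 6-face; each voxel has up to 13 candidate
  events (6 jump + 6 dup + 1 die).
* ``J`` is fixed to 1 and ``kBT`` is expressed in units of ``J``.
* Only bonds between two in-array voxels carry energy.  Explicitly
  labelled BOUNDARY voxels contribute ``s = -1`` (penalising tumor against
  the organ surface) but are never event targets.  Sites beyond a
  non-periodic array edge carry no bond and are never targets; simulation
  geometries always wrap the organ in an explicit BOUNDARY shell, so the
  array edge is never reached in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "HEALTHY",
    "TUMOR",
    "BOUNDARY",
    "INFINITE_TAU",
    "EventKind",
    "Event",
    "Lattice",
    "ModelParams",
    "spin_of",
    "total_energy",
    "delta_energy",
    "propensity",
    "enumerate_events",
]

HEALTHY: int = 0
TUMOR: int = 1
BOUNDARY: int = 2

#: Sentinel disabling an event class (tau = infinity => zero propensity).
INFINITE_TAU: float = math.inf

_VALID_LABELS = (HEALTHY, TUMOR, BOUNDARY)

#: Face-neighbour direction order used everywhere (slots, kernels, logs):
#: -x, +x, -y, +y, -z, +z.
DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (-1, 0, 0),
    (1, 0, 0),
    (0, -1, 0),
    (0, 1, 0),
    (0, 0, -1),
    (0, 0, 1),
)


class EventKind(IntEnum):
    JUMP = 0
    DUP = 1
    DIE = 2


class Event(NamedTuple):
    """A candidate state transition.

    ``source`` must be a TUMOR voxel; ``target`` is the face-adjacent
    HEALTHY voxel for JUMP/DUP and ``None`` for DIE.
    """

    kind: EventKind
    source: tuple[int, int, int]
    target: tuple[int, int, int] | None = None


@dataclass
class Lattice:
    """3-D voxel state field with spacing and boundary-condition metadata."""

    states: np.ndarray
    spacing: float
    periodic: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self) -> None:
        self.states = np.ascontiguousarray(self.states, dtype=np.int8)
        if self.states.ndim != 3:
            raise ValueError("states must be a 3-D array")
        if self.states.size == 0:
            raise ValueError("lattice has no voxels")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not np.isin(self.states, _VALID_LABELS).all():
            raise ValueError("states contains labels outside {HEALTHY, TUMOR, BOUNDARY}")
        self.periodic = tuple(bool(p) for p in self.periodic)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.states.shape  # type: ignore[return-value]

    def copy(self) -> "Lattice":
        return Lattice(self.states.copy(), self.spacing, self.periodic)

    def neighbors(self, voxel: tuple[int, int, int]) -> Iterator[tuple[int, int, int]]:
        """Yield in-array face neighbours (periodic wrap where enabled).

        On a periodic axis of length 2 the same neighbour is yielded twice,
        once per direction, matching the 6-direction neighbour relation.
        """
        x, y, z = voxel
        nx, ny, nz = self.shape
        for dx, dy, dz in DIRECTIONS:
            cx, cy, cz = x + dx, y + dy, z + dz
            if not 0 <= cx < nx:
                if not self.periodic[0] or nx == 1:
                    continue
                cx %= nx
            if not 0 <= cy < ny:
                if not self.periodic[1] or ny == 1:
                    continue
                cy %= ny
            if not 0 <= cz < nz:
                if not self.periodic[2] or nz == 1:
                    continue
                cz %= nz
            yield (cx, cy, cz)


@dataclass(frozen=True)
class ModelParams:
    """The four model parameters plus horizon and grid spacing.

    ``kBT`` (the cell activity) is expressed in units of the interaction
    strength ``J``; ``J`` itself is fixed to 1.  A ``tau`` of
    :data:`INFINITE_TAU` disables that event class.  Time is in the
    arbitrary simulation unit shared by the taus and ``tend``.
    """

    kBT: float
    tau_jump: float
    tau_dup: float
    tau_die: float
    tend: float = 0.0
    dx: float = 0.25
    J: float = 1.0

    def __post_init__(self) -> None:
        if not self.kBT > 0:
            raise ValueError("kBT must be positive")
        if not self.J > 0:
            raise ValueError("J must be positive")
        for name in ("tau_jump", "tau_dup", "tau_die"):
            tau = getattr(self, name)
            if not tau > 0:  # inf passes
                raise ValueError(f"{name} must be positive or infinite")
        if self.tend < 0:
            raise ValueError("tend must be nonnegative")
        if not self.dx > 0:
            raise ValueError("dx must be positive")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def tau(self, kind: EventKind) -> float:
        return (self.tau_jump, self.tau_dup, self.tau_die)[int(kind)]


def spin_of(label: int) -> int:
    """Ising spin of a voxel label: +1 for TUMOR, -1 otherwise."""
    if label == TUMOR:
        return 1
    if label in (HEALTHY, BOUNDARY):
        return -1
    raise ValueError(f"unknown voxel label {label!r}")


def _spins(lattice: Lattice) -> np.ndarray:
    return np.where(lattice.states == TUMOR, 1, -1).astype(np.int64)


def total_energy(lattice: Lattice, J: float = 1.0) -> float:
    """Total Ising energy -(1/2) sum_i sum_<j,i> J s_i s_j.

    Each unordered in-array face-adjacent pair is counted once (the 1/2
    cancels the double sum over ordered pairs).  On a periodic axis the
    wrap-around bonds are included; a periodic axis of length 2 carries a
    double bond between its two sites, consistent with the 6-direction
    neighbour relation.
    """
    s = _spins(lattice)
    e = 0.0
    for axis in range(3):
        n = s.shape[axis]
        if n > 1:
            a = np.take(s, range(0, n - 1), axis=axis)
            b = np.take(s, range(1, n), axis=axis)
            e -= float(np.sum(a * b))
        if lattice.periodic[axis] and n > 1:
            a = np.take(s, [n - 1], axis=axis)
            b = np.take(s, [0], axis=axis)
            e -= float(np.sum(a * b))
    return J * e


def _neighbor_spin_sum(lattice: Lattice, voxel: tuple[int, int, int]) -> int:
    states = lattice.states
    return sum(1 if states[c] == TUMOR else -1 for c in lattice.neighbors(voxel))


def _check_event(event: Event, lattice: Lattice) -> None:
    if lattice.states[event.source] != TUMOR:
        raise ValueError(f"invalid event: source {event.source} is not TUMOR")
    if event.kind == EventKind.DIE:
        if event.target is not None:
            raise ValueError("DIE events carry no target")
        return
    if event.target is None:
        raise ValueError(f"{event.kind.name} event requires a target")
    if lattice.states[event.target] != HEALTHY:
        raise ValueError(f"invalid event: target {event.target} is not HEALTHY")
    if tuple(event.target) not in set(lattice.neighbors(event.source)):
        raise ValueError("target is not a face neighbour of source")


def delta_energy(event: Event, lattice: Lattice, J: float = 1.0) -> float:
    """Energy change E(after) - E(before) of an event, computed locally.

    DIE flips the source spin: dE = 2 J sum_nb(s).  DUP flips the target:
    dE = -2 J sum_nb(s).  JUMP is the exact composition of a removal at
    the source followed by an addition at the target, so the source-target
    bond is handled once.
    """
    _check_event(event, lattice)
    if event.kind == EventKind.DIE:
        return 2.0 * J * _neighbor_spin_sum(lattice, event.source)
    if event.kind == EventKind.DUP:
        return -2.0 * J * _neighbor_spin_sum(lattice, event.target)  # type: ignore[arg-type]
    # JUMP: remove at source, then add at target on the intermediate state.
    d_e = 2.0 * J * _neighbor_spin_sum(lattice, event.source)
    states = lattice.states
    old = states[event.source]
    states[event.source] = HEALTHY
    try:
        d_e += -2.0 * J * _neighbor_spin_sum(lattice, event.target)  # type: ignore[arg-type]
    finally:
        states[event.source] = old
    return d_e


def propensity(event: Event, lattice: Lattice, params: ModelParams) -> float:
    """Rate (1/tau_a) * exp(-dE / kBT); zero for a disabled event class."""
    tau = params.tau(event.kind)
    if math.isinf(tau):
        return 0.0
    d_e = delta_energy(event, lattice, params.J)
    return (1.0 / tau) * math.exp(-d_e / (params.kBT * params.J))


def enumerate_events(lattice: Lattice, voxel: tuple[int, int, int]) -> list[Event]:
    """All candidate events of one voxel (empty unless it is TUMOR).

    A tumor voxel has one DIE event plus one JUMP and one DUP per
    face-adjacent HEALTHY neighbour -- at most 6 + 6 + 1 = 13 events.
    BOUNDARY and TUMOR sites are never targets.
    """
    voxel = tuple(voxel)  # type: ignore[assignment]
    if lattice.states[voxel] != TUMOR:
        return []
    events: list[Event] = []
    for nb in lattice.neighbors(voxel):
        if lattice.states[nb] == HEALTHY:
            events.append(Event(EventKind.JUMP, voxel, nb))
            events.append(Event(EventKind.DUP, voxel, nb))
    events.append(Event(EventKind.DIE, voxel))
    return events
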