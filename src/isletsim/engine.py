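"""Exact stochastic simulation (Gillespie SSA) of the lattice model.

The engine implements the direct method: the waiting time to the next
event is exponential with rate equal to the total propensity, and the
event itself is drawn with probability proportional to its propensity by
a prefix-sum search on a segment tree (see :mod:`isletsim._kernel`).
After an event fires, only the propensity slots of voxels near the
changed sites are refreshed, so the cost per event is O(log Ne).

The last waiting time is truncated at the horizon: if ``clock + wait``
would pass ``tend`` (or no event is possible) the clock is set to
``tend`` and nothing fires.  Trajectories are bit-reproducible for a
fixed seed, lattice and parameters; replicate ``k`` of a batch should be
seeded ``base_seed + k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .lattice import (
    TUMOR,
    Event,
    EventKind,
    Lattice,
    ModelParams,
    enumerate_events,
    propensity,
)

__all__ = ["SimState", "build", "step", "run_until", "check_consistency"]

_KIND_NAMES = ("jump", "dup", "die")


def _inv_tau(tau: float) -> float:
    return 0.0 if math.isinf(tau) else 1.0 / tau


@dataclass
class SimState:
    """Mutable simulation state: lattice + clock + propensity index + RNG."""

    lattice: Lattice
    params: ModelParams
    clock: float
    tree: np.ndarray
    rng: np.ndarray
    counts: np.ndarray  # fired events by kind (jump, dup, die)
    seed: int
    event_log: pd.DataFrame | None = None
    antithetic: bool = False

    @property
    def total_propensity(self) -> float:
        return float(self.tree[1])

    @property
    def event_counts(self) -> dict[str, int]:
        return {name: int(c) for name, c in zip(_KIND_NAMES, self.counts)}

    def _geom(self):
        nx, ny, nz = self.lattice.shape
        px, py, pz = self.lattice.periodic
        return nx, ny, nz, px, py, pz

    @property
    def _flat_states(self) -> np.ndarray:
        return self.lattice.states.reshape(-1)


def build(lattice: Lattice, params: ModelParams, seed: int,
          antithetic: bool = False) -> SimState:
    """Initialise a simulation: propensity index over every valid event.

    The input lattice is copied; ``params.dx`` is synchronised with the
    lattice spacing check (they must agree).  ``antithetic=True`` runs
    the trajectory on the antithetic waiting-time stream of the same
    seed (a variance-reduction device for paired replicates).
    """
    if lattice.states.size == 0:
        raise ValueError("lattice has no voxels")
    if not math.isclose(params.dx, lattice.spacing, rel_tol=1e-9):
        raise ValueError(
            f"params.dx ({params.dx}) disagrees with lattice spacing ({lattice.spacing})"
        )
    lattice = lattice.copy()
    nx, ny, nz = lattice.shape
    px, py, pz = lattice.periodic
    tree = _kernel.build_tree(
        lattice.states.reshape(-1),
        _inv_tau(params.tau_jump),
        _inv_tau(params.tau_dup),
        _inv_tau(params.tau_die),
        params.kBT / params.J,
        nx, ny, nz, px, py, pz,
    )
    return SimState(
        lattice=lattice,
        params=params,
        clock=0.0,
        tree=tree,
        rng=_kernel.rng_seed(seed),
        counts=np.zeros(3, np.int64),
        seed=int(seed),
        antithetic=bool(antithetic),
    )


def _run(state: SimState, tend: float, max_events: int, log_capacity: int):
    p = state.params
    nx, ny, nz, px, py, pz = state._geom()
    log_t = np.empty(log_capacity, np.float64)
    log_kind = np.empty(log_capacity, np.int8)
    log_src = np.empty(log_capacity, np.int64)
    log_tgt = np.empty(log_capacity, np.int64)
    clock, nfired = _kernel.run_kernel(
        state._flat_states, state.tree, _kernel.NSLOT * state.lattice.states.size,
        state.rng, state.clock, tend,
        _inv_tau(p.tau_jump), _inv_tau(p.tau_dup), _inv_tau(p.tau_die),
        p.kBT / p.J, nx, ny, nz, px, py, pz,
        state.counts, max_events,
        log_t, log_kind, log_src, log_tgt, 1 if state.antithetic else 0,
    )
    state.clock = clock
    nrec = min(nfired, log_capacity)
    return nfired, (log_t[:nrec], log_kind[:nrec], log_src[:nrec], log_tgt[:nrec])


def _unravel(flat: int, shape: tuple[int, int, int]) -> tuple[int, int, int]:
    nx, ny, nz = shape
    z = flat % nz
    r = flat // nz
    return (r // ny, r % ny, z)


def step(state: SimState, tend: float | None = None) -> tuple[Event | None, float]:
    """Fire at most one event; returns (event or None, new clock).

    ``None`` means the horizon was reached first (or no event is
    possible, in which case the clock jumps to the horizon).
    """
    if tend is None:
        tend = state.params.tend
    if tend < state.clock:
        raise ValueError("tend is in the past")
    nfired, (lt, lk, ls, lg) = _run(state, tend, max_events=1, log_capacity=1)
    if nfired == 0:
        return None, state.clock
    kind = EventKind(int(lk[0]))
    src = _unravel(int(ls[0]), state.lattice.shape)
    tgt = None if kind == EventKind.DIE else _unravel(int(lg[0]), state.lattice.shape)
    return Event(kind, src, tgt), state.clock


def run_until(
    state: SimState,
    tend: float | None = None,
    record: bool = False,
    max_record: int = 1_000_000,
    max_events: int = 0,
) -> SimState:
    """Advance the SSA until the horizon; optionally record the event log.

    With ``record=True`` the fired events are collected (in chunks of
    ``max_record``) into ``state.event_log``, a DataFrame with columns
    (time, kind, source, target); recording does not change the
    trajectory.

    ``max_events`` > 0 stops the run after that many fired events even
    if the horizon has not been reached (a safeguard for runaway
    parameter regions during calibration sweeps).
    """
    if tend is None:
        tend = state.params.tend
    if tend < state.clock:
        raise ValueError("tend is in the past")
    cap = max_record if record else 0
    total_fired = 0
    frames = []
    while True:
        remaining = max_events - total_fired if max_events > 0 else 0
        if max_events > 0 and remaining <= 0:
            break
        chunk = min(cap, remaining) if (record and max_events > 0) else (
            cap if record else remaining
        )
        nfired, logs = _run(state, tend, max_events=chunk, log_capacity=cap)
        total_fired += nfired
        if record and nfired > 0:
            lt, lk, ls, lg = logs
            frames.append(pd.DataFrame({
                "time": lt,
                "kind": [_KIND_NAMES[k] for k in lk],
                "source": [(_unravel(int(s), state.lattice.shape)) for s in ls],
                "target": [None if k == 2 else _unravel(int(g), state.lattice.shape)
                           for k, g in zip(lk, lg)],
            }))
        if state.clock >= tend or not record or nfired < cap:
            break
    if record:
        state.event_log = (
            pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["time", "kind", "source", "target"])
        )
    return state


def check_consistency(state: SimState, rebuild: bool = True) -> float:
    """Max absolute discrepancy between index leaves and fresh propensities.

    Re-derives every valid event's propensity through the pure-Python
    reference path (:func:`isletsim.lattice.propensity`) and compares with
    the segment-tree leaves; also verifies the root against the naive
    leaf sum.  Intended for tests on small lattices.
    """
    lat = state.lattice
    n = lat.states.size
    M = _kernel.NSLOT * n
    leaves = state.tree[M:]
    expected = np.zeros(M)
    from .lattice import DIRECTIONS

    for flat in range(n):
        vox = _unravel(flat, lat.shape)
        for ev in enumerate_events(lat, vox):
            if ev.kind == EventKind.DIE:
                slot = 12
                expected[flat * 13 + slot] += propensity(ev, lat, state.params)
            else:
                # map target to direction slot(s); periodic length-2 axes give
                # the same neighbour in two directions
                for d, off in enumerate(DIRECTIONS):
                    cand = tuple(
                        (v + o) % s if lat.periodic[a] else v + o
                        for a, (v, o, s) in enumerate(zip(vox, off, lat.shape))
                    )
                    if cand == ev.target:
                        slot = d if ev.kind == EventKind.JUMP else 6 + d
                        expected[flat * 13 + slot] = propensity(ev, lat, state.params)
    err = float(np.max(np.abs(expected - leaves))) if M else 0.0
    root_err = abs(float(state.tree[1]) - float(leaves.sum()))
    return max(err, root_err)
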