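"""Numba-compiled SSA core: propensity slots, segment tree, event loop.

Layout
------
States live in a flat ``int8`` array (C-order ravel of the (nx, ny, nz)
grid).  Every voxel owns a fixed block of 13 propensity slots:

    slot 0..5   JUMP in direction (-x, +x, -y, +y, -z, +z)
    slot 6..11  DUP, same direction order
    slot 12     DIE

Invalid events (non-tumor source, non-healthy target, disabled class)
hold exactly 0.  The slots are the leaves of a flat binary segment tree
``tree`` of length ``2*M`` with ``M = 13 * n_voxels``: leaf ``j`` sits at
``M + j`` and every internal node ``i`` stores ``tree[2i] + tree[2i+1]``.
Point updates climb the tree recomputing each parent from its children,
so the root is always the exact pairwise sum of the leaves (no
accumulated drift); selection descends from the root with a prefix-sum
search, breaking numerical ties toward the lowest slot index.  Both are
O(log Ne) per event.

After an event only sites within L1 distance 2 of a changed voxel can
see a different propensity (a slot's rate depends on the neighbour-spin
sums of its source and target), so exactly those voxel blocks are
refreshed -- a constant amount of work per event.

The RNG is xoshiro256++ seeded through splitmix64; its four-word state is
carried in a ``uint64[4]`` array, giving bit-reproducible trajectories.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

HEALTHY = 0
TUMOR = 1
BOUNDARY = 2
NSLOT = 13


def _ball2_offsets() -> np.ndarray:
    out = []
    for a in range(-2, 3):
        for b in range(-2, 3):
            for c in range(-2, 3):
                if abs(a) + abs(b) + abs(c) <= 2:
                    out.append((a, b, c))
    return np.array(out, dtype=np.int64)


_BALL2 = _ball2_offsets()  # 25 offsets with L1 norm <= 2

#: Boltzmann exponents are clamped at this value: exp(250) ~ 3.7e108, large
#: enough that such events fire "instantly" on any simulated time scale while
#: keeping partial sums finite for any realistic leaf count.
MAX_EXPONENT = 250.0


@njit(cache=True, inline="always")
def _boltz(d_e, kbt):
    a = -d_e / kbt
    if a > MAX_EXPONENT:
        a = MAX_EXPONENT
    return math.exp(a)


# ---------------------------------------------------------------------------
# RNG: splitmix64 seeding + xoshiro256++
# ---------------------------------------------------------------------------

@njit(cache=True)
def rng_seed(seed):
    s = np.empty(4, np.uint64)
    z = np.uint64(seed)
    for i in range(4):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        s[i] = t ^ (t >> np.uint64(31))
    return s


@njit(cache=True)
def rng_next(s):
    a = s[0] + s[3]
    res = ((a << np.uint64(23)) | (a >> np.uint64(41))) + s[0]
    t = s[1] << np.uint64(17)
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = (s[3] << np.uint64(45)) | (s[3] >> np.uint64(19))
    return res


@njit(cache=True)
def rng_uniform(s):
    """Uniform double in [0, 1)."""
    return (rng_next(s) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


# ---------------------------------------------------------------------------
# Geometry helpers on the flat index
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _nbr(i, d, nx, ny, nz, px, py, pz):
    """Flat index of face neighbour in direction d, or -1 if absent."""
    z = i % nz
    r = i // nz
    y = r % ny
    x = r // ny
    if d == 0:
        x -= 1
    elif d == 1:
        x += 1
    elif d == 2:
        y -= 1
    elif d == 3:
        y += 1
    elif d == 4:
        z -= 1
    else:
        z += 1
    if x < 0 or x >= nx:
        if not px or nx == 1:
            return np.int64(-1)
        x %= nx
    if y < 0 or y >= ny:
        if not py or ny == 1:
            return np.int64(-1)
        y %= ny
    if z < 0 or z >= nz:
        if not pz or nz == 1:
            return np.int64(-1)
        z %= nz
    return np.int64((x * ny + y) * nz + z)


@njit(cache=True, inline="always")
def _ssum(states, i, nx, ny, nz, px, py, pz):
    """Sum of neighbour spins (in-array neighbours only)."""
    s = 0
    for d in range(6):
        j = _nbr(i, d, nx, ny, nz, px, py, pz)
        if j >= 0:
            s += 1 if states[j] == TUMOR else -1
    return s


# ---------------------------------------------------------------------------
# Segment tree
# ---------------------------------------------------------------------------

@njit(cache=True)
def tree_rebuild(tree, M):
    for i in range(M - 1, 0, -1):
        tree[i] = tree[2 * i] + tree[2 * i + 1]


@njit(cache=True, inline="always")
def _tree_set(tree, M, leaf, val):
    i = M + leaf
    if tree[i] == val:
        return
    tree[i] = val
    i >>= 1
    while i >= 1:
        tree[i] = tree[2 * i] + tree[2 * i + 1]
        i >>= 1


@njit(cache=True)
def tree_select(tree, M, r):
    """Leaf index whose cumulative-sum interval contains r."""
    i = 1
    while i < M:
        left = 2 * i
        if r < tree[left]:
            i = left
        else:
            r -= tree[left]
            i = left + 1
    return i - M


# ---------------------------------------------------------------------------
# Propensity refresh
# ---------------------------------------------------------------------------

@njit(cache=True)
def refresh_voxel(states, tree, M, v, itj, itd, itk, kbt, nx, ny, nz, px, py, pz):
    """Recompute the 13 slots of voxel v from the current states."""
    base = v * NSLOT
    if states[v] != TUMOR:
        for slot in range(NSLOT):
            _tree_set(tree, M, base + slot, 0.0)
        return
    sv = _ssum(states, v, nx, ny, nz, px, py, pz)
    for d in range(6):
        jr = 0.0
        dr = 0.0
        t = _nbr(v, d, nx, ny, nz, px, py, pz)
        if t >= 0 and states[t] == HEALTHY:
            if itd > 0.0:
                d_e = -2.0 * _ssum(states, t, nx, ny, nz, px, py, pz)
                dr = itd * _boltz(d_e, kbt)
            if itj > 0.0:
                # composition: remove at v, then add at t
                states[v] = HEALTHY
                st2 = _ssum(states, t, nx, ny, nz, px, py, pz)
                states[v] = TUMOR
                d_e = 2.0 * sv - 2.0 * st2
                jr = itj * _boltz(d_e, kbt)
        _tree_set(tree, M, base + d, jr)
        _tree_set(tree, M, base + 6 + d, dr)
    if itk > 0.0:
        d_e = 2.0 * sv
        _tree_set(tree, M, base + 12, itk * _boltz(d_e, kbt))
    else:
        _tree_set(tree, M, base + 12, 0.0)


@njit(cache=True)
def build_tree(states, itj, itd, itk, kbt, nx, ny, nz, px, py, pz):
    n = states.size
    M = NSLOT * n
    tree = np.zeros(2 * M, np.float64)
    for v in range(n):
        if states[v] == TUMOR:
            refresh_voxel(states, tree, M, v, itj, itd, itk, kbt, nx, ny, nz, px, py, pz)
    tree_rebuild(tree, M)
    return tree


@njit(cache=True)
def _update_around(states, tree, M, s0, s1, itj, itd, itk, kbt, nx, ny, nz, px, py, pz):
    """Refresh every voxel within L1 distance 2 of the changed sites."""
    buf = np.empty(50, np.int64)
    cnt = 0
    for which in range(2):
        c = s0 if which == 0 else s1
        if c < 0:
            continue
        cz = c % nz
        r = c // nz
        cy = r % ny
        cx = r // ny
        for o in range(_BALL2.shape[0]):
            x = cx + _BALL2[o, 0]
            y = cy + _BALL2[o, 1]
            z = cz + _BALL2[o, 2]
            if x < 0 or x >= nx:
                if not px or nx == 1:
                    continue
                x %= nx
            if y < 0 or y >= ny:
                if not py or ny == 1:
                    continue
                y %= ny
            if z < 0 or z >= nz:
                if not pz or nz == 1:
                    continue
                z %= nz
            idx = (x * ny + y) * nz + z
            seen = False
            for k in range(cnt):
                if buf[k] == idx:
                    seen = True
                    break
            if seen:
                continue
            buf[cnt] = idx
            cnt += 1
            refresh_voxel(states, tree, M, idx, itj, itd, itk, kbt, nx, ny, nz, px, py, pz)


# ---------------------------------------------------------------------------
# SSA loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_kernel(states, tree, M, rng, t, tend, itj, itd, itk, kbt,
               nx, ny, nz, px, py, pz, counts, max_events,
               log_t, log_kind, log_src, log_tgt, anti):
    """Advance the SSA until tend (or max_events fired, if > 0).

    Returns (clock, events_fired_this_call).  ``counts`` accumulates
    fired events by kind (jump, dup, die).  If the log arrays are
    non-empty, the first ``len(log_t)`` events of this call are recorded.
    With ``anti`` nonzero the waiting-time uniforms are replaced by their
    complements (antithetic stream; selection draws are unchanged).
    """
    nlog = log_t.shape[0]
    nfired = 0
    while True:
        total = tree[1]
        if total <= 0.0:
            t = tend
            break
        u = rng_uniform(rng)
        if anti != 0:
            u = 1.0 - u
        wait = -math.log(1.0 - u) / total
        if t + wait > tend:
            t = tend
            break
        r = rng_uniform(rng) * total
        leaf = tree_select(tree, M, r)
        if tree[M + leaf] <= 0.0:
            # numerically degenerate search: restore exact sums, clamp to the
            # nearest positive leaf at or below slot order
            tree_rebuild(tree, M)
            total = tree[1]
            if total <= 0.0:
                t = tend
                break
            if r >= total:
                r = total * (1.0 - 1e-15)
            leaf = tree_select(tree, M, r)
            while leaf > 0 and tree[M + leaf] <= 0.0:
                leaf -= 1
            while leaf < M - 1 and tree[M + leaf] <= 0.0:
                leaf += 1
        t += wait
        v = leaf // NSLOT
        slot = leaf % NSLOT
        if slot == 12:
            kind = 2
            tgt = np.int64(-1)
            states[v] = HEALTHY
            _update_around(states, tree, M, v, np.int64(-1),
                           itj, itd, itk, kbt, nx, ny, nz, px, py, pz)
        elif slot < 6:
            kind = 0
            tgt = _nbr(v, slot, nx, ny, nz, px, py, pz)
            states[v] = HEALTHY
            states[tgt] = TUMOR
            _update_around(states, tree, M, np.int64(v), tgt,
                           itj, itd, itk, kbt, nx, ny, nz, px, py, pz)
        else:
            kind = 1
            tgt = _nbr(v, slot - 6, nx, ny, nz, px, py, pz)
            states[tgt] = TUMOR
            _update_around(states, tree, M, tgt, np.int64(-1),
                           itj, itd, itk, kbt, nx, ny, nz, px, py, pz)
        counts[kind] += 1
        if nfired < nlog:
            log_t[nfired] = t
            log_kind[nfired] = kind
            log_src[nfired] = v
            log_tgt[nfired] = tgt
        nfired += 1
        if max_events > 0 and nfired >= max_events:
            break
    return t, nfired
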