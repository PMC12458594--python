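"""Unit and property tests of the voxel model: spins, energy, events."""

import math

import numpy as np
import pytest

from isletsim.lattice import (
    BOUNDARY,
    HEALTHY,
    INFINITE_TAU,
    TUMOR,
    Event,
    EventKind,
    Lattice,
    ModelParams,
    delta_energy,
    enumerate_events,
    propensity,
    spin_of,
    total_energy,
)
from conftest import random_lattice


def brute_force_energy(lat: Lattice, J: float = 1.0) -> float:
    """Independent oracle: explicit loop over ordered neighbour pairs."""
    e = 0.0
    nx, ny, nz = lat.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                si = spin_of(int(lat.states[x, y, z]))
                for nb in lat.neighbors((x, y, z)):
                    e -= 0.5 * J * si * spin_of(int(lat.states[nb]))
    return e


def apply_event(lat: Lattice, ev: Event) -> Lattice:
    out = lat.copy()
    if ev.kind == EventKind.DIE:
        out.states[ev.source] = HEALTHY
    elif ev.kind == EventKind.DUP:
        out.states[ev.target] = TUMOR
    else:
        out.states[ev.source] = HEALTHY
        out.states[ev.target] = TUMOR
    return out


class TestSpin:
    def test_labels(self):
        assert spin_of(TUMOR) == 1
        assert spin_of(HEALTHY) == -1
        assert spin_of(BOUNDARY) == -1

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            spin_of(7)


class TestTotalEnergy:
    def test_all_healthy_cube(self, cube3):
        # 54 internal face-adjacent pairs, each contributing -J
        assert total_energy(cube3) == -54.0

    def test_center_tumor_flips_six_bonds(self, center_tumor):
        assert total_energy(center_tumor) == -42.0

    def test_even_in_spin_flip(self):
        rng = np.random.default_rng(3)
        lat = random_lattice(rng, p=(0.5, 0.5, 0.0))  # no boundary labels
        flipped = lat.copy()
        flipped.states[lat.states == TUMOR] = HEALTHY
        flipped.states[lat.states == HEALTHY] = TUMOR
        assert total_energy(flipped) == total_energy(lat)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for periodic in (False, True):
            for _ in range(5):
                lat = random_lattice(rng, periodic=periodic)
                assert total_energy(lat) == pytest.approx(brute_force_energy(lat))

    def test_translation_invariance_periodic(self):
        rng = np.random.default_rng(4)
        lat = random_lattice(rng, periodic=True)
        shifted = Lattice(np.roll(lat.states, 1, axis=0), lat.spacing, lat.periodic)
        assert total_energy(shifted) == total_energy(lat)


class TestDeltaEnergy:
    def test_die_isolated(self, center_tumor):
        ev = Event(EventKind.DIE, (1, 1, 1))
        assert delta_energy(ev, center_tumor) == -12.0

    def test_dup_onto_flat_surface(self):
        # tumor half-space z <= 2 in a 5x5x5 patch: target above has 1 tumor
        # neighbour and (within the array) 4 healthy ones
        states = np.zeros((5, 5, 7), np.int8)
        states[:, :, :3] = TUMOR
        lat = Lattice(states, 0.3)
        ev = Event(EventKind.DUP, (2, 2, 2), (2, 2, 3))
        assert delta_energy(ev, lat) == 8.0

    def test_jump_of_isolated_voxel(self, center_tumor):
        # translation symmetry holds in the bulk of a periodic lattice
        lat = Lattice(center_tumor.states, 0.3, periodic=(True, True, True))
        ev = Event(EventKind.JUMP, (1, 1, 1), (1, 1, 2))
        assert delta_energy(ev, lat) == 0.0

    def test_invalid_events_rejected(self, center_tumor):
        with pytest.raises(ValueError):
            delta_energy(Event(EventKind.DIE, (0, 0, 0)), center_tumor)
        with pytest.raises(ValueError):
            delta_energy(
                Event(EventKind.JUMP, (1, 1, 1), (1, 1, 1)), center_tumor
            )

    @pytest.mark.parametrize("periodic", [False, True])
    def test_matches_total_energy_difference(self, periodic):
        rng = np.random.default_rng(7 if periodic else 8)
        checked = 0
        while checked < 40:
            lat = random_lattice(rng, periodic=periodic)
            tumors = np.argwhere(lat.states == TUMOR)
            if tumors.size == 0:
                continue
            vox = tuple(tumors[rng.integers(len(tumors))])
            for ev in enumerate_events(lat, vox):
                exact = total_energy(apply_event(lat, ev)) - total_energy(lat)
                assert delta_energy(ev, lat) == pytest.approx(exact)
                checked += 1


class TestPropensity:
    PARAMS = ModelParams(
        kBT=0.3167, tau_jump=3.178, tau_dup=0.3992, tau_die=0.1138, dx=0.3
    )

    def test_zero_delta_jump(self, center_tumor):
        lat = Lattice(center_tumor.states, 0.3, periodic=(True, True, True))
        ev = Event(EventKind.JUMP, (1, 1, 1), (1, 1, 2))
        assert propensity(ev, lat, self.PARAMS) == pytest.approx(1 / 3.178)

    def test_disabled_class_is_zero(self, center_tumor):
        params = self.PARAMS.with_(tau_die=INFINITE_TAU)
        ev = Event(EventKind.DIE, (1, 1, 1))
        assert propensity(ev, center_tumor, params) == 0.0

    def test_die_of_isolated_voxel(self):
        # all six neighbours healthy -> dE = -12 J
        states = np.zeros((3, 3, 3), np.int8)
        states[1, 1, 1] = TUMOR
        lat = Lattice(states, 0.3, periodic=(True, True, True))
        ev = Event(EventKind.DIE, (1, 1, 1))
        expected = (1 / 0.1138) * math.exp(12.0 / 0.3167)
        assert propensity(ev, lat, self.PARAMS) == pytest.approx(expected)


class TestEnumerateEvents:
    def test_isolated_tumor_has_13(self, center_tumor):
        assert len(enumerate_events(center_tumor, (1, 1, 1))) == 13

    def test_fully_surrounded_has_only_die(self):
        states = np.full((3, 3, 3), TUMOR, np.int8)
        lat = Lattice(states, 0.3)
        evs = enumerate_events(lat, (1, 1, 1))
        assert [e.kind for e in evs] == [EventKind.DIE]

    def test_mixed_neighbourhood(self):
        # 2 healthy, 3 tumor, 1 boundary neighbours -> 2 + 2 + 1 = 5 events
        states = np.zeros((3, 3, 3), np.int8)
        states[1, 1, 1] = TUMOR
        states[0, 1, 1] = states[2, 1, 1] = states[1, 0, 1] = TUMOR
        states[1, 2, 1] = BOUNDARY
        lat = Lattice(states, 0.3)
        evs = enumerate_events(lat, (1, 1, 1))
        assert len(evs) == 5
        kinds = [e.kind for e in evs]
        assert kinds.count(EventKind.JUMP) == 2
        assert kinds.count(EventKind.DUP) == 2
        assert kinds.count(EventKind.DIE) == 1
        targets = {e.target for e in evs if e.target is not None}
        assert targets == {(1, 1, 0), (1, 1, 2)}

    def test_non_tumor_has_none(self, center_tumor):
        assert enumerate_events(center_tumor, (0, 0, 0)) == []

    def test_count_bounded_by_13(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            lat = random_lattice(rng)
            for vox in map(tuple, np.argwhere(lat.states == TUMOR)):
                assert len(enumerate_events(lat, vox)) <= 13


class TestModelParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelParams(kBT=0.0, tau_jump=1, tau_dup=1, tau_die=1)
        with pytest.raises(ValueError):
            ModelParams(kBT=1, tau_jump=-1, tau_dup=1, tau_die=1)
        # infinite taus are valid sentinels
        ModelParams(kBT=1, tau_jump=INFINITE_TAU, tau_dup=1, tau_die=1)
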