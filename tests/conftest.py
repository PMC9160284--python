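"""Shared fixtures: small configurations with known bonding geometry."""

from __future__ import annotations

import numpy as np
import pytest

from hblife.topology import Frame
from hblife.synthetic import water_like_topology


def place_water(coords: np.ndarray, mol: int, o_pos, h1_dir, h2_dir, oh: float = 1.0):
    """Write one water-like molecule into a coordinate array."""
    o = 3 * mol
    o_pos = np.asarray(o_pos, float)
    coords[o] = o_pos
    coords[o + 1] = o_pos + oh * np.asarray(h1_dir, float) / np.linalg.norm(h1_dir)
    coords[o + 2] = o_pos + oh * np.asarray(h2_dir, float) / np.linalg.norm(h2_dir)


@pytest.fixture
def water_dimer():
    """Two waters, linear O–H···O bond, O–O 2.8 Å in a 20 Å box."""
    topo = water_like_topology(2)
    coords = np.zeros((6, 3))
    place_water(coords, 0, [5.0, 5.0, 5.0], [1, 0, 0], [0, 1, 0])
    place_water(coords, 1, [7.8, 5.0, 5.0], [0.5, 0.8, 0], [0.5, -0.8, 0])
    frame = Frame(time=0.0, box=np.full(3, 20.0), coords=coords)
    return topo, frame


def random_water_frame(n_molecules: int, box: float, seed: int) -> tuple:
    """n randomly placed and oriented water-like molecules."""
    rng = np.random.default_rng(seed)
    topo = water_like_topology(n_molecules)
    coords = np.zeros((3 * n_molecules, 3))
    for m in range(n_molecules):
        d1 = rng.normal(size=3)
        d2 = rng.normal(size=3)
        place_water(coords, m, rng.uniform(0, box, 3), d1, d2)
    return topo, Frame(time=0.0, box=np.full(3, box), coords=coords)


def brute_force_hbonds(frame: Frame, topo, r_c: float, theta_c: float) -> set:
    """Independent all-pairs reference detector (pure numpy, arccos in
    degrees) for oracle comparisons."""
    box = frame.box
    coords = frame.coords
    found = set()
    for h, d in zip(topo.hydrogens, topo.donor_of_hydrogen):
        u = coords[h] - coords[d]
        u -= box * np.round(u / box)
        for a in topo.acceptors:
            if topo.mol_of_atom[a] == topo.mol_of_atom[d]:
                continue
            v = coords[a] - coords[d]
            v -= box * np.round(v / box)
            r = np.linalg.norm(v)
            if r > r_c:
                continue
            cosang = np.dot(u, v) / (np.linalg.norm(u) * r)
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang <= theta_c:
                found.add((int(d), int(h), int(a)))
    return found
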