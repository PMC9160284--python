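"""Topology reading, role assignment and trajectory round-trips."""

import numpy as np
import pytest

from hblife.synthetic import water_like_topology
from hblife.topology import (
    Frame,
    TopologyError,
    TrajectoryError,
    read_frames,
    read_topology,
    write_gro_frames,
    write_xyz_frames,
)

WATER_SPEC = {
    "SOL": {"species": "W",
            "roles": {"OW": ["donor", "acceptor"], "HW1": "hydrogen", "HW2": "hydrogen"}}
}
METHANOL_SPEC = {
    "MET": {"species": "M",
            "roles": {"CH3": "inert", "OM": ["donor", "acceptor"], "HM": "hydrogen"}}
}
HEXANE_SPEC = {"HEX": {"species": "H", "roles": {f"C{i}": "inert" for i in range(1, 7)}}}


def _write_gro(path, residues, box_nm=2.0):
    """residues: list of (resname, [(atomname, x, y, z in nm)])."""
    lines = ["test t= 0.00000", str(sum(len(at) for _, at in residues))]
    i = 0
    for r, (resname, atoms) in enumerate(residues, start=1):
        for name, x, y, z in atoms:
            i += 1
            lines.append(f"{r:5d}{resname:<5s}{name:>5s}{i:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{box_nm:10.5f}{box_nm:10.5f}{box_nm:10.5f}")
    path.write_text("\n".join(lines) + "\n")


def test_water_roles(tmp_path):
    p = tmp_path / "w.gro"
    _write_gro(p, [("SOL", [("OW", 0.5, 0.5, 0.5), ("HW1", 0.6, 0.5, 0.5),
                            ("HW2", 0.5, 0.6, 0.5)])])
    topo = read_topology(p, WATER_SPEC)
    assert len(topo.donor_map) == 2
    assert topo.acceptors.tolist() == [0]
    assert topo.species_of_mol == ["W"]
    assert topo.mole_fractions() == {"W": 1.0}


def test_methanol_roles(tmp_path):
    """United-atom methanol: one donor-hydrogen, one donor/acceptor oxygen,
    one inert methyl site."""
    p = tmp_path / "m.gro"
    _write_gro(p, [("MET", [("CH3", 0.5, 0.5, 0.5), ("OM", 0.64, 0.5, 0.5),
                            ("HM", 0.7, 0.57, 0.5)])])
    topo = read_topology(p, METHANOL_SPEC)
    assert len(topo.donor_map) == 1
    assert topo.donor_map == {2: 1}
    assert topo.acceptors.tolist() == [1]
    assert not topo.is_donor[0] and not topo.is_acceptor[0]


def test_all_inert_species(tmp_path):
    p = tmp_path / "h.gro"
    _write_gro(p, [("HEX", [(f"C{i}", 0.5 + 0.1 * i, 0.5, 0.5) for i in range(1, 7)])])
    topo = read_topology(p, HEXANE_SPEC)
    assert len(topo.donor_map) == 0
    assert len(topo.acceptors) == 0


def test_unmapped_residue_named_in_error(tmp_path):
    p = tmp_path / "x.gro"
    _write_gro(p, [("XYZ", [("OW", 0.5, 0.5, 0.5)])])
    with pytest.raises(TopologyError, match="XYZ"):
        read_topology(p, WATER_SPEC)


def test_hydrogen_without_donor_heavy_errors(tmp_path):
    p = tmp_path / "b.gro"
    _write_gro(p, [("BAD", [("HX", 0.5, 0.5, 0.5)])])
    spec = {"BAD": {"species": "B", "roles": {"HX": "hydrogen"}}}
    with pytest.raises(TopologyError, match="donor"):
        read_topology(p, spec)


def test_gro_nm_to_angstrom(tmp_path):
    p = tmp_path / "w.gro"
    _write_gro(p, [("SOL", [("OW", 0.5, 0.5, 0.5), ("HW1", 0.6, 0.5, 0.5),
                            ("HW2", 0.5, 0.6, 0.5)])], box_nm=2.0)
    (frame,) = read_frames(p)
    assert frame.box[0] == pytest.approx(20.0)
    assert frame.coords[1, 0] - frame.coords[0, 0] == pytest.approx(1.0)


class TestXYZ:
    def _frames(self, times, n=6, box=20.0, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, box, (n, 3))
        return [Frame(time=t, box=np.full(3, box), coords=coords + i * 0.1)
                for i, t in enumerate(times)]

    def test_round_trip(self, tmp_path):
        frames = self._frames([0.0, 0.002, 0.004])
        p = tmp_path / "t.xyz"
        write_xyz_frames(p, frames, ["O", "H", "H", "O", "H", "H"])
        back = read_frames(p)
        assert len(back) == 3
        for a, b in zip(frames, back):
            assert b.time == pytest.approx(a.time)
            np.testing.assert_allclose(b.coords, a.coords, atol=1e-6)
            np.testing.assert_allclose(b.box, a.box, atol=1e-6)

    def test_stride(self, tmp_path):
        frames = self._frames([0.0, 0.002, 0.004])
        p = tmp_path / "t.xyz"
        write_xyz_frames(p, frames, ["O"] * 6)
        got = read_frames(p, stride=2)
        assert [f.time for f in got] == pytest.approx([0.0, 0.004])

    def test_skipped_frame_time_errors(self, tmp_path):
        frames = self._frames([0.0, 0.002, 0.006])
        p = tmp_path / "t.xyz"
        write_xyz_frames(p, frames, ["O"] * 6)
        with pytest.raises(TrajectoryError, match="spacing"):
            read_frames(p)

    def test_atom_count_mismatch(self, tmp_path):
        frames = self._frames([0.0, 0.002])
        p = tmp_path / "t.xyz"
        write_xyz_frames(p, frames, ["O"] * 6)
        with pytest.raises(TrajectoryError, match="atoms"):
            read_frames(p, n_atoms=9)


def test_gro_round_trip(tmp_path):
    topo = water_like_topology(4)
    rng = np.random.default_rng(1)
    frames = [
        Frame(time=0.002 * i, box=np.full(3, 20.0), coords=rng.uniform(2, 18, (12, 3)))
        for i in range(3)
    ]
    p = tmp_path / "t.gro"
    write_gro_frames(p, frames, topo)
    back = read_frames(p)
    assert len(back) == 3
    for a, b in zip(frames, back):
        # GRO stores nm with 3 decimals: 0.01 Å printed precision
        np.testing.assert_allclose(b.coords, a.coords, atol=0.006)
        assert b.time == pytest.approx(a.time, abs=1e-5)


def test_role_counts_invariant_under_atom_reorder(tmp_path):
    orders = [
        [("OW", 0.5, 0.5, 0.5), ("HW1", 0.6, 0.5, 0.5), ("HW2", 0.5, 0.6, 0.5)],
        [("HW2", 0.5, 0.6, 0.5), ("OW", 0.5, 0.5, 0.5), ("HW1", 0.6, 0.5, 0.5)],
    ]
    counts = []
    for k, atoms in enumerate(orders):
        p = tmp_path / f"o{k}.gro"
        _write_gro(p, [("SOL", atoms)])
        topo = read_topology(p, WATER_SPEC)
        counts.append((len(topo.donor_map), len(topo.acceptors), int(topo.is_donor.sum())))
    assert counts[0] == counts[1]
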