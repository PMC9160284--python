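"""Molecular topology and trajectory I/O.

Carries species labels and hydrogen-bond roles (donor-heavy, donor-hydrogen,
acceptor-heavy, inert) from a structure file plus a role-assignment spec into
the in-memory :class:`SystemTopology`, and streams coordinate frames from
extended-XYZ or GRO trajectories as :class:`Frame` objects.

Internal units are Å and ps everywhere; converters sit at the I/O boundary
(GRO files are nm and are converted on read/write). Only orthorhombic boxes
are supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "TopologyError",
    "TrajectoryError",
    "SystemTopology",
    "Frame",
    "read_topology",
    "iter_frames",
    "read_frames",
    "write_xyz_frames",
    "write_gro_frames",
    "load_species_spec",
]

NM_TO_ANGSTROM = 10.0

#: recognised per-atom roles in a species spec
_ROLES = {"donor", "acceptor", "hydrogen", "inert"}


class TopologyError(ValueError):
    """Raised when a structure file or species spec is inconsistent."""


class TrajectoryError(ValueError):
    """Raised for malformed or non-uniform trajectories."""


@dataclass(frozen=True)
class Frame:
    """One trajectory snapshot: time [ps], orthorhombic box edges [Å],
    per-atom coordinates [Å]."""

    time: float
    box: np.ndarray  # (3,)
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        box = np.asarray(self.box, dtype=np.float64)
        coords = np.asarray(self.coords, dtype=np.float64)
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "coords", coords)
        if box.shape != (3,) or not np.all(box > 0):
            raise TrajectoryError(f"box edges must be 3 positive lengths, got {box}")
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError("non-finite coordinates in frame")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class SystemTopology:
    """Atoms, molecules, species labels and H-bond roles of one system.

    Atom order is identical to the source file.  Roles per atom:

    * ``is_donor`` — heavy atom carrying at least one covalent hydrogen
      available for donation (A_i of the geometric criterion);
    * ``is_acceptor`` — heavy atom able to receive a bond (B_j);
    * ``hydrogens``/``donor_of_hydrogen`` — every donor-hydrogen and the
      donor-heavy atom it rides on (an atom may be donor and acceptor at
      once, e.g. a hydroxyl oxygen).
    """

    atom_names: list[str]
    mol_of_atom: np.ndarray  # (n_atoms,) int molecule index
    species_of_mol: list[str]  # per molecule species label
    is_donor: np.ndarray  # (n_atoms,) bool
    is_acceptor: np.ndarray  # (n_atoms,) bool
    hydrogens: np.ndarray  # (n_h,) int atom indices of donor-hydrogens
    donor_of_hydrogen: np.ndarray  # (n_h,) int donor-heavy atom index

    def __post_init__(self) -> None:
        self.mol_of_atom = np.asarray(self.mol_of_atom, dtype=np.int64)
        self.is_donor = np.asarray(self.is_donor, dtype=bool)
        self.is_acceptor = np.asarray(self.is_acceptor, dtype=bool)
        self.hydrogens = np.asarray(self.hydrogens, dtype=np.int64)
        self.donor_of_hydrogen = np.asarray(self.donor_of_hydrogen, dtype=np.int64)
        for h, d in zip(self.hydrogens, self.donor_of_hydrogen):
            if self.mol_of_atom[h] != self.mol_of_atom[d]:
                raise TopologyError(
                    f"hydrogen {h} maps to donor-heavy atom {d} in another molecule"
                )
            if not self.is_donor[d]:
                raise TopologyError(f"atom {d} used as donor of hydrogen {h} lacks donor role")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_molecules(self) -> int:
        return len(self.species_of_mol)

    @property
    def donor_map(self) -> dict[int, int]:
        """donor-hydrogen atom index → its donor-heavy atom index."""
        return dict(zip(self.hydrogens.tolist(), self.donor_of_hydrogen.tolist()))

    @property
    def acceptors(self) -> np.ndarray:
        return np.flatnonzero(self.is_acceptor)

    @property
    def species_set(self) -> set[str]:
        return set(self.species_of_mol)

    def mole_fractions(self) -> dict[str, float]:
        """Mole fraction x of each species label over molecules."""
        labels, counts = np.unique(np.asarray(self.species_of_mol, dtype=object), return_counts=True)
        total = counts.sum()
        return {str(lab): float(c) / total for lab, c in zip(labels, counts)}

    def species_of_atom(self, atom: int) -> str:
        return self.species_of_mol[self.mol_of_atom[atom]]


def load_species_spec(spec: str | Path | Mapping) -> dict:
    """Load a species/role spec from a YAML path or accept a mapping.

    Schema::

        SOL:
          species: W
          roles:
            OW: [donor, acceptor]
            HW1: hydrogen
            HW2: hydrogen

    A role entry may be a string, a list of role strings, or a mapping
    ``{role: hydrogen, donor: <atom name>}`` when the donor-heavy partner is
    ambiguous (more than one donor-heavy atom in the molecule).
    """
    if isinstance(spec, (str, Path)):
        with open(spec) as fh:
            spec = yaml.safe_load(fh)
    if not isinstance(spec, Mapping):
        raise TopologyError("species spec must be a mapping of residue name -> roles")
    return dict(spec)


def _parse_role_entry(entry) -> tuple[set[str], str | None]:
    """Return (roles, explicit donor atom name or None) for one atom entry."""
    donor_name = None
    if isinstance(entry, str):
        roles = {entry}
    elif isinstance(entry, Mapping):
        role = entry.get("role", "hydrogen")
        roles = {role} if isinstance(role, str) else set(role)
        donor_name = entry.get("donor")
    else:
        roles = set(entry)
    bad = roles - _ROLES
    if bad:
        raise TopologyError(f"unknown role(s) {sorted(bad)}; allowed: {sorted(_ROLES)}")
    return roles, donor_name


def read_topology(path: str | Path, species_spec: str | Path | Mapping) -> SystemTopology:
    """Build a :class:`SystemTopology` from a GRO or PDB file plus a role spec.

    Molecules are the residues of the file; the spec assigns a species label
    and per-atom roles by residue name.  Raises :class:`TopologyError` for a
    residue name absent from the spec, an atom name absent from its residue's
    role map, or a donor-hydrogen without a donor-heavy partner in the same
    molecule.
    """
    import MDAnalysis as mda

    spec = load_species_spec(species_spec)
    with _quiet_mda():
        u = mda.Universe(str(path))

    atom_names: list[str] = [a.name for a in u.atoms]
    mol_of_atom = np.empty(len(u.atoms), dtype=np.int64)
    species_of_mol: list[str] = []
    is_donor = np.zeros(len(u.atoms), dtype=bool)
    is_acceptor = np.zeros(len(u.atoms), dtype=bool)
    hydrogens: list[int] = []
    donor_of_hydrogen: list[int] = []

    for mol_idx, res in enumerate(u.residues):
        resname = res.resname.strip()
        if resname not in spec:
            raise TopologyError(
                f"residue name {resname!r} has no entry in the species spec"
            )
        entry = spec[resname]
        species_of_mol.append(str(entry.get("species", resname)))
        role_map = entry.get("roles", {})
        donor_atoms: dict[str, int] = {}
        pending_h: list[tuple[int, str | None]] = []
        for atom in res.atoms:
            mol_of_atom[atom.ix] = mol_idx
            if atom.name not in role_map:
                raise TopologyError(
                    f"atom name {atom.name!r} of residue {resname!r} missing from role map"
                )
            roles, donor_name = _parse_role_entry(role_map[atom.name])
            if "donor" in roles:
                is_donor[atom.ix] = True
                donor_atoms[atom.name] = atom.ix
            if "acceptor" in roles:
                is_acceptor[atom.ix] = True
            if "hydrogen" in roles:
                pending_h.append((atom.ix, donor_name))
        for h_ix, donor_name in pending_h:
            if donor_name is not None:
                if donor_name not in donor_atoms:
                    raise TopologyError(
                        f"hydrogen {atom_names[h_ix]!r} of residue {resname!r} names donor "
                        f"{donor_name!r}, which is not a donor-heavy atom of the molecule"
                    )
                d_ix = donor_atoms[donor_name]
            elif len(donor_atoms) == 1:
                d_ix = next(iter(donor_atoms.values()))
            elif not donor_atoms:
                raise TopologyError(
                    f"donor-hydrogen {atom_names[h_ix]!r} of residue {resname!r} has no "
                    "donor-heavy partner in its molecule"
                )
            else:
                raise TopologyError(
                    f"residue {resname!r} has several donor-heavy atoms; hydrogen "
                    f"{atom_names[h_ix]!r} must name its donor explicitly"
                )
            hydrogens.append(h_ix)
            donor_of_hydrogen.append(d_ix)

    return SystemTopology(
        atom_names=atom_names,
        mol_of_atom=mol_of_atom,
        species_of_mol=species_of_mol,
        is_donor=is_donor,
        is_acceptor=is_acceptor,
        hydrogens=np.asarray(hydrogens, dtype=np.int64),
        donor_of_hydrogen=np.asarray(donor_of_hydrogen, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# trajectory reading


def iter_frames(
    path: str | Path,
    stride: int = 1,
    n_atoms: int | None = None,
) -> Iterator[Frame]:
    """Stream :class:`Frame` objects from a trajectory file.

    Supported text formats: extended-XYZ (comment line carrying ``Time=`` in
    ps and an orthorhombic ``Lattice=``) and multi-frame GRO (time from the
    GROMACS ``t=`` title token; nm converted to Å).  Any other extension is
    handed to MDAnalysis, with times taken from its reader.  Frames must be
    uniformly spaced in time; a skipped frame raises :class:`TrajectoryError`.
    ``stride`` keeps every stride-th frame, so the effective sampling interval
    is stride × the file spacing.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".xyz", ".extxyz"}:
        raw: Iterable[Frame] = _iter_xyz(path)
    elif suffix == ".gro":
        raw = _iter_gro(path)
    else:
        raw = _iter_mda(path)
    return _validated(raw, stride=stride, n_atoms=n_atoms)


def read_frames(path: str | Path, stride: int = 1, n_atoms: int | None = None) -> list[Frame]:
    """Materialise :func:`iter_frames` into a list."""
    return list(iter_frames(path, stride=stride, n_atoms=n_atoms))


def _validated(frames: Iterable[Frame], stride: int, n_atoms: int | None) -> Iterator[Frame]:
    dt: float | None = None
    prev_time: float | None = None
    kept = 0
    for i, frame in enumerate(frames):
        if n_atoms is not None and frame.n_atoms != n_atoms:
            raise TrajectoryError(
                f"frame {i} has {frame.n_atoms} atoms, topology has {n_atoms}"
            )
        if prev_time is not None:
            gap = frame.time - prev_time
            if gap <= 0:
                raise TrajectoryError(f"frame times not strictly increasing at frame {i}")
            if dt is None:
                dt = gap
            elif not math.isclose(gap, dt, rel_tol=1e-6, abs_tol=1e-12):
                raise TrajectoryError(
                    f"non-uniform frame spacing at frame {i}: {gap:g} ps vs {dt:g} ps"
                )
        prev_time = frame.time
        if i % stride == 0:
            kept += 1
            yield frame


def _parse_lattice(token: str) -> np.ndarray:
    vals = [float(v) for v in token.split()]
    if len(vals) != 9:
        raise TrajectoryError("Lattice= must list 9 numbers")
    mat = np.asarray(vals, dtype=np.float64).reshape(3, 3)
    off = mat - np.diag(np.diag(mat))
    if np.any(np.abs(off) > 1e-9):
        raise TrajectoryError("only orthorhombic (diagonal Lattice) boxes are supported")
    return np.diag(mat).copy()


def _parse_comment(line: str) -> dict[str, str]:
    """key=value pairs with possible double-quoted values."""
    out: dict[str, str] = {}
    i, n = 0, len(line)
    while i < n:
        eq = line.find("=", i)
        if eq < 0:
            break
        key = line[i:eq].strip().split()[-1]
        j = eq + 1
        if j < n and line[j] == '"':
            end = line.find('"', j + 1)
            out[key] = line[j + 1 : end]
            i = end + 1
        else:
            end = line.find(" ", j)
            if end < 0:
                end = n
            out[key] = line[j:end]
            i = end
    return out


def _iter_xyz(path: Path) -> Iterator[Frame]:
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                return
            n = int(header)
            meta = _parse_comment(fh.readline())
            if "Time" not in meta:
                raise TrajectoryError(f"{path}: extended-XYZ comment lacks a Time= token")
            if "Lattice" not in meta:
                raise TrajectoryError(f"{path}: extended-XYZ comment lacks a Lattice= token")
            box = _parse_lattice(meta["Lattice"])
            coords = np.empty((n, 3), dtype=np.float64)
            for k in range(n):
                parts = fh.readline().split()
                coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            yield Frame(time=float(meta["Time"]), box=box, coords=coords)


def _iter_gro(path: Path) -> Iterator[Frame]:
    with open(path) as fh:
        while True:
            title = fh.readline()
            if not title.strip():
                return
            time = 0.0
            if "t=" in title:
                time = float(title.rsplit("t=", 1)[1].split()[0])
            n = int(fh.readline())
            coords = np.empty((n, 3), dtype=np.float64)
            for k in range(n):
                line = fh.readline()
                # fixed columns: positions start at char 20, 8 chars each (nm)
                coords[k] = [
                    float(line[20:28]),
                    float(line[28:36]),
                    float(line[36:44]),
                ]
            box_vals = [float(v) for v in fh.readline().split()]
            if len(box_vals) > 3 and any(abs(v) > 1e-12 for v in box_vals[3:]):
                raise TrajectoryError("only orthorhombic boxes are supported (triclinic GRO)")
            box = np.asarray(box_vals[:3]) * NM_TO_ANGSTROM
            yield Frame(time=time, box=box, coords=coords * NM_TO_ANGSTROM)


def _iter_mda(path: Path) -> Iterator[Frame]:
    import MDAnalysis as mda

    with _quiet_mda():
        u = mda.Universe(str(path))
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or not np.all(np.abs(dims[3:] - 90.0) < 1e-6):
            raise TrajectoryError("only orthorhombic boxes are supported")
        yield Frame(time=float(ts.time), box=dims[:3].astype(np.float64),
                    coords=ts.positions.astype(np.float64))


# ---------------------------------------------------------------------------
# trajectory writing


def write_xyz_frames(
    path: str | Path,
    frames: Sequence[Frame] | Iterable[Frame],
    symbols: Sequence[str],
) -> None:
    """Write frames as extended-XYZ with ``Lattice=`` and ``Time=`` tokens."""
    with open(path, "w") as fh:
        for frame in frames:
            lat = " ".join(
                f"{v:.6f}" for v in np.diag(frame.box).reshape(-1)
            )
            fh.write(f"{frame.n_atoms}\n")
            fh.write(
                f'Lattice="{lat}" Properties=species:S:1:pos:R:3 Time={frame.time:.6f}\n'
            )
            for sym, (x, y, z) in zip(symbols, frame.coords):
                fh.write(f"{sym} {x:.6f} {y:.6f} {z:.6f}\n")


def write_gro_frames(
    path: str | Path,
    frames: Sequence[Frame] | Iterable[Frame],
    topo: SystemTopology,
    resnames: Mapping[str, str] | None = None,
) -> None:
    """Write frames as a (multi-frame) GRO file, converting Å → nm.

    ``resnames`` maps species label → residue name; defaults to the label
    itself (padded/truncated to 5 chars).
    """
    resnames = dict(resnames or {})
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"hblife t= {frame.time:.5f}\n{frame.n_atoms}\n")
            for i in range(frame.n_atoms):
                mol = int(topo.mol_of_atom[i])
                species = topo.species_of_mol[mol]
                resname = resnames.get(species, species)[:5]
                name = topo.atom_names[i][:5]
                x, y, z = frame.coords[i] / NM_TO_ANGSTROM
                fh.write(
                    f"{(mol + 1) % 100000:5d}{resname:<5s}{name:>5s}"
                    f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = frame.box / NM_TO_ANGSTROM
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


class _quiet_mda:
    """Suppress MDAnalysis' chatty UserWarnings about guessed attributes."""

    def __enter__(self):
        import warnings

        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        warnings.simplefilter("ignore")
        return self

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)
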