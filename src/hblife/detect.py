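"""Geometric hydrogen-bond detection under periodic boundaries.

A donor–hydrogen–acceptor triplet (D, H, A) is bonded in a frame when the
minimum-image distance D···A is ≤ r_C and the angle at D between the D→H and
D→A vectors is ≤ θ_C (both comparisons inclusive).  Intra-molecular pairs are
excluded.  Bond identity is the atom triplet, not the molecule pair: a water
donating both hydrogens to the same acceptor counts as two bonds with
independent lifetimes.

Two spatial-search paths exist — an O(N²) all-pairs loop and a cell list with
cell edge ≥ r_C — and they agree bit-exactly because both use the same
distance/cosine arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from numba import njit

from .topology import Frame, SystemTopology, TrajectoryError

__all__ = [
    "HBondCriteria",
    "BondTriplet",
    "BondSeries",
    "detect_hbonds",
    "detect_series",
    "iter_candidates",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric bonding criterion: distance cutoff r_C [Å] and donor-angle
    cutoff θ_C [degrees]."""

    r_c: float = 3.5
    theta_c: float = 30.0

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if not 0 < self.theta_c <= 180:
            raise ValueError("theta_c must lie in (0, 180] degrees")

    @property
    def cos_theta_c(self) -> float:
        return float(np.cos(np.deg2rad(self.theta_c)))


class BondTriplet(NamedTuple):
    """One candidate hydrogen bond: atom indices and its symmetric
    species-pair label (alphabetically sorted, so W–M ≡ M–W)."""

    donor: int
    hydrogen: int
    acceptor: int
    species_pair: tuple[str, str]


def species_pair_label(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _min_image(dx, dy, dz, bx, by, bz):
    dx -= bx * np.rint(dx / bx)
    dy -= by * np.rint(dy / by)
    dz -= bz * np.rint(dz / bz)
    return dx, dy, dz


@njit(cache=True)
def _pairs_allpairs(coords, box, hydrogens, donors, acceptors, mol_of_atom,
                    r_c, cos_tc):
    """All-pairs scan. Returns (h_slot, a_slot, distance) arrays for every
    triplet satisfying both criteria."""
    n_h = hydrogens.shape[0]
    n_a = acceptors.shape[0]
    bx, by, bz = box[0], box[1], box[2]
    out_h = np.empty(n_h * 4 + 16, dtype=np.int64)
    out_a = np.empty(n_h * 4 + 16, dtype=np.int64)
    out_d = np.empty(n_h * 4 + 16, dtype=np.float64)
    m = 0
    for ih in range(n_h):
        h = hydrogens[ih]
        d = donors[ih]
        dmol = mol_of_atom[d]
        dxh = coords[h, 0] - coords[d, 0]
        dyh = coords[h, 1] - coords[d, 1]
        dzh = coords[h, 2] - coords[d, 2]
        dxh, dyh, dzh = _min_image(dxh, dyh, dzh, bx, by, bz)
        nh = np.sqrt(dxh * dxh + dyh * dyh + dzh * dzh)
        for ia in range(n_a):
            a = acceptors[ia]
            if mol_of_atom[a] == dmol:
                continue
            dx = coords[a, 0] - coords[d, 0]
            dy = coords[a, 1] - coords[d, 1]
            dz = coords[a, 2] - coords[d, 2]
            dx, dy, dz = _min_image(dx, dy, dz, bx, by, bz)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > r_c * r_c:
                continue
            r = np.sqrt(r2)
            cosang = (dx * dxh + dy * dyh + dz * dzh) / (r * nh)
            if cosang >= cos_tc:
                if m >= out_h.shape[0]:
                    new_h = np.empty(out_h.shape[0] * 2, dtype=np.int64)
                    new_a = np.empty(out_h.shape[0] * 2, dtype=np.int64)
                    new_d = np.empty(out_h.shape[0] * 2, dtype=np.float64)
                    new_h[:m] = out_h[:m]
                    new_a[:m] = out_a[:m]
                    new_d[:m] = out_d[:m]
                    out_h, out_a, out_d = new_h, new_a, new_d
                out_h[m] = ih
                out_a[m] = ia
                out_d[m] = r
                m += 1
    return out_h[:m], out_a[:m], out_d[:m]


@njit(cache=True)
def _pairs_cells(coords, box, hydrogens, donors, acceptors, mol_of_atom,
                 r_c, cos_tc):
    """Cell-list scan: acceptors binned into cells of edge ≥ r_c; each
    donor checks its 27 neighbouring cells.  Same arithmetic as the
    all-pairs path, so results are bit-identical."""
    n_h = hydrogens.shape[0]
    n_a = acceptors.shape[0]
    bx, by, bz = box[0], box[1], box[2]
    ncx = max(1, int(bx / r_c))
    ncy = max(1, int(by / r_c))
    ncz = max(1, int(bz / r_c))
    ncells = ncx * ncy * ncz

    cell_of = np.empty(n_a, dtype=np.int64)
    counts = np.zeros(ncells + 1, dtype=np.int64)
    for ia in range(n_a):
        a = acceptors[ia]
        x = coords[a, 0] % bx
        y = coords[a, 1] % by
        z = coords[a, 2] % bz
        cx = min(int(x / bx * ncx), ncx - 1)
        cy = min(int(y / by * ncy), ncy - 1)
        cz = min(int(z / bz * ncz), ncz - 1)
        c = (cx * ncy + cy) * ncz + cz
        cell_of[ia] = c
        counts[c + 1] += 1
    for c in range(ncells):
        counts[c + 1] += counts[c]
    order = np.empty(n_a, dtype=np.int64)
    fill = counts.copy()
    for ia in range(n_a):
        c = cell_of[ia]
        order[fill[c]] = ia
        fill[c] += 1

    out_h = np.empty(n_h * 4 + 16, dtype=np.int64)
    out_a = np.empty(n_h * 4 + 16, dtype=np.int64)
    out_d = np.empty(n_h * 4 + 16, dtype=np.float64)
    m = 0
    for ih in range(n_h):
        h = hydrogens[ih]
        d = donors[ih]
        dmol = mol_of_atom[d]
        dxh = coords[h, 0] - coords[d, 0]
        dyh = coords[h, 1] - coords[d, 1]
        dzh = coords[h, 2] - coords[d, 2]
        dxh, dyh, dzh = _min_image(dxh, dyh, dzh, bx, by, bz)
        nh = np.sqrt(dxh * dxh + dyh * dyh + dzh * dzh)
        x = coords[d, 0] % bx
        y = coords[d, 1] % by
        z = coords[d, 2] % bz
        cx = min(int(x / bx * ncx), ncx - 1)
        cy = min(int(y / by * ncy), ncy - 1)
        cz = min(int(z / bz * ncz), ncz - 1)
        for ox in range(-1, 2):
            ccx = (cx + ox) % ncx
            for oy in range(-1, 2):
                ccy = (cy + oy) % ncy
                for oz in range(-1, 2):
                    ccz = (cz + oz) % ncz
                    c = (ccx * ncy + ccy) * ncz + ccz
                    for k in range(counts[c], counts[c + 1]):
                        ia = order[k]
                        a = acceptors[ia]
                        if mol_of_atom[a] == dmol:
                            continue
                        dx = coords[a, 0] - coords[d, 0]
                        dy = coords[a, 1] - coords[d, 1]
                        dz = coords[a, 2] - coords[d, 2]
                        dx, dy, dz = _min_image(dx, dy, dz, bx, by, bz)
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 > r_c * r_c:
                            continue
                        r = np.sqrt(r2)
                        cosang = (dx * dxh + dy * dyh + dz * dzh) / (r * nh)
                        if cosang >= cos_tc:
                            if m >= out_h.shape[0]:
                                new_h = np.empty(out_h.shape[0] * 2, dtype=np.int64)
                                new_a = np.empty(out_h.shape[0] * 2, dtype=np.int64)
                                new_d = np.empty(out_h.shape[0] * 2, dtype=np.float64)
                                new_h[:m] = out_h[:m]
                                new_a[:m] = out_a[:m]
                                new_d[:m] = out_d[:m]
                                out_h, out_a, out_d = new_h, new_a, new_d
                            out_h[m] = ih
                            out_a[m] = ia
                            out_d[m] = r
                            m += 1
    return out_h[:m], out_a[:m], out_d[:m]


def _find_pairs(frame: Frame, topo: SystemTopology, r_c: float, cos_tc: float,
                method: str = "auto"):
    """Dispatch to the cell list when each box dimension holds ≥ 3 cells of
    edge r_c, otherwise all-pairs (the cell loop would double-count)."""
    coords = np.ascontiguousarray(frame.coords)
    box = frame.box
    acceptors = topo.acceptors
    if method == "auto":
        ncells = np.floor(box / r_c).astype(int)
        method = "cells" if np.all(ncells >= 3) and len(acceptors) > 64 else "allpairs"
    kernel = _pairs_cells if method == "cells" else _pairs_allpairs
    ih, ia, dist = kernel(
        coords, box, topo.hydrogens, topo.donor_of_hydrogen, acceptors,
        topo.mol_of_atom, float(r_c), float(cos_tc),
    )
    # deterministic order independent of search path
    key = ih * (len(acceptors) + 1) + ia
    srt = np.argsort(key, kind="stable")
    return ih[srt], ia[srt], dist[srt]


def _make_triplet(topo: SystemTopology, ih: int, ia: int) -> BondTriplet:
    h = int(topo.hydrogens[ih])
    d = int(topo.donor_of_hydrogen[ih])
    a = int(topo.acceptors[ia])
    return BondTriplet(
        donor=d, hydrogen=h, acceptor=a,
        species_pair=species_pair_label(topo.species_of_atom(d), topo.species_of_atom(a)),
    )


def detect_hbonds(
    frame: Frame,
    topo: SystemTopology,
    crit: HBondCriteria = HBondCriteria(),
    method: str = "auto",
) -> set[BondTriplet]:
    """Hydrogen bonds of one frame under the geometric criterion.

    The result is invariant under any rigid translation of all coordinates
    modulo the box, and distance ties (r exactly r_C) count as bonded.
    """
    ih, ia, _ = _find_pairs(frame, topo, crit.r_c, crit.cos_theta_c, method)
    return {_make_triplet(topo, int(i), int(j)) for i, j in zip(ih, ia)}


def iter_candidates(
    frames: Iterable[Frame],
    topo: SystemTopology,
    theta_c: float,
    r_max: float,
    method: str = "auto",
) -> Iterator[tuple[float, np.ndarray, np.ndarray, np.ndarray]]:
    """Per frame, yield ``(time, h_slot, acceptor_slot, distance)`` for every
    triplet passing the angle test with distance ≤ r_max.

    Downstream r_c scans re-threshold the distances, which is identical to
    re-detection at each smaller cutoff because the angle test does not
    depend on r_c.
    """
    cos_tc = HBondCriteria(r_c=r_max, theta_c=theta_c).cos_theta_c
    for frame in frames:
        ih, ia, dist = _find_pairs(frame, topo, r_max, cos_tc, method)
        yield frame.time, ih, ia, dist


@dataclass
class BondSeries:
    """Boolean bond matrix (triplet × frame) with its triplet index, frame
    times [ps] and sampling interval Δt_save [ps]."""

    matrix: np.ndarray  # (n_triplets, n_frames) bool
    triplets: list[BondTriplet]
    times: np.ndarray
    dt: float

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    def episodes_frame(self):
        """Tabular episode export: one row per contiguous bonded run."""
        import pandas as pd

        from .lifetime import extract_intervals

        rows = []
        for iv in extract_intervals(self, self.dt):
            rows.append(
                {
                    "donor": iv.triplet.donor,
                    "hydrogen": iv.triplet.hydrogen,
                    "acceptor": iv.triplet.acceptor,
                    "species_pair": "-".join(iv.triplet.species_pair),
                    "t_start": iv.t_start,
                    "t_end": iv.t_end,
                    "lifetime": iv.lifetime,
                    "censored_left": iv.censored_left,
                    "censored_right": iv.censored_right,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "donor", "hydrogen", "acceptor", "species_pair",
                "t_start", "t_end", "lifetime", "censored_left", "censored_right",
            ],
        )


def detect_series(
    frames: Sequence[Frame] | Iterable[Frame],
    topo: SystemTopology,
    crit: HBondCriteria = HBondCriteria(),
    method: str = "auto",
) -> BondSeries:
    """Apply :func:`detect_hbonds` frame by frame into a boolean bond matrix.

    Column f equals the detection of frame f; triplets never bonded anywhere
    are absent.  Frames must be uniformly spaced in time.
    """
    per_frame: list[tuple[float, np.ndarray, np.ndarray]] = []
    index: dict[tuple[int, int], int] = {}
    for time, ih, ia, _ in iter_candidates(frames, topo, crit.theta_c, crit.r_c, method):
        for i, j in zip(ih, ia):
            key = (int(i), int(j))
            if key not in index:
                index[key] = len(index)
        per_frame.append((time, ih, ia))
    if not per_frame:
        raise TrajectoryError("detect_series requires at least one frame")
    times = np.array([t for t, _, _ in per_frame])
    if len(times) > 1:
        gaps = np.diff(times)
        if not np.allclose(gaps, gaps[0], rtol=1e-6, atol=1e-12):
            raise TrajectoryError("non-uniform frame spacing")
        dt = float(gaps[0])
    else:
        dt = 0.0
    matrix = np.zeros((len(index), len(per_frame)), dtype=bool)
    for f, (_, ih, ia) in enumerate(per_frame):
        for i, j in zip(ih, ia):
            matrix[index[(int(i), int(j))], f] = True
    triplets = [None] * len(index)
    for (i, j), row in index.items():
        triplets[row] = _make_triplet(topo, i, j)
    return BondSeries(matrix=matrix, triplets=triplets, times=times, dt=dt)
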