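"""Species-pair radial distribution functions g(r).

The first maximum and following minimum of g_OO(r) anchor the choice of the
bonding cutoff r_c: cutoffs below the first maximum see only tight dimers,
cutoffs near the first minimum capture the whole first coordination shell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .topology import Frame, SystemTopology

__all__ = ["RadialDistribution", "compute_rdf", "locate_extrema", "NoStructure"]


class NoStructure(Exception):
    """g(r) has no first maximum exceeding 1 (e.g. an ideal gas)."""


@dataclass
class RadialDistribution:
    """Binned pair correlation g(r) for one species-pair atom selection."""

    r_centers: np.ndarray  # Å
    g: np.ndarray  # dimensionless
    species_pair: tuple[str, str] | None = None
    bin_width: float = 0.0
    n_frames: int = 0
    raw_counts: np.ndarray | None = None

    def first_shell(self, smooth_window: int = 3) -> tuple[float, float]:
        return locate_extrema(self, smooth_window)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"r": self.r_centers, "g": self.g})

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.r_centers, self.g, **kwargs)
        ax.set_xlabel("r [Å]")
        ax.set_ylabel("g(r)")
        return ax


@njit(cache=True)
def _rdf_like(coords, idx, box, r_max, n_bins):
    counts = np.zeros(n_bins, dtype=np.int64)
    bx, by, bz = box[0], box[1], box[2]
    n = idx.shape[0]
    for i in range(n):
        a = idx[i]
        for j in range(i + 1, n):
            b = idx[j]
            dx = coords[b, 0] - coords[a, 0]
            dy = coords[b, 1] - coords[a, 1]
            dz = coords[b, 2] - coords[a, 2]
            dx -= bx * np.rint(dx / bx)
            dy -= by * np.rint(dy / by)
            dz -= bz * np.rint(dz / bz)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < r_max:
                k = int(r / r_max * n_bins)
                counts[k] += 1
    return counts


@njit(cache=True)
def _rdf_cross(coords, idx_a, idx_b, box, r_max, n_bins):
    counts = np.zeros(n_bins, dtype=np.int64)
    bx, by, bz = box[0], box[1], box[2]
    for i in range(idx_a.shape[0]):
        a = idx_a[i]
        for j in range(idx_b.shape[0]):
            b = idx_b[j]
            if a == b:
                continue
            dx = coords[b, 0] - coords[a, 0]
            dy = coords[b, 1] - coords[a, 1]
            dz = coords[b, 2] - coords[a, 2]
            dx -= bx * np.rint(dx / bx)
            dy -= by * np.rint(dy / by)
            dz -= bz * np.rint(dz / bz)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < r_max:
                k = int(r / r_max * n_bins)
                counts[k] += 1
    return counts


def compute_rdf(
    frames: Sequence[Frame] | Iterable[Frame],
    topo_or_indices,
    species_pair: tuple[str, str] | None = None,
    r_max: float | None = None,
    bin_width: float = 0.02,
    selection: str = "acceptor",
) -> RadialDistribution:
    """Pair-count g(r) between two atom selections under minimum image.

    ``topo_or_indices`` is either a :class:`SystemTopology` (atoms selected
    by species and role, default the acceptor-heavy atoms — the oxygens of
    g_OO) or a pair of explicit index arrays.  Normalization is the standard
    ideal-gas one: N(N−1)/2 distinct pairs for a like pair, N_a·N_b for a
    cross pair.  ``r_max`` defaults to min(10 Å, half the smallest box edge)
    and may not exceed the latter.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("compute_rdf needs at least one frame")
    box = frames[0].box
    half_box = float(box.min()) / 2.0
    if r_max is None:
        r_max = min(10.0, half_box)
    if r_max > half_box + 1e-9:
        raise ValueError(f"r_max {r_max} Å exceeds half the smallest box edge {half_box:.3f} Å")

    if isinstance(topo_or_indices, SystemTopology):
        topo = topo_or_indices
        if species_pair is None:
            species = sorted(topo.species_set)
            species_pair = (species[0], species[0])
        role = topo.is_acceptor if selection == "acceptor" else np.ones(topo.n_atoms, bool)
        spec_of_atom = np.array([topo.species_of_atom(i) for i in range(topo.n_atoms)], dtype=object)
        idx_a = np.flatnonzero(role & (spec_of_atom == species_pair[0]))
        idx_b = np.flatnonzero(role & (spec_of_atom == species_pair[1]))
    else:
        idx_a, idx_b = (np.asarray(v, dtype=np.int64) for v in topo_or_indices)

    like = np.array_equal(idx_a, idx_b)
    n_bins = int(round(r_max / bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    volume = 0.0
    for frame in frames:
        c = np.ascontiguousarray(frame.coords)
        if like:
            counts += _rdf_like(c, idx_a, frame.box, float(r_max), n_bins)
        else:
            counts += _rdf_cross(c, idx_a, idx_b, frame.box, float(r_max), n_bins)
        volume += float(np.prod(frame.box))
    volume /= len(frames)

    edges = np.linspace(0.0, r_max, n_bins + 1)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_pairs = len(idx_a) * (len(idx_a) - 1) / 2.0 if like else float(len(idx_a) * len(idx_b))
    if n_pairs == 0:
        raise ValueError("empty atom selection for g(r)")
    ideal = shell / volume * n_pairs * len(frames)
    g = counts / ideal
    return RadialDistribution(
        r_centers=0.5 * (edges[1:] + edges[:-1]), g=g,
        species_pair=species_pair, bin_width=bin_width,
        n_frames=len(frames), raw_counts=counts,
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(np.float64)
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.concatenate([np.repeat(y[0], pad), y, np.repeat(y[-1], pad)])
    return np.convolve(ypad, kernel, mode="valid")[: len(y)]


def locate_extrema(rdf: RadialDistribution, smooth_window: int = 3) -> tuple[float, float]:
    """First local maximum of g(r) with g > 1 and the following local minimum.

    The curve is smoothed with a centered moving average before extremum
    search; ties break toward smaller r.  Raises :class:`NoStructure` when no
    qualifying maximum exists (flat or gas-like g).
    """
    if rdf.g.size < 3:
        raise NoStructure("g(r) has too few bins")
    y = _smooth(rdf.g, smooth_window)
    r = rdf.r_centers
    i_max = None
    for i in range(1, len(y) - 1):
        if y[i] > 1.0 and y[i] > y[i - 1] and y[i] >= y[i + 1]:
            i_max = i
            break
    if i_max is None:
        raise NoStructure("g(r) shows no first maximum above 1")
    i_min = None
    for i in range(i_max + 1, len(y) - 1):
        if y[i] < y[i - 1] and y[i] <= y[i + 1]:
            i_min = i
            break
    if i_min is None:
        i_min = int(i_max + np.argmin(y[i_max:]))
    return float(r[i_max]), float(r[i_min])
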