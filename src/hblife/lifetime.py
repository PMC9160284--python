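"""Hydrogen-bond lifetimes and the normalized lifetime distribution L(t).

An uninterrupted run of bonded frames is one episode; its lifetime is

    τ = (f_last − f_first + 1) × Δt_save,

i.e. the episode's frame count times the sampling interval, so a single-frame
bond has τ = Δt_save and Σ τ equals total bonded time.  Episodes touching
either end of the measurement window are censored (their τ is only a lower
bound) and are excluded from L(t) by default.

L(t) is the histogram of lifetimes divided by (count × bin width), so its
Riemann sum is exactly one; the normalization constant Λ = count × bin width.
Resolved by species pair, distance cutoff r_c and mixture composition x, it
is the curve family L_ab(t, x, r_c) whose maxima the peak classifier labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .detect import BondSeries, BondTriplet, HBondCriteria, iter_candidates, species_pair_label
from .topology import Frame, SystemTopology

__all__ = [
    "BondInterval",
    "LifetimeDistribution",
    "extract_intervals",
    "compute_L",
    "scan_rc",
    "export_tail",
]


@dataclass(frozen=True)
class BondInterval:
    """One contiguous H-bond episode of a donor–hydrogen–acceptor triplet."""

    triplet: BondTriplet | None
    t_start: float  # ps, time of first bonded frame
    t_end: float  # ps, time of last bonded frame
    lifetime: float  # ps, (frame count) × Δt_save
    censored_left: bool
    censored_right: bool

    @property
    def censored(self) -> bool:
        return self.censored_left or self.censored_right


def extract_intervals(
    bond_matrix: BondSeries | np.ndarray,
    dt: float | None = None,
    triplets: Sequence[BondTriplet] | None = None,
    times: np.ndarray | None = None,
) -> list[BondInterval]:
    """Maximal runs of consecutive bonded frames, one :class:`BondInterval`
    per run.  Any single non-bonded frame terminates an episode (strict
    continuity).  Accepts a :class:`BondSeries` or a raw boolean matrix plus
    Δt_save."""
    if isinstance(bond_matrix, BondSeries):
        series = bond_matrix
        matrix = series.matrix
        dt = series.dt if dt is None else dt
        triplets = series.triplets if triplets is None else triplets
        times = series.times if times is None else times
    else:
        matrix = np.asarray(bond_matrix, dtype=bool)
    if dt is None or dt <= 0:
        raise ValueError("extract_intervals needs a positive Δt_save")
    n_frames = matrix.shape[1]
    if times is None:
        times = np.arange(n_frames) * dt
    out: list[BondInterval] = []
    for row in range(matrix.shape[0]):
        trip = triplets[row] if triplets is not None else None
        bonded = matrix[row]
        # run-length encode: starts where False→True, ends where True→False
        padded = np.concatenate(([False], bonded, [False]))
        flips = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = flips[::2], flips[1::2] - 1
        for f0, f1 in zip(starts, ends):
            out.append(
                BondInterval(
                    triplet=trip,
                    t_start=float(times[f0]),
                    t_end=float(times[f1]),
                    lifetime=(int(f1) - int(f0) + 1) * dt,
                    censored_left=bool(f0 == 0),
                    censored_right=bool(f1 == n_frames - 1),
                )
            )
    return out


@dataclass
class LifetimeDistribution:
    """Binned, normalized lifetime distribution L(t) for one species pair,
    cutoff r_c and composition x.

    ``density`` integrates (Riemann sum over ``bin_width``) to exactly one
    whenever ``n_intervals`` > 0; Λ = n_intervals × bin_width.
    """

    bin_centers: np.ndarray  # ps
    density: np.ndarray  # 1/ps
    lam: float  # Λ, normalization constant [ps]
    T0: float  # measurement window [ps]
    bin_width: float  # ps
    species_pair: tuple[str, str] | None = None
    r_c: float | None = None
    x: float | None = None
    n_intervals: int = 0
    n_censored: int = 0

    @property
    def is_empty(self) -> bool:
        return self.n_intervals == 0

    def integral(self) -> float:
        return float(self.density.sum() * self.bin_width)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.bin_centers, "L": self.density})

    def metadata(self) -> dict:
        return {
            "lambda": self.lam,
            "T0": self.T0,
            "bin_width": self.bin_width,
            "species_pair": list(self.species_pair) if self.species_pair else None,
            "r_c": self.r_c,
            "x": self.x,
            "n_intervals": self.n_intervals,
            "n_censored": self.n_censored,
        }

    def plot(self, ax=None, **kwargs):
        """Plot L(t) [1/ps] versus t [ps]."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = kwargs.pop("label", None)
        if label is None and self.r_c is not None:
            label = f"r_c = {self.r_c:g} Å"
        ax.plot(self.bin_centers, self.density, label=label, **kwargs)
        ax.set_xlabel("t [ps]")
        ax.set_ylabel("L(t) [1/ps]")
        return ax


def _bin_taus(taus: np.ndarray, T0: float, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram lifetimes into right-closed bins (0, bw], (bw, 2bw], ...

    Lifetimes are exact multiples of Δt_save; the 1e-9 relative guard keeps a
    τ that is numerically k·bw + ε in bin k.
    """
    n_bins = max(1, int(math.ceil(T0 / bin_width - 1e-9)))
    centers = (np.arange(n_bins) + 0.5) * bin_width
    idx = np.ceil(taus / bin_width - 1e-9).astype(np.int64) - 1
    if taus.size and (idx.min() < 0 or idx.max() >= n_bins):
        raise ValueError("lifetime outside (0, T0]; increase T0")
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    return centers, counts


def _distribution_from_taus(
    taus: np.ndarray,
    T0: float,
    bin_width: float,
    species_pair=None,
    r_c=None,
    x=None,
    n_censored: int = 0,
) -> LifetimeDistribution:
    taus = np.asarray(taus, dtype=np.float64)
    n = taus.size
    if n == 0:
        n_bins = max(1, int(math.ceil(T0 / bin_width - 1e-9)))
        centers = (np.arange(n_bins) + 0.5) * bin_width
        return LifetimeDistribution(
            bin_centers=centers, density=np.zeros(n_bins), lam=0.0, T0=T0,
            bin_width=bin_width, species_pair=species_pair, r_c=r_c, x=x,
            n_intervals=0, n_censored=n_censored,
        )
    centers, counts = _bin_taus(taus, T0, bin_width)
    lam = n * bin_width
    return LifetimeDistribution(
        bin_centers=centers, density=counts / lam, lam=lam, T0=T0,
        bin_width=bin_width, species_pair=species_pair, r_c=r_c, x=x,
        n_intervals=int(n), n_censored=n_censored,
    )


def compute_L(
    intervals: Iterable[BondInterval],
    T0: float,
    bin_width: float,
    species_pair: tuple[str, str] | str | None = None,
    drop_censored: bool = True,
    r_c: float | None = None,
    x: float | None = None,
) -> LifetimeDistribution:
    """Build the normalized L(t) from a set of bond intervals.

    ``species_pair`` restricts to one (symmetric) pair label; censored
    intervals are excluded unless ``drop_censored`` is False.  Zero usable
    intervals yield an empty-distribution marker, never a division by zero.
    """
    if isinstance(species_pair, str):
        parts = species_pair.split("-")
        species_pair = species_pair_label(*parts) if len(parts) == 2 else (species_pair,) * 2
    elif species_pair is not None:
        species_pair = species_pair_label(*species_pair)
    taus = []
    n_censored = 0
    for iv in intervals:
        if species_pair is not None and iv.triplet is not None:
            if iv.triplet.species_pair != species_pair:
                continue
        if iv.censored:
            n_censored += 1
            if drop_censored:
                continue
        taus.append(iv.lifetime)
    return _distribution_from_taus(
        np.asarray(taus), T0, bin_width, species_pair=species_pair,
        r_c=r_c, x=x, n_censored=n_censored,
    )


def scan_rc(
    frames: Sequence[Frame] | Iterable[Frame],
    topo: SystemTopology,
    theta_c: float,
    rc_list: Sequence[float],
    species_pairs: Sequence[tuple[str, str]] | None = None,
    bin_width: float | None = None,
    T0: float | None = None,
    drop_censored: bool = True,
    method: str = "auto",
) -> dict[tuple[tuple[str, str], float], LifetimeDistribution]:
    """Lifetime distributions for a family of distance cutoffs in one pass.

    Detection runs once at max(rc_list); smaller cutoffs re-threshold the
    stored donor–acceptor distances, which is exactly equivalent to separate
    detection passes because the angle criterion is r_c-independent.  Every
    distribution is normalized independently.  Returns a dict keyed by
    ``(species_pair, r_c)``.
    """
    rc_list = sorted(float(r) for r in rc_list)
    if not rc_list:
        raise ValueError("rc_list must be non-empty")
    HBondCriteria(r_c=rc_list[0], theta_c=theta_c)  # validate
    fractions = topo.mole_fractions()
    wanted = {species_pair_label(*p) for p in species_pairs} if species_pairs is not None else None
    n_acc = len(topo.acceptors)
    pair_of_slot: dict[tuple[int, int], tuple[str, str]] = {}

    # per rc: active runs {key: start_frame}; collected taus per (pair, rc)
    active: list[dict[int, int]] = [dict() for _ in rc_list]
    taus: dict[tuple[tuple[str, str], float], list[float]] = {}
    ncens: dict[tuple[tuple[str, str], float], int] = {}

    def pair_label(key: int) -> tuple[str, str]:
        ih, ia = divmod(key, n_acc + 1)
        slot = (ih, ia)
        lab = pair_of_slot.get(slot)
        if lab is None:
            d = int(topo.donor_of_hydrogen[ih])
            a = int(topo.acceptors[ia])
            lab = species_pair_label(topo.species_of_atom(d), topo.species_of_atom(a))
            pair_of_slot[slot] = lab
        return lab

    def close(rc_i: int, key: int, start: int, end: int, n_frames_total: int | None):
        lab = pair_label(key)
        if wanted is not None and lab not in wanted:
            return
        k = (lab, rc_list[rc_i])
        cen = start == 0 or (n_frames_total is not None and end == n_frames_total - 1)
        if cen:
            ncens[k] = ncens.get(k, 0) + 1
            if drop_censored:
                return
        taus.setdefault(k, []).append((end - start + 1))

    prev: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in rc_list]
    n_frames = 0
    times = []
    for time, ih, ia, dist in iter_candidates(frames, topo, theta_c, rc_list[-1], method):
        f = n_frames
        n_frames += 1
        times.append(time)
        keys_all = ih * (n_acc + 1) + ia
        for rc_i, rc in enumerate(rc_list):
            cur = np.sort(keys_all[dist <= rc])
            opened = np.setdiff1d(cur, prev[rc_i], assume_unique=True)
            closed = np.setdiff1d(prev[rc_i], cur, assume_unique=True)
            act = active[rc_i]
            for key in closed:
                close(rc_i, int(key), act.pop(int(key)), f - 1, None)
            for key in opened:
                act[int(key)] = f
            prev[rc_i] = cur
    if n_frames == 0:
        raise ValueError("scan_rc received an empty frame sequence")
    if len(times) > 1:
        dt = float(times[1] - times[0])
    else:
        dt = bin_width or 1.0
    # flush runs still open at the final frame (right-censored)
    for rc_i in range(len(rc_list)):
        for key, start in active[rc_i].items():
            close(rc_i, key, start, n_frames - 1, n_frames)

    bw = bin_width if bin_width is not None else dt
    window = T0 if T0 is not None else n_frames * dt
    pairs = set(lab for lab, _ in taus) | set(lab for lab, _ in ncens)
    if wanted is not None:
        pairs |= wanted
    out: dict[tuple[tuple[str, str], float], LifetimeDistribution] = {}
    for lab in sorted(pairs):
        x = fractions.get(lab[0])
        for rc in rc_list:
            k = (lab, rc)
            tau_arr = np.asarray(taus.get(k, []), dtype=np.float64) * dt
            out[k] = _distribution_from_taus(
                tau_arr, window, bw, species_pair=lab, r_c=rc, x=x,
                n_censored=ncens.get(k, 0),
            )
    return out


def export_tail(dist: LifetimeDistribution, t_min: float):
    """Long-time tail of L(t) on log–log axes.

    Returns a DataFrame with columns ``log10_t``/``log10_L`` restricted to
    occupied bins with center ≥ t_min; the input for eyeballing the algebraic
    decay of the tail (fitting it is out of scope here).
    """
    import pandas as pd

    if t_min >= dist.T0:
        raise ValueError("t_min must be below the measurement window T0")
    mask = (dist.density > 0) & (dist.bin_centers >= t_min)
    return pd.DataFrame(
        {
            "log10_t": np.log10(dist.bin_centers[mask]),
            "log10_L": np.log10(dist.density[mask]),
        }
    )
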