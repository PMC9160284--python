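"""Maxima of L(t) curve families and their primary/secondary/tertiary classes.

Scanning the bonding cutoff r_c produces a family of lifetime distributions
whose maxima behave in two distinct ways:

* the **primary** (dimer) peak moves to larger times and loses amplitude as
  r_c grows — a looser criterion keeps a lone pair "bonded" longer, but such
  dimers are rarer;
* once r_c passes the first maximum of g(r), one or two additional maxima
  appear at *fixed* positions whose amplitude grows with r_c.  The smaller-t
  stationary peak (**secondary**, ≈ 0.02 ps in OH-bonded liquids) reflects
  membership of the dimer in a larger cluster; the larger-t one
  (**tertiary**, ≈ 0.05 ps) reflects the topology of that cluster.

The classifier builds peak tracks across the r_c family (greedily from the
largest cutoff, where all features coexist, toward smaller ones) and labels
each track by its position drift and amplitude trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .lifetime import LifetimeDistribution
from .structure import _smooth

__all__ = ["PeakTrack", "PeakClassification", "find_maxima", "classify_across_rc"]


def find_maxima(
    dist: LifetimeDistribution,
    smooth_window: int = 3,
    min_prominence: float = 0.05,
) -> list[tuple[float, float]]:
    """Local maxima of one L(t) curve as ``(t_peak, amplitude)`` pairs.

    The curve is smoothed with a centered moving average; maxima must have a
    prominence of at least ``min_prominence`` × the smoothed curve's maximum.
    The reported position is the *unsmoothed* argmax within ± smooth_window
    bins of the smoothed peak, so smoothing cannot shift a sharp mode.
    Returns an empty list for flat or empty curves.
    """
    y = np.asarray(dist.density, dtype=np.float64)
    if y.size == 0 or not np.any(y > 0):
        return []
    ys = _smooth(y, smooth_window)
    top = float(ys.max())
    if top <= 0:
        return []
    idx, _ = find_peaks(ys, prominence=min_prominence * top)
    out: list[tuple[float, float]] = []
    seen: set[int] = set()
    for i in idx:
        lo = max(0, i - smooth_window)
        hi = min(len(y), i + smooth_window + 1)
        j = lo + int(np.argmax(y[lo:hi]))
        if j in seen:
            continue
        seen.add(j)
        out.append((float(dist.bin_centers[j]), float(y[j])))
    out.sort(key=lambda p: p[0])
    return out


@dataclass
class PeakTrack:
    """One maximum followed across the r_c family."""

    rc_values: list[float]  # ascending
    positions: list[float]  # ps, aligned with rc_values
    amplitudes: list[float]  # 1/ps
    label: str = "unclassified"

    @property
    def drift(self) -> float:
        """Position change from the smallest to the largest r_c [ps]."""
        return self.positions[-1] - self.positions[0]

    @property
    def amplitude_ratio(self) -> float:
        """Amplitude at the largest r_c over that at the smallest."""
        return self.amplitudes[-1] / self.amplitudes[0] if self.amplitudes[0] > 0 else np.inf

    @property
    def mean_position(self) -> float:
        return float(np.mean(self.positions))

    @property
    def position_spread(self) -> float:
        return float(np.std(self.positions))


@dataclass
class PeakClassification:
    """Classified peak tracks of one r_c family of L(t) curves.

    ``tau_secondary``/``tau_tertiary`` are the across-r_c mean positions of
    the two stationary tracks (ps; None when absent), with their across-r_c
    standard deviations as dispersions.
    """

    tracks: list[PeakTrack]
    peaks_by_rc: dict[float, list[tuple[float, float]]]
    stationary_tol: float

    def _track(self, label: str) -> PeakTrack | None:
        for t in self.tracks:
            if t.label == label:
                return t
        return None

    @property
    def tau_secondary(self) -> float | None:
        t = self._track("secondary")
        return t.mean_position if t else None

    @property
    def tau_tertiary(self) -> float | None:
        t = self._track("tertiary")
        return t.mean_position if t else None

    @property
    def tau_secondary_spread(self) -> float | None:
        t = self._track("secondary")
        return t.position_spread if t else None

    @property
    def tau_tertiary_spread(self) -> float | None:
        t = self._track("tertiary")
        return t.position_spread if t else None

    @property
    def primary_track(self) -> PeakTrack | None:
        return self._track("primary")

    def to_dict(self) -> dict:
        return {
            "tau_secondary": self.tau_secondary,
            "tau_tertiary": self.tau_tertiary,
            "tau_secondary_spread": self.tau_secondary_spread,
            "tau_tertiary_spread": self.tau_tertiary_spread,
            "stationary_tol": self.stationary_tol,
            "tracks": [
                {
                    "label": t.label,
                    "rc_values": t.rc_values,
                    "positions": t.positions,
                    "amplitudes": t.amplitudes,
                }
                for t in self.tracks
            ],
        }


def classify_across_rc(
    family: Mapping[float, LifetimeDistribution] | Mapping[float, Sequence[tuple[float, float]]],
    stationary_tol: float | None = None,
    smooth_window: int = 3,
    min_prominence: float = 0.05,
    match_window: float | None = None,
    amp_noise: float = 0.2,
) -> PeakClassification:
    """Track maxima across an r_c family and label primary/secondary/tertiary.

    ``family`` maps r_c [Å] to a :class:`LifetimeDistribution` (maxima found
    with the given smoothing/prominence) or directly to a peak list.  At
    least three r_c values are required.

    Tracks are built greedily from the largest r_c downward, matching by
    nearest time within ``match_window`` (default 3 × stationary_tol, wide
    enough to follow the drifting primary peak).  A track spanning the whole
    family whose position standard deviation is ≤ ``stationary_tol`` ("does
    not change up to statistical uncertainties") and whose amplitude is
    non-decreasing within ``amp_noise`` is stationary; among stationary
    tracks the smallest-t is the secondary and the next the tertiary.  A
    track with endpoint position increase beyond ``stationary_tol`` and
    decreasing amplitude is the primary.  Everything else stays unclassified.

    ``stationary_tol`` defaults to 2 histogram bins when distributions are
    supplied.
    """
    rcs = sorted(family)
    if len(rcs) < 3:
        raise ValueError("classify_across_rc needs at least 3 r_c values")

    peaks_by_rc: dict[float, list[tuple[float, float]]] = {}
    bin_width = None
    for rc in rcs:
        item = family[rc]
        if isinstance(item, LifetimeDistribution):
            bin_width = item.bin_width
            peaks_by_rc[rc] = find_maxima(item, smooth_window, min_prominence)
        else:
            peaks_by_rc[rc] = sorted((float(t), float(a)) for t, a in item)
    if stationary_tol is None:
        if bin_width is None:
            raise ValueError("stationary_tol is required when passing raw peak lists")
        stationary_tol = 2.0 * bin_width
    if match_window is None:
        match_window = 3.0 * stationary_tol

    # --- build tracks from the largest rc downward -------------------------
    tracks: list[dict] = []  # {"rc": [...desc...], "pos": [...], "amp": [...]}
    for rc in rcs[::-1]:
        peaks = peaks_by_rc[rc]
        taken: set[int] = set()
        # candidate (distance, track index, peak index), matched greedily
        cands = []
        for ti, tr in enumerate(tracks):
            last_pos = tr["pos"][-1]
            for pi, (t, a) in enumerate(peaks):
                d = abs(t - last_pos)
                if d <= match_window:
                    cands.append((d, ti, pi))
        cands.sort()
        matched_tracks: set[int] = set()
        for d, ti, pi in cands:
            if ti in matched_tracks or pi in taken:
                continue
            # only extend tracks that were alive at the previous (larger) rc
            matched_tracks.add(ti)
            taken.add(pi)
            t, a = peaks[pi]
            tracks[ti]["rc"].append(rc)
            tracks[ti]["pos"].append(t)
            tracks[ti]["amp"].append(a)
        for pi, (t, a) in enumerate(peaks):
            if pi not in taken:
                tracks.append({"rc": [rc], "pos": [t], "amp": [a]})

    built = [
        PeakTrack(
            rc_values=tr["rc"][::-1],
            positions=tr["pos"][::-1],
            amplitudes=tr["amp"][::-1],
        )
        for tr in tracks
    ]

    # --- label -------------------------------------------------------------
    stationary: list[PeakTrack] = []
    primary_cands: list[PeakTrack] = []
    for tr in built:
        spans_all = len(tr.rc_values) == len(rcs)
        # "does not change up to statistical uncertainties": judge position
        # scatter, which is robust to one jittery curve, not endpoint drift
        if spans_all and tr.position_spread <= stationary_tol and tr.amplitude_ratio >= 1.0 - amp_noise:
            stationary.append(tr)
        elif len(tr.rc_values) >= 2 and tr.drift > stationary_tol and tr.amplitude_ratio < 1.0:
            primary_cands.append(tr)

    stationary.sort(key=lambda t: t.mean_position)
    if stationary:
        stationary[0].label = "secondary"
    if len(stationary) > 1:
        stationary[1].label = "tertiary"
    if primary_cands:
        # the genuine dimer peak dominates the curve at its smallest rc
        primary_cands.sort(key=lambda t: -t.amplitudes[0])
        primary_cands[0].label = "primary"

    built.sort(key=lambda t: t.mean_position)
    return PeakClassification(tracks=built, peaks_by_rc=peaks_by_rc,
                              stationary_tol=float(stationary_tol))
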