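"""Interval extraction, L(t) normalization and the r_c scan."""

import numpy as np
import pytest

from hblife import compute_L, extract_intervals, export_tail, scan_rc
from hblife.detect import BondTriplet, HBondCriteria, detect_series
from hblife.lifetime import BondInterval
from hblife.synthetic import (
    KineticSpec,
    LifetimeLaw,
    generate_bond_series,
    simulate_toy_liquid,
)


def _intervals_from_taus(taus):
    return [
        BondInterval(triplet=None, t_start=0.0, t_end=t, lifetime=float(t),
                     censored_left=False, censored_right=False)
        for t in taus
    ]


class TestExtractIntervals:
    def test_all_false_row(self):
        assert extract_intervals(np.zeros((1, 10), bool), dt=0.002) == []

    def test_single_run_lifetime_convention(self):
        """True on frames 3..7 at Δt = 2 fs gives τ = 5 frames × 2 fs = 10 fs."""
        m = np.zeros((1, 10), bool)
        m[0, 3:8] = True
        (iv,) = extract_intervals(m, dt=0.002)
        assert iv.lifetime == pytest.approx(0.010)
        assert iv.t_start == pytest.approx(0.006)
        assert iv.t_end == pytest.approx(0.014)
        assert not iv.censored

    def test_single_frame_episode(self):
        m = np.zeros((1, 5), bool)
        m[0, 2] = True
        (iv,) = extract_intervals(m, dt=0.002)
        assert iv.lifetime == pytest.approx(0.002)

    def test_censoring_flags(self):
        m = np.array([[True, True, False, False, True]])
        a, b = extract_intervals(m, dt=1.0)
        assert a.censored_left and not a.censored_right
        assert b.censored_right and not b.censored_left

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_inversion_of_generator(self, seed):
        """Run-length decoding recovers every scripted episode's frame range
        and censoring flags for the event-based generator."""
        law = LifetimeLaw.exponential(0.03)
        gap = LifetimeLaw.exponential(0.05)
        matrix, truth = generate_bond_series(25, law, gap, dt=0.002, T0=2.0, seed=seed)
        got = extract_intervals(matrix, dt=0.002)
        got_tuples = sorted(
            (round(iv.t_start / 0.002), round((iv.t_end) / 0.002), iv.censored_left, iv.censored_right)
            for iv in got
        )
        exp_tuples = sorted(
            (ep.first_frame, ep.last_frame, ep.censored_left, ep.censored_right)
            for ep in truth
        )
        assert got_tuples == exp_tuples


class TestIntervalProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(arrays(bool, (4, 30)))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_groupby_rle_and_conserves_bonded_time(self, matrix):
        """Episodes equal an itertools.groupby run-length encoding row by
        row, and Σ τ equals total bonded time."""
        import itertools

        dt = 0.002
        ivs = extract_intervals(matrix, dt=dt)
        assert sum(iv.lifetime for iv in ivs) == pytest.approx(matrix.sum() * dt)
        got = sorted((round(iv.t_start / dt), round(iv.t_end / dt),
                      iv.censored_left, iv.censored_right) for iv in ivs)
        exp = []
        n = matrix.shape[1]
        for row in matrix:
            f = 0
            for bonded, grp in itertools.groupby(row):
                length = len(list(grp))
                if bonded:
                    exp.append((f, f + length - 1, f == 0, f + length == n))
                f += length
        assert got == sorted(exp)


class TestComputeL:
    def test_single_interval_mass(self):
        dist = compute_L(_intervals_from_taus([0.010]), T0=0.1, bin_width=0.002)
        assert dist.integral() == pytest.approx(1.0, abs=1e-12)
        occupied = np.flatnonzero(dist.density)
        assert len(occupied) == 1
        # the occupied bin contains t = 10 fs
        c = dist.bin_centers[occupied[0]]
        assert c - 0.001 <= 0.010 <= c + 0.001

    def test_normalization_many_seeds(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            taus = rng.exponential(0.05, 1000)
            taus = taus[taus > 0]
            dist = compute_L(_intervals_from_taus(taus), T0=taus.max() + 0.01, bin_width=0.002)
            assert abs(dist.integral() - 1.0) < 1e-9

    def test_empty_marker_no_division(self):
        dist = compute_L([], T0=1.0, bin_width=0.01)
        assert dist.is_empty
        assert dist.integral() == 0.0
        assert dist.lam == 0.0

    def test_censored_dropped_by_default(self):
        ivs = _intervals_from_taus([0.01, 0.02])
        cens = BondInterval(None, 0.0, 0.05, 0.05, censored_left=True, censored_right=False)
        dist = compute_L(ivs + [cens], T0=0.1, bin_width=0.002)
        assert dist.n_intervals == 2
        assert dist.n_censored == 1
        dist2 = compute_L(ivs + [cens], T0=0.1, bin_width=0.002, drop_censored=False)
        assert dist2.n_intervals == 3

    def test_exponential_histogram_matches_density(self):
        """10⁵ exponential lifetimes: every bin within 4 binomial standard
        errors of the closed-form density."""
        mean, n, bw = 0.05, 100_000, 0.005
        rng = np.random.default_rng(42)
        taus = rng.exponential(mean, n)
        T0 = float(taus.max()) + bw
        dist = compute_L(_intervals_from_taus(taus), T0=T0, bin_width=bw)
        edges_lo = dist.bin_centers - bw / 2
        edges_hi = dist.bin_centers + bw / 2
        p = np.exp(-edges_lo / mean) - np.exp(-edges_hi / mean)
        se = np.sqrt(np.maximum(p * (1 - p), 1e-30) * n)
        counts = dist.density * dist.lam
        bulk = n * p >= 10
        assert np.all(np.abs(counts[bulk] - n * p[bulk]) <= 4 * se[bulk])
        # sparse tail bins checked in aggregate
        tail_n, tail_p = counts[~bulk].sum(), p[~bulk].sum()
        assert abs(tail_n - n * tail_p) <= 4 * np.sqrt(n * tail_p * (1 - tail_p)) + 1

    def test_pair_symmetry(self):
        trip_ab = BondTriplet(0, 1, 3, ("A", "B"))
        ivs = [
            BondInterval(trip_ab, 0.0, t, t, False, False)
            for t in (0.01, 0.02, 0.02, 0.04)
        ]
        d1 = compute_L(ivs, T0=0.1, bin_width=0.002, species_pair=("A", "B"))
        d2 = compute_L(ivs, T0=0.1, bin_width=0.002, species_pair=("B", "A"))
        np.testing.assert_array_equal(d1.density, d2.density)
        assert d1.species_pair == d2.species_pair


class TestScanRc:
    def test_fixed_dimer_single_bin(self, water_dimer):
        from hblife.topology import Frame

        topo, frame = water_dimer
        frames = [Frame(time=0.002 * i, box=frame.box, coords=frame.coords) for i in range(6)]
        dists = scan_rc(frames, topo, 30.0, [3.5], drop_censored=False)
        d = dists[(("W", "W"), 3.5)]
        assert d.n_intervals == 1
        assert np.count_nonzero(d.density) == 1
        assert d.integral() == pytest.approx(1.0, abs=1e-12)

    def test_rethreshold_equals_redetection(self):
        """One pass at max r_c re-thresholded per cutoff gives the same
        intervals as independent detection at each cutoff."""
        res = simulate_toy_liquid(
            KineticSpec(n_particles=50, box=55.0, T_total=2.0, seed=11)
        )
        rc_list = [3.0, 3.3, 3.5]
        dists = scan_rc(res.frames, res.topology, 30.0, rc_list, drop_censored=True)
        for rc in rc_list:
            series = detect_series(res.frames, res.topology,
                                   HBondCriteria(r_c=rc, theta_c=30.0))
            ivs = [iv for iv in extract_intervals(series) if not iv.censored]
            ref = compute_L(ivs, T0=len(res.frames) * 0.002, bin_width=0.002,
                            species_pair=("W", "W"))
            got = dists[(("W", "W"), rc)]
            assert got.n_intervals == ref.n_intervals
            np.testing.assert_allclose(got.density, ref.density)

    def test_interval_count_monotone_in_rc(self):
        res = simulate_toy_liquid(
            KineticSpec(n_particles=40, box=50.0, T_total=2.0, seed=5)
        )
        dists = scan_rc(res.frames, res.topology, 30.0, [2.9, 3.2, 3.5, 4.0],
                        drop_censored=False)
        totals = [
            sum(d.n_intervals * d.bin_width * 0 + d.n_intervals
                for (pair, rc), d in dists.items() if rc == r)
            for r in (2.9, 3.2, 3.5, 4.0)
        ]
        # total bonded time (Σ τ = n × mean) grows with rc; interval count can
        # only grow when every bond at the smaller cutoff persists at the larger
        bonded_time = []
        for r in (2.9, 3.2, 3.5, 4.0):
            t = 0.0
            for (pair, rc), d in dists.items():
                if rc == r and d.n_intervals:
                    t += float((d.density * d.lam * d.bin_centers).sum())
            bonded_time.append(t)
        assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(bonded_time, bonded_time[1:]))

    def test_determinism(self):
        res = simulate_toy_liquid(KineticSpec(n_particles=30, box=50.0, T_total=1.0, seed=2))
        d1 = scan_rc(res.frames, res.topology, 30.0, [3.2, 3.5])
        d2 = scan_rc(res.frames, res.topology, 30.0, [3.2, 3.5])
        for key in d1:
            np.testing.assert_array_equal(d1[key].density, d2[key].density)


class TestExportTail:
    def test_all_mass_below_tmin(self):
        dist = compute_L(_intervals_from_taus([0.01, 0.012]), T0=1.0, bin_width=0.002)
        assert len(export_tail(dist, t_min=0.5)) == 0

    def test_exponential_tail_concave(self):
        """On log–log axes an exponential decay curves downward."""
        rng = np.random.default_rng(3)
        taus = rng.exponential(0.05, 200_000)
        dist = compute_L(_intervals_from_taus(taus), T0=float(taus.max()) + 0.01,
                         bin_width=0.01)
        tail = export_tail(dist, t_min=0.02)
        t, L = tail["log10_t"].to_numpy(), tail["log10_L"].to_numpy()
        keep = slice(0, 30)  # well-populated bins
        coeffs = np.polyfit(t[keep], L[keep], 2)
        assert coeffs[0] < -0.5  # strongly concave, nothing like a power law

    def test_pareto_tail_slope(self):
        """Power-law lifetimes give a log–log slope of −(α+1) within 5%."""
        alpha, t_min = 1.5, 0.1
        rng = np.random.default_rng(4)
        taus = t_min * (1.0 + rng.pareto(alpha, 300_000))
        T0 = 2.0
        taus = taus[taus <= T0 - 0.05]
        dist = compute_L(_intervals_from_taus(taus), T0=T0, bin_width=0.05)
        tail = export_tail(dist, t_min=2 * t_min)
        slope = np.polyfit(tail["log10_t"], tail["log10_L"], 1)[0]
        assert slope == pytest.approx(-(alpha + 1), rel=0.05)
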