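"""Ground-truth generators: bond series, kinetic toy liquid, toy MD."""

import math

import numpy as np
import pytest

from hblife import HBondCriteria, detect_series, extract_intervals
from hblife.synthetic import (
    KineticSpec,
    LifetimeLaw,
    ToyMDSpec,
    generate_bond_series,
    simulate_toy_liquid,
    simulate_toy_md,
)


class TestBondSeries:
    def test_seed_reproducibility(self):
        law, gap = LifetimeLaw.exponential(0.05), LifetimeLaw.exponential(0.05)
        m1, t1 = generate_bond_series(20, law, gap, dt=0.002, T0=1.0, seed=9)
        m2, t2 = generate_bond_series(20, law, gap, dt=0.002, T0=1.0, seed=9)
        np.testing.assert_array_equal(m1, m2)
        assert t1 == t2

    def test_discretization_floor(self):
        """Lifetimes far below Δt mostly land on single frames (τ = Δt)."""
        law = LifetimeLaw.exponential(0.0005)
        gap = LifetimeLaw.exponential(0.02)
        matrix, truth = generate_bond_series(200, law, gap, dt=0.002, T0=2.0, seed=1)
        frames = np.array([ep.lifetime_frames for ep in truth])
        assert (frames == 1).mean() > 0.9

    def test_truth_matches_matrix_run_lengths(self):
        """The interval-arithmetic ground truth equals a brute-force
        run-length decoding of the sampled boolean matrix."""
        law = LifetimeLaw.mixture(
            [LifetimeLaw.exponential(0.01), LifetimeLaw.lognormal(-3.5, 0.5)], [0.5, 0.5]
        )
        gap = LifetimeLaw.exponential(0.03)
        matrix, truth = generate_bond_series(50, law, gap, dt=0.002, T0=1.5, seed=4)
        brute = []
        for p in range(matrix.shape[0]):
            row = matrix[p]
            f = 0
            while f < len(row):
                if row[f]:
                    start = f
                    while f < len(row) and row[f]:
                        f += 1
                    brute.append((p, start, f - 1))
                else:
                    f += 1
        assert sorted((ep.pair, ep.first_frame, ep.last_frame) for ep in truth) == sorted(brute)

    def test_mean_recovery_with_discretization_bias(self):
        """Recovered mean lifetime equals the ground truth's frame-rounded
        mean exactly, and the frame-rounding bias follows the closed form
        m / P(≥1 sample) (checked by brute-force rounding of independent
        exponential episodes)."""
        m, dt = 0.05, 0.002
        law, gap = LifetimeLaw.exponential(m), LifetimeLaw.exponential(0.05)
        matrix, truth = generate_bond_series(2000, law, gap, dt=dt, T0=10.0, seed=7)
        ivs = [iv for iv in extract_intervals(matrix, dt=dt) if not iv.censored]
        taus = np.array([iv.lifetime for iv in ivs])
        assert len(taus) > 10_000
        truth_taus = np.array(
            [ep.lifetime_frames * dt for ep in truth if not (ep.censored_left or ep.censored_right)]
        )
        assert taus.mean() == pytest.approx(truth_taus.mean(), rel=1e-12)

        # bias formula vs brute-force rounding, free of episode merging
        rng = np.random.default_rng(17)
        n = 100_000
        L = rng.exponential(m, n)
        t_on = rng.uniform(0, dt, n)
        frames = np.ceil((t_on + L) / dt) - np.ceil(t_on / dt)
        rounded = frames[frames >= 1] * dt
        p0 = 1.0 - (m / dt) * (1.0 - math.exp(-dt / m))
        expected = m / (1.0 - p0)
        se = rounded.std(ddof=1) / math.sqrt(len(rounded))
        assert abs(rounded.mean() - expected) <= 3 * se


class TestToyLiquid:
    def test_episode_lifetimes_exponential(self):
        """Scripted lifetimes follow exponential(1/k_off): the recovered
        mean is within 3 SE of 1/k_off (+ half-frame discretization)."""
        spec = KineticSpec(n_particles=80, box=62.0, k_on=20.0, k_off=20.0, T_total=12.0, seed=2)
        res = simulate_toy_liquid(spec)
        taus = np.array([
            (f1 - f0 + 1) * spec.dt_save
            for _, _, _, f0, f1 in res.truth_triplets
            if f0 > 0 and f1 < len(res.frames) - 1
        ])
        assert len(taus) > 300
        # episode length in frames is geometric with p = 1 − e^{−k_off Δt}
        p = 1.0 - math.exp(-spec.k_off * spec.dt_save)
        expected = spec.dt_save / p
        se = taus.std(ddof=1) / math.sqrt(len(taus))
        assert abs(taus.mean() - expected) <= 3 * se

    def test_detection_recovers_script(self):
        res = simulate_toy_liquid(KineticSpec(n_particles=40, box=55.0, T_total=2.0, seed=8))
        series = detect_series(res.frames, res.topology, HBondCriteria())
        idx = {(t.donor, t.hydrogen, t.acceptor): i for i, t in enumerate(series.triplets)}
        truth = np.zeros_like(series.matrix)
        for d, h, a, f0, f1 in res.truth_triplets:
            assert (d, h, a) in idx, "scripted bond never detected"
            truth[idx[(d, h, a)], f0 : f1 + 1] = True
        assert (series.matrix == truth).mean() >= 0.99

    def test_k_on_zero_noise_floor(self):
        spec = KineticSpec(n_particles=40, box=55.0, k_on=0.0, T_total=1.0, seed=3)
        res = simulate_toy_liquid(spec)
        assert res.truth_triplets == []
        assert res.false_bond_rate < 0.01

    def test_seed_determinism(self):
        a = simulate_toy_liquid(KineticSpec(n_particles=20, box=50.0, T_total=0.5, seed=5))
        b = simulate_toy_liquid(KineticSpec(n_particles=20, box=50.0, T_total=0.5, seed=5))
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.coords, fb.coords)
        assert a.truth_triplets == b.truth_triplets


class TestToyMD:
    @pytest.fixture(scope="class")
    def short_run(self):
        return simulate_toy_md(
            ToyMDSpec(species="water", n_molecules=125, t_total=2.0, t_equil=1.0, seed=3)
        )

    def test_thermostat_holds_temperature(self, short_run):
        assert short_run.mean_temperature == pytest.approx(300.0, abs=15.0)

    def test_momentum_conserved(self, short_run):
        """Net momentum stays ≈ 0 (forces sum to zero, rescaling is uniform)."""
        p = (short_run.final_velocities * short_run.masses[:, None]).sum(axis=0)
        # thermal scale of a single atom's momentum for comparison
        scale = np.sqrt(short_run.masses.mean() * 0.008314 * 300.0 / 0.01)
        assert np.all(np.abs(p) < 1e-6 * len(short_run.masses) * scale + 1e-6)

    def test_nve_energy_drift(self):
        res = simulate_toy_md(
            ToyMDSpec(species="water", n_molecules=125, t_total=1.0, t_equil=0.5,
                      thermostat=False, seed=5)
        )
        e_tot = res.energies.sum(axis=1)
        assert abs(e_tot[-1] - e_tot[0]) < 0.01 * res.energies[:, 1].mean()

    def test_water_first_shell_brackets_cutoff(self, short_run):
        """g_OO of the toy water run has its first maximum below 3.5 Å and
        the following minimum near 3.5 Å — the operating regime for r_c."""
        from hblife import compute_rdf, locate_extrema

        rdf = compute_rdf(short_run.frames[::20], short_run.topology, ("W", "W"))
        rmax, rmin = locate_extrema(rdf)
        assert rmax < 3.5
        assert 2.9 < rmin < 4.1

    def test_seed_determinism(self):
        kw = dict(species="methanol", n_molecules=27, t_total=0.2, t_equil=0.1, seed=6)
        a = simulate_toy_md(ToyMDSpec(**kw))
        b = simulate_toy_md(ToyMDSpec(**kw))
        np.testing.assert_array_equal(a.frames[-1].coords, b.frames[-1].coords)

    def test_timestep_guard(self):
        with pytest.raises(ValueError):
            ToyMDSpec(timestep=0.002)
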