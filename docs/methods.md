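# Methods

## The quantity

For every donor–hydrogen–acceptor triplet (D–H···A) in a trajectory, a
hydrogen bond exists in a frame when the minimum-image distance D···A is
≤ r_C **and** the angle at D between D→H and D→A is ≤ θ_C (defaults
r_C = 3.5 Å, θ_C = 30°; both comparisons inclusive, so ties are bonded).
A maximal run of consecutively bonded frames is one episode with lifetime

    τ = (f_last − f_first + 1) · Δt_save,

the episode's frame count times the sampling interval.  The lifetime
distribution is the normalized histogram

    L(t) = (1/Λ) Σ_episodes δ_bin(t − τ),   Λ = n · Δbin,

so the Riemann sum ∫₀^{T₀} L dt is exactly 1 for every non-empty
distribution; T₀ is the measurement window.  L is resolved by symmetric
species pair (L_ab ≡ L_ba), by cutoff r_c and, in mixtures, by composition
x.  Episodes touching either end of the window are *censored* — their τ is
only a lower bound — and are excluded by default.

Conventions deliberately fixed here (external analyzers do not agree on
them): a single non-bonded frame ends an episode (an optional allowed-gap
parameter exists but defaults to 0); a single-frame episode has τ = Δt_save;
normalization is per curve, on the binned histogram.  Bond identity is the
atom triplet, not the molecule pair: a water donating both hydrogens to one
acceptor carries two independent bonds.

## The r_c scan and the three peaks

Scanning r_c produces a family of L(t) curves whose maxima separate into
two behaviours:

* **primary** — position grows and amplitude shrinks with r_c: the bonded
  *dimer* peak; a looser distance criterion keeps a pair "bonded" longer but
  such pairs are rarer;
* **secondary / tertiary** — appear once r_c passes the first maximum of the
  pair correlation g(r), at *fixed* positions (≈ 0.02 ps and ≈ 0.05 ps in
  OH-bonded liquids) with amplitude growing with r_c.  They are attributed to
  the dimer's membership in a larger H-bond cluster and to the cluster's
  topology (chain vs ring), respectively.

`classify_across_rc` mechanizes the visual classification: maxima of each
(smoothed) curve are tracked across the family greedily from the largest r_c
— where all features coexist — matching by nearest time within a window
(default 3 × stationary_tol; wide enough to follow the drifting primary).  A
track spanning the whole family whose position standard deviation is ≤
stationary_tol (default 2 bins) and whose amplitude does not decrease beyond
a 20 % noise allowance is *stationary*; scatter rather than endpoint drift is
used because a single curve's maximum can jitter by 2–3 bins at realistic
statistics.  Among stationary tracks the smallest-t is the secondary, the
next the tertiary, any others stay unclassified.  A track with endpoint
drift > stationary_tol and decreasing amplitude is the primary (the
largest-amplitude candidate wins if several qualify).  All thresholds
(smooth_window = 3 bins, min_prominence = 5 % of the curve maximum,
stationary_tol, match window) are exposed as configuration.

Peak positions are reported at the *unsmoothed* argmax within ±smooth_window
bins of the smoothed maximum, so smoothing cannot displace a sharp mode.

## Structure and clusters

g(r) uses the standard pair-count histogram against the ideal-gas shell
expectation (N(N−1)/2 for like pairs, N_a·N_b for cross pairs), computed
under minimum image with 0.02 Å bins by default.  First-shell extrema are
read from a 3-bin moving average; ties break toward smaller r.  The first
maximum/minimum of g_OO anchor the r_c family: cutoffs between the first
maximum and minimum are the regime where the stationary peaks emerge.

Per frame, bonded triplets collapse to an undirected molecule-level graph
(parallel triplets = one edge).  Connected components of size ≥ 2 are
clusters, classified by cycle rank c = E − V + 1 and degrees: dimer (2
nodes), chain (c = 0, max degree ≤ 2), branched-tree (c = 0, max degree
≥ 3), ring (c = 1, all degrees 2), lasso (c = 1, a degree-1 node),
multi-cycle (c ≥ 2).  The ring class is what the descriptive literature
calls a "loop"; branched-tree and multi-cycle complete the partition of all
connected graphs.  No temporal cluster tracking is attempted — cluster
lifetimes enter only through the L(t) peak taxonomy.

## Detection machinery

Two independent spatial-search paths — an O(N²) all-pairs loop and a cell
list with cell edge ≥ r_C (used when each box dimension holds ≥ 3 cells) —
share the same distance/cosine arithmetic and agree bit-exactly; the test
suite enforces equality against a separately written numpy/arccos oracle.
An r_c scan detects once at max(r_c) and re-thresholds stored donor–acceptor
distances, which is exactly equivalent to re-detection because the angle
test does not depend on r_c.  Only orthorhombic boxes are supported;
internal units are Å and ps with conversion at the I/O boundary (GRO is nm).

## Synthetic data: what it emulates and what it does not

**Bond series** (`generate_bond_series`): alternating bonded/unbonded
episodes with configurable laws (exponential, lognormal, Pareto, mixtures),
sampled at Δt.  The ground truth carries both continuous episode times and
their frame-rounded extents computed by interval arithmetic (episodes whose
separating gap contains no sample merge — exactly what run-length decoding
of the sampled series sees).  Discretization inflates the conditional mean
of an exponential(m) lifetime to m / P(≥ 1 sample) with
P(0 samples) = 1 − (m/Δt)(1 − e^{−Δt/m}); the tests verify this closed form
against brute-force rounding.

**Kinetic toy liquid** (`simulate_toy_liquid`): random-walking water-like
3-site particles; free pairs within a capture radius associate at rate k_on,
bonds break at k_off, each molecule holds at most one bond.  Bonded pairs
sit at 2.8 Å contact with the donor hydrogen exactly on the bond axis, so
geometric detection recovers the script; scripted lifetimes are exponential
(frame-discretized: geometric) with mean 1/k_off.  Free molecules carry
random orientations, so a low density is required for the unscripted
("false bond") rate to stay below 1 % per molecule-frame; the generator
measures this rate post hoc and raises if violated.  This generator tests
bookkeeping, not physics.

**Toy MD** (`simulate_toy_md`): velocity-Verlet dynamics of flexible 3-site
molecules — water-like (SPC/E-pattern charges and oxygen Lennard-Jones) or
united-atom methanol-like (CH3/O/H) — with harmonic bonds and angle,
reaction-field Coulomb (ε_RF = 78) and Lennard-Jones under a molecule-pair
(group) cutoff smoothly switched off over the last 1.5 Å, periodic minimum
image, Berendsen velocity rescaling (τ = 0.1 ps) and a 0.5 fs timestep.
Start-up: cubic lattice with random orientations → capped steepest descent →
5 ps thermalization → production with frames every 2 fs.

Parameter choices that matter:

* **Near-rigid internal geometry.**  Bond/angle force constants are set
  stiff (water: 6000 kJ/mol/Å², 1500 kJ/mol/rad²; methanol-like: 4000/6000
  and 4000) so that thermal bend fluctuations stay ≲ 2°.  Literature-style
  soft bends (≈ 400 kJ/mol/rad²) oscillate ±3–5° at a 17–21 fs period; that
  flaps the donor angle across the 30° cone and imprints an artifact comb on
  L(t) at bend-period harmonics (≈ 5–9, 24, 49 fs).  The molecules this
  engine stands in for have constrained geometry, so near-rigidity is the
  faithful surrogate; the 21 fs and ~47 fs methanol features were verified
  to survive a bend-period change from 17 to 9.4 fs, i.e. they are not
  vibrational artifacts.
* **Switched group cutoff.**  Plain group truncation injects ~16 % of the
  kinetic energy per ps in NVE; the quintic switch brings NVE drift below
  1 % per ps, which the test suite asserts.
* **Scale.**  125–250 molecules (55 ps including thermalization) keep one
  acceptance study around one to two minutes of compute while producing
  3–5 · 10⁴ episodes per curve — enough for the stationary peaks to stand
  out of bin noise.  The engine handles 250+ molecules if asked.

What the toy MD reproduces: hydrogen-bonded first shells (g_OO first
maximum ≈ 2.7 Å, first minimum ≈ 3.2–3.4 Å bracketing the 3.5 Å criterion),
sub-picosecond H-bond kinetics, and the r_c-scan peak phenomenology — for
the methanol-like liquid all three peak classes, with the stationary pair at
≈ 0.021 ps and ≈ 0.045–0.049 ps; for the water-like liquid a robust
stationary secondary at 17–19 fs.  What it does not reproduce: the
water-like surrogate shows no *distinct* tertiary maximum — the 35–50 fs
region is a monotone shoulder at every cutoff tried (including 250
molecules, 100 ps, NVE production, stiffer bends).  Its four-bonded network
appears to smear the topology mode that methanol's chain/ring clusters
resolve; recovering it presumably needs the full-scale rigid-water setups
this package deliberately does not include (PME, constraint solvers,
16 000-molecule boxes).  Passing tests on the toy systems therefore
demonstrate the *machinery* and the methanol-like phenomenology, not
quantitative water kinetics.

## Numerical details

* Histogram bins are right-closed, (k·Δbin, (k+1)·Δbin]; lifetimes are exact
  multiples of Δt_save and a 1e-9 relative guard keeps k·Δbin in bin k−1
  regardless of rounding.
* Empty distributions are explicit markers (n = 0, zero density), never a
  division by zero.
* Distance ties sit on the bonded side (≤); both search paths use identical
  arithmetic so the choice is consistent everywhere.
* Degenerate inputs: empty frame sequences, empty selections, fewer than
  three r_c curves, r_max beyond half the box, triclinic boxes and
  non-uniform frame spacing all raise typed errors with the offending value
  named.
* Determinism: every stochastic component takes an integer seed
  (numpy Generator); identical inputs give bit-identical outputs, which the
  suite asserts for the MD engine, the generators and the CLI artifacts.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* No intermittent (Luzar–Chandler C(t)) correlation functions, no survival
  corrections for censoring, no parametric fits of the long-time tail — the
  tail is exported as a log–log table only.
* The kinetic toy liquid allows at most one bond per molecule, so its
  cluster graphs are dimers (plus the deliberately constructed chain
  configurations).
* Toy-MD fidelity limits above; in particular the absent water-like tertiary
  mode.
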