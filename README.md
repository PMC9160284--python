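# hblife

Hydrogen-bond lifetime distributions in molecular liquids and mixtures:
geometric bond detection under periodic boundaries, the normalized lifetime
distribution L(t), an r_c-scan classifier for its primary/secondary/tertiary
maxima, and H-bond cluster topology — with synthetic generators (including a
small 3-site MD engine) so every stage runs and tests without external data.

## The science

Hydrogen-bonded liquids (water, alcohols) and their mixtures form transient
clusters.  For molecules *i*, *j* bonded at time scales of the simulation,
each uninterrupted bond episode has a lifetime τ_ij, and the normalized
distribution

    L(t) = (1/Λ) Σ_{ij∈𝒞} h_ij(t),      ∫₀^{T₀} L(t) dt = 1,

over the bonded set 𝒞 is a sensitive probe of short-time kinetics.  Bonds
are detected geometrically: donor–acceptor distance r ≤ r_C and donor angle
∠(H–D···A) ≤ θ_C (defaults 3.5 Å, 30°).

Scanning the cutoff r_c splits the maxima of L(t) into a **primary** dimer
peak (moves to larger t and shrinks as r_c grows) and, once r_c passes the
first maximum of g_OO(r), one or two **stationary** peaks in the
sub-picosecond regime (≈ 0.02 ps and ≈ 0.05 ps for OH-bonded liquids) whose
amplitude grows with r_c.  The stationary pair is attributed to bond
stabilization inside larger clusters (secondary) and to cluster topology —
chains, rings, lassos (tertiary).  `hblife` mechanizes the whole chain:
detection → episodes → L_ab(t, x, r_c) → peak tracking and classification →
cluster graphs, for pure liquids and mixtures alike.

## Worked example

```python
from hblife import HBondLifetimeModel
from hblife.synthetic import KineticSpec, simulate_toy_liquid

liq = simulate_toy_liquid(KineticSpec(n_particles=50, box=55.0,
                                      k_off=20.0, T_total=5.0, seed=7))
model = HBondLifetimeModel(liq.frames, liq.topology, rc_list=(3.0, 3.2, 3.5))
res = model.fit()
print(res.summary())
```

```
Hydrogen-bond lifetime analysis
================================================================
molecules: 50  (x_W = 1.000)
frames: 2501   Δt_save: 2 fs   window: 5.002 ps
θ_C: 30°   r_c family: [3.0, 3.2, 3.5] Å
----------------------------------------------------------------
    pair  r_c [Å]  n_intervals    ∫L dt
     W-W     3.00          481    1.000
     W-W     3.20          619    1.000
     W-W     3.50          864    1.000
----------------------------------------------------------------
    pair   τ_secondary [ps]   τ_tertiary [ps]  primary drift
     W-W                  —                 —              —
----------------------------------------------------------------
clusters (19 over sampled frames)  dimer: 1.00
```

Reading it: 50 water-like molecules sampled every 2 fs for 5 ps; at each
cutoff every non-empty L(t) integrates to exactly 1 (the Λ normalization);
the interval count grows with r_c because the bonded set at a smaller cutoff
is a subset of the one at a larger cutoff.  This scripted-kinetics liquid
has exponential lifetimes and at most one bond per molecule, so its cluster
graphs are all dimers and no stationary peak structure exists — the dashes
are correct, not missing data.

The physically interesting curves come from the toy MD engine:

```python
from hblife import HBondLifetimeModel
from hblife.synthetic import ToyMDSpec

model = HBondLifetimeModel.from_toy_md(
    ToyMDSpec(species="methanol", n_molecules=125, t_total=50.0, seed=1),
    rc_list=(3.2, 3.5, 4.0))
res = model.fit(species_pairs=[("M", "M")])
res.tau_secondary(("M", "M"))   # ≈ 0.020 ps, r_c-stationary
res.tau_tertiary(("M", "M"))    # ≈ 0.045–0.05 ps, r_c-stationary
res.plot_family(("M", "M"))     # the L(t) family, one curve per r_c
```

A `click` CLI mirrors the library (`hblife synth|detect|lifetimes|rdf|
peaks|clusters|full -c run.yaml`), writing CSV/JSON artifacts plus a
manifest that makes re-runs byte-identical under a fixed seed.

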