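"""Model/Results front end tying the pipeline together.

:class:`HBondLifetimeModel` is built from a trajectory plus a role-carrying
topology (or directly from a synthetic generator); :meth:`fit` runs
detection → interval extraction → L(t) over the r_c family, classifies the
peak tracks, and optionally computes g(r) and per-frame cluster topology.
The returned :class:`HBondLifetimeResults` carries the curve family, the
classified peaks with their across-r_c dispersions, diagnostics, and a
``summary()`` table; exporting and plotting hang off it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import clusters as _clusters
from . import peaks as _peaks
from .detect import HBondCriteria, detect_hbonds, species_pair_label
from .lifetime import LifetimeDistribution, scan_rc
from .structure import NoStructure, RadialDistribution, compute_rdf
from .topology import Frame, SystemTopology, iter_frames, read_topology

__all__ = ["HBondLifetimeModel", "HBondLifetimeResults"]

DEFAULT_RC_LIST = (3.2, 3.5, 4.0)


class HBondLifetimeModel:
    """Hydrogen-bond lifetime analysis of one trajectory.

    Parameters
    ----------
    frames
        Trajectory frames (uniform spacing, Å / ps).
    topology
        :class:`SystemTopology` with species labels and donor/acceptor roles.
    rc_list
        Family of distance cutoffs r_c [Å] for the scan; the classifier
        needs at least three.
    theta_c
        Donor-angle cutoff θ_C [degrees].
    bin_width, T0
        L(t) histogram resolution and window [ps]; default Δt_save and the
        trajectory length.
    drop_censored
        Exclude episodes touching the window edges (default True).
    """

    def __init__(
        self,
        frames: Sequence[Frame],
        topology: SystemTopology,
        rc_list: Sequence[float] = DEFAULT_RC_LIST,
        theta_c: float = 30.0,
        bin_width: float | None = None,
        T0: float | None = None,
        drop_censored: bool = True,
    ):
        self.frames = list(frames)
        if not self.frames:
            raise ValueError("empty trajectory")
        self.topology = topology
        self.rc_list = sorted(float(r) for r in rc_list)
        self.theta_c = float(theta_c)
        HBondCriteria(r_c=self.rc_list[0], theta_c=self.theta_c)
        self.bin_width = bin_width
        self.T0 = T0
        self.drop_censored = drop_censored

    # ------------------------------------------------------------------
    @classmethod
    def from_files(
        cls,
        topology_path,
        trajectory_path,
        species_spec,
        stride: int = 1,
        **kwargs,
    ) -> "HBondLifetimeModel":
        """Build from a GRO/PDB topology, a trajectory file and a species
        role spec (YAML path or mapping)."""
        topo = read_topology(topology_path, species_spec)
        frames = list(iter_frames(trajectory_path, stride=stride, n_atoms=topo.n_atoms))
        return cls(frames, topo, **kwargs)

    @classmethod
    def from_toy_md(cls, spec=None, **kwargs) -> "HBondLifetimeModel":
        """Run the toy MD generator and analyse its production frames.

        ``spec`` is a :class:`~hblife.synthetic.ToyMDSpec`; extra keyword
        arguments go to the model constructor.
        """
        from .synthetic import ToyMDSpec, simulate_toy_md

        result = simulate_toy_md(spec or ToyMDSpec())
        model = cls(result.frames, result.topology, **kwargs)
        model.md_result = result
        return model

    @property
    def dt(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return float(self.frames[1].time - self.frames[0].time)

    # ------------------------------------------------------------------
    def fit(
        self,
        species_pairs: Sequence[tuple[str, str]] | None = None,
        stationary_tol: float | None = None,
        smooth_window: int = 3,
        min_prominence: float = 0.05,
        match_window: float | None = None,
        with_rdf: bool = True,
        with_clusters: bool = True,
        cluster_frames: int = 25,
        cluster_rc: float | None = None,
    ) -> "HBondLifetimeResults":
        """Run the full analysis and return a results object."""
        distributions = scan_rc(
            self.frames, self.topology, self.theta_c, self.rc_list,
            species_pairs=species_pairs,
            bin_width=self.bin_width, T0=self.T0,
            drop_censored=self.drop_censored,
        )
        pairs = sorted({key[0] for key in distributions})
        classifications = {}
        for pair in pairs:
            family = {rc: distributions[(pair, rc)] for rc in self.rc_list}
            if all(d.is_empty for d in family.values()):
                continue
            classifications[pair] = _peaks.classify_across_rc(
                family, stationary_tol=stationary_tol,
                smooth_window=smooth_window, min_prominence=min_prominence,
                match_window=match_window,
            )

        rdfs: dict[tuple[str, str], RadialDistribution] = {}
        if with_rdf:
            for s in sorted(self.topology.species_set):
                try:
                    rdfs[(s, s)] = compute_rdf(self.frames[:: max(1, len(self.frames) // 200)],
                                               self.topology, (s, s))
                except ValueError:
                    continue

        cluster_records: list[_clusters.ClusterRecord] = []
        if with_clusters:
            rc = cluster_rc if cluster_rc is not None else (
                3.5 if 3.5 in self.rc_list else self.rc_list[-1]
            )
            crit = HBondCriteria(r_c=rc, theta_c=self.theta_c)
            step = max(1, len(self.frames) // cluster_frames)
            for frame in self.frames[::step]:
                bonds = detect_hbonds(frame, self.topology, crit)
                graph = _clusters.build_graph(bonds, self.topology)
                cluster_records.extend(
                    _clusters.find_clusters(graph, frame_time=frame.time, topo=self.topology)
                )

        return HBondLifetimeResults(
            model=self,
            distributions=distributions,
            classifications=classifications,
            rdfs=rdfs,
            cluster_records=cluster_records,
        )


@dataclass
class HBondLifetimeResults:
    """Fitted lifetime analysis: curve family, peak classes, g(r), clusters."""

    model: HBondLifetimeModel
    distributions: dict[tuple[tuple[str, str], float], LifetimeDistribution]
    classifications: dict[tuple[str, str], _peaks.PeakClassification]
    rdfs: dict[tuple[str, str], RadialDistribution]
    cluster_records: list

    # -- accessors ------------------------------------------------------
    @property
    def species_pairs(self) -> list[tuple[str, str]]:
        return sorted({key[0] for key in self.distributions})

    def distribution(self, pair, rc: float) -> LifetimeDistribution:
        if isinstance(pair, str):
            pair = tuple(pair.split("-"))
        return self.distributions[(species_pair_label(*pair), float(rc))]

    def tau_secondary(self, pair) -> float | None:
        cls = self.classifications.get(species_pair_label(*pair))
        return cls.tau_secondary if cls else None

    def tau_tertiary(self, pair) -> float | None:
        cls = self.classifications.get(species_pair_label(*pair))
        return cls.tau_tertiary if cls else None

    def cluster_summary(self):
        return _clusters.size_distribution(self.cluster_records)

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        topo = m.topology
        lines = []
        lines.append("Hydrogen-bond lifetime analysis")
        lines.append("=" * 64)
        fr = topo.mole_fractions()
        comp = ", ".join(f"x_{k} = {v:.3f}" for k, v in sorted(fr.items()))
        lines.append(f"molecules: {topo.n_molecules}  ({comp})")
        lines.append(
            f"frames: {len(m.frames)}   Δt_save: {m.dt * 1000:.3g} fs   "
            f"window: {len(m.frames) * m.dt:.4g} ps"
        )
        lines.append(f"θ_C: {m.theta_c:g}°   r_c family: {m.rc_list} Å")
        lines.append("-" * 64)
        lines.append(f"{'pair':>8} {'r_c [Å]':>8} {'n_intervals':>12} {'∫L dt':>8}")
        for (pair, rc), dist in sorted(self.distributions.items()):
            lines.append(
                f"{'-'.join(pair):>8} {rc:8.2f} {dist.n_intervals:12d} "
                f"{dist.integral():8.3f}"
            )
        lines.append("-" * 64)
        lines.append(
            f"{'pair':>8} {'τ_secondary [ps]':>18} {'τ_tertiary [ps]':>17} {'primary drift':>14}"
        )
        for pair, cls in sorted(self.classifications.items()):
            t2 = cls.tau_secondary
            t3 = cls.tau_tertiary
            s2 = f"{t2:.4f} ± {cls.tau_secondary_spread:.4f}" if t2 is not None else "—"
            s3 = f"{t3:.4f} ± {cls.tau_tertiary_spread:.4f}" if t3 is not None else "—"
            pt = cls.primary_track
            drift = f"{pt.drift:+.4f}" if pt is not None else "—"
            lines.append(f"{'-'.join(pair):>8} {s2:>18} {s3:>17} {drift:>14}")
        if self.cluster_records:
            lines.append("-" * 64)
            counts = {}
            for rec in self.cluster_records:
                counts[rec.topology_class] = counts.get(rec.topology_class, 0) + 1
            total = sum(counts.values())
            frac = "  ".join(
                f"{k}: {v / total:.2f}" for k, v in sorted(counts.items(), key=lambda kv: -kv[1])
            )
            lines.append(f"clusters ({total} over sampled frames)  {frac}")
        return "\n".join(lines)

    # -- export ---------------------------------------------------------
    def save(self, outdir) -> list[Path]:
        """Write curve CSVs with JSON sidecars, the peak report, g(r) and
        cluster tables.  Returns the list of files written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for (pair, rc), dist in sorted(self.distributions.items()):
            stem = f"L_{'-'.join(pair)}_rc{rc:g}"
            csv = outdir / f"{stem}.csv"
            dist.to_frame().to_csv(csv, index=False)
            sidecar = outdir / f"{stem}.json"
            sidecar.write_text(json.dumps(dist.metadata(), indent=2, sort_keys=True))
            written += [csv, sidecar]
        report = {
            "-".join(pair): cls.to_dict() for pair, cls in sorted(self.classifications.items())
        }
        peaks_json = outdir / "peaks.json"
        peaks_json.write_text(json.dumps(report, indent=2, sort_keys=True))
        written.append(peaks_json)
        rows = []
        for pair, cls in sorted(self.classifications.items()):
            for rc, peaks in sorted(cls.peaks_by_rc.items()):
                for t, a in peaks:
                    rows.append({"pair": "-".join(pair), "r_c": rc, "t": t, "amplitude": a})
        if rows:
            import pandas as pd

            maxima_csv = outdir / "maxima.csv"
            pd.DataFrame(rows, columns=["pair", "r_c", "t", "amplitude"]).to_csv(
                maxima_csv, index=False
            )
            written.append(maxima_csv)
        for pair, rdf in sorted(self.rdfs.items()):
            stem = f"g_{'-'.join(pair)}"
            csv = outdir / f"{stem}.csv"
            rdf.to_frame().to_csv(csv, index=False)
            written.append(csv)
            try:
                rmax, rmin = rdf.first_shell()
                extrema = {"first_max_r": rmax, "first_min_r": rmin}
            except NoStructure:
                extrema = {"first_max_r": None, "first_min_r": None, "no_structure": True}
            sidecar = outdir / f"{stem}.json"
            sidecar.write_text(json.dumps(extrema, indent=2, sort_keys=True))
            written.append(sidecar)
        if self.cluster_records:
            csv = outdir / "clusters.csv"
            _clusters.clusters_frame(self.cluster_records).to_csv(csv, index=False)
            written.append(csv)
        return written

    def plot_family(self, pair, ax=None, t_max: float | None = 0.2):
        """Overlay the L(t) family for one species pair, one line per r_c."""
        import matplotlib.pyplot as plt

        pair = species_pair_label(*pair)
        if ax is None:
            _, ax = plt.subplots()
        for rc in self.model.rc_list:
            self.distributions[(pair, rc)].plot(ax=ax)
        if t_max is not None:
            ax.set_xlim(0, t_max)
        ax.legend()
        ax.set_title(f"L(t), {'-'.join(pair)}")
        return ax
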