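"""End-to-end orchestration: run the analysis stages from a single YAML config,
write the report tables, and compare runs side by side.

The pipeline operates on synthetic channel systems (or on files the
structure_io readers understand) and executes stages in dependency order:
synth -> align -> geometry / dynamics -> ion_stats -> clusters -> charge_maps.
All stage outputs are plain CSV/JSON; a run is deterministic under its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .barrel_dynamics import correlation_map, identify_anticorrelation_axes, pearson_correlation
from .charge_maps import annotate_charges, delta_p_xy, delta_p_z
from .ion_clusters import cluster_positions, filter_clusters, lining_classification
from .ion_statistics import (
    detect_translocations,
    free_energy_profile,
    integrate_free_energy,
    lumen_occupancy,
    occupancy_correlation,
    permeation_ratio,
    selectivity_ratio,
)
from .pore_geometry import axis_distribution, ellipse_axis_series, lumen_radius_profile, nterm_calpha_profile
from .structure_io import align_channel, read_structure, read_trajectory, write_structure, write_trajectory
from .synthetic_data import (
    PotentialSpec,
    SyntheticSystemSpec,
    default_axis_pairs,
    generate_barrel_system,
    simulate_ion_tracks,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_isoforms"]

logger = logging.getLogger("porescope")

KNOWN_STAGES = ("synth", "align", "geometry", "dynamics", "ion_stats", "clusters", "charge_maps")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    output_dir: Path
    seed: int = 0
    name: str = "run"
    stages: tuple[str, ...] = KNOWN_STAGES
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; known: {list(KNOWN_STAGES)}")
        # execute in canonical dependency order regardless of listing order
        self.stages = tuple(s for s in KNOWN_STAGES if s in self.stages)
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return cls(
            output_dir=Path(raw.get("output_dir", "porescope_out")),
            seed=int(raw.get("seed", 0)),
            name=str(raw.get("name", "run")),
            stages=tuple(raw.get("stages", KNOWN_STAGES)),
            params={k: v for k, v in raw.items() if k in KNOWN_STAGES},
        )


@dataclass
class RunReport:
    name: str
    output_dir: Path
    manifests: dict[str, list[str]]
    parameters: dict
    summary: dict
    version: str = __version__

    def validate(self) -> None:
        for stage, files in self.manifests.items():
            for f in files:
                if not (self.output_dir / f).exists():
                    raise FileNotFoundError(f"stage {stage}: declared output {f} missing")

    def write(self) -> None:
        payload = {
            "name": self.name,
            "version": self.version,
            "parameters": self.parameters,
            "manifests": self.manifests,
            "summary": self.summary,
        }
        (self.output_dir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def load(cls, output_dir: str | Path) -> "RunReport":
        output_dir = Path(output_dir)
        payload = json.loads((output_dir / "report.json").read_text())
        return cls(
            name=payload["name"],
            output_dir=output_dir,
            manifests=payload["manifests"],
            parameters=payload["parameters"],
            summary=payload["summary"],
            version=payload.get("version", "?"),
        )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages and return a validated report.

    The synthetic system, its ion tracks and every stage table are written
    under ``config.output_dir``; the report's summary collects the headline
    scalars (axis means, selectivity, permeation ratio, integrated dG).
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    manifests: dict[str, list[str]] = {}
    summary: dict = {}
    p = config.params

    # ---- synth ------------------------------------------------------------
    synth_p = dict(p.get("synth", {}))
    n_frames = int(synth_p.pop("n_frames", 400))
    spec = SyntheticSystemSpec(seed=config.seed, **synth_p)
    model, traj = generate_barrel_system(spec, n_frames=n_frames)
    stage_files: list[str] = []
    if "synth" in config.stages:
        write_structure(model, out / "system.pdb")
        write_trajectory(traj, out / "trajectory.xyz")
        stage_files += ["system.pdb", "trajectory.xyz"]
        manifests["synth"] = stage_files
        logger.info("synth: %d residues, %d frames", len(model.residues), traj.n_frames)

    barrel_residues = model.metadata["barrel_residues"]
    helix_residues = model.metadata["helix_residues"]

    # ---- align ------------------------------------------------------------
    if "align" in config.stages:
        if "synth" in config.stages:
            # exercise the real I/O path: read the files back before aligning
            model_r = read_structure(out / "system.pdb")
            traj = read_trajectory(out / "trajectory.xyz", model_r, timestep=traj.timestep)
            traj.model.metadata.update(model.metadata)
            model = traj.model
        traj = align_channel(traj, barrel_residues, terminus_residues=helix_residues[:1])
        manifests["align"] = []

    # ---- geometry ----------------------------------------------------------
    if "geometry" in config.stages:
        geo_p = p.get("geometry", {})
        prof = lumen_radius_profile(
            traj,
            probe_radius=float(geo_p.get("probe_radius", 1.4)),
            slice_width=float(geo_p.get("slice_width", 0.5)),
            grid_spacing=float(geo_p.get("grid_spacing", 0.2)),
        )
        _write_csv(prof.to_frame(), out / "radius_profile.csv")
        nt = nterm_calpha_profile(traj, helix_residues)
        _write_csv(nt.to_frame(), out / "nterm_profile.csv")
        pairs = default_axis_pairs(model)
        series = ellipse_axis_series(traj, pairs)
        df = pd.DataFrame(
            {f"{s.axis_kind}_z{s.height:+.0f}": s.distances for s in series}
        )
        _write_csv(df, out / "axis_series.csv")
        for kind in ("longitudinal", "transversal"):
            sel = [s for s in series if s.axis_kind == kind and s.height == 0.0]
            _, _, mean_A, mean_nm = axis_distribution(sel)
            summary[f"{kind}_axis_mean_nm"] = round(mean_nm, 4)
        manifests["geometry"] = ["radius_profile.csv", "nterm_profile.csv", "axis_series.csv"]

    # ---- dynamics ----------------------------------------------------------
    if "dynamics" in config.stages:
        cmap = correlation_map(traj, helix_residues + barrel_residues)
        dfc = pd.DataFrame(cmap.matrix, columns=[str(r) for r in cmap.residue_indices])
        _write_csv(dfc, out / "correlation_map.csv")
        lon, tra = identify_anticorrelation_axes(cmap, helix_residues, barrel_residues)
        pairs = default_axis_pairs(model, heights=(0.0,))
        series = ellipse_axis_series(traj, pairs)
        rho = pearson_correlation(series[0].distances, series[1].distances)
        summary["axis_cross_correlation"] = round(rho, 4)
        summary["longitudinal_axis_pair"] = list(lon)
        summary["transversal_axis_pair"] = list(tra)
        manifests["dynamics"] = ["correlation_map.csv"]

    # ---- ion statistics ----------------------------------------------------
    tracks_cl: list = []
    tracks_k: list = []
    ion_p = dict(p.get("ion_stats", {}))
    if "ion_stats" in config.stages or "clusters" in config.stages:
        n_steps = int(ion_p.get("n_steps", 40000))
        dt = float(ion_p.get("dt", 0.002))
        n_replicas = int(ion_p.get("n_replicas", 3))
        well_cl = float(ion_p.get("well_depth_cl", 1.0))
        well_k = float(ion_p.get("well_depth_k", -0.5))
        zr = spec.z_max
        pot_cl = PotentialSpec.gaussian_well(well_cl, width=6.0, z_lo=-zr, z_hi=zr)
        pot_k = PotentialSpec.gaussian_well(well_k, width=6.0, z_lo=-zr, z_hi=zr)
        for rep in range(n_replicas):
            seed = config.seed * 1000 + rep
            tracks_cl.append(
                simulate_ion_tracks(pot_cl, spec, n_steps, dt, species="Cl",
                                    burn_in=n_steps // 10, seed=seed)
            )
            tracks_k.append(
                simulate_ion_tracks(pot_k, spec, n_steps, dt, species="K",
                                    burn_in=n_steps // 10, seed=seed + 5000)
            )

    if "ion_stats" in config.stages:
        dt = float(ion_p.get("dt", 0.002))
        occ_cl = [lumen_occupancy(t, replica_id=i) for i, t in enumerate(tracks_cl)]
        occ_k = [lumen_occupancy(t, replica_id=i) for i, t in enumerate(tracks_k)]
        sel_mean, sel_sd, _ = selectivity_ratio(occ_cl, occ_k)
        corr_mean, corr_sd, _ = occupancy_correlation(occ_cl, occ_k)
        ev_cl = [
            [e for t in rep for e in detect_translocations(t, timestep=dt)] for rep in tracks_cl
        ]
        ev_k = [
            [e for t in rep for e in detect_translocations(t, timestep=dt)] for rep in tracks_k
        ]
        perm = permeation_ratio(ev_cl, ev_k)
        prof_cl = free_energy_profile([t for rep in tracks_cl for t in rep], z_range=(-spec.z_max, spec.z_max))
        prof_k = free_energy_profile([t for rep in tracks_k for t in rep], z_range=(-spec.z_max, spec.z_max))
        table = pd.DataFrame(
            {
                "z": prof_cl.bin_centers,
                "delta_g_cl": prof_cl.delta_g,
                "delta_g_k": prof_k.delta_g,
            }
        )
        _write_csv(table, out / "free_energy.csv")
        occ_df = pd.DataFrame(
            {
                "replica": [o.replica_id for o in occ_cl],
                "cl_mean": [o.mean for o in occ_cl],
                "k_mean": [o.mean for o in occ_k],
            }
        )
        _write_csv(occ_df, out / "occupancy.csv")
        summary.update(
            {
                "cl_inside_mean": round(float(np.mean([o.mean for o in occ_cl])), 4),
                "k_inside_mean": round(float(np.mean([o.mean for o in occ_k])), 4),
                "selectivity": round(sel_mean, 4),
                "selectivity_sd": round(sel_sd, 4),
                "occupancy_correlation": round(corr_mean, 4),
                "permeation_ratio_pooled": round(perm["pooled"], 4),
                "n_events_cl": int(sum(len(e) for e in ev_cl)),
                "n_events_k": int(sum(len(e) for e in ev_k)),
            }
        )
        try:
            summary["integrated_dg_cl_kcal_mol_nm"] = round(integrate_free_energy(prof_cl), 4)
            summary["integrated_dg_k_kcal_mol_nm"] = round(integrate_free_energy(prof_k), 4)
        except ValueError:
            logger.warning("ion_stats: masked bins in lumen; integral not reported")
        manifests["ion_stats"] = ["free_energy.csv", "occupancy.csv"]

    # ---- clusters ----------------------------------------------------------
    annotations = None
    clusters = {}
    if "clusters" in config.stages:
        cl_p = p.get("clusters", {})
        rows = []
        for species, reps in (("Cl", tracks_cl), ("K", tracks_k)):
            pts = np.concatenate(
                [t.positions[~np.isnan(t.z)] for rep in reps for t in rep]
            )
            total = sum(rep[0].positions.shape[0] for rep in reps)
            cls = cluster_positions(
                pts,
                total_frames=total,
                cutoff=float(cl_p.get("cutoff", 6.0)),
                min_occurrence=float(cl_p.get("min_occurrence", 0.10)),
                species=species,
            )
            clusters[species] = filter_clusters(cls, float(cl_p.get("display_threshold", 0.20)))
            for c in clusters[species]:
                rows.append(
                    {
                        "species": species,
                        "x": c.center[0],
                        "y": c.center[1],
                        "z": c.center[2],
                        "population": c.population,
                        "occurrence": c.occurrence,
                    }
                )
        _write_csv(pd.DataFrame(rows), out / "ion_clusters.csv")
        annotations = annotate_charges(model)
        report = lining_classification(
            clusters.get("Cl", []), clusters.get("K", []), annotations,
            contact_cutoff=float(cl_p.get("contact_cutoff", 5.0)),
        )
        lining_rows = [{"category": k, "count": v} for k, v in report.summary.items()]
        for sp in ("Cl", "K"):
            pa, na = report.averages.get(sp, (0.0, 0.0))
            pt, nt = report.totals.get(sp, (0, 0))
            lining_rows += [
                {"category": f"P average ({sp})", "count": pa},
                {"category": f"N average ({sp})", "count": na},
                {"category": f"P total ({sp})", "count": pt},
                {"category": f"N total ({sp})", "count": nt},
            ]
        _write_csv(pd.DataFrame(lining_rows), out / "cluster_lining.csv")
        summary["n_clusters_cl"] = len(clusters.get("Cl", []))
        summary["n_clusters_k"] = len(clusters.get("K", []))
        manifests["clusters"] = ["ion_clusters.csv", "cluster_lining.csv"]

    # ---- charge maps --------------------------------------------------------
    if "charge_maps" in config.stages:
        cm_p = p.get("charge_maps", {})
        if annotations is None:
            annotations = annotate_charges(model)
        prof = delta_p_z(annotations, bin_width=float(cm_p.get("bin_width", 2.0)),
                         lumen_facing_only=False)
        _write_csv(
            pd.DataFrame(
                {
                    "z": prof.bin_centers,
                    "p_plus": prof.p_plus,
                    "p_minus": prof.p_minus,
                    "delta_p_z": prof.delta,
                }
            ),
            out / "delta_p_z.csv",
        )
        cmap_xy = delta_p_xy(annotations, bin_width=float(cm_p.get("bin_width", 2.0)))
        dfxy = pd.DataFrame(cmap_xy.delta, columns=[f"{y:.1f}" for y in cmap_xy.y_centers])
        dfxy.insert(0, "x", cmap_xy.x_centers)
        _write_csv(dfxy, out / "delta_p_xy.csv")
        n_plus = sum(1 for a in annotations if a.sign > 0)
        n_minus = sum(1 for a in annotations if a.sign < 0)
        summary["net_charge"] = n_plus - n_minus
        manifests["charge_maps"] = ["delta_p_z.csv", "delta_p_xy.csv"]

    report = RunReport(
        name=config.name,
        output_dir=out,
        manifests=manifests,
        parameters={"seed": config.seed, "stages": list(config.stages), **p},
        summary=summary,
    )
    report.validate()
    report.write()
    return report


def compare_isoforms(reports: list[RunReport], tolerance: float = 1e-9) -> pd.DataFrame:
    """Side-by-side comparison of run summaries; rows whose values differ by
    more than ``tolerance`` across runs are flagged in the ``differs`` column."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    keys = set(reports[0].summary)
    for r in reports[1:]:
        if set(r.summary) != keys:
            raise ValueError("reports carry different summary keys; cannot compare")
    rows = []
    for key in sorted(keys):
        values = [r.summary[key] for r in reports]
        if all(isinstance(v, (int, float)) for v in values):
            differs = (max(values) - min(values)) > tolerance
        else:
            differs = len({str(v) for v in values}) > 1
        rows.append({"metric": key, **{r.name: r.summary[key] for r in reports}, "differs": differs})
    return pd.DataFrame(rows)
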