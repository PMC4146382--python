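# porescope

Trajectory analyses for β-barrel ion channels — built around the human
voltage-dependent anion-selective channel (VDAC), the 19-stranded β-barrel of
the outer mitochondrial membrane whose N-terminal helix lies inside the pore.

Given a channel structure and coordinate trajectories (multi-model PDB or XYZ,
one file per replica) with labelled K⁺/Cl⁻ ion records, the package computes
the standard panel of analyses used to compare channel isoforms:

* **Pore geometry** — accessible lumen radius per 0.5 Å slice from the
  solvent-accessible cross-section (1.4 Å probe), N-terminal Cα z/radial
  profiles, and cross-barrel "breathing" axis series.
* **Barrel dynamics** — Cα fluctuation correlation maps
  C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), identification of the
  longitudinal/transversal anti-correlation axes, Pearson cross-correlations
  of axis lengths, a minimal H-bond-pattern secondary-structure classifier
  (α: i→i+4, 3₁₀: i→i+3), and H-bond occurrence tables with replica statistics.
* **Ion statistics** — lumen occupancy (−18 ≤ z ≤ +18 Å), Cl⁻/K⁺ selectivity
  and occupancy cross-correlation, translocation-event detection and the
  permeation ratio, and potential-of-mean-force profiles by Boltzmann
  inversion,

      ΔG(z) = −k_B T ln( ρ(z) / ρ_bulk ),

  with trapezoidal integrals over the lumen in kcal mol⁻¹ nm.
* **Ion clustering** — the greedy neighbour-count clustering of pooled ion
  positions (6.0 Å cutoff, 10% minimum occurrence) and classification of the
  positively/negatively charged residues lining each cluster.
* **Charge maps** — formal-charge annotation (Lys/Arg +1, Asp/Glu −1, His
  neutral), ΔP_z and ΔP_xy charged-residue distribution maps, Kyte–Doolittle
  hydropathy with a weighted 3-residue window (30% edge weight), and sequence
  charge summaries.
* **Synthetic data** — generators with planted, known statistical structure
  (breathing pseudo-barrels, overdamped-Langevin ion tracks in prescribed
  axial potentials, Gaussian cluster mixtures, ideal helices), so every
  analysis stage is testable without microsecond MD output.

## Worked example

```python
import numpy as np
from porescope import (
    SyntheticSystemSpec, PotentialSpec, generate_barrel_system,
    simulate_ion_tracks, align_channel, ellipse_axis_series,
    pearson_correlation, free_energy_profile, integrate_free_energy,
)
from porescope.synthetic_data import default_axis_pairs

# a breathing 19-strand pseudo-barrel with planted axis correlation -0.8
spec = SyntheticSystemSpec(seed=13, breathing_cross_correlation=-0.8)
model, traj = generate_barrel_system(spec, n_frames=10_000)
traj = align_channel(traj, model.metadata["barrel_residues"],
                     terminus_residues=model.metadata["helix_residues"][:1])
lon, tra = ellipse_axis_series(traj, default_axis_pairs(model, heights=(0.0,)))
print(f"axis cross-correlation: {pearson_correlation(lon.distances, tra.distances):+.3f}")

# chloride tracks in a planted 2 kcal/mol attractive well, then Eq.-1 inversion
pot = PotentialSpec.gaussian_well(2.0, width=5.0, z_lo=-spec.z_max, z_hi=spec.z_max)
tracks = simulate_ion_tracks(pot, spec, n_steps=120_000, dt=0.002,
                             n_ions=100, stride=12, seed=1)
prof = free_energy_profile(tracks, z_range=(-spec.z_max, spec.z_max), bulk_region=22.0)
print(f"well depth recovered: {np.nanmin(prof.delta_g):.2f} kcal/mol")
print(f"integrated dG(-18..18): {integrate_free_energy(prof):.2f} kcal/mol/nm")
```

Output:

```
axis cross-correlation: -0.792
well depth recovered: -2.00 kcal/mol
integrated dG(-18..18): -2.55 kcal/mol/nm
```

The recovered cross-correlation sits within sampling error of the planted
−0.8; the Boltzmann inversion reproduces the 2 kcal/mol well depth, and the
integral (the well integrated over the 3.6 nm lumen, in kcal mol⁻¹ nm)
summarises the anion-attractive lumen the well emulates.

A full end-to-end run (synthesis → alignment → geometry → dynamics → ion
statistics → clustering → charge maps) is driven by a YAML config:

```bash
porescope run config.yaml        # all stage tables as CSV + report.json
porescope synth --out demo/      # write a synthetic system to disk
porescope compare runA/ runB/    # side-by-side summary of two runs
```

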