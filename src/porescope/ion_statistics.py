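"""Ion occupancy, selectivity, translocation events and Boltzmann-inversion
free-energy profiles.

The lumen is the region ``z_lo <= z <= z_hi`` (default -18..+18 A) after axis
alignment, optionally gated radially to exclude same-height ions outside the
barrel.  The free-energy profile is the potential of mean force estimated by
Boltzmann inversion of the axial ion density,

    dG(z) = -k_B T ln(rho(z) / rho_bulk),

with rho_bulk the averaged density in the bulk (reservoir) region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, KB_KCAL_MOL_K
from .structure_io import IonTrack

__all__ = [
    "OccupancySeries",
    "TranslocationEvent",
    "DensityProfile",
    "FreeEnergyProfile",
    "lumen_occupancy",
    "selectivity_ratio",
    "occupancy_correlation",
    "unwrap_track",
    "detect_translocations",
    "permeation_ratio",
    "free_energy_profile",
    "integrate_free_energy",
]

DEFAULT_LUMEN_BOUNDS = (-18.0, 18.0)


@dataclass
class OccupancySeries:
    species: str
    counts: np.ndarray  # per-frame ion count inside the gated lumen
    replica_id: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("occupancy counts must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.counts.mean())


@dataclass
class TranslocationEvent:
    species: str
    ion_id: int
    direction: str  # "+z" | "-z"
    entry_frame: int
    exit_frame: int
    passage_time: float  # ns = (exit - entry) * timestep

    def __post_init__(self):
        if self.exit_frame < self.entry_frame:
            raise ValueError("exit frame precedes entry frame")


@dataclass
class DensityProfile:
    bin_centers: np.ndarray
    density: np.ndarray  # ions / A^3 (or per unit length if volumes omitted)
    bulk_density: float


@dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray  # A
    delta_g: np.ndarray  # kcal/mol; NaN at masked bins
    mask: np.ndarray  # True where the bin had zero samples
    temperature: float = DEFAULT_TEMPERATURE_K
    k_b: float = KB_KCAL_MOL_K
    density: DensityProfile | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"z": self.bin_centers, "delta_g": self.delta_g, "masked": self.mask}
        )


def lumen_occupancy(
    tracks: Sequence[IonTrack],
    z_bounds: tuple[float, float] = DEFAULT_LUMEN_BOUNDS,
    radial_gate: float | None = 20.0,
    replica_id: int = 0,
) -> OccupancySeries:
    """Per-frame count of ions inside the lumen slab (and radial gate)."""
    z_lo, z_hi = z_bounds
    if z_lo >= z_hi:
        raise ValueError("z_bounds must satisfy z_lo < z_hi")
    if not tracks:
        raise ValueError("no ion tracks supplied")
    species = tracks[0].species
    pos = np.stack([t.positions for t in tracks])  # (ions, frames, 3)
    with np.errstate(invalid="ignore"):
        inside = (pos[:, :, 2] >= z_lo) & (pos[:, :, 2] <= z_hi)
        if radial_gate is not None:
            inside &= np.hypot(pos[:, :, 0], pos[:, :, 1]) <= radial_gate
    return OccupancySeries(species, inside.sum(axis=0), replica_id)


def _mean_sd(values) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), sd


def selectivity_ratio(
    occ_cl: Sequence[OccupancySeries],
    occ_k: Sequence[OccupancySeries],
    mode: str = "ratio-of-means",
):
    """Cl/K lumen selectivity, mean +- stdev over replicas.

    ``ratio-of-means`` (default) divides the time-averaged counts within each
    replica; ``mean-of-ratios`` averages the per-frame count ratio instead
    (frames with zero K ions are skipped in that mode).
    Returns ``(mean, sd, per_replica_ratios)``.
    """
    if len(occ_cl) != len(occ_k):
        raise ValueError("replica lists differ in length")
    ratios = []
    for c, k in zip(occ_cl, occ_k):
        if len(c.counts) != len(k.counts):
            raise ValueError("occupancy series differ in frame count")
        if mode == "ratio-of-means":
            mk = k.counts.mean()
            if mk == 0:
                raise ZeroDivisionError(
                    f"replica {k.replica_id}: mean K occupancy is zero; ratio undefined"
                )
            ratios.append(c.counts.mean() / mk)
        elif mode == "mean-of-ratios":
            ok = k.counts > 0
            if not ok.any():
                raise ZeroDivisionError(
                    f"replica {k.replica_id}: no frames with K inside; ratio undefined"
                )
            ratios.append(float((c.counts[ok] / k.counts[ok]).mean()))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    mean, sd = _mean_sd(ratios)
    return mean, sd, ratios


def occupancy_correlation(
    occ_cl: Sequence[OccupancySeries], occ_k: Sequence[OccupancySeries]
):
    """Pearson correlation of the Cl and K per-frame counts, per replica then
    mean +- stdev.  Returns ``(mean, sd, per_replica)``."""
    from .barrel_dynamics import pearson_correlation

    if len(occ_cl) != len(occ_k):
        raise ValueError("replica lists differ in length")
    coeffs = [
        pearson_correlation(c.counts.astype(float), k.counts.astype(float))
        for c, k in zip(occ_cl, occ_k)
    ]
    mean, sd = _mean_sd(coeffs)
    return mean, sd, coeffs


def unwrap_track(track: IonTrack, box: Sequence[float]) -> IonTrack:
    """Remove periodic-boundary jumps from an ion track (minimum image).

    ``box`` gives the periodic box lengths (Lx, Ly, Lz) in A.  Frame-to-frame
    displacements larger than half a box length in any dimension are folded
    back; NaN (absent) frames pass through and the accumulated image offset is
    carried across them.  Apply before event detection on wrapped MD output.
    """
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive lengths")
    pos = track.positions.copy()
    offset = np.zeros(3)
    prev = None
    for i in range(len(pos)):
        if np.any(np.isnan(pos[i])):
            continue
        raw = pos[i].copy()
        if prev is not None:
            delta = raw - prev
            offset -= box * np.round(delta / box)
        pos[i] = raw + offset
        prev = raw
    return IonTrack(species=track.species, ion_id=track.ion_id, positions=pos)


def detect_translocations(
    track: IonTrack,
    z_bounds: tuple[float, float] = DEFAULT_LUMEN_BOUNDS,
    timestep: float = 1.0,
) -> list[TranslocationEvent]:
    """Complete lumen passages of one ion, as a crossing state machine.

    An event is recorded when the ion, having entered the lumen through one
    boundary, next leaves through the opposite boundary; re-exit through the
    entry boundary resets the state with no event.  ``entry_frame`` is the
    first frame inside, ``exit_frame`` the last frame inside, and the passage
    time is ``(exit - entry) * timestep``.  A single step jumping across the
    whole lumen scores an event of zero passage time.  Missing (NaN) positions
    reset the state.
    """
    z_lo, z_hi = z_bounds
    if z_lo >= z_hi:
        raise ValueError("z_bounds must satisfy z_lo < z_hi")
    z = track.z
    events: list[TranslocationEvent] = []
    entry_side: str | None = None  # boundary the ion entered through
    entry_frame = -1
    prev_region: str | None = None

    def region(zi: float) -> str | None:
        if np.isnan(zi):
            return None
        if zi < z_lo:
            return "below"
        if zi > z_hi:
            return "above"
        return "inside"

    for i, zi in enumerate(z):
        reg = region(zi)
        if reg is None:
            entry_side, prev_region = None, None
            continue
        if reg == "inside":
            if prev_region in ("below", "above"):
                entry_side, entry_frame = prev_region, i
            elif prev_region is None:
                entry_side = None  # started inside / after a gap: no countable entry
        elif prev_region == "inside" and entry_side is not None:
            if reg != entry_side:
                direction = "+z" if reg == "above" else "-z"
                events.append(
                    TranslocationEvent(
                        species=track.species,
                        ion_id=track.ion_id,
                        direction=direction,
                        entry_frame=entry_frame,
                        exit_frame=i - 1,
                        passage_time=(i - 1 - entry_frame) * timestep,
                    )
                )
            entry_side = None
        elif prev_region is not None and reg != prev_region and prev_region != "inside":
            # jumped straight across the lumen in one step
            direction = "+z" if reg == "above" else "-z"
            events.append(
                TranslocationEvent(
                    species=track.species,
                    ion_id=track.ion_id,
                    direction=direction,
                    entry_frame=i,
                    exit_frame=i,
                    passage_time=0.0,
                )
            )
            entry_side = None
        prev_region = reg
    return events


def _event_count(x) -> float:
    if np.isscalar(x):
        return float(x)
    return float(len(x))


def permeation_ratio(
    cl_events_per_replica: Sequence,
    k_events_per_replica: Sequence,
):
    """Overall Cl/K translocation-event ratio.

    Arguments are per-replica event lists (or plain counts).  Returns a dict
    with the pooled ratio (all events of both directions summed over replicas)
    and the per-replica mean +- stdev.
    """
    cl = [_event_count(x) for x in cl_events_per_replica]
    k = [_event_count(x) for x in k_events_per_replica]
    if sum(k) == 0:
        raise ZeroDivisionError("no K translocation events; permeation ratio undefined")
    pooled = sum(cl) / sum(k)
    per_rep = [c / kk for c, kk in zip(cl, k) if kk > 0]
    mean, sd = _mean_sd(per_rep) if per_rep else (float("nan"), float("nan"))
    return {"pooled": pooled, "per_replica_mean": mean, "per_replica_sd": sd}


def free_energy_profile(
    tracks: Sequence[IonTrack],
    bin_width: float = 0.5,
    z_range: tuple[float, float] = (-30.0, 30.0),
    bulk_region: float = 25.0,
    temperature: float = DEFAULT_TEMPERATURE_K,
    radial_gate: float | None = None,
    bin_areas: np.ndarray | None = None,
    n_frames: int | None = None,
) -> FreeEnergyProfile:
    """Boltzmann inversion of the pooled axial ion density.

    Positions from all tracks (pool replicas by concatenating their track
    lists) are histogrammed along z; ``rho_bulk`` is the mean density in the
    bins with ``|z| > bulk_region``.  ``bin_areas`` supplies per-bin
    cross-section areas when pore and reservoir geometry differ (pore bins: the
    gated cylinder; bulk bins: the slab); densities are per unit length when it
    is omitted, which cancels in the ratio for uniform cross-sections.
    """
    z_lo, z_hi = z_range
    edges = np.arange(z_lo, z_hi + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    zs = []
    for t in tracks:
        z = t.z
        ok = ~np.isnan(z)
        if radial_gate is not None:
            ok &= np.hypot(t.positions[:, 0], t.positions[:, 1]) <= radial_gate
        zs.append(z[ok])
    z_all = np.concatenate(zs)
    counts, _ = np.histogram(z_all, bins=edges)
    if n_frames is None:
        n_frames = max(t.positions.shape[0] for t in tracks)
    volumes = bin_width * (bin_areas if bin_areas is not None else np.ones(len(centers)))
    density = counts / (volumes * n_frames)  # per-frame number density
    bulk_bins = np.abs(centers) > bulk_region
    if not bulk_bins.any() or counts[bulk_bins].sum() == 0:
        raise ValueError("bulk region not sampled; rho_bulk undefined")
    rho_bulk = density[bulk_bins].mean()
    mask = counts == 0
    kT = KB_KCAL_MOL_K * temperature
    dg = np.full(len(centers), np.nan)
    with np.errstate(divide="ignore"):
        dg[~mask] = -kT * np.log(density[~mask] / rho_bulk)
    return FreeEnergyProfile(
        bin_centers=centers,
        delta_g=dg,
        mask=mask,
        temperature=temperature,
        density=DensityProfile(centers, density, rho_bulk),
    )


def integrate_free_energy(
    profile: FreeEnergyProfile,
    z_range: tuple[float, float] = DEFAULT_LUMEN_BOUNDS,
) -> float:
    """Integral of dG(z) over the lumen, in kcal/mol/nm.

    Trapezoidal over the bin centers inside ``z_range``, with the half-bin
    margins at either end closed by rectangles at the edge-bin value (exact for
    linear profiles).  Raises if any bin in range is masked.
    """
    sel = (profile.bin_centers >= z_range[0]) & (profile.bin_centers <= z_range[1])
    if not sel.any():
        raise ValueError("no bins inside the requested range")
    if profile.mask[sel].any():
        bad = profile.bin_centers[sel & profile.mask]
        raise ValueError(f"masked (unsampled) bins inside range at z = {bad[:5]}")
    z = profile.bin_centers[sel]
    g = profile.delta_g[sel]
    width = z[1] - z[0] if len(z) > 1 else 0.0
    integral_A = np.trapezoid(g, z) + 0.5 * width * (g[0] + g[-1])
    return float(integral_A / 10.0)  # A -> nm
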