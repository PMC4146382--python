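"""Lumen radius profiles, N-terminal CA geometry and cross-barrel axis series.

All operations assume the trajectory has been put in the channel frame
(:func:`porescope.structure_io.align_channel`): barrel centroid at the origin,
barrel axis along z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .structure_io import MolecularModel, Trajectory, map_residue_label

__all__ = [
    "RadiusProfile",
    "NTermProfile",
    "AxisSeries",
    "lumen_radius_profile",
    "nterm_calpha_profile",
    "ellipse_axis_series",
    "axis_distribution",
]


@dataclass
class RadiusProfile:
    """Effective accessible radius per 0.5 A slice: mean +- stdev over replicas."""

    slice_centers: np.ndarray  # A
    radius_mean: np.ndarray  # A
    radius_sd: np.ndarray
    unbounded: np.ndarray  # bool: flood fill reached the grid edge / empty slice

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "z": self.slice_centers,
                "radius_mean": self.radius_mean,
                "radius_sd": self.radius_sd,
                "unbounded": self.unbounded,
            }
        )


@dataclass
class NTermProfile:
    labels: list[str]
    z_mean: np.ndarray
    z_sd: np.ndarray
    r_mean: np.ndarray
    r_sd: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "residue": self.labels,
                "z_mean": self.z_mean,
                "z_sd": self.z_sd,
                "r_mean": self.r_mean,
                "r_sd": self.r_sd,
            }
        )


@dataclass
class AxisSeries:
    """Per-frame length of one cross-barrel CA-CA axis."""

    axis_kind: str  # "longitudinal" | "transversal"
    height: float  # z-level in A
    residue_pair: tuple[int, int]
    distances: np.ndarray  # A
    replica_id: int = 0

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances <= 0):
            raise ValueError("axis distances must be positive")


def _check_aligned(traj: Trajectory, tol: float = 5.0) -> None:
    xyz = traj.frames[0].coordinates
    centroid = xyz.mean(axis=0)
    if np.linalg.norm(centroid[:2]) > tol:
        raise ValueError(
            "trajectory does not look aligned (protein centroid off-axis); "
            "apply align_channel first"
        )


def _as_replicas(trajs) -> list[Trajectory]:
    return [trajs] if isinstance(trajs, Trajectory) else list(trajs)


def _slice_radius(
    xy: np.ndarray,
    radii: np.ndarray,
    grid_spacing: float,
    max_radius: float,
) -> tuple[float, bool]:
    """Effective accessible radius of one slice from a 2D grid flood fill.

    The accessible cross-section is the connected set of grid points around the
    pore axis whose distance to every atom centre exceeds that atom's inflated
    radius; the effective radius is sqrt(area / pi).
    """
    if len(xy) == 0:
        return max_radius, True
    n = int(np.ceil(2 * max_radius / grid_spacing)) + 1
    axis_pts = np.linspace(-max_radius, max_radius, n)
    occupied = np.zeros((n, n), dtype=bool)
    for (x, y), r in zip(xy, radii):
        i0 = np.searchsorted(axis_pts, x - r)
        i1 = np.searchsorted(axis_pts, x + r, side="right")
        j0 = np.searchsorted(axis_pts, y - r)
        j1 = np.searchsorted(axis_pts, y + r, side="right")
        if i0 >= n or j0 >= n or i1 <= 0 or j1 <= 0:
            continue
        gx = axis_pts[i0:i1][:, None] - x
        gy = axis_pts[j0:j1][None, :] - y
        occupied[i0:i1, j0:j1] |= gx**2 + gy**2 <= r**2
    free = ~occupied
    labels, _ = ndimage.label(free)
    centre = n // 2
    lab = labels[centre, centre]
    if lab == 0:
        return 0.0, False
    component = labels == lab
    unbounded = bool(
        component[0, :].any() or component[-1, :].any()
        or component[:, 0].any() or component[:, -1].any()
    )
    if unbounded:
        return max_radius, True
    area = component.sum() * grid_spacing**2
    return float(np.sqrt(area / np.pi)), False


def lumen_radius_profile(
    replicas: Trajectory | Sequence[Trajectory],
    probe_radius: float = 1.4,
    slice_width: float = 0.5,
    grid_spacing: float = 0.1,
    max_radius: float = 20.0,
    z_range: tuple[float, float] | None = None,
) -> RadiusProfile:
    """Accessible lumen radius per ``slice_width`` section normal to z.

    For every slice, atoms whose probe-inflated sphere (vdW + probe radius)
    intersects the slab contribute a 2D disk; the accessible area is the
    axis-connected free region of a 2D grid (``grid_spacing`` resolution) and
    the effective radius is sqrt(area/pi).  Atom-free or wall-less slices are
    reported at ``max_radius`` and flagged unbounded.  Per-replica profiles are
    averaged over frames first, then mean +- sample stdev across replicas.
    """
    replicas = _as_replicas(replicas)
    for t in replicas:
        _check_aligned(t)
    model = replicas[0].model
    n_protein = sum(len(r.atoms) for r in model.residues)
    vdw = np.array([a.vdw_radius for a in model.atoms[:n_protein]])
    inflated = vdw + probe_radius

    if z_range is None:
        zs = np.concatenate([t.frames[0].coordinates[:n_protein, 2] for t in replicas])
        z_range = (zs.min(), zs.max())
    lo = np.floor(z_range[0] / slice_width) * slice_width
    hi = np.ceil(z_range[1] / slice_width) * slice_width
    if hi - lo < slice_width:  # degenerate range (e.g. a flat ring): one slice
        lo -= slice_width / 2
        hi = lo + slice_width
    centers = np.arange(lo + slice_width / 2, hi, slice_width)

    per_replica = []
    any_unbounded = np.zeros(len(centers), dtype=bool)
    for traj in replicas:
        acc = np.zeros(len(centers))
        for fr in traj.frames:
            xyz = fr.coordinates[:n_protein]
            for k, zc in enumerate(centers):
                sel = np.abs(xyz[:, 2] - zc) <= slice_width / 2 + inflated
                r, unb = _slice_radius(
                    xyz[sel, :2], inflated[sel], grid_spacing, max_radius
                )
                acc[k] += r
                any_unbounded[k] |= unb
        per_replica.append(acc / traj.n_frames)
    stack = np.vstack(per_replica)
    sd = stack.std(axis=0, ddof=1) if len(replicas) > 1 else np.zeros(len(centers))
    return RadiusProfile(centers, stack.mean(axis=0), sd, any_unbounded)


def nterm_calpha_profile(
    replicas: Trajectory | Sequence[Trajectory],
    residue_indices: Iterable[int],
    isoform: str | None = None,
) -> NTermProfile:
    """Time-averaged z and radial distance of each CA, mean +- stdev over replicas."""
    replicas = _as_replicas(replicas)
    residue_indices = sorted(residue_indices)
    model = replicas[0].model
    ca_idx = model.calpha_indices(residue_indices)
    if len(ca_idx) != len(residue_indices):
        raise ValueError("a requested residue is missing its CA atom")
    z_rep, r_rep = [], []
    for traj in replicas:
        coords = traj.coordinate_array()[:, ca_idx, :]  # (frames, res, 3)
        z_rep.append(coords[:, :, 2].mean(axis=0))
        r_rep.append(np.linalg.norm(coords[:, :, :2], axis=2).mean(axis=0))
    z_rep, r_rep = np.vstack(z_rep), np.vstack(r_rep)
    nrep = len(replicas)
    labels = [
        map_residue_label(isoform, i) if isoform else str(i) for i in residue_indices
    ]
    return NTermProfile(
        labels=labels,
        z_mean=z_rep.mean(axis=0),
        z_sd=z_rep.std(axis=0, ddof=1) if nrep > 1 else np.zeros(len(ca_idx)),
        r_mean=r_rep.mean(axis=0),
        r_sd=r_rep.std(axis=0, ddof=1) if nrep > 1 else np.zeros(len(ca_idx)),
    )


def ellipse_axis_series(
    traj: Trajectory,
    pairs: Sequence[tuple[int, int, str, float]],
) -> list[AxisSeries]:
    """Per-frame CA-CA distance for each ``(res_i, res_j, axis_kind, height)`` pair."""
    out = []
    coords = traj.coordinate_array()
    for res_i, res_j, kind, height in pairs:
        if res_i == res_j:
            raise ValueError(f"axis pair ({res_i}, {res_j}) must name two residues")
        ia = traj.model.calpha_indices([res_i])
        ib = traj.model.calpha_indices([res_j])
        if len(ia) != 1 or len(ib) != 1:
            raise ValueError(f"axis pair ({res_i}, {res_j}): CA atom missing")
        d = np.linalg.norm(coords[:, ia[0], :] - coords[:, ib[0], :], axis=1)
        out.append(
            AxisSeries(
                axis_kind=kind,
                height=height,
                residue_pair=(res_i, res_j),
                distances=d,
                replica_id=traj.replica_id,
            )
        )
    return out


def axis_distribution(
    series: AxisSeries | Sequence[AxisSeries],
    bin_width: float = 0.25,
):
    """Pooled-over-replica probability density of an axis length.

    Returns ``(bin_centers, density, mean_A, mean_nm)``; the histogram has unit
    integral.  Pass the same axis from several replicas to pool them.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if isinstance(series, AxisSeries):
        series = [series]
    data = np.concatenate([s.distances for s in series])
    lo = np.floor(data.min() / bin_width) * bin_width
    hi = np.ceil(data.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    density, edges = np.histogram(data, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = float(data.mean())
    return centers, density, mean, mean / 10.0
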