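"""Synthetic systems with planted, known statistical structure.

Every downstream analysis stage in this package is testable without access to
microsecond MD output: this module generates

* pseudo-barrels (CA-only cylinders with an interior "N-terminal" helix) whose
  cross-barrel diameters breathe with a planted amplitude and cross-correlation,
* overdamped-Langevin ion tracks in piecewise axial potentials with bulk
  reservoirs, whose stationary density is the Boltzmann weight of the planted
  potential,
* Gaussian-mixture point sets for the position-clustering stage,
* ideal helices (alpha / 3_10 / extended) built from canonical dihedrals for
  the secondary-structure classifier, and
* Bernoulli contact series for occurrence statistics.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KB_KCAL_MOL_K, DEFAULT_TEMPERATURE_K
from .structure_io import Atom, Frame, IonTrack, MolecularModel, Residue, Trajectory

__all__ = [
    "PotentialSpec",
    "SyntheticSystemSpec",
    "generate_barrel_system",
    "simulate_ion_tracks",
    "sample_cluster_points",
    "generate_ideal_helix",
    "generate_hbond_series",
]


# ---------------------------------------------------------------------------
# axial potentials


@dataclass
class PotentialSpec:
    """Piecewise axial potential U(z) in kcal/mol over z in Angstrom.

    ``pieces`` is a list of ``(z_lo, z_hi, form, params)`` with forms

    * ``constant``:       params ``{value}``
    * ``harmonic``:       params ``{k, z0}`` -> 0.5 k (z - z0)^2
    * ``gaussian-well``:  params ``{depth, center, width}`` -> -depth exp(-(z-c)^2 / 2 w^2)
    * ``linear``:         params ``{slope, value_at_lo}``

    Pieces must tile the simulated z-range contiguously and the potential must
    be continuous at junctions (checked to 1e-6 kcal/mol).
    """

    pieces: list[tuple[float, float, str, dict]]
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        if not self.pieces:
            raise ValueError("potential needs at least one piece")
        self.pieces = sorted(self.pieces, key=lambda p: p[0])
        for (lo, hi, form, _) in self.pieces:
            if hi <= lo:
                raise ValueError(f"piece [{lo}, {hi}] has non-positive extent")
            if form not in ("constant", "harmonic", "gaussian-well", "linear"):
                raise ValueError(f"unknown potential form {form!r}")
        for (a, b) in zip(self.pieces, self.pieces[1:]):
            if abs(a[1] - b[0]) > 1e-9:
                raise ValueError(f"pieces do not tile the range: gap at z={a[1]}")
            z = a[1]
            ua = self._piece_energy(a, np.array([z]))[0]
            ub = self._piece_energy(b, np.array([z]))[0]
            if abs(ua - ub) > 1e-6:
                raise ValueError(f"potential discontinuous at z={z}: {ua} vs {ub}")

    @property
    def z_range(self) -> tuple[float, float]:
        return self.pieces[0][0], self.pieces[-1][1]

    @staticmethod
    def _piece_energy(piece, z):
        lo, hi, form, p = piece
        if form == "constant":
            return np.full_like(z, float(p["value"]))
        if form == "harmonic":
            return 0.5 * p["k"] * (z - p["z0"]) ** 2
        if form == "gaussian-well":
            return -p["depth"] * np.exp(-((z - p["center"]) ** 2) / (2 * p["width"] ** 2))
        return p["value_at_lo"] + p["slope"] * (z - lo)

    @staticmethod
    def _piece_force(piece, z):
        lo, hi, form, p = piece
        if form == "constant":
            return np.zeros_like(z)
        if form == "harmonic":
            return -p["k"] * (z - p["z0"])
        if form == "gaussian-well":
            w2 = p["width"] ** 2
            return -p["depth"] * np.exp(-((z - p["center"]) ** 2) / (2 * w2)) * (z - p["center"]) / w2
        return np.full_like(z, -p["slope"])

    def energy(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        for piece in self.pieces:
            lo, hi, _, _ = piece
            mask = (z >= lo) & (z <= hi) if piece is self.pieces[-1] else (z >= lo) & (z < hi)
            if mask.any():
                out[mask] = self._piece_energy(piece, z[mask])
        return out

    def force(self, z) -> np.ndarray:
        """-dU/dz, kcal/(mol A)."""
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        for piece in self.pieces:
            lo, hi, _, _ = piece
            mask = (z >= lo) & (z <= hi) if piece is self.pieces[-1] else (z >= lo) & (z < hi)
            if mask.any():
                out[mask] = self._piece_force(piece, z[mask])
        return out

    @classmethod
    def flat(cls, z_lo: float, z_hi: float, temperature: float = DEFAULT_TEMPERATURE_K):
        return cls([(z_lo, z_hi, "constant", {"value": 0.0})], temperature)

    @classmethod
    def gaussian_well(
        cls,
        depth: float,
        center: float = 0.0,
        width: float = 5.0,
        z_lo: float = -30.0,
        z_hi: float = 30.0,
        temperature: float = DEFAULT_TEMPERATURE_K,
    ):
        """A single Gaussian well (depth > 0 attracts) spanning the whole range."""
        return cls(
            [(z_lo, z_hi, "gaussian-well", {"depth": depth, "center": center, "width": width})],
            temperature,
        )


# ---------------------------------------------------------------------------
# system spec


@dataclass
class SyntheticSystemSpec:
    """Geometry, breathing and ion parameters of a synthetic channel system.

    Defaults emulate the simulated systems: a 19-strand pseudo-barrel of inner
    radius 12.5 A and height 36 A (inner diameter 2.0-2.5 nm, height ~4 nm),
    bathed in ~0.5 M KCl-like ion numbers (order 5-10 ions of each species in
    the lumen at a time), with breathing amplitudes ~1 A and an anti-correlated
    diameter pair (rho = -0.8) as observed for the strongly breathing isoforms.
    """

    n_strands: int = 19
    barrel_radius: float = 12.5  # A
    barrel_height: float = 36.0  # A
    breathing_amplitude_long: float = 1.0  # A, stdev of the longitudinal diameter
    breathing_amplitude_trans: float = 1.0  # A
    breathing_cross_correlation: float = -0.8
    breathing_ar_coefficient: float = 0.5  # lag-1 autocorrelation of stored frames
    jitter_amplitude: float = 0.05  # A, isotropic per-atom noise
    n_helix_residues: int = 12
    charged_fraction: float = 0.2  # fraction of residues given a charged identity
    n_cl: int = 12
    n_k: int = 12
    diffusion_coefficient: float = 100.0  # A^2/ns
    reservoir_thickness: float = 12.0  # A beyond each pore mouth
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0

    def __post_init__(self):
        if self.n_strands < 3:
            raise ValueError("n_strands must be >= 3")
        if self.breathing_amplitude_long < 0 or self.breathing_amplitude_trans < 0:
            raise ValueError("breathing amplitudes must be non-negative")
        if abs(self.breathing_cross_correlation) > 1:
            raise ValueError("cross-correlation must lie in [-1, 1]")

    @property
    def z_max(self) -> float:
        return self.barrel_height / 2 + self.reservoir_thickness

    @property
    def kT(self) -> float:
        return KB_KCAL_MOL_K * self.temperature


def _ar1_bivariate(rng, n, sigma_l, sigma_t, rho, phi):
    """Stationary bivariate AR(1) series with marginal stdevs and cross-correlation."""
    # Cholesky-like factor that tolerates zero amplitudes
    L = np.array(
        [
            [sigma_l, 0.0],
            [rho * sigma_t, sigma_t * np.sqrt(max(0.0, 1 - rho**2))],
        ]
    )
    u = np.empty((n, 2))
    innov_scale = np.sqrt(max(0.0, 1 - phi**2))
    u[0] = L @ rng.standard_normal(2)
    eps = rng.standard_normal((n - 1, 2)) if n > 1 else np.empty((0, 2))
    for t in range(1, n):
        u[t] = phi * u[t - 1] + innov_scale * (L @ eps[t - 1])
    return u  # columns: longitudinal, transversal diameter deviations


def generate_barrel_system(
    spec: SyntheticSystemSpec, n_frames: int = 1000, timestep: float = 0.01
) -> tuple[MolecularModel, Trajectory]:
    """Build a CA-only pseudo-barrel with an interior helix and breathing frames.

    The barrel is ``n_strands`` vertical strands of CA pseudo-atoms on a
    cylinder; an interior helical "N-terminal" segment runs along +x -> -x at
    z ~ 0, displaced towards the -y wall.  Per frame, the two orthogonal
    cross-barrel diameters (x: longitudinal, i.e. along the helix direction;
    y: transversal) are modulated by a stationary bivariate AR(1) process with
    the requested amplitudes and cross-correlation: atom positions scale as
    ``x -> x (1 + u_L / 2R)`` so the x-diameter length is ``2R + u_L`` exactly.
    The helix start rides the longitudinal mode and the helix centre the
    transversal mode, mimicking the anchored-start / central-crossing geometry
    that the anti-correlation-axis identification exploits.

    Returns the model and a single-replica trajectory; the planted diameter
    series are stored in ``model.metadata``.
    """
    rng = np.random.default_rng(spec.seed)
    R, H = spec.barrel_radius, spec.barrel_height
    rise = 3.3
    n_per_strand = max(3, int(round(H / rise)) + 1)

    residues: list[Residue] = []
    theta_of_residue: dict[int, float] = {}
    strand_of_residue: dict[int, int] = {}
    serial = 1
    res_index = 1

    def pick_name():
        if rng.random() < spec.charged_fraction:
            return rng.choice(["LYS", "ARG", "ASP", "GLU"])
        return "GLY"

    # interior "N-terminal" helix, residues 1..n_helix
    n_h = spec.n_helix_residues
    helix_x = np.linspace(0.8 * R, -0.8 * R, n_h)
    helix_y = np.full(n_h, -0.4 * R)
    helix_z = np.linspace(3.0, -3.0, n_h)  # start of the fragment on the +z side
    helix_range = range(1, n_h + 1)
    for i in range(n_h):
        atom = Atom(serial, "CA", "C", 1.70, res_index,
                    np.array([helix_x[i], helix_y[i], helix_z[i]]))
        residues.append(Residue(res_index, pick_name(), "A", [atom]))
        serial += 1
        res_index += 1

    # barrel strands
    z_levels = np.linspace(-H / 2, H / 2, n_per_strand)
    for s in range(spec.n_strands):
        theta = 2 * np.pi * s / spec.n_strands
        for z in z_levels:
            xyz = np.array([R * np.cos(theta), R * np.sin(theta), z])
            atom = Atom(serial, "CA", "C", 1.70, res_index, xyz)
            residues.append(Residue(res_index, pick_name(), "A", [atom]))
            theta_of_residue[res_index] = theta
            strand_of_residue[res_index] = s
            serial += 1
            res_index += 1

    model = MolecularModel(residues=residues, metadata={})
    base = np.array([a.coordinates for a in model.atoms])

    u = _ar1_bivariate(
        rng,
        n_frames,
        spec.breathing_amplitude_long,
        spec.breathing_amplitude_trans,
        spec.breathing_cross_correlation,
        spec.breathing_ar_coefficient,
    )

    n_atoms = base.shape[0]
    helix_idx = np.arange(n_h)
    barrel_idx = np.arange(n_h, n_atoms)
    helix_start = helix_idx[: n_h // 3]
    helix_mid = helix_idx[n_h // 3: 2 * n_h // 3]

    frames = []
    for t in range(n_frames):
        eps_l, eps_t = u[t, 0] / (2 * R), u[t, 1] / (2 * R)
        xyz = base.copy()
        xyz[barrel_idx, 0] *= 1 + eps_l
        xyz[barrel_idx, 1] *= 1 + eps_t
        # helix coupling: start -> longitudinal mode, centre -> transversal mode
        xyz[helix_start, 0] = base[helix_start, 0] * (1 + eps_l)
        xyz[helix_mid, 1] = base[helix_mid, 1] * (1 + eps_t)
        if spec.jitter_amplitude > 0:
            xyz = xyz + rng.normal(0.0, spec.jitter_amplitude, size=xyz.shape)
        frames.append(Frame(time=t * timestep, coordinates=xyz))

    model.metadata.update(
        {
            "planted_diameter_long": 2 * R + u[:, 0],
            "planted_diameter_trans": 2 * R + u[:, 1],
            "theta_of_residue": theta_of_residue,
            "strand_of_residue": strand_of_residue,
            "helix_residues": list(helix_range),
            "barrel_residues": sorted(theta_of_residue),
            "barrel_radius": R,
            "barrel_height": H,
        }
    )
    traj = Trajectory(model=model, frames=frames, replica_id=0, timestep=timestep)
    return model, traj


def barrel_residue_at(model: MolecularModel, theta: float, z: float) -> int:
    """Index of the barrel residue closest to cylinder angle ``theta`` and height ``z``."""
    thetas = model.metadata["theta_of_residue"]
    best, best_d = None, np.inf
    for idx, th in thetas.items():
        ca = model.residue_by_index(idx).atom("CA").coordinates
        dth = np.angle(np.exp(1j * (th - theta)))
        d = abs(dth) * model.metadata["barrel_radius"] + abs(ca[2] - z)
        if d < best_d:
            best, best_d = idx, d
    return best


def default_axis_pairs(model: MolecularModel, heights=(-8.0, 0.0, 8.0)):
    """Longitudinal (x-diameter) and transversal (y-diameter) residue pairs
    of a synthetic barrel at the requested z-levels."""
    pairs = []
    for h in heights:
        pairs.append(
            (barrel_residue_at(model, 0.0, h), barrel_residue_at(model, np.pi, h), "longitudinal", h)
        )
        pairs.append(
            (
                barrel_residue_at(model, np.pi / 2, h),
                barrel_residue_at(model, 3 * np.pi / 2, h),
                "transversal",
                h,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Langevin ion tracks


def simulate_ion_tracks(
    potential: PotentialSpec,
    spec: SyntheticSystemSpec,
    n_steps: int,
    dt: float,
    species: str = "Cl",
    n_ions: int | None = None,
    stride: int = 1,
    burn_in: int = 0,
    seed: int | None = None,
) -> list[IonTrack]:
    """Overdamped Langevin ion tracks in an axial potential with bulk reservoirs.

    Dynamics: ``z <- z - (D / k_B T) U'(z) dt + sqrt(2 D dt) xi`` with reflecting
    boundaries at ``+-(barrel_height/2 + reservoir_thickness)``.  Radially, ions
    inside the pore feel a harmonic confinement whose stiffness defaults to
    ``k_r = 2 k_B T / R^2`` so the pore's effective cross-section (``2 pi kT /
    k_r``) equals the reservoir area ``pi R^2``; ions in the reservoirs diffuse
    freely inside a reflecting cylinder of radius ``R = barrel_radius``.  The
    axial marginal of the stationary density is then exactly proportional to
    ``exp(-U(z)/k_B T)``, which is what the Boltzmann-inversion stage recovers.

    ``stride`` thins the recorded series; ``burn_in`` steps are discarded first.
    The per-step displacement ``sqrt(2 D dt)`` must stay below 1 A.
    """
    if species not in ("Cl", "K"):
        raise ValueError(f"unknown species {species!r}")
    D, kT = spec.diffusion_coefficient, spec.kT
    step_rms = np.sqrt(2 * D * dt)
    if step_rms >= 1.0:
        raise ValueError(
            f"step size too large: sqrt(2 D dt) = {step_rms:.2f} A >= 1 A; reduce dt"
        )
    n = n_ions if n_ions is not None else (spec.n_cl if species == "Cl" else spec.n_k)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    z_max, R, half_h = spec.z_max, spec.barrel_radius, spec.barrel_height / 2
    k_r = 2 * kT / R**2
    mobility = D / kT

    # start z from the stationary Boltzmann density (inverse-CDF on a fine
    # grid) so the recorded series needs no axial equilibration period
    zg = np.linspace(-z_max, z_max, 4001)
    w = np.exp(-potential.energy(zg) / kT)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    z = np.interp(rng.random(n), cdf, zg)
    sigma_r = np.sqrt(kT / k_r)
    xy = np.where(
        (np.abs(z) <= half_h)[:, None],
        rng.normal(0.0, sigma_r, size=(n, 2)),
        rng.uniform(-R / np.sqrt(2), R / np.sqrt(2), size=(n, 2)),
    )
    n_rec = (n_steps - burn_in + stride - 1) // stride if n_steps > burn_in else 0
    out = np.empty((n_rec, n, 3))
    rec = 0
    for step in range(n_steps):
        fz = potential.force(z)
        z = z + mobility * fz * dt + step_rms * rng.standard_normal(n)
        # reflecting axial walls
        z = np.where(z > z_max, 2 * z_max - z, z)
        z = np.where(z < -z_max, -2 * z_max - z, z)
        in_pore = np.abs(z) <= half_h
        fxy = np.where(in_pore[:, None], -k_r * xy, 0.0)
        xy = xy + mobility * fxy * dt + step_rms * rng.standard_normal((n, 2))
        # reflecting radial wall outside the pore
        r = np.linalg.norm(xy, axis=1)
        too_far = (~in_pore) & (r > R)
        if too_far.any():
            scale = (2 * R - r[too_far]) / r[too_far]
            xy[too_far] *= np.maximum(scale, 0.0)[:, None]
        if step >= burn_in and (step - burn_in) % stride == 0:
            out[rec, :, 0:2] = xy
            out[rec, :, 2] = z
            rec += 1
    return [IonTrack(species=species, ion_id=i, positions=out[:, i, :]) for i in range(n)]


# ---------------------------------------------------------------------------
# cluster fixtures


def sample_cluster_points(
    centers: Sequence[Sequence[float]],
    weights: Sequence[float],
    sigma: float,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` points from an isotropic Gaussian mixture (reproducible under seed)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    centers = np.asarray(centers, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 3:
        raise ValueError("centers must be (k, 3)")
    if len(weights) != len(centers) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must match centers and sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(centers), size=n, p=weights)
    return centers[comp] + rng.normal(0.0, sigma, size=(n, 3))


# ---------------------------------------------------------------------------
# ideal helices


_CANONICAL_DIHEDRALS = {
    "alpha": (-57.0, -47.0),
    "three_ten": (-49.0, -26.0),
    "extended": (180.0, 180.0),
}

# ideal backbone geometry (lengths A, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O, _A_C_N_H = 121.7, 111.2, 116.2, 120.8, 119.0


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement: position of the atom bonded to c, given chain a-b-c."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def generate_ideal_helix(kind: str, n_res: int) -> MolecularModel:
    """Backbone (N, CA, C, O and amide H) built from canonical dihedrals.

    ``alpha``: phi = -57, psi = -47; ``three_ten``: phi = -49, psi = -26;
    ``extended``: phi = psi = 180.  Bond lengths and angles are ideal; the
    amide H sits 1.01 A from N, anti to the preceding carbonyl carbon.  The
    first residue carries no amide H.
    """
    if kind not in _CANONICAL_DIHEDRALS:
        raise ValueError(f"unknown helix kind {kind!r}")
    if n_res < 4:
        raise ValueError("n_res must be >= 4")
    phi, psi = _CANONICAL_DIHEDRALS[kind]
    omega = 180.0

    # backbone chain N-CA-C-N-CA-C-... via NeRF
    coords: dict[tuple[int, str], np.ndarray] = {}
    coords[(0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(0, "CA")] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_N_CA_C)
    coords[(0, "C")] = coords[(0, "CA")] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        coords[(i, "N")] = _place_atom(
            coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")],
            _B_C_N, _A_CA_C_N, psi,
        )
        coords[(i, "CA")] = _place_atom(
            coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
            _B_N_CA, _A_C_N_CA, omega,
        )
        coords[(i, "C")] = _place_atom(
            coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
            _B_CA_C, _A_N_CA_C, phi,
        )
    for i in range(n_res):
        if i + 1 < n_res:
            # carbonyl O anti to the next amide N across the sp2 carbon
            coords[(i, "O")] = _place_atom(
                coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
                _B_C_O, _A_CA_C_O, psi + 180.0,
            )
        else:
            coords[(i, "O")] = _place_atom(
                coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
                _B_C_O, _A_CA_C_O, psi + 180.0,
            )
        if i > 0:
            coords[(i, "H")] = _place_atom(
                coords[(i, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
                _B_N_H, _A_C_N_H, 180.0,
            )

    residues = []
    serial = 1
    for i in range(n_res):
        atoms = []
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("H", "H")):
            if (i, name) not in coords:
                continue
            from .constants import VDW_RADII

            atoms.append(
                Atom(serial, name, element, VDW_RADII[element], i + 1, coords[(i, name)])
            )
            serial += 1
        residues.append(Residue(i + 1, "ALA", "A", atoms))
    return MolecularModel(residues=residues, metadata={"kind": kind})


# ---------------------------------------------------------------------------
# contact series


def generate_hbond_series(on_fraction: float, n_frames: int, seed: int = 0) -> np.ndarray:
    """i.i.d. Bernoulli(on_fraction) presence series for occurrence statistics."""
    if not 0.0 <= on_fraction <= 1.0:
        raise ValueError("on_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.random(n_frames) < on_fraction
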