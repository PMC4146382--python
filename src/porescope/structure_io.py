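"""Structures, trajectories and sequences: containers, readers/writers and axis alignment.

The in-memory containers are deliberately lightweight (plain dataclasses over
numpy arrays) so that synthetic systems, parsed PDB/XYZ files and downstream
analyses all share one representation.  Parsing of the standard formats is
delegated to MDAnalysis; FASTA goes through Biopython.

The channel is analysed in a frame where the barrel axis coincides with z and
the barrel centroid sits at the origin; :func:`align_channel` establishes that
frame per trajectory snapshot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import (
    CHLORIDE_RESNAMES,
    DEFAULT_VDW_RADIUS,
    POTASSIUM_RESNAMES,
    VDW_RADII,
)

__all__ = [
    "Atom",
    "Residue",
    "MolecularModel",
    "Frame",
    "Trajectory",
    "IonTrack",
    "StructureParseError",
    "TrajectoryError",
    "AlignmentError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "read_fasta",
    "align_channel",
    "map_residue_label",
]


class StructureParseError(ValueError):
    """A structure file could not be parsed."""


class TrajectoryError(ValueError):
    """A trajectory file is structurally inconsistent with its model."""


class AlignmentError(ValueError):
    """The barrel selection is degenerate and defines no axis."""


@dataclass(frozen=True)
class Atom:
    """One atom: identity plus static properties (coordinates live in frames)."""

    serial: int
    name: str
    element: str
    vdw_radius: float
    residue_index: int
    coordinates: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")
        object.__setattr__(self, "coordinates", coords)


@dataclass
class Residue:
    index: int
    name: str
    chain: str
    atoms: list[Atom]

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("residue index must be >= 1")
        if not self.atoms:
            raise ValueError(f"residue {self.name}{self.index}: empty atom list")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.index}: no atom named {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class MolecularModel:
    """A protein (ordered residues) plus free ions and provenance metadata."""

    residues: list[Residue]
    ions: list[tuple[str, Atom]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        by_chain: dict[str, int] = {}
        for res in self.residues:
            prev = by_chain.get(res.chain)
            if prev is not None and res.index <= prev:
                raise ValueError(
                    f"residue indices not strictly increasing in chain {res.chain!r} "
                    f"at {res.name}{res.index}"
                )
            by_chain[res.chain] = res.index

    @property
    def atoms(self) -> list[Atom]:
        out = [a for res in self.residues for a in res.atoms]
        out.extend(a for _, a in self.ions)
        return out

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues) + len(self.ions)

    def residue_by_index(self, index: int) -> Residue:
        for res in self.residues:
            if res.index == index:
                return res
        raise KeyError(f"no residue with index {index}")

    def calpha_indices(self, residue_indices: Iterable[int] | None = None) -> np.ndarray:
        """Flat atom indices of CA atoms, optionally restricted to a residue set."""
        wanted = None if residue_indices is None else set(residue_indices)
        idx, flat = [], 0
        for res in self.residues:
            for a in res.atoms:
                if a.name == "CA" and (wanted is None or res.index in wanted):
                    idx.append(flat)
                flat += 1
        return np.asarray(idx, dtype=int)

    def ion_atom_indices(self, species: str | None = None) -> np.ndarray:
        offset = sum(len(r.atoms) for r in self.residues)
        return np.asarray(
            [offset + i for i, (sp, _) in enumerate(self.ions) if species is None or sp == species],
            dtype=int,
        )


@dataclass
class Frame:
    time: float  # ns
    coordinates: np.ndarray  # (n_atoms, 3) A

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("frame coordinates must have shape (n_atoms, 3)")


@dataclass
class Trajectory:
    model: MolecularModel
    frames: list[Frame]
    replica_id: int = 0
    timestep: float = 1.0  # ns between stored frames

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        n = self.model.n_atoms
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise TrajectoryError(
                    f"frame {i}: {fr.coordinates.shape[0]} atoms, model has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """All frame coordinates stacked, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass
class IonTrack:
    """Per-ion position series; NaN rows mark frames where the ion is absent."""

    species: str
    ion_id: int
    positions: np.ndarray  # (n_frames, 3), NaN where not stored

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("ion track positions must have shape (n_frames, 3)")
        if self.species not in ("Cl", "K"):
            raise ValueError(f"unknown ion species {self.species!r}")

    @property
    def z(self) -> np.ndarray:
        return self.positions[:, 2]


def _element_from_pdb(name: str, element_field: str) -> str:
    el = element_field.strip().upper()
    if el:
        return el
    # fall back on the atom-name convention: strip digits, first letters
    stripped = name.strip().lstrip("0123456789")
    if stripped[:2].upper() in VDW_RADII and len(stripped) > 1 and not stripped[1].isdigit():
        return stripped[:2].upper()
    return stripped[:1].upper()


def _vdw_for(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def _ion_species(resname: str, cl_names: Sequence[str], k_names: Sequence[str]) -> str | None:
    rn = resname.strip().upper()
    if rn in (n.upper() for n in cl_names):
        return "Cl"
    if rn in (n.upper() for n in k_names):
        return "K"
    return None


def read_structure(
    path: str | Path,
    chloride_resnames: Sequence[str] = CHLORIDE_RESNAMES,
    potassium_resnames: Sequence[str] = POTASSIUM_RESNAMES,
) -> MolecularModel:
    """Read a PDB file into a :class:`MolecularModel`.

    Ion records are recognised from their residue names (CLA/CL and POT/K by
    default, configurable for other force-field dialects) and separated from
    the protein residue list.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    residues: list[Residue] = []
    ions: list[tuple[str, Atom]] = []
    current: list[Atom] = []
    current_key: tuple[str, int, str] | None = None

    def flush():
        nonlocal current, current_key
        if current_key is not None:
            chain, resseq, resname = current_key
            residues.append(Residue(index=resseq, name=resname, chain=chain, atoms=current))
        current, current_key = [], None

    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            if rec.strip() in ("ENDMDL", "MODEL") and any(
                l[:6] in ("ATOM  ", "HETATM") for l in lines[lineno:]
            ):
                raise StructureParseError(
                    f"{path}: multi-model file; use read_trajectory for trajectories"
                )
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            resname = line[17:20].strip() or line[17:21].strip()
            chain = line[21:22].strip() or "A"
            resseq = int(line[22:26])
            xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            element = _element_from_pdb(name, line[76:78] if len(line) >= 78 else "")
        except (ValueError, IndexError) as exc:
            raise StructureParseError(f"{path}: malformed record at line {lineno}: {exc}") from exc
        species = _ion_species(resname, chloride_resnames, potassium_resnames)
        atom = Atom(
            serial=serial,
            name=name,
            element=element,
            vdw_radius=_vdw_for("CL" if species == "Cl" else "K" if species == "K" else element),
            residue_index=resseq,
            coordinates=xyz,
        )
        if species is not None:
            ions.append((species, atom))
            continue
        key = (chain, resseq, resname)
        if key != current_key:
            flush()
            current_key = key
        current.append(atom)
    flush()
    if not residues and not ions:
        raise StructureParseError(f"{path}: no ATOM/HETATM records found")
    return MolecularModel(residues=residues, ions=ions, metadata={"source": str(path)})


def read_trajectory(
    path: str | Path,
    model: MolecularModel,
    timestep: float = 1.0,
    replica_id: int = 0,
) -> Trajectory:
    """Read a multi-model PDB or XYZ coordinate trajectory against ``model``.

    Frame times are assigned as ``frame_index * timestep`` (ns); every frame
    must carry exactly the model's atom count.
    """
    import MDAnalysis as mda

    path = Path(path)
    n_expected = model.n_atoms
    frames: list[Frame] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() == ".xyz":
            # validate per-frame atom counts up front: MDAnalysis assumes a
            # homogeneous file and reports the first count only
            _validate_xyz_counts(path, n_expected)
            u = mda.Universe(str(path), format="XYZ")
        else:
            u = mda.Universe(str(path))
        if len(u.atoms) != n_expected:
            raise TrajectoryError(
                f"{path}: frame 0 has {len(u.atoms)} atoms, model has {n_expected}"
            )
        for i, _ts in enumerate(u.trajectory):
            frames.append(Frame(time=i * timestep, coordinates=u.atoms.positions.copy()))
    return Trajectory(model=model, frames=frames, replica_id=replica_id, timestep=timestep)


def _validate_xyz_counts(path: Path, n_expected: int) -> None:
    with open(path) as fh:
        frame = 0
        while True:
            header = fh.readline()
            if not header.strip():
                if not header:
                    break
                continue
            try:
                n = int(header.split()[0])
            except ValueError as exc:
                raise TrajectoryError(f"{path}: bad XYZ frame header at frame {frame}") from exc
            if n != n_expected:
                raise TrajectoryError(
                    f"{path}: frame {frame} has {n} atoms, model has {n_expected}"
                )
            fh.readline()  # comment
            for k in range(n):
                if not fh.readline():
                    raise TrajectoryError(f"{path}: frame {frame} truncated at atom {k}")
            frame += 1


def write_structure(model: MolecularModel, path: str | Path, coordinates: np.ndarray | None = None) -> None:
    """Write the model as a single-model PDB (protein residues then ion HETATMs)."""
    path = Path(path)
    coords = coordinates if coordinates is not None else np.array([a.coordinates for a in model.atoms])
    with open(path, "w") as fh:
        fh.write(_pdb_block(model, coords))
        fh.write("END\n")


def _pdb_block(model: MolecularModel, coords: np.ndarray) -> str:
    lines = []
    i = 0
    serial = 1
    for res in model.residues:
        for a in res.atoms:
            lines.append(_pdb_line("ATOM", serial, a.name, res.name, res.chain, res.index, coords[i], a.element))
            serial += 1
            i += 1
    for species, a in model.ions:
        resname = "CLA" if species == "Cl" else "POT"
        lines.append(_pdb_line("HETATM", serial, a.name, resname, "I", a.residue_index, coords[i], a.element))
        serial += 1
        i += 1
    return "".join(lines)


def _pdb_line(rec, serial, name, resname, chain, resseq, xyz, element) -> str:
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"{rec:<6s}{serial % 100000:>5d} {name_f}{'':1s}{resname:<4s}{chain:1s}"
        f"{resseq % 10000:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def write_trajectory(traj: Trajectory, path: str | Path, fmt: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or XYZ (chosen by extension or ``fmt``)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        atoms = traj.model.atoms
        with open(path, "w") as fh:
            for fr in traj.frames:
                fh.write(f"{len(atoms)}\n t = {fr.time:.6f} ns\n")
                for a, xyz in zip(atoms, fr.coordinates):
                    fh.write(f"{a.element:<2s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n")
    elif fmt == "pdb":
        with open(path, "w") as fh:
            for i, fr in enumerate(traj.frames, start=1):
                fh.write(f"MODEL     {i:>4d}\n")
                fh.write(_pdb_block(traj.model, fr.coordinates))
                fh.write("ENDMDL\n")
            fh.write("END\n")
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {record id: sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# axis alignment


def _covariance_axis(cov: np.ndarray, reference_axis: np.ndarray | None = None) -> np.ndarray:
    """Barrel axis from a CA positional covariance matrix.

    A cylindrical CA shell has two near-equal in-plane eigenvalues (R^2/2) and
    one distinct axial eigenvalue (H^2/12): the axis is the eigenvector whose
    eigenvalue is most separated from the other two — the smallest for a flat
    ring, the largest for a barrel taller than its radius.  When a
    ``reference_axis`` is supplied (per-frame use), the eigenvector most
    parallel to it is taken instead, which keeps the choice stable on frames
    where a breathing excursion splits the in-plane pair.
    """
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] < 1e-10 * max(evals[2], 1e-30):
        raise AlignmentError("barrel selection is (near-)collinear; axis undefined")
    if reference_axis is not None:
        k = int(np.argmax(np.abs(evecs.T @ reference_axis)))
        return evecs[:, k]
    if (evals[2] - evals[1]) > (evals[1] - evals[0]):
        return evecs[:, 2]
    return evecs[:, 0]


def _alignment_transform(
    barrel_xyz: np.ndarray,
    terminus_xyz: np.ndarray | None,
    reference_axis: np.ndarray | None = None,
):
    """Rotation + translation putting the barrel centroid at the origin and the
    barrel axis on z.

    The rotation is the minimal (geodesic) rotation taking the axis onto the
    nearer pole — no in-plane spin — so that frame-to-frame orientation about z
    stays stable even while the barrel cross-section breathes.
    """
    centroid = barrel_xyz.mean(axis=0)
    centred = barrel_xyz - centroid
    cov = centred.T @ centred / len(centred)
    axis = _covariance_axis(cov, reference_axis)
    # rotate the (sign-free) axis to the nearer pole: the rotation stays small
    # and well-conditioned, so frame-to-frame orientation is stable
    if axis[2] < 0:
        axis = -axis
    ez = np.array([0.0, 0.0, 1.0])
    c = float(axis @ ez)
    u = np.cross(axis, ez)
    s = np.linalg.norm(u)
    if s < 1e-15:
        rot = np.eye(3)
    else:
        u = u / s
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        rot = np.eye(3) + s * K + (1 - c) * (K @ K)
    # put the terminus side on +z with a fixed (deterministic) flip about x
    if terminus_xyz is not None:
        if (rot @ (terminus_xyz - centroid))[2] < 0:
            rot = np.diag([1.0, -1.0, -1.0]) @ rot
    assert np.linalg.det(rot) > 0
    return rot, centroid


def align_channel(
    traj: Trajectory,
    barrel_selection: Iterable[int],
    terminus_residues: Iterable[int] | None = None,
) -> Trajectory:
    """Center the barrel at the origin and align its axis with z, per frame.

    ``barrel_selection`` is a set of residue indices whose CA atoms define the
    barrel; the axis is the smallest-eigenvalue eigenvector of their positional
    covariance (a barrel's CAs form a ring spread in-plane).  The axis sign is
    chosen so the side holding ``terminus_residues`` (default: first and last
    protein residues, i.e. the N/C-terminus side) gets positive z.
    """
    barrel_selection = sorted(set(barrel_selection))
    if not barrel_selection:
        raise ValueError("barrel_selection must be non-empty")
    ca_idx = traj.model.calpha_indices(barrel_selection)
    if len(ca_idx) != len(barrel_selection):
        raise ValueError("every barrel residue must have a CA atom")
    if terminus_residues is None:
        terminus_residues = [traj.model.residues[0].index, traj.model.residues[-1].index]
    term_idx = traj.model.calpha_indices(terminus_residues)

    # reference axis from the trajectory-mean covariance: breathing excursions
    # average out, so the axial/in-plane eigenvalue gap is unambiguous there
    mean_cov = np.zeros((3, 3))
    for fr in traj.frames:
        bx = fr.coordinates[ca_idx]
        c = bx - bx.mean(axis=0)
        mean_cov += c.T @ c / len(c)
    ref_axis = _covariance_axis(mean_cov / traj.n_frames)

    new_frames = []
    for fr in traj.frames:
        barrel_xyz = fr.coordinates[ca_idx]
        term_xyz = fr.coordinates[term_idx].mean(axis=0) if len(term_idx) else None
        rot, centroid = _alignment_transform(barrel_xyz, term_xyz, reference_axis=ref_axis)
        new_frames.append(Frame(time=fr.time, coordinates=(fr.coordinates - centroid) @ rot.T))
    return Trajectory(
        model=traj.model, frames=new_frames, replica_id=traj.replica_id, timestep=traj.timestep
    )


def map_residue_label(isoform: str, seq_position: int) -> str:
    """Map a 1-based sequence position to the comparative residue numbering.

    hVDAC2 carries an 11-residue N-terminal extension that does not align with
    the other two isoforms; its first 11 residues are labelled 1'..11' and the
    remainder renumbered to match hVDAC1/hVDAC3.
    """
    lengths = {"hVDAC1": 283, "hVDAC2": 294, "hVDAC3": 283}
    if isoform not in lengths:
        raise ValueError(f"unknown isoform {isoform!r}")
    if not 1 <= seq_position <= lengths[isoform]:
        raise ValueError(f"{isoform}: position {seq_position} out of range 1..{lengths[isoform]}")
    if isoform == "hVDAC2":
        if seq_position <= 11:
            return f"{seq_position}′"
        return str(seq_position - 11)
    return str(seq_position)
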