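"""Shared fixtures: tiny hand-built models and trajectories.

Everything is generated programmatically; no stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from porescope.structure_io import Atom, Frame, MolecularModel, Residue, Trajectory


def make_ca_model(coords, names=None) -> MolecularModel:
    """CA-only model with one residue per coordinate."""
    coords = np.asarray(coords, dtype=float)
    names = names or ["GLY"] * len(coords)
    residues = []
    for i, (xyz, nm) in enumerate(zip(coords, names), start=1):
        residues.append(Residue(i, nm, "A", [Atom(i, "CA", "C", 1.7, i, xyz)]))
    return MolecularModel(residues=residues)


def make_trajectory(model, frame_coords, timestep=1.0, replica_id=0) -> Trajectory:
    frames = [Frame(time=i * timestep, coordinates=np.asarray(c, float))
              for i, c in enumerate(frame_coords)]
    return Trajectory(model=model, frames=frames, timestep=timestep, replica_id=replica_id)


@pytest.fixture
def ring_model():
    """36 CA atoms on a circle of radius 12 A at z = 0 (axis = z)."""
    ang = np.linspace(0, 2 * np.pi, 36, endpoint=False)
    coords = np.stack([12 * np.cos(ang), 12 * np.sin(ang), np.zeros(36)], axis=1)
    return make_ca_model(coords)


@pytest.fixture
def minimal_pdb(tmp_path):
    text = (
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1      10.621   6.530  -4.120  1.00  0.00           C\n"
        "END\n"
    )
    p = tmp_path / "minimal.pdb"
    p.write_text(text)
    return p
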