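"""Formal-charge annotation, charged-residue distribution maps (dP_z, dP_xy),
Kyte-Doolittle weighted-window hydropathy and sequence charge summaries.

Charge convention: Lys and Arg carry +1, Asp and Glu carry -1, histidine and
every other residue are neutral, and the chain termini are not charged.  Each
charged residue is represented by its charged-group centroid (NZ for Lys, the
guanidinium carbon CZ for Arg, the carboxylate carbon for Asp/Glu).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .constants import KYTE_DOOLITTLE
from .structure_io import MolecularModel

__all__ = [
    "ChargeAnnotation",
    "ChargeProfileZ",
    "ChargeMapXY",
    "HydropathyProfile",
    "annotate_charges",
    "delta_p_z",
    "delta_p_xy",
    "hydropathy_profile",
    "sequence_charge_summary",
    "load_bundled_sequences",
]

_CHARGE_SITES = {
    "LYS": (+1, "NZ"),
    "ARG": (+1, "CZ"),
    "ASP": (-1, "CG"),
    "GLU": (-1, "CD"),
}

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ChargeAnnotation:
    label: str  # e.g. "LYS20"
    residue_index: int
    sign: int  # +1, -1 or 0
    position: np.ndarray  # charged-group centroid, A
    lumen_facing: bool = True
    fallback: bool = False  # True when the side chain was missing and CB/CA was used


@dataclass
class ChargeProfileZ:
    """Signed charged-residue density along z: dP_z = P+ - P- (per A)."""

    bin_centers: np.ndarray
    p_plus: np.ndarray  # density, counts / A
    p_minus: np.ndarray
    bin_width: float

    @property
    def delta(self) -> np.ndarray:
        return self.p_plus - self.p_minus


@dataclass
class ChargeMapXY:
    """Signed 2D histogram of charged residues on the xy-plane (counts/cell)."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    delta: np.ndarray  # (nx, ny) signed counts


@dataclass
class HydropathyProfile:
    labels: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    constant: bool = False


def annotate_charges(
    model: MolecularModel,
    positions: np.ndarray | None = None,
    lumen_radius_of_z=None,
    facing_fraction: float = 0.85,
) -> list[ChargeAnnotation]:
    """Assign formal charges and representative positions to every residue.

    ``positions`` may supply alternative (e.g. trajectory-averaged) coordinates
    for the model's flat atom order.  When ``lumen_radius_of_z`` (a callable
    z -> local barrel CA radius) is given, a charged residue is marked
    lumen-facing when its centroid's radial distance is below
    ``facing_fraction`` of the local radius; otherwise every residue is
    considered facing.
    """
    flat_pos = {}
    i = 0
    for res in model.residues:
        for a in res.atoms:
            flat_pos[(res.index, a.name)] = (
                positions[i] if positions is not None else a.coordinates
            )
            i += 1
    out = []
    for res in model.residues:
        sign, site = _CHARGE_SITES.get(res.name, (0, None))
        fallback = False
        if site is not None and (res.index, site) in flat_pos:
            pos = np.asarray(flat_pos[(res.index, site)], dtype=float)
        else:
            for alt in ("CB", "CA"):
                if (res.index, alt) in flat_pos:
                    pos = np.asarray(flat_pos[(res.index, alt)], dtype=float)
                    fallback = site is not None
                    break
            else:
                pos = np.asarray(res.atoms[0].coordinates, dtype=float)
                fallback = site is not None
        facing = True
        if lumen_radius_of_z is not None:
            local = lumen_radius_of_z(pos[2])
            facing = bool(np.hypot(pos[0], pos[1]) < facing_fraction * local)
        out.append(
            ChargeAnnotation(
                label=f"{res.name}{res.index}",
                residue_index=res.index,
                sign=sign,
                position=pos,
                lumen_facing=facing,
                fallback=fallback,
            )
        )
    return out


def delta_p_z(
    annotations: Sequence[ChargeAnnotation],
    bin_width: float = 2.0,
    z_range: tuple[float, float] = (-30.0, 30.0),
    lumen_facing_only: bool = True,
    smoothing_sigma: float | None = None,
) -> ChargeProfileZ:
    """Difference between the axial distributions of + and - residues.

    Unsmoothed, the profile is a signed histogram density whose integral equals
    the signed residue count (sum dP_z * dz = N+ - N-).  Optional Gaussian
    smoothing (sigma in A) is for display only and breaks that identity at the
    margins.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    sel = [
        a for a in annotations if a.sign != 0 and (a.lumen_facing or not lumen_facing_only)
    ]
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    zp = [a.position[2] for a in sel if a.sign > 0]
    zm = [a.position[2] for a in sel if a.sign < 0]
    p_plus, _ = np.histogram(zp, bins=edges)
    p_minus, _ = np.histogram(zm, bins=edges)
    p_plus = p_plus / bin_width
    p_minus = p_minus / bin_width
    if smoothing_sigma:
        from scipy import ndimage

        s = smoothing_sigma / bin_width
        p_plus = ndimage.gaussian_filter1d(p_plus, s)
        p_minus = ndimage.gaussian_filter1d(p_minus, s)
    return ChargeProfileZ(centers, p_plus, p_minus, bin_width)


def delta_p_xy(
    annotations: Sequence[ChargeAnnotation],
    bin_width: float = 2.0,
    xy_range: tuple[float, float] = (-20.0, 20.0),
    z_range: tuple[float, float] | None = None,
    lumen_facing_only: bool = False,
) -> ChargeMapXY:
    """Signed 2D histogram of charged residues on the xy-plane.

    The unsmoothed grid sums to the signed count of mapped residues.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = xy_range
    if hi <= lo:
        raise ValueError("degenerate xy range")
    sel = [
        a for a in annotations if a.sign != 0 and (a.lumen_facing or not lumen_facing_only)
    ]
    if z_range is not None:
        sel = [a for a in sel if z_range[0] <= a.position[2] <= z_range[1]]
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    xp = np.array([a.position[:2] for a in sel if a.sign > 0]).reshape(-1, 2)
    xm = np.array([a.position[:2] for a in sel if a.sign < 0]).reshape(-1, 2)
    hp, _, _ = np.histogram2d(xp[:, 0], xp[:, 1], bins=(edges, edges))
    hm, _, _ = np.histogram2d(xm[:, 0], xm[:, 1], bins=(edges, edges))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ChargeMapXY(centers, centers, hp - hm)


def hydropathy_profile(
    sequence: str,
    window: int = 3,
    edge_weight: float = 0.30,
    labels: Sequence[str] | None = None,
) -> HydropathyProfile:
    """Kyte-Doolittle hydropathy with a weighted 3-residue window.

    Interior score: ``(w s[i-1] + s[i] + w s[i+1]) / (1 + 2 w)`` with
    ``w = edge_weight``; at the termini the missing neighbour's weight is
    dropped and the denominator renormalised.  The normalised profile is
    min-max scaled to [0, 1] (flagged constant when the raw profile is flat).
    """
    if window != 3:
        raise NotImplementedError("only the 3-residue window is implemented")
    sequence = sequence.upper()
    for i, c in enumerate(sequence):
        if c not in _STANDARD:
            raise ValueError(f"non-standard residue {c!r} at position {i + 1}")
    if len(sequence) < window:
        raise ValueError("sequence shorter than the window")
    s = np.array([KYTE_DOOLITTLE[c] for c in sequence])
    raw = np.empty(len(s))
    w = edge_weight
    for i in range(len(s)):
        num, den = s[i], 1.0
        if i > 0:
            num += w * s[i - 1]
            den += w
        if i + 1 < len(s):
            num += w * s[i + 1]
            den += w
        raw[i] = num / den
    span = raw.max() - raw.min()
    constant = span < 1e-12
    normalized = np.zeros_like(raw) if constant else (raw - raw.min()) / span
    if labels is None:
        labels = [str(i + 1) for i in range(len(s))]
    return HydropathyProfile(list(labels), raw, normalized, constant)


def sequence_charge_summary(sequence: str) -> tuple[int, int, int]:
    """(n_basic, n_acidic, net charge) of a one-letter sequence.

    Basic counts Lys + Arg, acidic counts Asp + Glu; histidine is treated as
    neutral.
    """
    sequence = sequence.upper()
    for i, c in enumerate(sequence):
        if c not in _STANDARD:
            raise ValueError(f"non-standard residue {c!r} at position {i + 1}")
    n_basic = sequence.count("K") + sequence.count("R")
    n_acidic = sequence.count("D") + sequence.count("E")
    return n_basic, n_acidic, n_basic - n_acidic


def load_bundled_sequences() -> dict[str, str]:
    """The three bundled human VDAC isoform sequences, keyed hVDAC1/2/3."""
    from Bio import SeqIO
    import io

    text = (resources.files("porescope") / "data" / "vdac_human.fasta").read_text()
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    key_of = {"VDAC1_HUMAN": "hVDAC1", "VDAC2_HUMAN": "hVDAC2", "VDAC3_HUMAN": "hVDAC3"}
    out = {}
    for rec in records:
        for tag, key in key_of.items():
            if tag in rec.id or tag in rec.description:
                out[key] = str(rec.seq)
    return out
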