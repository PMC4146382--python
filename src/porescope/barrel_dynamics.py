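"""Barrel dynamics: CA fluctuation correlation maps, breathing-axis
identification, secondary-structure assignment and hydrogen-bond occurrence.

Occurrence statistics follow the replica convention used throughout the
package: per-replica fractions first, then mean +- sample (n-1) standard
deviation across replicas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .structure_io import MolecularModel, Trajectory

__all__ = [
    "CorrelationMap",
    "SSRecord",
    "HBondRecord",
    "correlation_map",
    "identify_anticorrelation_axes",
    "pearson_correlation",
    "assign_secondary_structure",
    "ss_occurrence",
    "detect_hbonds",
    "hbond_occurrence_table",
]


@dataclass
class CorrelationMap:
    """Normalised CA fluctuation correlations; NaN entries mark zero-variance residues."""

    residue_indices: list[int]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.residue_indices)
        if self.matrix.shape != (n, n):
            raise ValueError("correlation matrix shape does not match residue list")
        self._pos = {r: i for i, r in enumerate(self.residue_indices)}

    def value(self, res_i: int, res_j: int) -> float:
        return float(self.matrix[self._pos[res_i], self._pos[res_j]])


@dataclass
class SSRecord:
    residue: int
    f_three_ten: float
    f_alpha: float
    f_unordered: float
    sd_three_ten: float = 0.0
    sd_alpha: float = 0.0
    sd_unordered: float = 0.0


@dataclass
class HBondRecord:
    donor: tuple[int, str]  # (residue index, heavy-atom name)
    acceptor: tuple[int, str]
    occurrence: float  # %
    occurrence_sd: float
    intra_nterm: bool = False


def correlation_map(
    replicas: Trajectory | Sequence[Trajectory],
    residue_indices: Iterable[int],
) -> CorrelationMap:
    """C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) of CA displacements.

    Displacements are taken from each CA's own time mean; maps are computed per
    replica and averaged.  Residues with zero positional variance yield NaN
    rows/columns (undefined correlation), except the unit diagonal.
    """
    if isinstance(replicas, Trajectory):
        replicas = [replicas]
    residue_indices = sorted(residue_indices)
    model = replicas[0].model
    ca_idx = model.calpha_indices(residue_indices)
    if len(ca_idx) != len(residue_indices):
        raise ValueError("a requested residue is missing its CA atom")
    maps = []
    for traj in replicas:
        if traj.n_frames < 2:
            raise ValueError("correlation map needs at least 2 frames")
        X = traj.coordinate_array()[:, ca_idx, :]
        dX = X - X.mean(axis=0)
        cov = np.einsum("tik,tjk->ij", dX, dX) / dX.shape[0]
        var = np.diag(cov).copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            C = cov / np.sqrt(np.outer(var, var))
        C[var <= 0, :] = np.nan
        C[:, var <= 0] = np.nan
        np.fill_diagonal(C, 1.0)
        maps.append(C)
    stacked = np.stack(maps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN entries stay NaN
        mean_map = np.nanmean(stacked, axis=0)
    return CorrelationMap(residue_indices, mean_map)


def _best_partner(cmap: CorrelationMap, ref_residues, candidates, maximise=True) -> int:
    """Barrel residue with extremal mean correlation to a reference set; ties
    break to the lower residue index."""
    scores = []
    for b in candidates:
        vals = [cmap.value(r, b) for r in ref_residues if r != b]
        vals = [v for v in vals if not np.isnan(v)]
        scores.append(np.mean(vals) if vals else np.nan)
    scores = np.asarray(scores)
    if maximise:
        best = np.nanmax(scores)
    else:
        best = np.nanmin(scores)
    for b, s in zip(candidates, scores):  # first hit = lowest index (candidates sorted)
        if s == best:
            return b
    raise ValueError("no defined correlations between reference and candidates")


def identify_anticorrelation_axes(
    cmap: CorrelationMap,
    nterm_range: Iterable[int],
    barrel_range: Iterable[int],
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the two cross-barrel anti-correlation axes from the map.

    Longitudinal axis: the barrel residue most positively correlated with the
    start of the N-terminal fragment (its anchored end), paired with the barrel
    residue of minimal correlation with it on the opposite wall.  Transversal
    axis: the same construction seeded from the central N-terminal residues.
    Ties break to the lower residue index.
    """
    nterm = sorted(set(nterm_range))
    barrel = sorted(set(barrel_range))
    if not nterm or not barrel:
        raise ValueError("nterm and barrel ranges must be non-empty")
    third = max(1, len(nterm) // 3)
    start_ref = nterm[:third]
    mid_ref = nterm[third: 2 * third] or nterm
    pairs = []
    for ref in (start_ref, mid_ref):
        anchor = _best_partner(cmap, ref, barrel, maximise=True)
        opposite = _best_partner(cmap, [anchor], barrel, maximise=False)
        pairs.append((anchor, opposite))
    return pairs[0], pairs[1]


def pearson_correlation(series_a, series_b) -> float:
    """Product-moment correlation coefficient of two equal-length series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# hydrogen bonds


def _backbone_coords(model: MolecularModel, coordinates: np.ndarray | None):
    """{residue index: {atom name: xyz}} for backbone atoms, building missing
    amide hydrogens at ideal geometry (1.01 A from N, anti to the previous C)."""
    flat = {}
    i = 0
    coords_of = {}
    for res in model.residues:
        coords_of[res.index] = {}
        for a in res.atoms:
            xyz = coordinates[i] if coordinates is not None else a.coordinates
            coords_of[res.index][a.name] = np.asarray(xyz, dtype=float)
            i += 1
    indices = [r.index for r in model.residues]
    for prev_idx, idx in zip(indices, indices[1:]):
        d = coords_of[idx]
        if "H" in d or "N" not in d:
            continue
        p = coords_of[prev_idx]
        if "C" not in p or "CA" not in d:
            continue
        v1 = d["N"] - p["C"]
        v2 = d["N"] - d["CA"]
        direction = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        d["H"] = d["N"] + 1.01 * direction / np.linalg.norm(direction)
    return coords_of


def detect_hbonds(
    model: MolecularModel,
    coordinates: np.ndarray | None = None,
    donors: Sequence[tuple[int, str, str]] | None = None,
    acceptors: Sequence[tuple[int, str]] | None = None,
    d_max: float = 3.5,
    angle_max: float = 30.0,
) -> list[tuple[tuple[int, str], tuple[int, str]]]:
    """Detected hydrogen bonds in one conformation.

    A donor triple ``(res, D, H)`` and acceptor pair ``(res, A)`` form a bond
    when the heavy-atom distance d(D, A) <= ``d_max`` (A) and the D-H...A
    deviation from linearity (180 deg minus the angle at H) <= ``angle_max``
    (deg).  Defaults scan backbone N-H donors against backbone O acceptors;
    hydrogens absent from the structure are placed geometrically.
    """
    coords_of = _backbone_coords(model, coordinates)
    if donors is None:
        donors = [
            (idx, "N", "H") for idx, d in coords_of.items() if "N" in d and "H" in d
        ]
    if acceptors is None:
        acceptors = [(idx, "O") for idx, d in coords_of.items() if "O" in d]
    found = []
    for (dres, dat, hat) in donors:
        dd = coords_of.get(dres, {})
        if dat not in dd or hat not in dd:
            continue
        D, H = dd[dat], dd[hat]
        for (ares, aat) in acceptors:
            if ares == dres:
                continue
            da = coords_of.get(ares, {})
            if aat not in da:
                continue
            A = da[aat]
            if np.linalg.norm(D - A) > d_max:
                continue
            v1, v2 = D - H, A - H
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if 180.0 - angle <= angle_max:
                found.append(((dres, dat), (ares, aat)))
    return found


def hbond_occurrence_table(
    replicas: Sequence[Trajectory],
    nterm_range: Iterable[int],
    donors: Sequence[tuple[int, str, str]] | None = None,
    acceptors: Sequence[tuple[int, str]] | None = None,
    threshold: float = 20.0,
    exclude_nterm_backbone_backbone: bool = True,
    d_max: float = 3.5,
    angle_max: float = 30.0,
) -> list[HBondRecord]:
    """Replica-averaged H-bond occurrence table for the N-terminal fragment.

    Per replica, a bond's occurrence is the percentage of frames it is
    detected; bonds whose replica-mean occurrence exceeds ``threshold`` (%) are
    returned sorted by donor residue then decreasing occurrence.  Bonds with
    both partners in ``nterm_range`` are flagged intra-N-terminal; backbone-
    backbone bonds internal to the fragment can be excluded (they restate the
    secondary structure).
    """
    nterm = set(nterm_range)
    per_bond: dict[tuple, list[float]] = {}
    n_rep = len(replicas)
    for ri, traj in enumerate(replicas):
        counts: dict[tuple, int] = {}
        for fr in traj.frames:
            for bond in detect_hbonds(
                traj.model, fr.coordinates, donors, acceptors, d_max, angle_max
            ):
                (dres, _), (ares, _) = bond
                if dres not in nterm and ares not in nterm:
                    continue
                counts[bond] = counts.get(bond, 0) + 1
        for bond, c in counts.items():
            per_bond.setdefault(bond, [0.0] * n_rep)[ri] = 100.0 * c / traj.n_frames
    records = []
    backbone_atoms = {"N", "O", "H"}
    for bond, occs in per_bond.items():
        (dres, dat), (ares, aat) = bond
        intra = dres in nterm and ares in nterm
        if (
            exclude_nterm_backbone_backbone
            and intra
            and dat in backbone_atoms
            and aat in backbone_atoms
        ):
            continue
        occs = np.asarray(occs)
        mean = float(occs.mean())
        if mean <= threshold:
            continue
        sd = float(occs.std(ddof=1)) if n_rep > 1 else 0.0
        records.append(HBondRecord(bond[0], bond[1], mean, sd, intra))
    records.sort(key=lambda r: (r.donor[0], -r.occurrence))
    return records


# ---------------------------------------------------------------------------
# secondary structure


def assign_secondary_structure(
    model: MolecularModel,
    coordinates: np.ndarray | None = None,
    residue_range: Iterable[int] | None = None,
    d_max: float = 3.5,
    angle_max: float = 30.0,
) -> dict[int, str]:
    """Label residues alpha / three_ten / unordered from backbone H-bond patterns.

    A helical turn of span n exists at residue i when the carbonyl O of i
    accepts the amide H of i+n.  Two consecutive i -> i+4 turns mark residues
    i+1..i+4 as alpha; two consecutive i -> i+3 turns mark i+1..i+3 as
    three_ten; alpha takes precedence where both patterns hold.  Everything
    else is unordered.
    """
    indices = [r.index for r in model.residues]
    if residue_range is not None:
        wanted = sorted(set(residue_range))
    else:
        wanted = indices
    missing = [
        r.index
        for r in model.residues
        if not (r.has_atom("N") and r.has_atom("CA") and r.has_atom("C") and r.has_atom("O"))
    ]
    if missing:
        raise ValueError(f"backbone atoms missing for residues {missing[:5]}")
    pos = {idx: k for k, idx in enumerate(indices)}
    bonds = detect_hbonds(model, coordinates, d_max=d_max, angle_max=angle_max)
    turns = {3: set(), 4: set()}
    for (dres, _), (ares, _) in bonds:
        if dres not in pos or ares not in pos:
            continue
        span = pos[dres] - pos[ares]
        if span in (3, 4):
            turns[span].add(pos[ares])
    labels = {idx: "unordered" for idx in indices}
    for i in sorted(turns[3]):
        if i + 1 in turns[3]:
            for j in range(i + 1, i + 4):
                if j < len(indices):
                    labels[indices[j]] = "three_ten"
    for i in sorted(turns[4]):
        if i + 1 in turns[4]:
            for j in range(i + 1, i + 5):
                if j < len(indices):
                    labels[indices[j]] = "alpha"
    return {idx: labels[idx] for idx in wanted}


def ss_occurrence(
    replicas: Sequence[Trajectory],
    residue_range: Iterable[int],
    **kwargs,
) -> list[SSRecord]:
    """Per-residue occurrence of 3_10 / alpha / unordered states.

    Fractions are computed per replica over frames (they sum to one exactly per
    residue per replica) and then averaged with a sample stdev across replicas.
    """
    residue_range = sorted(set(residue_range))
    n_rep = len(replicas)
    fr310 = np.zeros((n_rep, len(residue_range)))
    fra = np.zeros_like(fr310)
    fru = np.zeros_like(fr310)
    for ri, traj in enumerate(replicas):
        for fr in traj.frames:
            lab = assign_secondary_structure(
                traj.model, fr.coordinates, residue_range, **kwargs
            )
            for k, idx in enumerate(residue_range):
                if lab[idx] == "three_ten":
                    fr310[ri, k] += 1
                elif lab[idx] == "alpha":
                    fra[ri, k] += 1
                else:
                    fru[ri, k] += 1
        fr310[ri] /= traj.n_frames
        fra[ri] /= traj.n_frames
        fru[ri] /= traj.n_frames
    records = []
    for k, idx in enumerate(residue_range):
        sds = [
            float(x[:, k].std(ddof=1)) if n_rep > 1 else 0.0 for x in (fr310, fra, fru)
        ]
        records.append(
            SSRecord(
                residue=idx,
                f_three_ten=float(fr310[:, k].mean()),
                f_alpha=float(fra[:, k].mean()),
                f_unordered=float(fru[:, k].mean()),
                sd_three_ten=sds[0],
                sd_alpha=sds[1],
                sd_unordered=sds[2],
            )
        )
    return records
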