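"""Greedy neighbour-count clustering of recorded ion positions and
classification of the charged residues lining each cluster.

The clustering follows the iterative construction: count, for every recorded
ion position, its neighbours within the distance cutoff; the position with the
most neighbours seeds the first (most populated) cluster and is removed
together with its neighbours; repeat on the remainder until the next cluster's
occurrence (population / total analysed frames) falls below the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "IonCluster",
    "LiningReport",
    "cluster_positions",
    "filter_clusters",
    "lining_classification",
]

DEFAULT_REGION = ((-20.0, 20.0), (-20.0, 20.0), (-20.0, 20.0))


@dataclass
class IonCluster:
    species: str
    seed: np.ndarray  # position that seeded the cluster
    members: np.ndarray  # (m, 3) member positions incl. the seed
    occurrence: float  # population / total frames

    @property
    def population(self) -> int:
        return len(self.members)

    @property
    def center(self) -> np.ndarray:
        return self.members.mean(axis=0)


@dataclass
class LiningReport:
    """Charged residues lining the ion clusters, per species and summarised.

    ``per_cluster`` maps species -> list (one entry per cluster) of
    ``(positive labels, negative labels)``.  Totals are de-duplicated unions
    over a species' clusters; the summary splits residues into
    species-exclusive and shared ("both") categories.
    """

    per_cluster: dict[str, list[tuple[set, set]]]
    averages: dict[str, tuple[float, float]] = field(init=False)
    totals: dict[str, tuple[int, int]] = field(init=False)
    summary: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.averages, self.totals = {}, {}
        union: dict[str, tuple[set, set]] = {}
        for species, clusters in self.per_cluster.items():
            if clusters:
                self.averages[species] = (
                    float(np.mean([len(p) for p, _ in clusters])),
                    float(np.mean([len(n) for _, n in clusters])),
                )
            else:
                self.averages[species] = (0.0, 0.0)
            p_all = set().union(*[p for p, _ in clusters]) if clusters else set()
            n_all = set().union(*[n for _, n in clusters]) if clusters else set()
            self.totals[species] = (len(p_all), len(n_all))
            union[species] = (p_all, n_all)
        p_cl, n_cl = union.get("Cl", (set(), set()))
        p_k, n_k = union.get("K", (set(), set()))
        self.summary = {
            "P in Cl only": len(p_cl - p_k),
            "N in Cl only": len(n_cl - n_k),
            "P in K only": len(p_k - p_cl),
            "N in K only": len(n_k - n_cl),
            "P in both": len(p_cl & p_k),
            "N in both": len(n_cl & n_k),
        }


def cluster_positions(
    points: np.ndarray,
    total_frames: int,
    cutoff: float = 6.0,
    min_occurrence: float = 0.10,
    region: Sequence[tuple[float, float]] | None = DEFAULT_REGION,
    species: str = "Cl",
) -> list[IonCluster]:
    """Greedy neighbour-count clustering of ion positions.

    ``points`` are all recorded positions of one species pooled over frames and
    replicas; positions outside ``region`` are discarded first.  Neighbour
    counts are re-evaluated on the remaining pool at every iteration; ties on
    the neighbour count break to the lowest point index.  Iteration stops when
    the candidate cluster's occurrence drops below ``min_occurrence``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if total_frames <= 0:
        raise ValueError("total_frames must be positive")
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if region is not None:
        keep = np.ones(len(points), dtype=bool)
        for d, (lo, hi) in enumerate(region):
            keep &= (points[:, d] >= lo) & (points[:, d] <= hi)
        points = points[keep]
    clusters: list[IonCluster] = []
    if len(points) == 0:
        return clusters
    # neighbour counts are recomputed on the surviving pool each iteration; a
    # fresh KD-tree per round keeps memory flat even for ~1e5 pooled positions
    alive_idx = np.arange(len(points))
    while len(alive_idx):
        pool = points[alive_idx]
        tree = cKDTree(pool)
        counts = tree.query_ball_point(pool, cutoff, return_length=True)
        # first maximum = lowest original index (alive_idx stays sorted)
        seed_local = int(np.argmax(counts))
        members_local = np.asarray(tree.query_ball_point(pool[seed_local], cutoff), dtype=int)
        occurrence = len(members_local) / total_frames
        if occurrence < min_occurrence:
            break
        members_idx = alive_idx[members_local]
        clusters.append(
            IonCluster(
                species=species,
                seed=points[alive_idx[seed_local]].copy(),
                members=points[members_idx].copy(),
                occurrence=occurrence,
            )
        )
        keep = np.ones(len(alive_idx), dtype=bool)
        keep[members_local] = False
        alive_idx = alive_idx[keep]
    return clusters


def filter_clusters(
    clusters: Sequence[IonCluster], display_threshold: float = 0.20
) -> list[IonCluster]:
    """Clusters with occurrence >= threshold, order preserved."""
    return [c for c in clusters if c.occurrence >= display_threshold]


def lining_classification(
    clusters_cl: Sequence[IonCluster],
    clusters_k: Sequence[IonCluster],
    annotations,
    contact_cutoff: float = 5.0,
) -> LiningReport:
    """Classify charged residues lining the Cl and K clusters.

    ``annotations`` are :class:`porescope.charge_maps.ChargeAnnotation` records
    (the model must have been charge-annotated); a charged residue lines a
    cluster when its charged-group centroid lies within ``contact_cutoff`` of
    any member position.
    """
    charged = [a for a in annotations if a.sign != 0]
    if not charged and annotations is not None and len(list(annotations)) == 0:
        raise ValueError("model carries no charge annotations; run annotate_charges")
    per_cluster: dict[str, list[tuple[set, set]]] = {"Cl": [], "K": []}
    for species, clusters in (("Cl", clusters_cl), ("K", clusters_k)):
        for cl in clusters:
            tree = cKDTree(cl.members)
            pos, neg = set(), set()
            for ann in charged:
                if tree.query_ball_point(ann.position, contact_cutoff):
                    (pos if ann.sign > 0 else neg).add(ann.label)
            per_cluster[species].append((pos, neg))
    return LiningReport(per_cluster=per_cluster)
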