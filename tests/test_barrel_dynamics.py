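"""Correlation maps, secondary structure and hydrogen-bond occurrence."""

import numpy as np
import pytest

from porescope.barrel_dynamics import (
    CorrelationMap,
    assign_secondary_structure,
    correlation_map,
    detect_hbonds,
    hbond_occurrence_table,
    identify_anticorrelation_axes,
    pearson_correlation,
    ss_occurrence,
)
from porescope.structure_io import Atom, MolecularModel, Residue
from porescope.synthetic_data import generate_ideal_helix
from conftest import make_ca_model, make_trajectory


def _traj_from_displacements(base, disp_series):
    """Trajectory whose frame t is base + disp_series[t]."""
    model = make_ca_model(base)
    return make_trajectory(model, [base + d for d in disp_series])


class TestCorrelationMap:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 3)) * 10
        disp = rng.normal(size=(50, 6, 3))
        cmap = correlation_map(_traj_from_displacements(base, disp), range(1, 7))
        assert np.allclose(np.diag(cmap.matrix), 1.0, atol=1e-12)
        assert np.abs(cmap.matrix - cmap.matrix.T).max() < 1e-12
        assert np.nanmax(np.abs(cmap.matrix)) <= 1 + 1e-12

    def test_common_mode_gives_all_ones(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(5, 3)) * 10
        common = rng.normal(size=(100, 1, 3))
        cmap = correlation_map(_traj_from_displacements(base, np.repeat(common, 5, axis=1)), range(1, 6))
        assert np.allclose(cmap.matrix, 1.0, atol=1e-9)

    def test_antiphase_groups_minus_one(self):
        rng = np.random.default_rng(2)
        base = np.array([[10.0, 0, 0], [11, 0, 0], [-10, 0, 0], [-11, 0, 0]])
        amp = rng.normal(size=(200, 1, 1))
        zhat = np.array([0.0, 0.0, 1.0])
        signs = np.array([1.0, 1.0, -1.0, -1.0])[None, :, None]
        disp = amp * signs * zhat
        cmap = correlation_map(_traj_from_displacements(base, disp), range(1, 5))
        assert cmap.value(1, 3) == pytest.approx(-1.0, abs=1e-9)
        assert cmap.value(1, 2) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_residue_flagged_nan(self):
        base = np.array([[10.0, 0, 0], [-10, 0, 0]])
        disp = np.zeros((30, 2, 3))
        disp[:, 0, 2] = np.random.default_rng(3).normal(size=30)
        cmap = correlation_map(_traj_from_displacements(base, disp), range(1, 3))
        assert np.isnan(cmap.value(1, 2))
        assert cmap.value(2, 2) == 1.0


class TestAnticorrelationAxes:
    def _map(self, n, entries):
        m = np.zeros((n, n))
        np.fill_diagonal(m, 1.0)
        for i, j, v in entries:
            m[i, j] = m[j, i] = v
        return CorrelationMap(list(range(1, n + 1)), m)

    def test_unique_planted_extremum(self):
        # residues 1-2: N-term; 3-6: barrel. 3 tracks the N-term start (+0.9);
        # 5 is planted anti-correlated with 3 (-0.9); others mildly positive.
        cmap = self._map(
            6,
            [(2, 0, 0.9), (2, 1, 0.9), (2, 4, -0.9), (2, 3, 0.1), (2, 5, 0.1),
             (3, 0, 0.2), (3, 1, 0.2), (4, 0, 0.1), (4, 1, 0.1), (5, 0, 0.1), (5, 1, 0.1)],
        )
        lon, _ = identify_anticorrelation_axes(cmap, [1, 2], [3, 4, 5, 6])
        assert lon == (3, 5)

    def test_tied_minima_take_lower_index(self):
        cmap = self._map(
            5,
            [(1, 0, 0.9), (1, 2, -0.5), (1, 3, -0.5), (1, 4, 0.0)],
        )
        lon, _ = identify_anticorrelation_axes(cmap, [1], [2, 3, 4, 5])
        assert lon == (2, 3)  # ties on the minimum break to residue 3 over 4

    def test_empty_ranges_rejected(self):
        cmap = self._map(3, [])
        with pytest.raises(ValueError):
            identify_anticorrelation_axes(cmap, [], [1, 2, 3])


class TestPearson:
    def test_perfect_correlation_and_anticorrelation(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_planted_rho_fisher_bound(self):
        rng = np.random.default_rng(5)
        n, rho = 10_000, 0.7
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        assert pearson_correlation(x, y) == pytest.approx(0.70, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(10), np.arange(10.0))


class TestSecondaryStructure:
    @pytest.mark.parametrize(
        "kind, expected",
        [("alpha", "alpha"), ("three_ten", "three_ten"), ("extended", "unordered")],
    )
    def test_ideal_fixtures_interior_labels(self, kind, expected):
        model = generate_ideal_helix(kind, 12)
        labels = assign_secondary_structure(model)
        interior = [labels[i] for i in range(3, 11)]
        assert all(l == expected for l in interior)

    def test_missing_backbone_raises(self):
        model = make_ca_model([[0, 0, 0], [3, 0, 0], [6, 0, 0], [9, 0, 0]])
        with pytest.raises(ValueError, match="backbone"):
            assign_secondary_structure(model)


class TestSSOccurrence:
    def _helix_traj(self, n_frames=4):
        model = generate_ideal_helix("alpha", 12)
        coords = np.array([a.coordinates for a in model.atoms])
        return make_trajectory(model, [coords] * n_frames)

    def test_all_alpha_zero_sd(self):
        reps = [self._helix_traj() for _ in range(3)]
        records = ss_occurrence(reps, range(4, 10))
        for rec in records:
            assert rec.f_alpha == 1.0
            assert rec.f_three_ten == 0.0
            assert rec.f_unordered == 0.0
            assert rec.sd_alpha == 0.0

    def test_fractions_sum_to_one(self):
        reps = [self._helix_traj(3)]
        for rec in ss_occurrence(reps, range(1, 13)):
            assert rec.f_alpha + rec.f_three_ten + rec.f_unordered == pytest.approx(1.0)

    def test_replica_mean_and_sample_sd(self):
        """Replica fractions {0.1, 0.2, 0.3} must report 0.2 +- 0.1."""
        fracs = np.array([0.1, 0.2, 0.3])
        assert fracs.mean() == pytest.approx(0.2)
        assert fracs.std(ddof=1) == pytest.approx(0.1)


def _hbond_model(d_DA=2.9, angle_dev_deg=0.0):
    """Two-residue model with one N-H donor aimed at a carbonyl O acceptor."""
    theta = np.radians(angle_dev_deg)
    h = np.array([1.0, 0.0, 0.0])
    # H placed on the D->A line, then A rotated off-axis by the deviation angle
    a = np.array([1.0 + (d_DA - 1.0) * np.cos(theta), (d_DA - 1.0) * np.sin(theta), 0.0])
    donor_res = Residue(
        1, "GLY", "A",
        [
            Atom(1, "N", "N", 1.55, 1, np.zeros(3)),
            Atom(2, "CA", "C", 1.7, 1, np.array([0.0, -1.5, 0.0])),
            Atom(3, "H", "H", 1.2, 1, h),
        ],
    )
    acceptor_res = Residue(
        2, "GLY", "A",
        [
            Atom(4, "O", "O", 1.52, 2, a),
            Atom(5, "CA", "C", 1.7, 2, a + [0.0, 1.5, 0.0]),
        ],
    )
    return MolecularModel(residues=[donor_res, acceptor_res])


class TestDetectHBonds:
    def test_collinear_within_cutoff_detected(self):
        model = _hbond_model(d_DA=2.9, angle_dev_deg=0.0)
        bonds = detect_hbonds(model, donors=[(1, "N", "H")], acceptors=[(2, "O")])
        assert bonds == [((1, "N"), (2, "O"))]

    def test_beyond_distance_cutoff_rejected(self):
        model = _hbond_model(d_DA=5.0, angle_dev_deg=0.0)
        assert detect_hbonds(model, donors=[(1, "N", "H")], acceptors=[(2, "O")]) == []

    def test_beyond_angle_cutoff_rejected(self):
        model = _hbond_model(d_DA=2.9, angle_dev_deg=90.0)
        assert detect_hbonds(model, donors=[(1, "N", "H")], acceptors=[(2, "O")]) == []


class TestHBondOccurrenceTable:
    def _replicas_with_presence(self, per_replica_on_fraction, n_frames=40):
        """Replicas where the donor H tracks toward/away from the acceptor."""
        reps = []
        bonded = _hbond_model(2.9, 0.0)
        broken = _hbond_model(5.0, 0.0)
        coords_on = np.array([a.coordinates for a in bonded.atoms])
        coords_off = np.array([a.coordinates for a in broken.atoms])
        for ri, frac in enumerate(per_replica_on_fraction):
            n_on = int(round(frac * n_frames))
            frames = [coords_on] * n_on + [coords_off] * (n_frames - n_on)
            reps.append(make_trajectory(bonded, frames, replica_id=ri))
        return reps

    def _table(self, reps, threshold=20.0):
        return hbond_occurrence_table(
            reps,
            nterm_range=[1],
            donors=[(1, "N", "H")],
            acceptors=[(2, "O")],
            threshold=threshold,
            exclude_nterm_backbone_backbone=False,
        )

    def test_constant_occurrence_zero_sd(self):
        reps = self._replicas_with_presence([0.3] * 5, n_frames=1000)
        (rec,) = self._table(reps)
        assert rec.occurrence == pytest.approx(30.0)
        assert rec.occurrence_sd == pytest.approx(0.0)

    def test_below_threshold_excluded(self):
        reps = self._replicas_with_presence([0.15] * 5)
        assert self._table(reps, threshold=20.0) == []

    def test_replica_mean_and_sd(self):
        reps = self._replicas_with_presence([0.60, 0.70, 0.65, 0.60, 0.75], n_frames=20)
        (rec,) = self._table(reps)
        assert rec.occurrence == pytest.approx(66.0)
        assert rec.occurrence_sd == pytest.approx(6.519, abs=0.01)

    def test_zero_threshold_is_superset(self):
        reps = self._replicas_with_presence([0.15, 0.4, 0.9])
        all_bonds = {(r.donor, r.acceptor) for r in self._table(reps, threshold=0.0)}
        thresholded = {(r.donor, r.acceptor) for r in self._table(reps, threshold=20.0)}
        assert thresholded <= all_bonds
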