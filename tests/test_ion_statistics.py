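"""Occupancy, selectivity, translocation events and Boltzmann inversion."""

import numpy as np
import pytest

from porescope.constants import KT_300
from porescope.ion_statistics import (
    OccupancySeries,
    detect_translocations,
    free_energy_profile,
    integrate_free_energy,
    lumen_occupancy,
    occupancy_correlation,
    permeation_ratio,
    selectivity_ratio,
    FreeEnergyProfile,
)
from porescope.structure_io import IonTrack


def track_from_z(z, species="Cl", ion_id=0):
    z = np.asarray(z, dtype=float)
    pos = np.zeros((len(z), 3))
    pos[:, 2] = z
    return IonTrack(species=species, ion_id=ion_id, positions=pos)


def oracle_translocations(track, z_lo=-18.0, z_hi=18.0):
    """Independent formulation: compress the frame-region sequence into runs of
    outside visits separated by inside runs; opposite-side consecutive outside
    visits are events."""
    events = []
    segments = []  # list of (region, first_frame, last_frame) for below/above
    inside_run = None  # (first, last) of the current inside run
    pending = []
    last_outside = None  # ("below"|"above", inside_run_between)

    def reg(z):
        if np.isnan(z):
            return None
        return "below" if z < z_lo else "above" if z > z_hi else "inside"

    seq = [reg(z) for z in track.z]
    i = 0
    n = len(seq)
    prev_out = None  # ("below"/"above")
    run = None  # (first_inside, last_inside) since prev_out
    for i, r in enumerate(seq):
        if r is None:
            prev_out, run = None, None
        elif r == "inside":
            if prev_out is not None:
                run = (i, i) if run is None else (run[0], i)
        else:
            if prev_out is not None and r != prev_out:
                if run is not None:
                    entry, exit_ = run
                else:
                    entry = exit_ = i  # direct jump across the lumen
                events.append(
                    (track.ion_id, "+z" if r == "above" else "-z", entry, exit_)
                )
            prev_out, run = r, None
    return events


class TestLumenOccupancy:
    def test_single_ion_inside_counts_one(self):
        t = track_from_z([0.0])
        occ = lumen_occupancy([t], radial_gate=20.0)
        assert occ.counts.tolist() == [1]

    def test_outside_upper_bound_not_counted(self):
        t = track_from_z([19.0])
        assert lumen_occupancy([t]).counts.tolist() == [0]

    def test_radial_gate_excludes(self):
        pos = np.array([[25.0, 0.0, 0.0]])
        t = IonTrack(species="Cl", ion_id=0, positions=pos)
        assert lumen_occupancy([t], radial_gate=20.0).counts.tolist() == [0]

    def test_uniform_gas_mean_count(self):
        """Poisson sampling: mean count ~ n V within 3 standard errors."""
        rng = np.random.default_rng(0)
        n_frames, n_ions = 2000, 40
        L, R = 80.0, 20.0
        tracks = []
        for i in range(n_ions):
            pos = np.stack(
                [
                    rng.uniform(-R, R, n_frames),
                    rng.uniform(-R, R, n_frames),
                    rng.uniform(-L / 2, L / 2, n_frames),
                ],
                axis=1,
            )
            tracks.append(IonTrack("Cl", i, pos))
        occ = lumen_occupancy(tracks, z_bounds=(-18, 18), radial_gate=R)
        p = (36.0 / L) * (np.pi * R**2 / (2 * R) ** 2)
        expect = n_ions * p
        se = np.sqrt(n_ions * p * (1 - p) / n_frames)
        assert occ.counts.mean() == pytest.approx(expect, abs=3 * se)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            lumen_occupancy([track_from_z([0.0])], z_bounds=(5, -5))


class TestSelectivity:
    def test_worked_ratio_within_printed_band(self):
        """Per-replica mean counts 7.7 and 4.4 give 1.75, inside 1.7 +- 0.2."""
        occ_cl = [OccupancySeries("Cl", np.full(10, 7.7))]
        occ_k = [OccupancySeries("K", np.full(10, 4.4))]
        mean, sd, _ = selectivity_ratio(occ_cl, occ_k)
        assert mean == pytest.approx(1.75)
        assert 1.5 <= mean <= 1.9

    def test_identical_series_unity(self):
        occ = [OccupancySeries("Cl", np.array([3, 4, 5]))]
        occk = [OccupancySeries("K", np.array([3, 4, 5]))]
        mean, sd, _ = selectivity_ratio(occ, occk)
        assert mean == 1.0 and sd == 0.0

    def test_zero_mean_k_raises(self):
        occ = [OccupancySeries("Cl", np.array([1, 1]))]
        occk = [OccupancySeries("K", np.array([0, 0]))]
        with pytest.raises(ZeroDivisionError):
            selectivity_ratio(occ, occk)


class TestOccupancyCorrelation:
    def test_identical_series_plus_one(self):
        c = [OccupancySeries("Cl", np.array([1, 2, 3, 4]))]
        k = [OccupancySeries("K", np.array([1, 2, 3, 4]))]
        mean, _, _ = occupancy_correlation(c, k)
        assert mean == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(1)
        c = [OccupancySeries("Cl", rng.poisson(7, 10_000))]
        k = [OccupancySeries("K", rng.poisson(4, 10_000))]
        mean, _, _ = occupancy_correlation(c, k)
        assert mean == pytest.approx(0.0, abs=0.03)

    def test_paired_entry_positive(self):
        """K enters only when a Cl is inside: strong positive correlation."""
        rng = np.random.default_rng(2)
        cl = rng.poisson(0.7, 5000)  # lumen frequently empty of Cl
        k = np.where(cl > 0, rng.poisson(4, 5000), 0)
        mean, _, _ = occupancy_correlation(
            [OccupancySeries("Cl", cl)], [OccupancySeries("K", k)]
        )
        assert mean > 0.5


class TestUnwrapTrack:
    def test_wrapped_crossing_restored(self):
        """A trajectory wrapped into [-40, 40) unwraps to the original path."""
        from porescope.ion_statistics import unwrap_track

        true_z = np.linspace(-35, 55, 40)  # drifts past the +40 boundary
        box = np.array([80.0, 80.0, 80.0])
        wrapped = (true_z + 40) % 80 - 40
        t = track_from_z(wrapped)
        un = unwrap_track(t, box)
        assert np.allclose(un.z, true_z)
        # event detection sees one +z passage on the unwrapped track
        events = detect_translocations(un)
        assert [e.direction for e in events] == ["+z"]

    def test_nan_frames_pass_through(self):
        from porescope.ion_statistics import unwrap_track

        z = np.array([30.0, 39.0, np.nan, -39.0, -30.0])  # crosses +40 during the gap
        un = unwrap_track(track_from_z(z), (80, 80, 80))
        assert np.isnan(un.z[2])
        assert un.z[3] == pytest.approx(41.0)


class TestDetectTranslocations:
    def test_monotone_path_single_event(self):
        z = np.linspace(-25, 25, 51)  # crosses -18 at frame 7, +18 at frame 43
        events = detect_translocations(track_from_z(z), timestep=0.1)
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == "+z"
        inside = np.flatnonzero((z >= -18) & (z <= 18))
        assert ev.entry_frame == inside[0]
        assert ev.exit_frame == inside[-1]
        assert ev.passage_time == pytest.approx((inside[-1] - inside[0]) * 0.1)

    def test_retreat_resets_without_event(self):
        z = np.array([-25, -19, -17, -10, -17, -19, -25], float)
        assert detect_translocations(track_from_z(z)) == []

    def test_nan_gap_resets_state(self):
        z = np.array([-25, -10, np.nan, 10, 25], float)
        assert detect_translocations(track_from_z(z)) == []

    def test_oracle_equivalence_on_random_walks(self):
        """Event lists identical to the independent crossing-tally oracle on
        1000 randomised tracks."""
        rng = np.random.default_rng(3)
        for i in range(1000):
            n = int(rng.integers(20, 200))
            z = np.cumsum(rng.normal(0, 8, n)) + rng.uniform(-30, 30)
            if rng.random() < 0.2:  # occasional missing stretches
                k = rng.integers(0, n, size=max(1, n // 10))
                z[k] = np.nan
            track = track_from_z(z, ion_id=i)
            got = [
                (e.ion_id, e.direction, e.entry_frame, e.exit_frame)
                for e in detect_translocations(track)
            ]
            assert got == oracle_translocations(track), f"track {i}"


class TestPermeationRatio:
    def test_worked_examples_from_event_counts(self):
        """Printed per-direction mean counts: 51+44 vs 16+18 -> 95/34 = 2.79;
        43+49 vs 20+20 -> 92/40 = 2.30."""
        res = permeation_ratio([51 + 44], [16 + 18])
        assert res["pooled"] == pytest.approx(95 / 34, abs=1e-12)
        assert round(res["pooled"], 1) == 2.8
        res3 = permeation_ratio([43 + 49], [20 + 20])
        assert res3["pooled"] == pytest.approx(2.30)

    def test_equal_counts_unity(self):
        assert permeation_ratio([10, 12], [10, 12])["pooled"] == 1.0

    def test_no_k_events_raises(self):
        with pytest.raises(ZeroDivisionError):
            permeation_ratio([5], [0])


class TestFreeEnergyProfile:
    def test_uniform_density_zero_everywhere(self):
        rng = np.random.default_rng(4)
        tracks = [track_from_z(rng.uniform(-30, 30, 200_000))]
        prof = free_energy_profile(tracks, z_range=(-30, 30), bulk_region=25.0)
        assert np.nanmax(np.abs(prof.delta_g)) < 0.05

    def test_density_e_fold_gives_minus_kt(self):
        """A bin with rho = rho_bulk * e reads -k_B T = -0.596 kcal/mol at 300 K."""
        edges = np.arange(-30, 30.25, 0.5)
        centers = 0.5 * (edges[:-1] + edges[1:])
        per_bin = np.full(len(centers), 100)
        per_bin[np.argmin(np.abs(centers))] = int(round(100 * np.e))
        z = np.repeat(centers, per_bin)
        prof = free_energy_profile([track_from_z(z)], z_range=(-30, 30), bulk_region=25.0)
        k = np.argmin(np.abs(prof.bin_centers))
        assert prof.delta_g[k] == pytest.approx(-0.596, abs=2e-3)
        assert prof.delta_g[k] == pytest.approx(-KT_300 * np.log(np.e), abs=2e-3)

    def test_rescaling_invariance(self):
        """Eq. 1 output is invariant under common rescaling of all densities."""
        rng = np.random.default_rng(5)
        z = rng.uniform(-30, 30, 50_000)
        p1 = free_energy_profile([track_from_z(z)], z_range=(-30, 30))
        p2 = free_energy_profile([track_from_z(z), track_from_z(z)], z_range=(-30, 30))
        assert np.allclose(p1.delta_g, p2.delta_g, equal_nan=True)

    def test_density_conservation(self):
        """Sum over bins of density x bin volume = mean ions in the region."""
        rng = np.random.default_rng(6)
        n_frames, n_ions = 500, 7
        zs = [rng.uniform(-30, 30, n_frames) for _ in range(n_ions)]
        tracks = [track_from_z(z, ion_id=i) for i, z in enumerate(zs)]
        areas = np.full(120, 3.0)
        prof = free_energy_profile(tracks, z_range=(-30, 30), bin_areas=areas)
        mean_ions_in_region = np.sum(prof.density.density * 0.5 * areas)
        assert mean_ions_in_region == pytest.approx(n_ions, rel=1e-9)

    def test_empty_bulk_rejected(self):
        tracks = [track_from_z(np.zeros(100))]
        with pytest.raises(ValueError, match="bulk"):
            free_energy_profile(tracks, z_range=(-30, 30), bulk_region=25.0)


class TestIntegrateFreeEnergy:
    def _profile(self, values):
        centers = np.arange(-17.75, 18.0, 0.5)
        return FreeEnergyProfile(
            bin_centers=centers,
            delta_g=np.asarray(values, dtype=float),
            mask=np.zeros(len(centers), dtype=bool),
        )

    def test_zero_profile(self):
        prof = self._profile(np.zeros(72))
        assert integrate_free_energy(prof) == 0.0

    def test_constant_minus_one_over_range(self):
        prof = self._profile(np.full(72, -1.0))
        assert integrate_free_energy(prof) == pytest.approx(-3.6, abs=1e-12)

    def test_linear_ramp_matches_closed_form(self):
        centers = np.arange(-17.75, 18.0, 0.5)
        a, b = 0.07, -0.4
        prof = self._profile(a * centers + b)
        exact = (b * 36.0) / 10.0  # odd part integrates to zero over [-18, 18]
        assert integrate_free_energy(prof) == pytest.approx(exact, abs=1e-9)

    def test_masked_bin_in_range_rejected(self):
        prof = self._profile(np.zeros(72))
        prof.mask[30] = True
        prof.delta_g[30] = np.nan
        with pytest.raises(ValueError, match="masked"):
            integrate_free_energy(prof)
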