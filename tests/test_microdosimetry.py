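"""Packing, spectrum sampling, straight-track transport and tallies."""

import math

import numpy as np
import pytest

from rntlq import constants as C
from rntlq import spectrum as sp
from rntlq.errors import DomainError, PackingError
from rntlq.microdosimetry import (
    crossfire_experiment,
    daily_hit_bins,
    dose_actor,
    first_day_below,
    pack_cells,
    scale_tally,
    transport,
)


class TestPacking:
    def test_single_cell_deterministic(self):
        a = pack_cells(1, seed=9)
        b = pack_cells(1, seed=9)
        assert np.array_equal(a.cell_centers_um, b.cell_centers_um)
        assert a.n_cells == 1

    def test_full_scale_monolayer_packs(self):
        geom = pack_cells(5000, seed=1)
        assert geom.n_cells == 5000
        geom.validate()
        # dilute packing: ~2.7% of the floor area
        frac = 5000 * (geom.cell_diameter_um / 2) ** 2 / geom.well_radius_um**2
        assert frac < 0.03

    def test_min_pairwise_distance_is_cell_diameter(self):
        geom = pack_cells(300, well_radius_mm=0.4, seed=2)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(geom.cell_centers_um).query(geom.cell_centers_um, k=2)
        assert d[:, 1].min() >= geom.cell_diameter_um - 1e-9

    def test_infeasible_packing_signalled(self):
        with pytest.raises(PackingError):
            pack_cells(2000, well_radius_mm=0.1, seed=0)


class TestSpectrum:
    def test_sample_mean_matches_quoted_average(self):
        e = sp.sample_beta_energies(1_000_000, rng=1)
        assert e.mean() == pytest.approx(0.933, rel=0.01)

    def test_samples_never_exceed_endpoint(self):
        e = sp.sample_beta_energies(200_000, rng=2)
        assert e.max() <= sp.Y90_ENDPOINT_MEV

    def test_fixed_seed_bit_identical(self):
        a = sp.sample_beta_energies(1000, rng=7)
        b = sp.sample_beta_energies(1000, rng=7)
        assert np.array_equal(a, b)


class TestCSDARange:
    def test_endpoint_range(self):
        assert sp.csda_range(2.280) == pytest.approx(11.3, rel=0.10)

    def test_spectrum_average_range(self):
        e = sp.sample_beta_energies(200_000, rng=3)
        r = sp.csda_range(np.clip(e, 0.01, 2.3)).mean()
        assert r == pytest.approx(4.0, rel=0.15)

    def test_monotone_increasing(self):
        e = np.linspace(0.01, 2.3, 200)
        assert np.all(np.diff(sp.csda_range(e)) > 0)

    def test_out_of_table_rejected(self):
        with pytest.raises(DomainError):
            sp.csda_range(5.0)
        with pytest.raises(DomainError):
            sp.collision_stopping_power(0.001)

    def test_range_energy_inversion_round_trip(self):
        e = np.linspace(0.02, 2.2, 50)
        back = sp.energy_at_residual_range(sp.csda_range(e))
        assert np.allclose(back, e, rtol=1e-6)


class TestTransport:
    def test_energy_conservation(self, small_tally):
        assert small_tally.total_deposited_mev <= small_tally.total_emitted_mev
        cell_e = small_tally.energy_mev["cell"]
        assert cell_e <= small_tally.total_deposited_mev
        assert small_tally.energy_mev["nucleus"] + small_tally.energy_mev[
            "cytoplasm"
        ] == pytest.approx(cell_e, rel=1e-9)

    def test_seed_determinism_bit_identical(self, small_geometry):
        a = transport(small_geometry, 5000, seed=11)
        b = transport(small_geometry, 5000, seed=11)
        assert a.hits == b.hits
        assert np.array_equal(a.per_cell_nucleus_hits, b.per_cell_nucleus_hits)
        assert np.array_equal(a.per_cell_cell_energy_mev, b.per_cell_cell_energy_mev)
        assert a.total_deposited_mev == b.total_deposited_mev

    def test_nucleus_hits_bounded_by_cell_hits(self, small_tally):
        assert np.all(
            small_tally.per_cell_nucleus_hits <= small_tally.per_cell_cell_hits
        )
        assert np.all(small_tally.per_cell_nucleus_energy_mev <= small_tally.per_cell_cell_energy_mev + 1e-12)

    def test_hit_ratio_consistent_with_cross_sections(self, small_geometry):
        # expected nucleus/cell hit ratio ~ (r_nuc/r_cell)^2 under uniform
        # fluence; simplified physics only promises a factor of two
        tallies = [transport(small_geometry, 30000, seed=s) for s in (21, 22, 23)]
        nuc = sum(t.hits["nucleus"] for t in tallies)
        cell = sum(t.hits["cell"] for t in tallies)
        ratio = nuc / cell
        geometric = (C.NUCLEUS_DIAMETER_UM / C.CELL_DIAMETER_UM) ** 2
        assert geometric / 2 < ratio < geometric * 2

    def test_hit_linearity_in_particle_number(self, small_geometry):
        n = 4000
        singles = [transport(small_geometry, n, seed=100 + s).hits["cell"] for s in range(10)]
        doubles = [transport(small_geometry, 2 * n, seed=200 + s).hits["cell"] for s in range(10)]
        tot_1, tot_2 = sum(singles), sum(doubles)
        # doubling the primaries should double expected hits (Poisson errors)
        diff = tot_2 - 2 * tot_1
        sd = math.sqrt(tot_2 + 4 * tot_1)
        assert abs(diff) < 3 * sd


class TestScaleTally:
    def test_identity_and_doubling(self, small_tally):
        same = scale_tally(small_tally, float(small_tally.n_simulated))
        assert same.hits["cell"] == pytest.approx(small_tally.hits["cell"])
        double = scale_tally(small_tally, 2.0 * small_tally.n_simulated)
        assert double.hits["cell"] == pytest.approx(2 * small_tally.hits["cell"])
        assert double.energy_mev["nucleus"] == pytest.approx(
            2 * small_tally.energy_mev["nucleus"]
        )

    def test_full_activity_n_tilde_reported_with_uncertainty(self, small_tally):
        a_tilde = 8.45e10 * (0.5 / 3.25) ** 2  # volume-scaled top rung
        scaled = scale_tally(small_tally, a_tilde)
        assert scaled.n_tilde is not None and scaled.n_tilde > 0
        assert scaled.n_tilde_se is not None and scaled.n_tilde_se > 0
        assert math.isfinite(scaled.n_tilde)


class TestDailyHitBins:
    def test_bins_conserve_total_exactly(self):
        bins = daily_hit_bins(21.0, 0.0107)
        assert sum(bins) == pytest.approx(21.0, abs=1e-12)
        assert all(a > b for a, b in zip(bins, bins[1:]))

    def test_day_one_share(self):
        bins = daily_hit_bins(21.0, 0.0107)
        assert bins[0] == pytest.approx(21.0 * 0.260, abs=0.02)

    def test_threshold_crossing_day(self):
        bins = daily_hit_bins(21.0, 0.0107)
        # day-5 bin is 1.95 hits: the rate first drops below 2/day on day 5
        assert first_day_below(2.0, bins) == 5

    def test_never_below(self):
        bins = daily_hit_bins(1000.0, 0.0107)
        assert first_day_below(2.0, bins) is None
        assert first_day_below(0.0, bins) is None

    def test_empty_bins_rejected(self):
        with pytest.raises(DomainError):
            first_day_below(2.0, [])


class TestDoseActor:
    def test_energy_conservation_against_track_totals(self, small_geometry):
        tally = transport(small_geometry, 3000, seed=31, store_tracks=True)
        r = small_geometry.well_radius_um
        # region slightly taller than the well so the whole medium is covered
        grid = dose_actor(tally.tracks, 100.0, ((-r, r), (-r, r), (0.0, 6100.0)))
        # region covers the whole well: voxel sum equals in-well deposition
        assert grid.energy_mev.sum() == pytest.approx(
            tally.total_deposited_mev, rel=1e-6
        )
        assert np.all(grid.dose_gy >= 0)
        assert grid.ionisations.sum() == pytest.approx(
            grid.energy_mev.sum() * 1e6 / C.W_ION_PAIR_EV, rel=1e-9
        )

    def test_central_column_uniformity(self, small_geometry):
        tally = transport(small_geometry, 20000, seed=32, store_tracks=True)
        grid = dose_actor(
            tally.tracks, 100.0, ((-400.0, 400.0), (-400.0, 400.0), (0.0, 2000.0))
        )
        # central voxels at mid-depth should agree within 3 SD of their scatter
        central = grid.energy_mev[2:6, 2:6, 5:15].ravel()
        dev = np.abs(central - central.mean())
        assert dev.max() <= 3.0 * central.std(ddof=1) + 1e-12

    def test_zero_tracks_zero_grid(self, small_geometry):
        tally = transport(small_geometry, 1, seed=33, store_tracks=True)
        from rntlq.microdosimetry import Tracks

        empty = Tracks(
            origins_um=np.empty((0, 3)),
            directions=np.empty((0, 3)),
            energies_mev=np.empty(0),
            path_lengths_um=np.empty(0),
        )
        grid = dose_actor(empty, 50.0, ((0.0, 200.0), (0.0, 200.0), (0.0, 200.0)))
        assert grid.energy_mev.sum() == 0.0
        assert grid.hits.sum() == 0.0

    def test_degenerate_region_rejected(self, small_tally):
        with pytest.raises(DomainError):
            dose_actor(small_tally.tracks, 50.0, ((0.0, 0.0), (0.0, 100.0), (0.0, 100.0)))
        with pytest.raises(DomainError):
            dose_actor(small_tally.tracks, 33.0, ((0.0, 100.0), (0.0, 100.0), (0.0, 100.0)))


@pytest.fixture(scope="module")
def crossfire_result():
    return crossfire_experiment(30000, seed=6)


class TestCrossfire:
    def test_far_wells_receive_nothing(self, crossfire_result):
        result = crossfire_result
        # the third row sits ~18 mm from the sources, beyond the maximum
        # beta range: an isolated well sees zero external fraction
        far = result[result["role"] == "medium"]
        assert (far["external_fraction"] == 0).all()

    def test_active_wells_symmetric_within_poisson(self, crossfire_result):
        active = crossfire_result[crossfire_result["role"] == "active"]
        n1, n2 = active["external_entering"].to_numpy()
        assert abs(n1 - n2) <= 3 * math.sqrt(n1 + n2)

    def test_external_fraction_order_of_magnitude(self, crossfire_result):
        active = crossfire_result[crossfire_result["role"] == "active"]
        assert (active["external_fraction"] < 0.15).all()
        assert (active["external_fraction"] > 0).all()
        assert (active["external_fraction_se"] > 0).all()

    def test_doses_scale_with_activity(self):
        lo = crossfire_experiment(8000, seed=6, activity_bq=144e3)
        hi = crossfire_experiment(8000, seed=6, activity_bq=288e3)
        ratio = (
            hi[hi["role"] == "active"]["dose_gy"].to_numpy()
            / lo[lo["role"] == "active"]["dose_gy"].to_numpy()
        )
        assert np.allclose(ratio, 2.0, rtol=1e-9)
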