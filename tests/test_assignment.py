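import itertools

import numpy as np
import pytest
from scipy.stats import norm

from isomigrate import assignment, synthetic
from isomigrate.assignment import (AssignmentOptions, BinarySurface,
                                   DegeneratePosteriorError, PosteriorSurface)
from isomigrate.grid import GEOGRAPHIC, GeoGrid, GridSpec, Isoscape
from isomigrate.synthetic import DisplacementSpec, NoiseSpec

from conftest import toy_grid


def _iso(mean_rows, sd=1.0, **kw):
    g = toy_grid(mean_rows, **kw)
    return Isoscape(g, g.like(np.where(g.mask, sd, np.nan)))


class TestLikelihoodSurface:
    def test_constant_isoscape_gives_constant_density(self):
        iso = _iso([[-50.0] * 4] * 4, sd=2.0)
        dens = assignment.likelihood_surface(-50.0, 1.0, iso)
        assert np.nanstd(dens.values) == 0.0

    def test_density_ratio_matches_normal_pdf(self):
        iso = _iso([[0.0, 10.0]], sd=1.0)
        dens = assignment.likelihood_surface(0.0, 1e-9, iso)
        expect = norm.pdf(0.0, 0.0, 1.0) / norm.pdf(10.0, 0.0, 1.0)
        assert dens.values[0, 0] / dens.values[0, 1] == pytest.approx(
            expect, rel=1e-6)

    def test_doubling_sds_halves_peak_density(self):
        iso1 = _iso([[-50.0]], sd=2.0)
        iso2 = _iso([[-50.0]], sd=4.0)
        d1 = assignment.likelihood_surface(-50.0, 2.0, iso1)
        d2 = assignment.likelihood_surface(-50.0, 4.0, iso2)
        assert d2.values[0, 0] == pytest.approx(d1.values[0, 0] / 2)

    def test_nonpositive_sd_rejected(self):
        iso = _iso([[-50.0]])
        with pytest.raises(ValueError):
            assignment.likelihood_surface(-50.0, 0.0, iso)

    def test_nodata_propagates(self):
        iso = _iso([[0.0, np.nan]])
        dens = assignment.likelihood_surface(0.0, 1.0, iso)
        assert np.isnan(dens.values[0, 1])


class TestJointPosterior:
    def test_single_surface_is_normalized_identity(self):
        dens = toy_grid([[2.0, 6.0, 2.0]])
        post = assignment.joint_posterior([dens])
        np.testing.assert_allclose(post.probs.values, [[0.2, 0.6, 0.2]])

    def test_uniform_second_surface_changes_nothing(self):
        a = toy_grid([[2.0, 6.0, 2.0]])
        u = toy_grid([[1.0, 1.0, 1.0]])
        post = assignment.joint_posterior([a, u])
        np.testing.assert_allclose(post.probs.values, [[0.2, 0.6, 0.2]])

    def test_three_cell_product(self):
        """H (0.4, 0.4, 0.2) x Sr (0.9, 0.1, 0.0) -> (0.9, 0.1, 0.0)."""
        h = toy_grid([[0.4, 0.4, 0.2]])
        sr = toy_grid([[0.9, 0.1, 0.0]])
        post = assignment.joint_posterior([h, sr])
        np.testing.assert_allclose(post.probs.values, [[0.9, 0.1, 0.0]],
                                   atol=1e-12)

    def test_degenerate_product_rejected(self):
        a = toy_grid([[1.0, 0.0]])
        b = toy_grid([[0.0, 1.0]])
        with pytest.raises(DegeneratePosteriorError):
            assignment.joint_posterior([a, b])

    def test_mass_conserved_with_nodata(self):
        a = toy_grid([[2.0, np.nan, 6.0]])
        post = assignment.joint_posterior([a])
        assert np.nansum(post.probs.values) == pytest.approx(1.0)


def _brute_force_region(probs, odds=2.0):
    """Independent oracle: enumerate cells in descending probability,
    accumulate until the mass target is reached, include ties."""
    target = odds / (odds + 1.0)
    order = sorted(range(len(probs)), key=lambda i: -probs[i])
    chosen, mass = [], 0.0
    for i in order:
        chosen.append(i)
        mass += probs[i]
        if mass >= target - 1e-12:
            last = probs[i]
            chosen += [j for j in order if j not in chosen
                       and probs[j] == last]
            break
    return set(chosen)


class TestOddsRatioBinary:
    def test_three_cell_example(self, three_cell_posterior):
        b = assignment.odds_ratio_binary(three_cell_posterior)
        np.testing.assert_array_equal(b.mask_grid.values, [[1.0, 1.0, 0.0]])
        assert b.contained_mass == pytest.approx(0.8)

    def test_uniform_ties_all_included(self):
        post = PosteriorSurface(toy_grid([[1 / 3, 1 / 3, 1 / 3]]))
        b = assignment.odds_ratio_binary(post)
        assert b.n_cells == 3
        assert b.contained_mass == pytest.approx(1.0)

    def test_single_cell(self):
        post = PosteriorSurface(toy_grid([[1.0]]))
        b = assignment.odds_ratio_binary(post)
        assert b.n_cells == 1
        assert b.contained_mass == pytest.approx(1.0)

    def test_equals_brute_force_on_six_cell_permutations(self):
        probs = [0.35, 0.25, 0.15, 0.12, 0.08, 0.05]
        for perm in itertools.permutations(probs):
            post = PosteriorSurface(toy_grid([list(perm)]))
            b = assignment.odds_ratio_binary(post)
            got = {i for i in range(6) if b.mask_grid.values[0, i] == 1.0}
            assert got == _brute_force_region(list(perm))
            assert 2 / 3 - 1e-9 <= b.contained_mass <= 2 / 3 + max(perm) + 1e-9

    def test_cell_rank_mode_takes_top_third(self):
        probs = [0.35, 0.25, 0.15, 0.12, 0.08, 0.05]
        post = PosteriorSurface(toy_grid([probs]))
        b = assignment.odds_ratio_binary(post, mode="cell_rank")
        assert b.n_cells == 2  # ceil(6/3)


class TestMinDistance:
    def _binary(self, rows, **kw):
        g = toy_grid(rows, **kw)
        return BinarySurface(g, odds=2.0, contained_mass=1.0)

    def test_capture_inside_mask_is_zero(self):
        b = self._binary([[1.0, 0.0]])
        assert assignment.min_distance(b, 0.5, 0.5) == 0.0

    def test_one_degree_south_on_sphere(self):
        # 3x1 geographic grid; mask cell centred 1 degree south of capture
        g = toy_grid([[0.0], [0.0], [1.0]], crs=GEOGRAPHIC, x0=10.0, y0=40.0)
        b = BinarySurface(g, 2.0, 1.0)
        d = assignment.min_distance(b, 10.5, 41.5)
        assert d == pytest.approx(111.195, abs=0.01)

    def test_adding_cells_never_increases_distance(self):
        rng = np.random.default_rng(0)
        base = np.zeros((8, 8))
        base[6, 6] = 1.0
        b1 = self._binary(base.tolist())
        d1 = assignment.min_distance(b1, 0.5, 7.5)
        grown = base.copy()
        grown[3, 3] = 1.0
        b2 = self._binary(grown.tolist())
        assert assignment.min_distance(b2, 0.5, 7.5) <= d1

    def test_matches_brute_force_scan(self):
        from isomigrate import geo
        rng = np.random.default_rng(1)
        vals = (rng.uniform(size=(16, 16)) < 0.2).astype(float)
        vals[0, 0] = 1.0
        g = toy_grid(vals.tolist(), crs=GEOGRAPHIC, x0=-5.0, y0=10.0)
        b = BinarySurface(g, 2.0, 1.0)
        cap = (3.25, 12.75)
        got = assignment.min_distance(b, *cap)
        X, Y = g.spec.center_mesh()
        best = min(geo.great_circle_km(cap[0], cap[1], X[r, c], Y[r, c])
                   for r in range(16) for c in range(16) if vals[r, c] == 1.0)
        r0, c0 = g.spec.index_of(*cap)
        expect = 0.0 if vals[r0, c0] else best
        assert got == pytest.approx(expect, rel=1e-12)

    def test_empty_mask_rejected(self):
        b = self._binary([[0.0, 0.0]])
        with pytest.raises(ValueError):
            assignment.min_distance(b, 0.5, 0.5)


class TestPutativeLocalScreen:
    def test_zero_distance_is_local(self):
        assert assignment.screen_putative_local(0.0, True)

    def test_boundary_is_strict(self):
        assert assignment.screen_putative_local(99.9, False)
        assert not assignment.screen_putative_local(100.0, False)

    def test_distant_origins_flagged_migrant(self):
        """Specimens displaced 1000 km are overwhelmingly screened as
        migrants when the isoscapes are informative."""
        rates = []
        for seed in range(1, 6):
            world = synthetic.make_standard_world(seed)
            specs, _ = synthetic.simulate_specimens(
                world, 40, [(-5.0 + 2.0 * i, 36.5) for i in range(6)],
                DisplacementSpec(mean_km=1000.0, sd_km=100.0),
                NoiseSpec(seed=seed))
            metrics, _ = assignment.assign_table(
                specs, world.h_isoscape, world.sr_isoscape)
            rates.append(1.0 - metrics.putative_local.mean())
        assert np.mean(rates) >= 0.8


class TestStackBinaries:
    def _b(self, rows):
        return BinarySurface(toy_grid(rows), 2.0, 1.0)

    def test_single_binary_is_0_or_100(self):
        out = assignment.stack_binaries([self._b([[1.0, 0.0]])])
        np.testing.assert_allclose(out.values, [[100.0, 0.0]])

    def test_two_disjoint_masks(self):
        out = assignment.stack_binaries(
            [self._b([[1.0, 0.0]]), self._b([[0.0, 1.0]])])
        np.testing.assert_allclose(out.values, [[50.0, 50.0]])

    def test_three_masks_share_one_pixel(self):
        out = assignment.stack_binaries([
            self._b([[1.0, 1.0, 0.0]]),
            self._b([[1.0, 0.0, 1.0]]),
            self._b([[1.0, 0.0, 0.0]]),
        ])
        assert out.values[0, 0] == pytest.approx(100.0)
        assert out.values[0, 1] == pytest.approx(100 / 3)
        assert out.values[0, 2] == pytest.approx(100 / 3)

    def test_mixed_geometries_rejected(self):
        with pytest.raises(ValueError):
            assignment.stack_binaries(
                [self._b([[1.0, 0.0]]),
                 BinarySurface(toy_grid([[1.0, 0.0]], cell=2.0), 2.0, 1.0)])


class TestDirectionDistribution:
    def test_mass_due_south_means_northward_travel(self):
        # all posterior mass 1 degree south of the capture point
        g = toy_grid([[0.0], [0.0], [1.0]], crs=GEOGRAPHIC, x0=10.0, y0=40.0)
        post = PosteriorSurface(g)
        dens, mean_deg, resultant = assignment.direction_distribution(
            post, 10.5, 42.5)
        assert dens[0] == pytest.approx(1.0)
        assert mean_deg == pytest.approx(0.5)  # bin centre of [0, 1)
        assert resultant == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_mass_gives_zero_resultant(self):
        g = toy_grid([[0.5, np.nan, 0.5]])
        post = PosteriorSurface(g)
        dens, _, resultant = assignment.direction_distribution(
            post, 1.5, 0.5, distance_weighted=False)
        assert resultant == pytest.approx(0.0, abs=1e-9)

    def test_distance_weighting_hand_case(self):
        """Equal probabilities at 300 km (east of capture) and 100 km
        (west) -> distance-weighted bearing masses 0.75 and 0.25."""
        g = toy_grid([[0.5, np.nan, np.nan, np.nan, 0.5, np.nan, np.nan]],
                     cell=100.0)
        post = PosteriorSurface(g)
        dens, _, _ = assignment.direction_distribution(post, 350.0, 50.0)
        assert dens[90] == pytest.approx(0.75)   # origin at x=50, 300 km
        assert dens[270] == pytest.approx(0.25)  # origin at x=450, 100 km

    def test_density_sums_to_one(self, three_cell_posterior):
        dens, _, _ = assignment.direction_distribution(
            three_cell_posterior, 0.5, 0.5)
        assert dens.sum() == pytest.approx(1.0)


class TestBinaryCentroid:
    def test_single_cell_is_its_centre(self):
        g = toy_grid([[0.0, 1.0, 0.0]])
        c = assignment.binary_centroid(BinarySurface(g, 2.0, 1.0))
        assert c == (pytest.approx(1.5), pytest.approx(0.5))

    def test_symmetric_cells_centroid_on_meridian(self):
        g = toy_grid([[1.0, 0.0, 1.0]], crs=GEOGRAPHIC, x0=-1.5, y0=40.0)
        lon, lat = assignment.binary_centroid(BinarySurface(g, 2.0, 1.0))
        assert lon == pytest.approx(0.0, abs=1e-9)

    def test_antimeridian_uses_vector_mean(self):
        spec = GridSpec(1, 360, -180.0, 40.0, 1.0, crs=GEOGRAPHIC)
        vals = np.zeros((1, 360))
        vals[0, 0] = 1.0    # centre -179.5
        vals[0, 359] = 1.0  # centre +179.5
        lon, lat = assignment.binary_centroid(
            BinarySurface(GeoGrid(vals, spec), 2.0, 1.0))
        assert abs(lon) == pytest.approx(180.0, abs=1e-9)  # not 0


class TestAssignSpecimen:
    def _specimen(self, **kw):
        base = dict(id="s1", lon=0.5, lat=0.5, d2h=-50.0, d2h_sd=2.0,
                    sr=np.nan, sr_sd=np.nan)
        base.update(kw)
        return base

    def test_sr_omitted_equals_h_only(self, standard_world):
        specs, _ = synthetic.simulate_specimens(
            standard_world, 3, [(0.0, 36.0)], DisplacementSpec(800.0),
            NoiseSpec(seed=3))
        for _, s in specs.iterrows():
            a = assignment.assign_specimen(s, standard_world.h_isoscape, None)
            s2 = s.copy()
            s2["sr"] = np.nan
            b = assignment.assign_specimen(s2, standard_world.h_isoscape,
                                           standard_world.sr_isoscape)
            np.testing.assert_allclose(a.posterior.probs.values,
                                       b.posterior.probs.values,
                                       equal_nan=True)

    def test_informative_second_isotope_never_widens_toy_region(self):
        h = toy_grid([[0.4, 0.4, 0.2]])
        sr = toy_grid([[0.9, 0.1, 0.0]])
        single = assignment.odds_ratio_binary(
            assignment.joint_posterior([h]))
        dual = assignment.odds_ratio_binary(
            assignment.joint_posterior([h, sr]))
        assert dual.n_cells <= single.n_cells

    def test_zero_noise_specimen_mask_contains_true_origin(self,
                                                           standard_world):
        spec = standard_world.h_isoscape.spec
        r, c = spec.index_of(5.0, 20.0)
        s = self._specimen(
            lon=5.0, lat=20.0,
            d2h=float(standard_world.h_isoscape.mean.values[r, c]),
            d2h_sd=2.0,
            sr=float(standard_world.sr_isoscape.mean.values[r, c]),
            sr_sd=0.001)
        res = assignment.assign_specimen(s, standard_world.h_isoscape,
                                         standard_world.sr_isoscape)
        assert res.binary.cells[r, c]
        assert res.putative_local

    def test_no_isotope_rejected(self, standard_world):
        with pytest.raises(ValueError):
            assignment.assign_specimen(self._specimen(d2h=np.nan), None, None)

    def test_posterior_mass_conserved_through_pipeline(self, standard_world):
        specs, _ = synthetic.simulate_specimens(
            standard_world, 5, [(0.0, 36.0)], DisplacementSpec(1000.0),
            NoiseSpec(seed=8))
        _, results = assignment.assign_table(
            specs, standard_world.h_isoscape, standard_world.sr_isoscape)
        spec = standard_world.h_isoscape.spec
        for res, (_, s) in zip(results, specs.iterrows()):
            assert np.nansum(res.posterior.probs.values) == pytest.approx(1.0)
            assert res.direction_pdf.sum() == pytest.approx(1.0)
            # min distance is zero exactly when the capture cell is in
            # the highly probable region
            r, c = spec.index_of(s.lon, s.lat)
            assert (res.min_distance_km == 0.0) == bool(res.binary.cells[r, c])
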