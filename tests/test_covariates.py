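import itertools

import numpy as np
import pandas as pd
import pytest

from seaway.covariates import (
    ATTRACTION_FOR_SEASON,
    SampleMatrix,
    SphericalVariogram,
    build_samples,
    cost_distance,
    krige_field,
    match_covariates,
    reclassify_cost,
    sample_background,
)
from seaway.occurrence import PresenceRecord
from seaway.raster import Raster


# ---------------------------------------------------------------------------
# cost reclassification
# ---------------------------------------------------------------------------


class TestReclassifyCost:
    @pytest.mark.parametrize("depth,expected", [(50.0, 1.0), (5.0, 5.0), (300.0, 10.0),
                                                (10.0, 5.0), (200.0, 1.0)])
    def test_depth_class_mapping(self, depth, expected):
        r = Raster(np.full((2, 2), depth))
        assert reclassify_cost(r).values[0, 0] == expected

    def test_land_inside_mask_rejected(self):
        r = Raster(np.array([[50.0, -3.0]]))
        with pytest.raises(ValueError, match="mask"):
            reclassify_cost(r)

    def test_total_on_valid_cells(self, small_domain):
        bathy, _ = small_domain
        cost = reclassify_cost(bathy)
        assert set(np.unique(cost.values[cost.valid_mask])) <= {1.0, 5.0, 10.0}


# ---------------------------------------------------------------------------
# cost distance vs a brute-force relaxation oracle
# ---------------------------------------------------------------------------


def brute_force_cost_distance(cost: Raster, source: tuple[int, int]) -> np.ndarray:
    """Bellman-Ford-style relaxation over 8-neighbour moves until fixpoint.

    Independent of the shortest-path library used by the implementation.
    """
    n_rows, n_cols = cost.shape
    dist = np.full(cost.shape, np.inf)
    dist[source] = 0.0
    moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    changed = True
    while changed:
        changed = False
        for r in range(n_rows):
            for c in range(n_cols):
                if not cost.valid_mask[r, c] or np.isinf(dist[r, c]):
                    continue
                for dr, dc in moves:
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < n_rows and 0 <= c2 < n_cols):
                        continue
                    if not cost.valid_mask[r2, c2]:
                        continue
                    length = cost.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
                    step = 0.5 * (cost.values[r, c] + cost.values[r2, c2]) * length
                    if dist[r, c] + step < dist[r2, c2] - 1e-12:
                        dist[r2, c2] = dist[r, c] + step
                        changed = True
    return dist


class TestCostDistance:
    def test_uniform_strip_rook_distance(self):
        cost = Raster(np.ones((1, 12)), cell_size=2.0)
        field = cost_distance(cost, (0, 0))
        assert field.values[0, 10] == pytest.approx(10 * 2.0)

    def test_zero_at_attractor(self):
        cost = Raster(np.ones((5, 5)))
        assert cost_distance(cost, (2, 2)).values[2, 2] == 0.0

    def test_matches_brute_force_with_wall(self):
        vals = np.ones((5, 5))
        vals[:4, 2] = 10.0  # cost-10 wall with a gap at the bottom
        cost = Raster(vals)
        field = cost_distance(cost, (0, 0))
        oracle = brute_force_cost_distance(cost, (0, 0))
        np.testing.assert_allclose(field.values, oracle, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.choice([1.0, 5.0, 10.0], size=(6, 6))
        mask = rng.random((6, 6)) > 0.15
        src = tuple(np.argwhere(mask)[0])
        cost = Raster(vals, cell_size=1.0, valid_mask=mask)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # disconnected cells are fine here
            field = cost_distance(cost, src)
        oracle = brute_force_cost_distance(cost, src)
        np.testing.assert_allclose(field.values[mask], oracle[mask], rtol=1e-10)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(3)
        vals = rng.choice([1.0, 5.0, 10.0], size=(6, 6))
        cost = Raster(vals)
        cells = list(itertools.product(range(6), range(6)))
        fields = {c: cost_distance(cost, c).values for c in cells[:10]}
        for a in list(fields)[:5]:
            for b in list(fields)[:5]:
                for v in cells:
                    assert fields[a][v] <= fields[a][b] + fields[b][v] + 1e-9

    def test_invalid_attractor_rejected(self):
        mask = np.ones((4, 4), bool)
        mask[1, 1] = False
        cost = Raster(np.ones((4, 4)), valid_mask=mask)
        with pytest.raises(ValueError, match="attractor"):
            cost_distance(cost, (1, 1))

    def test_unreachable_cells_warned(self):
        mask = np.ones((3, 5), bool)
        mask[:, 2] = False  # split the strip in two
        cost = Raster(np.ones((3, 5)), valid_mask=mask)
        with pytest.warns(UserWarning, match="unreachable"):
            field = cost_distance(cost, (0, 0))
        assert np.isinf(field.values[0, 4])


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------


def target_geometry(n=8):
    return Raster(np.zeros((n, n)), cell_size=1.0, origin=(0.0, float(n)))


class TestKriging:
    def test_exact_at_data_points_zero_nugget(self):
        pts = [(1.5, 6.5, 3.0), (5.5, 2.5, -1.0), (2.5, 1.5, 4.0), (6.5, 6.5, 0.5)]
        vg = SphericalVariogram(nugget=0.0, psill=2.0, range_=10.0)
        field = krige_field(pts, target_geometry(), variogram=vg)
        # (1.5, 6.5) is the centre of cell row=1, col=1
        assert field.values[1, 1] == pytest.approx(3.0, abs=1e-8)
        assert field.values[5, 5] == pytest.approx(-1.0, abs=1e-8)

    def test_constant_field(self):
        pts = [(1.5, 6.5, 7.0), (5.5, 2.5, 7.0), (2.5, 1.5, 7.0)]
        field = krige_field(pts, target_geometry(),
                            variogram=SphericalVariogram(0.0, 1.0, 5.0))
        np.testing.assert_allclose(field.values, 7.0, atol=1e-8)

    def test_two_point_closed_form(self):
        # solve the 3x3 ordinary-kriging system by hand for one target cell
        vg = SphericalVariogram(nugget=0.0, psill=1.0, range_=20.0)
        p1, p2 = (0.5, 7.5, 2.0), (6.5, 1.5, 5.0)
        field = krige_field([p1, p2], target_geometry(), variogram=vg)
        tx, ty = 3.5, 4.5  # centre of cell (3, 3)
        g12 = vg(np.hypot(p1[0] - p2[0], p1[1] - p2[1]))
        g1 = vg(np.hypot(tx - p1[0], ty - p1[1]))
        g2 = vg(np.hypot(tx - p2[0], ty - p2[1]))
        A = np.array([[0.0, g12, 1.0], [g12, 0.0, 1.0], [1.0, 1.0, 0.0]])
        w = np.linalg.solve(A, np.array([g1, g2, 1.0]))
        expected = w[0] * p1[2] + w[1] * p2[2]
        assert field.values[3, 3] == pytest.approx(expected, abs=1e-10)

    def test_within_data_range_zero_nugget(self):
        rng = np.random.default_rng(0)
        pts = [(float(x), float(y), float(v))
               for x, y, v in zip(rng.uniform(0, 8, 12), rng.uniform(0, 8, 12),
                                  rng.uniform(-1, 1, 12))]
        field = krige_field(pts, target_geometry(),
                            variogram=SphericalVariogram(0.0, 1.0, 30.0))
        vals = np.array([p[2] for p in pts])
        spread = vals.max() - vals.min()
        assert field.values.min() >= vals.min() - 0.15 * spread
        assert field.values.max() <= vals.max() + 0.15 * spread

    def test_variogram_fit_recovers_smooth_surface(self):
        rng = np.random.default_rng(1)
        xs, ys = rng.uniform(0, 8, 40), rng.uniform(0, 8, 40)
        vals = np.sin(xs / 3.0) + 0.5 * ys
        pts = list(zip(xs, ys, vals))
        field = krige_field(pts, target_geometry())
        tx, ty = 4.5, 3.5  # centre of cell (4, 4)
        truth = np.sin(tx / 3.0) + 0.5 * ty
        assert field.values[4, 4] == pytest.approx(truth, abs=0.25)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            krige_field([(0.0, 0.0, 1.0), (1.0, 1.0, 2.0)], target_geometry())

    def test_collinear_points_rejected(self):
        pts = [(0.0, 0.0, 1.0), (1.0, 1.0, 2.0), (2.0, 2.0, 3.0)]
        with pytest.raises(ValueError, match="collinear"):
            krige_field(pts, target_geometry())


# ---------------------------------------------------------------------------
# covariate matching and background sampling
# ---------------------------------------------------------------------------


class TestMatchCovariates:
    def test_in_window_record_uses_own_year(self, small_stack):
        rec = PresenceRecord(row=30, col=35, lon=0.0, lat=0.0, season="summer", year=2005)
        row = match_covariates([rec], small_stack, window_years=(2004, 2006))
        expected = small_stack.seasonal[("summer", 2005)]["temp"].values[30, 35]
        assert row["temp"].iloc[0] == expected

    def test_out_of_window_record_uses_average(self, small_stack):
        rec = PresenceRecord(row=30, col=35, lon=0.0, lat=0.0, season="summer", year=1959,
                             source="report", month=7)
        row = match_covariates([rec], small_stack, window_years=(2004, 2006))
        expected = small_stack.seasonal[("summer", None)]["temp"].values[30, 35]
        assert row["temp"].iloc[0] == expected

    @pytest.mark.parametrize("season,attr", list(ATTRACTION_FOR_SEASON.items()))
    def test_season_restricted_attraction(self, small_stack, season, attr):
        rec = PresenceRecord(row=30, col=35, lon=0.0, lat=0.0, season=season, year=2005)
        row = match_covariates([rec], small_stack)
        other = ({"spawn_attr", "winter_attr"} - {attr}).pop()
        assert attr in row.columns
        assert other not in row.columns

    def test_missing_layer_named(self, small_stack):
        rec = PresenceRecord(row=30, col=35, lon=0.0, lat=0.0, season="summer", year=2010)
        with pytest.raises(KeyError, match="2010"):
            match_covariates([rec], small_stack, window_years=(2004, 2010))


class TestSampleBackground:
    def test_count_and_distinct(self, small_stack):
        bg = sample_background(small_stack, "summer", n=800, seed=1)
        assert len(bg) == 800
        assert len(set(bg.attrs["cells"])) == 800

    def test_deterministic(self, small_stack):
        a = sample_background(small_stack, "summer", n=100, seed=5)
        b = sample_background(small_stack, "summer", n=100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_points_rejected(self, small_stack):
        n_valid = int(small_stack.depth.valid_mask.sum())
        with pytest.raises(ValueError, match=str(n_valid)):
            sample_background(small_stack, "summer", n=n_valid + 1, seed=0)

    def test_selection_uniform_over_repeats(self):
        # 100-cell toy domain, 200 seeded draws of 20 -> uniform frequencies
        from scipy import stats

        from seaway.covariates import CovariateStack
        from seaway.raster import Raster

        zeros = Raster(np.zeros((10, 10)) + 50.0)
        layers = {n: Raster(np.zeros((10, 10))) for n in ("temp", "oxygen", "u_east", "v_north")}
        stack = CovariateStack(zeros, Raster(np.zeros((10, 10))), Raster(np.zeros((10, 10))),
                               {("summer", None): layers})
        counts = np.zeros(100)
        for seed in range(200):
            bg = sample_background(stack, "summer", n=20, seed=seed)
            for rr, cc in bg.attrs["cells"]:
                counts[rr * 10 + cc] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestSampleMatrix:
    def test_forbidden_attraction_column_rejected(self):
        data = pd.DataFrame({"depth": [1.0], "spawn_attr": [1.0], "temp": [5.0],
                             "oxygen": [90.0], "u_east": [0.0], "v_north": [0.0]})
        with pytest.raises(ValueError, match="season-restricted"):
            SampleMatrix(data, np.array([1]), "winter")

    def test_missing_values_rejected(self):
        data = pd.DataFrame({"depth": [np.nan], "temp": [5.0]})
        with pytest.raises(ValueError, match="missing"):
            SampleMatrix(data, np.array([1]), "summer")

    def test_csv_round_trip(self, small_stack, tmp_path, niche_samples):
        path = tmp_path / "samples.csv"
        niche_samples.to_csv(path)
        back = SampleMatrix.from_csv(path)
        assert back.season == niche_samples.season
        np.testing.assert_array_equal(back.labels, niche_samples.labels)
        pd.testing.assert_frame_equal(back.data, niche_samples.data, check_dtype=False)

    def test_build_samples_shape(self, small_stack, pipeline_result):
        sm = build_samples(pipeline_result.records, small_stack, "summer",
                           n_background=300, seed=2)
        assert sm.n_presence >= 1
        assert (sm.labels == 0).sum() == 300
        assert "winter_attr" not in sm.data.columns
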