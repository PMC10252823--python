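"""Isotope corrections, source screening and the mixing-polygon check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isoweb.errors import ConfigError, GeometryError, InputError
from isoweb.preprocess import (compute_delta, correct_consumers,
                               lipid_normalize, mixing_polygon_check,
                               points_in_hull, screen_sources,
                               summarize_sources, trophic_correct)


class TestComputeDelta:
    @pytest.mark.parametrize("rs, rstd, expected", [
        (1.0, 1.0, 0.0),
        (1.01, 1.0, 10.0),
        (0.98, 1.0, -20.0),
    ])
    def test_worked_examples(self, rs, rstd, expected):
        assert compute_delta(rs, rstd) == pytest.approx(expected)

    def test_nonpositive_ratio_raises(self):
        with pytest.raises(ValueError):
            compute_delta(-0.1, 1.0)
        with pytest.raises(ValueError):
            compute_delta(1.0, 0.0)


class TestLipidNormalize:
    def test_high_cn_applies_correction(self):
        assert lipid_normalize(-20.0, 4.0) == pytest.approx(-19.36)

    def test_missing_cn_passes_through(self):
        assert lipid_normalize(-25.0, None) == -25.0
        assert lipid_normalize(-25.0, float("nan")) == -25.0

    def test_threshold_cn_passes_through(self):
        assert lipid_normalize(-25.0, 3.5) == -25.0

    def test_nonpositive_cn_raises(self):
        with pytest.raises(ValueError):
            lipid_normalize(-20.0, -1.0)


class TestTrophicCorrect:
    def test_basal_level_identity(self):
        assert trophic_correct(-18.0, 8.0, tl=1.0) == (-18.0, 8.0)

    def test_hand_values(self):
        _, d15n = trophic_correct(0.0, 8.0, tl=2.4)
        assert d15n == pytest.approx(3.24)
        d13c, _ = trophic_correct(-18.0, 0.0, tl=3.0)
        assert d13c == pytest.approx(-18.8)

    @given(d13c=st.floats(-35, 0), d15n=st.floats(0, 15),
           tl=st.floats(1, 4))
    @settings(max_examples=50, deadline=None)
    def test_correction_idempotent_at_basal_level(self, d13c, d15n, tl):
        once = trophic_correct(d13c, d15n, tl)
        again = trophic_correct(*once, tl=1.0)
        assert again == once

    def test_unknown_guild_raises_naming_taxon(self):
        df = pd.DataFrame({"taxon": ["x"], "guild": ["shrubbery"],
                           "d13c": [-20.0], "d15n": [5.0]})
        with pytest.raises(ConfigError, match="shrubbery"):
            correct_consumers(df, {"piscivore": 3.0})

    def test_correct_consumers_applies_both_corrections(self):
        df = pd.DataFrame({"taxon": ["a", "b"], "guild": ["p", "p"],
                           "d13c": [-20.0, -20.0], "d15n": [8.0, 8.0],
                           "c_to_n": [4.0, np.nan]})
        out = correct_consumers(df, {"p": 2.0}, tdf=(0.4, 3.4))
        # row 0: lipid (-19.36) then trophic (-0.4)
        assert out["d13c_corr"].iloc[0] == pytest.approx(-19.76)
        assert out["d13c_corr"].iloc[1] == pytest.approx(-20.4)
        assert out["d15n_corr"].iloc[0] == pytest.approx(4.6)
        assert out["corrections_applied"].tolist() == ["lipid+trophic",
                                                       "trophic"]


def _source_table(values_by_source, area="A", season="s1"):
    rows = []
    for name, (c_vals, n_vals) in values_by_source.items():
        for c, n in zip(c_vals, n_vals):
            rows.append({"source": name, "area": area, "season": season,
                         "d13c": c, "d15n": n})
    return pd.DataFrame(rows)


class TestScreenSources:
    def test_identical_series_r_one(self):
        vals = ([-25.0, -24.0, -23.0, -22.0], [2.0, 3.0, 4.0, 5.0])
        table = _source_table({"a": vals, "b": vals})
        res = screen_sources(table)
        rr = res.r_matrix
        assert rr["r"].round(9).eq(1.0).all()
        assert res.dropped   # redundant pair flagged

    def test_perfect_anticorrelation(self):
        table = _source_table({
            "a": ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]),
            "b": ([3.0, 2.0, 1.0], [3.0, 2.0, 1.0])})
        rr = screen_sources(table).r_matrix
        assert rr["r"].round(9).eq(-1.0).all()

    def test_independent_long_series_both_retained(self):
        rng = np.random.default_rng(5)
        table = _source_table({
            "a": (rng.standard_normal(1000), rng.standard_normal(1000)),
            "b": (rng.standard_normal(1000), rng.standard_normal(1000))})
        res = screen_sources(table)
        assert res.dropped == []
        assert (res.r_matrix["r"].abs() < 0.1).all()

    def test_priority_list_controls_victim(self):
        vals_a = ([-25.0, -24.0, -23.0, -22.0], [2.0, 3.0, 4.0, 5.0])
        table = _source_table({"phyto": vals_a, "seston": vals_a})
        res = screen_sources(table, priority=["seston"])
        assert res.dropped == ["seston"]
        assert res.retained == ["phyto"]

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(50)
        y = 0.8 * x + 0.3 * rng.standard_normal(50)
        t1 = _source_table({"a": (x, x), "b": (y, y)})
        t2 = _source_table({"a": (y, y), "b": (x, x)})
        r1 = screen_sources(t1).r_matrix["r"].to_numpy()
        r2 = screen_sources(t2).r_matrix["r"].to_numpy()
        assert np.allclose(r1, r2)
        # affine rescaling of one series leaves |r| unchanged
        t3 = _source_table({"a": (x, x), "b": (5.0 * y - 2.0, y)})
        r3 = screen_sources(t3).r_matrix["r"].to_numpy()
        assert np.allclose(np.abs(r1), np.abs(r3))

    def test_single_source_raises(self):
        table = _source_table({"a": ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])})
        with pytest.raises(InputError):
            screen_sources(table)

    def test_default_scenario_drops_only_seston(self, sources_df):
        res = screen_sources(sources_df, priority=["seston"])
        assert res.dropped == ["seston"]
        rr = res.r_matrix
        pair = rr[(rr.source_a == "phytoplankton")
                  & (rr.source_b == "seston") & (rr.isotope == "d13c")]
        assert 0.5 < pair["r"].iloc[0] < 0.95


class TestSummarizeSources:
    def test_hand_computed_mean_sd(self):
        table = _source_table({"a": ([-28.0, -26.0], [1.0, 3.0])})
        out = summarize_sources(table)
        assert out["mu13"].iloc[0] == pytest.approx(-27.0)
        assert out["sd13"].iloc[0] == pytest.approx(np.sqrt(2.0))
        assert out["n"].iloc[0] == 2

    def test_single_replicate_flagged(self):
        table = _source_table({"a": ([-28.0], [1.0])})
        with pytest.warns(UserWarning, match="incomplete"):
            out = summarize_sources(table)
        assert out["incomplete"].iloc[0]
        assert np.isnan(out["sd13"].iloc[0])


def _orientation_inside(point, hull_pts):
    """Brute-force oracle: point is inside a convex polygon iff it lies on
    the same side of (or on) every directed hull edge."""
    from scipy.spatial import ConvexHull
    hull = ConvexHull(hull_pts)
    verts = hull_pts[hull.vertices]
    signs = []
    for i in range(len(verts)):
        a, b = verts[i], verts[(i + 1) % len(verts)]
        cross = ((b[0] - a[0]) * (point[1] - a[1])
                 - (b[1] - a[1]) * (point[0] - a[0]))
        signs.append(cross)
    signs = np.asarray(signs)
    return (signs >= -1e-9).all() or (signs <= 1e-9).all()


class TestPointInHull:
    def test_agrees_with_orientation_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n_hull = rng.integers(3, 5)
            hull_pts = rng.uniform(-1, 1, (n_hull, 2))
            pts = rng.uniform(-1.5, 1.5, (5, 2))
            try:
                mine = points_in_hull(pts, hull_pts)
            except GeometryError:
                continue
            oracle = [_orientation_inside(p, hull_pts) for p in pts]
            assert list(mine) == oracle

    def test_boundary_counts_inside(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        assert points_in_hull(np.array([[0.5, 0.0]]), square)[0]

    def test_too_few_points_raises(self):
        with pytest.raises(GeometryError):
            points_in_hull([[0, 0]], [[0, 0], [1, 1]])


def _summary(mus, sds):
    return pd.DataFrame({
        "source": [f"s{i}" for i in range(len(mus))],
        "mu13": [m[0] for m in mus], "sd13": [s[0] for s in sds],
        "mu15": [m[1] for m in mus], "sd15": [s[1] for s in sds]})


class TestMixingPolygonCheck:
    triangle = [(-28.0, 1.0), (-10.0, 3.0), (-20.0, 10.0)]

    def _consumers(self, points):
        return pd.DataFrame({"d13c_corr": [p[0] for p in points],
                             "d15n_corr": [p[1] for p in points]})

    def test_centroid_of_tight_sources_inside(self):
        centroid = np.mean(self.triangle, axis=0)
        out = mixing_polygon_check(
            self._consumers([centroid]),
            _summary(self.triangle, [(0.01, 0.01)] * 3),
            n_iter=200, seed=0)
        assert out["p_inside"].iloc[0] >= 0.99

    def test_far_exterior_probability_zero(self):
        out = mixing_polygon_check(
            self._consumers([(1000.0, 1000.0)]),
            _summary(self.triangle, [(1.0, 1.0)] * 3),
            n_iter=200, seed=0)
        assert out["p_inside"].iloc[0] == 0.0
        assert out["polygon_excluded"].iloc[0]

    def test_zero_sd_matches_deterministic_test(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-30, -5, (40, 2)) * [1, -0.2]
        out = mixing_polygon_check(
            self._consumers(list(map(tuple, pts))),
            _summary(self.triangle, [(0.0, 0.0)] * 3),
            n_iter=100, seed=1)
        deterministic = points_in_hull(pts, np.asarray(self.triangle))
        assert set(out["p_inside"]).issubset({0.0, 1.0})
        assert np.array_equal(out["p_inside"] == 1.0, deterministic)

    def test_fewer_than_three_sources_raises(self):
        with pytest.raises(GeometryError):
            mixing_polygon_check(self._consumers([(0, 0)]),
                                 _summary(self.triangle[:2],
                                          [(1, 1)] * 2), n_iter=100)
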