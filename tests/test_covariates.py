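import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from duckscape.covariates import (
    extract_segment_values,
    filter_correlated,
    focal_cv,
    focal_mean,
    idw_interpolate,
    make_lags,
)
from duckscape.grids import Grid
from duckscape.simdata import Segment, Stratum, SurveyDesign, Transect

CELL = 400.0
CELL_KM2 = 0.16


def grid_of(data):
    return Grid(np.asarray(data, dtype=float), cell_size=CELL)


def disc_area(radius_cells):
    """Window area whose exact disc radius is the given number of cells."""
    return np.pi * (radius_cells * CELL / 1000.0) ** 2


# ------------------------------------------------------------------ focal mean


def test_focal_mean_of_constant_is_constant():
    g = grid_of(np.full((9, 9), 3.25))
    out = focal_mean(g, 11.0)
    assert np.allclose(out.data, 3.25)


def test_single_cell_window_is_identity():
    rng = np.random.default_rng(1)
    g = grid_of(rng.normal(size=(6, 6)))
    out = focal_mean(g, CELL_KM2)
    assert np.allclose(out.data, g.data)


def test_focal_mean_matches_brute_force_disc():
    # oracle: explicit enumeration of the cells inside a 3-cell-radius disc
    g = grid_of(np.arange(1.0, 26.0).reshape(5, 5))
    area = disc_area(3.0)
    out = focal_mean(g, area)
    r, c = 2, 2
    members = []
    for i in range(5):
        for j in range(5):
            if np.hypot(i - r, j - c) <= 3.0 + 1e-9:
                members.append(g.data[i, j])
    assert np.isclose(out.data[r, c], np.mean(members), atol=1e-9)


def test_focal_mean_bounded_by_input_range():
    rng = np.random.default_rng(2)
    g = grid_of(rng.uniform(5, 9, size=(12, 12)))
    out = focal_mean(g, 11.0)
    assert out.data.min() >= 5 - 1e-9 and out.data.max() <= 9 + 1e-9


def test_focal_mean_ignores_nodata_neighbors():
    data = np.full((5, 5), 4.0)
    data[0, 0] = -9999.0
    out = focal_mean(grid_of(data), disc_area(1.0))
    assert np.allclose(out.data[out.mask()], 4.0)


def test_window_smaller_than_cell_rejected():
    with pytest.raises(ValueError):
        focal_mean(grid_of(np.ones((3, 3))), CELL_KM2 / 2)


# -------------------------------------------------------------------- focal cv


def test_cv_of_flat_surface_is_zero():
    out = focal_cv(grid_of(np.full((6, 6), 700.0)), 41.0)
    assert np.allclose(out.data, 0.0)


def test_cv_is_scale_invariant():
    rng = np.random.default_rng(3)
    data = rng.uniform(100, 900, size=(8, 8))
    a = focal_cv(grid_of(data), 41.0)
    b = focal_cv(grid_of(3.7 * data), 41.0)
    assert np.allclose(a.data, b.data, atol=1e-12)


def test_cv_matches_direct_formula_at_center():
    # oracle: direct sd/mean over the enumerated disc on a 7x7 toy raster
    rng = np.random.default_rng(4)
    data = rng.uniform(200, 800, size=(7, 7))
    radius = 2.0
    out = focal_cv(grid_of(data), disc_area(radius))
    r = c = 3
    members = [
        data[i, j]
        for i in range(7)
        for j in range(7)
        if np.hypot(i - r, j - c) <= radius + 1e-9
    ]
    expected = np.std(members) / np.mean(members)
    assert np.isclose(out.data[r, c], expected, atol=1e-9)


def test_cv_nonpositive_mean_becomes_nodata():
    data = np.zeros((5, 5))
    with pytest.warns(UserWarning, match="mean"):
        out = focal_cv(grid_of(data), disc_area(1.0))
    assert not out.mask().any()


# ------------------------------------------------------------------------- idw


def _point_grid():
    # 1x1 grid whose single cell center sits at the origin
    return Grid(np.zeros((1, 1)), cell_size=2.0, x_origin=-1.0, y_origin=-1.0)


def test_idw_exact_at_sample_point():
    g = _point_grid()
    pts = np.array([[0.0, 0.0, 42.0], [5.0, 0.0, 7.0]])
    out = idw_interpolate(pts, g)
    assert out.data[0, 0] == 42.0


def test_idw_constant_field_is_constant():
    rng = np.random.default_rng(5)
    g = Grid(np.zeros((6, 8)), cell_size=400.0)
    pts = np.column_stack([rng.uniform(0, 3200, 10), rng.uniform(0, 2400, 10), np.full(10, 3.5)])
    out = idw_interpolate(pts, g)
    assert np.allclose(out.data, 3.5)


def test_idw_hand_computed_weights():
    # oracle: distances 1, 2, 2 with values 10, 4, 4 and power 2
    # -> (10*1 + 4*0.25 + 4*0.25) / 1.5 = 8.0
    g = _point_grid()
    pts = np.array([[0.0, 1.0, 10.0], [2.0, 0.0, 4.0], [0.0, -2.0, 4.0]])
    out = idw_interpolate(pts, g, power=2.0, k_neighbors=3)
    assert np.isclose(out.data[0, 0], 8.0, atol=1e-12)


def test_idw_bounded_by_sample_range():
    rng = np.random.default_rng(6)
    g = Grid(np.zeros((10, 10)), cell_size=400.0)
    vals = rng.uniform(-3, 11, 15)
    pts = np.column_stack([rng.uniform(0, 4000, 15), rng.uniform(0, 4000, 15), vals])
    out = idw_interpolate(pts, g)
    assert out.data.min() >= vals.min() - 1e-9
    assert out.data.max() <= vals.max() + 1e-9


def test_idw_rejects_bad_inputs():
    g = _point_grid()
    with pytest.raises(ValueError):
        idw_interpolate(np.empty((0, 3)), g)
    with pytest.raises(ValueError):
        idw_interpolate(np.array([[0.0, 0.0, 1.0]]), g, power=0.0)


# ------------------------------------------------------------------------ lags


def test_lag_of_constant_series_is_constant():
    values = {y: 5.0 for y in range(6)}
    lags = make_lags(values, years=[2, 3, 4, 5])
    assert all(v == 5.0 for v in lags[1].values())
    assert all(v == 5.0 for v in lags[2].values())


def test_lag_shift_by_one():
    values = {0: 1, 1: 2, 2: 3, 3: 4}
    lags = make_lags(values, years=[2, 3], lags=(1,))
    assert lags[1] == {2: 2, 3: 3}


def test_lag2_is_lag1_of_lag1():
    # oracle: composition identity on a random series
    rng = np.random.default_rng(7)
    values = {y: rng.normal() for y in range(10)}
    direct = make_lags(values, years=range(4, 10), lags=(2,))[2]
    once = make_lags(values, years=range(3, 10), lags=(1,))[1]
    twice = make_lags(once, years=range(4, 10), lags=(1,))[1]
    assert direct == twice


def test_insufficient_history_names_first_valid_year():
    values = {2: 1.0, 3: 2.0}
    with pytest.raises(ValueError, match="first valid year is 4"):
        make_lags(values, years=[3], lags=(1, 2))


# ---------------------------------------------------------- correlation filter


def test_high_correlation_drops_lower_priority_column():
    rng = np.random.default_rng(8)
    x = rng.normal(size=300)
    df = pd.DataFrame({"a": x, "b": 0.95 * x + 0.3 * rng.normal(size=300)})
    assert abs(df["a"].corr(df["b"])) > 0.65
    assert filter_correlated(df, threshold=0.65, priority=["a", "b"]) == ["a"]
    assert filter_correlated(df, threshold=0.65, priority=["b", "a"]) == ["b"]


def test_orthogonal_columns_all_retained():
    rng = np.random.default_rng(9)
    df = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
    assert filter_correlated(df, threshold=0.65) == list("abcd")


def test_retained_set_is_pairwise_weakly_correlated():
    # oracle: exhaustive pairwise verification of the retained set
    rng = np.random.default_rng(10)
    base = rng.normal(size=(400, 2))
    df = pd.DataFrame(
        {
            "a": base[:, 0],
            "b": base[:, 0] + 0.1 * rng.normal(size=400),
            "c": base[:, 1],
            "d": base[:, 1] - 0.2 * rng.normal(size=400),
            "e": rng.normal(size=400),
        }
    )
    kept = filter_correlated(df, threshold=0.65)
    for i, u in enumerate(kept):
        for v in kept[i + 1 :]:
            assert abs(df[u].corr(df[v])) <= 0.65


def test_constant_column_dropped_with_warning():
    df = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
    with pytest.warns(UserWarning, match="constant"):
        kept = filter_correlated(df)
    assert kept == ["b"]


@given(st.permutations(["a", "b", "c", "d"]))
def test_filter_result_independent_of_column_order(order):
    rng = np.random.default_rng(11)
    base = rng.normal(size=(300, 4))
    base[:, 1] = base[:, 0] + 0.05 * rng.normal(size=300)
    df = pd.DataFrame(base, columns=list("abcd"))
    reference = filter_correlated(df, priority=list("abcd"))
    shuffled = filter_correlated(df[list(order)], subset=list(order), priority=list("abcd"))
    assert shuffled == reference


# ---------------------------------------------------------- segment extraction


def _toy_design():
    # one east-west segment on the row of cell centers at y = 600 (row 1 of 3)
    seg = Segment(
        id="t000s0",
        transect_id=0,
        stratum_id=0,
        x_start_m=0.0,
        x_end_m=1000.0,
        y_m=600.0,
        length_km=1.0,
        strip_half_width_m=200.0,
        area_km2=0.4,
    )
    stratum = Stratum(id=0, row_start=0, row_stop=3, area_km2=3 * 3 * 0.16, country=0)
    transect = Transect(id=0, stratum_id=0, y_m=600.0, x_start_m=0.0, x_end_m=1000.0)
    return SurveyDesign(strata=[stratum], transects=[transect], segments=[seg])


def test_extract_constant_raster_either_mode():
    g = Grid(np.full((3, 3), 6.5), cell_size=400.0)
    design = _toy_design()
    for mode in ("focal_mean_within_segment", "nearest_pixel_to_centroid"):
        vals = extract_segment_values(g, design, mode)
        assert vals["t000s0"] == 6.5


def test_extract_two_cell_strip_mean():
    data = np.zeros((3, 3))
    data[1, 0], data[1, 1] = 4.0, 8.0
    g = Grid(data, cell_size=400.0)
    vals = extract_segment_values(g, _toy_design())
    assert vals["t000s0"] == 6.0


def test_centroid_mode_matches_brute_force_nearest():
    # oracle: exhaustive distance scan over all pixel centers
    rng = np.random.default_rng(12)
    g = Grid(rng.normal(size=(3, 3)), cell_size=400.0)
    design = _toy_design()
    cx, cy = design.segments[0].centroid
    x, y = g.cell_centers()
    d = np.hypot(x - cx, y - cy)
    r, c = np.unravel_index(np.argmin(d), d.shape)
    vals = extract_segment_values(g, design, "nearest_pixel_to_centroid")
    assert vals["t000s0"] == g.data[r, c]


def test_extract_rejects_unknown_mode():
    g = Grid(np.zeros((3, 3)), cell_size=400.0)
    with pytest.raises(ValueError):
        extract_segment_values(g, _toy_design(), "bilinear")
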