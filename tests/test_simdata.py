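import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from duckscape import simdata
from duckscape.simdata import (
    N_BURNIN,
    SettlingParams,
    SimConfig,
    build_design,
    design_from_geojson,
    design_to_geojson,
    detection_probabilities,
    generate_landscape,
    generate_year_sequence,
    segment_cells,
    settle_population,
    settling_weights,
    simulate_observations,
    simulate_survey,
    write_records_csv,
)

from conftest import config_for, tiny_landscape, tiny_states, with_seed


# ---------------------------------------------------------------------- config


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(grid_ncols=0)
    with pytest.raises(ValueError):
        SimConfig(detection_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        SimConfig(n_years=2, population_series=(1000,))
    with pytest.raises(ValueError):
        SimConfig(moisture_ar1=1.0)


# ------------------------------------------------------------------- landscape


def test_landscape_deterministic_under_seed(small_config):
    a = generate_landscape(small_config)
    b = generate_landscape(small_config)
    for name, grid in a.as_dict().items():
        assert np.array_equal(grid.data, b.as_dict()[name].data), name


def test_zero_wetland_density_gives_empty_basins(small_config):
    cfg = dataclasses.replace(small_config, wetland_density=0.0)
    land = generate_landscape(cfg)
    assert np.all(land.wetland_count.data == 0)


def test_landcover_proportions_bounded(small_config):
    land = generate_landscape(small_config)
    total = land.crop.data + land.grass.data + land.forest.data
    assert total.max() <= 1.0 + 1e-9
    assert land.wetland_area.data.min() >= 0


@pytest.mark.parametrize("coupling, sign", [(1.0, 1), (-1.0, -1)])
def test_crop_ami_correlation_sign_matches_coupling(coupling, sign):
    # oracle: direct correlation of the two emitted rasters on a 100x100 grid
    cfg = SimConfig(
        grid_ncols=100,
        grid_nrows=100,
        n_years=1,
        population_series=(1000,),
        crop_ami_coupling=coupling,
        seed=11,
    )
    land = generate_landscape(cfg)
    r = np.corrcoef(land.crop.data.ravel(), land.ami.data.ravel())[0, 1]
    assert np.sign(r) == sign
    assert abs(r) > 0.2


# ----------------------------------------------------------------- year cycle


def test_constant_saturated_forcing_wets_every_basin(small_config):
    cfg = dataclasses.replace(small_config, moisture_sd=0.0, pond_logistic_intercept=50.0)
    land = generate_landscape(cfg)
    for state in generate_year_sequence(land, cfg):
        assert np.array_equal(state.ponds.data, land.wetland_count.data)


def test_constant_midrange_forcing_freezes_pond_pattern(small_config):
    cfg = dataclasses.replace(small_config, moisture_sd=0.0, pond_logistic_intercept=0.0)
    land = generate_landscape(cfg)
    states = generate_year_sequence(land, cfg)
    first = states[0].ponds.data
    assert 0 < first.sum() < land.wetland_count.data.sum()
    for state in states[1:]:
        assert np.array_equal(state.ponds.data, first)


def test_ponds_bounded_by_basins(small_config):
    land = generate_landscape(small_config)
    for state in generate_year_sequence(land, small_config):
        assert np.all(state.ponds.data >= 0)
        assert np.all(state.ponds.data <= land.wetland_count.data)


def test_moisture_ar1_recovered_from_long_series():
    # oracle: sample lag-1 autocorrelation of the spatially averaged index
    n_years = 198
    cfg = SimConfig(
        grid_ncols=30,
        grid_nrows=30,
        n_years=n_years,
        population_series=tuple([1000] * n_years),
        moisture_ar1=0.6,
        seed=5,
    )
    land = generate_landscape(cfg)
    states = generate_year_sequence(land, cfg)
    series = np.array([s.moisture_index.data.mean() for s in states])
    z = series - series.mean()
    rho = np.dot(z[1:], z[:-1]) / np.dot(z, z)
    assert abs(rho - 0.6) < 0.1


# -------------------------------------------------------------------- settling


def test_single_habitable_cell_takes_whole_population():
    land = tiny_landscape(4, 5, wetland=0.0)
    cfg = config_for(land, settling=SettlingParams(baseline=0.0, pond_lag1=0.0, pond_lag2=0.0))
    states = tiny_states(land, cfg.n_total_years, ponds_value=0.0)
    states[N_BURNIN].ponds.data[2, 3] = 5.0
    truth = settle_population(land, states, N_BURNIN, cfg)
    assert truth.pairs.data[2, 3] == cfg.population_series[0]
    assert truth.total == cfg.population_series[0]


def test_no_habitable_cells_is_an_error():
    land = tiny_landscape(4, 5, wetland=0.0)
    cfg = config_for(land, settling=SettlingParams(baseline=0.0, pond_lag1=0.0, pond_lag2=0.0))
    states = tiny_states(land, cfg.n_total_years, ponds_value=0.0)
    with pytest.raises(ValueError, match="no habitable cells"):
        settle_population(land, states, N_BURNIN, cfg)


def test_uniform_weights_spread_population_evenly():
    land = tiny_landscape(4, 5)
    cfg = config_for(land, population_series=(20000,))
    states = tiny_states(land, cfg.n_total_years)
    truth = settle_population(land, states, N_BURNIN, cfg)
    k = truth.pairs.data.size
    expected = cfg.population_series[0] / k
    sd = np.sqrt(cfg.population_series[0] * (1 / k) * (1 - 1 / k))
    assert np.all(np.abs(truth.pairs.data - expected) <= 4 * sd)


def test_allocation_follows_weights_in_the_long_run():
    # oracle: multinomial law of large numbers on a 20-cell example
    land = tiny_landscape(4, 5, wetland=3.0)
    base_cfg = config_for(land, population_series=(2000,))
    states = tiny_states(land, base_cfg.n_total_years)
    # non-uniform ponds -> non-uniform weights
    states[N_BURNIN].ponds.data[:] = np.arange(20, dtype=float).reshape(4, 5)
    w = settling_weights(land, states, N_BURNIN, base_cfg)
    probs = w / w.sum()
    totals = np.zeros_like(w)
    n_rep = 100
    for i in range(n_rep):
        truth = settle_population(land, states, N_BURNIN, with_seed(base_cfg, 100 + i))
        totals += truth.pairs.data
    observed = totals / (n_rep * base_cfg.population_series[0])
    assert np.max(np.abs(observed - probs)) < 0.005


def test_population_conserved_every_year(small_config):
    _, _, truths, _, _ = simulate_survey(small_config)
    for year, truth in truths.items():
        assert truth.total == small_config.population_for_year(year)


# ---------------------------------------------------------------------- design


def test_design_geometry(small_config):
    land = generate_landscape(small_config)
    design = build_design(small_config, land)
    # strata tile the grid
    rows = sorted((s.row_start, s.row_stop) for s in design.strata)
    assert rows[0][0] == 0 and rows[-1][1] == small_config.grid_nrows
    for (a, b), (c, d) in zip(rows, rows[1:]):
        assert b == c
    # every segment belongs to one transect/stratum; area identity (400-m strip)
    for seg in design.segments:
        assert np.isclose(seg.area_km2, seg.length_km * 0.4)
    assert set(s.id for s in design.comparison_segments) <= {s.id for s in design.segments}


def test_spacing_of_grid_height_gives_one_transect_per_stratum(small_config):
    cfg = dataclasses.replace(small_config, transect_spacing_km=small_config.height_km)
    land = generate_landscape(cfg)
    design = build_design(cfg, land)
    per_stratum = pd.Series([t.stratum_id for t in design.transects]).value_counts()
    assert (per_stratum == 1).all()


def test_segment_longer_than_transect_rejected(small_config):
    cfg = dataclasses.replace(small_config, segment_length_km=1000.0)
    land = generate_landscape(cfg)
    with pytest.raises(ValueError, match="segment length"):
        build_design(cfg, land)


def test_strip_cells_partition_exactly(small_config):
    # oracle: exhaustive check that every strip cell maps to exactly one segment
    land = generate_landscape(small_config)
    design = build_design(small_config, land)
    grid = land.grid()
    seen = {}
    for seg in design.segments:
        rr, cc = segment_cells(seg, grid)
        for r, c in zip(rr, cc):
            assert (r, c) not in seen, "cell assigned to two segments"
            seen[(r, c)] = seg.id
    # the strip rows are fully covered across the grid width
    transect_rows = {grid.row_of_y(t.y_m) for t in design.transects}
    assert len(seen) == len(transect_rows) * small_config.grid_ncols


def test_total_sampled_area_identity(small_config):
    land = generate_landscape(small_config)
    design = build_design(small_config, land)
    total = sum(s.area_km2 for s in design.segments)
    expected = sum(s.length_km for s in design.segments) * 0.4
    assert np.isclose(total, expected)


def test_design_geojson_round_trip(tmp_path, small_config):
    land = generate_landscape(small_config)
    design = build_design(small_config, land)
    obj = design_to_geojson(design, land.grid())
    path = tmp_path / "design.geojson"
    path.write_text(json.dumps(obj))
    back = design_from_geojson(json.loads(path.read_text()))
    assert len(back.segments) == len(design.segments)
    assert len(back.strata) == len(design.strata)
    for a, b in zip(design.segments, back.segments):
        assert a.id == b.id and a.stratum_id == b.stratum_id
        assert np.isclose(a.area_km2, b.area_km2)
        assert a.is_comparison == b.is_comparison


# ---------------------------------------------------------------- observations


def _one_year(config):
    land = generate_landscape(config)
    states = generate_year_sequence(land, config)
    design = build_design(config, land)
    truth = settle_population(land, states, N_BURNIN, config)
    return land, states, design, truth


def test_perfect_detection_reproduces_strip_truth(small_config):
    cfg = dataclasses.replace(small_config, detection_range=(1.0, 1.0))
    land, states, design, truth = _one_year(cfg)
    recs = simulate_observations(truth, states[N_BURNIN], design, cfg)
    assert (recs["aerial_pairs"] == recs["true_pairs"]).all()
    assert (recs["aerial_ponds"] == recs["true_ponds"]).all()


def test_vanishing_detection_sees_nothing(small_config):
    cfg = dataclasses.replace(small_config, detection_range=(1e-12, 1e-12))
    land, states, design, truth = _one_year(cfg)
    recs = simulate_observations(truth, states[N_BURNIN], design, cfg)
    assert (recs["aerial_pairs"] == 0).all()


def test_detection_rate_recovered(small_config):
    # oracle: binomial mean -- aerial/true ratio ~ p over many segment draws
    cfg = dataclasses.replace(small_config, detection_range=(0.6, 0.6))
    land, states, design, truth = _one_year(cfg)
    total_aerial = total_true = 0
    for i in range(50):
        recs = simulate_observations(truth, states[N_BURNIN], design, with_seed(cfg, 500 + i))
        total_aerial += recs["aerial_pairs"].sum()
        total_true += recs["true_pairs"].sum()
    assert abs(total_aerial / total_true - 0.6) < 0.03


def test_ground_counts_exceed_aerial_on_average(small_config):
    *_, records = simulate_survey(small_config)
    comp = records.dropna(subset=["ground_pairs"])
    assert comp["ground_pairs"].sum() >= comp["aerial_pairs"].sum()
    assert (comp["ground_pairs"] == comp["true_pairs"]).all()


def test_detection_probabilities_fixed_across_years(small_config):
    p1 = detection_probabilities(small_config)
    p2 = detection_probabilities(small_config)
    assert np.array_equal(p1, p2)
    lo, hi = small_config.detection_range
    assert np.all((p1 >= lo) & (p1 <= hi))


def test_records_csv_format(tmp_path, small_config):
    *_, records = simulate_survey(small_config)
    path = tmp_path / "records.csv"
    write_records_csv(records, path)
    back = pd.read_csv(path)
    assert list(back.columns) == [
        "year",
        "segment_id",
        "stratum_id",
        "aerial_pairs",
        "aerial_ponds",
        "ground_pairs",
        "ground_ponds",
    ]
    assert len(back) == len(records)


def test_full_simulation_reproducible(small_config):
    *_, rec_a = simulate_survey(small_config)
    *_, rec_b = simulate_survey(small_config)
    pd.testing.assert_frame_equal(rec_a, rec_b)
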