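"""Predictor construction: focal statistics, IDW surfaces, lags, pruning.

Habitat is characterized at a ~11 km^2 scale: every raster predictor is
passed through a circular focal mean of exactly that area before segment
values are extracted, so a segment's covariate and a grid cell's covariate
share the same spatial support.  Point-supported variables (segment pond
counts, coarse moisture-index stations) are first spread across the grid by
inverse-distance weighting.  Climate normals are pruned to a mutually
weakly correlated subset (|r| <= 0.65) before modeling.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import Grid
from .simdata import LandscapeStack, SimConfig, SurveyDesign, YearState, segment_cells

#: area of the habitat-characterization window (km^2); a disc of this area
#: has radius 1.871 km
WINDOW_AREA_KM2 = 11.0
#: area of the topographic-variation window (km^2); disc radius 3.612 km
CV_WINDOW_AREA_KM2 = 41.0

MODES = ("focal_mean_within_segment", "nearest_pixel_to_centroid")

#: the predictor set offered to the yearly models
PREDICTOR_COLUMNS = [
    "ponds_t",
    "ponds_t1",
    "ponds_t2",
    "pdsi_t1",
    "pdsi_t2",
    "ndwi_t",
    "wetland_count",
    "wetland_area",
    "srtm_cv",
    "dd5",
    "ami",
    "sspb",
    "crop",
    "grass",
    "forest",
    "gpp_t1",
    "gpp_t2",
    "country",
]
CLIMATE_COLUMNS = ["dd5", "ami", "sspb"]
RESPONSE_COLUMN = "corrected_pairs"


def _disc_offsets(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells + 1e-9))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = np.hypot(dy, dx) <= radius_cells + 1e-9
    kernel = np.zeros(dy.shape)
    kernel[keep] = 1.0
    return kernel


def _focal_sums(data: np.ndarray, valid: np.ndarray, kernel: np.ndarray):
    filled = np.where(valid, data, 0.0)
    total = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    count = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    return total, count


def focal_mean(grid: Grid, window_area_km2: float) -> Grid:
    """Circular moving-window mean of exact target area.

    Each cell becomes the mean of the input over a disc of the given area
    centered on it; cells near the edge are normalized by the cells actually
    present (shrink-window normalization, no padding).  A window of one cell
    area is the identity.
    """
    if window_area_km2 < grid.cell_area_km2 * (1 - 1e-9):
        raise ValueError("window area must be at least one cell area")
    radius_cells = np.sqrt(window_area_km2 / np.pi) / (grid.cell_size / 1000.0)
    kernel = _disc_offsets(radius_cells)
    valid = grid.mask()
    total, count = _focal_sums(grid.data, valid, kernel)
    out = np.full(grid.data.shape, grid.nodata)
    ok = count > 0
    out[ok] = total[ok] / count[ok]
    return grid.like(out)


def focal_cv(grid: Grid, window_area_km2: float) -> Grid:
    """Coefficient of variation (sd/mean) over a circular window.

    The CV is undefined where the window mean is not strictly positive;
    such cells become nodata with a warning.
    """
    radius_cells = np.sqrt(window_area_km2 / np.pi) / (grid.cell_size / 1000.0)
    kernel = _disc_offsets(radius_cells)
    valid = grid.mask()
    total, count = _focal_sums(grid.data, valid, kernel)
    total_sq, _ = _focal_sums(grid.data**2, valid, kernel)
    out = np.full(grid.data.shape, grid.nodata)
    ok = count > 0
    mean = np.where(ok, total / np.maximum(count, 1), 0.0)
    var = np.where(ok, total_sq / np.maximum(count, 1) - mean**2, 0.0)
    var = np.clip(var, 0.0, None)  # guards tiny negative round-off
    pos = ok & (mean > 0)
    if np.any(ok & ~pos):
        warnings.warn("focal_cv: window mean <= 0 in some cells; emitted as nodata")
    out[pos] = np.sqrt(var[pos]) / mean[pos]
    return grid.like(out)


def idw_interpolate(
    points: np.ndarray,
    grid: Grid,
    power: float = 2.0,
    k_neighbors: int = 12,
) -> Grid:
    """Inverse-distance-weighted surface from (x, y, value) samples.

    Cell value = sum(w_i v_i)/sum(w_i) with w_i = d_i^(-power) over the k
    nearest samples; a cell coincident with a sample returns that sample's
    value exactly.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] == 0 or points.shape[1] != 3:
        raise ValueError("points must be a nonempty (n, 3) array of x, y, value")
    if power <= 0:
        raise ValueError("power must be positive")
    tree = cKDTree(points[:, :2])
    k = min(k_neighbors, len(points))
    x, y = grid.cell_centers()
    query = np.column_stack([x.ravel(), y.ravel()])
    dist, idx = tree.query(query, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    vals = points[idx, 2]
    exact = dist[:, 0] < 1e-9
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[exact, :] = 0.0
    w[exact, 0] = 1.0
    out = (w * vals).sum(axis=1) / w.sum(axis=1)
    return grid.like(out.reshape(grid.data.shape))


def make_lags(
    values: Mapping[int, object],
    years: Iterable[int],
    lags: Sequence[int] = (1, 2),
) -> dict[int, dict[int, object]]:
    """Lagged views of a per-year mapping.

    ``out[lag][year]`` is ``values[year - lag]``; every requested year must
    have the needed history (the simulator's burn-in years provide it for
    the first modeled year).
    """
    years = list(years)
    out: dict[int, dict[int, object]] = {}
    for lag in lags:
        out[lag] = {}
        for year in years:
            if year - lag not in values:
                first_valid = min(values) + max(lags)
                raise ValueError(
                    f"insufficient history for lag {lag} at year {year}; first valid year is {first_valid}"
                )
            out[lag][year] = values[year - lag]
    return out


def filter_correlated(
    matrix: pd.DataFrame,
    subset: Sequence[str] | None = None,
    threshold: float = 0.65,
    priority: Sequence[str] | None = None,
) -> list[str]:
    """Greedy correlation pruning.

    Columns are visited in priority order; a column is dropped when its
    absolute Pearson correlation with any already-retained column exceeds
    the threshold.  Constant columns have undefined correlation and are
    dropped with a warning.  The result depends only on the priority list,
    not on the input column order.
    """
    cols = list(subset) if subset is not None else list(matrix.columns)
    order = [c for c in (priority if priority is not None else cols) if c in cols]
    missing = set(cols) - set(order)
    if missing:
        raise ValueError(f"priority list missing columns: {sorted(missing)}")
    retained: list[str] = []
    for col in order:
        x = matrix[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"filter_correlated: column {col!r} is constant; dropped")
            continue
        ok = True
        for kept in retained:
            r = np.corrcoef(x, matrix[kept].to_numpy(dtype=float))[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            retained.append(col)
    return retained


def extract_segment_values(
    grid: Grid,
    design: SurveyDesign,
    mode: str = "focal_mean_within_segment",
) -> pd.Series:
    """Per-segment covariate values from a raster.

    ``focal_mean_within_segment``: mean over the cells whose centers fall in
    the segment's 400-m strip.  ``nearest_pixel_to_centroid``: the value of
    the single pixel nearest the segment centroid.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    values = {}
    for seg in design.segments:
        if mode == "focal_mean_within_segment":
            rr, cc = segment_cells(seg, grid)
            vals = grid.data[rr, cc]
            valid = ~np.isclose(vals, grid.nodata)
            if not valid.any():
                raise ValueError(f"segment {seg.id}: empty strip")
            values[seg.id] = float(vals[valid].mean())
        else:
            cx, cy = seg.centroid
            col = int(np.clip(np.floor((cx - grid.x_origin) / grid.cell_size), 0, grid.ncols - 1))
            row = grid.row_of_y(cy)
            values[seg.id] = float(grid.data[row, col])
    return pd.Series(values, name=mode)


# ---------------------------------------------------------------------------
# pipeline assembly


def _moisture_stations(state: YearState, step_cells: int = 20) -> np.ndarray:
    """Coarse (x, y, value) samples of the moisture field, emulating the
    sparse station support of a drought index before interpolation."""
    g = state.moisture_index
    rows = np.arange(step_cells // 2, g.nrows, step_cells)
    cols = np.arange(step_cells // 2, g.ncols, step_cells)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    x = g.x_origin + (cc.ravel() + 0.5) * g.cell_size
    y = g.y_origin + (g.nrows - rr.ravel() - 0.5) * g.cell_size
    return np.column_stack([x, y, g.data[rr.ravel(), cc.ravel()]])


def build_analysis_inputs(
    landscape: LandscapeStack,
    year_states: list[YearState],
    design: SurveyDesign,
    corrected_records: pd.DataFrame,
    config: SimConfig,
    idw_power: float = 2.0,
    idw_k: int = 12,
    min_length_fraction: float = 0.5,
):
    """Assemble the segment-year covariate matrix and per-year grid stacks.

    ``corrected_records`` must carry VCF-corrected counts (columns
    ``corrected_pairs`` and ``corrected_ponds``) for every simulated year,
    burn-in included, so pond lags exist for the first modeled year.

    Returns ``(matrix, grid_stacks)``: the matrix has one row per
    (segment, modeled year) with the full predictor set plus the response;
    ``grid_stacks[year][name]`` is the matching prediction raster.  Pond
    surfaces are IDW extrapolations of the segment-level corrected counts;
    the moisture index is sampled at coarse stations, IDW-interpolated, and
    focally averaged; all other rasters are 11-km^2 focal means of the
    landscape/year fields (GPP stays at native pixel support, matching its
    centroid-pixel extraction).
    """
    grid = landscape.grid()
    recs = corrected_records.set_index(["year", "segment_id"])

    # trailing partial segments (under half the nominal length) are kept in
    # the survey but excluded from modeling: their counts reflect sampled
    # area, not habitat, and would poison both the response and the
    # interpolated pond surfaces
    min_len = min_length_fraction * config.segment_length_km
    model_segments = [s for s in design.segments if s.length_km >= min_len]
    if not model_segments:
        raise ValueError("no segments meet the minimum modeling length")
    centroids = {s.id: s.centroid for s in model_segments}
    seg_ids = [s.id for s in model_segments]

    all_years = sorted(corrected_records["year"].unique())
    pond_surface: dict[int, Grid] = {}
    pdsi_surface: dict[int, Grid] = {}
    for year in all_years:
        pts = np.array(
            [
                [centroids[sid][0], centroids[sid][1], recs.loc[(year, sid), "corrected_ponds"]]
                for sid in seg_ids
            ]
        )
        pond_surface[year] = idw_interpolate(pts, grid, power=idw_power, k_neighbors=idw_k)
        stations = _moisture_stations(year_states[year])
        pdsi_surface[year] = focal_mean(
            idw_interpolate(stations, grid, power=idw_power, k_neighbors=idw_k), WINDOW_AREA_KM2
        )

    static_rasters = {
        "wetland_count": focal_mean(landscape.wetland_count, WINDOW_AREA_KM2),
        "wetland_area": focal_mean(landscape.wetland_area, WINDOW_AREA_KM2),
        "srtm_cv": focal_cv(landscape.elevation, CV_WINDOW_AREA_KM2),
        "dd5": focal_mean(landscape.dd5, WINDOW_AREA_KM2),
        "ami": focal_mean(landscape.ami, WINDOW_AREA_KM2),
        "sspb": focal_mean(landscape.sspb, WINDOW_AREA_KM2),
        "crop": focal_mean(landscape.crop, WINDOW_AREA_KM2),
        "grass": focal_mean(landscape.grass, WINDOW_AREA_KM2),
        "forest": focal_mean(landscape.forest, WINDOW_AREA_KM2),
        "country": landscape.country,
    }
    static_segment = {
        name: extract_segment_values(r, design, "focal_mean_within_segment")
        for name, r in static_rasters.items()
    }

    ndwi_focal = {y: focal_mean(year_states[y].ndwi, WINDOW_AREA_KM2) for y in all_years}

    modeled = [y for y in config.modeled_years if y in all_years]
    pond_by_year = {
        y: recs.xs(y, level="year")["corrected_ponds"].reindex(seg_ids) for y in all_years
    }
    pond_lags = make_lags(pond_by_year, modeled)
    pdsi_lags = make_lags(pdsi_surface, modeled)
    gpp_native = {y: year_states[y].gpp for y in all_years}
    gpp_lags = make_lags(gpp_native, modeled)

    rows = []
    grid_stacks: dict[int, dict[str, Grid]] = {}
    for year in modeled:
        pdsi1_seg = extract_segment_values(pdsi_lags[1][year], design)
        pdsi2_seg = extract_segment_values(pdsi_lags[2][year], design)
        ndwi_seg = extract_segment_values(ndwi_focal[year], design)
        gpp1_seg = extract_segment_values(gpp_lags[1][year], design, "nearest_pixel_to_centroid")
        gpp2_seg = extract_segment_values(gpp_lags[2][year], design, "nearest_pixel_to_centroid")
        for seg in model_segments:
            sid = seg.id
            row = {
                "year": year,
                "segment_id": sid,
                "stratum_id": seg.stratum_id,
                "ponds_t": float(pond_by_year[year][sid]),
                "ponds_t1": float(pond_lags[1][year][sid]),
                "ponds_t2": float(pond_lags[2][year][sid]),
                "pdsi_t1": float(pdsi1_seg[sid]),
                "pdsi_t2": float(pdsi2_seg[sid]),
                "ndwi_t": float(ndwi_seg[sid]),
                "gpp_t1": float(gpp1_seg[sid]),
                "gpp_t2": float(gpp2_seg[sid]),
                RESPONSE_COLUMN: float(recs.loc[(year, sid), "corrected_pairs"]),
            }
            for name in static_segment:
                row[name] = float(static_segment[name][sid])
            rows.append(row)
        grid_stacks[year] = {
            "ponds_t": pond_surface[year],
            "ponds_t1": pond_surface[year - 1],
            "ponds_t2": pond_surface[year - 2],
            "pdsi_t1": pdsi_lags[1][year],
            "pdsi_t2": pdsi_lags[2][year],
            "ndwi_t": ndwi_focal[year],
            "gpp_t1": gpp_lags[1][year],
            "gpp_t2": gpp_lags[2][year],
            **static_rasters,
        }

    matrix = pd.DataFrame(rows)
    matrix = matrix[["year", "segment_id", "stratum_id"] + PREDICTOR_COLUMNS + [RESPONSE_COLUMN]]
    if matrix[PREDICTOR_COLUMNS + [RESPONSE_COLUMN]].isna().any().any():
        raise ValueError("covariate matrix contains missing values")
    return matrix, grid_stacks


def offered_predictors(matrix: pd.DataFrame, threshold: float = 0.65) -> list[str]:
    """The predictor set offered to the forests after climate pruning.

    Only the long-term climate normals are screened for collinearity
    (priority DD5 > AMI > SSPB); every other predictor is always offered.
    """
    retained_climate = filter_correlated(matrix, subset=CLIMATE_COLUMNS, threshold=threshold, priority=CLIMATE_COLUMNS)
    return [c for c in PREDICTOR_COLUMNS if c not in CLIMATE_COLUMNS or c in retained_climate]
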