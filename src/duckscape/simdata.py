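"""Synthetic prairie-pothole landscape, population, and survey simulator.

This module generates everything the abundance analysis consumes, with the
statistical structure the analysis assumes about the real system:

* a static landscape of wetland basins, topography, 30-year climate normals
  and landcover on a regular metric grid;
* a yearly wet/dry moisture cycle (spatially correlated AR(1) field) that
  drives how many basins hold ponded water each May;
* ideal-free-style settling of a fixed yearly pair population across cells,
  dominated by a saturating response to current ponds with weaker lagged
  pond, landcover, and moisture effects;
* a stratified east-west strip-transect survey with ~29-km segments,
  per-stratum imperfect aerial detection, and perfect ground counts on a
  comparison subset of segments.

Everything is a pure function of :class:`SimConfig` (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import box

from .grids import Grid

# rng stream ids (spawned as default_rng([seed, stream, ...]))
_STREAM_LANDSCAPE = 0
_STREAM_MOISTURE = 1
_STREAM_SETTLE = 2
_STREAM_DESIGN = 3
_STREAM_DETECTION = 4
_STREAM_OBSERVE = 5

N_BURNIN = 2  # years preceding the first modeled year, so t-1/t-2 lags exist


@dataclass
class SettlingParams:
    """Weights of the cellwise settling function.

    The settling weight of a cell is

        w = max(0, b0 + bp*s(P_t) + bp1*s(P_{t-1}) + bp2*s(P_{t-2}))
            * exp(bg*grass + bc*crop + bm1*M_{t-1} + bm2*M_{t-2})

    with ``s(x) = x / (h + x)`` the saturating pond response, P pond counts
    per cell, and M the moisture-index field.  Defaults make the current-year
    pond term the dominant driver, with weaker lagged-pond, landcover, and
    lagged-moisture effects — the ordering the analysis is meant to recover.
    """

    pond: float = 1.0
    pond_lag1: float = 0.1
    pond_lag2: float = 0.05
    grass: float = 0.6
    crop: float = -0.6
    moisture_lag1: float = 0.05
    moisture_lag2: float = 0.02
    half_saturation: float = 3.0
    baseline: float = 0.05


def _default_population_series() -> tuple[int, ...]:
    # Yearly pair totals fluctuating ~2.3x, as breeding populations do over a
    # wet/dry cycle; scaled so the mean segment count is ~117 pairs.
    return (35000, 27000, 42000, 30000, 50000, 38000, 22000, 45000, 33000)


@dataclass
class SimConfig:
    """Full configuration of the synthetic study system."""

    grid_ncols: int = 290
    grid_nrows: int = 200
    cell_size_m: float = 400.0
    n_strata: int = 8
    transect_spacing_km: float = 1.2
    segment_length_km: float = 29.0
    strip_half_width_m: float = 200.0
    comparison_fraction: float = 0.3
    n_years: int = 9
    detection_range: tuple[float, float] = (0.5, 0.9)
    population_series: tuple[int, ...] = field(default_factory=_default_population_series)
    moisture_ar1: float = 0.6
    moisture_sd: float = 1.0
    pond_logistic_intercept: float = 0.0
    pond_logistic_slope: float = 3.5
    wetland_density: float = 1.8
    wetland_latitude_gradient: float = 0.5
    mean_basin_area_km2: float = 0.012
    crop_ami_coupling: float = 1.0
    settling: SettlingParams = field(default_factory=SettlingParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_ncols <= 0 or self.grid_nrows <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        lo, hi = self.detection_range
        if not (0 < lo <= 1 and 0 < hi <= 1 and lo <= hi):
            raise ValueError("detection probabilities must lie in (0, 1]")
        if len(self.population_series) != self.n_years:
            raise ValueError("population_series length must equal n_years")
        if not 0 <= self.moisture_ar1 < 1:
            raise ValueError("moisture_ar1 must lie in [0, 1)")
        if self.wetland_density < 0:
            raise ValueError("wetland_density must be nonnegative")

    @property
    def n_total_years(self) -> int:
        return self.n_years + N_BURNIN

    @property
    def modeled_years(self) -> range:
        """Indices (into the simulated year sequence) of modeled years."""
        return range(N_BURNIN, self.n_total_years)

    @property
    def width_km(self) -> float:
        return self.grid_ncols * self.cell_size_m / 1000.0

    @property
    def height_km(self) -> float:
        return self.grid_nrows * self.cell_size_m / 1000.0

    def population_for_year(self, year: int) -> int:
        """Total pair population for a simulated year index (burn-in included)."""
        if year < N_BURNIN:
            return int(self.population_series[0])
        return int(self.population_series[year - N_BURNIN])


@dataclass
class LandscapeStack:
    """Static covariate rasters on a common grid."""

    wetland_count: Grid  # basins per cell
    wetland_area: Grid  # km^2 of basin area per cell
    elevation: Grid  # m
    dd5: Grid  # degree-days > 5 C
    ami: Grid  # dd5 / mean annual precipitation
    sspb: Grid  # summer:spring precipitation balance
    crop: Grid
    grass: Grid
    forest: Grid
    country: Grid  # 1 = north (Canada analogue), 0 = south

    def grid(self) -> Grid:
        return self.wetland_count

    def as_dict(self) -> dict[str, Grid]:
        return {
            name: getattr(self, name)
            for name in (
                "wetland_count",
                "wetland_area",
                "elevation",
                "dd5",
                "ami",
                "sspb",
                "crop",
                "grass",
                "forest",
                "country",
            )
        }


@dataclass
class YearState:
    """Dynamic fields for one simulated year."""

    year: int
    ponds: Grid  # wet basins per cell, integer, <= wetland_count
    moisture_index: Grid  # PDSI-like, zero-centered
    ndwi: Grid
    gpp: Grid


@dataclass
class TrueAbundance:
    """Ground-truth pair counts per cell for one year."""

    year: int
    pairs: Grid

    @property
    def total(self) -> int:
        return int(self.pairs.data.sum())


@dataclass
class Stratum:
    id: int
    row_start: int  # inclusive, raster row indexing (0 = north)
    row_stop: int  # exclusive
    area_km2: float
    country: int

    def polygon(self, grid: Grid):
        y_top = grid.y_origin + (grid.nrows - self.row_start) * grid.cell_size
        y_bot = grid.y_origin + (grid.nrows - self.row_stop) * grid.cell_size
        x0 = grid.x_origin
        x1 = grid.x_origin + grid.ncols * grid.cell_size
        return box(x0, y_bot, x1, y_top)


@dataclass
class Transect:
    id: int
    stratum_id: int
    y_m: float  # center line y coordinate
    x_start_m: float
    x_end_m: float


@dataclass
class Segment:
    id: str
    transect_id: int
    stratum_id: int
    x_start_m: float
    x_end_m: float
    y_m: float
    length_km: float
    strip_half_width_m: float
    area_km2: float
    is_comparison: bool = False

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.x_start_m + self.x_end_m) / 2.0, self.y_m)


@dataclass
class SurveyDesign:
    strata: list[Stratum]
    transects: list[Transect]
    segments: list[Segment]

    def stratum(self, stratum_id: int) -> Stratum:
        for s in self.strata:
            if s.id == stratum_id:
                return s
        raise KeyError(f"no stratum {stratum_id}")

    def segments_in(self, stratum_id: int) -> list[Segment]:
        return [s for s in self.segments if s.stratum_id == stratum_id]

    @property
    def comparison_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.is_comparison]

    def segment(self, segment_id: str) -> Segment:
        for s in self.segments:
            if s.id == segment_id:
                return s
        raise KeyError(f"no segment {segment_id}")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": [s.id for s in self.segments],
                "transect_id": [s.transect_id for s in self.segments],
                "stratum_id": [s.stratum_id for s in self.segments],
                "length_km": [s.length_km for s in self.segments],
                "area_km2": [s.area_km2 for s in self.segments],
                "is_comparison": [s.is_comparison for s in self.segments],
            }
        )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Spatially correlated standard-normal field (Gaussian-filtered noise)."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def generate_landscape(config: SimConfig) -> LandscapeStack:
    """Generate the static landscape rasters.

    Climate follows broad north-south (temperature) and east-west
    (precipitation) gradients with smooth local structure; landcover is
    coupled to the moisture index of the climate (cropland tracks the drier,
    warmer end when ``crop_ami_coupling`` is positive); wetland basin counts
    are Poisson with a spatially clustered intensity.
    """
    shape = (config.grid_nrows, config.grid_ncols)
    rng = np.random.default_rng([config.seed, _STREAM_LANDSCAPE])
    base = Grid(np.zeros(shape), cell_size=config.cell_size_m)
    x_m, y_m = base.cell_centers()
    x_km, y_km = x_m / 1000.0, y_m / 1000.0

    f_elev = _smooth_field(rng, shape, 18)
    f_dd5 = _smooth_field(rng, shape, 25)
    f_prec = _smooth_field(rng, shape, 25)
    f_sspb = _smooth_field(rng, shape, 25)
    f_crop = _smooth_field(rng, shape, 20)
    f_grass = _smooth_field(rng, shape, 20)
    f_forest = _smooth_field(rng, shape, 20)
    f_wet = _smooth_field(rng, shape, 15)
    f_area = _smooth_field(rng, shape, 15)

    elevation = np.clip(600.0 + 120.0 * f_elev, 1.0, None)
    dd5 = 1400.0 + 5.0 * (config.height_km / 2.0 - y_km) + 80.0 * f_dd5
    precip = 450.0 + 1.5 * (x_km - config.width_km / 2.0) + 50.0 * f_prec
    precip = np.clip(precip, 150.0, None)
    ami = dd5 / precip
    sspb = 1.1 + 0.25 * f_sspb

    z_ami = (ami - ami.mean()) / (ami.std() if ami.std() > 0 else 1.0)
    c = config.crop_ami_coupling
    crop = np.clip(0.45 + 0.18 * c * z_ami + 0.08 * f_crop, 0.0, 0.85)
    grass = np.clip(0.40 - 0.15 * c * z_ami + 0.08 * f_grass, 0.0, 0.85)
    forest = np.clip(0.05 - 0.03 * z_ami + 0.04 * f_forest, 0.0, 0.5)
    total = crop + grass + forest
    over = total > 0.98
    scale = np.where(over, 0.98 / np.where(total > 0, total, 1.0), 1.0)
    crop, grass, forest = crop * scale, grass * scale, forest * scale

    # basin density rises toward the north of the landscape (pothole density
    # in the real system varies severalfold along regional gradients)
    lat = 2.0 * (y_km / config.height_km) - 1.0
    intensity = config.wetland_density * np.exp(
        0.7 * f_wet - 0.7**2 / 2.0 + config.wetland_latitude_gradient * lat
    )
    wetland_count = rng.poisson(intensity).astype(float)
    basin_area = config.mean_basin_area_km2 * np.exp(0.3 * f_area - 0.3**2 / 2.0)
    wetland_area = np.minimum(wetland_count * basin_area, base.cell_area_km2)

    country = (y_km >= config.height_km / 2.0).astype(float)

    g = base.like
    return LandscapeStack(
        wetland_count=g(wetland_count),
        wetland_area=g(wetland_area),
        elevation=g(elevation),
        dd5=g(dd5),
        ami=g(ami),
        sspb=g(sspb),
        crop=g(crop),
        grass=g(grass),
        forest=g(forest),
        country=g(country),
    )


def generate_year_sequence(landscape: LandscapeStack, config: SimConfig) -> list[YearState]:
    """Simulate the yearly moisture cycle and derived dynamic fields.

    The moisture index evolves as a stationary spatially correlated AR(1)
    field: ``M_t = a*M_{t-1} + sqrt(1-a^2)*sd*E_t``.  Each cell's pond count
    is binomial(basins, logistic(moisture)) realized through a fixed latent
    wet-propensity uniform per cell, so the *same* basins tend to be the
    wet-prone ones year after year (and constant forcing yields identical
    pond rasters).  NDWI and GPP are noisy monotone transforms of moisture.

    The returned sequence includes the burn-in years, so lagged covariates
    exist for the first modeled year.
    """
    if not 0 <= config.moisture_ar1 < 1:
        raise ValueError("moisture_ar1 must lie in [0, 1)")
    shape = (config.grid_nrows, config.grid_ncols)
    rng = np.random.default_rng([config.seed, _STREAM_MOISTURE])
    base = landscape.grid()
    basins = landscape.wetland_count.data

    # latent per-cell wet propensity, fixed across years
    u = rng.uniform(1e-9, 1 - 1e-9, size=shape)

    a = config.moisture_ar1
    sd = config.moisture_sd
    m = sd * _smooth_field(rng, shape, 20) if sd > 0 else np.zeros(shape)
    states: list[YearState] = []
    for year in range(config.n_total_years):
        if year > 0:
            innov = _smooth_field(rng, shape, 20) if sd > 0 else np.zeros(shape)
            m = a * m + np.sqrt(1 - a**2) * sd * innov
        p_wet = 1.0 / (1.0 + np.exp(-(config.pond_logistic_intercept + config.pond_logistic_slope * m)))
        ponds = stats.binom.ppf(u, basins.astype(int), p_wet)
        ponds = np.nan_to_num(ponds, nan=0.0)
        ndwi = 0.35 * m + 0.35 * _smooth_field(rng, shape, 8)
        gpp = 800.0 + 150.0 * np.tanh(0.5 * m) + 80.0 * _smooth_field(rng, shape, 8)
        states.append(
            YearState(
                year=year,
                ponds=base.like(ponds),
                moisture_index=base.like(m.copy()),
                ndwi=base.like(ndwi),
                gpp=base.like(gpp),
            )
        )
    return states


def settling_weights(
    landscape: LandscapeStack, year_states: list[YearState], year: int, config: SimConfig
) -> np.ndarray:
    """Cellwise settling weights for one year (requires lagged states)."""
    if year < N_BURNIN:
        raise ValueError(f"year {year} lacks t-1/t-2 history (burn-in = {N_BURNIN} years)")
    p = config.settling
    h = p.half_saturation

    def sat(x: np.ndarray) -> np.ndarray:
        return x / (h + x)

    ponds_t = year_states[year].ponds.data
    ponds_t1 = year_states[year - 1].ponds.data
    ponds_t2 = year_states[year - 2].ponds.data
    m1 = year_states[year - 1].moisture_index.data
    m2 = year_states[year - 2].moisture_index.data

    additive = (
        p.baseline + p.pond * sat(ponds_t) + p.pond_lag1 * sat(ponds_t1) + p.pond_lag2 * sat(ponds_t2)
    )
    multiplier = np.exp(
        p.grass * landscape.grass.data
        + p.crop * landscape.crop.data
        + p.moisture_lag1 * m1
        + p.moisture_lag2 * m2
    )
    return np.clip(additive, 0.0, None) * multiplier


def settle_population(
    landscape: LandscapeStack, year_states: list[YearState], year: int, config: SimConfig
) -> TrueAbundance:
    """Allocate the year's pair population multinomially over cells.

    Cell probabilities are the normalized settling weights; the cellwise sum
    equals the year's population total exactly.
    """
    w = settling_weights(landscape, year_states, year, config)
    total_w = w.sum()
    if total_w <= 0:
        raise ValueError("no habitable cells: all settling weights are zero")
    n = config.population_for_year(year)
    rng = np.random.default_rng([config.seed, _STREAM_SETTLE, year])
    counts = rng.multinomial(n, (w / total_w).ravel()).reshape(w.shape)
    return TrueAbundance(year=year, pairs=landscape.grid().like(counts.astype(float)))


def build_design(config: SimConfig, landscape: LandscapeStack) -> SurveyDesign:
    """Lay out strata, east-west transects, segments, and comparison segments.

    Strata are horizontal bands tiling the grid.  Within each stratum,
    transects run east-west at the configured spacing (at least one per
    stratum); each transect is cut into segments of the configured length,
    the last possibly shorter, with the true sampled area recorded.
    """
    grid = landscape.grid()
    cell = config.cell_size_m
    width_m = config.grid_ncols * cell
    seg_len_m = config.segment_length_km * 1000.0
    if seg_len_m > width_m:
        raise ValueError("segment length exceeds transect length")
    if config.transect_spacing_km <= 0:
        raise ValueError("transect spacing must be positive")

    band = config.grid_nrows // config.n_strata
    if band < 1:
        raise ValueError("more strata than grid rows")
    strata: list[Stratum] = []
    for s in range(config.n_strata):
        row_start = s * band
        row_stop = (s + 1) * band if s < config.n_strata - 1 else config.grid_nrows
        n_rows = row_stop - row_start
        area = n_rows * config.grid_ncols * grid.cell_area_km2
        country = int(np.round(landscape.country.data[row_start:row_stop].mean()))
        strata.append(Stratum(id=s, row_start=row_start, row_stop=row_stop, area_km2=area, country=country))

    spacing_m = config.transect_spacing_km * 1000.0
    transects: list[Transect] = []
    segments: list[Segment] = []
    tid = 0
    for st in strata:
        # y extents of the band (row_start is the northern edge)
        y_top = grid.y_origin + (config.grid_nrows - st.row_start) * cell
        y_bot = grid.y_origin + (config.grid_nrows - st.row_stop) * cell
        ys = []
        y = y_bot + spacing_m / 2.0
        while y < y_top:
            ys.append(y)
            y += spacing_m
        if not ys:
            ys = [(y_bot + y_top) / 2.0]
        for y in ys:
            # snap the flight line onto the nearest cell-center row
            row = grid.row_of_y(y)
            y_c = grid.y_origin + (config.grid_nrows - row - 0.5) * cell
            transects.append(Transect(id=tid, stratum_id=st.id, y_m=y_c, x_start_m=0.0, x_end_m=width_m))
            x0 = 0.0
            k = 0
            while x0 < width_m - 1e-9:
                x1 = min(x0 + seg_len_m, width_m)
                length_km = (x1 - x0) / 1000.0
                area_km2 = length_km * 2.0 * config.strip_half_width_m / 1000.0
                segments.append(
                    Segment(
                        id=f"t{tid:03d}s{k}",
                        transect_id=tid,
                        stratum_id=st.id,
                        x_start_m=x0,
                        x_end_m=x1,
                        y_m=y_c,
                        length_km=length_km,
                        strip_half_width_m=config.strip_half_width_m,
                        area_km2=area_km2,
                    )
                )
                x0 = x1
                k += 1
            tid += 1

    rng = np.random.default_rng([config.seed, _STREAM_DESIGN])
    for st in strata:
        segs = [s for s in segments if s.stratum_id == st.id]
        n_comp = max(1, int(round(config.comparison_fraction * len(segs))))
        for idx in rng.choice(len(segs), size=min(n_comp, len(segs)), replace=False):
            segs[idx].is_comparison = True
    return SurveyDesign(strata=strata, transects=transects, segments=segments)


def segment_cells(segment: Segment, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of cells whose centers fall in the segment's strip.

    A cell belongs to the strip when its center is strictly within the
    half-width of the flight line and its x-center lies in
    ``[x_start, x_end)`` — a deterministic partition of strip cells among
    the segments of a transect.
    """
    rows_all = np.arange(grid.nrows)
    y_centers = grid.y_origin + (grid.nrows - rows_all - 0.5) * grid.cell_size
    in_rows = rows_all[np.abs(y_centers - segment.y_m) < segment.strip_half_width_m]
    if in_rows.size == 0:
        in_rows = np.array([grid.row_of_y(segment.y_m)])
    cols_all = np.arange(grid.ncols)
    x_centers = grid.x_origin + (cols_all + 0.5) * grid.cell_size
    in_cols = cols_all[(x_centers >= segment.x_start_m) & (x_centers < segment.x_end_m)]
    if in_cols.size == 0:
        raise ValueError(f"segment {segment.id} has no strip cells")
    rr, cc = np.meshgrid(in_rows, in_cols, indexing="ij")
    return rr.ravel(), cc.ravel()


def detection_probabilities(config: SimConfig) -> np.ndarray:
    """Per-stratum aerial detection probabilities (fixed across years)."""
    rng = np.random.default_rng([config.seed, _STREAM_DETECTION])
    lo, hi = config.detection_range
    return rng.uniform(lo, hi, size=config.n_strata)


def simulate_observations(
    truth: TrueAbundance,
    year_state: YearState,
    design: SurveyDesign,
    config: SimConfig,
) -> pd.DataFrame:
    """Simulate one year's aerial (and comparison-segment ground) counts.

    Aerial pair and pond counts are independent binomial thinnings of the
    strip truth at the stratum's detection probability.  Ground crews on
    comparison segments count perfectly, so the true visibility correction
    factor of a stratum is 1/p.  True strip totals are carried along for
    validation; the survey CSV written by :func:`write_records_csv` contains
    only the observable columns.
    """
    p_strata = detection_probabilities(config)
    rng = np.random.default_rng([config.seed, _STREAM_OBSERVE, truth.year])
    rows = []
    for seg in design.segments:
        rr, cc = segment_cells(seg, truth.pairs)
        true_pairs = int(truth.pairs.data[rr, cc].sum())
        true_ponds = int(year_state.ponds.data[rr, cc].sum())
        p = p_strata[seg.stratum_id]
        aerial_pairs = int(rng.binomial(true_pairs, p))
        aerial_ponds = int(rng.binomial(true_ponds, p))
        rows.append(
            {
                "year": truth.year,
                "segment_id": seg.id,
                "stratum_id": seg.stratum_id,
                "aerial_pairs": aerial_pairs,
                "aerial_ponds": aerial_ponds,
                "ground_pairs": float(true_pairs) if seg.is_comparison else np.nan,
                "ground_ponds": float(true_ponds) if seg.is_comparison else np.nan,
                "true_pairs": true_pairs,
                "true_ponds": true_ponds,
            }
        )
    return pd.DataFrame(rows)


def simulate_survey(config: SimConfig):
    """Run the full simulation: landscape, years, truth, design, observations.

    Returns ``(landscape, year_states, truths, design, records)`` where
    ``truths`` maps year index -> :class:`TrueAbundance` (all simulated
    years, burn-in included) and ``records`` stacks every year's
    observations.
    """
    landscape = generate_landscape(config)
    year_states = generate_year_sequence(landscape, config)
    design = build_design(config, landscape)
    truths: dict[int, TrueAbundance] = {}
    frames = []
    for year in range(N_BURNIN, config.n_total_years):
        truth = settle_population(landscape, year_states, year, config)
        truths[year] = truth
        frames.append(simulate_observations(truth, year_states[year], design, config))
    records = pd.concat(frames, ignore_index=True)
    return landscape, year_states, truths, design, records


# ---------------------------------------------------------------------------
# on-disk formats


def write_landscape(landscape: LandscapeStack, outdir) -> None:
    """Write every static raster as `<name>.asc` (ESRI ASCII grid)."""
    from pathlib import Path

    from .grids import write_ascii_grid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, grid in landscape.as_dict().items():
        write_ascii_grid(grid, outdir / f"{name}.asc")


def write_year_state(state: YearState, outdir) -> None:
    """Write a year's dynamic rasters as `<field>_<year>.asc`."""
    from pathlib import Path

    from .grids import write_ascii_grid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("ponds", "moisture_index", "ndwi", "gpp"):
        write_ascii_grid(getattr(state, name), outdir / f"{name}_{state.year}.asc")


def write_records_csv(records: pd.DataFrame, path) -> None:
    cols = ["year", "segment_id", "stratum_id", "aerial_pairs", "aerial_ponds", "ground_pairs", "ground_ponds"]
    records[cols].to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def design_to_geojson(design: SurveyDesign, grid: Grid) -> dict:
    """SurveyDesign as a GeoJSON FeatureCollection (strata + segments)."""
    features = []
    for st in design.strata:
        poly = st.polygon(grid)
        features.append(
            {
                "type": "Feature",
                "geometry": poly.__geo_interface__,
                "properties": {
                    "kind": "stratum",
                    "id": st.id,
                    "area_km2": st.area_km2,
                    "country": st.country,
                    "row_start": st.row_start,
                    "row_stop": st.row_stop,
                },
            }
        )
    for seg in design.segments:
        geom = {
            "type": "LineString",
            "coordinates": [[seg.x_start_m, seg.y_m], [seg.x_end_m, seg.y_m]],
        }
        features.append(
            {
                "type": "Feature",
                "geometry": geom,
                "properties": {
                    "kind": "segment",
                    "id": seg.id,
                    "transect_id": seg.transect_id,
                    "stratum": seg.stratum_id,
                    "length_km": seg.length_km,
                    "area_km2": seg.area_km2,
                    "strip_half_width_m": seg.strip_half_width_m,
                    "comparison": seg.is_comparison,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def design_from_geojson(obj: dict) -> SurveyDesign:
    strata, segments = [], []
    transect_ids: dict[int, Transect] = {}
    for feat in obj["features"]:
        props = feat["properties"]
        if props["kind"] == "stratum":
            strata.append(
                Stratum(
                    id=props["id"],
                    row_start=props["row_start"],
                    row_stop=props["row_stop"],
                    area_km2=props["area_km2"],
                    country=props["country"],
                )
            )
        else:
            (x0, y), (x1, _) = feat["geometry"]["coordinates"]
            seg = Segment(
                id=props["id"],
                transect_id=props["transect_id"],
                stratum_id=props["stratum"],
                x_start_m=x0,
                x_end_m=x1,
                y_m=y,
                length_km=props["length_km"],
                strip_half_width_m=props["strip_half_width_m"],
                area_km2=props["area_km2"],
                is_comparison=props["comparison"],
            )
            segments.append(seg)
            if seg.transect_id not in transect_ids:
                transect_ids[seg.transect_id] = Transect(
                    id=seg.transect_id, stratum_id=seg.stratum_id, y_m=y, x_start_m=x0, x_end_m=x1
                )
            else:
                t = transect_ids[seg.transect_id]
                t.x_start_m = min(t.x_start_m, x0)
                t.x_end_m = max(t.x_end_m, x1)
    return SurveyDesign(strata=strata, transects=list(transect_ids.values()), segments=segments)
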