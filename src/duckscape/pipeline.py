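"""End-to-end synthetic analysis: simulate, correct, fit, map, reconcile.

`run_analysis` wires the whole chain together on one configuration:

1. simulate the landscape, yearly dynamics, true settling, survey design,
   and imperfectly detected counts;
2. estimate visibility correction factors from comparison segments and
   correct the aerial counts;
3. assemble the segment-year covariate matrix and the per-year prediction
   grids;
4. fit the per-year forests with model-improvement-ratio selection;
5. project each year model onto the grid, aggregate surfaces, and bin the
   mean surface into percent-population classes;
6. compute design-based and model-based stratum estimates and their
   concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparison, covariates, modeling, simdata, surfaces, survey


@dataclass
class AnalysisResult:
    config: simdata.SimConfig
    landscape: simdata.LandscapeStack
    year_states: list[simdata.YearState]
    truths: dict[int, simdata.TrueAbundance]
    design: simdata.SurveyDesign
    records: pd.DataFrame  # corrected observation records, all years
    vcf: pd.DataFrame
    matrix: pd.DataFrame
    grid_stacks: dict[int, dict]
    offered: list[str]
    models: list[modeling.YearModel]
    fit_summaries: list[modeling.FitSummary]
    yearly_surfaces: list[surfaces.AbundanceSurface]
    mean_surface: surfaces.AbundanceSurface
    sd_surface: surfaces.AbundanceSurface
    max_surface: surfaces.AbundanceSurface
    percent_map: surfaces.PercentPopulationMap
    estimates: pd.DataFrame  # stratum-year model vs design estimates
    regression: comparison.RegressionResult
    residuals: pd.DataFrame
    flagged_strata: list[int] = field(default_factory=list)
    trend: pd.DataFrame | None = None
    pond_totals: dict[int, float] = field(default_factory=dict)

    def model_summary(self) -> pd.DataFrame:
        return modeling.year_model_summary(self.models)


def run_analysis(
    config: simdata.SimConfig | None = None,
    forest_params: modeling.ForestParams | None = None,
) -> AnalysisResult:
    """Run the full pipeline on a (default desk-scale) configuration."""
    config = config or simdata.SimConfig()
    forest_params = forest_params or modeling.ForestParams()

    landscape, year_states, truths, design, raw_records = simdata.simulate_survey(config)
    vcf = survey.estimate_vcf(raw_records)
    records = survey.correct_counts(raw_records, vcf)

    # burn-in years carry no modeled response but their corrected pond
    # counts feed the lagged covariates; observe ponds only there
    burnin_frames = [
        _observe_burnin_ponds(year_states[year], design, config, year)
        for year in range(simdata.N_BURNIN)
    ]
    burnin = survey.correct_counts(pd.concat(burnin_frames, ignore_index=True), vcf)
    all_records = pd.concat([burnin, records], ignore_index=True).sort_values(["year", "segment_id"])

    matrix, grid_stacks = covariates.build_analysis_inputs(landscape, year_states, design, all_records, config)
    offered = covariates.offered_predictors(matrix)

    models: list[modeling.YearModel] = []
    fit_summaries: list[modeling.FitSummary] = []
    yearly: list[surfaces.AbundanceSurface] = []
    for year in config.modeled_years:
        sub = matrix[matrix["year"] == year]
        X = sub[offered]
        y = sub[covariates.RESPONSE_COLUMN].to_numpy()
        model = modeling.select_model_mir(X, y, forest_params, seed=config.seed + year, year=year)
        models.append(model)
        fit_summaries.append(modeling.goodness_of_fit(model.oob_pred, y, year=year))
        yearly.append(surfaces.predict_surface(model, grid_stacks[year]))

    mean_s, sd_s, max_s = surfaces.aggregate_surfaces(yearly)
    percent_map = surfaces.percent_population_bins(mean_s)

    design_est = survey.design_estimates_frame(records, design)
    rows = []
    for surf, year in zip(yearly, config.modeled_years):
        for st in design.strata:
            m_est = comparison.model_based_stratum_estimate(surf, design, st.id, year=year)
            d_row = design_est[(design_est["stratum_id"] == st.id) & (design_est["year"] == year)]
            rows.append(
                {
                    "stratum_id": st.id,
                    "year": year,
                    "model": m_est.estimate,
                    "design": float(d_row["estimate"].iloc[0]),
                    "design_se": float(d_row["se"].iloc[0]),
                }
            )
    estimates = pd.DataFrame(rows)
    regression = comparison.regress_estimates(estimates["model"].to_numpy(), estimates["design"].to_numpy())
    residuals, flagged = comparison.standardized_residuals(estimates, regression)
    trend = comparison.aggregate_trend_comparison(estimates)

    pond_totals = {
        int(year): float(grp["corrected_ponds"].sum())
        for year, grp in records.groupby("year")
    }

    return AnalysisResult(
        config=config,
        landscape=landscape,
        year_states=year_states,
        truths=truths,
        design=design,
        records=all_records,
        vcf=vcf,
        matrix=matrix,
        grid_stacks=grid_stacks,
        offered=offered,
        models=models,
        fit_summaries=fit_summaries,
        yearly_surfaces=yearly,
        mean_surface=mean_s,
        sd_surface=sd_s,
        max_surface=max_s,
        percent_map=percent_map,
        estimates=estimates,
        regression=regression,
        residuals=residuals,
        flagged_strata=flagged,
        trend=trend,
        pond_totals=pond_totals,
    )


def _observe_burnin_ponds(
    year_state: simdata.YearState,
    design: simdata.SurveyDesign,
    config: simdata.SimConfig,
    year: int,
) -> pd.DataFrame:
    """Pond-only observations for a burn-in year (pair columns zeroed)."""
    p_strata = simdata.detection_probabilities(config)
    rng = np.random.default_rng([config.seed, 5, year])
    rows = []
    for seg in design.segments:
        rr, cc = simdata.segment_cells(seg, year_state.ponds)
        true_ponds = int(year_state.ponds.data[rr, cc].sum())
        p = p_strata[seg.stratum_id]
        rows.append(
            {
                "year": year,
                "segment_id": seg.id,
                "stratum_id": seg.stratum_id,
                "aerial_pairs": 0,
                "aerial_ponds": int(rng.binomial(true_ponds, p)),
                "ground_pairs": np.nan,
                "ground_ponds": float(true_ponds) if seg.is_comparison else np.nan,
                "true_pairs": 0,
                "true_ponds": true_ponds,
            }
        )
    return pd.DataFrame(rows)
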