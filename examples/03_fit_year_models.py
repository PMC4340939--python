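"""Fit year-specific random-forest settling models with variable selection.

Runs the full pipeline on a reduced landscape, then prints the per-year
model summary (variance explained, model size, top variables with scaled
importances) and the out-of-bag goodness-of-fit table.
"""

from duckscape import ForestParams, SimConfig, run_analysis

# 29-km segments (the survey's native unit) so segment strips match the
# ~11 km^2 prediction support of the abundance surfaces
config = SimConfig(
    grid_ncols=145,
    grid_nrows=60,
    n_strata=3,
    transect_spacing_km=1.6,
    segment_length_km=29.0,
    n_years=3,
    population_series=(24000, 18000, 30000),
    seed=42,
)
result = run_analysis(config, forest_params=ForestParams(n_trees=300, min_rows=20))

print("Per-year settling models (selected by model improvement ratio):")
print(result.model_summary().to_string(index=False))
print()
print("The top variable each year carries scaled importance 1.00 by")
print("construction. At the default study scale current-year pond count")
print("dominates every year; at this reduced scale (36 segments/year) a")
print("correlated wetland covariate can occasionally edge it out.\n")

print("Out-of-bag residual summaries (predicted - observed, pairs/segment):")
for fs in result.fit_summaries:
    print(
        f"year {fs.year}: rmse {fs.rmse:6.1f} | min {fs.min:7.1f} | q1 {fs.q1:6.1f} "
        f"| median {fs.median:5.1f} | mean {fs.mean:5.1f} | q3 {fs.q3:5.1f} | max {fs.max:6.1f}"
    )
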