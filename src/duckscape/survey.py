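"""Visibility correction and design-based stratified abundance estimation.

Aerial crews undercount; ground crews on a comparison subset of segments
provide the detection reference.  The visibility correction factor (VCF) of
a stratum-year is the ratio of summed ground to summed aerial counts on the
comparison segments, estimated separately for pairs and ponds, with a
pooled-across-years fallback within the stratum.  Corrected counts feed
both the yearly abundance models and a classical stratified strip-transect
expansion estimator (transects as primary sampling units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import SurveyDesign

#: pairs -> individuals; applied in both the design- and model-based
#: estimators so the two are unit-consistent
PAIRS_TO_INDIVIDUALS = 2.0


@dataclass
class StratumEstimate:
    stratum_id: int
    year: int
    estimate: float  # individuals
    sampled_area_km2: float
    stratum_area_km2: float
    se: float
    method: str  # "design" | "model"


def estimate_vcf(records: pd.DataFrame, pooled_fallback: bool = True) -> pd.DataFrame:
    """Per stratum-year VCFs for pairs and ponds from comparison segments.

    ``vcf = sum(ground) / sum(aerial)`` over the stratum-year's comparison
    segments.  Where the aerial sum is zero the stratum's counts are pooled
    across years; if that is still undefined a ValueError is raised.

    Returns a frame indexed by (stratum_id, year) with columns
    ``vcf_pairs`` and ``vcf_ponds``.
    """
    comp = records.dropna(subset=["ground_pairs"])
    if comp.empty:
        raise ValueError("no comparison-segment records")
    out = {}
    pooled = comp.groupby("stratum_id")[["aerial_pairs", "aerial_ponds", "ground_pairs", "ground_ponds"]].sum()
    for (stratum, year), grp in comp.groupby(["stratum_id", "year"]):
        row = {}
        for kind in ("pairs", "ponds"):
            aerial = grp[f"aerial_{kind}"].sum()
            ground = grp[f"ground_{kind}"].sum()
            if aerial > 0:
                row[f"vcf_{kind}"] = ground / aerial
            elif pooled_fallback and pooled.loc[stratum, f"aerial_{kind}"] > 0:
                row[f"vcf_{kind}"] = pooled.loc[stratum, f"ground_{kind}"] / pooled.loc[stratum, f"aerial_{kind}"]
            else:
                raise ValueError(f"VCF undefined for stratum {stratum} ({kind}, year {year})")
        out[(stratum, year)] = row
    table = pd.DataFrame.from_dict(out, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["stratum_id", "year"])
    return table.sort_index()


def correct_counts(records: pd.DataFrame, vcf: pd.DataFrame) -> pd.DataFrame:
    """Apply stratum-year VCFs: corrected = aerial x VCF.

    Stratum-years absent from the table fall back to the stratum's pooled
    (mean) VCF; a stratum with no VCF at all is an error.
    """
    stratum_mean = vcf.groupby(level="stratum_id").mean()
    out = records.copy()
    vcf_pairs = np.empty(len(out))
    vcf_ponds = np.empty(len(out))
    for i, (_, rec) in enumerate(out.iterrows()):
        key = (rec["stratum_id"], rec["year"])
        if key in vcf.index:
            vcf_pairs[i] = vcf.loc[key, "vcf_pairs"]
            vcf_ponds[i] = vcf.loc[key, "vcf_ponds"]
        elif rec["stratum_id"] in stratum_mean.index:
            vcf_pairs[i] = stratum_mean.loc[rec["stratum_id"], "vcf_pairs"]
            vcf_ponds[i] = stratum_mean.loc[rec["stratum_id"], "vcf_ponds"]
        else:
            raise ValueError(f"missing VCF for stratum {rec['stratum_id']}")
    out["corrected_pairs"] = out["aerial_pairs"] * vcf_pairs
    out["corrected_ponds"] = out["aerial_ponds"] * vcf_ponds
    return out


def design_based_estimate(
    corrected_records: pd.DataFrame,
    design: SurveyDesign,
    stratum_id: int,
    year: int,
) -> StratumEstimate:
    """Stratified strip-transect expansion for one stratum-year.

    density = sum(corrected pairs) / sum(sampled segment area);
    estimate = density x stratum area x 2 (pairs -> individuals).

    The SE treats transects as primary sampling units: with transect totals
    c_i over sampled areas a_i and D = sum(c)/sum(a), the ratio-estimator
    variance is ``n/(n-1) * sum((c_i - D a_i)^2) / (sum a)^2``, scaled by
    (2 x stratum area).  A single-transect stratum reports SE = nan.
    """
    segs = design.segments_in(stratum_id)
    if not segs:
        raise ValueError(f"no segments in stratum {stratum_id}")
    areas = {s.id: s.area_km2 for s in segs}
    transect_of = {s.id: s.transect_id for s in segs}
    sub = corrected_records[
        (corrected_records["stratum_id"] == stratum_id) & (corrected_records["year"] == year)
    ]
    sub = sub[sub["segment_id"].isin(areas)]
    if sub.empty:
        raise ValueError(f"no sampled segments in stratum {stratum_id}, year {year}")
    sampled_area = float(sum(areas[sid] for sid in sub["segment_id"]))
    if sampled_area <= 0:
        raise ValueError("zero sampled area")
    total_pairs = float(sub["corrected_pairs"].sum())
    density = total_pairs / sampled_area
    stratum_area = design.stratum(stratum_id).area_km2
    estimate = PAIRS_TO_INDIVIDUALS * density * stratum_area

    by_transect = sub.assign(
        transect=[transect_of[sid] for sid in sub["segment_id"]],
        area=[areas[sid] for sid in sub["segment_id"]],
    ).groupby("transect")[["corrected_pairs", "area"]].sum()
    n = len(by_transect)
    if n > 1:
        resid = by_transect["corrected_pairs"] - density * by_transect["area"]
        var_density = (n / (n - 1)) * float((resid**2).sum()) / sampled_area**2
        se = PAIRS_TO_INDIVIDUALS * stratum_area * np.sqrt(var_density)
    else:
        se = float("nan")
    return StratumEstimate(
        stratum_id=stratum_id,
        year=year,
        estimate=estimate,
        sampled_area_km2=sampled_area,
        stratum_area_km2=stratum_area,
        se=se,
        method="design",
    )


def design_estimates_frame(
    corrected_records: pd.DataFrame, design: SurveyDesign
) -> pd.DataFrame:
    """Design-based estimates for every stratum-year present in the records."""
    rows = []
    for (stratum, year), _ in corrected_records.groupby(["stratum_id", "year"]):
        est = design_based_estimate(corrected_records, design, stratum, year)
        rows.append(
            {
                "stratum_id": stratum,
                "year": year,
                "estimate": est.estimate,
                "se": est.se,
                "sampled_area_km2": est.sampled_area_km2,
                "stratum_area_km2": est.stratum_area_km2,
                "method": est.method,
            }
        )
    return pd.DataFrame(rows)
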