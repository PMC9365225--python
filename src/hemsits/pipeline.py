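"""End-to-end orchestration: simulate -> filter -> ITS -> hulls -> report."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cohort, its, service_area
from .config import AnalysisConfig, SimulationConfig
from .missions import apply_inclusion_criteria, assign_period
from .simulate import generate_missions

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    missions: pd.DataFrame          # included missions
    patients: pd.DataFrame
    tally: object
    monthly: pd.DataFrame
    model: its.InterruptedTimeSeriesRegressor
    hulls: list[service_area.HullResult]
    comparisons: list[dict]
    threshold_table: pd.DataFrame
    naca_table: pd.DataFrame


def run_pipeline(sim: SimulationConfig,
                 analysis: AnalysisConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the whole evaluation on a freshly generated synthetic registry.

    When ``outdir`` is given, the CSV report bundle, hull GeoJSON and the
    ITS figure are written there.
    """
    analysis = analysis or AnalysisConfig(intervention_date=sim.intervention_date)
    raw, patients = generate_missions(sim)
    for col in ("alarm_time", "takeoff_time", "on_scene_time"):
        raw[col] = pd.to_datetime(raw[col], utc=True)
    raw = assign_period(raw, analysis.intervention_date)
    included, tally = apply_inclusion_criteria(raw)
    patients = patients[patients["mission_id"].isin(included["mission_id"])]

    end = pd.Period(sim.study_start, freq="M") + sim.n_months - 1
    monthly = its.aggregate_monthly(included, study_start=sim.study_start,
                                    study_end=str(end))
    tpi_month = str(pd.Period(sim.study_start, freq="M") + sim.tpi)
    monthly = its.flag_excluded_months(monthly, tpi_month,
                                       z_threshold=analysis.z_threshold)
    model = its.select_error_model(monthly, sim.tpi,
                                   candidates=analysis.error_candidates)

    mappable = included[included["latitude"].notna()
                        & included["longitude"].notna()]
    hulls: list[service_area.HullResult] = []
    comparisons: list[dict] = []
    for base in sim.bases:
        sub = mappable[mappable["base_id"] == base.base_id]
        pre = sub[sub["period"] == "pre"]
        post = sub[sub["period"] == "post"]
        h_pre = service_area.analyze_base(pre["latitude"], pre["longitude"],
                                          base, "pre", analysis.quantile)
        h_post = service_area.analyze_base(post["latitude"], post["longitude"],
                                           base, "post", analysis.quantile)
        hulls += [h_pre, h_post]
        d_pre = service_area.base_distances_km(pre["latitude"],
                                               pre["longitude"], base)
        d_post = service_area.base_distances_km(post["latitude"],
                                                post["longitude"], base)
        comparisons.append(
            service_area.compare_periods(h_pre, h_post, d_pre, d_post))

    threshold_table = cohort.threshold_proportions(included,
                                                   analysis.threshold_minutes)
    naca_table = cohort.naca_summary(patients, included)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.build_report(outdir, missions=included, patients=patients,
                            tally=tally, its_summary=model.summary_dict(),
                            hull_comparisons=comparisons,
                            threshold=analysis.threshold_minutes)
        service_area.hulls_to_geojson(hulls, outdir / "hulls.geojson")
        monthly_out = monthly.copy()
        monthly_out["calendar_month"] = monthly_out["calendar_month"].astype(str)
        monthly_out.to_csv(outdir / "monthly_series.csv", index=False,
                           float_format="%.6f")
        its.plot_its(monthly, model, str(outdir / "its_fit.png"))

    return PipelineResult(included, patients, tally, monthly, model,
                          hulls, comparisons, threshold_table, naca_table)
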