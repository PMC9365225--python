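"""Descriptive comparison battery for the pre/post cohorts.

Group comparisons follow the convention of pre/post health-service
evaluations: Pearson chi-square (no continuity correction) for categorical
contrasts, Mann-Whitney U for skewed continuous variables (exact enumeration
for small untied samples, tie-corrected normal approximation otherwise),
Student's t (Welch by default) for means, and the Hodges-Lehmann estimator
with its rank-based 95% confidence interval for median differences.
Percentages are computed from unrounded counts and rounded only at render
time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .missions import response_time_minutes, scramble_flags

__all__ = [
    "chi_square_2xk", "mann_whitney", "HodgesLehmann", "hodges_lehmann_ci",
    "t_test", "threshold_proportions", "naca_summary", "build_report",
]


def chi_square_2xk(table) -> tuple[float, float]:
    """Pearson chi-square test on a contingency table of counts (no Yates
    continuity correction). Returns ``(statistic, p)``."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both samples are small (<= 20) and untied;
    otherwise the tie-corrected normal approximation with continuity
    correction. Returns ``(U, p)`` with U for the first sample.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    small = max(x.size, y.size) <= 20
    untied = np.unique(pooled).size == pooled.size
    method = "exact" if (small and untied) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class HodgesLehmann:
    estimate: float
    ci_low: float
    ci_high: float
    level: float


def hodges_lehmann_ci(x, y, level: float = 0.95) -> HodgesLehmann:
    """Hodges-Lehmann shift estimate (x relative to y) with its rank-based
    confidence interval.

    The point estimate is the median of all n*m pairwise differences
    x_i - y_j. The interval endpoints are order statistics of those
    differences at ranks obtained by inverting the Mann-Whitney test with a
    normal approximation to the null U distribution.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    if not 0.5 < level < 1.0:
        raise ValueError("level must be in (0.5, 1)")
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    est = float(np.median(diffs))
    n, m = x.size, y.size
    nm = n * m
    z = stats.norm.ppf(0.5 + level / 2.0)
    c = nm / 2.0 - z * np.sqrt(nm * (n + m + 1) / 12.0)
    k = int(np.floor(c))
    if k < 0:
        k = 0
    lo = diffs[k] if k < nm else diffs[0]
    hi = diffs[nm - 1 - k] if k < nm else diffs[-1]
    return HodgesLehmann(est, float(lo), float(hi), level)


def t_test(x, y, welch: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t test on means (Welch by default; set
    ``welch=False`` for the pooled-variance variant)."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                          equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def threshold_proportions(missions: pd.DataFrame,
                          threshold: float = 45.0) -> pd.DataFrame:
    """Fraction of missions reaching the scene within ``threshold`` minutes
    (inclusive), per base and overall, split pre/post, with the chi-square p
    for the pre/post contrast."""
    df = missions.copy()
    df["rt"] = response_time_minutes(df)
    df = df[df["rt"].notna()]
    rows = []
    groups = [("all", df)] + [(b, g) for b, g in df.groupby("base_id", sort=True)]
    for label, g in groups:
        pre = g[g["period"] == "pre"]["rt"]
        post = g[g["period"] == "post"]["rt"]
        if len(pre) == 0 or len(post) == 0:
            continue
        k_pre, k_post = int((pre <= threshold).sum()), int((post <= threshold).sum())
        tab = [[k_pre, len(pre) - k_pre], [k_post, len(post) - k_post]]
        try:
            _, p = chi_square_2xk(tab)
        except ValueError:
            p = np.nan  # degenerate margin (e.g. everyone within threshold)
        pct_pre = 100.0 * k_pre / len(pre)
        pct_post = 100.0 * k_post / len(post)
        rows.append({
            "base_id": label,
            "n_pre": len(pre), "within_pre": k_pre, "pct_pre": pct_pre,
            "n_post": len(post), "within_post": k_post, "pct_post": pct_post,
            "diff_pct": pct_post - pct_pre, "p": p,
        })
    return pd.DataFrame(rows)


def naca_summary(patients: pd.DataFrame, missions: pd.DataFrame) -> pd.DataFrame:
    """NACA severity comparison: mean score (Welch t) and the NACA 4-7
    proportion (chi-square) between periods."""
    period = missions.set_index("mission_id")["period"]
    pat = patients.copy()
    pat["period"] = pat["mission_id"].map(period)
    pat = pat[pat["period"].notna()]
    rows = []
    pre = pat[pat["period"] == "pre"]["naca"]
    post = pat[pat["period"] == "post"]["naca"]
    _, p_mean = t_test(pre, post)
    sev_pre, sev_post = int((pre >= 4).sum()), int((post >= 4).sum())
    tab = [[sev_pre, len(pre) - sev_pre], [sev_post, len(post) - sev_post]]
    _, p_sev = chi_square_2xk(tab)
    rows.append({
        "label": "naca_mean",
        "pre": pre.mean(), "post": post.mean(),
        "difference": post.mean() - pre.mean(), "test": "t_test", "p": p_mean,
    })
    rows.append({
        "label": "naca_4_7_pct",
        "pre": 100.0 * sev_pre / len(pre), "post": 100.0 * sev_post / len(post),
        "difference": 100.0 * (sev_post / len(post) - sev_pre / len(pre)),
        "test": "chi_square", "p": p_sev,
    })
    return pd.DataFrame(rows)


def scramble_summary(missions: pd.DataFrame) -> pd.DataFrame:
    """In-flight-scramble proportion per base and overall, pre vs post."""
    df = missions.copy()
    df["scramble"] = scramble_flags(df)
    rows = []
    groups = [("all", df)] + [(b, g) for b, g in df.groupby("base_id", sort=True)]
    for label, g in groups:
        pre = g[g["period"] == "pre"]["scramble"]
        post = g[g["period"] == "post"]["scramble"]
        if len(pre) == 0 or len(post) == 0:
            continue
        tab = [[int(pre.sum()), int((~pre).sum())],
               [int(post.sum()), int((~post).sum())]]
        try:
            _, p = chi_square_2xk(tab)
        except ValueError:
            p = np.nan
        rows.append({
            "base_id": label,
            "pct_pre": 100.0 * pre.mean(), "n_pre": int(pre.sum()),
            "pct_post": 100.0 * post.mean(), "n_post": int(post.sum()),
            "diff_pct": 100.0 * (post.mean() - pre.mean()), "p": p,
        })
    return pd.DataFrame(rows)


def mission_distribution(missions: pd.DataFrame) -> pd.DataFrame:
    """Share of regional missions flown by each base, pre vs post, with the
    overall chi-square test for a distribution shift."""
    rows = []
    tab = pd.crosstab(missions["base_id"], missions["period"])
    for base in tab.index:
        rows.append({
            "base_id": base,
            "pct_pre": 100.0 * tab.loc[base, "pre"] / tab["pre"].sum(),
            "n_pre": int(tab.loc[base, "pre"]),
            "pct_post": 100.0 * tab.loc[base, "post"] / tab["post"].sum(),
            "n_post": int(tab.loc[base, "post"]),
        })
    out = pd.DataFrame(rows)
    _, p = chi_square_2xk(tab.to_numpy().T)
    out["p_overall"] = p
    return out


def build_report(outdir: str | Path, *, missions: pd.DataFrame,
                 patients: pd.DataFrame, tally, its_summary: dict,
                 hull_comparisons: list[dict],
                 threshold: float = 45.0) -> Path:
    """Assemble the full report bundle: machine-readable CSV tables plus a
    plain-text summary. Raises if a stage output is missing. Deterministic
    for identical inputs."""
    for name, obj in [("missions", missions), ("patients", patients),
                      ("exclusion tally", tally), ("ITS fit", its_summary),
                      ("hull comparisons", hull_comparisons)]:
        if obj is None or (hasattr(obj, "__len__") and len(obj) == 0):
            raise ValueError(f"missing stage output: {name}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    float_fmt = "%.6f"
    naca = naca_summary(patients, missions)
    naca.to_csv(outdir / "patient_characteristics.csv", index=False,
                float_format=float_fmt)
    dist = mission_distribution(missions)
    scr = scramble_summary(missions)
    thr = threshold_proportions(missions, threshold)
    mission_tbl = pd.concat([
        dist.assign(table="mission_distribution"),
        scr.assign(table="inflight_scrambles"),
        thr.assign(table=f"within_{threshold:g}_min"),
    ])
    mission_tbl.to_csv(outdir / "mission_characteristics.csv", index=False,
                       float_format=float_fmt)
    pd.DataFrame([its_summary]).to_csv(outdir / "its_summary.csv", index=False,
                                       float_format=float_fmt)
    pd.DataFrame(hull_comparisons).to_csv(outdir / "hull_comparison.csv",
                                          index=False, float_format=float_fmt)
    tally.to_frame().to_csv(outdir / "exclusion_tally.csv", index=False)

    lines = ["regional HEMS coordinator evaluation — summary", ""]
    lines.append(f"missions analysed: {tally.included} of {tally.total} "
                 f"({tally.missing_gps} map-ineligible, missing GPS)")
    lines.append("")
    lines.append("interrupted time series (monthly mean response, minutes):")
    lines.append(f"  error model: {its_summary['error_spec']}  "
                 f"AICc={its_summary['aicc']:.2f}  R2={its_summary['r2']:.3f}")
    lines.append(f"  level change b2 = {its_summary['beta2']:+.2f} min "
                 f"(p = {its_summary['p_beta2']:.2f})")
    lines.append(f"  slope change b3 = {its_summary['beta3']:+.2f} min/month "
                 f"(p = {its_summary['p_beta3']:.2f})")
    lines.append(f"  winter effect b4 = {its_summary['beta4']:+.2f} min "
                 f"(p = {its_summary['p_beta4']:.3g})")
    lines.append("")
    lines.append("service areas (95%-filtered convex hulls):")
    for c in hull_comparisons:
        lines.append(
            f"  {c['base_id']}: {c['area_pre_km2']:.0f} -> "
            f"{c['area_post_km2']:.0f} km2 ({c['area_change_pct']:+.1f}%), "
            f"median distance {c['median_pre_km']:.1f} -> "
            f"{c['median_post_km']:.1f} km (MW p = {c['mw_p']:.3f})")
    lines.append("")
    for _, r in naca.iterrows():
        lines.append(f"  {r['label']}: {r['pre']:.2f} vs {r['post']:.2f} "
                     f"({r['test']}, p = {r['p']:.3g})")
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    return summary
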