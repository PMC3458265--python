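"""Report assembly: human-readable tables and machine-readable results.

Six delimited tables mirror the layout conventions of classical
macroecological trend studies: filter-vs-geography correlations, richness
correlation sheets, environment-vs-geography correlations, trend
assessment summaries (geographic and spatial), geography-vs-form partial
correlations, and the variation partitioning of each geographic trend.
Correlations are printed at 3 decimals, percentages at 2, both half-even
rounded, with ``*``/``**`` significance stars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import format_value, write_report_table
from .pipeline import GEO_TREND_CODES, TrendAnalysis
from .stats import pearson

__all__ = ["write_all_reports", "results_payload"]


def _fmt(r, p, decimal_style):
    return format_value(r, 3, p=p, decimal_style=decimal_style)


def _filters_vs_geography(analysis: TrendAnalysis, decimal_style: str) -> pd.DataFrame:
    space = analysis.space_
    rows = []
    for geo in space.geo_codes:
        row = {"variable": geo}
        g = space.values(geo)
        for f in space.spatial_codes:
            res = pearson(g, space.values(f))
            row[f] = _fmt(res.r, res.p, decimal_style)
        rows.append(row)
    return pd.DataFrame(rows)


def _richness_correlations(analysis: TrendAnalysis, decimal_style: str) -> pd.DataFrame:
    space = analysis.space_
    rows = []
    variables = (
        [("geographical", c) for c in space.geo_codes]
        + [("spatial", c) for c in space.spatial_codes]
        + [("environmental", c) for c in space.env_codes]
    )
    for category, code in variables:
        row = {"category": category, "variable": code}
        v = space.values(code)
        for group in space.table.richness_columns:
            y = space.table.column(group)
            if np.ptp(y) == 0:
                row[group] = ""
                continue
            res = pearson(y, v)
            row[group] = _fmt(res.r, res.p, decimal_style)
        rows.append(row)
    return pd.DataFrame(rows)


def _env_vs_geography(analysis: TrendAnalysis, decimal_style: str) -> pd.DataFrame:
    space = analysis.space_
    rows = []
    for code in tuple(space.geo_codes) + tuple(space.spatial_codes):
        row = {"variable": code}
        v = space.values(code)
        for env in space.env_codes:
            res = pearson(v, space.values(env))
            row[env] = _fmt(res.r, res.p, decimal_style)
        rows.append(row)
    return pd.DataFrame(rows)


def _assessments(analysis: TrendAnalysis, spatial: bool, decimal_style: str) -> pd.DataFrame:
    rows = []
    for a in analysis.assessments_:
        is_spatial = a.trend_code.startswith("SF_")
        if is_spatial != spatial:
            continue
        rows.append(
            {
                "group": a.group,
                "trend": a.trend_code,
                "r_trend": _fmt(a.trend_correlation.r, a.trend_correlation.p, decimal_style),
                "candidates": " ".join(a.candidates),
                "selected": " ".join(a.model.predictors),
                "model_r2": format_value(a.model.r_squared, 3, decimal_style=decimal_style),
                "partial_r_given_env": _fmt(
                    a.partial_after_env.r, a.partial_after_env.p, decimal_style
                ),
                "partial_r_given_env_area": _fmt(
                    a.partial_after_env_and_area.r,
                    a.partial_after_env_and_area.p,
                    decimal_style,
                ),
                "attribution": a.attribution,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "trend",
            "r_trend",
            "candidates",
            "selected",
            "model_r2",
            "partial_r_given_env",
            "partial_r_given_env_area",
            "attribution",
        ],
    )


def _geography_vs_form(analysis: TrendAnalysis, decimal_style: str) -> pd.DataFrame:
    rows = []
    for at in analysis.attributions_:
        if at.untested:
            rows.append(
                {
                    "group": at.group,
                    "geo_variable": at.geo_code,
                    "filters": "",
                    "partial_geo_given_filters": "",
                    "geo_label": at.geo_label + " (untested)",
                    "filter": "",
                    "partial_filter_given_geo": "",
                    "spatial_label": "",
                }
            )
            continue
        pg = at.partial_geo_given_filters
        for f in at.filters_used:
            pf = at.partial_filter_given_geo[f]
            rows.append(
                {
                    "group": at.group,
                    "geo_variable": at.geo_code,
                    "filters": " ".join(at.filters_used),
                    "partial_geo_given_filters": _fmt(pg.r, pg.p, decimal_style),
                    "geo_label": at.geo_label,
                    "filter": f,
                    "partial_filter_given_geo": _fmt(pf.r, pf.p, decimal_style),
                    "spatial_label": at.spatial_labels[f],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "geo_variable",
            "filters",
            "partial_geo_given_filters",
            "geo_label",
            "filter",
            "partial_filter_given_geo",
            "spatial_label",
        ],
    )


def _partitions(analysis: TrendAnalysis, decimal_style: str) -> pd.DataFrame:
    rows = []
    for p in analysis.partitions_:
        rows.append(
            {
                "group": p.group,
                "geo_variable": p.geo_code,
                "EGT": format_value(p.egt, 3, decimal_style=decimal_style),
                "PGT": format_value(p.pgt, 3, decimal_style=decimal_style),
                "pct_EGT": format_value(p.pct_egt, 2, decimal_style=decimal_style),
                "pct_PGT": format_value(p.pct_pgt, 2, decimal_style=decimal_style),
            }
        )
    return pd.DataFrame(
        rows, columns=["group", "geo_variable", "EGT", "PGT", "pct_EGT", "pct_PGT"]
    )


REPORT_BUILDERS = {
    "filters_vs_geography.csv": _filters_vs_geography,
    "richness_correlations.csv": _richness_correlations,
    "environment_vs_geography.csv": _env_vs_geography,
    "geographic_trend_assessments.csv": lambda a, d: _assessments(a, False, d),
    "spatial_trend_assessments.csv": lambda a, d: _assessments(a, True, d),
    "geography_vs_form.csv": _geography_vs_form,
    "variation_partitioning.csv": _partitions,
}


def _corr_dict(res):
    return {"r": res.r, "n": res.n, "p": res.p, "controls": list(res.controls)}


def results_payload(analysis: TrendAnalysis) -> dict:
    """Machine-readable mirror of every fitted result (full precision)."""
    payload: dict = {
        "normality": {
            c: {"statistic": r.statistic, "p": r.p, "retained": r.retained}
            for c, r in analysis.normality_.items()
        },
        "axes": {
            "eigenvalues": analysis.axes_.eigenvalues.tolist(),
            "variance_fraction": analysis.axes_.variance_fraction.tolist(),
            "first_axis_usable": analysis.axes_.first_axis_usable,
        },
        "filters": {
            "names": list(analysis.filters_.names),
            "eigenvalues": analysis.filters_.eigenvalues.tolist(),
            "selection_rule": analysis.filters_.selection_rule,
        },
        "trends": [
            {"group": g, "variable": c, **_corr_dict(r)} for g, c, r in analysis.trends_
        ],
        "assessments": [
            {
                "group": a.group,
                "trend": a.trend_code,
                "trend_correlation": _corr_dict(a.trend_correlation),
                "candidates": list(a.candidates),
                "selected": list(a.model.predictors),
                "intercept": a.model.intercept,
                "coefficients": a.model.coefficients.tolist(),
                "r_squared": a.model.r_squared,
                "vif": a.model.vif,
                "partial_after_env": _corr_dict(a.partial_after_env),
                "partial_after_env_and_area": _corr_dict(a.partial_after_env_and_area),
                "attribution": a.attribution,
                "max_autocorrelated_km": (
                    a.residual_diagnostics.max_autocorrelated_km
                    if a.residual_diagnostics
                    else None
                ),
            }
            for a in analysis.assessments_
        ],
        "attributions": [
            {
                "group": at.group,
                "geo_variable": at.geo_code,
                "filters": list(at.filters_used),
                "geo_label": at.geo_label,
                "spatial_labels": at.spatial_labels,
                "untested": at.untested,
            }
            for at in analysis.attributions_
        ],
        "partitions": [dataclasses.asdict(p) for p in analysis.partitions_],
    }
    return payload


def write_all_reports(
    analysis: TrendAnalysis, out_dir, decimal_style: str = "point"
) -> dict[str, int]:
    """Write the six report tables plus ``results.json``; returns row counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    for fname, builder in REPORT_BUILDERS.items():
        df = builder(analysis, decimal_style)
        write_report_table(df, out / fname, decimal_style=decimal_style)
        counts[fname] = len(df)
    payload = results_payload(analysis)
    (out / "results.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    counts["results.json"] = len(payload)
    return counts
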