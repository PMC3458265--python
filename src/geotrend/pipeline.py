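"""Trend detection, environmental attribution and variation partitioning.

The procedure, per richness group:

1. Correlate richness with each geographic variable (latitude, longitude,
   composite axis) and each retained spatial filter; significant pairs are
   geographic / spatial trends.
2. For each trend, screen environmental variables correlated *both* with
   richness and with the trend variable — the candidate explanations.
3. Reduce candidates by FDR-controlled forward stepwise regression, then
   partially correlate richness with the trend variable holding the
   selected predictors (and, as a robustness check, province area)
   constant.  A non-significant partial correlation means the environment
   explains the trend; a significant one leaves a residual (possibly pure)
   geographic pattern.
4. Contrast geographic against spatial trends by symmetric partial
   correlations (richness vs geographic variable controlling the filters,
   and vice versa) to decide whether a trend reflects the territory's
   spatial form rather than geography proper.
5. Quantify the split by variation partitioning of R²: the pure geographic
   trend is ``PGT = R²_total - R²_env`` and the environmentally explained
   share of the geographic trend is ``EGT = R²_geo - PGT``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import UnitTable
from .errors import DegenerateInputError
from .spatial import (
    CorrelogramResult,
    GeoAxes,
    MoranEigenvectorMaps,
    SpatialFilterSet,
    compute_composite_axis,
    residual_correlogram,
)
from .stats import (
    CorrelationResult,
    LinearModel,
    StepwiseOLS,
    partial_correlation,
    pearson,
    screen_normality,
)

__all__ = [
    "AnalysisConfig",
    "VariableSpace",
    "TrendAssessment",
    "AttributionResult",
    "PartitionResult",
    "TrendAnalysis",
    "detect_trends",
    "screen_candidates",
    "assess_trend",
    "attribute_geography_vs_form",
    "partition_variation",
]

GEO_TREND_CODES = ("La", "Lo", "NNE-SSW")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the full pipeline."""

    alpha: float = 0.05
    fdr_q: float = 0.05
    normality_alpha: float = 0.001
    truncation_km: float | None = None  # None -> 25th distance percentile
    sevm_variant: str = "mem"
    sevm_retention: str = "positive"
    sevm_top_k: int = 8
    fdr_stage: str = "screen"
    stepwise_direction: str = "forward"
    correlogram_classes: int = 4
    p_method: str = "normal"
    n_perm: int = 999
    diagnostics: bool = True
    area_code: str = "SA"
    seed: int = 0


class VariableSpace:
    """Resolves variable codes (table columns, axes, filters) to vectors."""

    def __init__(self, table: UnitTable, axes: GeoAxes, filters: SpatialFilterSet):
        self.table = table
        self.axes = axes
        self.filters = filters

    def values(self, code: str) -> np.ndarray:
        if code == "NNE-SSW":
            return self.axes.main_axis
        if code.startswith("SF_"):
            return self.filters.get(code)
        return self.table.column(code)

    @property
    def geo_codes(self) -> tuple[str, ...]:
        codes = ["La", "Lo"]
        if self.axes.first_axis_usable:
            codes.append("NNE-SSW")
        return tuple(codes)

    @property
    def spatial_codes(self) -> tuple[str, ...]:
        return self.filters.names

    @property
    def env_codes(self) -> tuple[str, ...]:
        return self.table.env_columns


def detect_trends(
    space: VariableSpace,
    alpha: float = 0.05,
    groups: tuple[str, ...] | None = None,
) -> list[tuple[str, str, CorrelationResult]]:
    """Significant (group, trend variable) correlations.

    Tests every richness group against every geographic variable and every
    retained spatial filter; returns the significant pairs sorted by |r|
    descending within each group.
    """
    groups = groups or space.table.richness_columns
    out: list[tuple[str, str, CorrelationResult]] = []
    for group in groups:
        y = space.table.column(group)
        if np.ptp(y) == 0:
            warnings.warn(f"richness column {group} is constant; skipped")
            continue
        hits = []
        for code in tuple(space.geo_codes) + tuple(space.spatial_codes):
            res = pearson(y, space.values(code))
            if res.p < alpha:
                hits.append((group, code, res))
        hits.sort(key=lambda t: -abs(t[2].r))
        out.extend(hits)
    return out


def screen_candidates(
    space: VariableSpace, group: str, trend_code: str, alpha: float = 0.05
) -> tuple[str, ...]:
    """Environmental codes correlated with both richness and the trend variable."""
    y = space.table.column(group)
    t = space.values(trend_code)
    out = []
    for code in space.env_codes:
        v = space.values(code)
        if np.ptp(v) == 0:
            continue
        if pearson(y, v).p < alpha and pearson(t, v).p < alpha:
            out.append(code)
    return tuple(out)


@dataclass
class TrendAssessment:
    """Verdict record for one (richness group, trend variable) pair."""

    group: str
    trend_code: str
    trend_correlation: CorrelationResult
    candidates: tuple[str, ...]
    model: LinearModel
    partial_after_env: CorrelationResult
    partial_after_env_and_area: CorrelationResult
    attribution: str  # environmentally_explained | not_explained
    residual_diagnostics: CorrelogramResult | None = None


def assess_trend(
    space: VariableSpace,
    group: str,
    trend_code: str,
    candidates: tuple[str, ...] | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> TrendAssessment:
    """Decide whether a detected trend is environmentally explained.

    Runs FDR-controlled stepwise selection over the candidate explanatory
    variables, then partially correlates richness with the trend variable
    controlling the selected predictors alone and together with province
    area.  The trend is ``environmentally_explained`` when the former
    partial correlation loses significance.
    """
    y = space.table.column(group)
    t = space.values(trend_code)
    trend_corr = pearson(y, t)
    if candidates is None:
        candidates = screen_candidates(space, group, trend_code, alpha=config.alpha)

    if candidates:
        est = StepwiseOLS(
            alpha_enter=config.alpha,
            q=config.fdr_q,
            fdr_stage=config.fdr_stage,
            direction=config.stepwise_direction,
        )
        X = pd.DataFrame({c: space.values(c) for c in candidates})
        est.fit(X, y, response=group)
        model = est.model_
    else:
        model = LinearModel(
            response=group,
            predictors=(),
            intercept=float(np.mean(y)),
            coefficients=np.array([]),
            r_squared=0.0,
            coefficient_p=np.array([]),
            residuals=y - float(np.mean(y)),
            n=y.size,
        )

    controls = [space.values(c) for c in model.predictors]
    partial_env = partial_correlation(
        y, t, controls if controls else None, control_names=model.predictors
    )
    if config.area_code in model.predictors:
        partial_env_area = partial_env
    else:
        area = space.values(config.area_code)
        partial_env_area = partial_correlation(
            y, t, controls + [area], control_names=model.predictors + (config.area_code,)
        )

    if model.predictors and not partial_env.significant(config.alpha):
        attribution = "environmentally_explained"
    else:
        attribution = "not_explained"

    diag = None
    if config.diagnostics and model.residuals is not None:
        if np.ptp(model.residuals) > 0:
            diag = residual_correlogram(
                model.residuals,
                space.table,
                n_classes=config.correlogram_classes,
                alpha=config.alpha,
                p_method=config.p_method,
                n_perm=config.n_perm,
                seed=config.seed,
            )
    return TrendAssessment(
        group=group,
        trend_code=trend_code,
        trend_correlation=trend_corr,
        candidates=tuple(candidates),
        model=model,
        partial_after_env=partial_env,
        partial_after_env_and_area=partial_env_area,
        attribution=attribution,
        residual_diagnostics=diag,
    )


@dataclass
class AttributionResult:
    """Geography-proper vs form-of-territory verdict for one geographic trend."""

    group: str
    geo_code: str
    filters_used: tuple[str, ...]
    partial_geo_given_filters: CorrelationResult | None
    partial_filter_given_geo: dict[str, CorrelationResult]
    geo_label: str  # form_of_country | geography_proper
    spatial_labels: dict[str, str]  # filter -> geography | form_of_country
    untested: bool = False


def attribute_geography_vs_form(
    space: VariableSpace,
    group: str,
    geo_code: str,
    correlated_filters: tuple[str, ...],
    alpha: float = 0.05,
) -> AttributionResult:
    """Contrast a geographic trend against the correlated spatial filters.

    The geographic trend is labeled ``form_of_country`` when the partial
    correlation of richness with the geographic variable, controlling all
    the correlated filters simultaneously, is non-significant; otherwise
    ``geography_proper``.  Symmetrically, each filter's spatial trend is
    labeled ``geography`` when richness and the filter decorrelate once the
    geographic variable is held constant.  With no correlated filter the
    geographic label defaults to ``geography_proper`` flagged as untested.
    """
    y = space.table.column(group)
    g = space.values(geo_code)
    if not correlated_filters:
        return AttributionResult(
            group=group,
            geo_code=geo_code,
            filters_used=(),
            partial_geo_given_filters=None,
            partial_filter_given_geo={},
            geo_label="geography_proper",
            spatial_labels={},
            untested=True,
        )
    filters_used = tuple(sorted(correlated_filters, key=lambda s: int(s.split("_")[1])))
    controls = [space.values(f) for f in filters_used]
    partial_geo = partial_correlation(y, g, controls, control_names=filters_used)
    geo_label = (
        "form_of_country" if not partial_geo.significant(alpha) else "geography_proper"
    )
    per_filter: dict[str, CorrelationResult] = {}
    spatial_labels: dict[str, str] = {}
    for f in filters_used:
        res = partial_correlation(y, space.values(f), [g], control_names=(geo_code,))
        per_filter[f] = res
        spatial_labels[f] = "geography" if not res.significant(alpha) else "form_of_country"
    return AttributionResult(
        group=group,
        geo_code=geo_code,
        filters_used=filters_used,
        partial_geo_given_filters=partial_geo,
        partial_filter_given_geo=per_filter,
        geo_label=geo_label,
        spatial_labels=spatial_labels,
    )


@dataclass
class PartitionResult:
    """R² decomposition of one geographic trend.

    ``PGT = max(0, R²_total - R²_env)`` is the pure geographic trend and
    ``EGT = R²_geo - PGT`` the environmentally explained share; the two sum
    to the geographic trend's R² and the percentages to 100.
    """

    group: str
    geo_code: str
    r2_geo: float
    r2_total: float
    r2_env: float
    egt: float
    pgt: float
    pct_egt: float
    pct_pgt: float
    pgt_unclamped: float
    clamped: bool


def partition_variation(
    r2_geo: float,
    r2_total: float,
    r2_env: float,
    group: str = "",
    geo_code: str = "",
) -> PartitionResult:
    """Variation partitioning of a geographic trend's R².

    Inputs are the coefficients of determination of richness on the
    geographic variable alone (``r2_geo``), on the geographic variable plus
    the selected environmental predictors (``r2_total``) and on the
    environmental predictors alone (``r2_env``).  With exactly nested fits
    ``r2_total >= r2_env`` always holds; a negative raw PGT can still occur
    when the inputs come from independently rounded sources and is clamped
    to zero, keeping the raw value in ``pgt_unclamped``.
    """
    for name, v in (("r2_geo", r2_geo), ("r2_total", r2_total), ("r2_env", r2_env)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if r2_total < r2_geo - 1e-9:
        raise ValueError("r2_total must be at least r2_geo (nested fits)")
    if r2_geo == 0:
        raise DegenerateInputError("r2_geo is zero; percentages undefined")
    raw_pgt = r2_total - r2_env
    pgt = max(0.0, raw_pgt)
    egt = r2_geo - pgt
    return PartitionResult(
        group=group,
        geo_code=geo_code,
        r2_geo=r2_geo,
        r2_total=r2_total,
        r2_env=r2_env,
        egt=egt,
        pgt=pgt,
        pct_egt=100.0 * egt / r2_geo,
        pct_pgt=100.0 * pgt / r2_geo,
        pgt_unclamped=raw_pgt,
        clamped=raw_pgt < 0,
    )


def _r2(y: np.ndarray, X: list[np.ndarray]) -> float:
    n = y.size
    design = np.column_stack([np.ones(n)] + X) if X else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / sst


class TrendAnalysis(BaseEstimator):
    """End-to-end pipeline over a unit table (fit-shaped orchestrator).

    ``fit`` runs: normality screen -> composite axes -> spatial filters ->
    trend detection -> per-trend candidate screening, stepwise selection and
    partial-correlation assessment -> geography-vs-form attribution ->
    variation partitioning of every geographic trend.

    Parameters mirror :class:`AnalysisConfig`; pass one via ``config``.

    Attributes
    ----------
    normality_ : dict of NormalityResult, per screened variable.
    axes_ : GeoAxes
    filters_ : SpatialFilterSet
    trends_ : list of (group, code, CorrelationResult)
    assessments_ : list of TrendAssessment (one per detected trend)
    attributions_ : list of AttributionResult (geographic trends only)
    partitions_ : list of PartitionResult (geographic trends only)
    """

    def __init__(self, config: AnalysisConfig | None = None):
        self.config = config

    def fit(self, table: UnitTable, y=None) -> "TrendAnalysis":
        cfg = self.config or AnalysisConfig()
        screened = ("La", "Lo") + table.env_columns + table.richness_columns
        self.normality_ = screen_normality(table, screened, alpha=cfg.normality_alpha)
        self.excluded_ = tuple(c for c, r in self.normality_.items() if not r.retained)
        if self.excluded_:
            warnings.warn(
                f"variables excluded by the normality screen: {self.excluded_}"
            )

        self.axes_ = compute_composite_axis(table)
        mem = MoranEigenvectorMaps(
            truncation_km=cfg.truncation_km,
            retention=cfg.sevm_retention,
            k=cfg.sevm_top_k,
            variant=cfg.sevm_variant,
        )
        mem.fit(table)
        self.filters_ = mem.filter_set_
        self.mem_ = mem

        groups = tuple(
            g for g in table.richness_columns if g not in self.excluded_
        )
        space = VariableSpace(table, self.axes_, self.filters_)
        self.space_ = space
        self.trends_ = detect_trends(space, alpha=cfg.alpha, groups=groups)

        self.assessments_ = []
        for group, code, _corr in self.trends_:
            self.assessments_.append(
                assess_trend(space, group, code, config=cfg)
            )

        # geography vs spatial form: filters correlated with the geographic
        # variable (a Table-2-style screen) and showing a spatial trend for
        # the same group
        trends_by_group: dict[str, set[str]] = {}
        for group, code, _ in self.trends_:
            trends_by_group.setdefault(group, set()).add(code)
        self.attributions_ = []
        for group, codes in trends_by_group.items():
            geo_hits = [c for c in codes if c in GEO_TREND_CODES]
            sf_hits = [c for c in codes if c.startswith("SF_")]
            for geo_code in geo_hits:
                gvals = space.values(geo_code)
                corr_filters = tuple(
                    f
                    for f in sf_hits
                    if pearson(gvals, space.values(f)).p < cfg.alpha
                )
                self.attributions_.append(
                    attribute_geography_vs_form(
                        space, group, geo_code, corr_filters, alpha=cfg.alpha
                    )
                )

        self.partitions_ = []
        for a in self.assessments_:
            if a.trend_code not in GEO_TREND_CODES:
                continue
            yv = table.column(a.group)
            g = space.values(a.trend_code)
            env = [space.values(c) for c in a.model.predictors]
            r2_geo = _r2(yv, [g])
            r2_env = _r2(yv, env) if env else 0.0
            r2_total = _r2(yv, [g] + env)
            self.partitions_.append(
                partition_variation(
                    r2_geo, r2_total, r2_env, group=a.group, geo_code=a.trend_code
                )
            )
        return self
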