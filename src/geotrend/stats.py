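"""Core statistics: correlation, partial correlation, FDR, stepwise OLS, VIF.

Significance conventions follow the starred two-sided style common in
macroecological tables: ``*`` for P < 0.05 and ``**`` for P < 0.01.  All
correlation p-values come from the exact t reference distribution,
``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2 - k`` for ``k`` controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .data import significance_mark
from .errors import CollinearityError, DegenerateInputError

__all__ = [
    "CorrelationResult",
    "LinearModel",
    "NormalityResult",
    "pearson",
    "partial_correlation",
    "bh_fdr",
    "vif",
    "ks_normality",
    "screen_normality",
    "StepwiseOLS",
    "stepwise_select",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A (partial) Pearson correlation with its t-based significance."""

    r: float
    n: int
    p: float
    controls: tuple[str, ...] = ()

    @property
    def df(self) -> int:
        return self.n - 2 - len(self.controls)

    @property
    def significance_mark(self) -> str:
        return significance_mark(self.p)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


@dataclass
class LinearModel:
    """An OLS fit: response, selected predictors and their diagnostics."""

    response: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    r_squared: float
    coefficient_p: np.ndarray
    vif: dict[str, float] = field(default_factory=dict)
    residuals: np.ndarray | None = None
    n: int = 0

    @property
    def is_intercept_only(self) -> bool:
        return len(self.predictors) == 0

    def equation(self, ndigits: int = 3) -> str:
        terms = [f"{self.intercept:.{ndigits}f}"]
        for name, b in zip(self.predictors, self.coefficients):
            sign = "+" if b >= 0 else "-"
            terms.append(f"{sign} {abs(b):.{ndigits}f} {name}")
        return f"{self.response} = " + " ".join(terms)


@dataclass(frozen=True)
class NormalityResult:
    """One-sample Kolmogorov-Smirnov screen against a fitted normal."""

    code: str
    statistic: float
    p: float
    retained: bool


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size < 3:
        raise DegenerateInputError(f"{name} needs at least 3 observations")
    if np.ptp(a) == 0:
        raise DegenerateInputError(f"{name} is constant; correlation undefined")
    return a


def _t_pvalue(r: float, df: int) -> float:
    if df < 1:
        raise DegenerateInputError("not enough degrees of freedom")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return float(np.finfo(float).tiny)
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with two-sided t significance."""
    xa = _as_array(x, "x")
    ya = _as_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return CorrelationResult(r=r, n=xa.size, p=_t_pvalue(r, xa.size - 2))


def partial_correlation(x, y, controls=None, control_names: tuple[str, ...] = ()) -> CorrelationResult:
    """Correlation of x and y after removing the linear effect of controls.

    Both variables are residualized on ``[1, controls]`` by least squares;
    the correlation of the residuals is referred to a t distribution on
    ``n - 2 - k`` degrees of freedom.
    """
    xa = _as_array(x, "x")
    ya = _as_array(y, "y")
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        res = pearson(xa, ya)
        return CorrelationResult(r=res.r, n=res.n, p=res.p, controls=tuple(control_names))
    Z = np.atleast_2d(np.asarray(controls, dtype=float))
    if Z.shape[0] == xa.size and Z.shape[1] != xa.size:
        pass
    elif Z.shape[1] == xa.size:
        Z = Z.T
    k = Z.shape[1]
    n = xa.size
    if n < 3 + k:
        raise DegenerateInputError(f"need n >= {3 + k} for {k} controls")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("control variables are rank deficient")
    rx = xa - design @ np.linalg.lstsq(design, xa, rcond=None)[0]
    ry = ya - design @ np.linalg.lstsq(design, ya, rcond=None)[0]
    sx = float(np.sqrt(rx @ rx))
    sy = float(np.sqrt(ry @ ry))
    tol_x = 1e-10 * max(1.0, float(np.linalg.norm(xa)))
    tol_y = 1e-10 * max(1.0, float(np.linalg.norm(ya)))
    if sx <= tol_x or sy <= tol_y:
        # a variable fully explained by the controls: zero partial correlation
        r = 0.0
    else:
        r = float((rx @ ry) / (sx * sy))
    names = tuple(control_names) if control_names else tuple(f"z{i+1}" for i in range(k))
    return CorrelationResult(r=r, n=n, p=_t_pvalue(r, n - 2 - k), controls=names)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: indices of hypotheses accepted at level q.

    Sort p ascending, find the largest k with ``p_(k) <= k*q/m`` and accept
    every hypothesis with ``p <= p_(k)``; the empty set if no such k exists.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * (np.arange(1, m + 1)) / m
    passing = np.flatnonzero(sorted_p <= thresh)
    if passing.size == 0:
        return np.array([], dtype=int)
    cutoff = sorted_p[passing[-1]]
    return np.sort(np.flatnonzero(p <= cutoff))


def vif(predictors: pd.DataFrame | dict) -> dict[str, float]:
    """Variance inflation factors ``1 / (1 - R2_j)`` per predictor.

    ``R2_j`` is the coefficient of determination of predictor j regressed
    (with intercept) on all remaining predictors.
    """
    X = pd.DataFrame(predictors)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out: dict[str, float] = {}
    n = len(X)
    for col in X.columns:
        others = X.drop(columns=[col]).to_numpy(float)
        target = X[col].to_numpy(float)
        design = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(design, target, rcond=None)
        resid = target - design @ beta
        sst = float(np.sum((target - target.mean()) ** 2))
        if sst == 0:
            raise DegenerateInputError(f"predictor {col!r} is constant")
        r2 = 1.0 - float(resid @ resid) / sst
        if r2 > 1 - 1e-12:
            raise CollinearityError(
                f"predictor {col!r} is exactly collinear with the others (infinite VIF)"
            )
        out[str(col)] = 1.0 / (1.0 - r2)
    return out


def ks_normality(values, alpha: float = 0.001, code: str = "") -> NormalityResult:
    """One-sample KS test against a normal with the sample mean and sd.

    Parameters are estimated from the data without a Lilliefors correction,
    which is conservative (under-rejects); at the screening level
    ``alpha = 0.001`` this bias is acceptable.  Constant input is treated as
    non-normal by convention.
    """
    a = np.asarray(values, dtype=float).ravel()
    if a.size < 5:
        raise DegenerateInputError("KS screen needs at least 5 observations")
    if np.ptp(a) == 0:
        return NormalityResult(code=code, statistic=1.0, p=0.0, retained=False)
    stat, p = sps.kstest(a, "norm", args=(a.mean(), a.std(ddof=1)))
    return NormalityResult(
        code=code, statistic=float(stat), p=float(p), retained=bool(p >= alpha)
    )


def screen_normality(table, codes, alpha: float = 0.001) -> dict[str, NormalityResult]:
    """Run the KS screen over the named columns of a unit table."""
    return {c: ks_normality(table.column(c), alpha=alpha, code=c) for c in codes}


# -- stepwise regression ----------------------------------------------


class StepwiseOLS(RegressorMixin, BaseEstimator):
    """Forward stepwise OLS with false-discovery-rate control.

    The default procedure ("screen" stage) first applies Benjamini-Hochberg
    FDR at level ``q`` to the marginal (single-predictor) regression
    p-values of all candidates and keeps only the accepted ones; forward
    selection then adds, at each step, the surviving candidate with the
    smallest partial-F p-value as long as it is below ``alpha_enter``.
    Under a global null this keeps the probability of selecting anything at
    ~``q`` regardless of the number of candidates.

    With ``fdr_stage="coefficients"`` the FDR pruning is instead applied to
    the coefficient p-values of the forward-selected model, dropping
    rejected predictors and refitting until stable.

    Parameters
    ----------
    alpha_enter : float, default 0.05
        Partial-F p-value a candidate must beat to enter.
    q : float, default 0.05
        FDR level for the Benjamini-Hochberg acceptance.
    fdr_stage : {"screen", "coefficients"}, default "screen"
        Where the FDR control is applied.
    direction : {"forward", "bidirectional"}, default "forward"
        ``bidirectional`` re-tests fitted predictors after each entry and
        removes any whose coefficient p-value exceeds ``alpha_remove``.
    alpha_remove : float, default 0.10
        Removal threshold for bidirectional elimination.
    vif_warn : float, default 3.0
        Warn when any variance inflation factor exceeds this value.

    Attributes
    ----------
    predictors_ : tuple of str
        Selected predictor names, in entry order.
    intercept_, coef_ : fitted coefficients.
    r_squared_ : float
    model_ : LinearModel
        Full record including coefficient p-values, VIF and residuals.
    """

    def __init__(
        self,
        alpha_enter: float = 0.05,
        q: float = 0.05,
        fdr_stage: str = "screen",
        direction: str = "forward",
        alpha_remove: float = 0.10,
        vif_warn: float = 3.0,
    ):
        self.alpha_enter = alpha_enter
        self.q = q
        self.fdr_stage = fdr_stage
        self.direction = direction
        self.alpha_remove = alpha_remove
        self.vif_warn = vif_warn

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y, response: str = "y") -> "StepwiseOLS":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != y.size:
            raise ValueError("X and y must have equal length")
        if X.shape[1] < 1:
            raise ValueError("at least one candidate predictor is required")
        if y.size <= X.shape[1] + 2:
            warnings.warn(
                "sample size is small relative to the candidate count; "
                "selection may be unstable",
                stacklevel=2,
            )
        if self.fdr_stage not in ("screen", "coefficients"):
            raise ValueError("fdr_stage must be 'screen' or 'coefficients'")

        candidates = list(X.columns)
        if self.fdr_stage == "screen":
            marginal_p = np.array(
                [self._fit_ols(y, X[[c]]).pvalues[1] for c in candidates]
            )
            keep = bh_fdr(marginal_p, q=self.q)
            candidates = [candidates[i] for i in keep]

        selected: list[str] = []
        while candidates:
            best = self._best_entry(y, X, selected, candidates)
            if best is None:
                break
            selected.append(best)
            candidates.remove(best)
            if self.direction == "bidirectional" and len(selected) > 1:
                selected = self._backward_pass(y, X, selected, protect=best)

        if self.fdr_stage == "coefficients":
            selected = self._fdr_prune(y, X, selected)

        self._finalize(y, X, selected, response)
        return self

    # ------------------------------------------------------------------
    @staticmethod
    def _fit_ols(y: np.ndarray, X: pd.DataFrame):
        design = sm.add_constant(X.to_numpy(float), has_constant="add")
        return sm.OLS(y, design).fit()

    def _best_entry(self, y, X, selected, candidates):
        """Candidate with smallest partial-F p-value (t-test of its slope).

        Ties broken by larger |t|, then alphabetically.
        """
        rows = []
        for c in candidates:
            fit = self._fit_ols(y, X[selected + [c]])
            p = float(fit.pvalues[-1])
            t = float(abs(fit.tvalues[-1]))
            rows.append((p, -t, str(c), c))
        rows.sort()
        p_best, _, _, best = rows[0]
        return best if p_best < self.alpha_enter else None

    def _backward_pass(self, y, X, selected, protect):
        while len(selected) > 1:
            fit = self._fit_ols(y, X[selected])
            pvals = fit.pvalues[1:]
            order = np.argsort(-pvals)
            dropped = False
            for i in order:
                name = selected[int(i)]
                if name != protect and pvals[int(i)] > self.alpha_remove:
                    selected = [s for s in selected if s != name]
                    dropped = True
                    break
            if not dropped:
                break
        return selected

    def _fdr_prune(self, y, X, selected):
        while selected:
            fit = self._fit_ols(y, X[selected])
            pvals = np.asarray(fit.pvalues[1:], dtype=float)
            keep = set(bh_fdr(pvals, q=self.q).tolist())
            if len(keep) == len(selected):
                break
            selected = [s for i, s in enumerate(selected) if i in keep]
        return selected

    def _finalize(self, y, X, selected, response):
        n = y.size
        if selected:
            fit = self._fit_ols(y, X[selected])
            self.intercept_ = float(fit.params[0])
            self.coef_ = np.asarray(fit.params[1:], dtype=float)
            self.r_squared_ = float(fit.rsquared)
            coef_p = np.asarray(fit.pvalues[1:], dtype=float)
            resid = np.asarray(fit.resid, dtype=float)
        else:
            self.intercept_ = float(np.mean(y))
            self.coef_ = np.array([])
            self.r_squared_ = 0.0
            coef_p = np.array([])
            resid = y - self.intercept_
        self.predictors_ = tuple(str(s) for s in selected)
        vifs: dict[str, float] = {}
        if len(selected) >= 2:
            vifs = vif(X[selected])
            high = {k: v for k, v in vifs.items() if v > self.vif_warn}
            if high:
                warnings.warn(
                    f"high collinearity among selected predictors (VIF > "
                    f"{self.vif_warn}): {high}",
                    stacklevel=2,
                )
        self.model_ = LinearModel(
            response=response,
            predictors=self.predictors_,
            intercept=self.intercept_,
            coefficients=self.coef_,
            r_squared=self.r_squared_,
            coefficient_p=coef_p,
            vif=vifs,
            residuals=resid,
            n=n,
        )

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        if self.model_.is_intercept_only:
            return np.full(len(X), self.intercept_)
        return self.intercept_ + X[list(self.predictors_)].to_numpy(float) @ self.coef_


def stepwise_select(
    y,
    candidates: pd.DataFrame | dict,
    q: float = 0.05,
    alpha_enter: float = 0.05,
    response: str = "y",
    fdr_stage: str = "screen",
) -> LinearModel:
    """Functional wrapper over :class:`StepwiseOLS`; returns the fitted model."""
    est = StepwiseOLS(alpha_enter=alpha_enter, q=q, fdr_stage=fdr_stage)
    est.fit(pd.DataFrame(candidates), y, response=response)
    return est.model_
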