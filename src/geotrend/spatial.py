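"""Spatial structure: composite geographic axes, connectivity, eigenvector
filters, Moran's I and distance-class correlograms.

The spatial filters are Moran's eigenvector maps (MEM): eigenvectors of the
doubly centered binary connectivity matrix ``H W H`` (``H = I - 11'/n``)
built from great-circle distances truncated at a fixed distance.
Eigenvectors with large positive eigenvalues describe broad-scale spatial
patterns of the study area irrespective of latitudinal or longitudinal
orientation; they are used downstream as "spatial variables" against which
geographic trends are contrasted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics.pairwise import haversine_distances

from .errors import ConfigError, DegenerateInputError

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoAxes",
    "ConnectivityMatrix",
    "SpatialFilterSet",
    "CorrelogramResult",
    "PrincipalAxes",
    "MoranEigenvectorMaps",
    "great_circle_km",
    "compute_composite_axis",
    "build_connectivity",
    "compute_spatial_filters",
    "morans_i",
    "residual_correlogram",
    "mst_truncation_km",
]

#: IUGG mean Earth radius.
EARTH_RADIUS_KM = 6371.0088


def great_circle_km(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between (lat, lon) rows in degrees.

    Haversine formula on a sphere of radius :data:`EARTH_RADIUS_KM`.
    """
    rad = np.radians(np.asarray(coords, dtype=float))
    return haversine_distances(rad) * EARTH_RADIUS_KM


# -- composite geographic axes ----------------------------------------


@dataclass
class GeoAxes:
    """Principal axes of the standardized (latitude, longitude) pair.

    ``scores[:, 0]`` is the composite main geographic axis (for a
    NNE-SSW-elongated territory, the "NNE-SSW" variable); eigenvalues of
    the 2x2 correlation matrix sum to 2, and the first equals
    ``1 + |r(La, Lo)|``.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    first_axis_usable: bool

    @property
    def main_axis(self) -> np.ndarray:
        return self.scores[:, 0]


class PrincipalAxes(TransformerMixin, BaseEstimator):
    """PCA of the standardized coordinate pair (La, Lo).

    A two-variable PCA on the correlation matrix; the first component is
    usable as a composite geographic variable only when its eigenvalue
    exceeds 1 (i.e. it captures genuine covariation between latitude and
    longitude).  Scores are sign-fixed to correlate non-negatively with
    latitude (axis 2: with longitude when the latitude correlation
    vanishes).

    Attributes
    ----------
    eigenvalues_ : ndarray of shape (2,), descending; sums to 2.
    variance_fraction_ : eigenvalue / 2.
    components_ : eigenvectors (rows).
    first_axis_usable_ : bool, True iff eigenvalues_[0] > 1.
    """

    def fit(self, X, y=None) -> "PrincipalAxes":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of (La, Lo)")
        if X.shape[0] < 3:
            raise DegenerateInputError("need at least 3 units")
        if np.ptp(X[:, 0]) == 0 or np.ptp(X[:, 1]) == 0:
            raise DegenerateInputError("constant coordinate column")
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        corr = np.corrcoef(Z, rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        scores = Z @ eigvec
        for j in range(2):
            ref = np.corrcoef(scores[:, j], X[:, 0])[0, 1]
            if abs(ref) < 1e-12:
                ref = np.corrcoef(scores[:, j], X[:, 1])[0, 1]
            if ref < 0:
                scores[:, j] *= -1
                eigvec[:, j] *= -1
        self.mean_, self.scale_ = X.mean(axis=0), X.std(axis=0, ddof=1)
        self.components_ = eigvec.T
        self.eigenvalues_ = eigval
        self.variance_fraction_ = eigval / 2.0
        self.first_axis_usable_ = bool(eigval[0] > 1.0)
        self.scores_ = scores
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.components_.T

    def to_axes(self) -> GeoAxes:
        return GeoAxes(
            scores=self.scores_,
            eigenvalues=self.eigenvalues_,
            variance_fraction=self.variance_fraction_,
            first_axis_usable=self.first_axis_usable_,
        )


def compute_composite_axis(table) -> GeoAxes:
    """Principal axes of a unit table's (La, Lo); see :class:`PrincipalAxes`."""
    return PrincipalAxes().fit(table.coords).to_axes()


# -- connectivity ------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """Symmetric binary short-distance connectivity with its distances."""

    weights: np.ndarray
    truncation_km: float
    distance_km: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if not np.allclose(W, W.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("weights must have a zero diagonal")
        if np.any(W < 0):
            raise ValueError("weights must be non-negative")
        self.weights = W

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all weights (both triangles)."""
        return float(self.weights.sum())

    @property
    def is_connected(self) -> bool:
        n_comp, _ = connected_components((self.weights > 0).astype(int), directed=False)
        return bool(n_comp == 1)

    def isolated_units(self) -> np.ndarray:
        return np.flatnonzero(self.weights.sum(axis=1) == 0)


def build_connectivity(table_or_coords, truncation_km: float) -> ConnectivityMatrix:
    """Binary connectivity: units within ``truncation_km`` are neighbours.

    Distances are great-circle (spherical haversine).  Emits a warning
    listing isolated units when the truncation leaves any unit without a
    neighbour, and a warning when the neighbour graph is disconnected.
    """
    if truncation_km <= 0:
        raise ConfigError("truncation_km must be positive")
    coords = getattr(table_or_coords, "coords", table_or_coords)
    D = great_circle_km(coords)
    W = ((D > 0) & (D <= truncation_km)).astype(float)
    np.fill_diagonal(W, 0.0)
    cm = ConnectivityMatrix(weights=W, truncation_km=float(truncation_km), distance_km=D)
    isolated = cm.isolated_units()
    if isolated.size:
        warnings.warn(
            f"truncation {truncation_km} km leaves isolated units at rows "
            f"{isolated.tolist()}",
            stacklevel=2,
        )
    elif not cm.is_connected:
        warnings.warn("connectivity graph is not connected", stacklevel=2)
    return cm


def mst_truncation_km(coords) -> float:
    """Longest edge of the minimum spanning tree of the distance matrix.

    A common helper for picking the smallest truncation that keeps the
    neighbour graph connected; offered as a convenience without any claim
    about how any particular published truncation was chosen.
    """
    from scipy.sparse.csgraph import minimum_spanning_tree

    D = great_circle_km(getattr(coords, "coords", coords))
    mst = minimum_spanning_tree(D).toarray()
    return float(mst.max())


# -- Moran eigenvector maps -------------------------------------------


@dataclass
class SpatialFilterSet:
    """Retained spatial filters (eigenvectors) with their eigenvalues."""

    filters: np.ndarray  # (n, m) columns ordered by descending eigenvalue
    eigenvalues: np.ndarray
    selection_rule: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.filters.shape[1]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f"SF_{i + 1}" for i in range(self.m))

    def get(self, name: str) -> np.ndarray:
        return self.filters[:, self.names.index(name)]


class MoranEigenvectorMaps(TransformerMixin, BaseEstimator):
    """Spatial filters from a truncated binary connectivity matrix.

    Eigen-decomposes ``H W H`` with ``H = I - 11'/n``; filters are the
    eigenvectors sorted by descending eigenvalue.  With the default
    retention rule all strictly positive eigenvalues are kept (patterns
    positively spatially autocorrelated under the given connectivity);
    ``retention="gt1"`` keeps eigenvalues > 1 and ``retention="top_k"``
    keeps the ``k`` largest.  A PCNM variant is available: large distances
    are replaced by ``4 * truncation`` and principal coordinates of the
    modified distance matrix are extracted instead.

    Each filter has zero mean and unit norm; the sign is fixed so that its
    correlation with latitude is non-positive (ties: first non-zero
    component positive).

    Parameters
    ----------
    truncation_km : float or None
        Neighbour threshold; ``None`` uses the 25th percentile of the
        positive pairwise distances.
    retention : {"positive", "gt1", "top_k"}
    k : int, used when ``retention="top_k"``.
    variant : {"mem", "pcnm"}
    """

    def __init__(
        self,
        truncation_km: float | None = None,
        retention: str = "positive",
        k: int = 8,
        variant: str = "mem",
    ):
        self.truncation_km = truncation_km
        self.retention = retention
        self.k = k
        self.variant = variant

    def fit(self, X, y=None) -> "MoranEigenvectorMaps":
        coords = np.asarray(getattr(X, "coords", X), dtype=float)
        n = coords.shape[0]
        if n < 4:
            raise DegenerateInputError("need at least 4 units for spatial filters")
        D = great_circle_km(coords)
        trunc = self.truncation_km
        if trunc is None:
            trunc = float(np.percentile(D[D > 0], 25))
        self.truncation_km_ = trunc
        self.connectivity_ = build_connectivity(coords, trunc)
        if self.variant == "mem":
            eigval, eigvec = _centered_eigendecomposition(self.connectivity_.weights)
        elif self.variant == "pcnm":
            Dmod = D.copy()
            Dmod[D > trunc] = 4.0 * trunc
            eigval, eigvec = _centered_eigendecomposition(-0.5 * Dmod**2)
        else:
            raise ConfigError(f"unknown SEVM variant {self.variant!r}")
        keep = self._retain(eigval)
        filters = eigvec[:, keep]
        filters = _fix_signs(filters, coords[:, 0])
        self.filter_set_ = SpatialFilterSet(
            filters=filters,
            eigenvalues=eigval[keep],
            selection_rule={
                "retention": self.retention,
                "k": self.k,
                "variant": self.variant,
                "truncation_km": trunc,
                "n_available": int(eigval.size),
            },
        )
        self.all_eigenvalues_ = eigval
        self._fitted_coords = coords
        if filters.shape[1] == 0:
            warnings.warn("no eigenvalue passed the retention cutoff; empty filter set")
        return self

    def _retain(self, eigval: np.ndarray) -> np.ndarray:
        if self.retention == "positive":
            return np.flatnonzero(eigval > 1e-10)
        if self.retention == "gt1":
            return np.flatnonzero(eigval > 1.0)
        if self.retention == "top_k":
            return np.arange(min(self.k, eigval.size))
        raise ConfigError(f"unknown retention rule {self.retention!r}")

    def transform(self, X) -> np.ndarray:
        coords = np.asarray(getattr(X, "coords", X), dtype=float)
        if coords.shape != self._fitted_coords.shape or not np.allclose(
            coords, self._fitted_coords
        ):
            raise ValueError(
                "Moran eigenvector maps are defined only for the units they "
                "were fitted on"
            )
        return self.filter_set_.filters


def _centered_eigendecomposition(A: np.ndarray):
    """Eigenpairs of H A H sorted by descending eigenvalue."""
    n = A.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    B = H @ A @ H
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    return eigval[order], eigvec[:, order]


def _fix_signs(filters: np.ndarray, latitude: np.ndarray) -> np.ndarray:
    out = filters.copy()
    for j in range(out.shape[1]):
        v = out[:, j]
        c = float(np.corrcoef(v, latitude)[0, 1]) if np.ptp(v) > 0 else 0.0
        if abs(c) > 1e-12:
            if c > 0:
                out[:, j] = -v
        else:
            nz = np.flatnonzero(np.abs(v) > 1e-12)
            if nz.size and v[nz[0]] < 0:
                out[:, j] = -v
    return out


def compute_spatial_filters(
    W: ConnectivityMatrix, retention: str = "positive", k: int = 8,
    latitude: np.ndarray | None = None,
) -> SpatialFilterSet:
    """Spatial filters from an existing connectivity matrix (MEM variant)."""
    eigval, eigvec = _centered_eigendecomposition(W.weights)
    if retention == "positive":
        keep = np.flatnonzero(eigval > 1e-10)
    elif retention == "gt1":
        keep = np.flatnonzero(eigval > 1.0)
    elif retention == "top_k":
        keep = np.arange(min(k, eigval.size))
    else:
        raise ConfigError(f"unknown retention rule {retention!r}")
    filters = eigvec[:, keep]
    if latitude is not None:
        filters = _fix_signs(filters, np.asarray(latitude, dtype=float))
    if filters.shape[1] == 0:
        warnings.warn("no eigenvalue passed the retention cutoff; empty filter set")
    return SpatialFilterSet(
        filters=filters,
        eigenvalues=eigval[keep],
        selection_rule={"retention": retention, "k": k, "variant": "mem"},
    )


# -- Moran's I ---------------------------------------------------------


def morans_i(
    values,
    W: ConnectivityMatrix | np.ndarray,
    p_method: str = "normal",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Moran's I with a two-sided p-value.

    ``I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with ``z`` the
    centered values and ``S0`` the sum of weights; the null expectation is
    ``-1 / (n - 1)``.  ``p_method="normal"`` uses the normality-assumption
    variance; ``"permutation"`` uses ``(#{|I_perm - E| >= |I_obs - E|} + 1)
    / (n_perm + 1)``.
    """
    weights = W.weights if isinstance(W, ConnectivityMatrix) else np.asarray(W, float)
    z = np.asarray(values, dtype=float).ravel()
    n = z.size
    if np.ptp(z) == 0:
        raise DegenerateInputError("values are constant; Moran's I undefined")
    s0 = float(weights.sum())
    if s0 <= 0:
        raise DegenerateInputError("connectivity has no positive weights")
    zc = z - z.mean()
    i_obs = (n / s0) * float(zc @ weights @ zc) / float(zc @ zc)
    e_i = -1.0 / (n - 1)
    if p_method == "normal":
        s1 = 0.5 * float(((weights + weights.T) ** 2).sum())
        s2 = float(((weights.sum(axis=0) + weights.sum(axis=1)) ** 2).sum())
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i**2
        if var <= 0:
            return i_obs, 1.0
        zscore = (i_obs - e_i) / np.sqrt(var)
        return i_obs, float(2.0 * sps.norm.sf(abs(zscore)))
    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        denom = float(zc @ zc)
        for _ in range(n_perm):
            perm = rng.permutation(zc)
            i_p = (n / s0) * float(perm @ weights @ perm) / denom
            if abs(i_p - e_i) >= abs(i_obs - e_i):
                count += 1
        return i_obs, (count + 1) / (n_perm + 1)
    raise ConfigError(f"unknown p_method {p_method!r}")


# -- correlogram -------------------------------------------------------


@dataclass(frozen=True)
class CorrelogramClass:
    upper_km: float
    morans_i: float
    p: float
    n_pairs: int


@dataclass
class CorrelogramResult:
    """Moran's I per distance class plus the largest autocorrelated bound."""

    classes: list[CorrelogramClass]
    max_autocorrelated_km: float | None

    @property
    def total_pairs(self) -> int:
        return sum(c.n_pairs for c in self.classes)


def residual_correlogram(
    residuals,
    table_or_coords,
    n_classes: int = 4,
    alpha: float = 0.05,
    p_method: str = "normal",
    n_perm: int = 999,
    seed: int | None = None,
    min_pairs: int = 8,
) -> CorrelogramResult:
    """Distance-class Moran's I correlogram of model residuals.

    Pairwise distances are split into ``n_classes`` classes with equal pair
    counts (distance quantiles); within each class Moran's I uses a binary
    weight matrix restricted to that class.  Classes holding fewer than
    ``min_pairs`` pairs are merged into their left neighbour (with a
    warning).  ``max_autocorrelated_km`` is the largest class bound whose
    class is significant at ``alpha`` (None when no class is).
    """
    if n_classes < 2:
        raise ConfigError("n_classes must be >= 2")
    coords = np.asarray(getattr(table_or_coords, "coords", table_or_coords), float)
    z = np.asarray(residuals, dtype=float).ravel()
    D = great_circle_km(coords)
    iu = np.triu_indices_from(D, k=1)
    dists = D[iu]
    edges = np.quantile(dists, np.linspace(0, 1, n_classes + 1))
    edges[0] = 0.0
    edges = np.unique(edges)
    bounds = list(zip(edges[:-1], edges[1:]))

    def pair_count(lo, hi):
        return int(np.count_nonzero((dists > lo) & (dists <= hi)))

    merged = []
    for lo, hi in bounds:
        if merged and pair_count(*merged[-1]) < min_pairs:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    if merged and len(merged) > 1 and pair_count(*merged[-1]) < min_pairs:
        last = merged.pop()
        merged[-1] = (merged[-1][0], last[1])
    if len(merged) < len(bounds):
        warnings.warn(
            f"distance classes with fewer than {min_pairs} pairs were merged "
            f"({len(bounds)} -> {len(merged)} classes)",
            stacklevel=2,
        )

    classes: list[CorrelogramClass] = []
    max_km: float | None = None
    for idx, (lo, hi) in enumerate(merged):
        Wc = ((D > lo) & (D <= hi)).astype(float)
        np.fill_diagonal(Wc, 0.0)
        npairs = pair_count(lo, hi)
        class_seed = None if seed is None else seed + idx
        i_val, p = morans_i(z, Wc, p_method=p_method, n_perm=n_perm, seed=class_seed)
        classes.append(CorrelogramClass(upper_km=float(hi), morans_i=i_val, p=p, n_pairs=npairs))
        if p < alpha:
            max_km = float(hi) if max_km is None else max(max_km, float(hi))
    return CorrelogramResult(classes=classes, max_autocorrelated_km=max_km)
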