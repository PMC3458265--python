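"""Composite axes, connectivity, Moran eigenvector maps, Moran's I."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import exact_correlated_pair
from geotrend.errors import DegenerateInputError
from geotrend.spatial import (
    ConnectivityMatrix,
    MoranEigenvectorMaps,
    PrincipalAxes,
    build_connectivity,
    compute_composite_axis,
    compute_spatial_filters,
    great_circle_km,
    morans_i,
    mst_truncation_km,
    residual_correlogram,
)


def random_coords(n, seed):
    g = np.random.default_rng(seed)
    la = g.uniform(-55, -22, n)
    lo = g.uniform(-73, -53, n)
    return np.column_stack([la, lo])


# -- great-circle distance --------------------------------------------


def test_one_degree_at_equator():
    coords = np.array([[0.0, 0.0], [0.0, 1.0]])
    d = great_circle_km(coords)[0, 1]
    assert d == pytest.approx(2 * np.pi * 6371.0088 / 360.0, rel=1e-9)
    assert d == pytest.approx(111.195, abs=0.001)


@settings(deadline=None, max_examples=50)
@given(seed=st.integers(0, 10_000))
def test_distance_metric_properties(seed):
    coords = np.random.default_rng(seed).uniform(-80, 80, size=(3, 2))
    D = great_circle_km(coords)
    assert np.allclose(D, D.T)
    assert np.all(D >= 0)
    assert D[0, 2] <= D[0, 1] + D[1, 2] + 1e-9


# -- composite axes ----------------------------------------------------


def test_first_eigenvalue_is_one_plus_abs_r():
    la, lo = exact_correlated_pair(0.448, n=23, seed=0)
    axes = PrincipalAxes().fit(np.column_stack([la, lo]))
    assert axes.eigenvalues_[0] == pytest.approx(1.448, abs=1e-10)
    assert axes.variance_fraction_[0] == pytest.approx(0.724, abs=1e-10)
    assert axes.eigenvalues_.sum() == pytest.approx(2.0, abs=1e-12)
    assert axes.first_axis_usable_


def test_uncorrelated_coordinates_not_usable():
    la, lo = exact_correlated_pair(0.0, n=20, seed=1)
    axes = PrincipalAxes().fit(np.column_stack([la, lo]))
    np.testing.assert_allclose(axes.eigenvalues_, [1.0, 1.0], atol=1e-12)
    assert not axes.first_axis_usable_


def test_axes_match_dense_eigendecomposition():
    coords = random_coords(23, seed=2)
    axes = PrincipalAxes().fit(coords)
    Z = (coords - coords.mean(0)) / coords.std(0, ddof=1)
    ref = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    np.testing.assert_allclose(axes.eigenvalues_, ref, atol=1e-10)
    # scores: zero mean, uncorrelated, non-negative correlation with La
    assert abs(axes.scores_.mean(0)).max() < 1e-10
    assert abs(np.corrcoef(axes.scores_, rowvar=False)[0, 1]) < 1e-10
    assert np.corrcoef(axes.scores_[:, 0], coords[:, 0])[0, 1] >= 0


def test_constant_coordinate_is_degenerate():
    coords = np.column_stack([np.full(10, -30.0), np.linspace(-60, -55, 10)])
    with pytest.raises(DegenerateInputError):
        compute_composite_axis(type("T", (), {"coords": coords})())


# -- connectivity ------------------------------------------------------


def test_binary_weights_within_truncation():
    coords = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 5.0]])
    cm = build_connectivity(coords, truncation_km=200.0)
    assert cm.weights[0, 1] == 1.0
    assert cm.weights[0, 2] == 0.0
    assert np.all(np.diag(cm.weights) == 0)
    assert np.allclose(cm.weights, cm.weights.T)


def test_tiny_truncation_warns_about_isolation():
    coords = random_coords(6, seed=3)
    dmin = great_circle_km(coords)
    dmin = dmin[dmin > 0].min()
    with pytest.warns(UserWarning, match="isolated"):
        cm = build_connectivity(coords, truncation_km=dmin * 0.5)
    assert cm.s0 == 0


def test_mst_truncation_connects_graph():
    coords = random_coords(23, seed=4)
    t = mst_truncation_km(coords)
    cm = build_connectivity(coords, truncation_km=t + 1e-9)
    assert cm.is_connected


# -- Moran eigenvector maps -------------------------------------------


def path_graph_connectivity(n=4):
    W = np.zeros((n, n))
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = 1.0
    D = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    return ConnectivityMatrix(weights=W, truncation_km=1.0, distance_km=D)


def test_path_graph_filters_match_dense_eigen_oracle():
    cm = path_graph_connectivity(4)
    fs = compute_spatial_filters(cm)
    n = 4
    H = np.eye(n) - np.ones((n, n)) / n
    ref = np.sort(np.linalg.eigvalsh(H @ cm.weights @ H))[::-1]
    assert fs.m == np.count_nonzero(ref > 1e-10)
    np.testing.assert_allclose(fs.eigenvalues, ref[: fs.m], atol=1e-10)
    assert np.all(np.diff(fs.eigenvalues) <= 1e-12)


def test_complete_graph_has_no_positive_structure():
    n = 6
    W = np.ones((n, n)) - np.eye(n)
    cm = ConnectivityMatrix(weights=W, truncation_km=1.0, distance_km=W)
    with pytest.warns(UserWarning, match="empty filter set"):
        fs = compute_spatial_filters(cm)
    assert fs.m == 0


@pytest.mark.parametrize("seed", range(5))
def test_filters_orthonormal_zero_mean(seed):
    coords = random_coords(20, seed=100 + seed)
    mem = MoranEigenvectorMaps(truncation_km=mst_truncation_km(coords) * 1.2).fit(coords)
    F = mem.filter_set_.filters
    assert F.shape[1] >= 1
    assert abs(F.mean(axis=0)).max() < 1e-10
    gram = F.T @ F
    np.testing.assert_allclose(gram, np.eye(F.shape[1]), atol=1e-10)
    # non-increasing eigenvalues
    assert np.all(np.diff(mem.filter_set_.eigenvalues) <= 1e-12)


def test_filter_sign_convention_non_positive_latitude_correlation():
    coords = random_coords(25, seed=9)
    mem = MoranEigenvectorMaps(truncation_km=mst_truncation_km(coords) * 1.2).fit(coords)
    for j in range(mem.filter_set_.m):
        c = np.corrcoef(mem.filter_set_.filters[:, j], coords[:, 0])[0, 1]
        assert c <= 1e-12


def test_pcnm_variant_produces_orthogonal_axes():
    coords = random_coords(20, seed=10)
    mem = MoranEigenvectorMaps(variant="pcnm").fit(coords)
    F = mem.filter_set_.filters
    np.testing.assert_allclose(F.T @ F, np.eye(F.shape[1]), atol=1e-8)


# -- Moran's I ---------------------------------------------------------


def test_moran_identity_for_eigenvectors():
    coords = random_coords(23, seed=11)
    mem = MoranEigenvectorMaps(truncation_km=mst_truncation_km(coords) * 1.2).fit(coords)
    cm = mem.connectivity_
    n = cm.n
    for j in range(mem.filter_set_.m):
        lam = mem.filter_set_.eigenvalues[j]
        i_val, _ = morans_i(mem.filter_set_.filters[:, j], cm)
        assert i_val == pytest.approx((n / cm.s0) * lam, abs=1e-8)


def test_moran_null_expectation_sign_conventions():
    cm = path_graph_connectivity(6)
    checker = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    i_val, _ = morans_i(checker, cm)
    assert i_val < 0
    smooth = np.arange(6.0)
    i_smooth, p = morans_i(smooth, cm)
    assert i_smooth > 0
    assert 0 < p <= 1


def test_moran_permutation_p_is_valid_and_seeded():
    cm = path_graph_connectivity(10)
    vals = np.arange(10.0)
    i1, p1 = morans_i(vals, cm, p_method="permutation", n_perm=199, seed=5)
    i2, p2 = morans_i(vals, cm, p_method="permutation", n_perm=199, seed=5)
    assert (i1, p1) == (i2, p2)
    assert p1 < 0.05  # a monotone gradient on a chain is strongly autocorrelated


def test_moran_constant_values_raise():
    cm = path_graph_connectivity(5)
    with pytest.raises(DegenerateInputError):
        morans_i(np.ones(5), cm)


# -- correlogram -------------------------------------------------------


def test_correlogram_pair_counts_sum():
    coords = random_coords(20, seed=12)
    g = np.random.default_rng(0)
    res = residual_correlogram(g.standard_normal(20), coords, n_classes=4)
    assert res.total_pairs == 20 * 19 // 2


def test_correlogram_merges_sparse_classes():
    coords = random_coords(6, seed=13)  # 15 pairs, 8-pair minimum forces merging
    g = np.random.default_rng(1)
    with pytest.warns(UserWarning, match="merged"):
        res = residual_correlogram(g.standard_normal(6), coords, n_classes=5)
    assert len(res.classes) < 5
    assert res.total_pairs == 15


def test_correlogram_detects_short_range_structure():
    # residuals = broad-scale spatial filter -> significant short-distance class
    coords = random_coords(40, seed=14)
    mem = MoranEigenvectorMaps(truncation_km=mst_truncation_km(coords) * 1.2).fit(coords)
    resid = mem.filter_set_.filters[:, 0] + 0.05 * np.random.default_rng(2).standard_normal(40)
    res = residual_correlogram(resid, coords, n_classes=4, alpha=0.05)
    assert res.max_autocorrelated_km is not None
    assert res.classes[0].p < 0.05
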