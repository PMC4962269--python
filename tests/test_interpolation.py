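"""The four exposure estimators: hand oracles, limits and invariants."""

import numpy as np
import pandas as pd
import pytest

import ozexpo as oz
from ozexpo.interpolation import _kriging_system

from conftest import constant_panel


def spherical_gamma(h, c0, c1, a):
    """Independent spherical semivariogram for oracles."""
    if h <= 0:
        return 0.0
    if h >= a:
        return c0 + c1
    r = h / a
    return c0 + c1 * (1.5 * r - 0.5 * r**3)


def kriging_direct(coords, values, c0, c1, a, point):
    """Brute-force solve of the augmented ordinary-kriging system."""
    n = len(values)
    A = np.ones((n + 1, n + 1))
    A[n, n] = 0.0
    for i in range(n):
        for j in range(n):
            A[i, j] = spherical_gamma(np.linalg.norm(coords[i] - coords[j]),
                                      c0, c1, a)
    b = np.ones(n + 1)
    for i in range(n):
        b[i] = spherical_gamma(np.linalg.norm(coords[i] - point), c0, c1, a)
    sol = np.linalg.solve(A, b)
    return float(sol[:n] @ values), sol[:n]


# ---------------------------------------------------------------- averaging


def test_simple_average_examples():
    assert oz.simple_average(pd.Series({"a": 10.0, "b": 20.0, "c": 30.0})
                             ).value == pytest.approx(20.0)
    assert oz.simple_average(pd.Series({"a": 42.2})).value == pytest.approx(42.2)


def test_all_missing_raises(tri_network):
    empty = pd.Series({"M01": np.nan, "M02": np.nan, "M03": np.nan})
    with pytest.raises(oz.NoDataError):
        oz.simple_average(empty)
    with pytest.raises(oz.NoDataError):
        oz.nearest_neighbor(empty, tri_network, (1.0, 1.0))
    with pytest.raises(oz.NoDataError):
        oz.idw(empty, tri_network, (1.0, 1.0))


# ------------------------------------------------------------------ nearest


def test_nearest_at_monitor_and_fallback(tri_network, tri_day):
    assert oz.nearest_neighbor(tri_day, tri_network,
                               (0.0, 0.0)).value == 30.0
    gappy = tri_day.copy()
    gappy["M01"] = np.nan  # nearest missing -> next nearest (M03 at d=sqrt10)
    assert oz.nearest_neighbor(gappy, tri_network, (0.0, 0.0)).value == 40.0


def test_nearest_tie_breaks_by_lowest_id():
    net = oz.MonitorNetwork(ids=("M02", "M01"),
                            coordinates=np.array([[0.0, 1.0], [0.0, -1.0]]))
    day = pd.Series({"M02": 20.0, "M01": 10.0})
    assert oz.nearest_neighbor(day, net, (0.0, 0.0)).value == 10.0


# ---------------------------------------------------------------------- idw


def test_idw_two_monitor_oracle():
    net = oz.MonitorNetwork(ids=("A", "B"),
                            coordinates=np.array([[1.0, 0.0], [3.0, 0.0]]))
    day = pd.Series({"A": 10.0, "B": 20.0})
    # weights 1/1 and 1/3 normalize to (3/4, 1/4)
    assert oz.idw(day, net, (0.0, 0.0)).value == pytest.approx(12.5)


def test_idw_equidistant_equals_average(tri_day):
    net = oz.MonitorNetwork(
        ids=("M01", "M02", "M03"),
        coordinates=np.array([[1.0, 0.0], [-0.5, np.sqrt(3) / 2],
                              [-0.5, -np.sqrt(3) / 2]]))
    got = oz.idw(tri_day, net, (0.0, 0.0)).value
    assert got == pytest.approx(tri_day.mean(), abs=1e-12)


def test_idw_at_monitor_returns_exact_value(tri_network, tri_day):
    assert oz.idw(tri_day, tri_network, (4.0, 0.0)).value == 50.0


# ------------------------------------------------------------- semivariance


def test_semivariogram_zero_for_constant_field(tri_network):
    day = pd.Series({"M01": 5.0, "M02": 5.0, "M03": 5.0})
    bins = oz.empirical_semivariogram(day, tri_network, n_bins=3, max_lag=10)
    assert (bins["gamma"] == 0).all()


def test_semivariogram_matches_pair_enumeration(tri_network):
    rng = np.random.default_rng(3)
    days = pd.DataFrame(rng.uniform(20, 60, size=(4, 3)),
                        columns=["M01", "M02", "M03"])
    n_bins, max_lag = 4, 6.0
    bins = oz.empirical_semivariogram(days, tri_network, n_bins=n_bins,
                                      max_lag=max_lag)
    # brute force: every (day, pair) squared difference into its bin
    coords = dict(zip(tri_network.ids, tri_network.coordinates))
    edges = np.linspace(0, max_lag, n_bins + 1)
    acc = {b: [] for b in range(n_bins)}
    for _, row in days.iterrows():
        for i, a in enumerate(tri_network.ids):
            for b_ in tri_network.ids[i + 1:]:
                d = np.linalg.norm(coords[a] - coords[b_])
                for b in range(n_bins):
                    if edges[b] < d <= edges[b + 1]:
                        acc[b].append((row[a] - row[b_]) ** 2)
    expected = {b: np.mean(v) / 2 for b, v in acc.items() if v}
    assert len(bins) == len(expected)
    for (_, r), (b, g) in zip(bins.iterrows(), sorted(expected.items())):
        assert r["gamma"] == pytest.approx(g)
        assert r["n_pairs"] == len(acc[b])


def test_semivariogram_pair_count_identity(small_panel, small_study):
    net = small_study.network
    bins = oz.empirical_semivariogram(small_panel.iloc[[0]], net,
                                      n_bins=5, max_lag=net.diameter() + 1)
    n = len(net)
    assert bins["n_pairs"].sum() == n * (n - 1) // 2


def test_semivariogram_needs_two_monitors(tri_network):
    with pytest.raises(oz.InsufficientDataError):
        oz.empirical_semivariogram(pd.Series({"M01": 4.0}), tri_network)


# ------------------------------------------------------------ model fitting


def test_fit_recovers_noiseless_spherical_bins():
    h = np.linspace(0.8, 14.0, 8)
    g = [spherical_gamma(x, 0.0, 100.0, 10.0) for x in h]
    bins = pd.DataFrame({"lag_km": h, "gamma": g, "n_pairs": 12})
    vg = oz.fit_spherical_variogram(bins)
    assert vg.nugget == pytest.approx(0.0, abs=1e-6)
    assert vg.partial_sill == pytest.approx(100.0, rel=1e-4)
    assert vg.range_km == pytest.approx(10.0, rel=1e-4)


def test_fit_zero_gammas_degenerate_flat_model():
    bins = pd.DataFrame({"lag_km": [1.0, 2.0, 3.0], "gamma": 0.0,
                         "n_pairs": 5})
    vg = oz.fit_spherical_variogram(bins)
    assert vg.nugget == 0.0 and vg.partial_sill == 0.0


def test_fit_needs_three_bins():
    bins = pd.DataFrame({"lag_km": [1.0, 2.0], "gamma": [1.0, 2.0],
                         "n_pairs": 5})
    with pytest.raises(oz.InsufficientDataError):
        oz.fit_spherical_variogram(bins)


# ------------------------------------------------------------------ kriging


def test_kriging_pure_nugget_equals_simple_average(tri_network, tri_day):
    vg = oz.VariogramModel(nugget=25.0, partial_sill=0.0, range_km=5.0)
    pred = oz.ordinary_kriging(tri_day, tri_network, vg, (2.0, 1.0))
    assert pred.value == pytest.approx(tri_day.mean(), abs=1e-10)


def test_kriging_zero_nugget_exact_at_monitors(tri_network, tri_day):
    vg = oz.VariogramModel(nugget=0.0, partial_sill=80.0, range_km=6.0)
    for mid, (x, y) in zip(tri_network.ids, tri_network.coordinates):
        pred = oz.ordinary_kriging(tri_day, tri_network, vg, (x, y))
        assert pred.value == pytest.approx(tri_day[mid], abs=1e-8)
        assert pred.variance == pytest.approx(0.0, abs=1e-8)


@pytest.mark.parametrize("n_mon", [3, 4, 5])
def test_kriging_matches_direct_solve(n_mon):
    rng = np.random.default_rng(n_mon)
    coords = rng.uniform(0, 20, size=(n_mon, 2))
    values = rng.uniform(20, 70, size=n_mon)
    net = oz.MonitorNetwork(ids=tuple(f"M{i:02d}" for i in range(n_mon)),
                            coordinates=coords)
    day = pd.Series(values, index=net.ids)
    vg = oz.VariogramModel(nugget=5.0, partial_sill=60.0, range_km=12.0)
    for point in [(3.0, 4.0), (15.0, 2.0), (9.0, 18.0)]:
        expected, lam = kriging_direct(coords, values, 5.0, 60.0, 12.0,
                                       np.asarray(point))
        pred = oz.ordinary_kriging(day, net, vg, point)
        assert pred.value == pytest.approx(expected, rel=1e-8)
        assert lam.sum() == pytest.approx(1.0, abs=1e-8)


def test_kriging_weights_sum_to_one(tri_network):
    vg = oz.VariogramModel(nugget=3.0, partial_sill=40.0, range_km=8.0)
    lam, _, _ = _kriging_system(tri_network, vg,
                                np.array([[2.0, 2.0], [0.5, 0.1]]))
    np.testing.assert_allclose(lam.sum(axis=0), 1.0, atol=1e-8)


def test_kriging_needs_two_monitors(tri_network):
    vg = oz.VariogramModel(nugget=1.0, partial_sill=1.0, range_km=1.0)
    day = pd.Series({"M01": 10.0, "M02": np.nan, "M03": np.nan})
    with pytest.raises(oz.InsufficientDataError):
        oz.ordinary_kriging(day, tri_network, vg, (0.0, 0.0))


# -------------------------------------------------------------- panel-level


def test_predict_all_constant_panel_every_method(tri_network):
    panel = constant_panel(tri_network, n_days=3, value=40.0)
    locs = pd.DataFrame({"x_km": [0.5, 2.5], "y_km": [0.5, 1.5]},
                        index=["S1", "S2"])
    for method in oz.METHODS:
        preds = oz.predict_all(panel, tri_network, locs, method)
        np.testing.assert_allclose(preds.to_numpy(), 40.0, atol=1e-9)


def test_predict_all_simple_average_shared_value(small_panel, small_study):
    locs = small_study.ground_truth.residences.iloc[:5]
    preds = oz.predict_all(small_panel, small_study.network, locs,
                           "simple_average")
    assert (preds.nunique(axis=1) == 1).all()


def test_single_monitor_all_methods_identical():
    net = oz.MonitorNetwork(ids=("M01",), coordinates=np.array([[1.0, 1.0]]))
    panel = constant_panel(net, n_days=2, value=37.5)
    panel.iloc[1] = 22.0
    locs = pd.DataFrame({"x_km": [9.0], "y_km": [9.0]}, index=["S1"])
    results = [oz.predict_all(panel, net, locs, m) for m in oz.METHODS]
    for r in results[1:]:
        pd.testing.assert_frame_equal(r, results[0])
    np.testing.assert_allclose(results[0]["S1"], [37.5, 22.0])


def test_translation_equivariance(small_panel, small_study):
    locs = small_study.ground_truth.residences.iloc[:4]
    vg = oz.VariogramModel(nugget=5.0, partial_sill=50.0, range_km=10.0)
    policy = oz.VariogramPolicy(mode="fixed", fixed=vg)
    shift = 7.25
    for method in oz.METHODS:
        base = oz.predict_all(small_panel, small_study.network, locs, method,
                              variogram_policy=policy)
        moved = oz.predict_all(small_panel + shift, small_study.network,
                               locs, method, variogram_policy=policy)
        pd.testing.assert_frame_equal(moved, base + shift, atol=1e-8,
                                      check_exact=False)


def test_methods_bounded_by_daily_extremes(small_panel, small_study):
    """Average, nearest and IDW cannot extrapolate beyond daily extremes."""
    locs = small_study.ground_truth.residences.iloc[:10]
    lo = small_panel.min(axis=1)
    hi = small_panel.max(axis=1)
    for method in ("simple_average", "nearest", "idw"):
        preds = oz.predict_all(small_panel, small_study.network, locs, method)
        assert (preds.ge(lo - 1e-9, axis=0)
                & preds.le(hi + 1e-9, axis=0)).all().all()


def test_unknown_method_rejected(small_panel, small_study):
    locs = small_study.ground_truth.residences.iloc[:2]
    with pytest.raises(ValueError, match="unknown method"):
        oz.predict_all(small_panel, small_study.network, locs, "spline")
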