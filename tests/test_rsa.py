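"""Condition patterns, neural RDMs, Kendall tau, model comparison, MDS."""

import numpy as np
import pytest
from scipy.stats import kendalltau as scipy_kendalltau

from vividness import (
    build_model_rdm,
    classical_mds,
    compare_models,
    compute_neural_rdm_series,
    estimate_condition_patterns,
    kendall_tau_lower,
    smooth_rdm_series,
)
from vividness.rsa import NeuralRDMSeries
from vividness.simulate import EpochedRecording


def test_condition_patterns_equal_one_hot_least_squares(noisy_graded):
    pats = estimate_condition_patterns(noisy_graded)
    # oracle: normal-equations solve of the dummy-coded design at one sample
    labels = noisy_graded.labels
    stims = sorted(labels["stimulus"].unique())
    X = np.zeros((len(labels), 8))
    for i, s in enumerate(stims):
        for r in (1, 2, 3, 4):
            X[((labels["stimulus"] == s) & (labels["pas"] == r)).to_numpy(), 4 * i + r - 1] = 1
    t = 30
    Y = noisy_graded.data[:, :, t]
    beta = np.linalg.solve(X.T @ X, X.T @ Y)
    assert np.allclose(pats.coefficients[:, :, t], beta, atol=1e-10)


def test_single_trial_condition_pattern_is_that_trial(behavior):
    import pandas as pd
    rows = behavior.groupby(["stimulus", "pas"]).head(1).reset_index(drop=True)
    rng = np.random.default_rng(0)
    data = rng.standard_normal((len(rows), 5, 10))
    rec = EpochedRecording(data, -200 + 4.0 * np.arange(10), rows)
    pats = estimate_condition_patterns(rec)
    stims = sorted(rows["stimulus"].unique())
    for i, cond in enumerate(pats.conditions):
        stim, pas = cond.rsplit("-", 1)
        r = {"NE": 1, "WG": 2, "ACE": 3, "CE": 4}[pas]
        j = rows.index[(rows["stimulus"] == stim) & (rows["pas"] == r)][0]
        assert np.array_equal(pats.coefficients[i], data[j])


def test_missing_condition_error_names_it(behavior):
    sub = behavior[~((behavior["stimulus"] == "square") & (behavior["pas"] == 4))]
    rng = np.random.default_rng(0)
    rec = EpochedRecording(rng.standard_normal((len(sub), 4, 6)),
                           -200 + 4.0 * np.arange(6), sub.reset_index(drop=True))
    with pytest.raises(ValueError, match="square-PAS4"):
        estimate_condition_patterns(rec)


def test_pearson_distance_matches_direct_formula(noisy_graded):
    pats = estimate_condition_patterns(noisy_graded)
    series = compute_neural_rdm_series(pats)
    t = 55
    x = pats.coefficients[:, :, t]
    for i in range(8):
        for j in range(8):
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            expected = 1 - (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            assert series.values[t, i, j] == pytest.approx(expected, abs=1e-12)
    assert (series.values >= -1e-9).all() and (series.values <= 2 + 1e-9).all()


def test_identical_and_opposite_patterns():
    coeffs = np.zeros((8, 6, 1))
    base = np.array([1.0, -1, 2, 0, 3, -2])
    coeffs[:, :, 0] = base
    coeffs[4, :, 0] = -base
    from vividness.rsa import ConditionPatterns
    series = compute_neural_rdm_series(
        ConditionPatterns(coeffs, [f"c{i}" for i in range(8)], np.array([0.0])))
    assert series.values[0, 0, 1] == pytest.approx(0.0, abs=1e-12)
    assert series.values[0, 0, 4] == pytest.approx(2.0, abs=1e-12)


def test_zero_variance_pattern_gets_neutral_distance():
    coeffs = np.zeros((8, 5, 1))
    coeffs[1:, :, 0] = np.random.default_rng(1).standard_normal((7, 5))
    from vividness.rsa import ConditionPatterns
    series = compute_neural_rdm_series(
        ConditionPatterns(coeffs, [f"c{i}" for i in range(8)], np.array([0.0])))
    assert np.allclose(series.values[0, 0, 1:], 1.0)
    assert series.values[0, 0, 0] == 0.0


def test_sensor_permutation_leaves_rdm_unchanged(noisy_graded):
    series = compute_neural_rdm_series(estimate_condition_patterns(noisy_graded))
    perm = np.random.default_rng(2).permutation(noisy_graded.data.shape[1])
    shuffled = EpochedRecording(noisy_graded.data[:, perm, :], noisy_graded.time_ms,
                                noisy_graded.labels)
    series2 = compute_neural_rdm_series(estimate_condition_patterns(shuffled))
    assert np.allclose(series.values, series2.values, atol=1e-12)


def test_smoothing_kernel_is_15_samples_at_60ms():
    values = np.zeros((31, 8, 8))
    values[15, 0, 1] = values[15, 1, 0] = 1.0
    series = NeuralRDMSeries(values, -200 + 4.0 * np.arange(31))
    sm = smooth_rdm_series(series, kernel_ms=60.0)
    cell = sm.values[:, 0, 1]
    assert np.isclose(cell[15], 1 / 15)
    assert (cell > 0).sum() == 15
    # constant series unchanged
    const = NeuralRDMSeries(np.ones((31, 8, 8)), series.time_ms)
    assert np.allclose(smooth_rdm_series(const).values, 1.0)


def _brute_force_tau_a(x, y):
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return s / (n * (n - 1) / 2)


def test_tau_matches_exhaustive_pair_counting():
    rng = np.random.default_rng(3)
    for _ in range(5):
        x = rng.integers(0, 5, 28).astype(float)  # tie-rich
        y = rng.standard_normal(28)
        assert kendall_tau_lower(x, y) == pytest.approx(_brute_force_tau_a(x, y), abs=1e-12)


def test_tau_edge_cases_and_antisymmetry():
    x = np.arange(28.0)
    assert kendall_tau_lower(x, x) == 1.0
    assert kendall_tau_lower(x, -x) == -1.0
    rng = np.random.default_rng(4)
    a, b = rng.standard_normal(28), rng.standard_normal(28)
    assert kendall_tau_lower(a, -b) == pytest.approx(-kendall_tau_lower(a, b), abs=1e-12)
    assert kendall_tau_lower(a, np.full(28, 2.0)) == 0.0


def test_tau_b_variant_matches_scipy():
    rng = np.random.default_rng(5)
    x, y = rng.standard_normal(28), rng.standard_normal(28)
    assert kendall_tau_lower(x, y, variant="b") == pytest.approx(
        scipy_kendalltau(x, y).statistic, abs=1e-12)
    # tie-free tau-a equals tau-b
    assert kendall_tau_lower(x, y) == pytest.approx(
        kendall_tau_lower(x, y, variant="b"), abs=1e-12)


def test_batch_tau_b_matches_scipy_per_timepoint(noisy_graded):
    from vividness.rsa import _tau_batch
    rng = np.random.default_rng(12)
    X = rng.integers(0, 4, (6, 28)).astype(float)  # tie-rich rows
    y = rng.integers(0, 3, 28).astype(float)
    batch = _tau_batch(X, y, "b")
    for i in range(6):
        assert batch[i] == pytest.approx(scipy_kendalltau(X[i], y).statistic, abs=1e-12)


def test_tau_b_recovers_discrete_geometry_where_tau_a_cannot():
    # on exactly discrete neural data, tau-a scores the discrete and graded
    # models identically; tau-b credits the tie-rich (coarser) model more
    discrete_neural = build_model_rdm("abstract_discrete").values
    graded = build_model_rdm("abstract_graded")
    disc = build_model_rdm("abstract_discrete")
    assert kendall_tau_lower(discrete_neural, graded) == pytest.approx(
        kendall_tau_lower(discrete_neural, disc), abs=1e-12)
    assert kendall_tau_lower(discrete_neural, disc, variant="b") > \
        kendall_tau_lower(discrete_neural, graded, variant="b") + 0.1


def test_compare_models_rejects_uniform_null():
    series = NeuralRDMSeries(np.random.default_rng(6).random((4, 8, 8)),
                             np.arange(4.0))
    with pytest.raises(ValueError, match="uniform"):
        compare_models(series, [build_model_rdm("specific_discrete")])
    with pytest.raises(ValueError):
        compare_models(series, [])


def test_compare_models_invariant_under_monotone_transform(noisy_graded):
    series = compute_neural_rdm_series(estimate_condition_patterns(noisy_graded))
    m = build_model_rdm("abstract_graded")
    cubed = type(m)(m.values**3, m.kind)
    a = compare_models(series, [m])["tau"].to_numpy()
    b = compare_models(series, [cubed])["tau"].to_numpy()
    assert np.allclose(a, b, atol=1e-12)


def _procrustes_rmse(a, b):
    a = a - a.mean(0)
    b = b - b.mean(0)
    u, _, vt = np.linalg.svd(b.T @ a)
    rot = u @ vt
    scale = np.trace(a.T @ b @ rot) / np.trace(a.T @ a)
    return np.sqrt(np.mean((b - scale * a @ rot.T) ** 2))


def test_mds_recovers_planar_configuration():
    rng = np.random.default_rng(7)
    pts = rng.standard_normal((8, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    coords = classical_mds(d, k=2)
    assert coords.shape == (8, 2)
    assert _procrustes_rmse(pts, coords) < 1e-8


def test_mds_orders_ratings_along_first_dimension():
    coords = classical_mds(build_model_rdm("abstract_graded"), k=2)
    dim1 = coords[:, 0]
    sign = np.sign(dim1[3] - dim1[0])
    for stim in (0, 1):
        vals = sign * dim1[4 * stim:4 * stim + 4]
        assert np.all(np.diff(vals) > 0)  # NE < WG < ACE < CE
    # identical embedding for both stimuli (content-invariant model)
    assert np.allclose(coords[:4], coords[4:], atol=1e-8)


def test_mds_eigenvalues_nonnegative_for_euclidean_input():
    rng = np.random.default_rng(8)
    pts = rng.standard_normal((8, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    n = 8
    j = np.eye(n) - np.ones((n, n)) / n
    eigval = np.linalg.eigvalsh(-0.5 * j @ (d**2) @ j)
    assert eigval.min() > -1e-10
    # asking for more dimensions than exist returns fewer, not garbage
    coords = classical_mds(d, k=7)
    assert coords.shape[1] <= 3 + 1
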