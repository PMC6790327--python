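"""Static/dynamic FC construction, Fisher z, vectorization, reporting helpers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_pearson
from wmgfc.connectivity import (
    FCMatrix,
    dynamic_fc,
    fisher_z,
    group_mean_fc,
    matrix_from_vector,
    n_windows,
    rms_over_windows,
    static_fc_cross,
    static_fc_within,
    threshold_mask,
    vectorize,
)


def _labels(prefix, n):
    return [f"{prefix}_{i + 1:02d}" for i in range(n)]


# ------------------------------------------------------------------- static


def test_duplicate_column_gives_r_one():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(50)
    data = np.column_stack([x, x, rng.standard_normal(50)])
    fc = static_fc_within(data, _labels("GM", 3))
    assert fc.values[0, 1] == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(np.diag(fc.values), 1.0)
    np.testing.assert_allclose(fc.values, fc.values.T, atol=1e-15)


def test_negated_shifted_column_gives_minus_one():
    x = np.random.default_rng(1).standard_normal(40)
    data = np.column_stack([x, -x + 3.0])
    fc = static_fc_within(data, _labels("GM", 2))
    assert fc.values[0, 1] == pytest.approx(-1.0, abs=1e-12)


def test_pearson_worked_example():
    data = np.column_stack([[1, 2, 3, 4.0], [1, 2, 3, 5.0]])
    fc = static_fc_within(data, _labels("GM", 2))
    assert fc.values[0, 1] == pytest.approx(0.9827, abs=5e-5)


def test_zero_variance_column_edges_zeroed():
    rng = np.random.default_rng(2)
    data = np.column_stack([rng.standard_normal(30), np.full(30, 2.0)])
    fc = static_fc_within(data, _labels("GM", 2))
    assert fc.values[0, 1] == 0.0
    assert fc.values[1, 1] == 1.0


def test_cross_equals_within_on_same_input():
    rng = np.random.default_rng(3)
    data = rng.standard_normal((60, 4))
    lab = _labels("GM", 4)
    within = static_fc_within(data, lab)
    cross = static_fc_cross(data, data, lab, lab)
    np.testing.assert_allclose(cross.values, within.values, atol=1e-12)
    np.testing.assert_allclose(np.diag(cross.values), 1.0)


def test_cross_null_correlations_bounded():
    rng = np.random.default_rng(4)
    wm = rng.standard_normal((500, 5))
    gm = rng.standard_normal((500, 6))
    fc = static_fc_cross(wm, gm, _labels("WM", 5), _labels("GM", 6))
    assert np.abs(fc.values).max() < 0.15  # ~3/sqrt(T)


def test_cross_detects_identical_roi():
    rng = np.random.default_rng(5)
    gm = rng.standard_normal((40, 6))
    wm = gm[:, [4]]
    fc = static_fc_cross(wm, gm, ["WM_01"], _labels("GM", 6))
    assert fc.values[0, 4] == 1.0


def test_cross_length_mismatch_errors():
    with pytest.raises(ValueError, match="length"):
        static_fc_cross(np.zeros((10, 2)), np.zeros((12, 2)), ["a", "b"], ["c", "d"])


# ------------------------------------------------------------------ dynamic


def test_window_count_formula():
    assert n_windows(140, 30, 1) == 111
    d = dynamic_fc(
        np.random.default_rng(0).standard_normal((140, 2)), None, _labels("GM", 2)
    )
    assert d.n_windows == 111


def test_identical_series_all_windows_one():
    x = np.random.default_rng(1).standard_normal((50, 1))
    d = dynamic_fc(np.hstack([x, x]), None, _labels("GM", 2), window_length=10)
    np.testing.assert_allclose(d.values, 1.0, atol=1e-12)


def test_window_longer_than_series_errors():
    with pytest.raises(ValueError, match="window"):
        dynamic_fc(np.zeros((20, 2)), None, _labels("GM", 2), window_length=30)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_windowed_correlations_match_bruteforce(seed):
    """Every windowed C^k equals an independent Pearson r on the extracted
    sub-series (0-based half-open windows)."""
    rng = np.random.default_rng(seed)
    t_len = int(rng.integers(20, 60))
    w = int(rng.integers(3, 12))
    step = int(rng.integers(1, 4))
    a = rng.standard_normal((t_len, 2))
    b = rng.standard_normal((t_len, 3))
    d = dynamic_fc(a, b, ["r1", "r2"], ["c1", "c2", "c3"], window_length=w, step=step)
    assert d.n_windows == (t_len - w) // step + 1
    for e, (rl, cl) in enumerate(d.edge_index):
        i = ["r1", "r2"].index(rl)
        j = ["c1", "c2", "c3"].index(cl)
        for k in range(d.n_windows):
            sub_a = a[k * step : k * step + w, i]
            sub_b = b[k * step : k * step + w, j]
            assert d.values[e, k] == pytest.approx(brute_pearson(sub_a, sub_b), abs=1e-12)


def test_degenerate_window_gives_zero_and_keeps_k():
    x = np.random.default_rng(2).standard_normal((30, 1))
    const = np.ones((30, 1))
    d = dynamic_fc(np.hstack([x, const]), None, _labels("GM", 2), window_length=10)
    np.testing.assert_array_equal(d.values, 0.0)
    assert d.n_windows == 21
    assert d.n_degenerate_windows > 0


# ---------------------------------------------------------------------- RMS


def test_rms_constant_windows():
    d = dynamic_fc(
        np.random.default_rng(0).standard_normal((40, 2)), None, _labels("GM", 2),
        window_length=10,
    )
    d.values[:] = 0.5
    assert rms_over_windows(d).values[0, 1] == pytest.approx(0.5)


def test_rms_two_window_worked_example():
    d = dynamic_fc(
        np.random.default_rng(0).standard_normal((10, 2)), None, _labels("GM", 2),
        window_length=9,
    )
    assert d.n_windows == 2
    d.values[0] = [0.6, -0.8]
    assert rms_over_windows(d).values[0, 1] == pytest.approx(np.sqrt(0.5), abs=1e-5)


def test_single_full_window_rms_equals_abs_static():
    rng = np.random.default_rng(6)
    data = rng.standard_normal((50, 4))
    lab = _labels("GM", 4)
    d = dynamic_fc(data, None, lab, window_length=50)
    assert d.n_windows == 1
    rms = rms_over_windows(d)
    static = static_fc_within(data, lab)
    np.testing.assert_allclose(rms.values[np.triu_indices(4, 1)],
                               np.abs(static.values)[np.triu_indices(4, 1)],
                               atol=1e-12)


def test_rms_at_least_abs_mean():
    rng = np.random.default_rng(7)
    d = dynamic_fc(rng.standard_normal((60, 3)), None, _labels("GM", 3), window_length=15)
    rms = rms_over_windows(d).values[np.triu_indices(3, 1)]
    mean_abs = np.abs(d.values.mean(axis=1))
    assert (rms + 1e-12 >= mean_abs).all()


# ----------------------------------------------------------------- fisher z


def test_fisher_z_basic_values():
    m = FCMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), "static_r",
                 _labels("GM", 2), _labels("GM", 2), True)
    z = fisher_z(m)
    assert z.values[0, 1] == 0.0
    m2 = FCMatrix(np.array([[0.5]]), "static_r", ["WM_01"], ["GM_01"], False)
    assert fisher_z(m2).values[0, 0] == pytest.approx(0.54931, abs=1e-5)


@settings(max_examples=50, deadline=None)
@given(st.floats(-0.999, 0.999))
def test_fisher_z_odd_and_invertible(r):
    def z_of(v):
        m = FCMatrix(np.array([[v]]), "static_r", ["a"], ["b"], False)
        return fisher_z(m).values[0, 0]

    assert z_of(-r) == pytest.approx(-z_of(r), abs=1e-12)
    assert np.tanh(z_of(r)) == pytest.approx(r, abs=1e-6)


def test_fisher_z_monotone():
    r = np.linspace(-0.999, 0.999, 101)
    m = FCMatrix(r[None, :], "static_r", ["a"], [f"c{i}" for i in range(101)], False)
    z = fisher_z(m).values[0]
    assert (np.diff(z) > 0).all()


def test_fisher_z_rejects_out_of_range():
    m = FCMatrix.__new__(FCMatrix)  # bypass validation to feed bad values
    m.values = np.array([[1.5]])
    m.kind = "static_r"
    m.row_labels, m.col_labels, m.symmetric = ["a"], ["b"], False
    with pytest.raises(ValueError, match=r"\[-1, 1\]"):
        fisher_z(m)


def test_fisher_z_finite_at_perfect_correlation():
    m = FCMatrix(np.array([[1.0]]), "static_r", ["a"], ["b"], False)
    assert np.isfinite(fisher_z(m).values).all()


# -------------------------------------------------------------- vectorize


def test_feature_counts_at_study_dimensions():
    gm = _labels("GM", 82)
    wm = _labels("WM", 48)
    sym = FCMatrix(np.eye(82), "static_r", gm, gm, True)
    vec, idx = vectorize(sym)
    assert len(vec) == len(idx) == 3321
    rect = FCMatrix(np.zeros((48, 82)), "static_r", wm, gm, False)
    vec, idx = vectorize(rect)
    assert len(vec) == len(idx) == 3936


def test_vectorize_round_trip():
    rng = np.random.default_rng(8)
    lab = _labels("GM", 5)
    sym = static_fc_within(rng.standard_normal((30, 5)), lab)
    vec, idx = vectorize(sym)
    back = matrix_from_vector(vec, idx, lab, lab, sym.kind, True)
    np.testing.assert_allclose(back.values, sym.values, atol=1e-12)
    rect = static_fc_cross(rng.standard_normal((30, 3)), rng.standard_normal((30, 4)),
                           _labels("WM", 3), _labels("GM", 4))
    vec, idx = vectorize(rect)
    back = matrix_from_vector(vec, idx, rect.row_labels, rect.col_labels, rect.kind, False)
    np.testing.assert_allclose(back.values, rect.values, atol=1e-12)


# ------------------------------------------------------- mean and threshold


def test_group_mean_single_and_cancel():
    lab = _labels("GM", 3)
    rng = np.random.default_rng(9)
    m = static_fc_within(rng.standard_normal((30, 3)), lab)
    np.testing.assert_array_equal(group_mean_fc([m]).values, m.values)
    neg = FCMatrix(-m.values, m.kind, lab, lab, True)
    np.testing.assert_allclose(group_mean_fc([m, neg]).values, 0.0, atol=1e-15)
    c1 = FCMatrix(np.full((2, 3), 0.2), "rms", ["a", "b"], ["x", "y", "z"], False)
    c2 = FCMatrix(np.full((2, 3), 0.6), "rms", ["a", "b"], ["x", "y", "z"], False)
    np.testing.assert_allclose(group_mean_fc([c1, c2]).values, 0.4)


def test_group_mean_shape_mismatch_errors():
    a = FCMatrix(np.zeros((2, 2)), "rms", ["a", "b"], ["a", "b"], True)
    b = FCMatrix(np.zeros((2, 3)), "rms", ["a", "b"], ["x", "y", "z"], False)
    with pytest.raises(ValueError):
        group_mean_fc([a, b])


def test_threshold_mask_is_strict_and_uses_abs():
    m = FCMatrix(np.array([[0.5, -0.6], [0.0, 0.51]]), "static_r",
                 ["a", "b"], ["x", "y"], False)
    mask = threshold_mask(m, 0.5)
    assert mask.tolist() == [[False, True], [False, True]]
    zero = FCMatrix(np.zeros((2, 2)), "rms", ["a", "b"], ["x", "y"], False)
    assert not threshold_mask(zero, 0.5).any()
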