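"""Unit and property tests for the optimal-scaling PCA engine."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.isotonic import IsotonicRegression

from coldheat import (CategoricalDataset, NonlinearPCA, ScalingSpec,
                      forced_classification_fit, monotone_regression,
                      spline_basis)


# ----------------------------------------------------------------------
# monotone regression (PAVA)
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "values, weights, expected",
    [
        ([1, 3, 2], [1, 1, 1], [1, 2.5, 2.5]),
        ([2, 1], [3, 1], [1.75, 1.75]),
        ([1, 2, 3], [1, 1, 1], [1, 2, 3]),  # already monotone: identity
        ([3, 2, 1], [1, 1, 1], [2, 2, 2]),
    ],
)
def test_pava_known_values(values, weights, expected):
    np.testing.assert_allclose(monotone_regression(values, weights), expected)


def _brute_force_monotone(y, w):
    """Exhaustive minimization over monotone fits: every fit is a piecewise
    weighted mean over an ordered partition into blocks."""
    k = len(y)
    best, best_loss = None, np.inf
    for cuts in itertools.product([0, 1], repeat=k - 1):
        blocks, start = [], 0
        for i, c in enumerate(cuts, start=1):
            if c:
                blocks.append(slice(start, i))
                start = i
        blocks.append(slice(start, k))
        fit = np.empty(k)
        for b in blocks:
            fit[b] = np.average(y[b], weights=w[b])
        if np.all(np.diff(fit) >= -1e-12):
            loss = np.sum(w * (y - fit) ** 2)
            if loss < best_loss - 1e-12:
                best, best_loss = fit, loss
    return best


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    y=st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=5),
    wseed=st.integers(0, 10_000),
)
def test_pava_equals_exhaustive_search(y, wseed):
    y = np.asarray(y)
    w = np.random.default_rng(wseed).uniform(0.5, 3.0, len(y))
    np.testing.assert_allclose(
        monotone_regression(y, w), _brute_force_monotone(y, w), atol=1e-9)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(y=st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=30))
def test_pava_matches_isotonic_oracle_and_is_monotone(y):
    fit = monotone_regression(y)
    assert np.all(np.diff(fit) >= -1e-10)
    oracle = IsotonicRegression().fit_transform(np.arange(len(y)), y)
    np.testing.assert_allclose(fit, oracle, atol=1e-8)


# ----------------------------------------------------------------------
# spline bases
# ----------------------------------------------------------------------
def test_spline_basis_rank():
    B = spline_basis(np.arange(1, 8), degree=2, interior_knots=1)
    assert B.shape == (7, 4)
    assert np.linalg.matrix_rank(B) == 4  # degree + knots + 1


def test_monotone_basis_nonneg_combinations_nondecreasing():
    rng = np.random.default_rng(0)
    M = spline_basis(np.arange(1, 10), degree=2, interior_knots=2, monotone=True)
    for _ in range(25):
        coef = rng.uniform(0, 2, M.shape[1])
        fit = M @ coef
        assert np.all(np.diff(fit) >= -1e-10)


def test_knots_reduced_when_too_few_categories():
    B = spline_basis(np.arange(1, 4), degree=2, interior_knots=2)
    # only 3 positions: knots drop to 0, basis rank = 3
    assert np.linalg.matrix_rank(B) == 3


def _numeric_dataset(seed=0, n=20, m=10, k=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, m))
    df = pd.DataFrame({f"x{j}": np.argsort(np.argsort(X[:, j])) + 1 for j in range(m)})
    return df


def test_degree1_no_knot_spline_equals_numeric_level():
    df = _numeric_dataset(seed=2, n=15, m=4)
    num = {c: ScalingSpec(analysis_level="numeric") for c in df.columns}
    spl = {c: ScalingSpec(analysis_level="spline-nominal", degree=1, interior_knots=0)
           for c in df.columns}
    # affine transformations cannot beat (or lose to) the linear level
    v_num = NonlinearPCA(CategoricalDataset(df, num)).fit(tol=1e-12, seed=0).total_vaf
    v_spl = NonlinearPCA(CategoricalDataset(df, spl)).fit(tol=1e-12, seed=0).total_vaf
    assert v_spl == pytest.approx(v_num, abs=1e-8)


# ----------------------------------------------------------------------
# ALS engine
# ----------------------------------------------------------------------
def test_numeric_level_equals_classical_pca():
    df = _numeric_dataset(seed=0, n=20, m=10)
    specs = {c: ScalingSpec(analysis_level="numeric") for c in df.columns}
    res = NonlinearPCA(CategoricalDataset(df, specs)).fit(tol=1e-12, seed=1)
    Z = (df - df.mean()) / df.std(ddof=0)
    top_ev = np.linalg.eigvalsh(np.cov(Z.T, ddof=0)).max()
    assert res.total_vaf == pytest.approx(top_ev / df.shape[1], abs=1e-8)


def test_total_vaf_monotone_over_iterations(study_dataset):
    ds, _ = study_dataset
    res = NonlinearPCA(ds.subset_variables(ds.variables[:20])).fit(seed=0)
    assert np.all(np.diff(res.vaf_history) >= -1e-10)


def test_normalization_invariants(study_dataset):
    ds, _ = study_dataset
    sub = ds.subset_variables(ds.variables[:12])
    res = NonlinearPCA(sub).fit(seed=0)
    n = sub.n_subjects
    x = res.object_scores[:, 0]
    assert x.mean() == pytest.approx(0, abs=1e-9)
    assert x @ x == pytest.approx(n, rel=1e-9)
    for v in sub.variables:
        q = res.quantifications[v][sub.data[v].to_numpy() - 1]
        assert q.mean() == pytest.approx(0, abs=1e-8)
        assert q @ q == pytest.approx(n, rel=1e-6)
        assert res.vaf_per_variable[v] == pytest.approx(
            float(res.loadings[v][0] ** 2), abs=1e-12)
        assert 0 <= res.vaf_per_variable[v] <= 1 + 1e-12


def test_identical_variables_get_equal_loadings():
    rng = np.random.default_rng(4)
    col = rng.integers(1, 5, 30)
    df = pd.DataFrame({"a": col, "b": col, "c": rng.integers(1, 5, 30)})
    res = NonlinearPCA(CategoricalDataset(df)).fit(seed=0)
    assert res.loadings["a"][0] == pytest.approx(res.loadings["b"][0], abs=1e-6)
    assert res.vaf_per_variable["a"] == pytest.approx(res.vaf_per_variable["b"], abs=1e-6)


def test_ordinal_equals_nominal_when_means_already_monotone():
    # two strongly correlated ordinal variables: category means of the target
    # are monotone, so the PAVA projection is a no-op
    rng = np.random.default_rng(7)
    base = rng.integers(1, 6, 60)
    noise = np.clip(base + rng.integers(-1, 2, 60), 1, 5)
    df = pd.DataFrame({"a": base, "b": noise})
    res_o = NonlinearPCA(CategoricalDataset(
        df, {c: ScalingSpec(analysis_level="ordinal") for c in df})).fit(tol=1e-12, seed=0)
    res_n = NonlinearPCA(CategoricalDataset(
        df, {c: ScalingSpec(analysis_level="nominal") for c in df})).fit(tol=1e-12, seed=0)
    for v in df.columns:
        qo, qn = res_o.quantifications[v], res_n.quantifications[v]
        # same up to component sign
        sign = np.sign(qo @ qn) or 1.0
        np.testing.assert_allclose(qo, sign * qn, atol=1e-5)


def test_feasible_set_nesting_vaf_ordering(study_dataset):
    """Less restricted levels cannot explain less variance: numeric <=
    spline-ordinal <= spline-nominal <= ordinal/nominal, and 1 knot <= 2."""
    ds, _ = study_dataset
    clin = [v for v in ds.variables if v.startswith("b")][:10]
    sub = ds.subset_variables(clin + ["class"])

    def vaf(level, knots=1):
        specs = {v: ScalingSpec(analysis_level=level, degree=2, interior_knots=knots)
                 for v in clin}
        if level == "numeric":
            specs = {v: ScalingSpec(analysis_level="numeric") for v in clin}
        res = forced_classification_fit(sub.with_specs(specs), "class", seed=0)
        return res.substantive_vaf

    v_num = vaf("numeric")
    v_so = vaf("spline-ordinal", 2)
    v_sn = vaf("spline-nominal", 2)
    v_sn1 = vaf("spline-nominal", 1)
    tol = 1e-6
    assert v_num <= v_so + tol
    assert v_so <= v_sn + tol
    assert v_sn1 <= v_sn + tol


# ----------------------------------------------------------------------
# forced classification + prediction
# ----------------------------------------------------------------------
def test_forced_classification_separates_classes(study_dataset):
    ds, _ = study_dataset
    res = forced_classification_fit(ds, "class", seed=0)
    assert res.separated
    x = res.object_scores[:, 0]
    codes = ds.data["class"].to_numpy()
    assert x[codes == 1].max() < x[codes == 2].min()
    # sign convention: Heat (code 2) positive
    assert x[codes == 2].mean() > 0


def test_forced_classification_on_pure_noise_still_separates():
    rng = np.random.default_rng(11)
    df = pd.DataFrame({f"v{j}": rng.integers(1, 5, 24) for j in range(6)})
    df["class"] = np.repeat([1, 2], 12)
    res = forced_classification_fit(CategoricalDataset(df), "class", seed=0)
    assert res.separated
    others = [v for v in df.columns if v != "class"]
    assert all(res.vaf_per_variable[v] < 0.35 for v in others)


def test_flipping_class_coding_flips_loading_signs(study_dataset):
    ds, _ = study_dataset
    res1 = forced_classification_fit(ds, "class", seed=0)
    flipped = ds.copy()
    flipped.data["class"] = 3 - flipped.data["class"]
    res2 = forced_classification_fit(flipped, "class", seed=0)
    for v in ds.variables:
        if v == "class":
            continue
        assert res1.loadings[v][0] == pytest.approx(-res2.loadings[v][0], abs=1e-4)


def test_training_subjects_repredicted_correctly(study_dataset):
    ds, _ = study_dataset
    res = forced_classification_fit(ds, "class", seed=0)
    assert res.separated
    new = ds.data[[v for v in ds.variables if v != "class"]]
    labels, scores = res.predict(new)
    true = ds.data["class"].to_numpy()
    assert np.mean(labels.astype(int) == true) == 1.0


def test_predict_refuses_mostly_missing_subjects(study_dataset):
    ds, _ = study_dataset
    res = forced_classification_fit(ds, "class", seed=0)
    few = ds.data[[v for v in ds.variables if v != "class"][:3]]
    with pytest.raises(ValueError, match="missing"):
        res.predict(few)


def test_single_category_variable_rejected():
    df = pd.DataFrame({"a": [1] * 10, "b": np.r_[np.ones(5), 2 * np.ones(5)].astype(int)})
    with pytest.raises(ValueError, match="single category"):
        NonlinearPCA(CategoricalDataset(df))
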