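"""Category merging, binning, presence filtering, scaling and QC screening."""

import numpy as np
import pandas as pd
import pytest

from coldheat import (CategoricalDataset, CohortConfig, ScalingSpec,
                      generate_feature_table, generate_questionnaire)
from coldheat.preprocess import (bin_clinical, drop_single_category_variables,
                                 filter_presence, merge_sparse_categories,
                                 qc_screen, replace_zeros, scale_features)
from conftest import column_with_counts


# ----------------------------------------------------------------------
# category merging and removal
# ----------------------------------------------------------------------
def _dataset(cols: dict) -> CategoricalDataset:
    return CategoricalDataset(pd.DataFrame(cols))


def test_ordinal_sparse_category_merges_with_neighbor():
    ds = _dataset({"a": column_with_counts([20, 3, 16]), "pad": column_with_counts([20, 19])})
    merged, log = merge_sparse_categories(ds, min_count=7)
    counts = merged.category_counts("a")
    assert counts.tolist() == [23, 16]
    assert "a" in log


def test_all_categories_dense_unchanged():
    ds = _dataset({"a": column_with_counts([10, 12, 8]), "pad": column_with_counts([15, 15])})
    merged, log = merge_sparse_categories(ds, min_count=7)
    assert merged.category_counts("a").tolist() == [10, 12, 8]
    assert "a" not in log


def test_all_sparse_collapses_to_single_category():
    ds = _dataset({"a": column_with_counts([2, 3, 1]), "pad": column_with_counts([3, 3])})
    merged, _ = merge_sparse_categories(ds, min_count=7)
    assert merged.n_categories("a") == 1
    reduced, removed = drop_single_category_variables(merged)
    assert "a" in removed


def test_nominal_sparse_categories_pool_into_other():
    col = column_with_counts([10, 3, 2, 9])
    ds = CategoricalDataset(
        pd.DataFrame({"a": col, "pad": column_with_counts([12, 12])}),
        {"a": ScalingSpec(analysis_level="nominal", measurement_level="nominal")})
    merged, _ = merge_sparse_categories(ds, min_count=7)
    counts = merged.category_counts("a")
    assert (counts >= 7).all() or merged.n_categories("a") == 1
    assert counts.sum() == 24


def test_merge_then_drop_is_idempotent():
    q, _ = generate_questionnaire(CohortConfig(seed=9))
    once, _ = merge_sparse_categories(q)
    once, _ = drop_single_category_variables(once)
    twice, log2 = merge_sparse_categories(once)
    twice, removed2 = drop_single_category_variables(twice)
    assert not log2 and not removed2
    pd.testing.assert_frame_equal(once.data, twice.data)


def test_study_shaped_57_items_reduce_to_42():
    """15 constant items of 57 are removed after merging, leaving 42."""
    q, _ = generate_questionnaire(CohortConfig(seed=0))
    merged, _ = merge_sparse_categories(q)
    reduced, removed = drop_single_category_variables(merged)
    assert len(removed) == 15
    assert len(reduced.variables) == 42


def test_all_constant_dataset_degenerates():
    ds = _dataset({"a": np.ones(10, int), "b": np.ones(10, int)})
    reduced, removed = drop_single_category_variables(ds)
    assert removed == ["a", "b"]
    assert reduced.data.shape[1] == 0


# ----------------------------------------------------------------------
# clinical binning
# ----------------------------------------------------------------------
def test_bin_clinical_closed_form_edges():
    codes = bin_clinical(np.arange(19, dtype=float), n_bins=19)
    assert codes.tolist() == list(range(1, 20))


def test_bin_clinical_constant_and_edges():
    assert bin_clinical(np.full(5, 3.3)).tolist() == [1] * 5
    # value exactly on an interior edge goes right (half-open convention)
    codes = bin_clinical(np.array([0.0, 1.0, 19.0]), n_bins=19)
    assert codes.tolist() == [1, 2, 19]


def test_bin_clinical_preserves_rank_order():
    rng = np.random.default_rng(0)
    x = rng.normal(size=100)
    codes = bin_clinical(x, 19)
    order = np.argsort(x)
    assert np.all(np.diff(codes[order]) >= 0)


def test_bin_clinical_rejects_nan():
    with pytest.raises(ValueError, match="NaN"):
        bin_clinical(np.array([1.0, np.nan, 2.0]))


# ----------------------------------------------------------------------
# metabolomics preprocessing
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def urine(small_config):
    table, _ = generate_feature_table(small_config, "urine")
    return table


def _toy_table(values, labels, qc_rows=0):
    from coldheat.datasets import FeatureTable
    n = len(values)
    idx = [f"s{i}" for i in range(n)] + [f"q{i}" for i in range(qc_rows)]
    vals = np.vstack([values] + [np.mean(values, axis=0)] * qc_rows)
    cols = [f"f{j}" for j in range(vals.shape[1])]
    sm = pd.DataFrame({"class_label": list(labels) + [None] * qc_rows,
                       "is_qc": [False] * n + [True] * qc_rows,
                       "injection_order": range(n + qc_rows)}, index=idx)
    fm = pd.DataFrame({"mz": np.arange(vals.shape[1]) + 100.0,
                       "rt": np.arange(vals.shape[1]) + 1.0,
                       "ion_mode": "pos", "fragments": ""}, index=cols)
    return FeatureTable(pd.DataFrame(vals, index=idx, columns=cols), sm, fm)


def test_presence_filter_rule_by_hand():
    # f0: 100% Cold / 10% Heat -> retained; f1: 70% both -> removed
    cold = np.ones((10, 2))
    heat = np.ones((10, 2))
    heat[1:, 0] = 0  # 10% nonzero in Heat
    cold[3:, 1] = 0  # 30% nonzero in Cold
    heat[3:, 1] = 0
    table = _toy_table(np.vstack([cold, heat]), ["Cold"] * 10 + ["Heat"] * 10)
    filtered, removed = filter_presence(table, 0.8)
    assert list(filtered.intensities.columns) == ["f0"]
    assert removed == 1


def test_presence_filter_all_nonzero_identity():
    table = _toy_table(np.ones((8, 3)), ["Cold"] * 4 + ["Heat"] * 4)
    filtered, removed = filter_presence(table, 0.8)
    assert removed == 0
    assert filtered.intensities.shape == table.intensities.shape


def test_replace_zeros_per_feature_minimum():
    table = _toy_table(np.array([[0.0, 5], [4, 5], [6, 5], [0, 5]]),
                       ["Cold", "Cold", "Heat", "Heat"])
    out = replace_zeros(table)
    assert out.intensities["f0"].tolist() == [2.0, 4.0, 6.0, 2.0]
    assert out.intensities["f1"].tolist() == [5.0] * 4  # no zeros: identity


def test_filter_then_replace_leaves_no_zeros(small_config):
    table, _ = generate_feature_table(small_config, "urine")
    filtered, _ = filter_presence(table, 0.8)
    out = replace_zeros(filtered)
    assert (out.intensities.to_numpy() > 0).all()


def test_autoscale_and_center_contracts(urine):
    filtered, _ = filter_presence(urine, 0.8)
    filled = replace_zeros(filtered)
    auto = scale_features(filled, "autoscale")
    study = auto.study_matrix()
    np.testing.assert_allclose(study.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(study.std(axis=0, ddof=1), 1, atol=1e-12)
    cent1 = scale_features(filled, "center")
    # centering twice equals once (study means already zero)
    cent2 = scale_features(cent1, "center")
    np.testing.assert_allclose(cent1.intensities.to_numpy(),
                               cent2.intensities.to_numpy(), atol=1e-9)


def test_qc_transformed_with_study_parameters(urine):
    filled = replace_zeros(filter_presence(urine, 0.8)[0])
    auto = scale_features(filled, "autoscale")
    study = filled.study_matrix()
    mean, sd = study.mean(axis=0), study.std(axis=0, ddof=1)
    qc_raw = filled.intensities.loc[filled.is_qc]
    expected = (qc_raw - mean) / sd
    np.testing.assert_allclose(auto.intensities.loc[auto.is_qc].to_numpy(),
                               expected.to_numpy(), atol=1e-9)


# ----------------------------------------------------------------------
# QC screen
# ----------------------------------------------------------------------
def test_qc_screen_detects_injection_order_drift():
    cfg = CohortConfig(seed=2, n_cold=14, n_heat=14, n_features_urine=150,
                       missing_rate=0.0, drift_slope=0.05, n_qc=10)
    table, _ = generate_feature_table(cfg, "urine")
    scaled = scale_features(replace_zeros(filter_presence(table)[0]), "autoscale")
    report = qc_screen(scaled)
    assert report.stability_assessable
    assert abs(report.trend_rho) > 0 and report.trend_p < 0.05


def test_qc_screen_no_drift_no_trend():
    cfg = CohortConfig(seed=2, n_cold=14, n_heat=14, n_features_urine=150,
                       missing_rate=0.0, drift_slope=0.0, n_qc=10)
    table, _ = generate_feature_table(cfg, "urine")
    scaled = scale_features(replace_zeros(filter_presence(table)[0]), "autoscale")
    report = qc_screen(scaled)
    assert report.trend_p > 0.05
    # QC replicates are near-copies of the mean profile: tight dispersion
    assert report.dispersion_ratio < 0.5


def test_qc_screen_flags_shifted_sample():
    rng = np.random.default_rng(1)
    vals = rng.lognormal(3, 0.2, size=(20, 50))
    vals[4, :] *= 25  # one sample shifted far up on every feature
    table = _toy_table(vals, ["Cold"] * 10 + ["Heat"] * 10, qc_rows=3)
    scaled = scale_features(replace_zeros(filter_presence(table)[0]), "center")
    report = qc_screen(scaled)
    assert "s4" in report.outliers


def test_qc_score_plot_written(tmp_path):
    table = _toy_table(np.random.default_rng(2).lognormal(3, 0.3, (14, 25)),
                       ["Cold"] * 7 + ["Heat"] * 7, qc_rows=3)
    from coldheat.preprocess import plot_qc_scores
    out = tmp_path / "qc_scores.png"
    plot_qc_scores(scale_features(table, "center"), out)
    assert out.exists() and out.stat().st_size > 0


def test_qc_screen_too_few_qc_not_assessable():
    table = _toy_table(np.random.default_rng(0).lognormal(3, 0.3, (12, 20)),
                       ["Cold"] * 6 + ["Heat"] * 6, qc_rows=1)
    report = qc_screen(scale_features(table, "center"))
    assert not report.stability_assessable
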