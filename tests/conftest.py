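import logging

import numpy as np
import pandas as pd
import pytest

from coldheat import (CategoricalDataset, CohortConfig, ScalingSpec,
                      generate_cohort)
from coldheat.preprocess import (bin_clinical, drop_single_category_variables,
                                 merge_sparse_categories)

logging.getLogger("coldheat").setLevel(logging.ERROR)


def cohort_dataset(seed: int = 3, with_clinical: bool = True):
    """Study-shaped categorical dataset: questionnaire + binned clinical +
    class variable, merged and pruned."""
    cfg = CohortConfig(seed=seed)
    q, clin, _, _, truth = generate_cohort(cfg)
    data = q.data.copy()
    specs = dict(q.specs)
    if with_clinical:
        for col in clin.columns:
            data[col] = bin_clinical(clin[col], 19)
            specs[col] = ScalingSpec(analysis_level="spline-nominal", degree=2,
                                     interior_knots=2,
                                     measurement_level="numeric-binned")
    data["class"] = truth.class_labels.map({"Cold": 1, "Heat": 2})
    ds = CategoricalDataset(data, specs)
    ds, _ = merge_sparse_categories(ds)
    ds, _ = drop_single_category_variables(ds)
    return ds, truth


@pytest.fixture(scope="session")
def study_dataset():
    return cohort_dataset(seed=3)


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast feature-table work."""
    return CohortConfig(seed=5, n_cold=14, n_heat=14, n_features_urine=200,
                        n_features_plasma=120, missing_rate=0.1)


def column_with_counts(counts, start_code=1):
    """Integer column realizing the given per-category counts."""
    codes = np.concatenate([
        np.full(c, start_code + i) for i, c in enumerate(counts)
    ])
    return pd.Series(codes)
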