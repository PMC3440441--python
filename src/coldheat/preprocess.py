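"""Data-reduction rules applied before modelling.

Questionnaire / clinical side: categories observed fewer than 7 times are
merged (ordinal variables with the nearer adjacent category, nominal
variables into a pooled "other" category), variables left with a single
category are removed, and continuous clinical chemistry values are uniformly
binned into 19 categories.

Metabolomics side: features must be present (nonzero) in at least 80% of the
samples of at least one class; remaining zeros are non-detects and are
replaced by half the smallest measured value of that feature; urine tables
are mean-centered and plasma tables autoscaled; a PCA-based QC screen reports
outliers, QC dispersion relative to study samples, and injection-order trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .datasets import CategoricalDataset, FeatureTable

__all__ = [
    "merge_sparse_categories",
    "drop_single_category_variables",
    "bin_clinical",
    "filter_presence",
    "replace_zeros",
    "scale_features",
    "qc_screen",
    "plot_qc_scores",
    "QCReport",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# categorical side
# ----------------------------------------------------------------------
def _merge_ordinal(col: pd.Series, min_count: int) -> tuple[pd.Series, list[str]]:
    """Merge sparse categories of an ordinal variable with the nearer adjacent
    observed category (code distance; ties toward the lower code)."""
    col = col.copy()
    log: list[str] = []
    while True:
        counts = col.value_counts().sort_index()
        if len(counts) <= 1:
            break
        sparse = counts[counts < min_count]
        if sparse.empty:
            break
        # sparsest category first, ties toward the lower code
        cat = sparse.sort_values(kind="stable").index[0]
        cats = counts.index.to_numpy()
        pos = int(np.where(cats == cat)[0][0])
        neighbors = []
        if pos > 0:
            neighbors.append(cats[pos - 1])
        if pos < len(cats) - 1:
            neighbors.append(cats[pos + 1])
        # nearer neighbor in code distance; ties toward lower code
        target = min(neighbors, key=lambda c: (abs(c - cat), c))
        col = col.replace(cat, target)
        log.append(f"{cat}->{target}")
    return col, log


def _merge_nominal(col: pd.Series, min_count: int) -> tuple[pd.Series, list[str]]:
    """Pool all sparse categories of a nominal variable into one 'other' code."""
    col = col.copy()
    log: list[str] = []
    counts = col.value_counts()
    sparse = sorted(counts[counts < min_count].index)
    if len(sparse) >= 2:
        target = sparse[0]
        for cat in sparse[1:]:
            col = col.replace(cat, target)
            log.append(f"{cat}->{target}")
    # pooled 'other' may itself still be sparse: fold it into the smallest
    # remaining regular category
    counts = col.value_counts()
    if len(counts) > 1:
        small = counts.sort_values(kind="stable")
        if small.iloc[0] < min_count:
            cat = small.index[0]
            rest = counts.drop(cat).sort_values(kind="stable")
            target = rest.index[0]
            col = col.replace(cat, target)
            log.append(f"{cat}->{target}")
    return col, log


def merge_sparse_categories(
    dataset: CategoricalDataset, min_count: int = 7
) -> tuple[CategoricalDataset, dict[str, list[str]]]:
    """Merge scoring categories containing fewer than ``min_count`` observations.

    Ordinal (and numeric-binned) variables merge each sparse category with its
    nearer adjacent observed category, preserving order; nominal variables
    pool sparse categories into a single "other" category.  Codes are
    re-indexed to consecutive ``1..k`` afterwards.

    Returns the merged dataset and a per-variable merge log.
    """
    out = {}
    merge_log: dict[str, list[str]] = {}
    for name in dataset.variables:
        spec = dataset.specs[name]
        col = dataset.data[name]
        if spec.measurement_level == "nominal":
            merged, log = _merge_nominal(col, min_count)
        else:
            merged, log = _merge_ordinal(col, min_count)
        out[name] = merged
        if log:
            merge_log[name] = log
    merged_ds = CategoricalDataset(
        pd.DataFrame(out, index=dataset.data.index), dict(dataset.specs)
    ).recode()
    return merged_ds, merge_log


def drop_single_category_variables(
    dataset: CategoricalDataset,
) -> tuple[CategoricalDataset, list[str]]:
    """Remove variables with a single observed category (no variation).

    Returns the reduced dataset and the removal list.  If every variable is
    constant the returned dataset is empty-width and downstream fitting will
    refuse it.
    """
    removed = [v for v in dataset.variables if dataset.n_categories(v) < 2]
    kept = [v for v in dataset.variables if v not in removed]
    if removed:
        logger.info("removing %d single-category variables: %s", len(removed), removed)
    if not kept:
        # degenerate: signal with an empty frame the caller must check
        empty = CategoricalDataset.__new__(CategoricalDataset)
        empty.data = dataset.data[[]].copy()
        empty.specs = {}
        return empty, removed
    return dataset.subset_variables(kept), removed


def bin_clinical(values, n_bins: int = 19) -> np.ndarray:
    """Uniformly bin a continuous clinical variable into ``1..n_bins`` codes.

    Equal-width bins span [min, max]; interior edges follow the half-open
    convention (a value exactly on an edge goes to the right bin) and the
    rightmost bin is closed.  A constant vector maps to all code 1.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        bad = list(np.where(np.isnan(x))[0])
        raise ValueError(f"NaN clinical values for subjects at positions {bad}")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return np.ones(len(x), dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    codes = np.digitize(x, edges[1:-1], right=False) + 1
    return codes.astype(int)


# ----------------------------------------------------------------------
# metabolomics side
# ----------------------------------------------------------------------
def filter_presence(
    table: FeatureTable, min_fraction: float = 0.8, mode: str = "any-class"
) -> tuple[FeatureTable, int]:
    """Drop features not present in at least ``min_fraction`` of one class.

    Presence means a nonzero intensity; QC samples are excluded from the
    count.  ``mode='any-class'`` retains a feature when either class reaches
    the fraction (the default reading); ``mode='all-classes'`` requires every
    class to reach it.
    """
    labels = table.class_labels()
    classes = labels.dropna().unique()
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    X = table.study_matrix()
    fracs = pd.DataFrame(
        {c: (X.loc[labels[labels == c].index] > 0).mean(axis=0) for c in classes}
    )
    if mode == "any-class":
        keep = (fracs >= min_fraction).any(axis=1)
    elif mode == "all-classes":
        keep = (fracs >= min_fraction).all(axis=1)
    else:
        raise ValueError("mode must be 'any-class' or 'all-classes'")
    removed = int((~keep).sum())
    return table.subset_features(keep.index[keep]), removed


def replace_zeros(table: FeatureTable) -> FeatureTable:
    """Replace zeros by half the smallest measured (nonzero) value.

    The convention is per feature; an all-zero feature should have been
    removed by the presence filter and raises here.
    """
    X = table.intensities.copy()
    arr = X.to_numpy(dtype=float)
    for j, col in enumerate(X.columns):
        v = arr[:, j]
        nz = v[v > 0]
        if nz.size == 0:
            raise ValueError(f"feature {col!r} is all-zero; run filter_presence first")
        arr[v == 0, j] = nz.min() / 2.0
    out = table.copy()
    out.intensities = pd.DataFrame(arr, index=X.index, columns=X.columns)
    return out


def scale_features(table: FeatureTable, mode: str) -> FeatureTable:
    """Mean-center (urine) or autoscale (plasma) the feature columns.

    Scaling parameters are computed on the study (non-QC) samples and applied
    to all samples, QC included.  Zero-variance features under autoscaling are
    removed with a warning.
    """
    if mode not in ("center", "autoscale"):
        raise ValueError("mode must be 'center' or 'autoscale'")
    study = table.study_matrix()
    mean = study.mean(axis=0)
    X = table.intensities - mean
    if mode == "autoscale":
        sd = study.std(axis=0, ddof=1)
        dead = sd.index[sd <= 0]
        if len(dead):
            logger.warning("removing %d zero-variance features under autoscale", len(dead))
            keep = sd.index[sd > 0]
            table = table.subset_features(keep)
            X = X[keep]
            sd = sd[keep]
        X = X / sd
    out = table.copy()
    out.intensities = X
    out.scaling = "centered" if mode == "center" else "autoscaled"
    return out


@dataclass
class QCReport:
    """PCA-based screen of a scaled feature table."""

    outliers: list = field(default_factory=list)
    dispersion_ratio: float | None = None  # QC / study score spread on PC1-2
    trend_rho: float = np.nan  # Spearman(PC1, injection order), study samples
    trend_p: float = np.nan
    stability_assessable: bool = True

    def to_dict(self) -> dict:
        return {
            "outliers": list(self.outliers),
            "dispersion_ratio": self.dispersion_ratio,
            "trend_rho": None if np.isnan(self.trend_rho) else float(self.trend_rho),
            "trend_p": None if np.isnan(self.trend_p) else float(self.trend_p),
            "stability_assessable": self.stability_assessable,
        }


def qc_screen(table: FeatureTable, mad_threshold: float = 4.0, min_qc: int = 3) -> QCReport:
    """Screen a scaled table for outliers, QC stability, and time trends.

    PCA on all samples; a sample is an outlier when its score on PC1 or PC2
    deviates from the median by more than ``mad_threshold`` MADs.  Stability
    is the ratio of QC to study score dispersion on PC1-2 (near 0 for tight
    QC replicates); the trend statistic is the Spearman correlation of PC1
    scores with injection order.
    """
    X = table.intensities.to_numpy(dtype=float)
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    scores = PCA(n_components=n_comp, random_state=0).fit_transform(X - X.mean(axis=0))

    report = QCReport()
    outliers = set()
    for k in range(scores.shape[1]):
        s = scores[:, k]
        med = np.median(s)
        mad = np.median(np.abs(s - med))
        if mad <= 0:
            continue
        # 1.4826: MAD -> sd under normality
        flag = np.abs(s - med) / (1.4826 * mad) > mad_threshold
        outliers.update(table.intensities.index[flag])
    report.outliers = sorted(outliers)

    qc_mask = table.is_qc.to_numpy()
    if qc_mask.sum() >= min_qc:
        qc_s, st_s = scores[qc_mask, :], scores[~qc_mask, :]
        qc_disp = np.sqrt(np.mean(np.sum((qc_s - qc_s.mean(axis=0)) ** 2, axis=1)))
        st_disp = np.sqrt(np.mean(np.sum((st_s - st_s.mean(axis=0)) ** 2, axis=1)))
        report.dispersion_ratio = float(qc_disp / st_disp) if st_disp > 0 else np.inf
    else:
        report.stability_assessable = False
        logger.warning("fewer than %d QC samples; stability not assessable", min_qc)

    order = table.sample_meta["injection_order"].to_numpy()
    if len(order) >= 3:
        rho, p = spearmanr(scores[:, 0], order)
        report.trend_rho, report.trend_p = float(rho), float(p)
    return report


def plot_qc_scores(table: FeatureTable, path=None):
    """PC1/PC2 score plot with QC samples highlighted (study samples colored
    by class).  Saves to ``path`` when given, else returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = table.intensities.to_numpy(dtype=float)
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    scores = PCA(n_components=n_comp, random_state=0).fit_transform(X - X.mean(axis=0))
    if scores.shape[1] < 2:
        scores = np.column_stack([scores, np.zeros(len(scores))])

    fig, ax = plt.subplots(figsize=(5, 4))
    qc = table.is_qc.to_numpy()
    labels = table.sample_meta["class_label"]
    for cls, color in zip(sorted(labels.dropna().unique(), key=str), ("C0", "C3")):
        m = (~qc) & (labels == cls).to_numpy()
        ax.scatter(scores[m, 0], scores[m, 1], s=18, c=color, label=str(cls))
    ax.scatter(scores[qc, 0], scores[qc, 1], s=30, c="k", marker="^", label="QC")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
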