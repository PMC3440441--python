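"""In-memory containers for the two data families the pipelines consume.

Two containers cover everything:

* :class:`CategoricalDataset` — subjects x categorical variables (questionnaire
  items on a 1–7 severity scale, clinical chemistry values discretized into
  uniform bins), each variable carrying a :class:`ScalingSpec` that fixes its
  optimal-scaling analysis level and weight.
* :class:`FeatureTable` — samples x LC-MS features (urine or plasma), with
  feature metadata (m/z, retention time, ion mode, fragment masses) and sample
  metadata (class label, QC flag, injection order).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["ScalingSpec", "CategoricalDataset", "FeatureTable"]

#: analysis levels understood by the optimal-scaling engine
ANALYSIS_LEVELS = ("nominal", "ordinal", "spline-nominal", "spline-ordinal", "numeric")

MEASUREMENT_LEVELS = ("ordinal", "nominal", "numeric-binned")


@dataclass(frozen=True)
class ScalingSpec:
    """Optimal-scaling treatment of one variable.

    Parameters
    ----------
    analysis_level
        Constraint set on the category quantifications: ``nominal`` (free),
        ``ordinal`` (monotone), ``spline-nominal`` / ``spline-ordinal``
        (smooth piecewise polynomial, optionally monotone) or ``numeric``
        (linear in the category codes).
    degree
        Spline degree; only used by the spline levels.  Default 2 (quadratic).
    interior_knots
        Number of interior knots for the spline levels (typically 1 or 2).
    weight
        Variable weight in the loss.  The binary classification variable is
        given a very large weight (1000) under forced classification so the
        first component aligns with class separation.
    measurement_level
        Documentation of how the variable was measured; not used by the
        fitting engine.
    """

    analysis_level: str = "ordinal"
    degree: int = 2
    interior_knots: int = 2
    weight: float = 1.0
    measurement_level: str = "ordinal"

    def __post_init__(self) -> None:
        if self.analysis_level not in ANALYSIS_LEVELS:
            raise ValueError(f"unknown analysis level {self.analysis_level!r}")
        if self.degree < 1:
            raise ValueError("spline degree must be >= 1")
        if self.interior_knots < 0:
            raise ValueError("interior knot count must be >= 0")
        if self.weight <= 0:
            raise ValueError("variable weight must be positive")
        if self.analysis_level.startswith("spline") and self.degree + self.interior_knots < 1:
            raise ValueError("spline levels require degree + knots >= 1")

    def with_(self, **kwargs) -> "ScalingSpec":
        return replace(self, **kwargs)


class CategoricalDataset:
    """Subjects x categorical variables, integer category codes ``1..k_j``.

    Codes need not be consecutive on input; :meth:`recode` maps the observed
    categories of every variable onto consecutive positive integers, which is
    the form the optimal-scaling engine requires.
    """

    def __init__(self, data: pd.DataFrame, specs: dict[str, ScalingSpec] | None = None):
        if data.shape[1] == 0:
            raise ValueError("dataset needs at least one variable")
        arr = data.to_numpy()
        if not np.isfinite(arr.astype(float)).all():
            raise ValueError("category codes must be finite integers")
        self.data = data.astype(int)
        specs = dict(specs or {})
        self.specs: dict[str, ScalingSpec] = {
            name: specs.get(name, ScalingSpec()) for name in data.columns
        }

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def n_categories(self, name: str) -> int:
        return int(self.data[name].nunique())

    def category_counts(self, name: str) -> pd.Series:
        return self.data[name].value_counts().sort_index()

    # ------------------------------------------------------------------
    def recode(self) -> "CategoricalDataset":
        """Map observed categories of every variable to consecutive 1..k codes."""
        out = {}
        for name in self.data.columns:
            col = self.data[name]
            cats = np.sort(col.unique())
            mapping = {c: i + 1 for i, c in enumerate(cats)}
            out[name] = col.map(mapping)
        return CategoricalDataset(pd.DataFrame(out, index=self.data.index), self.specs)

    def is_recoded(self) -> bool:
        for name in self.data.columns:
            cats = np.sort(self.data[name].unique())
            if cats[0] != 1 or not np.array_equal(cats, np.arange(1, len(cats) + 1)):
                return False
        return True

    def subset_variables(self, names) -> "CategoricalDataset":
        names = list(names)
        return CategoricalDataset(self.data[names].copy(), {n: self.specs[n] for n in names})

    def subset_subjects(self, index) -> "CategoricalDataset":
        return CategoricalDataset(self.data.loc[index].copy(), dict(self.specs))

    def with_specs(self, specs: dict[str, ScalingSpec]) -> "CategoricalDataset":
        merged = dict(self.specs)
        merged.update(specs)
        return CategoricalDataset(self.data.copy(), merged)

    def copy(self) -> "CategoricalDataset":
        return CategoricalDataset(self.data.copy(), dict(self.specs))

    def __repr__(self) -> str:  # pragma: no cover
        return f"CategoricalDataset({self.n_subjects} subjects x {len(self.variables)} variables)"


@dataclass
class FeatureTable:
    """Samples x LC-MS features with metadata.

    Attributes
    ----------
    intensities
        DataFrame samples x features; non-negative before scaling.
    sample_meta
        DataFrame indexed like ``intensities`` with columns ``class_label``
        (NaN/None for QC samples), ``is_qc`` (bool) and ``injection_order``
        (unique ints).
    feature_meta
        DataFrame indexed by feature id with columns ``mz``, ``rt``,
        ``ion_mode`` and ``fragments`` (semicolon-joined fragment m/z values,
        empty string when none were recorded).
    scaling
        One of ``raw``, ``centered``, ``autoscaled``.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    scaling: str = "raw"

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.sample_meta.index):
            raise ValueError("sample metadata index must match intensity rows")
        if not self.intensities.columns.equals(self.feature_meta.index):
            raise ValueError("feature metadata index must match intensity columns")
        if self.sample_meta["injection_order"].duplicated().any():
            raise ValueError("injection_order must be unique")
        qc = self.sample_meta["is_qc"].astype(bool)
        if self.sample_meta.loc[qc, "class_label"].notna().any():
            raise ValueError("QC samples must not carry a class label")
        if self.scaling == "raw" and (self.intensities.to_numpy() < 0).any():
            raise ValueError("raw intensities must be non-negative")

    # ------------------------------------------------------------------
    @property
    def is_qc(self) -> pd.Series:
        return self.sample_meta["is_qc"].astype(bool)

    @property
    def study_samples(self) -> pd.Index:
        return self.intensities.index[~self.is_qc]

    def class_labels(self) -> pd.Series:
        """Class labels of the study (non-QC) samples."""
        return self.sample_meta.loc[self.study_samples, "class_label"]

    def study_matrix(self) -> pd.DataFrame:
        return self.intensities.loc[self.study_samples]

    def subset_features(self, names) -> "FeatureTable":
        names = list(names)
        return FeatureTable(
            self.intensities[names].copy(),
            self.sample_meta.copy(),
            self.feature_meta.loc[names].copy(),
            self.scaling,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.sample_meta.copy(), self.feature_meta.copy(), self.scaling
        )

    def __repr__(self) -> str:  # pragma: no cover
        n_qc = int(self.is_qc.sum())
        return (
            f"FeatureTable({self.intensities.shape[0]} samples "
            f"[{n_qc} QC] x {self.intensities.shape[1]} features, {self.scaling})"
        )
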