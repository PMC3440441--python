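"""File I/O and run configuration.

Interchange format is CSV throughout (one header row, UTF-8, ``.`` decimal):
subjects x variables for the categorical tables, samples x features plus two
side tables (sample metadata, feature metadata) for LC-MS data, a one-column
label file, and JSON for ground truth, reports and QC summaries.  Run
configuration is a dataclass serializable to YAML whose defaults are the
published analysis constants (merge threshold 7, 19 clinical bins, VAF
threshold 0.20, 80% presence, 250 permutations, class weight 1000).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel

from .datasets import CategoricalDataset, FeatureTable, ScalingSpec
from .synthetic import SyntheticTruth

__all__ = [
    "RunConfig",
    "write_cohort",
    "load_cohort",
    "read_labels",
    "ReportSchema",
    "validate_report",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and paths driving a pipeline run; defaults are the
    published constants."""

    min_category_count: int = 7
    n_bins: int = 19
    vaf_threshold: float = 0.20
    presence_fraction: float = 0.8
    n_permutations: int = 250
    class_weight: float = 1000.0
    seed: int = 0
    scaling_overrides: dict = field(default_factory=dict)  # variable -> analysis level

    def __post_init__(self) -> None:
        if self.min_category_count < 1:
            raise ValueError("min_category_count must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 0 <= self.vaf_threshold < 1:
            raise ValueError("vaf_threshold must be in [0, 1)")
        if not 0 < self.presence_fraction <= 1:
            raise ValueError("presence_fraction must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.class_weight <= 0:
            raise ValueError("class_weight must be positive")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ----------------------------------------------------------------------
def write_cohort(outdir, questionnaire=None, clinical=None, urine=None,
                 plasma=None, labels=None, truth: SyntheticTruth | None = None) -> None:
    """Write cohort tables as CSV (+ JSON truth) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if questionnaire is not None:
        questionnaire.data.to_csv(outdir / "questionnaire.csv", index_label="subject")
    if clinical is not None:
        clinical.to_csv(outdir / "clinical.csv", index_label="subject")
    for name, table in (("urine", urine), ("plasma", plasma)):
        if table is None:
            continue
        table.intensities.to_csv(outdir / f"{name}_intensities.csv", index_label="sample")
        table.sample_meta.to_csv(outdir / f"{name}_samples.csv", index_label="sample")
        table.feature_meta.to_csv(outdir / f"{name}_features.csv", index_label="feature")
    if labels is not None:
        labels.rename("class_label").to_csv(outdir / "labels.csv", index_label="subject")
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))


def read_labels(path) -> pd.Series:
    """Read the subject -> class label file; exactly two classes required."""
    df = pd.read_csv(path, index_col=0)
    labels = df.iloc[:, 0].astype(str)
    if labels.index.duplicated().any():
        dups = labels.index[labels.index.duplicated()].tolist()
        raise ValueError(f"duplicate subject ids in label file: {dups}")
    classes = labels.unique()
    if len(classes) != 2:
        raise ValueError(f"label file must contain exactly 2 classes, found {len(classes)}")
    return labels


def _read_feature_table(stem: Path, name: str) -> FeatureTable | None:
    ipath = stem / f"{name}_intensities.csv"
    if not ipath.exists():
        return None
    intensities = pd.read_csv(ipath, index_col=0)
    sample_meta = pd.read_csv(stem / f"{name}_samples.csv", index_col=0)
    sample_meta["is_qc"] = sample_meta["is_qc"].astype(bool)
    sample_meta["class_label"] = sample_meta["class_label"].where(
        sample_meta["class_label"].notna(), None)
    feature_meta = pd.read_csv(stem / f"{name}_features.csv", index_col=0)
    feature_meta["fragments"] = feature_meta["fragments"].fillna("")
    return FeatureTable(intensities, sample_meta, feature_meta)


def load_cohort(indir, config: RunConfig | None = None):
    """Load cohort tables written by :func:`write_cohort`.

    Missing files skip their stage with a warning; subject ids are aligned
    against the label file, and a subject present in a data table but absent
    from the labels is an error.

    Returns ``(questionnaire, clinical, urine, plasma, labels)`` with
    ``None`` for missing stages.
    """
    indir = Path(indir)
    labels = read_labels(indir / "labels.csv")

    questionnaire = clinical = None
    qpath = indir / "questionnaire.csv"
    if qpath.exists():
        qdata = pd.read_csv(qpath, index_col=0)
        _check_subjects(qdata.index, labels.index, "questionnaire")
        specs = {c: ScalingSpec(analysis_level="ordinal") for c in qdata.columns}
        if config:
            for v, lvl in config.scaling_overrides.items():
                if v in specs:
                    specs[v] = ScalingSpec(analysis_level=lvl)
        questionnaire = CategoricalDataset(qdata.loc[labels.index], specs)
    else:
        logger.warning("no questionnaire.csv; questionnaire stage skipped")

    cpath = indir / "clinical.csv"
    if cpath.exists():
        clinical = pd.read_csv(cpath, index_col=0)
        _check_subjects(clinical.index, labels.index, "clinical")
        clinical = clinical.loc[labels.index]
    else:
        logger.warning("no clinical.csv; clinical stage skipped")

    urine = _read_feature_table(indir, "urine")
    plasma = _read_feature_table(indir, "plasma")
    if urine is None:
        logger.warning("no urine feature table; urine stage skipped")
    if plasma is None:
        logger.warning("no plasma feature table; plasma stage skipped")
    return questionnaire, clinical, urine, plasma, labels


def _check_subjects(found, expected, stage):
    extra = pd.Index(found).difference(expected)
    if len(extra):
        raise ValueError(f"{stage} table has subjects absent from labels: {list(extra)}")
    missing = pd.Index(expected).difference(found)
    if len(missing):
        raise ValueError(f"{stage} table is missing labelled subjects: {list(missing)}")


# ----------------------------------------------------------------------
# report schema (pydantic models double as the machine-checkable schema)
# ----------------------------------------------------------------------
class LoadingRow(BaseModel):
    variable: str
    loading: float
    vaf: float


class NlpcaReport(BaseModel):
    total_vaf: float
    cv_error: float
    permutation_p: float | None = None
    separated: bool
    vaf_threshold: float
    selected: list[LoadingRow]


class FeatureRow(BaseModel):
    importance: int
    feature: str
    b: float
    log2_cold_heat: float | None = None


class PlsdaReport(BaseModel):
    compartment: str
    n_selected: int
    n_components: int
    cv_error: float
    pre_selection_error: float
    permutation_p: float | None = None
    top_features: list[FeatureRow]


class ReportSchema(BaseModel):
    """Top-level pipeline report."""

    seed: int
    config: dict
    nlpca: NlpcaReport | None = None
    plsda: list[PlsdaReport] = []


def validate_report(payload: dict) -> ReportSchema:
    """Validate a report dict against the shipped schema (raises on failure)."""
    return ReportSchema.model_validate(payload)
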