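"""The questionnaire/clinical analysis protocol around forced-classification
nonlinear PCA.

Protocol: (1) compare analysis levels for the clinical variables (numeric vs
spline-ordinal vs spline-nominal; 1 vs 2 interior knots) via the total VAF of
forced-classification fits; (2) select variables with per-variable VAF above
0.20; (3) estimate the classification error by leave-two-out cross-validation
(stratified pairs, one subject per class where possible); (4) assess the
final model against label-permuted null models.

Variable selection is performed once on the full data before cross-validation,
matching the published protocol (model built on the selected variables, then
validated); this is optimistically biased, and passing ``vaf_threshold`` to
:func:`leave_two_out_cv` re-runs the selection inside every training fold
instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catpca import NLPCAResults, forced_classification_fit
from .datasets import CategoricalDataset, ScalingSpec
from .pls import PermutationResult

__all__ = [
    "compare_analysis_levels",
    "select_variables",
    "leave_two_out_cv",
    "permutation_test_nlpca",
    "nlpca_protocol",
    "CvResult",
    "ProtocolResult",
]

logger = logging.getLogger(__name__)


@dataclass
class CvResult:
    """Leave-two-out cross-validation outcome."""

    error: float
    folds: list[np.ndarray]
    predictions: pd.Series
    true_labels: pd.Series

    def to_dict(self) -> dict:
        return {"error": self.error, "n_folds": len(self.folds)}


# ----------------------------------------------------------------------
def compare_analysis_levels(
    dataset: CategoricalDataset,
    class_variable: str,
    level_sets: dict[str, dict[str, ScalingSpec]],
    class_weight: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the forced-classification model under several scaling-spec sets.

    ``level_sets`` maps a set name (e.g. ``"spline-nominal-2knot"``) to
    per-variable spec overrides.  Returns a tidy frame with the total VAF per
    set, the per-variable VAF, and — for each pair of consecutive sets — the
    variable contributing most of the total-VAF gain (how a variable like
    MCHC is spotted as the driver of a 2-knot improvement).
    """
    records = []
    fits: dict[str, NLPCAResults] = {}
    for set_name, specs in level_sets.items():
        res = forced_classification_fit(
            dataset.with_specs(specs), class_variable,
            class_weight=class_weight, seed=seed)
        fits[set_name] = res
        for v in res.dataset.variables:
            if v == class_variable:
                continue
            records.append({"level_set": set_name, "variable": v,
                            "vaf": res.vaf_per_variable[v],
                            "total_vaf": res.total_vaf})
    df = pd.DataFrame(records)

    names = list(level_sets)
    gains = []
    for lo, hi in zip(names[:-1], names[1:]):
        a = df[df.level_set == lo].set_index("variable")["vaf"]
        b = df[df.level_set == hi].set_index("variable")["vaf"]
        delta = (b - a).dropna()
        top = delta.idxmax() if len(delta) else None
        gains.append({"from": lo, "to": hi,
                      "total_vaf_gain": float(fits[hi].total_vaf - fits[lo].total_vaf),
                      "top_variable": top,
                      "top_variable_gain": float(delta.max()) if len(delta) else np.nan})
    df.attrs["gains"] = gains
    df.attrs["total_vaf"] = {k: fits[k].total_vaf for k in names}
    return df


def select_variables(results: NLPCAResults, vaf_threshold: float = 0.20) -> list[str]:
    """Variables with per-variable VAF strictly above the threshold.

    The classification variable is always retained.  The list is ordered by
    decreasing |loading|; an empty selection (class variable only) raises.
    """
    cls = results.class_variable
    chosen = [v for v in results.dataset.variables
              if v != cls and results.vaf_per_variable[v] > vaf_threshold]
    if not chosen:
        raise ValueError(
            f"no variable exceeds VAF {vaf_threshold}; lower the threshold")
    chosen.sort(key=lambda v: -abs(results.loadings[v][0]))
    return ([cls] + chosen) if cls is not None else chosen


# ----------------------------------------------------------------------
def _stratified_pair_folds(labels: pd.Series, rng) -> list[np.ndarray]:
    classes = labels.unique()
    idx = {c: rng.permutation(np.flatnonzero(labels.to_numpy() == c)) for c in classes}
    a, b = idx[classes[0]], idx[classes[1]]
    folds = [np.array([i, j]) for i, j in zip(a, b)]
    rest = np.concatenate([a[len(b):], b[len(a):]])
    for i in range(0, len(rest) - 1, 2):
        folds.append(rest[i:i + 2])
    if len(rest) % 2:
        folds.append(rest[-1:])
    return folds


def leave_two_out_cv(
    dataset: CategoricalDataset,
    class_variable: str,
    class_weight: float = 1000.0,
    seed: int = 0,
    vaf_threshold: float | None = None,
) -> CvResult:
    """Leave-two-out cross-validation of the forced-classification model.

    Subjects are partitioned into disjoint stratified pairs (one per class
    where possible; leftovers pair up within the larger class, an odd last
    subject forms a singleton fold).  Per fold the model is refitted on the
    remaining subjects and the held-out pair's class is predicted from its
    estimated object score.  With ``vaf_threshold`` set, variable selection
    is re-run inside every training fold (selection-inside-CV mode).
    """
    n = dataset.n_subjects
    if n < 4:
        raise ValueError("need at least 4 subjects")
    labels = dataset.data[class_variable].astype(str)
    rng = np.random.default_rng(seed)
    folds = _stratified_pair_folds(labels, rng)

    preds = pd.Series(index=dataset.data.index, dtype=object)
    for fold in folds:
        test_ids = dataset.data.index[fold]
        train_ids = dataset.data.index.difference(test_ids)
        train = dataset.subset_subjects(train_ids)
        # drop variables that lost all variation in the training split
        keep = [v for v in train.variables if train.data[v].nunique() >= 2]
        if class_variable not in keep:
            raise ValueError("class variable constant in a training fold")
        train = train.subset_variables(keep).recode()
        res = forced_classification_fit(train, class_variable,
                                        class_weight=class_weight, seed=seed)
        if vaf_threshold is not None:
            try:
                selected = select_variables(res, vaf_threshold)
                train_sel = train.subset_variables(selected).recode()
                res = forced_classification_fit(train_sel, class_variable,
                                                class_weight=class_weight, seed=seed)
            except ValueError:
                pass  # selection emptied: fall back to the full-fold model
        new = dataset.data.loc[test_ids, [v for v in res.dataset.variables
                                          if v != class_variable]]
        # map raw codes onto the training fold's recoded categories
        new = _recode_like(dataset, train if vaf_threshold is None else res.dataset,
                           new, class_variable)
        lab_pred, _ = res.predict(new)
        preds.loc[test_ids] = [str(p) for p in lab_pred]

    true = labels.astype(str)
    error = float((preds != true).mean())
    return CvResult(error=error, folds=folds, predictions=preds, true_labels=true)


def _recode_like(full: CategoricalDataset, train: CategoricalDataset,
                 new: pd.DataFrame, class_variable: str) -> pd.DataFrame:
    """Express held-out subjects' raw codes on the training fold's recoded scale.

    Training recoding maps the fold's observed raw categories onto 1..k;
    held-out raw codes between two observed categories land between the
    corresponding recoded values by linear interpolation (fractional codes
    are understood by the prediction lookup), outside values clamp.
    """
    out = {}
    for v in new.columns:
        raw_train = np.sort(full.data[v].loc[train.data.index].unique())
        recoded = np.arange(1, len(raw_train) + 1, dtype=float)
        out[v] = np.interp(new[v].to_numpy(dtype=float), raw_train, recoded)
    return pd.DataFrame(out, index=new.index)


# ----------------------------------------------------------------------
def permutation_test_nlpca(
    dataset: CategoricalDataset,
    class_variable: str,
    n_permutations: int = 250,
    seed: int = 0,
    class_weight: float = 1000.0,
    vaf_threshold: float | None = 0.20,
    observed_error: float | None = None,
) -> PermutationResult:
    """Permutation test of the full protocol's cross-validated error.

    Class labels are permuted without replacement (class sizes preserved)
    *before* variable selection, and the whole protocol — fit, select, CV —
    is re-run per permutation.  ``p = (1 + #{null <= observed}) /
    (n_permutations + 1)``.
    """
    if n_permutations < 19:
        warnings.warn("fewer than 19 permutations: the p-value floor exceeds 0.05")
    rng = np.random.default_rng(seed)

    def protocol(ds: CategoricalDataset, s: int) -> float:
        if vaf_threshold is not None:
            full = forced_classification_fit(ds, class_variable,
                                             class_weight=class_weight, seed=s)
            try:
                selected = select_variables(full, vaf_threshold)
                ds = ds.subset_variables(selected).recode()
            except ValueError:
                pass
        return leave_two_out_cv(ds, class_variable, class_weight=class_weight,
                                seed=s).error

    if observed_error is None:
        observed_error = protocol(dataset, seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = dataset.copy()
        perm.data[class_variable] = rng.permutation(perm.data[class_variable].to_numpy())
        null[i] = protocol(perm, seed + i + 1)
    p = (1 + np.sum(null <= observed_error)) / (n_permutations + 1)
    significant = observed_error < np.percentile(null, 5)
    return PermutationResult(float(observed_error), null, float(p),
                             int(n_permutations), bool(significant))


# ----------------------------------------------------------------------
@dataclass
class ProtocolResult:
    """End-to-end questionnaire/clinical analysis outcome."""

    final_model: NLPCAResults
    selected: list[str]
    cv: CvResult
    permutation: PermutationResult | None = None
    level_comparison: pd.DataFrame | None = None

    def loadings_table(self) -> pd.DataFrame:
        df = self.final_model.loadings_frame()
        return df.loc[[v for v in df.index if v != self.final_model.class_variable]]

    def summary(self) -> str:
        lines = [self.final_model.summary(), "",
                 f"selected variables (VAF > threshold): {len(self.selected) - 1}",
                 f"leave-two-out CV error: {self.cv.error:.1%}"]
        if self.permutation is not None:
            lines.append(f"permutation p-value: {self.permutation.p_value:.4f} "
                         f"({self.permutation.n_permutations} permutations)")
        return "\n".join(lines)


def nlpca_protocol(
    dataset: CategoricalDataset,
    class_variable: str,
    vaf_threshold: float = 0.20,
    class_weight: float = 1000.0,
    n_permutations: int = 250,
    seed: int = 0,
    run_permutation: bool = True,
) -> ProtocolResult:
    """The full published protocol: fit, select, refit, cross-validate, permute."""
    screening = forced_classification_fit(dataset, class_variable,
                                          class_weight=class_weight, seed=seed)
    selected = select_variables(screening, vaf_threshold)
    reduced = dataset.subset_variables(selected).recode()
    final = forced_classification_fit(reduced, class_variable,
                                      class_weight=class_weight, seed=seed)
    cv = leave_two_out_cv(reduced, class_variable, class_weight=class_weight, seed=seed)
    perm = None
    if run_permutation:
        perm = permutation_test_nlpca(
            dataset, class_variable, n_permutations=n_permutations, seed=seed,
            class_weight=class_weight, vaf_threshold=vaf_threshold,
            observed_error=cv.error)
    return ProtocolResult(final_model=final, selected=selected, cv=cv, permutation=perm)
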