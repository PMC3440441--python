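"""PLS discriminant analysis with double cross-validation and jack-knife
variable elimination.

PLS-DA regresses a −1/+1 class coding on the (centered or autoscaled)
feature matrix via partial least squares, and classifies by the sign of the
prediction.  Model complexity (the number of latent variables A) is chosen
in an inner cross-validation loop; an outer loop, never touching the inner
choice, estimates the classification error — the *double* cross-validation
that keeps the error estimate honest at n ≈ 28.

Variable selection is by jack-knife: regression vectors are collected across
the outer training folds, each feature's coefficient standard error is its
standard deviation over folds, and a descending threshold schedule removes
features whose coefficient is unstable — small relative to its standard
error — step by step; the step with the lowest double-CV error wins (the
stop-once-error-increases rule is evaluated and recorded alongside the full
trace).

Significance of the final error is assessed by permutation: the whole double
CV is re-run on label-shuffled data (250 times by default) and the observed
error is compared with the null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSDA",
    "PLSDAResults",
    "fit_pls",
    "double_cv",
    "jackknife_select",
    "permutation_test_plsda",
    "rank_features",
    "stratified_pairs",
    "PermutationResult",
    "JackknifeTrace",
    "DoubleCvResult",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# core PLS
# ----------------------------------------------------------------------
def fit_pls(X, y, n_components):
    """Deterministic PLS1 (NIPALS) with orthogonal score vectors.

    Parameters
    ----------
    X : ndarray (n, m)
        Feature matrix, assumed centered/scaled by the caller.
    y : ndarray (n,)
        Class coding in {−1, +1} (any centered numeric response works).
    n_components : int
        Number of latent variables A; must not exceed ``min(n−1, m)``.

    Returns
    -------
    dict with keys
        ``B`` — (m, A) regression vectors for models with 1..A components,
        on the scale of the given X;
        ``intercepts`` — (A,) intercepts;
        ``T, W, P`` — scores, weights, loadings;
        ``x_mean, y_mean`` — centering constants.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    A = int(n_components)
    if A < 1 or A > min(n - 1, m):
        raise ValueError(f"n_components must be in [1, {min(n - 1, m)}]")

    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((m, A))
    P = np.zeros((m, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-14:
            # response fully explained; freeze remaining components
            A = a
            W, P, T, q = W[:, :A], P[:, :A], T[:, :A], q[:A]
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        q[a] = yd @ t / tt
        Xd = Xd - np.outer(t, p)
        W[:, a], P[:, a], T[:, a] = w, p, t
    if A == 0:
        raise ValueError("response is constant; nothing to fit")

    # regression vectors for every truncation 1..A: b_a = W_a (P_a' W_a)^{-1} q_a
    B = np.zeros((m, A))
    for a in range(1, A + 1):
        R = np.linalg.solve((P[:, :a].T @ W[:, :a]), np.eye(a))
        B[:, a - 1] = W[:, :a] @ (R @ q[:a])
    intercepts = y_mean - x_mean @ B
    return {"B": B, "intercepts": intercepts, "T": T, "W": W, "P": P,
            "x_mean": x_mean, "y_mean": y_mean, "n_components": A}


def _predict_pls(fit, X, n_components=None):
    a = (fit["n_components"] if n_components is None else n_components) - 1
    return np.asarray(X, dtype=float) @ fit["B"][:, a] + fit["intercepts"][a]


def _classify(yhat):
    """Sign decision rule; exactly zero goes to the Cold-coded class (−1)."""
    return np.where(yhat > 0, 1.0, -1.0)


# ----------------------------------------------------------------------
# cross-validation machinery
# ----------------------------------------------------------------------
def stratified_pairs(y, rng) -> list[np.ndarray]:
    """Disjoint leave-two-out folds: one subject per class per pair where
    possible; leftovers of the larger class pair among themselves, an odd
    last subject forms a singleton fold."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    idx_a = rng.permutation(np.flatnonzero(y == classes[0]))
    idx_b = rng.permutation(np.flatnonzero(y == classes[1]))
    folds = [np.array([a, b]) for a, b in zip(idx_a, idx_b)]
    rest = np.concatenate([idx_a[len(idx_b):], idx_b[len(idx_a):]])
    for i in range(0, len(rest) - 1, 2):
        folds.append(rest[i:i + 2])
    if len(rest) % 2:
        folds.append(rest[-1:])
    return folds


@dataclass
class DoubleCvResult:
    error: float
    chosen_components: list[int]
    folds: list[np.ndarray]
    predictions: np.ndarray

    def to_dict(self) -> dict:
        return {"error": self.error,
                "chosen_components": [int(a) for a in self.chosen_components]}


def _scale_train_apply(Xtr, Xte, mode):
    mean = Xtr.mean(axis=0)
    if mode == "autoscale":
        sd = Xtr.std(axis=0, ddof=1)
        sd[sd <= 0] = 1.0
        return (Xtr - mean) / sd, (Xte - mean) / sd
    if mode == "center":
        return Xtr - mean, Xte - mean
    return Xtr, Xte  # 'none': caller scaled globally


def double_cv(X, y, seed=0, max_components=10, scale="none", n_folds=None) -> DoubleCvResult:
    """Nested leave-two-out cross-validation of a PLS-DA classifier.

    Outer loop: stratified leave-two-out pairs; per outer fold an inner
    leave-two-out CV on the training remainder picks the component count A
    with minimal inner misclassification (ties toward smaller A), then the
    outer model is refit at that A and predicts the held-out pair.

    Parameters
    ----------
    scale : 'none' | 'center' | 'autoscale'
        Per-training-fold scaling, recomputed inside every fold to avoid
        information leak.  'none' assumes the caller scaled globally.
    n_folds : int, optional
        Override for true k-fold splitting instead of leave-two-out pairs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 8:
        raise ValueError("need at least 8 samples for double CV")
    rng = np.random.default_rng(seed)
    if n_folds is None:
        outer = stratified_pairs(y, rng)
    else:
        perm = rng.permutation(n)
        outer = [np.sort(perm[i::n_folds]) for i in range(n_folds)]

    preds = np.full(n, np.nan)
    chosen: list[int] = []
    for fold in outer:
        tr = np.setdiff1d(np.arange(n), fold)
        if len(np.unique(y[tr])) < 2:
            # rebalance: return the smallest fold member of the missing class
            logger.info("rebalancing a fold missing one class")
            missing = np.setdiff1d(np.unique(y), np.unique(y[tr]))[0]
            swap = np.flatnonzero(y == missing)[0]
            fold = np.setdiff1d(fold, [swap])
            tr = np.setdiff1d(np.arange(n), fold)
        a_max = min(max_components, len(tr) - 2, X.shape[1])
        inner = stratified_pairs(y[tr], rng)
        errors = np.zeros(a_max)
        for ifold in inner:
            itr = np.setdiff1d(np.arange(len(tr)), ifold)
            if len(np.unique(y[tr][itr])) < 2:
                continue
            Xi, Xv = _scale_train_apply(X[tr][itr], X[tr][ifold], scale)
            amax_i = min(a_max, len(itr) - 1, X.shape[1])
            fit = fit_pls(Xi, y[tr][itr], amax_i)
            for a in range(1, fit["n_components"] + 1):
                yh = _classify(_predict_pls(fit, Xv, a))
                errors[a - 1] += np.sum(yh != y[tr][ifold])
            # components beyond what the fit supports inherit its last error
            for a in range(fit["n_components"] + 1, a_max + 1):
                yh = _classify(_predict_pls(fit, Xv))
                errors[a - 1] += np.sum(yh != y[tr][ifold])
        best_a = int(np.argmin(errors)) + 1  # argmin takes the first (smallest A)
        chosen.append(best_a)
        Xtr, Xte = _scale_train_apply(X[tr], X[fold], scale)
        fit = fit_pls(Xtr, y[tr], min(best_a, len(tr) - 1))
        preds[fold] = _classify(_predict_pls(fit, Xte))
    error = float(np.mean(preds != y))
    return DoubleCvResult(error=error, chosen_components=chosen,
                          folds=outer, predictions=preds)


# ----------------------------------------------------------------------
# jack-knife selection
# ----------------------------------------------------------------------
@dataclass
class JackknifeTrace:
    thresholds: list[float]
    n_retained: list[int]
    errors: list[float]
    chosen_step: int
    stop_step: int  # step the stop-once-error-increases rule lands on
    feature_sets: list[np.ndarray] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold_quantile": self.thresholds,
                             "n_retained": self.n_retained,
                             "error": self.errors})


def _fold_regression_vectors(X, y, folds, scale, max_components):
    """Regression vector per outer training fold at that fold's best A."""
    n = len(y)
    vecs = []
    for fold in folds:
        tr = np.setdiff1d(np.arange(n), fold)
        if len(np.unique(y[tr])) < 2:
            continue
        Xtr, _ = _scale_train_apply(X[tr], X[tr][:1], scale)
        a = min(max_components, len(tr) - 1, X.shape[1])
        fit = fit_pls(Xtr, y[tr], a)
        vecs.append(fit["B"][:, fit["n_components"] - 1])
    return np.array(vecs)


def jackknife_select(
    X, y, threshold_schedule=None, seed=0, max_components=10, scale="none"
) -> tuple[JackknifeTrace, np.ndarray]:
    """Stepwise jack-knife elimination of unstable features.

    Regression vectors are collected across the outer-CV training folds and
    each feature's coefficient standard error is its standard deviation over
    folds.  Elimination is driven by the *relative* standard error
    ``SE / |mean coefficient|`` — the scale-free instability of a
    coefficient: noise features have coefficients indistinguishable from
    zero (relative SE large), discriminating features have stable ones.  The
    default schedule walks descending quantiles (1.0, 0.95, …, 0.5) of the
    relative-SE distribution; each step removes features above the quantile
    and re-runs the double CV.  The chosen step attains the minimal error
    (first minimum on ties); the full trace is always recorded.

    Returns the trace and the selected feature index array.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if threshold_schedule is None:
        threshold_schedule = [1.0, 0.95, 0.9, 0.85, 0.8, 0.75, 0.7, 0.65, 0.6, 0.55, 0.5]
    rng = np.random.default_rng(seed)
    base_folds = stratified_pairs(y, rng)
    vecs = _fold_regression_vectors(X, y, base_folds, scale, max_components)
    sd = vecs.std(axis=0, ddof=1)
    mean_b = np.abs(vecs.mean(axis=0))
    se = sd / np.maximum(mean_b, 1e-12 * max(sd.max(), 1e-300))

    thresholds, retained, errors, sets = [], [], [], []
    stop_step = None
    for step, qt in enumerate(threshold_schedule):
        cut = np.quantile(se, qt)
        keep = np.flatnonzero(se <= cut)
        if keep.size == 0:
            logger.info("schedule step q=%.2f empties the feature set; skipped", qt)
            continue
        res = double_cv(X[:, keep], y, seed=seed, max_components=max_components, scale=scale)
        thresholds.append(float(qt))
        retained.append(int(keep.size))
        errors.append(res.error)
        sets.append(keep)
        if stop_step is None and len(errors) >= 2 and errors[-1] > errors[-2]:
            stop_step = len(errors) - 2  # error started increasing: previous step
    if not errors:
        raise ValueError("threshold schedule produced no usable steps")
    chosen = int(np.argmin(errors))  # first minimum on ties
    if stop_step is None:
        stop_step = chosen
    trace = JackknifeTrace(thresholds, retained, errors, chosen, stop_step, sets)
    return trace, sets[chosen]


# ----------------------------------------------------------------------
# permutation testing
# ----------------------------------------------------------------------
@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_permutations: int
    significant_95: bool

    def to_dict(self) -> dict:
        return {"observed": self.observed, "p_value": self.p_value,
                "n_permutations": self.n_permutations,
                "significant_95": bool(self.significant_95)}


def permutation_test_plsda(
    X, y, n_permutations=250, seed=0, max_components=10, scale="none",
    with_jackknife=False, observed_error=None,
) -> PermutationResult:
    """Compare the double-CV error against label-permuted null models.

    Labels are shuffled without replacement (class sizes preserved) and the
    full double CV (optionally with jack-knife selection) is re-run per
    permutation.  Significance at the 95% criterion means the observed error
    is below the 5th percentile of the null errors; the p-value carries the
    +1 correction ``(1 + #{null <= observed}) / (n_permutations + 1)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)

    def pipeline(Xp, yp, s):
        if with_jackknife:
            _, keep = jackknife_select(Xp, yp, seed=s, max_components=max_components,
                                       scale=scale)
            Xp = Xp[:, keep]
        return double_cv(Xp, yp, seed=s, max_components=max_components, scale=scale).error

    if observed_error is None:
        observed_error = pipeline(X, y, seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        yp = rng.permutation(y)
        null[i] = pipeline(X, yp, seed + i + 1)
    p = (1 + np.sum(null <= observed_error)) / (n_permutations + 1)
    significant = observed_error < np.percentile(null, 5)
    return PermutationResult(float(observed_error), null, float(p),
                             int(n_permutations), bool(significant))


# ----------------------------------------------------------------------
# model / results facade
# ----------------------------------------------------------------------
class PLSDA:
    """PLS discriminant model for a two-class feature matrix.

    Parameters
    ----------
    X : DataFrame or ndarray (samples x features)
        Scaled feature matrix (use ``scale='center'|'autoscale'`` to have
        fold-wise scaling handled internally from raw values).
    y : array-like
        Class labels; mapped to −1 (first class, "Cold") and +1.
    scale : 'none' | 'center' | 'autoscale'
    """

    def __init__(self, X, y, scale="none", max_components=10,
                 cold_label=None, heat_label=None):
        self.feature_names = (list(X.columns) if isinstance(X, pd.DataFrame)
                              else [f"x{j}" for j in range(np.asarray(X).shape[1])])
        self.X = np.asarray(X, dtype=float)
        labels = pd.Series(list(y))
        classes = sorted(labels.unique(), key=str)
        if len(classes) != 2:
            raise ValueError("PLSDA needs exactly two classes")
        if cold_label is None:
            cold_label = "Cold" if "Cold" in classes else classes[0]
        if heat_label is None:
            heat_label = [c for c in classes if c != cold_label][0]
        self.cold_label, self.heat_label = cold_label, heat_label
        self.y = np.where(labels == cold_label, -1.0, 1.0)
        self.scale = scale
        self.max_components = max_components

    def fit(self, seed=0, jackknife=True, n_permutations=250,
            threshold_schedule=None, run_permutation=True) -> "PLSDAResults":
        """Run double CV, optional jack-knife selection, final fit and
        (optionally) the permutation test."""
        X, y = self.X, self.y
        base = double_cv(X, y, seed=seed, max_components=self.max_components,
                         scale=self.scale)
        trace, keep = (None, np.arange(X.shape[1]))
        if jackknife:
            trace, keep = jackknife_select(
                X, y, threshold_schedule=threshold_schedule, seed=seed,
                max_components=self.max_components, scale=self.scale)
        final_cv = (base if trace is None
                    else double_cv(X[:, keep], y, seed=seed,
                                   max_components=self.max_components, scale=self.scale))
        a_final = int(np.median(final_cv.chosen_components)) or 1
        Xs, _ = _scale_train_apply(X[:, keep], X[:1, keep], self.scale)
        fit = fit_pls(Xs, y, min(a_final, len(y) - 1, keep.size))

        perm = None
        if run_permutation:
            perm = permutation_test_plsda(
                X[:, keep], y, n_permutations=n_permutations, seed=seed,
                max_components=self.max_components, scale=self.scale,
                observed_error=final_cv.error)
        b = fit["B"][:, fit["n_components"] - 1]
        return PLSDAResults(
            model=self, selected=keep, b=b,
            n_components=fit["n_components"],
            cv_error=final_cv.error, pre_selection_error=base.error,
            chosen_components=final_cv.chosen_components,
            trace=trace, permutation=perm,
        )


@dataclass
class PLSDAResults:
    """Fitted PLS-DA pipeline: selection, final model, validation."""

    model: PLSDA
    selected: np.ndarray
    b: np.ndarray
    n_components: int
    cv_error: float
    pre_selection_error: float
    chosen_components: list[int]
    trace: JackknifeTrace | None
    permutation: PermutationResult | None

    @property
    def selected_features(self) -> list[str]:
        return [self.model.feature_names[j] for j in self.selected]

    def summary(self) -> str:
        lines = [
            "PLS-DA with double cross-validation",
            "=" * 46,
            f"samples: {len(self.model.y)}   features: {self.model.X.shape[1]}"
            f" -> selected: {len(self.selected)}",
            f"latent variables (final): {self.n_components}",
            f"double-CV error: {self.cv_error:.1%}"
            f" (before selection: {self.pre_selection_error:.1%})",
        ]
        if self.permutation is not None:
            lines.append(
                f"permutation test: p = {self.permutation.p_value:.4f} "
                f"({self.permutation.n_permutations} permutations; "
                f"significant at 95% criterion: {self.permutation.significant_95})"
            )
        return "\n".join(lines)


def rank_features(results: PLSDAResults, raw_table=None, labels=None, top_k=50) -> pd.DataFrame:
    """Importance-ranked feature report (largest |b| = rank 1).

    When ``raw_table`` (DataFrame of raw intensities, samples x features) and
    ``labels`` are given, each feature is annotated with its 2log Cold/Heat
    class-mean ratio.
    """
    from .metabolites import log2_ratio

    order = np.argsort(-np.abs(results.b), kind="stable")
    rows = []
    for rank, pos in enumerate(order[:top_k], start=1):
        name = results.selected_features[pos]
        row = {"importance": rank, "feature": name, "b": float(results.b[pos])}
        if raw_table is not None and labels is not None:
            row["log2_cold_heat"] = log2_ratio(
                raw_table[name], labels,
                cold_label=results.model.cold_label,
                heat_label=results.model.heat_label)
        rows.append(row)
    return pd.DataFrame(rows).set_index("importance")
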