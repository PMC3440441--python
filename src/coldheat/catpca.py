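"""Optimal-scaling nonlinear principal component analysis (CATPCA).

Classical PCA assumes numeric variables linearly related to the components.
Questionnaire items scored 1–7 and binned clinical chemistry values violate
both assumptions, so instead each variable receives *category
quantifications*: numeric values assigned to its categories so that the
variance of the transformed variables accounted for by the principal
components (VAF) is maximal, subject to the variable's analysis level —
nominal (free), ordinal (monotone nondecreasing), spline-nominal /
spline-ordinal (smooth piecewise polynomial, optionally monotone) or numeric
(linear in the codes).

The model is fitted by alternating least squares over three blocks: object
scores ``X`` (n x p, column mean 0, X'X = nI), per-variable quantified
variables ``q_j`` (mean 0, sum of squares n) and loadings ``a_j = X'q_j / n``.
With one component the per-variable VAF is the squared loading and total VAF
is the weight-averaged squared loading.  Every ALS sweep can only increase
total VAF; the fit asserts this.

*Forced classification* adds the binary subtype label as a nominal variable
with a very large weight (default 1000), which pulls the single component
onto the class contrast so that the two classes separate into subclouds of
object scores.

The public surface follows the statsmodels convention: build a
:class:`NonlinearPCA` model from a :class:`~coldheat.datasets.CategoricalDataset`
and call :meth:`~NonlinearPCA.fit`, which returns :class:`NLPCAResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import nnls

from .datasets import CategoricalDataset, ScalingSpec

__all__ = [
    "NonlinearPCA",
    "NLPCAResults",
    "monotone_regression",
    "spline_basis",
    "forced_classification_fit",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------
def monotone_regression(values, weights=None):
    """Weighted least-squares monotone (nondecreasing) regression.

    Pool-adjacent-violators: scan left to right, pooling adjacent blocks
    whenever their weighted means violate the ordering; pooled blocks carry
    the weighted mean of their members.

    Parameters
    ----------
    values : array-like
        Finite values in category order.
    weights : array-like, optional
        Positive weights (typically category frequencies); default all one.

    Returns
    -------
    ndarray
        The nondecreasing fit, same length as ``values``.
    """
    y = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
    if y.ndim != 1 or w.shape != y.shape:
        raise ValueError("values and weights must be 1-D and the same length")
    if not np.isfinite(y).all():
        raise ValueError("values must be finite")
    if (w <= 0).any():
        raise ValueError("weights must be positive")

    # blocks as (mean, weight, length) triples on a stack
    means: list[float] = []
    wts: list[float] = []
    sizes: list[int] = []
    for yi, wi in zip(y, w):
        means.append(float(yi))
        wts.append(float(wi))
        sizes.append(1)
        while len(means) > 1 and means[-2] >= means[-1]:
            m2, w2, s2 = means.pop(), wts.pop(), sizes.pop()
            m1, w1, s1 = means.pop(), wts.pop(), sizes.pop()
            means.append((m1 * w1 + m2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
            sizes.append(s1 + s2)
    return np.repeat(means, sizes)


def spline_basis(positions, degree=2, interior_knots=2, monotone=False, weights=None):
    """Piecewise-polynomial basis evaluated at category positions.

    Interior knots are placed at quantiles of the (frequency-weighted)
    category distribution.  The non-monotone basis is the clamped B-spline
    basis of the requested degree; because the columns form a partition of
    unity, its span contains the constant function and has rank
    ``degree + interior_knots + 1``.

    The monotone variant returns right-tail cumulative sums of the B-spline
    columns (dropping the constant first column): each column is a
    nondecreasing function of position, so any nonnegative combination —
    plus a free intercept — is nondecreasing (an I-spline basis).

    Parameters
    ----------
    positions : array-like
        Distinct, increasing category positions (typically ``1..k``).
    degree, interior_knots : int
        Spline order parameters.  If there are too few distinct positions to
        support the requested knots, the knot count is reduced with a logged
        warning.
    monotone : bool
        Return the integrated (monotone) basis instead.
    weights : array-like, optional
        Category frequencies used for knot placement quantiles.

    Returns
    -------
    ndarray of shape (len(positions), n_basis)
    """
    x = np.asarray(positions, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("positions must be strictly increasing")
    k = len(x)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    # need at least degree + knots + 1 distinct positions to identify the basis
    max_knots = max(k - degree - 1, 0)
    knots = interior_knots
    if knots > max_knots:
        logger.warning(
            "reducing interior knots from %d to %d (%d categories)", knots, max_knots, k
        )
        knots = max_knots

    if weights is None:
        weights = np.ones(k)
    w = np.asarray(weights, dtype=float)
    # interior knots at quantiles of the weighted category distribution
    if knots > 0:
        cw = np.cumsum(w) / w.sum()
        probs = np.arange(1, knots + 1) / (knots + 1)
        inner = np.interp(probs, cw, x)
        # keep knots strictly inside the range
        inner = np.clip(inner, x[0] + 1e-9, x[-1] - 1e-9)
    else:
        inner = np.array([])

    t = np.concatenate([[x[0]] * (degree + 1), inner, [x[-1]] * (degree + 1)])
    n_basis = len(t) - degree - 1
    B = np.empty((k, n_basis))
    for i in range(n_basis):
        c = np.zeros(n_basis)
        c[i] = 1.0
        B[:, i] = BSpline(t, c, degree, extrapolate=False)(x)
    B = np.nan_to_num(B)
    # clamped basis: rightmost point belongs to the last basis function
    B[-1, -1] = 1.0

    if not monotone:
        return B
    # I-spline style: right-tail sums of a partition of unity are nondecreasing
    M = np.cumsum(B[:, ::-1], axis=1)[:, ::-1]
    return M[:, 1:]  # drop the constant column; intercept handled separately


def _make_basis(counts, spec: ScalingSpec):
    """Pre-build the spline basis for one variable (None for non-spline levels)."""
    if not spec.analysis_level.startswith("spline"):
        return None
    pos = np.arange(1, len(counts) + 1, dtype=float)
    return spline_basis(pos, spec.degree, spec.interior_knots,
                        monotone=spec.analysis_level == "spline-ordinal",
                        weights=counts)


def _project_quantification(cat_means, counts, spec: ScalingSpec, basis=None):
    """Project unconstrained category means onto the analysis level's feasible set."""
    level = spec.analysis_level
    if level == "nominal":
        return cat_means
    if level == "ordinal":
        return monotone_regression(cat_means, counts)
    if level == "numeric":
        # linear in the category codes; handled by the caller (fixed quantification)
        raise AssertionError("numeric level does not re-estimate quantifications")

    if basis is None:
        basis = _make_basis(counts, spec)
    sw = np.sqrt(counts)
    if level == "spline-nominal":
        coef, *_ = np.linalg.lstsq(basis * sw[:, None], cat_means * sw, rcond=None)
        return basis @ coef
    if level == "spline-ordinal":
        # intercept profiled out: weighted-center both sides, then NNLS
        M = basis
        wsum = counts.sum()
        ybar = (counts @ cat_means) / wsum
        Mbar = (counts @ M) / wsum
        A = (M - Mbar) * sw[:, None]
        b = (cat_means - ybar) * sw
        coef, _ = nnls(A, b)
        return M @ coef + (ybar - Mbar @ coef)
    raise ValueError(f"unknown analysis level {level!r}")


def _normalize_scores(q, n):
    """Center and scale a vector to mean 0, sum of squares n; None if degenerate."""
    q = q - q.mean()
    ss = q @ q
    if ss <= 1e-14 * n:
        return None
    return q * np.sqrt(n / ss)


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------
class NonlinearPCA:
    """Optimal-scaling nonlinear PCA model for a categorical dataset.

    Parameters
    ----------
    dataset
        Recoded :class:`CategoricalDataset` (consecutive 1..k codes per
        variable, each with >= 2 observed categories).  Scaling specs ride on
        the dataset; pass ``specs`` to override.
    n_components
        Number of principal components p (1 for forced classification).
    specs
        Optional per-variable :class:`ScalingSpec` overrides.
    """

    def __init__(self, dataset: CategoricalDataset, n_components: int = 1, specs=None):
        if specs:
            dataset = dataset.with_specs(specs)
        if not dataset.is_recoded():
            dataset = dataset.recode()
        if len(dataset.variables) < 2:
            raise ValueError("need at least two variables")
        if dataset.n_subjects < 3:
            raise ValueError("need at least three subjects")
        for name in dataset.variables:
            if dataset.n_categories(name) < 2:
                raise ValueError(f"variable {name!r} has a single category; drop it first")
        self.dataset = dataset
        self.n_components = int(n_components)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    # ------------------------------------------------------------------
    def fit(self, max_iter: int = 500, tol: float = 1e-8, seed: int | None = 0) -> "NLPCAResults":
        """Run the ALS loop until the total-VAF gain drops below ``tol``."""
        ds = self.dataset
        n, p = ds.n_subjects, self.n_components
        names = ds.variables
        codes = {v: ds.data[v].to_numpy() - 1 for v in names}  # 0-based
        counts = {v: np.bincount(codes[v]).astype(float) for v in names}
        weights = np.array([ds.specs[v].weight for v in names])
        wsum = weights.sum()

        # numeric level: quantification fixed at standardized codes
        quants: dict[str, np.ndarray] = {}
        q_vecs: dict[str, np.ndarray] = {}
        for v in names:
            y0 = np.arange(1, len(counts[v]) + 1, dtype=float)
            q = _normalize_scores(y0[codes[v]], n)
            quants[v] = self._cat_values(q, codes[v])
            q_vecs[v] = q

        bases = {v: _make_basis(counts[v], ds.specs[v]) for v in names}

        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        X = self._orthonormalize(X, n)

        loadings = {v: X.T @ q_vecs[v] / n for v in names}
        vaf_history: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            # (i) object scores from current quantifications and loadings
            Z = np.zeros((n, p))
            for v, w in zip(names, weights):
                Z += w * np.outer(q_vecs[v], loadings[v])
            X = self._orthonormalize(Z, n)

            # (ii)+(iii) loadings and quantifications per variable
            for v in names:
                spec = ds.specs[v]
                a = X.T @ q_vecs[v] / n
                if spec.analysis_level != "numeric":
                    target = X @ a  # rank-1 restricted target
                    cm = np.bincount(codes[v], weights=target) / counts[v]
                    y = _project_quantification(cm, counts[v], spec, bases[v])
                    q = _normalize_scores(y[codes[v]], n)
                    if q is not None:
                        q_vecs[v] = q
                        quants[v] = self._cat_values(q, codes[v])
                loadings[v] = X.T @ q_vecs[v] / n

            total_vaf = float(
                sum(w * (loadings[v] @ loadings[v]) for v, w in zip(names, weights)) / wsum
            )
            if vaf_history and total_vaf < vaf_history[-1] - 1e-10:
                raise AssertionError("total VAF decreased across an ALS sweep")
            gain = total_vaf - vaf_history[-1] if vaf_history else np.inf
            vaf_history.append(total_vaf)
            if gain < tol:
                converged = True
                break

        vaf_per_var = {v: float(loadings[v] @ loadings[v]) for v in names}
        return NLPCAResults(
            model=self,
            object_scores=X,
            quantifications={v: quants[v].copy() for v in names},
            loadings={v: loadings[v].copy() for v in names},
            vaf_per_variable=vaf_per_var,
            total_vaf=vaf_history[-1],
            vaf_history=np.array(vaf_history),
            n_iter=n_iter,
            converged=converged,
        )

    # ------------------------------------------------------------------
    @staticmethod
    def _orthonormalize(Z, n):
        Z = Z - Z.mean(axis=0)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        if np.any(s <= 1e-12):
            # degenerate direction: fall back to QR of a jittered matrix
            Q, _ = np.linalg.qr(Z + 1e-9)
            Q = Q - Q.mean(axis=0)
            U, s, Vt = np.linalg.svd(Q, full_matrices=False)
        return U @ Vt * np.sqrt(n)

    @staticmethod
    def _cat_values(q, codes):
        counts = np.bincount(codes).astype(float)
        return np.bincount(codes, weights=q) / counts


@dataclass
class NLPCAResults:
    """Fitted optimal-scaling PCA.

    Attributes
    ----------
    object_scores : ndarray (n, p)
        Principal scores of the subjects, columns mean 0 and sum of squares n.
    quantifications : dict
        Per variable, the category quantifications on the normalized scale
        (the quantified variable ``q_j = y_j[code]`` has mean 0, SS n).
    loadings : dict
        Per variable, the p-vector of component loadings ``a_j``.
    vaf_per_variable : dict
        Squared loading norm per variable (for p=1 simply ``a_j**2``).
    total_vaf : float
        Weight-averaged VAF over variables.
    """

    model: NonlinearPCA
    object_scores: np.ndarray
    quantifications: dict[str, np.ndarray]
    loadings: dict[str, np.ndarray]
    vaf_per_variable: dict[str, float]
    total_vaf: float
    vaf_history: np.ndarray
    n_iter: int
    converged: bool
    class_variable: str | None = None
    class_quantifications: dict | None = None
    separated: bool | None = None
    class_weight: float | None = None

    # ------------------------------------------------------------------
    @property
    def dataset(self) -> CategoricalDataset:
        return self.model.dataset

    @property
    def substantive_vaf(self) -> float:
        """Weighted-mean VAF over the non-class variables.

        Under forced classification the class variable's huge weight pins the
        overall weighted mean near 1; this is the VAF of the variables of
        scientific interest (the figure a report quotes as "total VAF").
        """
        names = [v for v in self.dataset.variables if v != self.class_variable]
        w = np.array([self.dataset.specs[v].weight for v in names])
        vaf = np.array([self.vaf_per_variable[v] for v in names])
        return float((w @ vaf) / w.sum())

    def loadings_frame(self) -> pd.DataFrame:
        rows = [
            {"variable": v, "loading": float(self.loadings[v][0]), "vaf": self.vaf_per_variable[v]}
            for v in self.dataset.variables
        ]
        df = pd.DataFrame(rows).set_index("variable")
        return df.sort_values("loading", ascending=False)

    def transformation_table(self, variable: str) -> pd.DataFrame:
        """Category -> optimally scaled quantification (transformation-plot data)."""
        y = self.quantifications[variable]
        return pd.DataFrame(
            {"category": np.arange(1, len(y) + 1), "quantification": y}
        ).set_index("category")

    def summary(self) -> str:
        lines = [
            "Optimal-scaling nonlinear PCA",
            "=" * 46,
            f"subjects: {self.dataset.n_subjects}   variables: {len(self.dataset.variables)}",
            f"components: {self.model.n_components}   iterations: {self.n_iter}"
            f"   converged: {self.converged}",
            f"total VAF: {self.total_vaf:.4f}",
        ]
        if self.class_variable is not None:
            lines.append(
                f"forced classification on {self.class_variable!r} "
                f"(weight {self.class_weight:g}); classes separated: {self.separated}"
            )
            lines.append(f"total VAF excluding class variable: {self.substantive_vaf:.4f}")
        lines.append("")
        lines.append(f"{'variable':<28}{'loading':>10}{'VAF':>10}")
        lines.append("-" * 48)
        for v, row in self.loadings_frame().iterrows():
            lines.append(f"{v:<28}{row['loading']:>10.3f}{row['vaf']:>10.3f}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def predict(self, new_data: pd.DataFrame, max_missing_fraction: float = 0.5):
        """Predict class labels and object scores for new subjects.

        Transformed values are looked up from the trained quantifications
        (unseen ordinal/spline categories are linearly interpolated between
        neighbouring trained categories; unseen nominal categories take the
        modal category's quantification).  The object score is the weighted
        least-squares estimate over the non-class variables,
        ``x = sum' w_j a_j q_j / sum' w_j a_j^2``; the predicted label is the
        class whose trained class-quantification is nearer on the forced
        component, ties broken toward Cold.
        """
        if self.class_variable is None:
            raise ValueError("predict requires a forced-classification fit")
        names = [v for v in self.dataset.variables if v != self.class_variable]
        missing = [v for v in names if v not in new_data.columns]
        if len(missing) > 0.5 * len(names):
            raise ValueError("new subjects are missing more than half the model variables")
        usable = [v for v in names if v in new_data.columns]
        if len(usable) < max_missing_fraction * len(names):
            raise ValueError("new subjects are missing more than half the model variables")

        specs = self.dataset.specs
        num = np.zeros(len(new_data))
        den = 0.0
        for v in usable:
            a = float(self.loadings[v][0])
            w = specs[v].weight
            y = self.quantifications[v]
            codes = new_data[v].to_numpy().astype(float)
            qv = np.interp(codes, np.arange(1, len(y) + 1), y)  # clamps + interpolates
            if specs[v].analysis_level == "nominal":
                counts = self.dataset.category_counts(v).to_numpy()
                mode_q = y[int(np.argmax(counts))]
                seen = (codes >= 1) & (codes <= len(y)) & (codes == np.round(codes))
                qv = np.where(seen, qv, mode_q)
            num += w * a * qv
            den += w * a * a
        if den <= 0:
            raise ValueError("degenerate model: all loadings zero")
        scores = num / den

        cq = self.class_quantifications
        labels = []
        for x in scores:
            dists = {lab: abs(x - val) for lab, val in cq.items()}
            best = sorted(dists.items(), key=lambda kv: (kv[1], str(kv[0])))
            # exact tie broken toward the Cold-coded (negative-score) class
            if len(best) > 1 and np.isclose(best[0][1], best[1][1]):
                neg = min(cq, key=cq.get)
                labels.append(neg)
            else:
                labels.append(best[0][0])
        return np.array(labels, dtype=object), scores


# ----------------------------------------------------------------------
def forced_classification_fit(
    dataset: CategoricalDataset,
    class_variable: str,
    class_weight: float = 1000.0,
    seed: int | None = 0,
    max_weight: float = 1e6,
    heat_label=None,
    label_map: dict | None = None,
    **fit_kwargs,
) -> NLPCAResults:
    """Fit a single-component NLPCA with the class label as a heavy variable.

    The class variable must be binary.  The fit asserts complete separation of
    the two classes' object-score intervals; if they overlap, the class weight
    is doubled and the model refitted, up to ``max_weight``.  The component
    sign is fixed so the Heat-coded class (the higher category code unless
    ``heat_label``/``label_map`` say otherwise) has positive scores; a
    negative quantification then corresponds to the Cold classification.

    Parameters
    ----------
    label_map
        Optional mapping from category code (1, 2) to class label used in the
        returned ``class_quantifications``.
    """
    if class_variable not in dataset.variables:
        raise ValueError(f"class variable {class_variable!r} not in dataset")
    col = dataset.data[class_variable]
    if col.nunique() != 2:
        raise ValueError("class variable must be binary")

    dataset = dataset.with_specs(
        {class_variable: ScalingSpec(analysis_level="nominal", weight=class_weight)}
    )
    if not dataset.is_recoded():
        dataset = dataset.recode()
    codes = dataset.data[class_variable].to_numpy()

    weight = class_weight
    while True:
        model = NonlinearPCA(dataset.with_specs(
            {class_variable: ScalingSpec(analysis_level="nominal", weight=weight)}
        ), n_components=1)
        res = model.fit(seed=seed, **fit_kwargs)
        x = res.object_scores[:, 0]
        lo_max = x[codes == 1].max()
        hi_min = x[codes == 2].min()
        separated = lo_max < hi_min or x[codes == 2].max() < x[codes == 1].min()
        if separated or weight >= max_weight:
            break
        weight *= 2
        logger.warning("classes not separated; doubling class weight to %g", weight)

    # sign convention: Heat-coded class gets positive scores
    if label_map is None:
        cats = np.sort(col.unique())
        label_map = {1: cats[0], 2: cats[1]}
    heat_code = 2
    if heat_label is not None:
        heat_code = [c for c, lab in label_map.items() if lab == heat_label]
        heat_code = heat_code[0] if heat_code else 2
    if x[codes == heat_code].mean() < 0:
        res.object_scores = -res.object_scores
        res.loadings = {v: -a for v, a in res.loadings.items()}

    x = res.object_scores[:, 0]
    res.class_variable = class_variable
    res.class_weight = weight
    res.separated = bool(separated)
    res.class_quantifications = {
        label_map[c]: float(x[codes == c].mean()) for c in (1, 2)
    }
    if not separated:
        warnings.warn("classes could not be completely separated at the weight cap")
    return res
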