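"""Descriptive statistics and annotation heuristics for discriminating features.

Covers the reporting layer around the multivariate models: 2log Cold/Heat
class-mean ratios, the acylcarnitine neutral-loss flag (59.0747 Da with a
retention-time-vs-mass sanity check), joint-symptom positivity summaries with
Mann-Whitney U tests, and two-sample t-tests computed from published summary
statistics (mean ± sd, n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import NEUTRAL_LOSS_CARNITINE

__all__ = [
    "log2_ratio",
    "flag_acylcarnitines",
    "symptom_positive_summary",
    "ttest_from_summary",
    "CompoundAnnotation",
]


def log2_ratio(values, labels, cold_label="Cold", heat_label="Heat", geometric=False):
    """Base-2 log of the Cold/Heat ratio of class means.

    Arithmetic class means by default (``geometric=True`` switches to
    geometric means, i.e. the mean of the 2log values).  Values must be
    strictly positive — run zero replacement first.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if (v <= 0).any():
        raise ValueError("values must be strictly positive (replace zeros first)")
    vc, vh = v[lab == cold_label], v[lab == heat_label]
    if vc.size == 0 or vh.size == 0:
        raise ValueError("both classes must be non-empty")
    if geometric:
        return float(np.mean(np.log2(vc)) - np.mean(np.log2(vh)))
    mc, mh = vc.mean(), vh.mean()
    if mc <= 0 or mh <= 0:
        raise ValueError("class means must be positive")
    return float(np.log2(mc / mh))


@dataclass
class CompoundAnnotation:
    """Per-feature annotation evidence."""

    feature_id: str
    precursor_mz: float
    rt: float
    losses: list[float] = field(default_factory=list)
    acylcarnitine_like: bool = False
    notes: str = ""


def _parse_fragments(frag) -> list[float]:
    if frag is None or (isinstance(frag, float) and np.isnan(frag)):
        return []
    if isinstance(frag, str):
        return [float(f) for f in frag.replace(",", ";").split(";") if f.strip()]
    if isinstance(frag, (int, float, np.floating)):
        return [float(frag)]
    return [float(f) for f in frag]


def flag_acylcarnitines(feature_meta: pd.DataFrame, mass_tolerance: float = 0.005):
    """Flag features whose fragmentation shows the carnitine neutral loss.

    A feature is acylcarnitine-like when some precursor − fragment mass
    difference falls within ``mass_tolerance`` of 59.0747 Da.  Acylcarnitines
    of increasing chain length are increasingly apolar, so over the flagged
    set retention time should increase with precursor mass; the returned
    consistency check reports the Spearman correlation and passes when it is
    positive and significant (or perfectly monotone on tiny sets).

    Parameters
    ----------
    feature_meta : DataFrame
        Indexed by feature id with columns ``mz``, ``rt``, ``fragments``
        (semicolon-separated string or list of fragment m/z).

    Returns
    -------
    annotations : list[CompoundAnnotation]
    consistency : dict with ``rho``, ``p`` and ``consistent`` keys
    """
    annotations = []
    for fid, row in feature_meta.iterrows():
        losses = [row["mz"] - f for f in _parse_fragments(row.get("fragments"))]
        losses = [lo for lo in losses if lo >= 0]
        flagged = any(abs(lo - NEUTRAL_LOSS_CARNITINE) <= mass_tolerance for lo in losses)
        annotations.append(CompoundAnnotation(
            feature_id=str(fid), precursor_mz=float(row["mz"]), rt=float(row["rt"]),
            losses=losses, acylcarnitine_like=flagged,
            notes="neutral loss 59.0747" if flagged else ""))

    flagged_set = [a for a in annotations if a.acylcarnitine_like]
    consistency = {"rho": np.nan, "p": np.nan, "consistent": False,
                   "n_flagged": len(flagged_set)}
    if len(flagged_set) >= 3:
        mz = [a.precursor_mz for a in flagged_set]
        rt = [a.rt for a in flagged_set]
        rho, p = stats.spearmanr(mz, rt)
        consistency.update(rho=float(rho), p=float(p),
                           consistent=bool(rho > 0 and (p < 0.05 or rho == 1.0)))
    return annotations, consistency


def symptom_positive_summary(scores: pd.DataFrame, labels, positive_above: int = 1):
    """Joint-symptom positivity table plus per-symptom Mann-Whitney U tests.

    ``scores`` holds 1–7 severity scores for (typically three) symptoms; a
    score above 1 counts as positive.  Per class the table gives the
    percentage of subjects with exactly 0, at least 1, at least 2 and exactly
    all-k positive symptoms.  Group differences per symptom are evaluated
    with the tie-corrected two-sided Mann-Whitney U test.

    Returns ``(summary DataFrame, tests DataFrame)``.
    """
    arr = scores.to_numpy()
    if ((arr < 1) | (arr > 7)).any():
        bad = scores.index[((arr < 1) | (arr > 7)).any(axis=1)].tolist()
        raise ValueError(f"scores outside 1..7 for subjects {bad}")
    lab = pd.Series(np.asarray(labels), index=scores.index)
    k = scores.shape[1]
    n_pos = (scores > positive_above).sum(axis=1)

    rows = {}
    for cls, idx in lab.groupby(lab).groups.items():
        npos = n_pos.loc[idx]
        n = len(idx)
        rows[cls] = {
            "0": 100.0 * (npos == 0).sum() / n,
            ">=1": 100.0 * (npos >= 1).sum() / n,
            ">=2": 100.0 * (npos >= 2).sum() / n,
            f"={k}": 100.0 * (npos == k).sum() / n,
        }
    summary = pd.DataFrame(rows)
    summary.index.name = "n_symptoms"

    tests = []
    classes = list(summary.columns)
    for sym in scores.columns:
        a = scores.loc[lab == classes[0], sym]
        b = scores.loc[lab == classes[1], sym]
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        tests.append({"symptom": sym, "U": float(u), "p": float(p)})
    return summary, pd.DataFrame(tests).set_index("symptom")


def ttest_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance two-sample Student t-test from summary statistics.

    Returns ``(t, df, two-sided p)``.  Suitable for published tables that
    report only mean ± sd and group size.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    df = n1 + n2 - 2
    return float(res.statistic), int(df), float(res.pvalue)
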