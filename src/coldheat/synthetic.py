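"""Seeded synthetic cohorts with the statistical structure the analyses assume.

The study this pipeline targets enrolled two balanced classes of rheumatoid
arthritis patients (20 Cold / 19 Heat), scored 57 questionnaire items on a
1–7 severity scale (15 of which carry no variation after category merging),
measured ~40 clinical chemistry variables — some shifted monotonically
between classes, some with a "high as well as low" two-tailed pattern — and
acquired urine and plasma LC-MS feature tables with pooled-QC replicates.
No patient-level data were deposited, so this module generates cohorts with
that design, together with the ground truth (which variables/features are
informative and with what effect) needed for recovery tests.

Generative choices:

* Questionnaire items come from a proportional-odds (ordered logit) model:
  a latent logistic variable shifted by a per-item class effect is cut at
  fixed thresholds into the 1–7 categories.
* Quadratic clinical variables put one class in both tails and the other in
  the middle of the range, mimicking the nonmonotone class relationships the
  spline-nominal analysis level exists to capture.
* LC-MS intensities are log-normal; informative features are multiplied by
  ``2**effect`` in the Cold class, so the 2log Cold/Heat ratio of class means
  converges to the configured effect.  Zeros are left-censoring at a
  detection limit placed at the ``missing_rate`` quantile of intensity.
* QC samples are the cohort mean profile plus small noise, scaled by
  ``(1 + drift_slope * injection_index)``.
* An acylcarnitine-like family stores a fragment at precursor − 59.0747 Da
  with retention time strictly increasing with mass.

A single global seed fans out to per-table child seeds so each table can be
regenerated independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CategoricalDataset, FeatureTable, ScalingSpec

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "generate_questionnaire",
    "generate_clinical",
    "generate_feature_table",
    "generate_cohort",
    "NEUTRAL_LOSS_CARNITINE",
]

logger = logging.getLogger(__name__)

#: diagnostic neutral loss of acylcarnitines (trimethylamine + ..., Da)
NEUTRAL_LOSS_CARNITINE = 59.0747

#: 2log Cold/Heat effects of the verified/flagged urine metabolites
URINE_EFFECTS = [-0.73, -0.70, -0.89, -0.75, -2.40, -0.98, -0.92, -0.55,
                 -1.21, -0.53, -1.19, -0.23, -2.26, -0.66, 0.42]
#: 2log Cold/Heat effects of the standard-verified plasma metabolites
PLASMA_EFFECTS = [-0.96, -0.25, -0.44, -0.25, -0.65, -0.26, -0.23, -0.13]


@dataclass
class CohortConfig:
    """Design of one synthetic cohort; defaults mirror the study design."""

    n_cold: int = 20
    n_heat: int = 19
    # questionnaire
    n_items: int = 57
    n_constant_items: int = 15
    n_sparse_items: int = 8
    n_informative_items: int = 10
    item_effect: float = 2.0  # latent ordered-logit shift for informative items
    # clinical chemistry
    n_clinical: int = 40
    n_monotone_clinical: int = 4
    n_quadratic_clinical: int = 2
    clinical_effect: float = 1.5  # class mean shift in sd units
    # LC-MS
    n_features_urine: int = 300
    n_features_plasma: int = 200
    n_informative_features: int = len(URINE_EFFECTS)
    log2_effects: list[float] = field(default_factory=lambda: list(URINE_EFFECTS))
    missing_rate: float = 0.10
    n_qc: int = 8
    drift_slope: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_cold, self.n_heat, self.n_items, self.n_constant_items,
                  self.n_sparse_items, self.n_clinical, self.n_monotone_clinical,
                  self.n_quadratic_clinical, self.n_features_urine,
                  self.n_features_plasma, self.n_informative_features, self.n_qc]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_cold + self.n_heat < 8:
            raise ValueError("need at least 8 subjects")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_informative_features > min(self.n_features_urine, self.n_features_plasma):
            raise ValueError("more informative features than features")
        if len(self.log2_effects) != self.n_informative_features:
            raise ValueError("log2_effects must have one value per informative feature")
        if self.n_constant_items + self.n_sparse_items + self.n_informative_items > self.n_items:
            raise ValueError("item roles exceed n_items")
        if self.n_monotone_clinical + self.n_quadratic_clinical > self.n_clinical:
            raise ValueError("clinical roles exceed n_clinical")

    @property
    def n_subjects(self) -> int:
        return self.n_cold + self.n_heat

    def child_seed(self, stream: str) -> np.random.SeedSequence:
        offsets = {"questionnaire": 1, "clinical": 2, "urine": 3, "plasma": 4, "labels": 5}
        return np.random.SeedSequence([self.seed, offsets[stream]])


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    class_labels: pd.Series | None = None
    informative_item_ids: list[str] = field(default_factory=list)
    informative_clinical_ids: dict[str, str] = field(default_factory=dict)  # id -> relation
    informative_feature_ids: dict[str, float] = field(default_factory=dict)  # id -> 2log effect
    acylcarnitine_ids: dict[str, list[str]] = field(default_factory=dict)  # table -> ids

    def merged_with(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            class_labels=self.class_labels if self.class_labels is not None else other.class_labels,
            informative_item_ids=self.informative_item_ids + other.informative_item_ids,
            informative_clinical_ids={**self.informative_clinical_ids,
                                      **other.informative_clinical_ids},
            informative_feature_ids={**self.informative_feature_ids,
                                     **other.informative_feature_ids},
            acylcarnitine_ids={**self.acylcarnitine_ids, **other.acylcarnitine_ids},
        )

    def to_dict(self) -> dict:
        return {
            "class_labels": None if self.class_labels is None else self.class_labels.to_dict(),
            "informative_item_ids": self.informative_item_ids,
            "informative_clinical_ids": self.informative_clinical_ids,
            "informative_feature_ids": self.informative_feature_ids,
            "acylcarnitine_ids": self.acylcarnitine_ids,
        }


def _labels(config: CohortConfig) -> pd.Series:
    ids = [f"s{i+1:03d}" for i in range(config.n_subjects)]
    labels = ["Cold"] * config.n_cold + ["Heat"] * config.n_heat
    return pd.Series(labels, index=ids, name="class_label")


# ----------------------------------------------------------------------
def generate_questionnaire(config: CohortConfig) -> tuple[CategoricalDataset, SyntheticTruth]:
    """Subjects x items table of 1–7 severity scores.

    Informative items follow an ordered-logit model whose latent mean shifts
    by ``item_effect`` between the classes; exactly ``n_constant_items``
    columns are constant and exactly ``n_sparse_items`` columns contain a
    category observed fewer than 7 times.
    """
    rng = np.random.default_rng(config.child_seed("questionnaire"))
    labels = _labels(config)
    n = config.n_subjects
    z_class = (labels == "Heat").to_numpy().astype(float)  # Heat shifted up

    n_const, n_sparse = config.n_constant_items, config.n_sparse_items
    n_info = config.n_informative_items
    names = [f"v{k+1}" for k in range(config.n_items)]
    roles = (["constant"] * n_const + ["informative"] * n_info + ["sparse"] * n_sparse
             + ["noise"] * (config.n_items - n_const - n_sparse - n_info))
    rng.shuffle(roles)

    # symmetric thresholds for 7 categories on the logistic latent scale
    cuts = np.array([-3.0, -1.8, -0.6, 0.6, 1.8, 3.0])
    cols = {}
    truth = SyntheticTruth(class_labels=labels)
    for name, role in zip(names, roles):
        if role == "constant":
            cols[name] = np.ones(n, dtype=int)
            continue
        effect = config.item_effect if role == "informative" else 0.0
        if role == "informative":
            effect *= rng.choice([-1.0, 1.0])
            truth.informative_item_ids.append(name)
        latent = effect * (z_class - 0.5) + rng.logistic(0, 1, size=n)
        if abs(effect) > 2 * abs(cuts).max():
            logger.warning("item %s effect clamps the latent scale", name)
        codes = np.digitize(latent, cuts) + 1  # 1..7
        cols[name] = codes
        if role == "sparse":
            # force one category observed fewer than 7 times
            counts = np.bincount(codes, minlength=8)[1:]
            if not ((counts > 0) & (counts < 7)).any():
                codes = codes.copy()
                modal = int(np.argmax(counts)) + 1
                unused = np.flatnonzero(counts == 0)
                if unused.size:
                    # seed an unused code with 3 subjects from the modal one
                    idx = np.flatnonzero(codes == modal)[:3]
                    codes[idx] = int(unused[-1]) + 1
                else:
                    # all 7 codes dense: thin the smallest down to 6
                    small = int(np.argmin(counts)) + 1
                    idx = np.flatnonzero(codes == small)[: counts[small - 1] - 6]
                    codes[idx] = modal
                cols[name] = codes
        elif role in ("noise", "informative"):
            # keep non-sparse columns free of sparse categories by collapsing
            cols[name] = _densify(codes, min_count=7)

    data = pd.DataFrame(cols, index=labels.index)[names]
    specs = {name: ScalingSpec(analysis_level="ordinal", measurement_level="ordinal")
             for name in names}
    return CategoricalDataset(data, specs), truth


def _densify(codes: np.ndarray, min_count: int = 7) -> np.ndarray:
    """Collapse realized categories observed < min_count into a neighbour.

    Keeps at least two categories (splitting at the median if merging would
    collapse the column entirely), so designated non-sparse items are neither
    sparse nor constant.
    """
    codes = codes.copy()
    while True:
        cats = np.unique(codes)
        if len(cats) <= 1:
            break
        counts = {c: int((codes == c).sum()) for c in cats}
        sparse = [c for c in cats if counts[c] < min_count]
        if not sparse:
            return codes
        c = min(sparse, key=lambda c: (counts[c], c))
        pos = int(np.where(cats == c)[0][0])
        nbrs = [cats[i] for i in (pos - 1, pos + 1) if 0 <= i < len(cats)]
        tgt = min(nbrs, key=lambda t: (abs(t - c), t))
        codes[codes == c] = tgt
    # collapsed entirely: split at the median rank into two halves
    order = np.argsort(codes, kind="stable")
    out = np.ones_like(codes)
    out[order[len(codes) // 2:]] = 2
    return out


# ----------------------------------------------------------------------
def generate_clinical(config: CohortConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Continuous clinical chemistry table with planted class relationships.

    Monotone-informative variables shift the class means by
    ``clinical_effect`` standard deviations; quadratic-informative variables
    put the Heat class in both tails (|z| around ±2) and the Cold class in
    the middle, the pattern a nonmonotone spline transformation can pick up
    but a monotone one cannot.  The rest is standard normal noise.
    """
    rng = np.random.default_rng(config.child_seed("clinical"))
    labels = _labels(config)
    n = config.n_subjects
    heat = (labels == "Heat").to_numpy()

    names = [f"b{k+1}" for k in range(config.n_clinical)]
    roles = (["monotone"] * config.n_monotone_clinical
             + ["quadratic"] * config.n_quadratic_clinical
             + ["noise"] * (config.n_clinical - config.n_monotone_clinical
                            - config.n_quadratic_clinical))
    rng.shuffle(roles)

    truth = SyntheticTruth(class_labels=labels)
    cols = {}
    for name, role in zip(names, roles):
        if role == "monotone":
            sign = rng.choice([-1.0, 1.0])
            x = rng.normal(0, 1, n) + sign * config.clinical_effect * (heat - 0.5)
            truth.informative_clinical_ids[name] = "monotone"
        elif role == "quadratic":
            x = np.where(
                heat,
                rng.choice([-1.0, 1.0], size=n) * 2.0 + rng.normal(0, 0.5, n),
                rng.normal(0, 0.5, n),
            )
            truth.informative_clinical_ids[name] = "quadratic"
        else:
            x = rng.normal(0, 1, n)
        cols[name] = x
    return pd.DataFrame(cols, index=labels.index)[names], truth


# ----------------------------------------------------------------------
def generate_feature_table(
    config: CohortConfig, compartment: str = "urine"
) -> tuple[FeatureTable, SyntheticTruth]:
    """Samples x features LC-MS intensity table with QC replicates.

    Informative features carry the configured 2log Cold/Heat effects; an
    acylcarnitine-like family (first up to 13 informative features in urine)
    stores a fragment mass at precursor − 59.0747 with retention time
    strictly increasing with precursor mass.
    """
    if compartment not in ("urine", "plasma"):
        raise ValueError("compartment must be 'urine' or 'plasma'")
    if config.missing_rate >= 1:
        raise ValueError("missing_rate must be < 1")
    rng = np.random.default_rng(config.child_seed(compartment))
    labels = _labels(config)
    n = config.n_subjects
    n_feat = config.n_features_urine if compartment == "urine" else config.n_features_plasma
    cold = (labels == "Cold").to_numpy()

    # feature metadata
    mz = np.sort(rng.uniform(100, 1000, n_feat))
    rt = rng.uniform(0.5, 30.0, n_feat)
    ion_mode = rng.choice(["pos", "neg"], size=n_feat)

    info_idx = rng.choice(n_feat, size=config.n_informative_features, replace=False)
    effects = np.asarray(config.log2_effects, dtype=float)

    # acylcarnitine-like family among the informative features (urine, pos mode)
    fragments = ["" for _ in range(n_feat)]
    acyl_ids: list[int] = []
    if compartment == "urine" and len(info_idx) > 0:
        fam = info_idx[: min(13, len(info_idx))]
        fam_mz = np.sort(204.123 + 14.0157 * np.arange(len(fam)) + rng.uniform(0, 4, len(fam)))
        fam_rt = np.sort(2.0 + 0.8 * np.arange(len(fam)) + rng.uniform(0, 0.3, len(fam)))
        for j, (f, m, r) in enumerate(zip(fam, fam_mz, fam_rt)):
            mz[f] = m
            rt[f] = r
            ion_mode[f] = "pos"
            fragments[f] = repr(float(m - NEUTRAL_LOSS_CARNITINE))  # full precision
        acyl_ids = list(fam)

    feat_names = [f"F{mz[j]:.4f}_{rt[j]:.2f}" for j in range(n_feat)]

    # log-normal base intensities; Cold multiplied by 2**effect on informative
    base_log2 = rng.uniform(10, 20, n_feat)
    sigma = 0.8  # within-class 2log sd
    L = base_log2[None, :] + rng.normal(0, sigma, size=(n, n_feat))
    for e, j in zip(effects, info_idx):
        L[cold, j] += e
    X = np.exp2(L)

    # left-censoring at a detection limit: missing_rate quantile of 2log intensity
    if config.missing_rate > 0:
        lod = np.quantile(L, config.missing_rate)
        X[L < lod] = 0.0

    # QC samples: cohort mean profile + small noise, multiplicative drift
    n_qc = config.n_qc
    mean_profile = X.mean(axis=0)
    orders = [int(o) for o in rng.permutation(np.arange(n))]
    qc_rows = []
    for q in range(n_qc):
        noise = np.exp2(rng.normal(0, 0.05, n_feat))
        inj = n + q
        qc_rows.append(mean_profile * noise * (1.0 + config.drift_slope * inj))
        orders.append(inj)
    index = list(labels.index) + [f"QC{q+1:02d}" for q in range(n_qc)]
    full = np.vstack([X] + ([np.vstack(qc_rows)] if n_qc else []))

    sample_meta = pd.DataFrame(
        {
            "class_label": list(labels) + [None] * n_qc,
            "is_qc": [False] * n + [True] * n_qc,
            "injection_order": orders,
        },
        index=index,
    )
    feature_meta = pd.DataFrame(
        {"mz": mz, "rt": rt, "ion_mode": ion_mode, "fragments": fragments},
        index=feat_names,
    )
    table = FeatureTable(
        pd.DataFrame(full, index=index, columns=feat_names), sample_meta, feature_meta
    )
    truth = SyntheticTruth(
        class_labels=labels,
        informative_feature_ids={feat_names[j]: float(e) for j, e in zip(info_idx, effects)},
        acylcarnitine_ids={compartment: [feat_names[j] for j in acyl_ids]},
    )
    return table, truth


# ----------------------------------------------------------------------
def generate_cohort(config: CohortConfig):
    """Generate the full cohort: questionnaire, clinical, urine, plasma, truth.

    Returns ``(questionnaire, clinical, urine, plasma, truth)`` where the
    truth object merges the per-table ground truths.
    """
    q, t1 = generate_questionnaire(config)
    c, t2 = generate_clinical(config)
    u, t3 = generate_feature_table(config, "urine")
    p, t4 = generate_feature_table(config, "plasma")
    truth = t1.merged_with(t2).merged_with(t3).merged_with(t4)
    return q, c, u, p, truth
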