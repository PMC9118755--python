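"""Metrics, repeated cross-validation and the case-study ranking protocols.

Threshold metrics (accuracy, sensitivity, specificity, precision, F1, MCC)
are computed from confusion counts at a 0.5 probability cut; ranking quality
uses AUC (Mann-Whitney, ties counted 1/2) and AUPR (precision-recall step
integral).  ``cross_validate`` runs the full pipeline — similarity views,
representation learning, stacking ensemble — under repeated stratified
k-fold splits of the balanced pair set.  With ``leakage_safe`` on (the
default) the fold's held-out association cells are zeroed out of the
association matrix before the GIP/functional views and the reconstruction
loss are computed, so no test information reaches the embeddings; the
``paper_faithful`` alternative learns representations once from the full
matrix, matching the published pipeline order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .ensemble import (
    EnsembleConfig,
    PairDataset,
    build_pairs,
    fit_stacking,
    pair_features,
    predict_stacking,
)
from .io_formats import AssociationMatrix
from .representation import GcnConfig, train_representations
from .similarity import (
    SimilarityView,
    gip_similarity,
    lncrna_functional_similarity,
)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "CvPlan",
    "confusion_metrics",
    "rank_metrics",
    "cross_validate",
    "summarize_cv",
    "rank_candidates",
]

THRESHOLD_METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1", "mcc")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts sum to zero")

    @classmethod
    def from_predictions(cls, labels: np.ndarray, predicted: np.ndarray) -> "ConfusionCounts":
        labels = np.asarray(labels).astype(bool)
        predicted = np.asarray(predicted).astype(bool)
        return cls(
            tp=int((labels & predicted).sum()),
            fp=int((~labels & predicted).sum()),
            tn=int((~labels & ~predicted).sum()),
            fn=int((labels & ~predicted).sum()),
        )


@dataclass
class MetricReport:
    """Threshold and ranking metrics; undefined values stay None and flagged."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    mcc: float | None = None
    auc: float | None = None
    aupr: float | None = None
    undefined: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, float]:
        return {
            name: (np.nan if getattr(self, name) is None else getattr(self, name))
            for name in (*THRESHOLD_METRICS, "auc", "aupr")
        }


@dataclass
class CvPlan:
    """Repeated stratified k-fold plan (default: 5 repeats of 5-fold)."""

    k: int = 5
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")


def confusion_metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity, specificity, precision, F1 and MCC from counts.

    A zero denominator makes the metric undefined: it is reported as None
    and listed in ``undefined``, never coerced to 0.
    """
    report = MetricReport()

    def ratio(name: str, num: float, den: float) -> float | None:
        if den == 0:
            report.undefined.add(name)
            return None
        return num / den

    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    report.accuracy = ratio("accuracy", tn + tp, tn + tp + fn + fp)
    report.sensitivity = ratio("sensitivity", tp, tp + fn)
    report.specificity = ratio("specificity", tn, tn + fp)
    report.precision = ratio("precision", tp, tp + fp)
    if report.precision is None or report.sensitivity is None:
        report.undefined.add("f1")
    else:
        report.f1 = ratio(
            "f1", 2 * report.precision * report.sensitivity, report.precision + report.sensitivity
        )
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    if denom == 0:
        report.undefined.add("mcc")
    else:
        report.mcc = (tp * tn - fp * fn) / sqrt(denom)
    return report


def rank_metrics(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """(AUC, AUPR) of scores against binary labels; needs both classes."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("rank metrics require both classes to be present")
    return float(roc_auc_score(labels, scores)), float(
        average_precision_score(labels, scores)
    )


def evaluate_predictions(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> MetricReport:
    """Full metric report from probabilities: threshold metrics + AUC/AUPR."""
    counts = ConfusionCounts.from_predictions(labels, probabilities >= threshold)
    report = confusion_metrics(counts)
    report.auc, report.aupr = rank_metrics(labels, probabilities)
    return report


# ---------------------------------------------------------------------------
# Full-pipeline cross-validation
# ---------------------------------------------------------------------------

def _derived_views(
    ld: AssociationMatrix, dss: SimilarityView, lss: SimilarityView
) -> tuple[list[SimilarityView], list[SimilarityView]]:
    """The LD-dependent views (LFS, LGS, DGS) plus the static DSS/LSS."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lfs = lncrna_functional_similarity(ld, dss)
    lgs = gip_similarity(ld, "lncrna")
    dgs = gip_similarity(ld, "disease")
    return [lfs, lss, lgs], [dss, dgs]


def _balanced_cells(
    ld: AssociationMatrix, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """All positive cells plus an equal seeded sample of negatives."""
    pos = np.argwhere(ld.values == 1)
    neg_pool = np.argwhere(ld.values == 0)
    if len(neg_pool) < len(pos):
        raise ValueError("not enough unknown pairs to balance the positives")
    rng = np.random.default_rng(seed)
    neg = neg_pool[rng.choice(len(neg_pool), size=len(pos), replace=False)]
    cells = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return cells, labels


def cross_validate(
    ld: AssociationMatrix,
    dss: SimilarityView,
    lss: SimilarityView,
    plan: CvPlan,
    gcn_cfg: GcnConfig,
    ens_cfg: EnsembleConfig,
    shuffle_labels: bool = False,
) -> pd.DataFrame:
    """Repeated stratified k-fold CV of the whole pipeline.

    Returns one row per (repeat, fold) with all metrics.  ``shuffle_labels``
    permutes the pair labels before splitting — the resulting AUC should sit
    at chance and serves as a negative control.
    """
    rows = []
    for repeat in range(plan.repeats):
        seed_r = plan.seed + repeat
        cells, labels = _balanced_cells(ld, seed_r)
        if shuffle_labels:
            labels = np.random.default_rng(seed_r + 7919).permutation(labels)
        if not gcn_cfg.leakage_safe:
            views_l, views_d = _derived_views(ld, dss, lss)
            cfg_full = GcnConfig(**{**gcn_cfg.__dict__, "seed": seed_r % 2**31})
            x_full, y_full, _ = train_representations(views_l, views_d, ld, cfg_full)
        splitter = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=seed_r)
        for fold, (train_idx, test_idx) in enumerate(splitter.split(cells, labels)):
            if gcn_cfg.leakage_safe:
                test_cells = cells[test_idx]
                hide = np.zeros(ld.shape, dtype=bool)
                hide[test_cells[:, 0], test_cells[:, 1]] = True
                ld_train = ld.masked(hide)
                loss_mask = (~hide).astype(float)
                views_l, views_d = _derived_views(ld_train, dss, lss)
                cfg_fold = GcnConfig(
                    **{**gcn_cfg.__dict__, "seed": (seed_r * 1009 + fold) % 2**31}
                )
                x, y, _ = train_representations(
                    views_l, views_d, ld_train, cfg_fold, loss_mask=loss_mask
                )
            else:
                x, y = x_full, y_full
            feats = pair_features(x, y, cells)
            train = PairDataset(
                feats[train_idx],
                labels[train_idx],
                [("", "")] * len(train_idx),
            )
            fold_cfg = EnsembleConfig(
                learner_params=ens_cfg.learner_params,
                meta_params=ens_cfg.meta_params,
                learners=ens_cfg.learners,
                n_folds=ens_cfg.n_folds,
                seed=(seed_r * 31 + fold) % 2**31,
            )
            model = fit_stacking(train, fold_cfg)
            probs, _ = predict_stacking(model, feats[test_idx])
            report = evaluate_predictions(labels[test_idx], probs)
            rows.append({"repeat": repeat, "fold": fold, **report.as_dict()})
    return pd.DataFrame(rows)


def summarize_cv(table: pd.DataFrame) -> pd.Series:
    """Mean of each metric over all folds and repeats (NaN-aware)."""
    return table.drop(columns=["repeat", "fold"]).mean()


# ---------------------------------------------------------------------------
# Case-study ranking protocols
# ---------------------------------------------------------------------------

def rank_candidates(
    disease: str,
    mode: str,
    ld: AssociationMatrix,
    dss: SimilarityView,
    lss: SimilarityView,
    gcn_cfg: GcnConfig,
    ens_cfg: EnsembleConfig,
    top_n: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank candidate lncRNAs for one disease.

    ``unknown_only``: train on all known associations plus matched negatives
    that never involve the disease, then score only the disease's unknown
    pairs (known partners are excluded from the ranking).
    ``leave_disease_out``: first delete every association of the disease so
    it behaves like a new disease, then score all lncRNAs against it.
    Ties are broken by score descending, then lncRNA id ascending.
    """
    if disease not in ld.disease_ids:
        raise KeyError(f"unknown disease id {disease!r}")
    if mode not in ("unknown_only", "leave_disease_out"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    col = ld.disease_index(disease)

    if mode == "leave_disease_out":
        hide = np.zeros(ld.shape, dtype=bool)
        hide[:, col] = True
        ld_train = ld.masked(hide)
        test_rows = np.arange(ld.shape[0])
    else:
        ld_train = ld
        test_rows = np.flatnonzero(ld.values[:, col] == 0)

    views_l, views_d = _derived_views(ld_train, dss, lss)
    cfg = GcnConfig(**{**gcn_cfg.__dict__, "seed": seed % 2**31})
    x, y, _ = train_representations(views_l, views_d, ld_train, cfg)
    train = build_pairs(x, y, ld_train, seed=seed, exclude_diseases=[disease])
    model = fit_stacking(
        train,
        EnsembleConfig(
            learner_params=ens_cfg.learner_params,
            meta_params=ens_cfg.meta_params,
            learners=ens_cfg.learners,
            n_folds=ens_cfg.n_folds,
            seed=seed % 2**31,
        ),
    )
    test_cells = np.column_stack([test_rows, np.full(len(test_rows), col)])
    probs, _ = predict_stacking(model, pair_features(x, y, test_cells))
    table = pd.DataFrame(
        {"lncrna_id": [ld.lncrna_ids[i] for i in test_rows], "score": probs}
    )
    table = table.sort_values(
        ["score", "lncrna_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table.head(top_n)
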