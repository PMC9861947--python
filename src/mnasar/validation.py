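"""Accuracy estimation: IAP (= ROC AUC) under analytic LOO and seeded k-fold CV.

IAP — invariant accuracy of prediction — is the probability that a randomly
chosen active outscores a randomly chosen inactive, with half credit for
ties; numerically it is the area under the ROC curve.  It is computed here by
midrank statistics in O(n log n) and is invariant under any strictly monotone
transform of the scores.

Leave-one-out IAP falls straight out of a trained model's calibration arrays
(those *are* the LOO scores of all training compounds).  k-fold IAP partitions
compounds into seeded, label-stratified folds, trains on the remainder of each
fold, and pools the out-of-fold scores into a single IAP — pooling keeps the
estimate stable for activities with few actives.  With k = N the folds have
size one and pooled k-fold IAP coincides with analytic LOO IAP exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import LabeledSet
from .mna import DescriptorSet
from .model import ModelConfig, SarModel, train

log = logging.getLogger(__name__)

__all__ = ["iap", "loo_iap", "kfold_iap", "ReportRow", "ValidationReport", "validate", "select_activities"]

DEFAULT_K = 20
DEFAULT_AUC_THRESHOLD = 0.8


def iap(scores_active, scores_inactive) -> float:
    """Probability that an active outscores an inactive, ties at half credit.

    Equals (#{pairs s_act > s_inact} + 0.5 * #{tied pairs}) / (n_act * n_inact),
    computed via sorted-array rank positions rather than the quadratic pair loop.
    """
    a = np.asarray(scores_active, dtype=float)
    b = np.sort(np.asarray(scores_inactive, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("iap requires at least one score in each class")
    lo = np.searchsorted(b, a, side="left")   # inactives strictly below each active
    hi = np.searchsorted(b, a, side="right")  # plus ties
    wins = lo.sum() + 0.5 * (hi - lo).sum()
    return float(wins / (a.size * b.size))


def loo_iap(model: SarModel, activity_id: str) -> float:
    """Analytic leave-one-out IAP of one trained activity."""
    stats = model.activities[activity_id]
    if stats.cal_active.size == 0 or stats.cal_inactive.size == 0:
        raise ValueError(f"model for {activity_id!r} carries no calibration arrays")
    return iap(stats.cal_active, stats.cal_inactive)


def _stratified_folds(actives: list[str], inactives: list[str], k: int, rng: np.random.Generator) -> dict[str, int]:
    """Fold index per compound: each class is shuffled, then dealt round-robin.

    The deal continues across classes (inactives pick up where the actives
    stopped), so fold sizes stay balanced and k = N yields singleton folds.
    """
    act = list(actives)
    rng.shuffle(act)
    ina = list(inactives)
    rng.shuffle(ina)
    return {cid: i % k for i, cid in enumerate(act + ina)}


def kfold_iap(
    labeled: LabeledSet,
    features: dict[str, DescriptorSet],
    config: ModelConfig | None = None,
    k: int = DEFAULT_K,
    seed: int = 0,
) -> float:
    """Pooled k-fold cross-validated IAP for one activity.

    Folds are label-stratified and fully determined by ``seed``.  A fold whose
    training remainder loses either class is skipped with a warning.  ``k``
    larger than the corpus collapses to leave-one-out.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or ModelConfig()
    actives = labeled.actives
    inactives = labeled.inactives
    k = min(k, len(labeled.members))
    if min(len(actives), len(inactives)) < k:
        log.warning(
            "activity %r: a class has fewer members (%d actives / %d inactives) than k=%d; "
            "stratification degrades to best effort",
            labeled.activity_id, len(actives), len(inactives), k,
        )
    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(actives, inactives, k, rng)

    pooled_active: list[float] = []
    pooled_inactive: list[float] = []
    for fold in range(k):
        test = [cid for cid, _ in labeled.members if fold_of[cid] == fold]
        if not test:
            continue
        train_members = tuple((cid, act) for cid, act in labeled.members if fold_of[cid] != fold)
        n_tr_act = sum(1 for _, act in train_members if act)
        if n_tr_act == 0 or n_tr_act == len(train_members):
            log.warning("activity %r: fold %d training set lost a class; fold skipped", labeled.activity_id, fold)
            continue
        # min_actives is a curation gate, not a per-fold one; folds may dip below it
        fold_cfg = ModelConfig(
            max_level=config.max_level,
            regularization=config.regularization,
            min_actives=1,
            ruleset=config.ruleset,
        )
        sub = LabeledSet(activity_id=labeled.activity_id, members=train_members)
        model = train([sub], features, fold_cfg, compute_calibration=False)
        is_active = dict(labeled.members)
        for cid in test:
            s = model.score(features[cid], labeled.activity_id)
            (pooled_active if is_active[cid] else pooled_inactive).append(s)
    return iap(pooled_active, pooled_inactive)


@dataclass(frozen=True)
class ReportRow:
    activity_id: str
    n_active: int
    n_inactive: int
    iap_loo: float
    iap_kfold: float
    selected: bool


@dataclass
class ValidationReport:
    """Per-activity accuracy table plus the run's resolved parameters."""

    rows: list[ReportRow]
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def mean_iap(self, selected_only: bool = True, which: str = "iap_loo") -> float:
        vals = [getattr(r, which) for r in self.rows if r.selected or not selected_only]
        if not vals:
            return float("nan")
        return float(np.mean(vals))


def validate(
    labeled: list[LabeledSet],
    features: dict[str, DescriptorSet],
    config: ModelConfig | None = None,
    *,
    k: int = DEFAULT_K,
    seed: int = 0,
    auc_threshold: float = DEFAULT_AUC_THRESHOLD,
) -> ValidationReport:
    """Train, cross-validate and report every activity.

    ``selected`` is a strictly-greater-than filter on the LOO IAP: an activity
    at exactly the threshold is not selected.
    """
    config = config or ModelConfig()
    model = train(labeled, features, config)
    rows = []
    for ls in labeled:
        if ls.activity_id not in model.activities:
            continue
        il = loo_iap(model, ls.activity_id)
        ik = kfold_iap(ls, features, config, k=k, seed=seed)
        rows.append(
            ReportRow(
                activity_id=ls.activity_id,
                n_active=ls.n_active,
                n_inactive=model.N - model.activities[ls.activity_id].n_a,
                iap_loo=il,
                iap_kfold=ik,
                selected=il > auc_threshold,
            )
        )
    metadata = {
        "k": k,
        "seed": seed,
        "auc_threshold": auc_threshold,
        "min_actives": config.min_actives,
        "max_level": config.max_level,
        "regularization": config.regularization,
    }
    return ValidationReport(rows=rows, metadata=metadata)


def select_activities(report: ValidationReport, auc_threshold: float = DEFAULT_AUC_THRESHOLD) -> list[str]:
    """Activities whose LOO IAP strictly exceeds the threshold (default 0.8)."""
    return [r.activity_id for r in report.rows if r.iap_loo > auc_threshold]
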