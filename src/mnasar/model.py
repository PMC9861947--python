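"""Naive-Bayes SAR model with rank-calibrated Pa/Pi outputs.

The model tabulates, over a training corpus of N compounds represented by
their unique-descriptor sets, the number of compounds n_d containing each
descriptor d and, per activity a, the number of actives n_a and the number of
actives containing d, n_da.  Compounds not labeled active for an activity are
its inactives: inactivity is the absence of evidence of activity, mirroring
how cytotoxicity and mechanism-of-action corpora are curated.

Scoring.  The per-descriptor conditional probability of activity is the
regularized estimate

    p_da = (n_da + c * p_a) / (n_d + c),      p_a = n_a / N,  c = 1 by default,

and a compound x scores the arcsine-stabilized mean

    s(x, a) = mean over d in D(x) ∩ vocabulary of  arcsin(2 * p_da - 1),

falling back to arcsin(2 * p_a - 1) when the intersection is empty, so
arbitrary novel structures still get a (prior-level) score.

Calibration.  Pa and Pi are rank positions of the query score within the
*leave-one-out* score distributions of the training actives and inactives:

    Pa = (#{LOO-active scores < s} + 0.5 * ties) / n_a
    Pi = (#{LOO-inactive scores > s} + 0.5 * ties) / (N - n_a)

LOO scores (each training compound scored with its own contributions removed
from every count) are computed analytically and are exactly what retraining
without the compound would give.  Calibrating against LOO rather than plain
training scores is what makes the Pa of a typical training active uniform on
[0, 1] — so a Pa > 0.7 selection filter loses about 70% of true actives, a
Pa > 0.5 filter about half.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .curation import LabeledSet
from .mna import DescriptorSet, DEFAULT_MAX_LEVEL

log = logging.getLogger(__name__)

__all__ = ["ModelConfig", "ActivityStats", "Prediction", "SarModel", "train"]

MODEL_FORMAT = "mnasar-model"
MODEL_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Training configuration carried inside the model file."""

    max_level: int = DEFAULT_MAX_LEVEL
    regularization: float = 1.0   # c in p_da = (n_da + c*p_a)/(n_d + c); keeps arcsin off its poles
    min_actives: int = 3
    ruleset: str = ""             # provenance note only

    def __post_init__(self):
        if self.regularization <= 0:
            raise ValueError("regularization must be > 0")


@dataclass
class ActivityStats:
    """Per-activity counts and LOO-score calibration arrays."""

    n_a: int
    n_da: dict[str, int]
    cal_active: np.ndarray    # sorted LOO scores of the n_a training actives
    cal_inactive: np.ndarray  # sorted LOO scores of the N - n_a training inactives


@dataclass(frozen=True)
class Prediction:
    activity_id: str
    score: float
    pa: float
    pi: float


def _mean_arcsin_score(
    descriptors,
    *,
    N: int,
    n_a: int,
    c: float,
    n_d_lookup,
    n_da_lookup,
) -> float:
    """s(x,a) over descriptors whose training count is positive; prior fallback otherwise."""
    p_a = n_a / N
    total = 0.0
    k = 0
    for d in descriptors:
        n_d = n_d_lookup(d)
        if n_d <= 0:
            continue  # outside the (possibly reduced) vocabulary
        p_da = (n_da_lookup(d) + c * p_a) / (n_d + c)
        total += math.asin(2.0 * p_da - 1.0)
        k += 1
    if k == 0:
        return math.asin(2.0 * p_a - 1.0)
    return total / k


class SarModel:
    """Trained descriptor -> activity predictor.

    Attributes
    ----------
    N : total number of training compounds.
    n_d : per-descriptor compound counts over the whole corpus (the vocabulary).
    activities : per-activity :class:`ActivityStats`.
    config : :class:`ModelConfig`.
    """

    def __init__(self, N: int, n_d: dict[str, int], activities: dict[str, ActivityStats], config: ModelConfig):
        self.N = N
        self.n_d = n_d
        self.activities = activities
        self.config = config

    # ------------------------------------------------------------------ scoring

    def score(self, x: DescriptorSet, activity_id: str) -> float:
        """Evidence score of a query for one activity; unseen descriptors are ignored."""
        stats = self._stats(activity_id)
        return _mean_arcsin_score(
            sorted(x.descriptors),
            N=self.N,
            n_a=stats.n_a,
            c=self.config.regularization,
            n_d_lookup=lambda d: self.n_d.get(d, 0),
            n_da_lookup=lambda d: stats.n_da.get(d, 0),
        )

    def loo_score(self, x: DescriptorSet, activity_id: str, is_active: bool) -> float:
        """Score of a *training* compound with its own contributions removed.

        Removing x decrements N, decrements n_d for every descriptor x
        contains, and (iff x is active) decrements n_a and the n_da of x's
        descriptors.  A descriptor whose remaining count reaches zero is
        excluded — it would not be in the vocabulary of a model trained
        without x — so this exactly equals retraining without the compound.
        """
        stats = self._stats(activity_id)
        N1 = self.N - 1
        if N1 <= 0:
            raise ValueError("cannot leave one out of a single-compound corpus")
        act = 1 if is_active else 0
        n_a1 = stats.n_a - act
        if n_a1 == 0:
            log.debug("LOO of %s leaves activity %r with zero actives; degenerate prior", x.source_id, activity_id)
        dset = set(x.descriptors)
        return _mean_arcsin_score(
            sorted(dset),
            N=N1,
            n_a=n_a1,
            c=self.config.regularization,
            n_d_lookup=lambda d: self.n_d.get(d, 0) - 1,  # d in D(x), so x counted in n_d
            n_da_lookup=lambda d: stats.n_da.get(d, 0) - act,
        )

    def predict(self, x: DescriptorSet, activities: list[str] | None = None) -> list[Prediction]:
        """Per-activity (score, Pa, Pi), sorted by Pa - Pi descending.

        The more probable activities come first; ties break on activity id so
        output is deterministic.
        """
        if len(x) == 0:
            raise ValueError("cannot predict for an empty descriptor set")
        names = sorted(self.activities) if activities is None else list(activities)
        preds = []
        for aid in names:
            stats = self._stats(aid)
            s = self.score(x, aid)
            pa = _rank_position_below(stats.cal_active, s)
            pi = _rank_position_above(stats.cal_inactive, s)
            preds.append(Prediction(activity_id=aid, score=s, pa=pa, pi=pi))
        preds.sort(key=lambda p: (-(p.pa - p.pi), p.activity_id))
        return preds

    def loo_pa_of_actives(self, activity_id: str) -> np.ndarray:
        """LOO-predicted Pa of every training active (its LOO score ranked in the calibration)."""
        stats = self._stats(activity_id)
        return np.array([_rank_position_below(stats.cal_active, s) for s in stats.cal_active])

    def _stats(self, activity_id: str) -> ActivityStats:
        try:
            return self.activities[activity_id]
        except KeyError:
            raise KeyError(f"unknown activity {activity_id!r}") from None

    # ------------------------------------------------------------ serialization

    def save(self, path) -> None:
        """Write the versioned, self-describing JSON model file."""
        payload = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "config": asdict(self.config),
            "N": self.N,
            "n_d": self.n_d,
            "activities": {
                aid: {
                    "n_a": st.n_a,
                    "n_da": st.n_da,
                    "cal_active": st.cal_active.tolist(),
                    "cal_inactive": st.cal_inactive.tolist(),
                }
                for aid, st in self.activities.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SarModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != MODEL_FORMAT:
            raise ValueError(f"{path}: not a {MODEL_FORMAT} file")
        if payload.get("version") != MODEL_VERSION:
            raise ValueError(f"{path}: unsupported model version {payload.get('version')}")
        activities = {
            aid: ActivityStats(
                n_a=st["n_a"],
                n_da={k: int(v) for k, v in st["n_da"].items()},
                cal_active=np.array(st["cal_active"], dtype=float),
                cal_inactive=np.array(st["cal_inactive"], dtype=float),
            )
            for aid, st in payload["activities"].items()
        }
        return cls(
            N=int(payload["N"]),
            n_d={k: int(v) for k, v in payload["n_d"].items()},
            activities=activities,
            config=ModelConfig(**payload["config"]),
        )


def _rank_position_below(sorted_scores: np.ndarray, s: float) -> float:
    """(#scores < s + 0.5 * ties) / n — the Pa-style rank position."""
    n = len(sorted_scores)
    lo = int(np.searchsorted(sorted_scores, s, side="left"))
    hi = int(np.searchsorted(sorted_scores, s, side="right"))
    return (lo + 0.5 * (hi - lo)) / n


def _rank_position_above(sorted_scores: np.ndarray, s: float) -> float:
    """(#scores > s + 0.5 * ties) / n — the Pi-style rank position."""
    n = len(sorted_scores)
    lo = int(np.searchsorted(sorted_scores, s, side="left"))
    hi = int(np.searchsorted(sorted_scores, s, side="right"))
    return ((n - hi) + 0.5 * (hi - lo)) / n


def train(
    labeled: list[LabeledSet],
    features: dict[str, DescriptorSet],
    config: ModelConfig | None = None,
    *,
    compute_calibration: bool = True,
) -> SarModel:
    """Train the Bayesian model on curated labeled sets.

    The corpus is the union of all compounds across labeled sets; a compound
    not listed active for an activity counts as inactive for it.  Activities
    with fewer than ``config.min_actives`` actives or without a single
    inactive are excluded (logged); if all are excluded, training fails.
    With ``compute_calibration`` (the default) the per-activity LOO score
    distributions are computed and stored; cross-validation loops that only
    need raw scores can switch it off.
    """
    config = config or ModelConfig()
    corpus: set[str] = set()
    for ls in labeled:
        corpus.update(cid for cid, _ in ls.members)
    missing = sorted(cid for cid in corpus if cid not in features)
    if missing:
        raise ValueError(f"{len(missing)} labeled compounds lack descriptor sets, e.g. {missing[:3]}")
    corpus_ids = sorted(corpus)
    N = len(corpus_ids)
    if N < 2:
        raise ValueError("training requires at least two compounds")

    n_d: dict[str, int] = {}
    for cid in corpus_ids:
        for d in features[cid].descriptors:
            n_d[d] = n_d.get(d, 0) + 1

    activities: dict[str, ActivityStats] = {}
    for ls in labeled:
        active_ids = set(ls.actives)
        n_a = len(active_ids)
        n_inact = N - n_a
        if n_a < config.min_actives or n_inact == 0:
            log.info(
                "activity %r excluded from training: %d actives (min %d), %d inactives",
                ls.activity_id, n_a, config.min_actives, n_inact,
            )
            continue
        n_da: dict[str, int] = {}
        for cid in active_ids:
            for d in features[cid].descriptors:
                n_da[d] = n_da.get(d, 0) + 1
        activities[ls.activity_id] = ActivityStats(
            n_a=n_a,
            n_da=n_da,
            cal_active=np.empty(0),
            cal_inactive=np.empty(0),
        )

    if not activities:
        raise ValueError("every activity was excluded from training (too few actives or no inactives)")

    model = SarModel(N=N, n_d=n_d, activities=activities, config=config)

    if compute_calibration:
        by_id = {ls.activity_id: ls for ls in labeled}
        for aid, stats in activities.items():
            act_ids = set(by_id[aid].actives)
            sa, si = [], []
            for cid in corpus_ids:
                is_active = cid in act_ids
                s = model.loo_score(features[cid], aid, is_active)
                (sa if is_active else si).append(s)
            stats.cal_active = np.sort(np.array(sa))
            stats.cal_inactive = np.sort(np.array(si))

    return model
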