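"""Training-set curation: raw activity tables to per-activity binary labels.

Two rulesets are implemented:

* CHEMBL_PUBCHEM — potency endpoints (IC50/GI50/Ki/Kact) converted to nM;
  a compound is active when the value is strictly below 10,000 nM, or when
  percent inhibition strictly exceeds 50%.  Everything tested but not active
  is inactive.
* NCI60 — growth-inhibition screens expressed as -log10(GI50).  Rows carrying
  a failure reason are deleted; replicate values per compound x cell line are
  aggregated (median by default) and the compound is active when the aggregate
  is >= 9, 8 or 7 for the 1 nM, 10 nM and 100 nM thresholds respectively.

Conflicts between records of one compound for one activity resolve
active-wins: inactivity is only the absence of any qualifying active
measurement, so row order never matters.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Endpoint",
    "Ruleset",
    "Nci60Threshold",
    "Label",
    "ActivityRecord",
    "LabeledSet",
    "CurationSummary",
    "to_nanomolar",
    "label_record",
    "aggregate_nci60",
    "normalize_activity_name",
    "build_labeled_sets",
]

ACTIVE_POTENCY_NM = 10_000.0       # active iff potency < 10,000 nM (strict)
ACTIVE_INHIBITION_PCT = 50.0       # active iff % inhibition > 50 (strict)
NEG_LOG_GI50_SANITY = (0.0, 15.0)  # plausible -log10(GI50 in M) window


class Endpoint(str, enum.Enum):
    IC50 = "IC50"
    GI50 = "GI50"
    KI = "Ki"
    KACT = "Kact"
    PCT_INHIBITION = "PCT_INHIBITION"
    NEG_LOG_GI50 = "NEG_LOG_GI50"


POTENCY_ENDPOINTS = {Endpoint.IC50, Endpoint.GI50, Endpoint.KI, Endpoint.KACT}


class Ruleset(str, enum.Enum):
    CHEMBL_PUBCHEM = "chembl_pubchem"
    NCI60 = "nci60"


class Nci60Threshold(str, enum.Enum):
    """Potency threshold of the NCI60 labeling: active iff -log10(GI50) >= cutoff."""

    NM_1 = "1nM"
    NM_10 = "10nM"
    NM_100 = "100nM"

    @property
    def neg_log_cutoff(self) -> float:
        return {"1nM": 9.0, "10nM": 8.0, "100nM": 7.0}[self.value]


class Label(str, enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    DROPPED = "dropped"


_UNIT_TO_NM = {
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,   # µM
    "μm": 1e3,   # μM (Greek mu)
    "mm": 1e6,
    "m": 1e9,
}


def to_nanomolar(value: float, units: str) -> float:
    """Convert a molar concentration to nM; conversions are exact powers of 10."""
    key = units.strip().lower()
    if key not in _UNIT_TO_NM:
        raise ValueError(f"unrecognized concentration units: {units!r}")
    return value * _UNIT_TO_NM[key]


@dataclass(frozen=True)
class ActivityRecord:
    """One experimental measurement of one compound against one activity."""

    compound_id: str
    activity_id: str
    endpoint: Endpoint
    value: float
    units: str = "nM"
    failure_reason: str = ""

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite value for {self.compound_id}/{self.activity_id}")
        ep = Endpoint(self.endpoint)
        object.__setattr__(self, "endpoint", ep)
        if ep is Endpoint.PCT_INHIBITION:
            if self.units.strip() not in ("%", "percent", ""):
                raise ValueError(f"% inhibition must carry percent units, got {self.units!r}")
        elif ep is Endpoint.NEG_LOG_GI50:
            pass  # dimensionless
        else:
            to_nanomolar(1.0, self.units)  # validates units


@dataclass(frozen=True)
class LabeledSet:
    """Per-activity binary labels after curation; one label per compound."""

    activity_id: str
    members: tuple[tuple[str, bool], ...]  # (compound_id, is_active)

    def __post_init__(self):
        ids = [cid for cid, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate compound ids in LabeledSet {self.activity_id!r}")

    @property
    def actives(self) -> list[str]:
        return [cid for cid, act in self.members if act]

    @property
    def inactives(self) -> list[str]:
        return [cid for cid, act in self.members if not act]

    @property
    def n_active(self) -> int:
        return sum(1 for _, act in self.members if act)

    @property
    def n_inactive(self) -> int:
        return len(self.members) - self.n_active


@dataclass
class CurationSummary:
    """Record-level accounting per activity: every input row lands in exactly one bucket."""

    rows: list[dict] = field(default_factory=list)

    def as_records(self) -> list[dict]:
        return list(self.rows)


def label_record(
    rec: ActivityRecord,
    ruleset: Ruleset | str,
    nci60_threshold: Nci60Threshold | str | None = None,
) -> Label:
    """Label one measurement under the given ruleset.

    Boundary semantics are deliberate: potency exactly at 10,000 nM is
    inactive, inhibition exactly at 50% is inactive, and -log10(GI50) exactly
    at the NCI60 cutoff is active.
    """
    ruleset = Ruleset(ruleset)
    if ruleset is Ruleset.NCI60:
        if nci60_threshold is None:
            raise ValueError("NCI60 ruleset requires an nci60_threshold")
        threshold = Nci60Threshold(nci60_threshold)
        if rec.failure_reason.strip():
            return Label.DROPPED
        if rec.endpoint is not Endpoint.NEG_LOG_GI50:
            raise ValueError(f"NCI60 ruleset expects NEG_LOG_GI50 records, got {rec.endpoint}")
        lo, hi = NEG_LOG_GI50_SANITY
        if not lo <= rec.value <= hi:
            log.warning(
                "dropping %s/%s: -log10 GI50 %.3g outside sanity window [%g, %g]",
                rec.compound_id, rec.activity_id, rec.value, lo, hi,
            )
            return Label.DROPPED
        return Label.ACTIVE if rec.value >= threshold.neg_log_cutoff else Label.INACTIVE
    if nci60_threshold is not None:
        raise ValueError("nci60_threshold only applies to the NCI60 ruleset")
    if rec.endpoint is Endpoint.PCT_INHIBITION:
        return Label.ACTIVE if rec.value > ACTIVE_INHIBITION_PCT else Label.INACTIVE
    if rec.endpoint in POTENCY_ENDPOINTS:
        return Label.ACTIVE if to_nanomolar(rec.value, rec.units) < ACTIVE_POTENCY_NM else Label.INACTIVE
    raise ValueError(f"endpoint {rec.endpoint} not supported under {ruleset.value}")


def aggregate_nci60(values: list[float], method: str = "median") -> float:
    """Aggregate replicate -log10(GI50) values for one compound x cell line."""
    if not values:
        raise ValueError("no retained replicate values to aggregate")
    if method == "median":
        return float(np.median(values))
    if method == "mean":
        return float(np.mean(values))
    raise ValueError(f"unknown aggregation method {method!r}")


_NORM_STRIP = re.compile(r"[\s\-_./()]+")


def normalize_activity_name(raw: str, synonym_table: dict[str, str] | None = None) -> str:
    """Standardize an activity (cell line / mechanism) name.

    The lookup key is case-folded with whitespace and common punctuation
    removed, then mapped through the user-supplied synonym table (whose keys
    are normalized the same way).  Unmapped names pass through with outer and
    repeated whitespace collapsed, and are logged.
    """
    key = _NORM_STRIP.sub("", raw).casefold()
    if synonym_table:
        table = {_NORM_STRIP.sub("", k).casefold(): v for k, v in synonym_table.items()}
        if key in table:
            return table[key]
    cleaned = " ".join(raw.split())
    if synonym_table:
        log.debug("activity name %r not in synonym table; passing through as %r", raw, cleaned)
    return cleaned


def build_labeled_sets(
    records: list[ActivityRecord],
    ruleset: Ruleset | str,
    min_actives: int = 3,
    *,
    nci60_threshold: Nci60Threshold | str | None = None,
    synonym_table: dict[str, str] | None = None,
    aggregation: str = "median",
) -> tuple[list[LabeledSet], CurationSummary]:
    """Turn raw measurements into per-activity labeled sets.

    NCI60 replicates are aggregated per compound x activity before
    thresholding; under CHEMBL_PUBCHEM each record is labeled independently
    and per-compound conflicts resolve active-wins.  Activities with fewer
    than ``min_actives`` actives or with no inactive are omitted (logged).
    Returns the surviving sets sorted by activity id plus a record-level
    accounting summary.
    """
    ruleset = Ruleset(ruleset)
    by_activity: dict[str, list[ActivityRecord]] = {}
    for rec in records:
        name = normalize_activity_name(rec.activity_id, synonym_table)
        by_activity.setdefault(name, []).append(rec)

    sets: list[LabeledSet] = []
    summary = CurationSummary()
    for activity_id in sorted(by_activity):
        recs = by_activity[activity_id]
        n_rec_active = n_rec_inactive = n_rec_dropped = 0
        compound_active: dict[str, bool] = {}
        if ruleset is Ruleset.NCI60:
            retained: dict[str, list[float]] = {}
            for rec in recs:
                lab = label_record(rec, ruleset, nci60_threshold)
                if lab is Label.DROPPED:
                    n_rec_dropped += 1
                    continue
                if lab is Label.ACTIVE:
                    n_rec_active += 1
                else:
                    n_rec_inactive += 1
                retained.setdefault(rec.compound_id, []).append(rec.value)
            cutoff = Nci60Threshold(nci60_threshold).neg_log_cutoff
            for cid, vals in retained.items():
                compound_active[cid] = aggregate_nci60(vals, aggregation) >= cutoff
        else:
            for rec in recs:
                lab = label_record(rec, ruleset)
                if lab is Label.ACTIVE:
                    n_rec_active += 1
                    compound_active[rec.compound_id] = True
                else:
                    n_rec_inactive += 1
                    compound_active.setdefault(rec.compound_id, False)

        members = tuple(sorted(compound_active.items()))
        n_active = sum(1 for _, a in members if a)
        n_inactive = len(members) - n_active
        kept = n_active >= min_actives and n_inactive >= 1
        summary.rows.append(
            {
                "activity_id": activity_id,
                "n_active": n_active,
                "n_inactive": n_inactive,
                "n_records_active": n_rec_active,
                "n_records_inactive": n_rec_inactive,
                "n_records_dropped": n_rec_dropped,
                "kept": kept,
            }
        )
        if kept:
            sets.append(LabeledSet(activity_id=activity_id, members=members))
        else:
            log.info(
                "activity %r omitted: %d actives (min %d), %d inactives",
                activity_id, n_active, min_actives, n_inactive,
            )

    if not sets:
        raise ValueError(
            "no activity survived curation; summary: "
            + "; ".join(f"{r['activity_id']}: {r['n_active']}a/{r['n_inactive']}i" for r in summary.rows)
        )
    return sets, summary
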