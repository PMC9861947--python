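"""Synthetic fixtures: descriptor sets and molecules with planted structure-activity signal.

Two generators, both driven by a single seeded :class:`numpy.random.Generator`:

* :func:`make_descriptor_dataset` — the primary test substrate.  Each compound
  is a random subset of an abstract descriptor vocabulary drawn by independent
  per-item inclusion; a block of *enriched* items is included with a higher
  probability in actives than in inactives, planting a signal of exactly known
  strength.  Labels are exact by construction.

* :func:`make_smiles_dataset` — an end-to-end smoke layer.  Small druglike
  SMILES are assembled from a fixed fragment library; actives carry a planted
  sulfonamide substructure, so the full parse -> descriptor -> model path can
  recover the signal.  The accompanying activity table uses IC50 values that
  round-trip cleanly through curation.

Defaults mimic a mid-sized single-activity cytotoxicity training set: 300
actives against 1200 inactives over a 500-item vocabulary, 10 enriched items
at inclusion probabilities 0.9 (actives) vs 0.1 (inactives) on a 0.05
background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chem import parse_structure
from .curation import LabeledSet
from .mna import DescriptorSet

__all__ = ["SynthConfig", "make_descriptor_dataset", "make_smiles_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    n_active: int = 300
    n_inactive: int = 1200
    vocab_size: int = 500
    n_enriched: int = 10
    p_enriched_in_active: float = 0.9
    p_enriched_in_inactive: float = 0.1
    p_background: float = 0.05
    seed: int = 0
    activity_id: str = "SYNTH-CYTOTOX"

    def __post_init__(self):
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("both classes must be non-empty")
        if not 0 < self.n_enriched <= self.vocab_size:
            raise ValueError("n_enriched must be in 1..vocab_size")
        for p in (self.p_enriched_in_active, self.p_enriched_in_inactive, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def make_descriptor_dataset(cfg: SynthConfig) -> tuple[dict[str, DescriptorSet], LabeledSet]:
    """Draw a labeled descriptor-level dataset; byte-identical for a given seed."""
    rng = np.random.default_rng(cfg.seed)
    vocab = np.array([f"D{i:04d}" for i in range(cfg.vocab_size)])
    p_active = np.full(cfg.vocab_size, cfg.p_background)
    p_active[: cfg.n_enriched] = cfg.p_enriched_in_active
    p_inactive = np.full(cfg.vocab_size, cfg.p_background)
    p_inactive[: cfg.n_enriched] = cfg.p_enriched_in_inactive

    features: dict[str, DescriptorSet] = {}
    members: list[tuple[str, bool]] = []

    def draw(cid: str, p: np.ndarray, active: bool) -> None:
        mask = rng.random(cfg.vocab_size) < p
        if not mask.any():
            mask[rng.integers(cfg.vocab_size)] = True  # no empty compounds
        features[cid] = DescriptorSet(descriptors=frozenset(vocab[mask]), source_id=cid)
        members.append((cid, active))

    for i in range(cfg.n_active):
        draw(f"ACT{i:05d}", p_active, True)
    for i in range(cfg.n_inactive):
        draw(f"INA{i:05d}", p_inactive, False)

    return features, LabeledSet(activity_id=cfg.activity_id, members=tuple(members))


# Fragment library for assembled molecules.  Prefixes attach by plain SMILES
# concatenation to any core below, which keeps every combination valid.
_CORES = (
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc(Cl)cc1",
    "c1ccc(OC)cc1",
    "c1ccc(C)cc1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOC1",
)
_PREFIXES = ("", "C", "CC", "CCC", "CCO", "CN(C)", "OC", "N", "O=C(O)", "CC(C)")
_PLANTED = "NS(=O)(=O)"  # primary sulfonamide, the activity-conferring substructure


def make_smiles_dataset(
    cfg: SynthConfig | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Assemble druglike SMILES plus an activity table with planted signal.

    Returns ``(structures, table)`` where ``structures`` is a list of
    (compound_id, SMILES) pairs and ``table`` is an IC50 activity table
    (columns: compound_id, smiles, activity_id, endpoint, value, units,
    failure_reason) in which actives — the sulfonamide-bearing molecules —
    carry sub-10 µM potencies and inactives carry clearly inactive ones.
    Every emitted SMILES is checked to parse.
    """
    cfg = cfg or replace(SynthConfig(), n_active=40, n_inactive=120)
    rng = np.random.default_rng(cfg.seed)
    structures: list[tuple[str, str]] = []
    rows: list[dict] = []

    def emit(cid: str, smiles: str, active: bool) -> None:
        parse_structure(smiles, source_id=cid)  # generator contract: valid SMILES
        structures.append((cid, smiles))
        if active:
            value_nm = float(rng.uniform(10.0, 5000.0))
        else:
            value_nm = float(rng.uniform(20000.0, 500000.0))
        # mix units to exercise conversion
        if rng.random() < 0.5:
            value, units = value_nm / 1e3, "uM"
        else:
            value, units = value_nm, "nM"
        rows.append(
            {
                "compound_id": cid,
                "smiles": smiles,
                "activity_id": cfg.activity_id,
                "endpoint": "IC50",
                "value": value,
                "units": units,
                "failure_reason": "",
            }
        )

    for i in range(cfg.n_active):
        core = _CORES[rng.integers(len(_CORES))]
        prefix = _PREFIXES[rng.integers(len(_PREFIXES))]
        emit(f"SACT{i:04d}", prefix + _PLANTED + core, True)
    for i in range(cfg.n_inactive):
        core = _CORES[rng.integers(len(_CORES))]
        prefix = _PREFIXES[rng.integers(len(_PREFIXES))]
        smiles = (prefix + core) if prefix else "C" + core
        emit(f"SINA{i:04d}", smiles, False)

    return structures, pd.DataFrame(rows)
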