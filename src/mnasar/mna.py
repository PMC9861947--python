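"""Multilevel Neighborhoods of Atoms (MNA) descriptors.

An MNA descriptor is a canonical linear notation for an atom-centered
fragment.  Level 0 is the atom label itself (element symbol plus formal-charge
sign).  Level k wraps the lexicographically sorted level-(k-1) descriptors of
the atom's neighbors in parentheses:

    MNA_0(a) = label(a)
    MNA_k(a) = label(a) + "(" + "".join(sorted(MNA_{k-1}(b) for b in N(a))) + ")"

Because neighbor sublabels are sorted, the string is independent of atom input
order; because the underlying graph stores no bond orders or stereo flags, so
are the descriptors.  A compound is represented by the *set* of unique
descriptors over all atoms and all levels 0..max_level.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import MoleculeGraph

__all__ = ["DescriptorSet", "mna_atom", "descriptor_set", "DEFAULT_MAX_LEVEL"]

# The neighborhood depth is not fixed by the descriptor definition; 2 is the
# conventional choice in the MNA literature and is a config knob everywhere.
DEFAULT_MAX_LEVEL = 2


@dataclass(frozen=True)
class DescriptorSet:
    """Unique MNA descriptor strings of one compound (presence/absence semantics)."""

    descriptors: frozenset[str]
    source_id: str = ""

    def __post_init__(self):
        if not self.descriptors:
            raise ValueError("DescriptorSet must be non-empty")

    def __iter__(self):
        return iter(self.descriptors)

    def __len__(self):
        return len(self.descriptors)

    def __contains__(self, label: str) -> bool:
        return label in self.descriptors


def _level_labels(mol: MoleculeGraph, level: int) -> list[list[str]]:
    """Per-level, per-atom MNA labels for levels 0..level."""
    nbrs = mol.neighbor_lists()
    base = [mol.atom_label(i) for i in range(mol.n_atoms)]
    levels = [base]
    for _ in range(level):
        prev = levels[-1]
        cur = [base[i] + "(" + "".join(sorted(prev[j] for j in nbrs[i])) + ")" for i in range(mol.n_atoms)]
        levels.append(cur)
    return levels


def mna_atom(mol: MoleculeGraph, atom_index: int, level: int) -> str:
    """The level-``level`` MNA descriptor of one atom."""
    if not 0 <= atom_index < mol.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range for {mol.n_atoms} atoms")
    if level < 0:
        raise ValueError("level must be >= 0")
    return _level_labels(mol, level)[level][atom_index]


def descriptor_set(
    mol: MoleculeGraph,
    max_level: int = DEFAULT_MAX_LEVEL,
    *,
    cumulative: bool = True,
) -> DescriptorSet:
    """All unique MNA descriptors of a molecule.

    With ``cumulative`` (the default) the set is the union over levels
    0..max_level, which nests monotonically in max_level and degrades
    gracefully for tiny molecules; with ``cumulative=False`` only the top
    level is kept.
    """
    if max_level < 0:
        raise ValueError("max_level must be >= 0")
    if mol.n_atoms == 0:
        raise ValueError("cannot featurize an empty molecule")
    levels = _level_labels(mol, max_level)
    if not cumulative:
        levels = levels[-1:]
    labels = frozenset(lab for level in levels for lab in level)
    return DescriptorSet(descriptors=labels, source_id=mol.source_id)
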