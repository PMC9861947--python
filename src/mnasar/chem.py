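"""Structure input: SMILES and MDL Molfile/SDF to hydrogen-explicit molecular graphs.

The downstream descriptor machinery works on a deliberately impoverished view of
a molecule: atoms carry only an element symbol and a formal charge, edges carry
no bond order or aromaticity, stereochemistry is erased, and every hydrogen
implied by valence and charge is materialized as an explicit node.  Two
structures that differ only in stereochemistry, bond-order assignment of the
same connectivity, or atom input order are therefore indistinguishable from
here on.  RDKit does the parsing and valence bookkeeping; this module throws
the extra information away on purpose.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

__all__ = [
    "StructureFormat",
    "StructureParseError",
    "MoleculeGraph",
    "atom_label",
    "parse_structure",
    "iter_smiles_records",
    "iter_sdf_records",
    "read_structures",
]


class StructureFormat(str, enum.Enum):
    SMILES = "smiles"
    MOLFILE = "molfile"


class StructureParseError(ValueError):
    """Raised when a structure record cannot be parsed.

    Carries the record identifier and (for line-oriented input) the line number
    so batch runs can report exactly which record failed.
    """

    def __init__(self, message: str, *, record: str | None = None, line: int | None = None):
        ctx = []
        if record:
            ctx.append(f"record={record!r}")
        if line is not None:
            ctx.append(f"line={line}")
        super().__init__(f"{message}" + (f" ({', '.join(ctx)})" if ctx else ""))
        self.record = record
        self.line = line


def atom_label(symbol: str, charge: int) -> str:
    """Atom label used in descriptors: element symbol, charge sign appended when nonzero.

    A carboxylate oxygen ('O-') is distinct from a neutral oxygen ('O');
    a doubly charged atom repeats the sign ('Ca++').
    """
    if charge > 0:
        return symbol + "+" * charge
    if charge < 0:
        return symbol + "-" * (-charge)
    return symbol


@dataclass(frozen=True)
class MoleculeGraph:
    """Hydrogen-explicit, bond-type-agnostic molecular graph.

    ``atoms`` is a tuple of (element symbol, formal charge); ``adjacency`` is a
    tuple of unordered atom-index pairs (i < j).  Bond orders and stereo
    annotations are absent by design.
    """

    atoms: tuple[tuple[str, int], ...]
    adjacency: tuple[tuple[int, int], ...]
    source_id: str = ""
    canonical_smiles: str = ""

    def __post_init__(self):
        n = len(self.atoms)
        for i, j in self.adjacency:
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) out of range for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_label(self, index: int) -> str:
        symbol, charge = self.atoms[index]
        return atom_label(symbol, charge)

    def neighbor_lists(self) -> list[list[int]]:
        """Adjacency lists; symmetric by construction."""
        nbrs: list[list[int]] = [[] for _ in self.atoms]
        for i, j in self.adjacency:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    # Largest by heavy-atom count; canonical-SMILES tie-break keeps the choice
    # deterministic for equal-sized fragments.
    return max(frags, key=lambda m: (m.GetNumAtoms(), Chem.MolToSmiles(m)))


def _graph_from_rdkit(mol: Chem.Mol, source_id: str, strip_salts: bool) -> MoleculeGraph:
    if mol.GetNumAtoms() == 0:
        raise StructureParseError("empty molecule", record=source_id)
    Chem.RemoveStereochemistry(mol)
    if strip_salts:
        mol = _largest_fragment(mol)
    canonical = Chem.MolToSmiles(mol)
    molh = Chem.AddHs(mol)
    atoms = tuple((a.GetSymbol(), a.GetFormalCharge()) for a in molh.GetAtoms())
    adjacency = tuple(
        sorted(
            (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            for b in molh.GetBonds()
        )
    )
    return MoleculeGraph(atoms=atoms, adjacency=adjacency, source_id=source_id, canonical_smiles=canonical)


def parse_structure(
    text: str,
    fmt: StructureFormat | str = StructureFormat.SMILES,
    *,
    source_id: str = "",
    strip_salts: bool = True,
) -> MoleculeGraph:
    """Parse one SMILES string or one MDL Molfile block into a MoleculeGraph.

    The largest covalent component is retained when the input holds several
    fragments (salt stripping; disable with ``strip_salts=False``).  Formal
    charges are preserved; stereochemistry is discarded.
    """
    fmt = StructureFormat(fmt)
    if not text or not text.strip():
        raise StructureParseError("empty structure input", record=source_id)
    if fmt is StructureFormat.SMILES:
        mol = Chem.MolFromSmiles(text.strip())
    else:
        mol = Chem.MolFromMolBlock(text, sanitize=True)
    if mol is None:
        raise StructureParseError(f"could not parse {fmt.value} input", record=source_id or text.strip()[:40])
    return _graph_from_rdkit(mol, source_id, strip_salts)


def iter_smiles_records(text: str, *, strip_salts: bool = True):
    """Iterate (id, MoleculeGraph) over a SMILES file body.

    One record per line: a SMILES string optionally followed by a
    whitespace-separated identifier.  Lines that fail to parse raise with the
    line number attached.
    """
    seen_any = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        ident = parts[1].strip() if len(parts) > 1 else f"MOL{lineno}"
        try:
            yield ident, parse_structure(smiles, StructureFormat.SMILES, source_id=ident, strip_salts=strip_salts)
        except StructureParseError as exc:
            raise StructureParseError(str(exc), record=ident, line=lineno) from exc
        seen_any = True
    if not seen_any:
        raise StructureParseError("no structure records in input")


def iter_sdf_records(text: str, *, strip_salts: bool = True):
    """Iterate (id, MoleculeGraph) over a multi-record SDF body (V2000)."""
    blocks = [b for b in text.split("$$$$") if b.strip()]
    if not blocks:
        raise StructureParseError("no SDF records in input")
    for recno, block in enumerate(blocks, start=1):
        block = block.lstrip("\n")
        name = block.splitlines()[0].strip() if block.splitlines() else ""
        ident = name or f"SDF{recno}"
        mol = Chem.MolFromMolBlock(block, sanitize=True)
        if mol is None:
            raise StructureParseError("could not parse SDF record", record=ident, line=recno)
        yield ident, _graph_from_rdkit(mol, ident, strip_salts)


def read_structures(path, fmt: str | None = None, *, strip_salts: bool = True) -> list[tuple[str, MoleculeGraph]]:
    """Read a structure file; format inferred from the extension unless given.

    ``.sdf``/``.mol`` are treated as MDL, anything else as a SMILES file.
    """
    path = str(path)
    with open(path) as fh:
        text = fh.read()
    if fmt is None:
        fmt = "sdf" if path.lower().endswith((".sdf", ".mol")) else "smiles"
    if fmt in ("sdf", "molfile", "mol"):
        return list(iter_sdf_records(text, strip_salts=strip_salts))
    return list(iter_smiles_records(text, strip_salts=strip_salts))
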