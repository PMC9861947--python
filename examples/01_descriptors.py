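"""Generate MNA descriptors for a few small molecules.

MNA (Multilevel Neighborhoods of Atoms) descriptors are canonical strings for
atom-centered fragments: level 0 is the atom label, level k wraps the sorted
level-(k-1) labels of the neighbors.  Hydrogens are explicit, bond orders and
stereochemistry are ignored, so the two butene stereoisomers below produce
identical sets.
"""

from mnasar import descriptor_set, parse_structure

for name, smiles in [("water", "O"), ("methane", "C"), ("aspirin", "CC(=O)Oc1ccccc1C(=O)O")]:
    mol = parse_structure(smiles, source_id=name)
    ds = descriptor_set(mol, max_level=1)
    print(f"{name} ({smiles}): {len(ds)} descriptors at levels 0-1")
    print("  " + "  ".join(sorted(ds.descriptors)[:8]) + (" ..." if len(ds) > 8 else ""))

cis = descriptor_set(parse_structure("C/C=C\\C"))
trans = descriptor_set(parse_structure("C/C=C/C"))
print(f"\ncis-2-butene and trans-2-butene identical: {cis.descriptors == trans.descriptors}")
print("(stereochemistry is deliberately invisible to the descriptors)")
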