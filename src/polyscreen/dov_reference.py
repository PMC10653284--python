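"""Brute-force circular-environment enumeration.

A slow, independent reference for the fingerprint-based novelty counter in
:mod:`polyscreen.dov`: environments of radius 0..R around every atom are
enumerated explicitly, identified by (radius, rooted canonical submol
SMILES with atoms labeled by their invariant class), and deduplicated by
bond set in the same radius-major order the circular-fingerprint algorithm
uses.  An invariant-class registry must be shared across all molecules of
a comparison so labels are commensurable.
"""

from __future__ import annotations

from rdkit import Chem


def atom_invariant(atom: Chem.Atom) -> tuple:
    """The connectivity invariant identifying an atom at radius 0."""
    return (
        atom.GetAtomicNum(),
        atom.GetTotalDegree(),
        atom.GetTotalNumHs(),
        atom.GetFormalCharge(),
        atom.GetMass(),
        atom.IsInRing(),
    )


def enumerate_environments(
    smiles: str, radius: int = 2, registry: dict | None = None
) -> set:
    """All distinct circular environments of a molecule as explicit ids.

    ``registry`` maps invariant tuples to stable small-integer labels and
    must be shared across every molecule entering one train/query
    comparison.
    """
    registry = registry if registry is not None else {}
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    invariants = [atom_invariant(a) for a in mol.GetAtoms()]

    labeled = Chem.Mol(mol)
    for a in labeled.GetAtoms():
        inv = invariants[a.GetIdx()]
        if inv not in registry:
            registry[inv] = len(registry) + 1
        a.SetAtomMapNum(registry[inv])

    ids: set = set()
    seen_bond_sets: set[frozenset[int]] = set()
    for a in mol.GetAtoms():
        ids.add((0, invariants[a.GetIdx()]))
    for r in range(1, radius + 1):
        for a in mol.GetAtoms():
            bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, r, a.GetIdx())
            if not bonds:
                continue
            bond_set = frozenset(bonds)
            if bond_set in seen_bond_sets:
                continue  # same coverage already identified at a smaller radius
            seen_bond_sets.add(bond_set)
            atom_map: dict[int, int] = {}
            sub = Chem.PathToSubmol(labeled, bonds, atomMap=atom_map)
            rooted = Chem.MolToSmiles(
                sub, rootedAtAtom=atom_map[a.GetIdx()], canonical=True
            )
            ids.add((r, rooted))
    return ids


def corpus_environments(smiles_list, radius: int = 2, registry: dict | None = None) -> set:
    """Union of environment ids over a corpus (shared registry)."""
    registry = registry if registry is not None else {}
    pooled: set = set()
    for s in smiles_list:
        pooled |= enumerate_environments(
            getattr(s, "smiles", s), radius=radius, registry=registry
        )
    return pooled


def reference_novel_count(query, train_smiles, radius: int = 2) -> int:
    """Set-difference novelty count computed entirely by enumeration."""
    registry: dict = {}
    train = corpus_environments(train_smiles, radius=radius, registry=registry)
    query_ids = enumerate_environments(
        getattr(query, "smiles", query), radius=radius, registry=registry
    )
    return len(query_ids - train)
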