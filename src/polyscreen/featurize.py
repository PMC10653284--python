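"""Categorical graph featurization of polymer chains.

Atoms and bonds are mapped to one-hot vocabulary indices.  An atom token is
the tuple (element, aromatic flag, ring membership, heavy-atom degree,
attached H count); a bond token is (bond order, ring membership, sorted end
element symbols).  Hydrogens stay implicit — they are folded into the atom
token rather than expanded into nodes.  Tokens unseen during vocabulary
construction map to a reserved unknown index, never raise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem


class FeaturizeError(ValueError):
    pass


def atom_token(atom: Chem.Atom) -> str:
    return "|".join(
        (
            atom.GetSymbol(),
            "ar" if atom.GetIsAromatic() else "al",
            "ring" if atom.IsInRing() else "chain",
            f"d{atom.GetDegree()}",
            f"h{atom.GetTotalNumHs()}",
        )
    )


def bond_token(bond: Chem.Bond) -> str:
    ends = sorted((bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()))
    return "|".join(
        (
            str(bond.GetBondType()),
            "ring" if bond.IsInRing() else "chain",
            ends[0],
            ends[1],
        )
    )


@dataclass(frozen=True)
class FeatureVocabulary:
    """Dense token→index maps with a reserved unknown index (index 0).

    Tokens occurring fewer than ``min_count`` times in the training corpus
    fold into the unknown index.  Ordering is lexicographic by token, so two
    corpora with the same token multiset yield identical vocabularies.
    """

    atom_index: dict[str, int]
    bond_index: dict[str, int]
    min_count: int = 1

    UNKNOWN: int = 0

    @property
    def n_atom_tokens(self) -> int:
        return len(self.atom_index) + 1

    @property
    def n_bond_tokens(self) -> int:
        return len(self.bond_index) + 1

    def atom_id(self, token: str) -> int:
        return self.atom_index.get(token, self.UNKNOWN)

    def bond_id(self, token: str) -> int:
        return self.bond_index.get(token, self.UNKNOWN)

    def to_json(self) -> str:
        return json.dumps(
            {
                "atom_index": self.atom_index,
                "bond_index": self.bond_index,
                "min_count": self.min_count,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureVocabulary":
        d = json.loads(text)
        return cls(
            atom_index=d["atom_index"],
            bond_index=d["bond_index"],
            min_count=d["min_count"],
        )


@dataclass(frozen=True)
class MoleculeGraph:
    """A featurized heavy-atom graph.

    ``edges`` lists each undirected bond twice, once per direction, as
    (source atom, target atom); ``edge_bond`` gives the undirected bond index
    behind each directed edge.
    """

    atom_indices: np.ndarray  # (n_atoms,) vocabulary ids
    bond_indices: np.ndarray  # (n_bonds,) vocabulary ids
    edges: np.ndarray  # (2*n_bonds, 2) directed (src, dst)
    edge_bond: np.ndarray  # (2*n_bonds,) undirected bond id per edge

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)

    @property
    def n_bonds(self) -> int:
        return len(self.bond_indices)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizeError(f"SMILES does not parse: {smiles!r}")
    return mol


def iter_tokens(smiles: str) -> tuple[list[str], list[str]]:
    mol = _mol_from_smiles(smiles)
    atoms = [atom_token(a) for a in mol.GetAtoms()]
    bonds = [bond_token(b) for b in mol.GetBonds()]
    return atoms, bonds


def build_vocabulary(structures, min_count: int = 1) -> FeatureVocabulary:
    """Learn token→index maps from a training corpus.

    ``structures`` may be SMILES strings or objects with a ``smiles``
    attribute.  Raises on an empty corpus.
    """
    smiles_list = [getattr(s, "smiles", s) for s in structures]
    if not smiles_list:
        raise FeaturizeError("cannot build a vocabulary from an empty corpus")

    atom_counts: dict[str, int] = {}
    bond_counts: dict[str, int] = {}
    for smi in smiles_list:
        atoms, bonds = iter_tokens(smi)
        for t in atoms:
            atom_counts[t] = atom_counts.get(t, 0) + 1
        for t in bonds:
            bond_counts[t] = bond_counts.get(t, 0) + 1

    atom_index = {
        t: i + 1
        for i, t in enumerate(sorted(t for t, n in atom_counts.items() if n >= min_count))
    }
    bond_index = {
        t: i + 1
        for i, t in enumerate(sorted(t for t, n in bond_counts.items() if n >= min_count))
    }
    return FeatureVocabulary(atom_index=atom_index, bond_index=bond_index, min_count=min_count)


def featurize(smiles: str, vocab: FeatureVocabulary) -> MoleculeGraph:
    """Convert a chain SMILES into an indexed molecular graph."""
    mol = _mol_from_smiles(smiles)
    atom_ids = np.array([vocab.atom_id(atom_token(a)) for a in mol.GetAtoms()], dtype=np.int64)
    bond_ids = np.array(
        [vocab.bond_id(bond_token(b)) for b in mol.GetBonds()], dtype=np.int64
    )
    edges = []
    edge_bond = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        edges.append((i, j))
        edges.append((j, i))
        edge_bond.extend([b.GetIdx(), b.GetIdx()])
    edges_arr = (
        np.array(edges, dtype=np.int64) if edges else np.zeros((0, 2), dtype=np.int64)
    )
    return MoleculeGraph(
        atom_indices=atom_ids,
        bond_indices=bond_ids,
        edges=edges_arr,
        edge_bond=np.array(edge_bond, dtype=np.int64),
    )
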