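"""Domain of validity via circular-substructure hashing.

Structural novelty of a prediction target is the number of distinct
radius-≤2 Morgan environment hashes in its chain structure that are absent
from the pooled hash set of the training corpus.  A polymer is inside the
domain of validity when that count is at most the threshold (default 6;
7 or more novel substructures puts it outside).  Hashes are unfolded raw
environment identifiers, not folded bit vectors, so small counts are not
distorted by collisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

DEFAULT_RADIUS = 2
DEFAULT_THRESHOLD = 6


class DoVError(ValueError):
    pass


@dataclass(frozen=True)
class SubstructureHashSet:
    """Pooled circular-environment hashes of a training corpus."""

    radius: int
    hashes: frozenset[int]

    def __contains__(self, h: int) -> bool:
        return h in self.hashes

    def union(self, other: "SubstructureHashSet") -> "SubstructureHashSet":
        if other.radius != self.radius:
            raise DoVError("cannot union hash sets with different radii")
        return SubstructureHashSet(self.radius, self.hashes | other.hashes)


@dataclass(frozen=True)
class DoVReport:
    """Novelty report for one structure (or merged replicate set)."""

    novel_count: int
    inside: bool
    threshold: int
    novel_atoms: dict[int, tuple[tuple[int, ...], ...]] = field(default_factory=dict)


def _mol(structure) -> Chem.Mol:
    smiles = getattr(structure, "smiles", structure)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DoVError(f"SMILES does not parse: {smiles!r}")
    return mol


def _environment_hashes(mol: Chem.Mol, radius: int) -> dict[int, list[tuple[int, int]]]:
    """Map hash -> [(center atom, radius), ...] for all environments of
    radius 0..radius."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    return {h: list(envs) for h, envs in ao.GetBitInfoMap().items()}


def _env_atoms(mol: Chem.Mol, center: int, radius: int) -> tuple[int, ...]:
    if radius == 0:
        return (center,)
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    atoms = {center}
    for b in bonds:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return tuple(sorted(atoms))


def collect_hashes(structures, radius: int = DEFAULT_RADIUS) -> SubstructureHashSet:
    """Pool every circular-environment hash (radii 0..radius) over all atoms
    of all training structures."""
    structures = list(structures)
    if not structures:
        raise DoVError("cannot collect hashes from an empty corpus")
    pooled: set[int] = set()
    for s in structures:
        pooled.update(_environment_hashes(_mol(s), radius))
    return SubstructureHashSet(radius=radius, hashes=frozenset(pooled))


def novel_count(
    structure,
    train: SubstructureHashSet,
    threshold: int = DEFAULT_THRESHOLD,
) -> DoVReport:
    """Count distinct environment hashes of ``structure`` absent from the
    training hash set; locate the atoms of each novel environment."""
    mol = _mol(structure)
    envs = _environment_hashes(mol, train.radius)
    novel = {h: e for h, e in envs.items() if h not in train}
    novel_atoms = {
        h: tuple(_env_atoms(mol, center, rad) for center, rad in e)
        for h, e in novel.items()
    }
    n = len(novel)
    return DoVReport(
        novel_count=n,
        inside=n <= threshold,
        threshold=threshold,
        novel_atoms=novel_atoms,
    )


def novel_count_merged(
    structures,
    train: SubstructureHashSet,
    threshold: int = DEFAULT_THRESHOLD,
) -> DoVReport:
    """DoV for a replicate set: the union of each replicate's novel hashes
    is counted once."""
    pooled: set[int] = set()
    for s in structures:
        pooled.update(
            h for h in _environment_hashes(_mol(s), train.radius) if h not in train
        )
    n = len(pooled)
    return DoVReport(novel_count=n, inside=n <= threshold, threshold=threshold)
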