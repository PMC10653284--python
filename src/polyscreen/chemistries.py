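"""Condensation/addition chemistry registry.

Chemistries are data, not code: each entry declares which functional-group
pairings form a linkage, the reaction SMARTS describing the transformation,
and the condensate eliminated per step.  The builder executes the
transformation with index-tracked molecule editing so that growth can be
restricted to the live chain end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors

# Functional-group SMARTS.  The tuple order of matched atoms is relied on by
# the linkage surgery in builder.py (documented per pattern).
GROUP_SMARTS: dict[str, str] = {
    # (acid C, carbonyl O, hydroxyl O)
    "carboxylic_acid": "[CX3](=[OX1])[OX2H1]",
    # (hydroxyl O, sp3 C) — excludes carboxylic OH by the CX4 requirement
    "alcohol": "[OX2H1][CX4]",
    # (N, sp3 C)
    "primary_amine": "[NX3H2][CX4]",
    # (N, central C, O)
    "isocyanate": "[NX2]=[CX2]=[OX1]",
    # (methyl C, ester O, carbonate C, carbonyl O) — one methyl ester site of
    # a dialkyl carbonate; dimethyl carbonate matches twice
    "carbonate_ester": "[CH3][OX2][CX3]=[OX1]",
    # (terminal CH2, substituted C)
    "vinyl": "[CX3H2]=[CX3]",
}

_GROUP_QUERIES = {kind: Chem.MolFromSmarts(s) for kind, s in GROUP_SMARTS.items()}


def group_matches(mol: Chem.Mol, kind: str) -> list[tuple[int, ...]]:
    """All matches of a functional-group pattern, deduplicated on key atoms."""
    query = _GROUP_QUERIES[kind]
    seen: set[int] = set()
    out = []
    for match in mol.GetSubstructMatches(query):
        if match[0] in seen:
            continue
        seen.add(match[0])
        out.append(match)
    return out


@dataclass(frozen=True)
class LinkageTemplate:
    """One bond-forming step of a polymerization chemistry."""

    chemistry: str
    group_a: str  # electrophile-side functional group
    group_b: str  # nucleophile-side functional group
    reaction_smarts: str
    condensate: str | None  # SMILES of the eliminated small molecule


LINKAGES: dict[str, LinkageTemplate] = {
    "polyester": LinkageTemplate(
        chemistry="polyester",
        group_a="carboxylic_acid",
        group_b="alcohol",
        reaction_smarts=(
            "[C:1](=[O:2])[OX2H1].[OX2H1:3][CX4:4]>>[C:1](=[O:2])[O:3][C:4]"
        ),
        condensate="O",
    ),
    "polyamide": LinkageTemplate(
        chemistry="polyamide",
        group_a="carboxylic_acid",
        group_b="primary_amine",
        reaction_smarts=(
            "[C:1](=[O:2])[OX2H1].[NX3H2:3][CX4:4]>>[C:1](=[O:2])[N:3][C:4]"
        ),
        condensate="O",
    ),
    "polycarbonate": LinkageTemplate(
        chemistry="polycarbonate",
        group_a="carbonate_ester",
        group_b="alcohol",
        reaction_smarts=(
            "[CH3][OX2][C:1]=[O:2].[OX2H1:3][CX4:4]>>[C:1](=[O:2])[O:3][C:4]"
        ),
        condensate="CO",  # methanol from transesterification
    ),
    "polyurethane": LinkageTemplate(
        chemistry="polyurethane",
        group_a="isocyanate",
        group_b="alcohol",
        reaction_smarts=(
            "[N:1]=[C:2]=[O:3].[OX2H1:4][CX4:5]>>[N:1][C:2](=[O:3])[O:4][C:5]"
        ),
        condensate=None,
    ),
    "vinyl": LinkageTemplate(
        chemistry="vinyl",
        group_a="vinyl",
        group_b="vinyl",
        reaction_smarts="[C:1]=[C:2].[CX3H2:3]=[C:4]>>[C:1][C:2][C:3][C:4]",
        condensate=None,
    ),
}

# Monomer classes allowed to participate in each chemistry.
CHEMISTRY_CLASSES: dict[str, set[str]] = {
    "polyester": {"diacid", "diol", "hydroxy_acid"},
    "polyamide": {"diacid", "diamine", "amino_acid"},
    "polycarbonate": {"carbonate_source", "diol"},
    "polyurethane": {"diisocyanate", "diol"},
    "vinyl": {"vinyl"},
}

# Functional-group pairing table per chemistry: a chain end bearing the key
# group accepts a monomer bearing the value group (and vice versa).
CHEMISTRY_PAIRS: dict[str, set[frozenset[str]]] = {
    "polyester": {frozenset({"carboxylic_acid", "alcohol"})},
    "polyamide": {frozenset({"carboxylic_acid", "primary_amine"})},
    "polycarbonate": {frozenset({"carbonate_ester", "alcohol"})},
    "polyurethane": {frozenset({"isocyanate", "alcohol"})},
    "vinyl": {frozenset({"vinyl"})},
}


def condensate_mw(chemistry: str) -> float:
    """Molecular weight of the small molecule eliminated per linkage (0 for
    addition chemistries)."""
    smi = LINKAGES[chemistry].condensate
    if smi is None:
        return 0.0
    return Descriptors.MolWt(Chem.MolFromSmiles(smi))


def compatible_group_kinds(chemistry: str, end_kind: str) -> set[str]:
    """Functional-group kinds that can react with ``end_kind`` under a
    chemistry."""
    out = set()
    for pair in CHEMISTRY_PAIRS[chemistry]:
        if end_kind in pair:
            if len(pair) == 1:
                out.add(end_kind)
            else:
                out.update(pair - {end_kind})
    return out
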