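"""Monomer classification from SMILES.

A monomer is assigned a class from its detected functional groups
(carboxylic acid, alcohol, primary amine, isocyanate, methyl carbonate
ester, vinyl).  Bifunctional condensation monomers (AA or AB) map to the
classic classes; anything without a recognized polymerizable pairing —
including tri-functional crosslinkers — is classed ``non_polymerizable``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemistries import GROUP_SMARTS, group_matches


class MonomerClass(str, Enum):
    DIACID = "diacid"
    DIOL = "diol"
    DIAMINE = "diamine"
    HYDROXY_ACID = "hydroxy_acid"
    AMINO_ACID = "amino_acid"
    CARBONATE_SOURCE = "carbonate_source"
    DIISOCYANATE = "diisocyanate"
    VINYL = "vinyl"
    NON_POLYMERIZABLE = "non_polymerizable"


class MonomerError(ValueError):
    """Raised for unparseable monomer SMILES."""


@dataclass(frozen=True)
class Monomer:
    """A classified monomer.

    ``functional_groups`` lists (group kind, count) for every detected group
    kind with a nonzero count, in the fixed registry order.
    """

    smiles: str
    monomer_class: MonomerClass
    functional_groups: tuple[tuple[str, int], ...]
    molecular_weight: float

    def group_count(self, kind: str) -> int:
        return dict(self.functional_groups).get(kind, 0)

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


def _classify(counts: dict[str, int]) -> MonomerClass:
    acid = counts["carboxylic_acid"]
    oh = counts["alcohol"]
    amine = counts["primary_amine"]
    iso = counts["isocyanate"]
    carb = counts["carbonate_ester"]
    vinyl = counts["vinyl"]

    if acid == 2 and oh == 0 and amine == 0 and iso == 0:
        return MonomerClass.DIACID
    if oh == 2 and acid == 0 and amine == 0 and iso == 0:
        return MonomerClass.DIOL
    if amine == 2 and acid == 0 and oh == 0 and iso == 0:
        return MonomerClass.DIAMINE
    if acid == 1 and oh == 1 and amine == 0 and iso == 0:
        return MonomerClass.HYDROXY_ACID
    if acid == 1 and amine == 1 and oh == 0 and iso == 0:
        return MonomerClass.AMINO_ACID
    if iso == 2 and acid == 0 and oh == 0 and amine == 0:
        return MonomerClass.DIISOCYANATE
    if carb >= 2:
        return MonomerClass.CARBONATE_SOURCE
    if vinyl >= 1 and acid + oh + amine + iso == 0:
        return MonomerClass.VINYL
    return MonomerClass.NON_POLYMERIZABLE


def classify_monomer(smiles: str) -> Monomer:
    """Detect functional groups by substructure matching and assign a class.

    Precedence for ambiguous molecules is: exact bifunctional AA classes,
    then AB classes (hydroxy acid, amino acid), then diisocyanate, carbonate
    source, vinyl; a molecule whose groups form no valid pairing (or more
    than two condensation groups) is ``non_polymerizable``.

    Raises
    ------
    MonomerError
        If the SMILES does not parse or is disconnected.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MonomerError(f"unparseable monomer SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise MonomerError(f"monomer SMILES is not a single molecule: {smiles!r}")

    counts = {kind: len(group_matches(mol, kind)) for kind in GROUP_SMARTS}
    cls = _classify(counts)
    groups = tuple((kind, n) for kind, n in counts.items() if n > 0)
    return Monomer(
        smiles=Chem.MolToSmiles(mol),
        monomer_class=cls,
        functional_groups=groups,
        molecular_weight=Descriptors.MolWt(mol),
    )
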