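"""Explicit polymer-chain construction from monomer SMILES.

A chain is grown monomer by monomer: the first residue is drawn from the
molar ratios, and each subsequent monomer is drawn from the ratios
renormalized over the monomers chemically compatible with the live chain
end, then attached with random regio-orientation.  Growth is executed by
index-tracked molecule editing following the linkage templates in
:mod:`polyscreen.chemistries`; condensation steps eliminate the template's
condensate (water for ester/amide, methanol for carbonate) so mass balance
is exact.

End groups are left un-capped: a finished polyester chain still carries its
free acid/hydroxyl termini.  Stereo descriptors present in the input SMILES
are preserved; none are invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemistries import (
    CHEMISTRY_CLASSES,
    CHEMISTRY_PAIRS,
    LINKAGES,
    compatible_group_kinds,
    condensate_mw,
    group_matches,
)
from .monomers import Monomer, MonomerClass

_LIVE = "ps_live"
_LIVE_KIND = "ps_live_kind"
_RESIDUE = "ps_residue"


class BuilderError(ValueError):
    """Base class for polymer-construction failures."""


class ChemistryMismatchError(BuilderError):
    """No valid reactive pairing exists under the requested chemistry."""


class GrowthError(BuilderError):
    """The chain cannot be extended to the requested DP."""


@dataclass(frozen=True)
class PolymerSpec:
    """Recipe for building polymer chains.

    ``molar_ratios=None`` means equal molar.  ``degree_of_polymerization``
    counts monomer residues (the initial dimer has DP 2).
    """

    monomers: tuple[Monomer, ...]
    chemistry: str
    degree_of_polymerization: int
    molar_ratios: tuple[float, ...] | None = None
    replicate_count: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.chemistry not in LINKAGES:
            raise ChemistryMismatchError(f"unknown chemistry {self.chemistry!r}")
        if self.degree_of_polymerization < 1:
            raise BuilderError("degree_of_polymerization must be >= 1")
        if self.replicate_count < 1:
            raise BuilderError("replicate_count must be >= 1")
        if not self.monomers:
            raise BuilderError("at least one monomer is required")
        if self.molar_ratios is not None:
            if len(self.molar_ratios) != len(self.monomers):
                raise BuilderError("molar_ratios length must match monomers")
            if abs(sum(self.molar_ratios) - 1.0) > 1e-9:
                raise BuilderError("molar_ratios must sum to 1")
            if any(r < 0 for r in self.molar_ratios):
                raise BuilderError("molar_ratios must be non-negative")
        allowed = CHEMISTRY_CLASSES[self.chemistry]
        for m in self.monomers:
            if m.monomer_class.value not in allowed:
                raise ChemistryMismatchError(
                    f"monomer {m.smiles} ({m.monomer_class.value}) is not "
                    f"compatible with {self.chemistry} chemistry"
                )

    @property
    def ratios(self) -> np.ndarray:
        if self.molar_ratios is None:
            return np.full(len(self.monomers), 1.0 / len(self.monomers))
        return np.asarray(self.molar_ratios, dtype=float)


@dataclass(frozen=True)
class PolymerStructure:
    """An explicit linear chain with its residue provenance.

    ``residue_sequence`` holds (monomer index into the generating spec,
    orientation flag) per residue, in insertion order; index -1 marks a
    residue added by a manual :func:`condensation_step`.
    """

    smiles: str
    residue_sequence: tuple[tuple[int, bool], ...]
    chemistry: str
    _mol: Chem.Mol | None = field(default=None, compare=False, repr=False)

    @property
    def degree_of_polymerization(self) -> int:
        return len(self.residue_sequence)

    @property
    def molecular_weight(self) -> float:
        return Descriptors.MolWt(Chem.MolFromSmiles(self.smiles))


def _reactive_kinds(chemistry: str) -> set[str]:
    kinds: set[str] = set()
    for pair in CHEMISTRY_PAIRS[chemistry]:
        kinds.update(pair)
    return kinds


def _clear_live_tags(mol: Chem.Mol) -> None:
    for atom in mol.GetAtoms():
        if atom.HasProp(_LIVE):
            atom.ClearProp(_LIVE)
        if atom.HasProp(_LIVE_KIND):
            atom.ClearProp(_LIVE_KIND)


def _find_live_match(mol: Chem.Mol, chemistry: str) -> tuple[str, tuple[int, ...]] | None:
    """Locate the tagged live-end group after an editing step."""
    for kind in _reactive_kinds(chemistry):
        for match in group_matches(mol, kind):
            if mol.GetAtomWithIdx(match[0]).HasProp(_LIVE):
                return kind, match
    # vinyl live end is a plain carbon, not a functional-group match
    for atom in mol.GetAtoms():
        if atom.HasProp(_LIVE):
            return "vinyl_end", (atom.GetIdx(),)
    return None


class _GrowingChain:
    """Internal mutable chain state: an RDKit mol with tagged live end."""

    def __init__(self, mol: Chem.Mol, chemistry: str, residues):
        self.mol = mol
        self.chemistry = chemistry
        self.residues = list(residues)

    @property
    def live(self) -> tuple[str, tuple[int, ...]] | None:
        return _find_live_match(self.mol, self.chemistry)


def _monomer_attach_candidates(
    monomer: Monomer, kinds: set[str]
) -> list[tuple[str, tuple[int, ...]]]:
    mol = monomer.mol
    out = []
    for kind in sorted(kinds):
        for match in group_matches(mol, kind):
            out.append((kind, match))
    return out


def _init_chain(
    monomer: Monomer, monomer_idx: int, flag: bool, chemistry: str
) -> _GrowingChain:
    mol = Chem.RWMol(monomer.mol)
    for atom in mol.GetAtoms():
        atom.SetIntProp(_RESIDUE, 0)

    if chemistry == "vinyl":
        matches = group_matches(mol, "vinyl")
        if not matches:
            raise ChemistryMismatchError(
                f"{monomer.smiles} has no vinyl group for addition chemistry"
            )
        c1, c2 = matches[0][0], matches[0][1]
        mol.GetBondBetweenAtoms(c1, c2).SetBondType(Chem.BondType.SINGLE)
        live_atom = c2 if flag else c1
        mol.GetAtomWithIdx(live_atom).SetIntProp(_LIVE, 1)
    else:
        kinds = _reactive_kinds(chemistry)
        candidates = _monomer_attach_candidates(monomer, kinds)
        if not candidates:
            raise ChemistryMismatchError(
                f"{monomer.smiles} has no reactive group for {chemistry}"
            )
        if len(candidates) >= 2:
            kind, match = candidates[1] if flag else candidates[0]
        else:
            kind, match = candidates[0]
        mol.GetAtomWithIdx(match[0]).SetIntProp(_LIVE, 1)
        mol.GetAtomWithIdx(match[0]).SetProp(_LIVE_KIND, kind)

    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return _GrowingChain(out, chemistry, [(monomer_idx, flag)])


def _attach(
    chain: _GrowingChain,
    monomer: Monomer,
    monomer_idx: int,
    flag: bool,
    rng: np.random.Generator | None = None,
) -> _GrowingChain:
    """Form one linkage between the chain's live end and a monomer."""
    chemistry = chain.chemistry
    live = chain.live
    if live is None:
        raise GrowthError("chain has no live end; growth is blocked")
    live_kind, live_match = live

    if chemistry == "vinyl":
        return _attach_vinyl(chain, monomer, monomer_idx, flag)

    compat = compatible_group_kinds(chemistry, live_kind)
    candidates = _monomer_attach_candidates(monomer, compat)
    if not candidates:
        raise ChemistryMismatchError(
            f"monomer {monomer.smiles} has no group compatible with the "
            f"chain end ({live_kind}) under {chemistry} chemistry"
        )
    if len(candidates) >= 2:
        attach_kind, attach_match = candidates[1] if flag else candidates[0]
    else:
        attach_kind, attach_match = candidates[0]

    offset = chain.mol.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(chain.mol, monomer.mol))
    residue_idx = len(chain.residues)
    for i in range(offset, combined.GetNumAtoms()):
        combined.GetAtomWithIdx(i).SetIntProp(_RESIDUE, residue_idx)
    _clear_live_tags(combined)

    attach_atoms = tuple(i + offset for i in attach_match)
    template = LINKAGES[chemistry]
    if live_kind == template.group_a:
        a_atoms, b_atoms = live_match, attach_atoms
    else:
        a_atoms, b_atoms = attach_atoms, live_match

    to_remove: list[int] = []
    if chemistry in ("polyester", "polyamide"):
        # a = (acid C, carbonyl O, hydroxyl O); b = (O or N, sp3 C)
        combined.AddBond(a_atoms[0], b_atoms[0], Chem.BondType.SINGLE)
        to_remove.append(a_atoms[2])
    elif chemistry == "polycarbonate":
        # a = (methyl C, ester O, carbonate C, carbonyl O); b = (O, C)
        combined.AddBond(a_atoms[2], b_atoms[0], Chem.BondType.SINGLE)
        to_remove.extend([a_atoms[0], a_atoms[1]])
    elif chemistry == "polyurethane":
        # a = (N, C, O); b = (O, C)
        combined.GetBondBetweenAtoms(a_atoms[0], a_atoms[1]).SetBondType(
            Chem.BondType.SINGLE
        )
        combined.AddBond(a_atoms[1], b_atoms[0], Chem.BondType.SINGLE)
    else:  # pragma: no cover - registry and branches kept in sync
        raise ChemistryMismatchError(f"unsupported chemistry {chemistry!r}")

    # tag the incoming monomer's remaining reactive group as the new live end
    monomer_mol = monomer.mol
    new_live = None
    for kind in sorted(_reactive_kinds(chemistry)):
        for match in group_matches(monomer_mol, kind):
            if match[0] == attach_match[0]:
                continue
            new_live = (kind, tuple(i + offset for i in match))
            break
        if new_live:
            break
    if new_live is not None:
        kind, match = new_live
        atom = combined.GetAtomWithIdx(match[0])
        atom.SetIntProp(_LIVE, 1)
        atom.SetProp(_LIVE_KIND, kind)

    for idx in sorted(to_remove, reverse=True):
        combined.RemoveAtom(idx)

    out = combined.GetMol()
    Chem.SanitizeMol(out)
    return _GrowingChain(out, chemistry, chain.residues + [(monomer_idx, flag)])


def _attach_vinyl(
    chain: _GrowingChain, monomer: Monomer, monomer_idx: int, flag: bool
) -> _GrowingChain:
    live = chain.live
    if live is None or live[0] != "vinyl_end":
        raise GrowthError("vinyl chain has no live carbon end")
    live_atom = live[1][0]

    matches = group_matches(monomer.mol, "vinyl")
    if not matches:
        raise ChemistryMismatchError(
            f"monomer {monomer.smiles} has no vinyl group"
        )
    c1, c2 = matches[0][0], matches[0][1]
    attach_local, other_local = (c2, c1) if flag else (c1, c2)

    offset = chain.mol.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(chain.mol, monomer.mol))
    residue_idx = len(chain.residues)
    for i in range(offset, combined.GetNumAtoms()):
        combined.GetAtomWithIdx(i).SetIntProp(_RESIDUE, residue_idx)
    _clear_live_tags(combined)

    combined.GetBondBetweenAtoms(c1 + offset, c2 + offset).SetBondType(
        Chem.BondType.SINGLE
    )
    combined.AddBond(live_atom, attach_local + offset, Chem.BondType.SINGLE)
    combined.GetAtomWithIdx(other_local + offset).SetIntProp(_LIVE, 1)

    out = combined.GetMol()
    Chem.SanitizeMol(out)
    return _GrowingChain(out, chain.chemistry, chain.residues + [(monomer_idx, flag)])


def _finish(chain: _GrowingChain, chemistry: str) -> PolymerStructure:
    mol = Chem.Mol(chain.mol)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise BuilderError("built chain is not a single connected component")
    return PolymerStructure(
        smiles=Chem.MolToSmiles(mol),
        residue_sequence=tuple(chain.residues),
        chemistry=chemistry,
        _mol=mol,
    )


def _polymerize_stream(spec: PolymerSpec, rng: np.random.Generator) -> PolymerStructure:
    ratios = spec.ratios
    monomers = spec.monomers
    dp = spec.degree_of_polymerization

    first = int(rng.choice(len(monomers), p=ratios))
    flag = bool(rng.random() < 0.5)
    chain = _init_chain(monomers[first], first, flag, spec.chemistry)

    while len(chain.residues) < dp:
        live = chain.live
        if live is None:
            raise GrowthError(
                f"both chain ends are dead at DP={len(chain.residues)}; "
                f"cannot reach DP={dp}"
            )
        live_kind = live[0]
        if spec.chemistry == "vinyl":
            candidates = list(range(len(monomers)))
        else:
            compat = compatible_group_kinds(spec.chemistry, live_kind)
            candidates = [
                i
                for i, m in enumerate(monomers)
                if any(m.group_count(k) > 0 for k in compat)
            ]
        if not candidates:
            raise GrowthError(
                f"chain end ({live_kind}) has no compatible partner among the "
                f"spec's monomers under {spec.chemistry} chemistry"
            )
        p = ratios[candidates]
        if p.sum() <= 0:
            raise GrowthError(
                f"all monomers compatible with the chain end ({live_kind}) "
                "have zero molar ratio"
            )
        p = p / p.sum()
        nxt = int(np.asarray(candidates)[rng.choice(len(candidates), p=p)])
        flag = bool(rng.random() < 0.5)
        chain = _attach(chain, monomers[nxt], nxt, flag)

    return _finish(chain, spec.chemistry)


def polymerize(spec: PolymerSpec) -> PolymerStructure:
    """Build one explicit chain; deterministic given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    return _polymerize_stream(spec, rng)


def build_replicates(spec: PolymerSpec) -> list[PolymerStructure]:
    """Build ``spec.replicate_count`` chains from one seeded random stream.

    Replicates differ in comonomer order and regio-orientation; the list is
    reproducible from ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    return [_polymerize_stream(spec, rng) for _ in range(spec.replicate_count)]


def condensation_step(
    chain: PolymerStructure,
    monomer: Monomer,
    chemistry: str | None = None,
    *,
    orientation: bool = False,
    monomer_index: int = -1,
) -> PolymerStructure:
    """Attach one monomer to a chain's live end under a chemistry template.

    Increments the residue count by one and eliminates the template's
    condensate.  Raises :class:`ChemistryMismatchError` if the chain end and
    monomer carry no compatible reactive pair.
    """
    chemistry = chemistry or chain.chemistry
    if chemistry != chain.chemistry:
        raise ChemistryMismatchError(
            f"chain was built with {chain.chemistry}, not {chemistry}"
        )

    growing = _as_growing(chain, chemistry)
    new = _attach(growing, monomer, monomer_index, orientation)
    return _finish(new, chemistry)


def _as_growing(chain: PolymerStructure, chemistry: str) -> _GrowingChain:
    if chain._mol is not None:
        return _GrowingChain(chain._mol, chemistry, chain.residue_sequence)
    # Re-parsed chain: adopt the first free reactive group as the live end.
    mol = Chem.RWMol(Chem.MolFromSmiles(chain.smiles))
    if mol is None:
        raise BuilderError(f"chain SMILES does not parse: {chain.smiles!r}")
    found = False
    for kind in sorted(_reactive_kinds(chemistry)):
        matches = group_matches(mol, kind)
        if matches:
            mol.GetAtomWithIdx(matches[0][0]).SetIntProp(_LIVE, 1)
            mol.GetAtomWithIdx(matches[0][0]).SetProp(_LIVE_KIND, kind)
            found = True
            break
    if not found:
        raise ChemistryMismatchError(
            f"chain {chain.smiles} carries no free reactive group for {chemistry}"
        )
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return _GrowingChain(out, chemistry, chain.residue_sequence)


def expected_molecular_weight(spec_monomers: list[Monomer], residue_sequence, chemistry: str) -> float:
    """Closed-form chain mass: sum of residue monomer masses minus one
    condensate per linkage."""
    dp = len(residue_sequence)
    total = sum(spec_monomers[i].molecular_weight for i, _ in residue_sequence)
    return total - (dp - 1) * condensate_mw(chemistry)
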