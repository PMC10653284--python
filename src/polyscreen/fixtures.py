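"""Seeded synthetic data: monomer libraries, group-contribution property
labels, and hand-built toy metabolic models.

These generators make every part of the toolkit testable without any
external download.  Labels follow a known closed-form group-contribution
rule (per-group coefficients on substructure counts normalized by heavy
atom count, plus Gaussian noise), so model recovery can be checked against
ground truth.  The fixture property scale mimics a realistic Tg range
(roughly -100 to 300 °C) so robust scaling is exercised meaningfully;
non-Tg properties are observed with a configurable probability to exercise
the missing-label mask path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import cobra
from rdkit import Chem

from .builder import PolymerSpec, PolymerStructure, polymerize
from .model import N_PROPERTIES, PropertyRecord, TrainingRecord
from .monomers import Monomer, classify_monomer

# ---------------------------------------------------------------------------
# monomer library

_ALKYL_POOLS = {
    "diacid": [f"OC(=O){'C' * n}C(=O)O" for n in range(2, 9)],
    "diol": [f"O{'C' * n}O" for n in range(2, 9)],
    "diamine": [f"N{'C' * n}N" for n in range(2, 9)],
    "hydroxy_acid": [f"O{'C' * n}C(=O)O" for n in range(2, 9)],
}

_AROMATIC_POOLS = {
    "diacid": [
        "OC(=O)c1ccc(C(=O)O)cc1",  # terephthalic acid
        "OC(=O)c1cccc(C(=O)O)c1",  # isophthalic acid
        "OC(=O)c1ccc(C(=O)O)o1",  # furan-2,5-dicarboxylic acid
    ],
    "diol": [
        "OCc1ccc(CO)cc1",  # 1,4-benzenedimethanol
        "OCc1cccc(CO)c1",
    ],
    "diamine": [
        "NCc1ccc(CN)cc1",  # p-xylylenediamine
    ],
    "hydroxy_acid": [
        "OCc1ccc(C(=O)O)cc1",  # 4-(hydroxymethyl)benzoic acid
    ],
}


def generate_monomer_library(
    seed: int, sizes: dict[str, int] | None = None
) -> list[Monomer]:
    """Draw a seeded monomer library of the requested class sizes.

    Pools are linear alkyl chains (lengths 2-8) plus aromatic variants;
    aromatic members are included whenever a class size exceeds half the
    alkyl pool draw, and always at least one for sizes >= 3.
    """
    sizes = sizes or {"diacid": 5, "diol": 5, "diamine": 3, "hydroxy_acid": 2}
    rng = np.random.default_rng(seed)
    out: list[Monomer] = []
    for cls, n in sizes.items():
        if n < 1:
            raise ValueError(f"need at least one monomer of class {cls}")
        alkyl = _ALKYL_POOLS[cls]
        aromatic = _AROMATIC_POOLS[cls]
        n_arom = min(len(aromatic), max(1, n // 3) if n >= 3 else 0)
        n_alkyl = n - n_arom
        if n_alkyl > len(alkyl):
            raise ValueError(f"class {cls} pool supports at most "
                             f"{len(alkyl) + len(aromatic)} monomers")
        chosen = list(rng.choice(alkyl, size=n_alkyl, replace=False))
        chosen += list(rng.choice(aromatic, size=n_arom, replace=False))
        for smi in chosen:
            m = classify_monomer(smi)
            assert m.monomer_class.value == cls, (smi, m.monomer_class)
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# group-contribution labels

GROUP_PATTERNS = {
    "amide": "[CX3](=[OX1])[NX3]",
    "ester": "[CX3](=[OX1])[OX2][#6]",
    "ether": "[CX4][OX2][CX4]",
    "methyl": "[CX4H3]",
    "carbonyl": "[CX3]=[OX1]",
}
_GROUP_QUERIES = {k: Chem.MolFromSmarts(v) for k, v in GROUP_PATTERNS.items()}


def group_counts(smiles: str) -> dict[str, int]:
    """Substructure counts used by the synthetic property rule (aromatic
    ring count comes from the ring info)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    counts = {k: len(mol.GetSubstructMatches(q)) for k, q in _GROUP_QUERIES.items()}
    ri = mol.GetRingInfo()
    counts["aromatic_ring"] = sum(
        1
        for ring in ri.AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )
    counts["n_heavy"] = mol.GetNumHeavyAtoms()
    return counts


@dataclass(frozen=True)
class GroupContributionRule:
    """Closed-form synthetic Tg rule.

    Tg = intercept + sum_g coefficient_g * (count_g / heavy atoms) + noise,
    with Gaussian noise of sd ``noise_sd`` (°C).  The aromatic-ring
    coefficient is deliberately the largest so aromatic substructures are a
    planted signal that bond attributions should recover.
    """

    intercept: float = 0.0
    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "aromatic_ring": 800.0,
            "amide": 600.0,
            "ester": 200.0,
            "ether": -300.0,
            "methyl": -400.0,
            "carbonyl": 150.0,
        }
    )
    noise_sd: float = 10.0
    rng_seed: int = 0

    def exact_tg(self, smiles: str) -> float:
        counts = group_counts(smiles)
        n = counts["n_heavy"]
        return self.intercept + sum(
            c * counts.get(g, 0) / n for g, c in self.coefficients.items()
        )


def generate_labels(
    structures: list[PolymerStructure],
    rule: GroupContributionRule,
    mask_prob: float = 0.5,
) -> list[PropertyRecord]:
    """Synthetic 8-property labels for built chains.

    Tg is always observed.  The remaining properties are deterministic
    functions of the same normalized group counts (different coefficients),
    each observed with probability ``mask_prob`` to exercise the multitask
    mask path.  Permeabilities are positive by construction.
    """
    rng = np.random.default_rng(rule.rng_seed)
    out = []
    for s in structures:
        counts = group_counts(s.smiles)
        n = counts["n_heavy"]
        arom = counts["aromatic_ring"] / n
        amide = counts["amide"] / n
        ester = counts["ester"] / n
        tg = rule.exact_tg(s.smiles) + rng.normal(0.0, rule.noise_sd)
        noise = lambda sd: rng.normal(0.0, sd)  # noqa: E731
        values = np.array(
            [
                tg,
                1.3 * rule.exact_tg(s.smiles) + 120.0 + noise(rule.noise_sd),
                1.0 + 1.5 * arom + 0.8 * amide + noise(0.02),
                1000.0 + 8000.0 * arom + 5000.0 * amide + noise(50.0),
                10.0 ** (1.0 - 8.0 * arom - 4.0 * amide + noise(0.1)),
                10.0 ** (0.5 - 8.0 * arom - 4.0 * amide + noise(0.1)),
                10.0 ** (1.5 - 8.0 * arom + 2.0 * ester + noise(0.1)),
                10.0 ** (2.0 - 4.0 * arom + noise(0.1)),
            ]
        )
        mask = np.ones(N_PROPERTIES, dtype=bool)
        mask[1:] = rng.random(N_PROPERTIES - 1) < mask_prob
        out.append(PropertyRecord(values=values, mask=mask))
    return out


def generate_fixture_dataset(
    n_polymers: int = 300,
    seed: int = 0,
    dp: int = 8,
    noise_sd: float = 10.0,
    mask_prob: float = 0.5,
    library: list[Monomer] | None = None,
    rule: GroupContributionRule | None = None,
    return_specs: bool = False,
):
    """A labeled fixture corpus of polyesters and polyamides.

    Each record is a single built chain (one seeded replicate, mirroring
    single-chain training) with synthetic labels; polymer classes alternate
    between polyester (AA+BB or AB) and polyamide.
    """
    rng = np.random.default_rng(seed)
    library = library or generate_monomer_library(seed)
    rule = rule or GroupContributionRule(noise_sd=noise_sd, rng_seed=seed + 1)
    by_class: dict[str, list[Monomer]] = {}
    for m in library:
        by_class.setdefault(m.monomer_class.value, []).append(m)

    structures: list[PolymerStructure] = []
    classes: list[str] = []
    specs: list[PolymerSpec] = []
    attempts = 0
    while len(structures) < n_polymers:
        attempts += 1
        if attempts > 20 * n_polymers:
            raise RuntimeError("fixture generation failed to converge")
        chemistry = "polyester" if rng.random() < 0.5 else "polyamide"
        if chemistry == "polyester":
            if "hydroxy_acid" in by_class and rng.random() < 0.2:
                monomers = (_pick(rng, by_class["hydroxy_acid"]),)
            else:
                monomers = (
                    _pick(rng, by_class["diacid"]),
                    _pick(rng, by_class["diol"]),
                )
        else:
            monomers = (
                _pick(rng, by_class["diacid"]),
                _pick(rng, by_class["diamine"]),
            )
        spec = PolymerSpec(
            monomers=monomers,
            chemistry=chemistry,
            degree_of_polymerization=dp,
            rng_seed=int(rng.integers(2**31 - 1)),
        )
        structures.append(polymerize(spec))
        classes.append(chemistry)
        specs.append(spec)

    labels = generate_labels(structures, rule, mask_prob=mask_prob)
    records = [
        TrainingRecord(structure=s, record=r, polymer_class=c)
        for s, r, c in zip(structures, labels, classes)
    ]
    if return_specs:
        return records, specs
    return records


def _pick(rng: np.random.Generator, pool: list[Monomer]) -> Monomer:
    return pool[int(rng.integers(len(pool)))]


# ---------------------------------------------------------------------------
# toy metabolic models


def _met(mid: str, formula: str) -> cobra.Metabolite:
    return cobra.Metabolite(mid, formula=formula, compartment="c")


def generate_toy_metabolic_model(variant: str = "lactate") -> cobra.Model:
    """A hand-built glucose-fermentation model, elementally balanced.

    ``lactate``: glucose -> 2 lactate with 2 ATP; the lactate carbon yield
    is exactly 1.  ``ethanol_co2``: glucose -> 2 ethanol + 2 CO2 with 2 ATP
    and CO2 export only; the ethanol carbon yield is exactly 4/6.  Both
    carry an ATP maintenance reaction with a positive lower bound (1
    mmol/gDW/h) and glucose uptake capped at 10 mmol/gDW/h.
    """
    if variant not in ("lactate", "ethanol_co2"):
        raise ValueError(f"unknown toy model variant {variant!r}")

    model = cobra.Model(f"toy_{variant}")
    glc = _met("glc", "C6H12O6")
    atp = _met("atp", "C10H16N5O13P3")
    adp = _met("adp", "C10H15N5O10P2")
    pi = _met("pi", "H3O4P")  # keeps ADP + Pi -> ATP + H2O exactly balanced
    h2o = _met("h2o", "H2O")

    atpm = cobra.Reaction("ATPM", lower_bound=1.0, upper_bound=1000.0)
    atpm.add_metabolites({atp: -1, h2o: -1, adp: 1, pi: 1})

    if variant == "lactate":
        lac = _met("lac", "C3H6O3")
        ferment = cobra.Reaction("GLY_LAC", lower_bound=0.0, upper_bound=1000.0)
        ferment.add_metabolites(
            {glc: -1, adp: -2, pi: -2, lac: 2, atp: 2, h2o: 2}
        )
        product = lac
    else:
        etoh = _met("etoh", "C2H6O")
        co2 = _met("co2", "CO2")
        ferment = cobra.Reaction("GLY_ETOH", lower_bound=0.0, upper_bound=1000.0)
        ferment.add_metabolites(
            {glc: -1, adp: -2, pi: -2, etoh: 2, co2: 2, atp: 2, h2o: 2}
        )
        product = etoh

    def exchange(met: cobra.Metabolite, lb: float, ub: float) -> cobra.Reaction:
        rxn = cobra.Reaction(f"EX_{met.id}", lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites({met: -1})
        return rxn

    exchanges = [
        exchange(glc, -10.0, 0.0),  # glucose uptake only, capped
        exchange(product, 0.0, 1000.0),  # product export only
        exchange(h2o, -1000.0, 1000.0),
    ]
    if variant == "ethanol_co2":
        exchanges.append(exchange(co2, 0.0, 1000.0))  # CO2 export only
    model.add_reactions([atpm, ferment] + exchanges)
    return model
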