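"""Candidate-polymer screening funnel.

Monomers are prescreened (CHNO elements, MW < 300 Da, exactly two reactive
groups forming a valid condensation pairing), combined combinatorially per
chemistry (diacid+diol polyesters, diacid+diamine polyamides,
carbonate+diol polycarbonates, AB homopolymers), predicted with a trained
ensemble, gated by domain of validity, and flagged against performance
criteria.  Reference-polymer criteria (e.g. "at most PET's O2
permeability") are resolved by predicting the reference with the same
ensemble, so the comparison is internally consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem

from .builder import BuilderError, PolymerSpec, build_replicates
from .dov import DEFAULT_THRESHOLD, DoVReport, SubstructureHashSet, novel_count_merged
from .model import EnsembleModel, EnsemblePrediction, PROPERTY_NAMES, predict_structures
from .monomers import Monomer, MonomerClass, MonomerError, classify_monomer

log = logging.getLogger(__name__)

ALLOWED_ELEMENTS = frozenset({"C", "H", "N", "O"})


@dataclass(frozen=True)
class MonomerFilterCriteria:
    max_molecular_weight: float = 300.0
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS
    require_bifunctional: bool = True

    def __post_init__(self):
        if self.max_molecular_weight <= 0:
            raise ValueError("max_molecular_weight must be positive")


# classes with exactly two reactive groups forming a condensation pairing
_BIFUNCTIONAL = {
    MonomerClass.DIACID,
    MonomerClass.DIOL,
    MonomerClass.DIAMINE,
    MonomerClass.HYDROXY_ACID,
    MonomerClass.AMINO_ACID,
    MonomerClass.DIISOCYANATE,
    MonomerClass.CARBONATE_SOURCE,
}


def filter_monomers(
    smiles_list: list[str],
    criteria: MonomerFilterCriteria | None = None,
) -> list[Monomer]:
    """Prescreen candidate monomers; rejects are logged, never fatal."""
    criteria = criteria or MonomerFilterCriteria()
    out = []
    for smi in smiles_list:
        try:
            m = classify_monomer(smi)
        except MonomerError as e:
            log.info("rejected %r: %s", smi, e)
            continue
        mol = Chem.MolFromSmiles(m.smiles)
        elements = {a.GetSymbol() for a in mol.GetAtoms()} | {"H"}
        if elements - (set(criteria.allowed_elements) | {"H"}):
            log.info("rejected %s: element filter", m.smiles)
            continue
        if m.molecular_weight >= criteria.max_molecular_weight:
            log.info("rejected %s: MW %.1f Da", m.smiles, m.molecular_weight)
            continue
        if criteria.require_bifunctional and m.monomer_class not in _BIFUNCTIONAL:
            log.info("rejected %s: not bifunctional (%s)", m.smiles, m.monomer_class.value)
            continue
        out.append(m)
    return out


@dataclass(frozen=True)
class PerformanceCriterion:
    """One pass/fail rule: property `cmp` threshold, where the threshold is
    a number or a reference polymer spec predicted with the same model."""

    property_name: str
    cmp: str  # ">=" or "<="
    threshold: float | None = None
    reference: PolymerSpec | None = None

    def __post_init__(self):
        if self.property_name not in PROPERTY_NAMES:
            raise ValueError(f"unknown property {self.property_name!r}")
        if self.cmp not in (">=", "<="):
            raise ValueError("cmp must be '>=' or '<='")
        if (self.threshold is None) == (self.reference is None):
            raise ValueError("exactly one of threshold or reference is required")


@dataclass
class CandidatePolymer:
    """A screened candidate with its prediction, DoV report and flags."""

    monomers: tuple[Monomer, ...]
    chemistry: str
    prediction: EnsemblePrediction | None = None
    dov: DoVReport | None = None
    criteria_passed: dict[str, bool] = field(default_factory=dict)

    @property
    def key(self) -> tuple:
        return (self.chemistry,) + tuple(sorted(m.smiles for m in self.monomers))

    @property
    def passes_performance(self) -> bool:
        return all(self.criteria_passed.values())

    @property
    def passes_all(self) -> bool:
        return self.passes_performance and self.dov is not None and self.dov.inside


_PAIR_RULES = {
    "polyester": (MonomerClass.DIACID, MonomerClass.DIOL),
    "polyamide": (MonomerClass.DIACID, MonomerClass.DIAMINE),
    "polycarbonate": (MonomerClass.CARBONATE_SOURCE, MonomerClass.DIOL),
}
_AB_RULES = {
    "polyester": MonomerClass.HYDROXY_ACID,
    "polyamide": MonomerClass.AMINO_ACID,
}


def enumerate_candidates(
    monomers: list[Monomer], chemistries: list[str]
) -> list[CandidatePolymer]:
    """All compatible AA+BB pairs plus AB homopolymers, deduplicated on the
    canonical (chemistry, sorted monomer SMILES) key."""
    seen: set[tuple] = set()
    out = []
    for chem in chemistries:
        if chem in _PAIR_RULES:
            cls_a, cls_b = _PAIR_RULES[chem]
            for ma in (m for m in monomers if m.monomer_class == cls_a):
                for mb in (m for m in monomers if m.monomer_class == cls_b):
                    cand = CandidatePolymer(monomers=(ma, mb), chemistry=chem)
                    if cand.key not in seen:
                        seen.add(cand.key)
                        out.append(cand)
        if chem in _AB_RULES:
            for m in (x for x in monomers if x.monomer_class == _AB_RULES[chem]):
                cand = CandidatePolymer(monomers=(m,), chemistry=chem)
                if cand.key not in seen:
                    seen.add(cand.key)
                    out.append(cand)
    return out


def _resolve_threshold(
    crit: PerformanceCriterion, ensemble: EnsembleModel, cache: dict
) -> float:
    if crit.threshold is not None:
        return crit.threshold
    key = (crit.reference.chemistry,) + tuple(m.smiles for m in crit.reference.monomers)
    if key not in cache:
        from .model import predict

        cache[key] = predict(ensemble, crit.reference)
    return cache[key].mean[crit.property_name]


def screen(
    candidates: list[CandidatePolymer],
    ensemble: EnsembleModel,
    train_hashes: SubstructureHashSet,
    performance: list[PerformanceCriterion],
    dov_threshold: int = DEFAULT_THRESHOLD,
    dp: int | None = None,
    seed: int = 0,
) -> list[CandidatePolymer]:
    """Predict, DoV-gate and flag every candidate; builder failures are
    logged and the candidate skipped.

    Candidates use 1:1 comonomer composition.  The result is sorted by
    (inside DoV, number of criteria passed, Tg margin), descending.
    """
    dp = dp or ensemble.config.dp_train
    ref_cache: dict = {}
    thresholds = {
        (c.property_name, c.cmp): _resolve_threshold(c, ensemble, ref_cache)
        for c in performance
    }
    screened = []
    for i, cand in enumerate(candidates):
        spec = PolymerSpec(
            monomers=cand.monomers,
            chemistry=cand.chemistry,
            degree_of_polymerization=dp,
            replicate_count=ensemble.config.replicates_predict,
            rng_seed=seed + i,
        )
        try:
            structures = build_replicates(spec)
        except BuilderError as e:
            log.warning("skipping candidate %s: %s", cand.key, e)
            continue
        cand.prediction = predict_structures(ensemble, structures)
        cand.dov = novel_count_merged(structures, train_hashes, threshold=dov_threshold)
        for crit in performance:
            thr = thresholds[(crit.property_name, crit.cmp)]
            val = cand.prediction.mean[crit.property_name]
            ok = val >= thr if crit.cmp == ">=" else val <= thr
            cand.criteria_passed[f"{crit.property_name}{crit.cmp}{thr:.6g}"] = bool(ok)
        screened.append(cand)

    def rank_key(c: CandidatePolymer):
        tg_margin = c.prediction.mean["tg_c"]
        return (
            c.dov.inside,
            sum(c.criteria_passed.values()),
            tg_margin,
        )

    return sorted(screened, key=rank_key, reverse=True)


def funnel_breakdown(candidates: list[CandidatePolymer]) -> dict[tuple[bool, bool], int]:
    """2x2 (inside DoV, passes performance) counts; sums to the candidate
    total."""
    out: dict[tuple[bool, bool], int] = {}
    for c in candidates:
        key = (bool(c.dov and c.dov.inside), c.passes_performance)
        out[key] = out.get(key, 0) + 1
    return out
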