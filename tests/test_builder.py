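import numpy as np
import pytest
from rdkit import Chem

from polyscreen import (
    ChemistryMismatchError,
    GrowthError,
    PolymerSpec,
    build_replicates,
    condensation_step,
    expected_molecular_weight,
    polymerize,
)
from polyscreen.chemistries import condensate_mw


def _spec(monomers, chemistry, dp, **kw):
    return PolymerSpec(
        monomers=tuple(monomers), chemistry=chemistry, degree_of_polymerization=dp, **kw
    )


class TestPolymerize:
    def test_dimer_ester_matches_manual_condensation(self, monomers):
        s = polymerize(_spec([monomers["adipic"], monomers["eg"]], "polyester", 2, rng_seed=1))
        assert s.smiles == Chem.CanonSmiles("OCCOC(=O)CCCCC(=O)O")
        mol = Chem.MolFromSmiles(s.smiles)
        ester = Chem.MolFromSmarts("[CX3](=[OX1])[OX2][CX4]")
        assert len(mol.GetSubstructMatches(ester)) == 1
        # one water eliminated
        assert s.molecular_weight == pytest.approx(146.142 + 62.068 - 18.015, abs=0.01)

    def test_dp_counts_residues(self, monomers):
        for dp in (1, 2, 5, 9):
            s = polymerize(_spec([monomers["adipic"], monomers["eg"]], "polyester", dp))
            assert s.degree_of_polymerization == dp

    def test_vinyl_dp1_is_saturated_monomer(self, monomers):
        s = polymerize(_spec([monomers["propylene"]], "vinyl", 1))
        assert s.smiles == "CCC"

    def test_vinyl_dp6_has_regio_variability(self, monomers):
        smiles = {
            polymerize(_spec([monomers["propylene"]], "vinyl", 6, rng_seed=seed)).smiles
            for seed in range(12)
        }
        assert len(smiles) > 1  # head/tail randomization produces isomers

    def test_omitted_ratios_equal_molar(self, monomers):
        spec_a = _spec([monomers["adipic"], monomers["eg"]], "polyester", 6, rng_seed=4)
        spec_b = _spec(
            [monomers["adipic"], monomers["eg"]],
            "polyester",
            6,
            molar_ratios=(0.5, 0.5),
            rng_seed=4,
        )
        assert polymerize(spec_a).smiles == polymerize(spec_b).smiles

    def test_incompatible_monomer_rejected_at_spec(self, monomers):
        with pytest.raises(ChemistryMismatchError):
            _spec([monomers["adipic"], monomers["hda"]], "polyester", 4)

    def test_blocked_growth_raises(self, monomers):
        # a diacid alone under polyester chemistry: the acid end has no partner
        with pytest.raises(GrowthError, match="carboxylic_acid"):
            polymerize(_spec([monomers["adipic"]], "polyester", 3))


class TestMassBalance:
    @pytest.mark.parametrize("chemistry", ["polyester", "polyamide"])
    def test_condensation_mass_balance_random_specs(self, chemistry, monomers, rng):
        """MW(polymer) = sum residue MW - (DP-1) * MW(water), exact."""
        if chemistry == "polyester":
            pool = [monomers["adipic"], monomers["terephthalic"], monomers["eg"],
                    monomers["bdo"], monomers["propanediol_12"]]
        else:
            pool = [monomers["adipic"], monomers["terephthalic"], monomers["hda"],
                    monomers["ahx"]]
        for _ in range(25):
            dp = int(rng.integers(2, 12))
            spec = _spec(pool, chemistry, dp, rng_seed=int(rng.integers(2**31 - 1)))
            s = polymerize(spec)
            expected = expected_molecular_weight(list(pool), s.residue_sequence, chemistry)
            assert s.molecular_weight == pytest.approx(expected, abs=1e-6)

    def test_polycarbonate_eliminates_methanol(self, monomers):
        spec = _spec([monomers["dmc"], monomers["bdo"]], "polycarbonate", 5, rng_seed=2)
        s = polymerize(spec)
        expected = expected_molecular_weight(
            [monomers["dmc"], monomers["bdo"]], s.residue_sequence, "polycarbonate"
        )
        assert s.molecular_weight == pytest.approx(expected, abs=1e-6)
        assert condensate_mw("polycarbonate") == pytest.approx(32.042, abs=0.01)

    def test_polyurethane_is_addition(self, monomers):
        spec = _spec([monomers["hdi"], monomers["bdo"]], "polyurethane", 5, rng_seed=2)
        s = polymerize(spec)
        expected = expected_molecular_weight(
            [monomers["hdi"], monomers["bdo"]], s.residue_sequence, "polyurethane"
        )
        assert s.molecular_weight == pytest.approx(expected, abs=1e-6)
        assert condensate_mw("polyurethane") == 0.0


class TestCondensationStep:
    def test_step_increments_dp_and_conserves_mass(self, monomers):
        chain = polymerize(_spec([monomers["adipic"], monomers["eg"]], "polyester", 3, rng_seed=0))
        # live end after DP3 (started from either end) accepts the partner class
        partner = (
            monomers["eg"]
            if chain.residue_sequence[-1][0] == 0
            else monomers["adipic"]
        )
        grown = condensation_step(chain, partner)
        assert grown.degree_of_polymerization == chain.degree_of_polymerization + 1
        water = condensate_mw("polyester")
        assert grown.molecular_weight == pytest.approx(
            chain.molecular_weight + partner.molecular_weight - water, abs=1e-6
        )

    def test_incompatible_pair_raises(self, monomers):
        chain = polymerize(_spec([monomers["eg"], monomers["adipic"]], "polyester", 2, rng_seed=7))
        # force an alcohol live end, then offer another diol
        if chain.residue_sequence[-1][0] != 0:
            chain = condensation_step(chain, monomers["eg"])
        with pytest.raises(ChemistryMismatchError):
            condensation_step(chain, monomers["bdo"])


class TestReplicates:
    def test_replicate_count_and_determinism(self, monomers):
        spec = _spec(
            [monomers["adipic"], monomers["eg"]],
            "polyester",
            6,
            replicate_count=7,
            rng_seed=42,
        )
        reps_a = build_replicates(spec)
        reps_b = build_replicates(spec)
        assert len(reps_a) == 7
        assert [s.smiles for s in reps_a] == [s.smiles for s in reps_b]

    def test_symmetric_homopolymer_collapses_to_one_structure(self, monomers):
        spec = _spec(
            [monomers["adipic"], monomers["hda"]],
            "polyamide",
            6,
            replicate_count=10,
            rng_seed=3,
        )
        smiles = {s.smiles for s in build_replicates(spec)}
        assert len(smiles) == 1  # symmetry collapses all orientation choices

    def test_different_seeds_vary_sequences(self, monomers):
        pool = [monomers["adipic"], monomers["eg"], monomers["bdo"]]
        seqs = {
            polymerize(_spec(pool, "polyester", 8, rng_seed=seed)).smiles
            for seed in range(10)
        }
        assert len(seqs) > 1


class TestCompositionStatistics:
    def test_comonomer_fractions_converge(self, monomers):
        """70:30 diol comonomer ratios are recovered within 3 binomial SEs."""
        pool = (monomers["adipic"], monomers["eg"], monomers["bdo"])
        spec = PolymerSpec(
            monomers=pool,
            chemistry="polyester",
            degree_of_polymerization=8,
            molar_ratios=(0.5, 0.35, 0.15),
            replicate_count=250,
            rng_seed=99,
        )
        counts = np.zeros(3)
        for s in build_replicates(spec):
            for idx, _ in s.residue_sequence:
                counts[idx] += 1
        n_diol = counts[1] + counts[2]
        frac = counts[1] / n_diol
        se = np.sqrt(0.7 * 0.3 / n_diol)
        assert abs(frac - 0.7) < 3 * se

    def test_orientation_flags_are_fair(self, monomers):
        """Regio-orientation draws are Bernoulli(1/2) for an asymmetric
        monomer."""
        spec = PolymerSpec(
            monomers=(monomers["adipic"], monomers["propanediol_12"]),
            chemistry="polyester",
            degree_of_polymerization=8,
            replicate_count=250,
            rng_seed=5,
        )
        flags = [
            flag
            for s in build_replicates(spec)
            for idx, flag in s.residue_sequence
            if idx == 1
        ]
        frac = np.mean(flags)
        se = np.sqrt(0.25 / len(flags))
        assert abs(frac - 0.5) < 3 * se

    def test_stereochemistry_preserved(self):
        from polyscreen import classify_monomer

        lactic = classify_monomer("C[C@H](O)C(=O)O")
        s = polymerize(_spec([lactic], "polyester", 4, rng_seed=0))
        assert "@" in s.smiles  # stereocenters survive chain building
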