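import numpy as np
import pytest

from polyscreen import (
    GroupContributionRule,
    MonomerClass,
    PolymerSpec,
    classify_monomer,
    generate_fixture_dataset,
    generate_labels,
    generate_monomer_library,
    group_counts,
    polymerize,
)
from polyscreen.io import (
    DatasetError,
    read_dataset,
    read_monomer_list,
    write_fixture_csv,
)


class TestMonomerLibrary:
    def test_sizes_and_classes(self):
        sizes = {"diacid": 3, "diol": 3, "diamine": 2}
        lib = generate_monomer_library(0, sizes)
        assert len(lib) == 8
        got = {}
        for m in lib:
            got[m.monomer_class.value] = got.get(m.monomer_class.value, 0) + 1
        assert got == sizes

    def test_round_trip_classification(self):
        for m in generate_monomer_library(5):
            assert classify_monomer(m.smiles).monomer_class == m.monomer_class

    def test_seeded_determinism(self):
        a = [m.smiles for m in generate_monomer_library(7)]
        b = [m.smiles for m in generate_monomer_library(7)]
        assert a == b

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            generate_monomer_library(0, {"diacid": 0})


class TestGroupContributionLabels:
    def test_zero_noise_matches_closed_form(self):
        records = generate_fixture_dataset(n_polymers=12, seed=2, dp=6, noise_sd=0.0)
        rule = GroupContributionRule(noise_sd=0.0, rng_seed=3)
        labels = generate_labels([r.structure for r in records], rule)
        for rec, lab in zip(records, labels):
            assert lab.values[0] == pytest.approx(rule.exact_tg(rec.structure.smiles))

    def test_nylon66_dp6_has_five_amide_linkages(self, monomers):
        spec = PolymerSpec(
            monomers=(monomers["adipic"], monomers["hda"]),
            chemistry="polyamide",
            degree_of_polymerization=6,
            rng_seed=0,
        )
        counts = group_counts(polymerize(spec).smiles)
        assert counts["amide"] == 5  # DP-1 linkages in an alternating chain

    def test_amide_coefficient_moves_polyamides_only(self):
        records = generate_fixture_dataset(n_polymers=40, seed=4, dp=6, noise_sd=0.0)
        structures = [r.structure for r in records]
        base = GroupContributionRule(noise_sd=0.0)
        coeffs = dict(base.coefficients)
        coeffs["amide"] *= 2
        boosted = GroupContributionRule(noise_sd=0.0, coefficients=coeffs)
        for rec in records:
            delta = boosted.exact_tg(rec.structure.smiles) - base.exact_tg(
                rec.structure.smiles
            )
            if rec.polymer_class == "polyamide":
                assert delta > 0
            else:
                assert delta == pytest.approx(0.0)

    def test_tg_always_observed_and_masking_applied(self):
        records = generate_fixture_dataset(n_polymers=60, seed=5, dp=6)
        mask = np.stack([r.record.mask for r in records])
        assert mask[:, 0].all()
        frac = mask[:, 1:].mean()
        assert 0.3 < frac < 0.7  # mask probability 0.5

    def test_reproducible_from_seed(self):
        a = generate_fixture_dataset(n_polymers=10, seed=9, dp=4)
        b = generate_fixture_dataset(n_polymers=10, seed=9, dp=4)
        assert [r.structure.smiles for r in a] == [r.structure.smiles for r in b]
        assert np.array_equal(
            np.stack([r.record.values for r in a]),
            np.stack([r.record.values for r in b]),
        )


class TestDatasetIO:
    def test_csv_round_trip(self, tmp_path):
        records, specs = generate_fixture_dataset(
            n_polymers=15, seed=1, dp=4, return_specs=True
        )
        path = tmp_path / "fixture.csv"
        write_fixture_csv(path, specs, records)
        loaded, errors = read_dataset(path, dp_train=4, seed=0)
        assert not errors
        assert len(loaded) == 15
        for orig, back in zip(records, loaded):
            assert back.polymer_class == orig.polymer_class
            assert np.array_equal(back.record.mask, orig.record.mask)
            obs = orig.record.mask
            assert np.allclose(back.record.values[obs], orig.record.values[obs])

    def test_blank_cell_means_masked(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "smiles_1,smiles_2,chemistry,polymer_class,tg_c,tm_c\n"
            "OC(=O)CCCCC(=O)O,OCCO,polyester,polyester,55.0,\n"
        )
        records, errors = read_dataset(path, dp_train=4)
        assert not errors
        assert records[0].record.mask.tolist() == [True] + [False] * 7

    def test_bad_smiles_reported_with_row_number(self, tmp_path):
        path = tmp_path / "d.csv"
        rows = ["OC(=O)CCCCC(=O)O,OCCO,polyester,polyester,55.0"] * 30
        rows[4] = "not((smiles,OCCO,polyester,polyester,55.0"
        path.write_text(
            "smiles_1,smiles_2,chemistry,polymer_class,tg_c\n" + "\n".join(rows) + "\n"
        )
        records, errors = read_dataset(path, dp_train=4)
        assert len(records) == 29
        assert [e.row for e in errors] == [5]
        assert "unparseable" in errors[0].message

    def test_abort_on_failure_rate(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "smiles_1,smiles_2,chemistry,polymer_class,tg_c\n"
            "bad((,OCCO,polyester,polyester,55.0\n"
            "OC(=O)CCCCC(=O)O,OCCO,polyester,polyester,55.0\n"
        )
        with pytest.raises(DatasetError, match="failed to parse"):
            read_dataset(path, dp_train=4)

    def test_monomer_list_formats(self, tmp_path):
        plain = tmp_path / "m.smi"
        plain.write_text("OCCO\nOC(=O)CCCCC(=O)O\n")
        assert read_monomer_list(plain) == ["OCCO", "OC(=O)CCCCC(=O)O"]
        csvf = tmp_path / "m.csv"
        csvf.write_text("smiles,name\nOCCO,ethylene glycol\n")
        assert read_monomer_list(csvf) == ["OCCO"]


class TestFixtureComposition:
    def test_classes_consistent_with_chemistry(self):
        records = generate_fixture_dataset(n_polymers=30, seed=8, dp=4)
        for r in records:
            assert r.polymer_class == r.structure.chemistry

    def test_monomer_classes_cover_both_chemistries(self):
        lib = generate_monomer_library(3)
        classes = {m.monomer_class for m in lib}
        assert {
            MonomerClass.DIACID,
            MonomerClass.DIOL,
            MonomerClass.DIAMINE,
            MonomerClass.HYDROXY_ACID,
        } <= classes
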