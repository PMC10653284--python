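import warnings

import numpy as np
import pytest
from rdkit import Chem

from polyscreen import (
    ModelConfig,
    PolymerSpec,
    bond_contributions,
    export_bond_states,
    featurize,
    predict,
    predict_structures,
    train_cv,
)
from polyscreen.model import ModelError, holdout_mae
from polyscreen.nn import batch_graphs


class TestTrainCv:
    def test_ensemble_has_ten_folds(self, tiny_ensemble):
        assert tiny_ensemble.n_folds == 10

    def test_holdout_is_twenty_percent_stratified(self, tiny_ensemble, fixture_records):
        assert len(tiny_ensemble.holdout) == round(0.2 * len(fixture_records))
        all_classes = [r.polymer_class for r in fixture_records]
        hold_classes = [r.polymer_class for r in tiny_ensemble.holdout]
        for cls in set(all_classes):
            expected = all_classes.count(cls) * 0.2
            assert abs(hold_classes.count(cls) - expected) <= 1

    def test_loss_decreases_during_training(self, tiny_ensemble):
        for hist in tiny_ensemble.history:
            assert hist["loss"][-1] < hist["loss"][0]

    def test_small_class_triggers_stratification_fallback(self, fixture_records):
        records = list(fixture_records[:20])
        records[0] = records[0].__class__(
            structure=records[0].structure,
            record=records[0].record,
            polymer_class="exotic",
        )
        config = ModelConfig(
            atom_feature_len=8, bond_feature_len=8, n_message_layers=2,
            epochs=1, dp_train=6, rng_seed=0,
        )
        with pytest.warns(UserWarning, match="unstratified"):
            train_cv(records, config)

    def test_too_few_records_rejected(self, fixture_records):
        config = ModelConfig(epochs=1)
        with pytest.raises(ModelError, match="at least 13"):
            train_cv(list(fixture_records[:5]), config)


class TestPrediction:
    def test_predictions_in_original_units(self, tiny_ensemble, fixture_records):
        """Tg comes back in °C on the fixture scale, not in scaled units."""
        tg = [r.record.values[0] for r in fixture_records]
        pred = predict_structures(tiny_ensemble, [fixture_records[0].structure])
        assert min(tg) - 100 < pred.mean["tg_c"] < max(tg) + 100
        assert abs(pred.mean["tg_c"]) > 5  # scaled-space values sit near 0
        assert pred.std["tg_c"] >= 0

    def test_identical_fold_models_have_zero_std(self, tiny_ensemble, fixture_records):
        import copy

        ens = copy.copy(tiny_ensemble)
        weights = tiny_ensemble.fold_models[0].get_weights()
        clones = []
        for net in tiny_ensemble.fold_models:
            clone = copy.deepcopy(net)
            clone.set_weights(weights)
            clones.append(clone)
        ens.fold_models = clones
        pred = predict_structures(ens, [fixture_records[0].structure])
        for s in pred.std.values():
            assert s == pytest.approx(0.0, abs=1e-9)

    def test_replicate_averaging_reduces_variance(self, tiny_ensemble, monomers):
        """Across build seeds, 7-replicate predictions vary less than
        single-replicate predictions for an asymmetric copolymer."""

        def tg_series(replicates):
            out = []
            for seed in range(10):
                spec = PolymerSpec(
                    monomers=(monomers["adipic"], monomers["propanediol_12"]),
                    chemistry="polyester",
                    degree_of_polymerization=6,
                    replicate_count=replicates,
                    rng_seed=seed,
                )
                from polyscreen.builder import build_replicates

                structures = build_replicates(spec)
                out.append(predict_structures(tiny_ensemble, structures).mean["tg_c"])
            return np.var(out)

        assert tg_series(7) < tg_series(1)

    def test_predict_builds_replicates(self, tiny_ensemble, monomers):
        spec = PolymerSpec(
            monomers=(monomers["adipic"], monomers["eg"]),
            chemistry="polyester",
            degree_of_polymerization=6,
            rng_seed=0,
        )
        pred = predict(tiny_ensemble, spec)
        assert np.isfinite(pred.mean["tg_c"])

    def test_holdout_mae_is_finite_and_bounded(self, tiny_ensemble, fixture_records):
        mae = holdout_mae(tiny_ensemble, "tg_c")
        tg = [r.record.values[0] for r in fixture_records]
        assert 0 < mae < np.ptp(tg)  # far better than chance on a spread corpus


class TestAttribution:
    def test_contributions_sum_to_scaled_prediction(self, tiny_ensemble, fixture_records):
        structure = fixture_records[0].structure
        att = bond_contributions(tiny_ensemble, structure, "tg_c")
        batch = batch_graphs([featurize(structure.smiles, tiny_ensemble.vocab)])
        fold_preds = [net.forward(batch)[0].data[0, 0] for net in tiny_ensemble.fold_models]
        assert att.total == pytest.approx(float(np.mean(fold_preds)), rel=1e-4)

    def test_unknown_property_rejected(self, tiny_ensemble, fixture_records):
        with pytest.raises(ModelError, match="unknown property"):
            bond_contributions(tiny_ensemble, fixture_records[0].structure, "hardness")


class TestBondStateEmbedding:
    def test_ester_amide_separation_grows_with_depth(self, tiny_ensemble, fixture_records):
        """Trained message passing separates ester from amide bond states
        more at the last layer than at initialization."""
        ester_q = Chem.MolFromSmarts("[CX3](=[OX1])[OX2][CX4]")
        amide_q = Chem.MolFromSmarts("[CX3](=[OX1])[NX3]")

        def states(layer):
            ester_rows, amide_rows = [], []
            for rec in fixture_records[:30]:
                mol = Chem.MolFromSmiles(rec.structure.smiles)
                picks = {}
                for q, rows in [(ester_q, ester_rows), (amide_q, amide_rows)]:
                    bond_ids = set()
                    for match in mol.GetSubstructMatches(q):
                        b = mol.GetBondBetweenAtoms(match[0], match[2])
                        if b is not None:
                            bond_ids.add(b.GetIdx())
                    if bond_ids:
                        g = featurize(rec.structure.smiles, tiny_ensemble.vocab)
                        s = export_bond_states(tiny_ensemble.fold_models[0], g, layer)
                        rows.extend(s[list(bond_ids)])
            return np.array(ester_rows), np.array(amide_rows)

        def centroid_distance(layer):
            ester, amide = states(layer)
            return np.linalg.norm(ester.mean(axis=0) - amide.mean(axis=0))

        last = tiny_ensemble.fold_models[0].n_layers
        assert centroid_distance(last) > centroid_distance(0)
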