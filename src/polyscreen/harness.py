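"""Scaled-down evaluation harnesses.

These drive the library end to end on synthetic fixtures: ensemble
recovery of a known group-contribution rule, the polymer-size /
network-depth interaction, planted-signal bond attribution, and a small
hyperparameter sweep.  Problem sizes (300-polymer corpora, 100-200 epochs,
32-dim states) are chosen so a full run finishes in minutes on one CPU
core while the statistical contracts stay testable.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

from .featurize import build_vocabulary, featurize
from .fixtures import generate_fixture_dataset
from .model import (
    EnsembleModel,
    ModelConfig,
    TrainingRecord,
    _scaled_targets,
    bond_contributions,
    fit_scaler,
    holdout_mae,
    train_cv,
    train_network,
)


def small_fixture_config(seed: int = 0, **overrides) -> ModelConfig:
    """The small training configuration used with fixture corpora:
    2 message layers, 32-dim states, 200 epochs, DP-8 chains."""
    kwargs = dict(
        atom_feature_len=32,
        bond_feature_len=32,
        n_message_layers=2,
        batch_size=32,
        learning_rate=3e-3,
        decay_rate=0.99,
        epochs=200,
        dp_train=8,
        rng_seed=seed,
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def aromatic_attribution_gap(
    ensemble: EnsembleModel, records: list[TrainingRecord], max_structures: int = 20
) -> dict:
    """Mean Tg bond attribution of aromatic-ring bonds minus all other
    bonds, over aromatic-containing structures.

    The fixture rule plants its largest positive coefficient on aromatic
    rings, so a model that recovered the rule assigns those bonds the
    largest contributions.
    """
    arom_vals: list[float] = []
    other_vals: list[float] = []
    used = 0
    for rec in records:
        mol = Chem.MolFromSmiles(rec.structure.smiles)
        is_arom = np.array([b.GetIsAromatic() for b in mol.GetBonds()])
        if not is_arom.any():
            continue
        att = bond_contributions(ensemble, rec.structure, "tg_c")
        arom_vals.extend(att.contributions[is_arom])
        other_vals.extend(att.contributions[~is_arom])
        used += 1
        if used >= max_structures:
            break
    if used == 0:
        raise ValueError("no aromatic-containing structures among the records")
    mean_arom = float(np.mean(arom_vals))
    mean_other = float(np.mean(other_vals))
    return {
        "mean_aromatic": mean_arom,
        "mean_other": mean_other,
        "gap": mean_arom - mean_other,
        "n_structures": used,
    }


def end_to_end_recovery(
    n_polymers: int = 300,
    noise_sd: float = 10.0,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> dict:
    """Train the 10-fold ensemble on a fixture corpus and measure held-out
    Tg MAE plus the planted-signal attribution gap."""
    config = config or small_fixture_config(seed)
    records = generate_fixture_dataset(
        n_polymers=n_polymers, seed=seed, dp=config.dp_train, noise_sd=noise_sd
    )
    ensemble = train_cv(records, config)
    mae = holdout_mae(ensemble, "tg_c")
    attribution = aromatic_attribution_gap(ensemble, ensemble.holdout)
    return {
        "tg_mae_c": mae,
        "noise_sd": noise_sd,
        "n_polymers": n_polymers,
        "attribution": attribution,
        "ensemble": ensemble,
    }


def _single_run_val_loss(
    records: list[TrainingRecord], config: ModelConfig, seed: int
) -> float:
    """Train one network on an 80/20 split; return the final validation
    loss (masked MAE, scaled space)."""
    rng = np.random.default_rng(seed)
    n = len(records)
    order = rng.permutation(n)
    n_val = max(1, n // 5)
    val_idx, train_idx = order[:n_val], order[n_val:]

    train_recs = [records[i] for i in train_idx]
    vocab = build_vocabulary([r.structure for r in train_recs], config.min_count)
    scaler = fit_scaler([r.record for r in train_recs])
    graphs = [featurize(r.structure.smiles, vocab) for r in records]
    targets, masks = _scaled_targets([r.record for r in records], scaler)

    _, hist = train_network(
        [graphs[i] for i in train_idx],
        targets[train_idx],
        masks[train_idx],
        config,
        np.random.default_rng(seed),
        vocab,
        val=([graphs[i] for i in val_idx], targets[val_idx], masks[val_idx]),
    )
    # median of the last 10 epochs smooths step-to-step jitter
    return float(np.median(hist["val_loss"][-10:]))


def depth_size_trend(
    seeds=(0, 1, 2),
    dp: int = 12,
    n_polymers: int = 150,
    epochs: int = 100,
    depths=(2, 8),
) -> dict:
    """Validation loss as a function of network depth on long (DP-12)
    chains: per depth, the median final validation loss over seeds.

    With long chains, deeper message passing can propagate structural
    information across more of the chain, so the 8-layer loss should not
    exceed the 2-layer loss.
    """
    out: dict[int, list[float]] = {d: [] for d in depths}
    for seed in seeds:
        records = generate_fixture_dataset(n_polymers=n_polymers, seed=seed, dp=dp)
        for d in depths:
            config = small_fixture_config(
                seed, n_message_layers=d, epochs=epochs, dp_train=dp
            )
            out[d].append(_single_run_val_loss(records, config, seed))
    return {
        "val_loss": out,
        "median": {d: float(np.median(v)) for d, v in out.items()},
    }


def hyperparameter_sweep(
    grid: dict[str, list] | None = None,
    n_polymers: int = 100,
    seed: int = 0,
    epochs: int = 50,
) -> list[dict]:
    """A small one-factor-at-a-time sweep around the small fixture config;
    returns one row per setting with its final validation loss."""
    grid = grid or {
        "n_message_layers": [1, 2, 4],
        "atom_feature_len": [16, 32],
        "learning_rate": [1e-3, 3e-3],
    }
    records = generate_fixture_dataset(n_polymers=n_polymers, seed=seed)
    rows = []
    for param, values in grid.items():
        for v in values:
            overrides = {param: v, "epochs": epochs}
            if param == "atom_feature_len":
                overrides["bond_feature_len"] = v
            config = small_fixture_config(seed, **overrides)
            loss = _single_run_val_loss(records, config, seed)
            rows.append({"parameter": param, "value": v, "val_loss": loss})
    return rows
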