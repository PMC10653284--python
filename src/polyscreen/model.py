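"""Multi-output property model: robust target scaling, masked-MAE training
over a 10-fold cross-validation ensemble, replicate-averaged prediction and
bond-level attribution.

Targets are the 8 polymer properties: Tg (°C), Tm (°C), density (g/cm³),
modulus (source units), and O2/N2/CO2/H2O permeability (Barrer).  The four
permeabilities span orders of magnitude and are log10-transformed before
robust scaling; predictions are returned in the original units.  Missing
labels carry a 0 mask bit and contribute nothing to the loss or its
gradients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .builder import PolymerSpec, PolymerStructure, build_replicates
from .featurize import FeatureVocabulary, MoleculeGraph, build_vocabulary, featurize
from .nn import Adam, BondGraphNetwork, GraphBatch, backward, batch_graphs, masked_mae_loss

PROPERTY_NAMES = (
    "tg_c",
    "tm_c",
    "density_g_cm3",
    "modulus",
    "perm_o2",
    "perm_n2",
    "perm_co2",
    "perm_h2o",
)
N_PROPERTIES = len(PROPERTY_NAMES)
# permeabilities are modeled in log10 space
LOG_SCALE = np.array([False, False, False, False, True, True, True, True])


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class PropertyRecord:
    """An 8-slot property vector with per-slot observation mask."""

    values: np.ndarray  # (8,) float; masked slots carry no meaning
    mask: np.ndarray  # (8,) bool, True = observed

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.values.shape != (N_PROPERTIES,) or self.mask.shape != (N_PROPERTIES,):
            raise ModelError("PropertyRecord needs 8 values and 8 mask bits")

    @classmethod
    def from_dict(cls, d: dict) -> "PropertyRecord":
        vals = np.full(N_PROPERTIES, np.nan)
        mask = np.zeros(N_PROPERTIES, dtype=bool)
        for i, name in enumerate(PROPERTY_NAMES):
            v = d.get(name)
            if v is not None and not (isinstance(v, float) and np.isnan(v)):
                vals[i] = float(v)
                mask[i] = True
        return cls(vals, mask)


@dataclass(frozen=True)
class TrainingRecord:
    """One labeled polymer: its explicit chain, labels, and class stratum."""

    structure: PolymerStructure
    record: PropertyRecord
    polymer_class: str


def target_transform(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Apply the log10 transform to permeability slots (observed entries
    only).  Non-positive observed permeabilities are rejected."""
    out = np.array(values, dtype=float)
    for i in np.flatnonzero(LOG_SCALE):
        if mask[..., i].any():
            obs = out[..., i][mask[..., i]]
            if np.any(obs <= 0):
                raise ModelError(
                    f"{PROPERTY_NAMES[i]} must be positive for log10 transform"
                )
            out[..., i] = np.where(mask[..., i], np.log10(np.where(mask[..., i], out[..., i], 1.0)), out[..., i])
    return out


def target_inverse(values: np.ndarray) -> np.ndarray:
    out = np.array(values, dtype=float)
    out[..., LOG_SCALE] = 10.0 ** out[..., LOG_SCALE]
    return out


class RobustScaler:
    """Per-property centering by the median and scaling by the interquartile
    range, fitted over observed entries only.  A zero IQR engages a
    degenerate-column guard (scale 1, with a warning)."""

    def __init__(self):
        self.center_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, values: np.ndarray, mask: np.ndarray) -> "RobustScaler":
        values = np.asarray(values, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        center = np.zeros(values.shape[1])
        scale = np.ones(values.shape[1])
        for j in range(values.shape[1]):
            col = values[mask[:, j], j]
            if len(col) < 2:
                raise ModelError(
                    f"property column {j} needs >= 2 observed values to fit the scaler"
                )
            center[j] = np.median(col)
            q1, q3 = np.percentile(col, [25, 75])
            iqr = q3 - q1
            if iqr <= 0:
                warnings.warn(
                    f"property column {j} has zero IQR; using unit scale",
                    stacklevel=2,
                )
                iqr = 1.0
            scale[j] = iqr
        self.center_, self.scale_ = center, scale
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center_) / self.scale_

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.scale_ + self.center_

    def to_json(self) -> str:
        return json.dumps({"center": self.center_.tolist(), "scale": self.scale_.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RobustScaler":
        d = json.loads(text)
        sc = cls()
        sc.center_ = np.asarray(d["center"], dtype=float)
        sc.scale_ = np.asarray(d["scale"], dtype=float)
        return sc


def fit_scaler(records: list[PropertyRecord]) -> RobustScaler:
    """Fit the robust scaler on (log-transformed) training labels."""
    values = np.stack([r.values for r in records])
    mask = np.stack([r.mask for r in records])
    return RobustScaler().fit(target_transform(values, mask), mask)


def masked_mae(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute error over unmasked entries; 0 (with a warning) if all
    entries are masked."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = mask.sum()
    if n == 0:
        warnings.warn("masked_mae over a fully masked batch is defined as 0", stacklevel=2)
        return 0.0
    return float(np.abs(pred - target)[mask].mean())


@dataclass
class ModelConfig:
    """Network and training hyperparameters.

    ``dp_train`` is the DP of the single chain built per labeled monomer set
    for training; prediction uses ``replicates_predict`` replicate chains.
    """

    atom_feature_len: int = 128
    bond_feature_len: int = 128
    n_message_layers: int = 8
    batch_size: int = 32
    learning_rate: float = 1e-3
    decay_rate: float = 0.995
    epochs: int = 1000
    dp_train: int = 12
    replicates_predict: int = 7
    min_count: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("atom_feature_len", "bond_feature_len", "n_message_layers",
                     "batch_size", "epochs", "dp_train", "replicates_predict"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


@dataclass
class EnsemblePrediction:
    """Fold-ensemble prediction in original property units."""

    mean: dict[str, float]
    std: dict[str, float]


@dataclass
class BondAttribution:
    """Per-bond additive contributions (scaled space) for one property,
    aligned to the bonds of ``graph``/``structure``."""

    property_name: str
    contributions: np.ndarray
    structure: PolymerStructure | None = None

    @property
    def total(self) -> float:
        return float(self.contributions.sum())


@dataclass
class EnsembleModel:
    """10 cross-validation fold networks sharing one vocabulary, scaler and
    config, plus the stratified 20% holdout for reporting."""

    fold_models: list[BondGraphNetwork]
    vocab: FeatureVocabulary
    scaler: RobustScaler
    config: ModelConfig
    history: list[dict] = field(default_factory=list)
    holdout: list[TrainingRecord] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.fold_models)


# ---------------------------------------------------------------------------
# training


def _scaled_targets(records: list[PropertyRecord], scaler: RobustScaler):
    values = np.stack([r.values for r in records])
    mask = np.stack([r.mask for r in records])
    transformed = target_transform(values, mask)
    scaled = scaler.transform(transformed)
    scaled = np.where(mask, scaled, 0.0)
    return scaled, mask


def _new_network(vocab: FeatureVocabulary, config: ModelConfig, rng) -> BondGraphNetwork:
    return BondGraphNetwork(
        n_atom_tokens=vocab.n_atom_tokens,
        n_bond_tokens=vocab.n_bond_tokens,
        atom_dim=config.atom_feature_len,
        bond_dim=config.bond_feature_len,
        n_layers=config.n_message_layers,
        n_outputs=N_PROPERTIES,
        rng=rng,
    )


def train_network(
    graphs: list[MoleculeGraph],
    targets: np.ndarray,
    masks: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
    vocab: FeatureVocabulary,
    val: tuple | None = None,
):
    """Train one network with Adam and per-epoch exponential learning-rate
    decay; returns (network, history of per-epoch losses)."""
    net = _new_network(vocab, config, rng)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    n = len(graphs)
    history = {"loss": [], "val_loss": []}

    val_batch = None
    if val is not None:
        val_graphs, val_targets, val_masks = val
        val_batch = batch_graphs(val_graphs)

    for epoch in range(config.epochs):
        opt.set_lr(config.learning_rate * config.decay_rate**epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_obs = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = batch_graphs([graphs[i] for i in idx])
            pred, _ = net.forward(batch)
            loss = masked_mae_loss(pred, targets[idx], masks[idx])
            opt.zero_grad()
            backward(loss)
            opt.step()
            k = int(masks[idx].sum())
            epoch_loss += float(loss.data) * k
            n_obs += k
        history["loss"].append(epoch_loss / max(n_obs, 1))
        if val_batch is not None:
            vpred, _ = net.forward(val_batch)
            history["val_loss"].append(masked_mae(vpred.data, val_targets, val_masks))
    return net, history


def stratified_split(records: list[TrainingRecord], config: ModelConfig):
    """20% stratified holdout, then stratified 10-fold assignment of the
    remainder.  Falls back to unstratified splitting (with a warning) when a
    class is too small."""
    classes = np.array([r.polymer_class for r in records])
    idx = np.arange(len(records))
    _, counts = np.unique(classes, return_counts=True)
    stratify = classes if counts.min() >= 2 else None
    if stratify is None:
        warnings.warn("a polymer class has < 2 members; holdout split unstratified")
    rest, hold = train_test_split(
        idx, test_size=0.2, stratify=stratify, random_state=config.rng_seed
    )

    rest_classes = classes[rest]
    _, rest_counts = np.unique(rest_classes, return_counts=True)
    if rest_counts.min() >= 10:
        kf = StratifiedKFold(n_splits=10, shuffle=True, random_state=config.rng_seed)
        folds = list(kf.split(rest, rest_classes))
    else:
        warnings.warn(
            "a polymer class has < 10 members; 10-fold assignment unstratified"
        )
        kf = KFold(n_splits=10, shuffle=True, random_state=config.rng_seed)
        folds = list(kf.split(rest))
    return rest, hold, folds


def train_cv(records: list[TrainingRecord], config: ModelConfig) -> EnsembleModel:
    """Train the 10-fold cross-validation ensemble.

    20% of the data is held out (stratified by polymer class); each of the
    10 folds trains on 9/10 of the remainder and validates on the held
    fold.  The vocabulary and scaler are fitted on the full 80% split and
    shared across folds.
    """
    if len(records) < 13:
        raise ModelError("need at least 13 records for a 20% holdout plus 10 folds")
    rest, hold, folds = stratified_split(records, config)

    train_pool = [records[i] for i in rest]
    vocab = build_vocabulary(
        [r.structure for r in train_pool], min_count=config.min_count
    )
    scaler = fit_scaler([r.record for r in train_pool])
    graphs = [featurize(r.structure.smiles, vocab) for r in train_pool]
    targets, masks = _scaled_targets([r.record for r in train_pool], scaler)

    fold_models = []
    history = []
    for k, (tr, va) in enumerate(folds):
        rng = np.random.default_rng((config.rng_seed, k))
        net, hist = train_network(
            [graphs[i] for i in tr],
            targets[tr],
            masks[tr],
            config,
            rng,
            vocab,
            val=([graphs[i] for i in va], targets[va], masks[va]),
        )
        fold_models.append(net)
        history.append(hist)

    return EnsembleModel(
        fold_models=fold_models,
        vocab=vocab,
        scaler=scaler,
        config=config,
        history=history,
        holdout=[records[i] for i in hold],
    )


# ---------------------------------------------------------------------------
# prediction and attribution


def _predict_scaled(net: BondGraphNetwork, batch: GraphBatch) -> np.ndarray:
    pred, _ = net.forward(batch)
    return pred.data


def predict_structures(
    ensemble: EnsembleModel, structures: list[PolymerStructure]
) -> EnsemblePrediction:
    """Ensemble prediction for replicate chains of one polymer: each fold's
    value is its mean over replicates; mean and std are over folds, in
    original units."""
    batch = batch_graphs([featurize(s.smiles, ensemble.vocab) for s in structures])
    per_fold = []
    for net in ensemble.fold_models:
        scaled = _predict_scaled(net, batch).mean(axis=0)
        per_fold.append(target_inverse(ensemble.scaler.inverse_transform(scaled)))
    per_fold = np.stack(per_fold)
    return EnsemblePrediction(
        mean=dict(zip(PROPERTY_NAMES, per_fold.mean(axis=0))),
        std=dict(zip(PROPERTY_NAMES, per_fold.std(axis=0))),
    )


def predict(ensemble: EnsembleModel, spec: PolymerSpec) -> EnsemblePrediction:
    """Build ``replicates_predict`` chains for the spec and predict."""
    spec = PolymerSpec(
        monomers=spec.monomers,
        chemistry=spec.chemistry,
        degree_of_polymerization=spec.degree_of_polymerization,
        molar_ratios=spec.molar_ratios,
        replicate_count=ensemble.config.replicates_predict,
        rng_seed=spec.rng_seed,
    )
    return predict_structures(ensemble, build_replicates(spec))


def bond_contributions(
    ensemble: EnsembleModel,
    structure: PolymerStructure,
    property_name: str,
) -> BondAttribution:
    """Fold-averaged per-bond contributions (scaled space) for one property.

    The contributions sum exactly to the fold-averaged scaled prediction.
    """
    if property_name not in PROPERTY_NAMES:
        raise ModelError(f"unknown property {property_name!r}")
    col = PROPERTY_NAMES.index(property_name)
    batch = batch_graphs([featurize(structure.smiles, ensemble.vocab)])
    per_fold = []
    for net in ensemble.fold_models:
        _, contrib = net.forward(batch)
        per_fold.append(contrib.data[:, col])
    return BondAttribution(
        property_name=property_name,
        contributions=np.stack(per_fold).mean(axis=0),
        structure=structure,
    )


def export_bond_states(
    net: BondGraphNetwork, graph: MoleculeGraph, layer: int
) -> np.ndarray:
    """Bond-state matrix after ``layer`` message-passing blocks (layer 0 is
    the initial embedding)."""
    if layer < 0 or layer > net.n_layers:
        raise ModelError(f"layer {layer} out of range 0..{net.n_layers}")
    batch = batch_graphs([graph])
    _, _, states = net.forward(batch, collect_bond_states=True)
    return states[layer]


def holdout_mae(ensemble: EnsembleModel, property_name: str = "tg_c") -> float:
    """Ensemble MAE on the 20% holdout, in original units."""
    col = PROPERTY_NAMES.index(property_name)
    errs = []
    for rec in ensemble.holdout:
        if not rec.record.mask[col]:
            continue
        pred = predict_structures(ensemble, [rec.structure]).mean[property_name]
        errs.append(abs(pred - rec.record.values[col]))
    if not errs:
        raise ModelError(f"holdout contains no observed {property_name}")
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# model bundle I/O


def save_ensemble(ensemble: EnsembleModel, path: str | Path) -> None:
    """Write a model bundle: per-fold weights (npz), vocabulary, scaler and
    config JSON."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "vocabulary.json").write_text(ensemble.vocab.to_json())
    (path / "scaler.json").write_text(ensemble.scaler.to_json())
    (path / "config.json").write_text(ensemble.config.to_json())
    for k, net in enumerate(ensemble.fold_models):
        np.savez(path / f"fold_{k}.npz", *net.get_weights())


def load_ensemble(path: str | Path) -> EnsembleModel:
    path = Path(path)
    vocab = FeatureVocabulary.from_json((path / "vocabulary.json").read_text())
    scaler = RobustScaler.from_json((path / "scaler.json").read_text())
    config = ModelConfig.from_json((path / "config.json").read_text())
    fold_models = []
    for f in sorted(path.glob("fold_*.npz")):
        with np.load(f) as data:
            weights = [data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))]
        rng = np.random.default_rng(0)
        net = _new_network(vocab, config, rng)
        net.set_weights(weights)
        fold_models.append(net)
    return EnsembleModel(
        fold_models=fold_models, vocab=vocab, scaler=scaler, config=config
    )
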