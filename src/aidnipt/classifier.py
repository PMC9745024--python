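"""Per-trisomy CNN training, cross-validation and the median ensemble.

For each target trisomy a binary model is trained on TRS images of each
of the three FD representatives (mean, median, IQR) under five-fold
cross-validation: the data are split 5:3:2 into training, validation
and test sets per fold (stratified by label; the test fifth rotates),
each sub-model is selected by validation loss, and a new sample's
per-representative probability is the mean of the five fold models'
outputs.

The ensemble takes, within each fold, the median of the three
representatives' probabilities, and averages those medians across
folds.  (Taking the median of the three fold-averaged probabilities is
a close but not identical alternative; the per-fold-first order is the
one implemented throughout.)  Calls are positive at probability >= 0.5.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .cnn import CNNClassifier, NetConfig
from .trs import REPRESENTATIVES, TRS_HEIGHT, TRS_WIDTH

__all__ = ["TrainConfig", "TrisomyModel", "train_models", "predict_proba",
           "ensemble_median", "call_sample", "DEFAULT_CUTOFF"]

DEFAULT_CUTOFF = 0.5


class FoldingError(ValueError):
    """Raised when cross-validation folds cannot be stratified."""


@dataclass
class TrainConfig:
    """Training hyperparameters shared by all sub-models of one target."""

    learning_rate: float = 3e-3
    n_conv_layers: int = 2
    kernel_size: int = 3
    n_conv_patches: int = 8      # filters in the first conv block
    n_dense_layers: int = 1
    activation: str = "relu"
    dropout_rate: float = 0.25
    folds: int = 5
    split_ratio: tuple[int, int, int] = (5, 3, 2)
    cutoff: float = DEFAULT_CUTOFF
    seed: int = 0
    max_epochs: int = 60
    patience: int = 8
    search_budget: int = 0       # >0 enables a small random hyperparameter search
    pool_input: int = 4
    dense_units: int = 32
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie in (0, 1)")
        if self.activation != "relu":
            raise ValueError("only the relu activation is implemented")

    def net_config(self, seed) -> NetConfig:
        return NetConfig(
            input_shape=(TRS_HEIGHT, TRS_WIDTH),
            pool_input=self.pool_input,
            n_conv=self.n_conv_layers,
            kernel_size=self.kernel_size,
            n_filters=self.n_conv_patches,
            n_dense=self.n_dense_layers,
            dense_units=self.dense_units,
            dropout=self.dropout_rate,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=seed,
        )


@dataclass
class TrisomyModel:
    """All fitted sub-models for one target trisomy.

    ``models[rep][k]`` is the fold-``k`` CNN for representative ``rep``
    (folds x representatives sub-models in total).  ``fold_of`` records
    the test-fold assignment of every training sample, and
    ``cv_probs[rep]`` its held-out probability (predicted by the fold
    in which the sample was in the test split).
    """

    target: str
    config: TrainConfig
    fold_of: np.ndarray
    models: dict[str, list[CNNClassifier]]
    cv_probs: dict[str, np.ndarray] = field(default_factory=dict)
    fit_info: dict = field(default_factory=dict)

    @property
    def n_submodels(self) -> int:
        return sum(len(v) for v in self.models.values())

    def heldout_ensemble(self) -> np.ndarray:
        """Held-out ensemble probability (per-fold median of the three reps)."""
        stacked = np.stack([self.cv_probs[rep] for rep in REPRESENTATIVES])
        return np.median(stacked, axis=0)

    # ------------------------------------------------------------ save/load

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        meta = {
            "target": self.target,
            "config": asdict(self.config),
            "fit_info": self.fit_info,
        }
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=1, default=str)
        arrays = {"fold_of": self.fold_of}
        for rep in REPRESENTATIVES:
            if rep in self.cv_probs:
                arrays[f"cv_probs_{rep}"] = self.cv_probs[rep]
            for k, model in enumerate(self.models[rep]):
                for i, w in enumerate(model.get_weights()):
                    arrays[f"w_{rep}_{k}_{i}"] = w
        np.savez_compressed(os.path.join(directory, "weights.npz"), **arrays)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "TrisomyModel":
        with open(os.path.join(directory, "model.json")) as fh:
            meta = json.load(fh)
        cfg_doc = meta["config"]
        cfg_doc["split_ratio"] = tuple(
            int(x) for x in str(cfg_doc["split_ratio"]).strip("()").split(",") if x.strip()
        ) if isinstance(cfg_doc["split_ratio"], str) else tuple(cfg_doc["split_ratio"])
        config = TrainConfig(**cfg_doc)
        data = np.load(os.path.join(directory, "weights.npz"), allow_pickle=False)
        models: dict[str, list[CNNClassifier]] = {}
        cv_probs: dict[str, np.ndarray] = {}
        for rep in REPRESENTATIVES:
            models[rep] = []
            if f"cv_probs_{rep}" in data:
                cv_probs[rep] = data[f"cv_probs_{rep}"]
            for k in range(config.folds):
                net = CNNClassifier(
                    config.net_config((config.seed, REPRESENTATIVES.index(rep), k)))
                weights = []
                i = 0
                while f"w_{rep}_{k}_{i}" in data:
                    weights.append(data[f"w_{rep}_{k}_{i}"])
                    i += 1
                net.set_weights(weights)
                models[rep].append(net)
        return cls(target=meta["target"], config=config, fold_of=data["fold_of"],
                   models=models, cv_probs=cv_probs, fit_info=meta.get("fit_info", {}))


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Assign each sample a fold 0..n_folds-1, stratified by label."""
    fold_of = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(len(idx)) % n_folds
    return fold_of


def _train_val_split(rest: np.ndarray, labels: np.ndarray, ratio: tuple[int, int, int],
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split the non-test samples into train/val per the 5:3 part of 5:3:2."""
    train_share = ratio[0] / (ratio[0] + ratio[1])
    train_idx, val_idx = [], []
    for cls in np.unique(labels[rest]):
        idx = rng.permutation(rest[labels[rest] == cls])
        n_train = max(int(round(train_share * len(idx))), 1)
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def train_models(images: dict[str, np.ndarray], labels: np.ndarray,
                 config: TrainConfig, target: str = "chr21") -> TrisomyModel:
    """Train the folds x representatives grid of binary CNNs for one target.

    ``images[rep]`` has shape (n_samples, 200, 400); ``labels`` is the
    binary truth for this target.  Deterministic given ``config.seed``:
    fold assignment, splits, initialisation and shuffling all derive
    from it.  Raises :class:`FoldingError` if any fold would be left
    without a positive training example.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    for rep in REPRESENTATIVES:
        if rep not in images:
            raise ValueError(f"missing images for representative {rep!r}")
        if images[rep].shape != (n, TRS_HEIGHT, TRS_WIDTH):
            raise ValueError(f"images[{rep!r}] must be (n, {TRS_HEIGHT}, {TRS_WIDTH})")
    if labels.sum() < config.folds:
        raise FoldingError(
            f"only {int(labels.sum())} positive samples for {config.folds}-fold "
            "stratified cross-validation; every fold needs at least one positive")

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    fold_of = _stratified_folds(labels, config.folds, rng)

    models: dict[str, list[CNNClassifier]] = {rep: [] for rep in REPRESENTATIVES}
    cv_probs = {rep: np.full(n, np.nan) for rep in REPRESENTATIVES}
    fit_info: dict = {"val_loss": {}}
    for k in range(config.folds):
        test = np.flatnonzero(fold_of == k)
        rest = np.flatnonzero(fold_of != k)
        if labels[rest].sum() == 0:
            raise FoldingError(f"fold {k} has no positive training samples; "
                               "use stratified folding")
        split_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, k)))
        train_idx, val_idx = _train_val_split(rest, labels, config.split_ratio, split_rng)
        for rep in REPRESENTATIVES:
            net = CNNClassifier(
                config.net_config((config.seed, REPRESENTATIVES.index(rep), k)))
            info = net.fit(images[rep][train_idx], labels[train_idx],
                           images[rep][val_idx], labels[val_idx])
            models[rep].append(net)
            cv_probs[rep][test] = net.predict_proba(images[rep][test])
            fit_info["val_loss"][f"{rep}/{k}"] = info["best_val_loss"]

    return TrisomyModel(target=target, config=config, fold_of=fold_of,
                        models=models, cv_probs=cv_probs, fit_info=fit_info)


def predict_proba(model: TrisomyModel, images: dict[str, np.ndarray]
                  ) -> dict[str, np.ndarray]:
    """Probabilities for new samples.

    Per representative: the mean of the five fold models' outputs.
    ``ensemble``: per fold, the median of the three representatives,
    then the mean across folds.
    """
    per_fold = {}
    for rep in REPRESENTATIVES:
        arr = np.asarray(images[rep])
        if arr.ndim != 3 or arr.shape[1:] != (TRS_HEIGHT, TRS_WIDTH):
            raise ValueError(f"images[{rep!r}] must be (n, {TRS_HEIGHT}, {TRS_WIDTH})")
        per_fold[rep] = np.stack([m.predict_proba(arr) for m in model.models[rep]])
    out = {rep: per_fold[rep].mean(axis=0) for rep in REPRESENTATIVES}
    fold_medians = np.median(np.stack([per_fold[rep] for rep in REPRESENTATIVES]), axis=0)
    out["ensemble"] = fold_medians.mean(axis=0)
    return out


def ensemble_median(p_mean, p_median, p_iqr):
    """Median of the three per-representative probabilities."""
    return np.median(np.stack([np.asarray(p_mean, dtype=float),
                               np.asarray(p_median, dtype=float),
                               np.asarray(p_iqr, dtype=float)]), axis=0)


def call_sample(probability, cutoff: float = DEFAULT_CUTOFF):
    """Positive call iff probability >= cutoff (boundary inclusive)."""
    return np.asarray(probability) >= cutoff


def random_search(images: dict[str, np.ndarray], labels: np.ndarray,
                  base: TrainConfig, budget: int, target: str = "chr21"
                  ) -> tuple[TrainConfig, TrisomyModel]:
    """Tiny random hyperparameter search (learning rate, filters, dropout).

    Candidates are scored by mean validation loss across sub-models;
    the best configuration's trained model is returned.
    """
    from dataclasses import replace
    rng = np.random.default_rng(np.random.SeedSequence((base.seed, 99)))
    best = (np.inf, base, None)
    for trial in range(max(budget, 1)):
        cfg = replace(
            base,
            learning_rate=float(10 ** rng.uniform(-3.3, -2.2)),
            n_conv_patches=int(rng.choice([4, 8, 16])),
            dropout_rate=float(rng.choice([0.0, 0.25, 0.4])),
            seed=base.seed + trial,
        ) if trial else base
        model = train_models(images, labels, cfg, target=target)
        score = float(np.mean(list(model.fit_info["val_loss"].values())))
        if score < best[0]:
            best = (score, cfg, model)
    return best[1], best[2]
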