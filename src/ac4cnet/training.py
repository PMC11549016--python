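"""Training, cross-validation, FGM robustness attacks and ablations.

The training protocol is Adam at learning rate 0.001 on a cross-entropy
loss, evaluated by k-fold cross-validation (default 10) in which each fold
serves once as the validation set and model parameters are freshly
re-initialized per fold from a fold-derived seed.

The fast-gradient method (FGM) builds the adversarial perturbation
``delta = epsilon * sign(dJ/dx)``.  Integer base codes are not
differentiable, so on path 1 the perturbation is applied to the embedding
output and on path 2 to the PseKNC feature vector; both targets are
selectable, and FGM can run either as a test-time attack or as an auxiliary
adversarial-training loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .autograd import cross_entropy, Adam
from .dataio import RnaRecord, make_folds
from .metrics import FoldMetrics, evaluate_scores, summarize
from .network import DualPathClassifier, NetworkConfig


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 64
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


FgmTarget = Literal["path1-embedding", "path2-features", "both"]
FgmMode = Literal["attack-at-test", "adversarial-train"]


@dataclass(frozen=True)
class FgmConfig:
    epsilon: float = 0.1
    target: FgmTarget = "both"
    mode: FgmMode = "attack-at-test"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def fgm_perturb(gradient: np.ndarray, epsilon: float) -> np.ndarray:
    """``delta = epsilon * sign(gradient)`` with sign(0) = 0.

    Every component of the result lies in {-epsilon, 0, +epsilon}; the
    perturbed input is ``x + delta``.
    """
    gradient = np.asarray(gradient, dtype=float)
    if not np.all(np.isfinite(gradient)):
        raise ValueError("non-finite gradient")
    return epsilon * np.sign(gradient)


# ---------------------------------------------------------------------------
# Single-fold training
# ---------------------------------------------------------------------------

def _input_taps_backward(
    model: DualPathClassifier,
    codes: np.ndarray | None,
    feats: np.ndarray | None,
    labels: np.ndarray,
) -> dict:
    """Evaluation-mode loss backward pass; returns the tapped input tensors."""
    taps: dict = {}
    logits = model.forward_logits(codes, feats, taps=taps)
    loss = cross_entropy(logits, labels)
    loss.backward()
    return taps


def _fgm_deltas(taps: dict, fgm: FgmConfig, config: NetworkConfig
                ) -> tuple[np.ndarray | None, np.ndarray | None]:
    delta_embed = delta_feat = None
    if config.use_path1 and fgm.target in ("path1-embedding", "both"):
        delta_embed = fgm_perturb(taps["embedded"].grad, fgm.epsilon)
    if config.use_path2 and fgm.target in ("path2-features", "both"):
        delta_feat = fgm_perturb(taps["features"].grad, fgm.epsilon)
    return delta_embed, delta_feat


def train_fold(
    train_records: Sequence[RnaRecord],
    val_records: Sequence[RnaRecord],
    net_config: NetworkConfig,
    train_config: TrainConfig,
    fgm: FgmConfig | None = None,
    seed: int | None = None,
    log: list[dict] | None = None,
) -> tuple[DualPathClassifier, FoldMetrics]:
    """Train one model from fresh parameters and report final-epoch validation.

    ``seed`` (default the TrainConfig seed) drives initialization, batch
    shuffling and dropout; identical seeds and data give identical results.
    """
    if not train_records or not val_records:
        raise ValueError("train and validation sets must be non-empty")
    overlap = {r.id for r in train_records} & {r.id for r in val_records}
    if overlap:
        raise ValueError("train/validation sets overlap")
    for part, name in ((train_records, "train"), (val_records, "validation")):
        if len({r.label for r in part}) < 2:
            raise ValueError(f"{name} set must contain both classes")

    seed = train_config.seed if seed is None else seed
    model = DualPathClassifier(net_config, seed=seed)
    rng = np.random.default_rng(seed + 1)

    codes_all, feats_all = model.encode_batch(train_records)
    labels_all = np.array([r.label for r in train_records], dtype=np.int64)
    use1, use2 = net_config.use_path1, net_config.use_path2

    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    n = len(train_records)
    adversarial = fgm is not None and fgm.mode == "adversarial-train"

    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            codes = codes_all[idx] if use1 else None
            feats = feats_all[idx] if use2 else None
            labels = labels_all[idx]
            optimizer.zero_grad()
            taps: dict = {}
            logits = model.forward_logits(
                codes, feats, train=True, dropout_rng=rng, taps=taps
            )
            loss = cross_entropy(logits, labels)
            loss.backward()
            epoch_loss += float(loss.data) * len(idx)
            if adversarial:
                delta_embed, delta_feat = _fgm_deltas(taps, fgm, net_config)
                adv_logits = model.forward_logits(
                    codes, feats, train=True, dropout_rng=rng,
                    delta_embed=delta_embed, delta_feat=delta_feat,
                )
                cross_entropy(adv_logits, labels).backward()
            optimizer.step()
        if log is not None:
            log.append({"epoch": epoch, "loss": epoch_loss / n})

    scores = model.predict_proba(list(val_records))
    val_labels = [r.label for r in val_records]
    return model, evaluate_scores(scores, val_labels)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    fold_metrics: list[FoldMetrics]
    models: list[DualPathClassifier]
    summary: dict[str, tuple[float, float]] = field(init=False)

    def __post_init__(self) -> None:
        self.summary = summarize(self.fold_metrics)

    def table(self) -> pd.DataFrame:
        rows = [dict(fold=i, **m.as_dict()) for i, m in enumerate(self.fold_metrics)]
        return pd.DataFrame(rows)


def cross_validate(
    records: Sequence[RnaRecord],
    k: int = 10,
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    fgm: FgmConfig | None = None,
    keep_models: bool = True,
) -> CrossValidationResult:
    """k-fold cross-validation with per-fold parameter resets.

    Fold seeds are ``master_seed + fold_index``, so each fold's
    initialization is independent yet the whole run is reproducible.
    """
    net_config = net_config or NetworkConfig()
    train_config = train_config or TrainConfig()
    folds = make_folds(records, k=k, seed=train_config.seed)
    fold_metrics: list[FoldMetrics] = []
    models: list[DualPathClassifier] = []
    for i, val_ids in enumerate(folds):
        val = [r for r in records if r.id in val_ids]
        train = [r for r in records if r.id not in val_ids]
        model, metrics = train_fold(
            train, val, net_config, train_config, fgm=fgm,
            seed=train_config.seed + i,
        )
        fold_metrics.append(metrics)
        models.append(model if keep_models else None)
    return CrossValidationResult(fold_metrics=fold_metrics, models=models)


# ---------------------------------------------------------------------------
# FGM attack evaluation
# ---------------------------------------------------------------------------

def attack_evaluate(
    model: DualPathClassifier,
    test_records: Sequence[RnaRecord],
    fgm: FgmConfig,
    batch_size: int = 128,
) -> tuple[FoldMetrics, FoldMetrics]:
    """Clean vs FGM-attacked metrics on a labelled test set.

    The perturbation is built per example from the input gradient of the
    cross-entropy loss at the *true* label, then the example is re-scored
    with ``x + delta``.  With epsilon = 0 the attacked metrics equal the
    clean metrics exactly.
    """
    labels = np.array([r.label for r in test_records], dtype=np.int64)
    clean_scores = model.predict_proba(list(test_records))
    cfg = model.config
    attacked: list[np.ndarray] = []
    for start in range(0, len(test_records), batch_size):
        batch = list(test_records[start : start + batch_size])
        y = labels[start : start + batch_size]
        codes, feats = model.encode_batch(batch)
        codes_in = codes if cfg.use_path1 else None
        feats_in = feats if cfg.use_path2 else None
        taps = _input_taps_backward(model, codes_in, feats_in, y)
        for p in model.parameters():
            p.grad = None
        delta_embed, delta_feat = _fgm_deltas(taps, fgm, cfg)
        logits = model.forward_logits(
            codes_in, feats_in, delta_embed=delta_embed, delta_feat=delta_feat
        )
        attacked.append(logits.softmax(axis=-1).data[:, 1])
    attacked_scores = np.concatenate(attacked)
    return (
        evaluate_scores(clean_scores, labels),
        evaluate_scores(attacked_scores, labels),
    )


# ---------------------------------------------------------------------------
# Ablation grid
# ---------------------------------------------------------------------------

def standard_ablation_grid() -> dict[str, dict]:
    """The canonical ablation cells: feature schemes, paths, PE, attention."""
    return {
        "combined": {},
        "integer-path1": {"use_path2": False, "feature_scheme": "integer"},
        "onehot-path1": {"use_path2": False, "feature_scheme": "onehot"},
        "pseknc-path2": {"use_path1": False},
        "no-positional-encoding": {"use_positional_encoding": False},
        "no-attention": {"use_attention": False},
    }


def run_ablation(
    records: Sequence[RnaRecord],
    grid: dict[str, dict] | None = None,
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int | None = None,
) -> pd.DataFrame:
    """One cross-validation per ablation cell; mean metrics per row."""
    grid = grid if grid is not None else standard_ablation_grid()
    net_config = net_config or NetworkConfig()
    train_config = train_config or TrainConfig()
    k = k or train_config.folds
    rows = []
    for name, overrides in grid.items():
        cfg = net_config.ablate(**overrides)
        result = cross_validate(records, k=k, net_config=cfg,
                                train_config=train_config, keep_models=False)
        row = {"cell": name}
        for metric, (mean, std) in result.summary.items():
            row[metric] = mean
            row[f"{metric}_std"] = std
        rows.append(row)
    return pd.DataFrame(rows)
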