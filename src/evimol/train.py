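"""Training loop, k-fold cross-validation, ensembling and grid search.

All randomness (parameter init, fold assignment, batch order, dropout) flows
from the single ``TrainConfig.seed``, so a run is fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import loss as loss_mod
from .encoder import EncoderConfig
from .loss import LossConfig
from .metrics import bedroc, classification_summary
from .mol_io import LabeledDataset, tally
from .models import (
    EvidentialClassifier,
    PredictionRecord,
    SoftmaxClassifier,
)
from .posterior import binary_entropy

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 1e-3
    k_folds: int = 5
    seed: int = 0
    early_stop_metric: str = "loss"  # or "auroc", "bedroc"
    patience: int = 15
    grid: list = field(default_factory=lambda: [(4, 6)])
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    n_density: int = 6
    batch_norm: bool = True
    loss: LossConfig = field(default_factory=LossConfig)
    stratified: bool = True

    def __post_init__(self):
        if self.early_stop_metric not in ("loss", "auroc", "bedroc", "none"):
            raise ValueError(f"unknown early_stop_metric {self.early_stop_metric!r}")
        for ld, nd in self.grid:
            if not (2 <= ld and 1 <= nd):
                raise ValueError(f"invalid grid cell ({ld}, {nd})")


@dataclass
class TrainedModel:
    """A fitted classifier with its config snapshot and training log."""

    model: EvidentialClassifier | SoftmaxClassifier
    config: TrainConfig
    head: str
    train_log: list = field(default_factory=list)

    def predict(self, data: LabeledDataset | Sequence) -> list[PredictionRecord]:
        mols = list(data)
        return self.model.predict(mols)


def _val_score(probs: np.ndarray, labels: np.ndarray,
               metric: str, val_loss: float) -> float:
    """Higher is better."""
    if metric == "loss":
        return -val_loss
    from sklearn.metrics import roc_auc_score

    if metric == "auroc":
        return float(roc_auc_score(labels, probs))
    return bedroc(probs, labels)


def train_model(train: LabeledDataset, val: LabeledDataset,
                cfg: TrainConfig, head: str = "postnet") -> TrainedModel:
    """Fit an evidential ("postnet") or Softmax baseline model.

    Minimizes the evidential objective (UCE minus weighted Dirichlet
    entropy) or standard cross-entropy by Adam, retaining the parameter
    state that scored best on ``early_stop_metric`` over the validation set.
    """
    from . import autodiff as ad

    if head not in ("postnet", "softmax"):
        raise ValueError(f"unknown head {head!r}")
    counts = train.class_counts
    if counts.n_negative == 0 or counts.n_positive == 0:
        raise ValueError(
            f"training set must contain both classes, got {counts}")
    if len(val) == 0:
        raise ValueError("validation set must be nonempty")

    if head == "postnet":
        model = EvidentialClassifier(cfg.encoder, n_density=cfg.n_density,
                                     batch_norm=cfg.batch_norm, seed=cfg.seed)
        model.class_counts = counts
    else:
        model = SoftmaxClassifier(cfg.encoder, seed=cfg.seed)
        model.class_counts = counts

    train_mols = [m for m in train if m.label is not None]
    labels = np.array([m.label for m in train_mols])
    items = model.encoder.prepare_items(train_mols)  # featurize once
    val_mols = [m for m in val if m.label is not None]
    val_inputs = model.prepare(val_mols)
    val_labels = np.array([m.label for m in val_mols])

    params = model.parameters()
    opt = ad.Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 10_007)
    n = len(train_mols)
    log: list[dict] = []
    best_score = -np.inf
    best_state = None
    best_epoch = -1

    def batch_inputs(idx: np.ndarray):
        if isinstance(items, np.ndarray):
            return items[idx]
        return model.encoder.collate([items[i] for i in idx])

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs >= 2 samples
            opt.zero_grad()
            if head == "postnet":
                a0, a1 = model.forward_alphas(batch_inputs(idx), training=True,
                                              rng=rng)
                lv = loss_mod.batch_loss(a0, a1, labels[idx], cfg.loss)
            else:
                logits = model.forward_logits(batch_inputs(idx), training=True,
                                              rng=rng)
                lv = loss_mod.cross_entropy(logits, labels[idx])
            lv.backward()
            opt.step()
            epoch_losses.append(lv.item())

        # validation pass
        if head == "postnet":
            a0v, a1v = model.forward_alphas(val_inputs, training=False)
            val_probs = (a1v.data / (a0v.data + a1v.data))[:, 0]
            val_loss = loss_mod.batch_loss(a0v, a1v, val_labels, cfg.loss).item()
        else:
            logits = model.forward_logits(val_inputs, training=False)
            shifted = logits.data - logits.data.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            val_probs = e[:, 1] / e.sum(axis=1)
            val_loss = loss_mod.cross_entropy(logits, val_labels).item()
        score = (float(epoch)  # "none": run to the end, keep the final state
                 if cfg.early_stop_metric == "none"
                 else _val_score(val_probs, val_labels, cfg.early_stop_metric,
                                 val_loss))
        log.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                    "val_loss": val_loss, "val_score": score})
        logger.info("epoch %d train_loss %.4f val_loss %.4f score %.4f",
                    epoch, log[-1]["train_loss"], val_loss, score)
        if score > best_score:
            best_score = score
            best_epoch = epoch
            best_state = [p.data.copy() for p in params]
            if head == "postnet" and model.normalizer is not None:
                best_state.append(model.normalizer.running_mean.copy())
                best_state.append(model.normalizer.running_var.copy())
        elif epoch - best_epoch >= cfg.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break

    if best_state is not None:
        for p, s in zip(params, best_state):
            p.data = s
        if head == "postnet" and model.normalizer is not None:
            model.normalizer.running_mean = best_state[-2]
            model.normalizer.running_var = best_state[-1]
    return TrainedModel(model=model, config=cfg, head=head, train_log=log)


def kfold_cv(data: LabeledDataset, cfg: TrainConfig, head: str = "postnet"):
    """Stratified k-fold CV; every sample is predicted once out-of-fold.

    Returns the per-fold trained models and the out-of-fold prediction
    records aligned with ``data`` order.
    """
    mols = [m for m in data if m.label is not None]
    labels = np.array([m.label for m in mols])
    k = cfg.k_folds
    if k < 2:
        raise ValueError("k_folds must be >= 2")
    n_min = min(tally(mols).n_negative, tally(mols).n_positive)
    if cfg.stratified and k > n_min:
        raise ValueError(
            f"cannot stratify {k} folds with minority class count {n_min}")
    splitter = (StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
                if cfg.stratified
                else KFold(n_splits=k, shuffle=True, random_state=cfg.seed))
    models: list[TrainedModel] = []
    oof: list[PredictionRecord | None] = [None] * len(mols)
    for fold, (tr_idx, te_idx) in enumerate(splitter.split(np.zeros(len(mols)), labels)):
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        tr = LabeledDataset([mols[i] for i in tr_idx], name=f"{data.name}-fold{fold}-train")
        te = LabeledDataset([mols[i] for i in te_idx], name=f"{data.name}-fold{fold}-val")
        tm = train_model(tr, te, fold_cfg, head=head)
        for i, rec in zip(te_idx, tm.predict(te)):
            oof[i] = rec
        models.append(tm)
    assert all(r is not None for r in oof)
    return models, oof


def ensemble_predict(models: Sequence[TrainedModel],
                     data: LabeledDataset | Sequence) -> list[PredictionRecord]:
    """Average member predictions; entropy is recomputed from the mean p.

    The averaged evidence is a mean of per-model Dirichlet evidences, not
    the evidence of a single Dirichlet; it is reported for ranking only.
    """
    if not models:
        raise ValueError("need at least one model")
    cfg0 = models[0].model.encoder_config
    for tm in models[1:]:
        if tm.model.encoder_config != cfg0:
            raise ValueError("all ensemble members must share featurization config")
    mols = list(data)
    per_model = [tm.predict(mols) for tm in models]
    out = []
    for i, m in enumerate(mols):
        p = float(np.mean([pm[i].p_mean for pm in per_model]))
        ev = float(np.mean([pm[i].evidence for pm in per_model]))
        a0 = float(np.mean([pm[i].alpha0 for pm in per_model]))
        a1 = float(np.mean([pm[i].alpha1 for pm in per_model]))
        out.append(PredictionRecord(m.mol_id, m.smiles, a0, a1, p, ev,
                                    float(binary_entropy(p))))
    return out


def grid_search(data: LabeledDataset, cfg: TrainConfig,
                grid: Sequence[tuple[int, int]] | None = None,
                metric: str = "auroc"):
    """Evaluate (latent_dim, n_density) cells by k-fold CV out-of-fold metric.

    Returns ``(best_cell, table)`` where table has one row per cell; ties
    break deterministically toward the smaller (latent_dim, n_density).
    """
    cells = sorted(grid if grid is not None else cfg.grid)
    if not cells:
        raise ValueError("empty grid")
    labels = data.labels
    table = []
    best_cell, best_val = None, -np.inf
    for latent_dim, n_density in cells:
        cell_cfg = replace(
            cfg,
            encoder=replace(cfg.encoder, latent_dim=latent_dim),
            n_density=n_density,
        )
        _, oof = kfold_cv(data, cell_cfg, head="postnet")
        probs = np.array([r.p_mean for r in oof])
        value = classification_summary(probs, labels)[metric]
        table.append({"latent_dim": latent_dim, "n_density": n_density,
                      metric: value})
        if value > best_val:  # strict: first (smallest) cell wins ties
            best_val = value
            best_cell = (latent_dim, n_density)
    return best_cell, table
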