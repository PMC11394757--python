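"""Supervised training of the vertex classifier.

Weighted binary cross-entropy on per-vertex labels, Adam (lr 5e-4,
weight decay 1e-5), batches of 4 structures (each structure is its own
graph; batch loss is the vertex-count-weighted mean of per-graph
losses, identical to a disjoint-union batch).  Early stopping on
validation loss within a 50-epoch cap; the best-validation checkpoint is
returned.  Splits are made at the group (family/archetype) level so no
group leaks across train/validation/test.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .nn.layers import Adam


class SplitError(ValueError):
    """Raised when grouped splitting is impossible."""


class TrainingError(RuntimeError):
    """Raised when the dataset cannot be trained on."""


@dataclass
class TrainConfig:
    batch_size: int = 4
    lr: float = 5e-4
    weight_decay: float = 1e-5
    max_epochs: int = 50
    seed: int = 0
    pos_weight: object = "auto"   # "auto" -> negatives/positives of train split
    early_stop_patience: int = 10

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1:
            raise ValueError("lr must be > 0 and batch_size >= 1")


@dataclass
class SplitSpec:
    fractions: tuple = (0.8, 0.1, 0.1)
    group_key: str = "group_key"

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9 or len(self.fractions) != 3:
            raise ValueError("fractions must be 3 values summing to 1")


def make_splits(items, spec: SplitSpec = None, seed: int = 0):
    """Split ``(structure_id, group_key)`` pairs into train/val/test id
    lists, assigning whole groups; deterministic given ``seed``."""
    spec = spec or SplitSpec()
    groups = {}
    for sid, gk in items:
        groups.setdefault(gk, []).append(sid)
    if len(groups) < 3:
        raise SplitError(f"need >=3 distinct groups, got {len(groups)}")
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n = len(keys)
    n_val = max(1, int(round(spec.fractions[1] * n)))
    n_test = max(1, int(round(spec.fractions[2] * n)))
    test_keys = keys[:n_test]
    val_keys = keys[n_test:n_test + n_val]
    train_keys = keys[n_test + n_val:]
    pick = lambda ks: [sid for k in ks for sid in groups[k]]
    return pick(train_keys), pick(val_keys), pick(test_keys)


def _eval(model, graphs, pos_weight):
    model.set_training(False)
    losses, weights = [], []
    probs, labels = [], []
    for enc in graphs:
        logits = model.logits(enc)
        losses.append(nn.bce_with_logits(logits, enc.vertex_labels,
                                         pos_weight).data.item())
        weights.append(len(enc.vertex_labels))
        probs.append(1.0 / (1.0 + np.exp(-logits.data.ravel())))
        labels.append(enc.vertex_labels)
    loss = float(np.average(losses, weights=weights))
    y = np.concatenate(labels)
    p = np.concatenate(probs)
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else float("nan")
    return loss, auc


def auto_pos_weight(graphs) -> float:
    labels = np.concatenate([enc.vertex_labels for enc in graphs])
    pos = int(labels.sum())
    neg = int(len(labels) - pos)
    if pos == 0 or neg == 0:
        raise TrainingError("training labels contain a single class only")
    return neg / pos


def train(train_graphs, model, cfg: TrainConfig = None, val_graphs=None,
          log_path=None):
    """Train ``model`` in place; returns ``(model, per-epoch log)``.

    The log is a list of dicts (epoch, train_loss, val_loss, val_auc).
    The model is restored to the best-validation-loss checkpoint (best
    train loss when no validation set is given).
    """
    cfg = cfg or TrainConfig()
    if not train_graphs:
        raise TrainingError("empty training set")
    pos_weight = (auto_pos_weight(train_graphs) if cfg.pos_weight == "auto"
                  else float(cfg.pos_weight))
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    log = []
    best = {"loss": np.inf, "state": None}
    patience_left = cfg.early_stop_patience
    for epoch in range(cfg.max_epochs):
        model.set_training(True)
        order = rng.permutation(len(train_graphs))
        epoch_losses, epoch_weights = [], []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_graphs[i] for i in order[start:start + cfg.batch_size]]
            n_v = sum(len(enc.vertex_labels) for enc in batch)
            opt.zero_grad()
            batch_loss = 0.0
            # per-graph backward with gradient accumulation: identical to
            # the disjoint-union batch loss, at single-graph peak memory
            for enc in batch:
                loss = nn.bce_with_logits(model.logits(enc),
                                          enc.vertex_labels, pos_weight)
                weighted = loss * (len(enc.vertex_labels) / n_v)
                weighted.backward()
                batch_loss += weighted.data.item()
            opt.step()
            epoch_losses.append(batch_loss)
            epoch_weights.append(n_v)
        train_loss = float(np.average(epoch_losses, weights=epoch_weights))
        if val_graphs:
            val_loss, val_auc = _eval(model, val_graphs, pos_weight)
        else:
            val_loss, val_auc = train_loss, float("nan")
        log.append({"epoch": epoch, "train_loss": train_loss,
                    "val_loss": val_loss, "val_auc": val_auc})
        if val_loss < best["loss"] - 1e-6:
            best = {"loss": val_loss,
                    "state": copy.deepcopy(model.state_arrays())}
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best["state"] is not None:
        model.load_state_arrays(best["state"])
    if log_path is not None:
        import pandas as pd
        pd.DataFrame(log).to_csv(log_path, index=False)
    return model, log
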