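"""Cross-validated training: stratified fold plans, minibatch Adam training
with early stopping, and the k-rotation campaign.

The protocol splits the dataset into k folds (default 10); in rotation r
fold r is the test set, fold (r+1) mod k the early-stopping set, and the
remaining k-2 folds the training set.  Training uses Adam (learning rate
5e-4, minibatch 100) and stops when the early-stopping loss has not
improved for ``early_stop_patience`` epochs, restoring the weights of the
best epoch.  Running all four tasks over 10 rotations trains 40 models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import EncodedDataset
from .models import SpliceModel, build_model

__all__ = [
    "FoldPlan",
    "TrainConfig",
    "TrainingError",
    "make_folds",
    "train_model",
    "run_cross_validation",
]


class TrainingError(RuntimeError):
    """Raised when optimisation diverges (non-finite loss)."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    batch_size: int = 100
    max_epochs: int = 150
    early_stop_patience: int = 10
    seed: int = 0
    init_sigma: float = 0.05
    padding: str = "same"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class FoldPlan:
    """Assignment of events to k folds, stratified by class."""

    k: int
    assignments: dict[str, int]
    seed: int

    def fold_indices(self, event_ids: np.ndarray) -> np.ndarray:
        return np.array([self.assignments[i] for i in event_ids])

    def rotation_roles(self, r: int) -> tuple[int, int, list[int]]:
        """(test fold, early-stop fold, training folds) for rotation r."""
        test = r % self.k
        val = (r + 1) % self.k
        train = [f for f in range(self.k) if f not in (test, val)]
        return test, val, train


def make_folds(dataset: EncodedDataset, k: int = 10, seed: int = 0, stratified: bool = True) -> FoldPlan:
    """Seed-deterministic fold assignment, stratified by class so each fold's
    class proportions match the dataset's within one event."""
    if len(dataset) < k:
        raise ValueError(f"need at least k={k} events, got {len(dataset)}")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    if stratified:
        groups = [np.flatnonzero(dataset.labels == c) for c in np.unique(dataset.labels)]
    else:
        groups = [np.arange(len(dataset))]
    for idx in groups:
        idx = idx[rng.permutation(len(idx))]
        for fold, chunk in enumerate(np.array_split(idx, k)):
            for i in chunk:
                assignments[dataset.event_ids[i]] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def train_model(
    model: SpliceModel,
    train: tuple[dict, np.ndarray],
    val: tuple[dict, np.ndarray],
    cfg: TrainConfig | None = None,
) -> tuple[SpliceModel, History]:
    """Minibatch Adam training with early stopping on the validation loss.

    Returns the model carrying the weights of the best validation epoch.
    With ``max_epochs=0`` the initialized model is returned untouched.
    """
    cfg = cfg or TrainConfig()
    train_batch, y_train = train
    val_batch, y_val = val
    n = len(y_train)
    if n == 0:
        raise ValueError("empty training set")
    opt = model.make_optimizer(lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0])
    history = History()
    best_val = np.inf
    best_weights = model.get_weights()
    history.best_epoch = -1
    since_best = 0
    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            batch = {k: v[sel] for k, v in train_batch.items()}
            opt.zero_grad()
            try:
                loss = model.train_step_grads(batch, y_train[sel])
            except FloatingPointError as exc:
                raise TrainingError(f"divergent loss at epoch {epoch}") from exc
            opt.step()
            epoch_loss += loss * len(sel)
        history.train_loss.append(epoch_loss / n)
        vloss = model.loss(val_batch, y_val, training=False)
        history.val_loss.append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                history.stopped_epoch = epoch
                break
    model.set_weights(best_weights)
    return model, history


def run_cross_validation(
    dataset: EncodedDataset,
    task: str,
    cfg: TrainConfig | None = None,
    k: int = 10,
    plan: FoldPlan | None = None,
) -> tuple[list[SpliceModel], pd.DataFrame]:
    """Train k rotations of one task and collect held-out predictions.

    Each event of the task's subset appears in exactly one rotation's test
    set.  Predictions are returned as a long DataFrame with columns
    event_id, task, fold, true_label, level, stratum and either ``score``
    (binary tasks) or ``p_CON..p_ALT5`` (DSC).
    """
    cfg = cfg or TrainConfig()
    sub = dataset.task_subset(task)
    y = sub.task_targets(task)
    if plan is None:
        plan = make_folds(sub, k=k, seed=cfg.seed)
    folds = plan.fold_indices(sub.event_ids)
    models: list[SpliceModel] = []
    rows: list[pd.DataFrame] = []
    for r in range(plan.k):
        test_f, val_f, train_fs = plan.rotation_roles(r)
        tr = np.flatnonzero(np.isin(folds, train_fs))
        va = np.flatnonzero(folds == val_f)
        te = np.flatnonzero(folds == test_f)
        assert not (set(tr) & set(te)) and not (set(va) & set(te))  # leakage check
        seed_r = int(np.random.SeedSequence([cfg.seed, 100 + r]).generate_state(1)[0] % (2**31))
        model = build_model(task, seed=seed_r, padding=cfg.padding, init_sigma=cfg.init_sigma)
        train_sub, val_sub, test_sub = sub.subset(tr), sub.subset(va), sub.subset(te)
        model, _ = train_model(
            model,
            (train_sub.batch(), y[tr]),
            (val_sub.batch(), y[va]),
            TrainConfig(
                learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size,
                max_epochs=cfg.max_epochs,
                early_stop_patience=cfg.early_stop_patience,
                seed=seed_r,
                init_sigma=cfg.init_sigma,
                padding=cfg.padding,
            ),
        )
        models.append(model)
        preds = model.predict(test_sub.batch())
        frame = {
            "event_id": test_sub.event_ids,
            "task": task,
            "fold": r,
            "true_label": test_sub.labels,
            "level": test_sub.levels,
            "stratum": np.where(
                test_sub.labels == "CON", "CON", np.where(test_sub.levels > 0.8, "HEvents", "MREvents")
            ),
        }
        if task == "DSC":
            for j, cls in enumerate(("CON", "ES", "ALT3", "ALT5")):
                frame[f"p_{cls}"] = preds[:, j]
        else:
            frame["score"] = preds
        rows.append(pd.DataFrame(frame))
    return models, pd.concat(rows, ignore_index=True)
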