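"""Mini-batch training with validation-based early stopping.

Sequences are bucketed into shuffled mini-batches (default size 15) and
padded to the batch maximum length; padding is marked in a boolean mask
consumed by the network and the loss.  Optimisation uses Adam (lr 5e-4,
eps 1e-8, betas 0.9/0.99, no weight decay by default).  After every epoch
the total multi-task loss on the validation set is measured; training stops
once it has failed to improve on the best value seen so far for ``patience``
(default 3) consecutive epochs, and the parameters from the best epoch are
restored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import ModelConfig, ProteinRecord, ResidueAnnotations
from .encode import EmbeddingMatrix, one_hot_encode
from .network import MultiTaskModel, encode_angles, save_checkpoint
from .objective import LossBreakdown, multitask_loss
from .nn import Adam


@dataclass
class TrainingExample:
    """One encoded sequence with its padded-ready target arrays."""

    id: str
    x: np.ndarray                 # (L, D)
    q8: np.ndarray                # (L,) int
    q3: np.ndarray                # (L,) int
    disorder: np.ndarray          # (L,) int 0/1
    rsa: np.ndarray               # (L,)
    phi_sincos: np.ndarray        # (L, 2)
    psi_sincos: np.ndarray        # (L, 2)
    valid_regression: np.ndarray  # (L,) bool

    def __len__(self) -> int:
        return self.x.shape[0]


def encode_dataset(
    pairs: Sequence[tuple[ProteinRecord, ResidueAnnotations]],
    embeddings: dict[str, EmbeddingMatrix] | None = None,
) -> list[TrainingExample]:
    """Turn (record, annotations) pairs into training examples.

    Uses the one-hot baseline encoding unless precomputed embedding
    matrices are supplied.
    """
    out = []
    for record, ann in pairs:
        emb = embeddings[record.id] if embeddings is not None else one_hot_encode(record)
        out.append(TrainingExample(
            id=record.id,
            x=emb.values,
            q8=ann.q8,
            q3=ann.q3,
            disorder=ann.disorder.astype(np.int64),
            rsa=ann.rsa,
            phi_sincos=encode_angles(ann.phi),
            psi_sincos=encode_angles(ann.psi),
            valid_regression=ann.valid_regression,
        ))
    return out


@dataclass
class Batch:
    ids: list[str]
    x: np.ndarray        # (B, Lmax, D)
    mask: np.ndarray     # (B, Lmax) bool, True at real positions
    targets: dict[str, np.ndarray]


def _pad_stack(arrays: list[np.ndarray], L: int, fill=0) -> np.ndarray:
    first = arrays[0]
    shape = (len(arrays), L) + first.shape[1:]
    out = np.full(shape, fill, dtype=first.dtype)
    for i, a in enumerate(arrays):
        out[i, : a.shape[0]] = a
    return out


def make_batches(
    dataset: Sequence[TrainingExample],
    batch_size: int,
    rng: np.random.Generator | None = None,
) -> list[Batch]:
    """Partition the dataset into padded mini-batches.

    Every example appears exactly once; order is shuffled when ``rng`` is
    given, else preserved.  Sequences are padded (trailing) to the batch
    maximum length with an accompanying mask of real positions.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    order = np.arange(len(dataset))
    if rng is not None:
        rng.shuffle(order)
    batches = []
    for lo in range(0, len(order), batch_size):
        chunk = [dataset[i] for i in order[lo:lo + batch_size]]
        L = max(len(ex) for ex in chunk)
        mask = np.zeros((len(chunk), L), dtype=bool)
        for i, ex in enumerate(chunk):
            mask[i, : len(ex)] = True
        batches.append(Batch(
            ids=[ex.id for ex in chunk],
            x=_pad_stack([ex.x for ex in chunk], L),
            mask=mask,
            targets={
                "q8": _pad_stack([ex.q8 for ex in chunk], L),
                "q3": _pad_stack([ex.q3 for ex in chunk], L),
                "disorder": _pad_stack([ex.disorder for ex in chunk], L),
                "rsa": _pad_stack([ex.rsa for ex in chunk], L),
                "phi_sincos": _pad_stack([ex.phi_sincos for ex in chunk], L),
                "psi_sincos": _pad_stack([ex.psi_sincos for ex in chunk], L),
                "valid_regression": _pad_stack(
                    [ex.valid_regression for ex in chunk], L, fill=False),
            },
        ))
    return batches


@dataclass
class TrainHistory:
    """Per-epoch loss records and the early-stopping outcome (1-based epochs)."""

    train_totals: list[float] = field(default_factory=list)
    val_totals: list[float] = field(default_factory=list)
    train_breakdowns: list[LossBreakdown] = field(default_factory=list)
    val_breakdowns: list[LossBreakdown] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


def early_stopping_trace(val_losses: Sequence[float], patience: int) -> tuple[int, int]:
    """Apply the stopping rule to a sequence of validation losses.

    An epoch "improves" when its loss is strictly below the best seen so
    far; training stops once ``patience`` consecutive epochs fail to
    improve.  Returns 1-based ``(best_epoch, stopped_epoch)``.
    """
    best = np.inf
    best_epoch = 0
    since_best = 0
    for epoch, loss in enumerate(val_losses, start=1):
        if loss < best:
            best, best_epoch, since_best = loss, epoch, 0
        else:
            since_best += 1
        if since_best >= patience:
            return best_epoch, epoch
    return best_epoch, len(val_losses)


def _dataset_loss(model: MultiTaskModel, batches: list[Batch],
                  weights) -> LossBreakdown:
    """Residue-weighted mean loss over batches (no gradient bookkeeping kept)."""
    sums = np.zeros(7)
    counts = 0
    for batch in batches:
        out = model(batch.x, batch.mask)
        _, bd = multitask_loss(out, batch.targets, batch.mask, weights)
        n = int(batch.mask.sum())
        vec = np.array([bd.q8, bd.q3, bd.disorder, bd.rsa, bd.phi, bd.psi, bd.total])
        sums += vec * n
        counts += n
    mean = sums / counts
    return LossBreakdown(*mean)


def train(
    model: MultiTaskModel,
    train_set: Sequence[TrainingExample],
    val_set: Sequence[TrainingExample],
    config: ModelConfig,
    checkpoint_path=None,
    log_path=None,
    epoch_callback: Callable[[int, LossBreakdown, LossBreakdown], None] | None = None,
) -> tuple[MultiTaskModel, TrainHistory]:
    """Train with early stopping; returns the best-validation model.

    The training set is reshuffled every epoch from the run seed; validation
    batches are fixed.  On completion the parameters of the best epoch are
    restored into ``model``.

    Raises
    ------
    RuntimeError
        If a non-finite loss is encountered, naming the epoch and batch.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.lr, betas=config.adam_betas,
                     eps=config.adam_eps, weight_decay=config.weight_decay)
    val_batches = make_batches(val_set, config.batch_size, rng=None)
    history = TrainHistory()
    best_state = None
    best_val = np.inf
    since_best = 0
    log_fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(1, config.max_epochs + 1):
            model.train()
            train_sums = np.zeros(7)
            train_n = 0
            for b_idx, batch in enumerate(make_batches(train_set, config.batch_size, rng)):
                out = model(batch.x, batch.mask)
                total, bd = multitask_loss(out, batch.targets, batch.mask,
                                           config.loss_weights)
                if not np.isfinite(bd.total):
                    raise RuntimeError(
                        f"non-finite loss {bd.total} at epoch {epoch}, batch {b_idx}"
                    )
                optimizer.zero_grad()
                total.backward()
                optimizer.step(grad_clip=config.grad_clip)
                n = int(batch.mask.sum())
                train_sums += np.array([bd.q8, bd.q3, bd.disorder, bd.rsa,
                                        bd.phi, bd.psi, bd.total]) * n
                train_n += n
            train_bd = LossBreakdown(*(train_sums / train_n))

            model.eval()
            val_bd = _dataset_loss(model, val_batches, config.loss_weights)
            history.train_breakdowns.append(train_bd)
            history.val_breakdowns.append(val_bd)
            history.train_totals.append(train_bd.total)
            history.val_totals.append(val_bd.total)
            if log_fh:
                log_fh.write(json.dumps({
                    "epoch": epoch, "train": train_bd.as_dict(),
                    "val": val_bd.as_dict()}) + "\n")
                log_fh.flush()
            if epoch_callback is not None:
                epoch_callback(epoch, train_bd, val_bd)

            if val_bd.total < best_val:
                best_val = val_bd.total
                history.best_epoch = epoch
                since_best = 0
                best_state = model.state_dict()
                if checkpoint_path is not None:
                    save_checkpoint(model, checkpoint_path)
            else:
                since_best += 1
            history.stopped_epoch = epoch
            if since_best >= config.patience:
                break
    finally:
        if log_fh:
            log_fh.close()
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
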