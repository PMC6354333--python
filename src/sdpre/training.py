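"""Mini-batch training with cross-entropy loss and Adam.

The default regime follows the reference setup: Adam at learning rate
1e-5, mini-batches of 32, dropout on the fully-connected layer.  All
randomness (shuffling, dropout, parameter init) flows from the single
seed in :class:`TrainConfig`, so single-threaded runs are bitwise
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ._autodiff import Adam, backward
from .corpus_io import EmbeddingTable, IntegrityError
from .model import ModelConfig, RelationClassifier, Vocabulary, make_batch
from .preprocess import RelationInstance

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 30
    seed: int = 0
    early_stop_patience: int | None = None
    val_fraction: float = 0.0  # held-out share used for best-epoch selection
    class_weights: dict | None = None  # optional, off by default

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


def batch_iterator(instances: list[RelationInstance], batch_size: int,
                   rng: np.random.Generator) -> Iterator[list[RelationInstance]]:
    """Shuffled epoch over all instances; the last batch may be smaller."""
    if batch_size < 1:
        raise ValueError("batch_size must be at least 1")
    order = rng.permutation(len(instances))
    for lo in range(0, len(instances), batch_size):
        yield [instances[i] for i in order[lo:lo + batch_size]]


@dataclass
class TrainResult:
    model: RelationClassifier
    loss_trace: list[float]
    val_f_trace: list[float]
    best_epoch: int


def train(instances: list[RelationInstance], model_config: ModelConfig,
          train_config: TrainConfig,
          pretrained: EmbeddingTable | None = None,
          vocab: Vocabulary | None = None) -> TrainResult:
    """Fit the classifier; returns the model plus the per-epoch loss trace.

    When ``val_fraction`` > 0 a document-disjoint tail of the shuffled
    instances is held out, never used for parameter updates, and the
    parameters from the best validation micro-F epoch are restored at the
    end; otherwise the last epoch's model is returned.
    """
    from .evaluation import micro_prf  # local import avoids a cycle

    if not instances:
        raise IntegrityError("cannot train on an empty instance set")
    for inst in instances:
        if not inst.masked_tokens:
            raise IntegrityError(f"{inst.instance_id}: instance has no tokens")

    rng = np.random.default_rng(train_config.seed)
    if vocab is None:
        vocab = Vocabulary.build(instances)
    model = RelationClassifier(model_config, vocab,
                               seed=int(rng.integers(2**31)),
                               pretrained=pretrained)
    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)

    train_set, val_set = instances, []
    if train_config.val_fraction > 0.0:
        docs = sorted({i.doc_id for i in instances})
        rng.shuffle(docs)
        n_val_docs = max(1, int(round(len(docs) * train_config.val_fraction)))
        val_docs = set(docs[:n_val_docs])
        train_set = [i for i in instances if i.doc_id not in val_docs]
        val_set = [i for i in instances if i.doc_id in val_docs]
        if not train_set:
            raise IntegrityError("validation split left no training instances")

    loss_trace: list[float] = []
    val_f_trace: list[float] = []
    best_f, best_epoch, best_params = -1.0, -1, None
    bad_epochs = 0
    for epoch in range(train_config.max_epochs):
        epoch_loss, n_batches = 0.0, 0
        for group in batch_iterator(train_set, train_config.batch_size, rng):
            batch = make_batch(group, vocab, model_config)
            weights = None
            if train_config.class_weights:
                weights = np.array([
                    float(train_config.class_weights.get(g.label.value, 1.0))
                    for g in group
                ])
            optimizer.zero_grad()
            loss = model.loss(batch, train=True, rng=rng, sample_weights=weights)
            backward(loss)
            optimizer.step()
            epoch_loss += float(loss.value)
            n_batches += 1
        loss_trace.append(epoch_loss / n_batches)

        if val_set:
            pred = model.predict(val_set)
            res = micro_prf([i.label for i in val_set], pred)
            val_f_trace.append(res.micro_f)
            if res.micro_f > best_f:
                best_f, best_epoch = res.micro_f, epoch
                best_params = {k: v.value.copy() for k, v in model.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if (train_config.early_stop_patience is not None
                        and bad_epochs > train_config.early_stop_patience):
                    logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                    break
        logger.debug("epoch %d: train loss %.4f", epoch, loss_trace[-1])

    if best_params is not None:
        for k, v in best_params.items():
            model.params[k].value = v
    else:
        best_epoch = len(loss_trace) - 1
    return TrainResult(model=model, loss_trace=loss_trace,
                       val_f_trace=val_f_trace, best_epoch=best_epoch)
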