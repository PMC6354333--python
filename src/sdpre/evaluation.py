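"""Micro-averaged evaluation and 5-fold cross-validation.

Micro precision/recall/F pool true/false positives and false negatives
over the positive relation classes (None is excluded by default, as is
standard for this task: predicting "no relation" correctly should not
inflate the score).  Cross-validation splits by *document*, never by
sentence, so no document contributes to both a training and a test fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import (EmbeddingTable, LABEL_ORDER, POSITIVE_LABELS,
                        RelationLabel)
from .model import LABEL_TO_INDEX, ModelConfig
from .preprocess import RelationInstance
from .training import TrainConfig, train

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    """Micro metrics (0–100 scale), per-class F, and the confusion matrix.

    ``confusion[i, j]`` counts instances with gold label ``LABEL_ORDER[i]``
    predicted as ``LABEL_ORDER[j]``.
    """

    micro_precision: float
    micro_recall: float
    micro_f: float
    per_class_f: dict[RelationLabel, float]
    confusion: np.ndarray

    def as_table(self) -> pd.DataFrame:
        rows = [{"relation": lab.value, "F (%)": round(f, 2)}
                for lab, f in self.per_class_f.items()]
        rows.append({"relation": "micro-average", "F (%)": round(self.micro_f, 2)})
        return pd.DataFrame(rows)


def _f_measure(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def confusion_matrix(gold: list[RelationLabel],
                     pred: list[RelationLabel]) -> np.ndarray:
    mat = np.zeros((len(LABEL_ORDER), len(LABEL_ORDER)), dtype=np.int64)
    for g, p in zip(gold, pred):
        mat[LABEL_TO_INDEX[g], LABEL_TO_INDEX[p]] += 1
    return mat


def result_from_confusion(confusion: np.ndarray,
                          positive_classes: frozenset[RelationLabel] = POSITIVE_LABELS
                          ) -> EvalResult:
    """Micro P/R/F and per-class F recomputed from a confusion matrix."""
    pos_idx = [LABEL_TO_INDEX[l] for l in LABEL_ORDER if l in positive_classes]
    tp = sum(confusion[i, i] for i in pos_idx)
    fp = sum(confusion[:, i].sum() - confusion[i, i] for i in pos_idx)
    fn = sum(confusion[i, :].sum() - confusion[i, i] for i in pos_idx)
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0

    per_class: dict[RelationLabel, float] = {}
    for label in LABEL_ORDER:
        if label not in positive_classes:
            continue
        i = LABEL_TO_INDEX[label]
        p_den = confusion[:, i].sum()
        r_den = confusion[i, :].sum()
        p = 100.0 * confusion[i, i] / p_den if p_den > 0 else 0.0
        r = 100.0 * confusion[i, i] / r_den if r_den > 0 else 0.0
        per_class[label] = _f_measure(p, r)

    return EvalResult(
        micro_precision=precision,
        micro_recall=recall,
        micro_f=_f_measure(precision, recall),
        per_class_f=per_class,
        confusion=confusion,
    )


def micro_prf(gold: list[RelationLabel], pred: list[RelationLabel],
              positive_classes: frozenset[RelationLabel] = POSITIVE_LABELS
              ) -> EvalResult:
    """Micro-averaged P/R/F over the positive classes, on the 0–100 scale."""
    if not gold:
        raise ValueError("cannot evaluate an empty prediction set")
    if len(gold) != len(pred):
        raise ValueError("gold and predicted label lists differ in length")
    return result_from_confusion(confusion_matrix(gold, pred), positive_classes)


@dataclass
class CrossValResult:
    pooled: EvalResult
    per_fold: list[EvalResult]
    fold_documents: list[list[str]]


def assign_folds(doc_ids: list[str], k: int,
                 rng: np.random.Generator) -> list[list[str]]:
    """Partition documents into k folds of near-equal size."""
    docs = sorted(set(doc_ids))
    if len(docs) < k:
        raise ValueError(f"need at least {k} documents for {k}-fold CV, got {len(docs)}")
    order = rng.permutation(len(docs))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(docs[idx])
    return folds


def cross_validate(instances: list[RelationInstance],
                   model_config: ModelConfig,
                   train_config: TrainConfig,
                   k: int = 5,
                   seed: int = 0,
                   pretrained: EmbeddingTable | None = None) -> CrossValResult:
    """Document-level k-fold cross-validation.

    Each fold's model is trained on the other folds' documents and
    predicts the fold's instances; the pooled result is computed from the
    union of all fold predictions (equivalently, the element-wise sum of
    fold confusion matrices).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds = assign_folds([i.doc_id for i in instances], k, rng)

    per_fold: list[EvalResult] = []
    pooled_confusion = np.zeros((len(LABEL_ORDER), len(LABEL_ORDER)), dtype=np.int64)
    for fold_i, test_docs in enumerate(folds):
        test_docs_set = set(test_docs)
        train_set = [i for i in instances if i.doc_id not in test_docs_set]
        test_set = [i for i in instances if i.doc_id in test_docs_set]
        if not test_set:
            logger.warning("fold %d has no instances", fold_i)
            continue
        fold_seed = int(rng.integers(2**31))
        fold_cfg = TrainConfig(**{**train_config.__dict__, "seed": fold_seed})
        result = train(train_set, model_config, fold_cfg, pretrained=pretrained)
        pred = result.model.predict(test_set)
        fold_res = micro_prf([i.label for i in test_set], pred)
        per_fold.append(fold_res)
        pooled_confusion += fold_res.confusion
        logger.info("fold %d micro-F %.2f", fold_i, fold_res.micro_f)

    return CrossValResult(
        pooled=result_from_confusion(pooled_confusion),
        per_fold=per_fold,
        fold_documents=folds,
    )
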