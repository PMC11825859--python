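"""Pixel-pooled evaluation metrics and the MCA weight summary.

Every pixel of every evaluated patch enters one flat pool (duplicates from
oversampled cancer patches included), over which the ROC/AUC and the pooled
(micro) cancer Dice at threshold 0.5 are computed.  Repeated-run reports are
aggregated as mean +/- sample standard deviation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics

log = logging.getLogger(__name__)


@dataclass
class PixelPool:
    probabilities: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64).ravel()
        self.labels = np.asarray(self.labels).ravel()
        if self.probabilities.shape != self.labels.shape:
            raise ValueError("probabilities and labels differ in length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        self.labels = self.labels.astype(np.int8)

    def __len__(self):
        return len(self.labels)


@dataclass
class MetricsReport:
    auc: float
    cancer_dice: float
    n_pixels: int
    threshold: float = 0.5


@dataclass
class MCAWeightSummary:
    """Entrywise means of the query/key/value projections per fusion stage."""

    stages: list          # [(label, q_mean, k_mean, v_mean)]
    init_row: tuple = ("Weight init", 0.0, 1.0, 1.0)

    def to_dataframe(self):
        import pandas as pd
        rows = [dict(cross=self.init_row[0], queries=self.init_row[1],
                     keys=self.init_row[2], values=self.init_row[3])]
        rows += [dict(cross=lbl, queries=q, keys=k, values=v)
                 for lbl, q, k, v in self.stages]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------- operations
def pool_pixels(predictions, masks) -> PixelPool:
    """Concatenate per-patch probability maps and masks, keeping duplicates."""
    predictions = list(predictions)
    masks = list(masks)
    if not predictions:
        raise ValueError("empty prediction set")
    if len(predictions) != len(masks):
        raise ValueError("predictions and masks differ in count")
    probs, labs = [], []
    for p, m in zip(predictions, masks):
        p = np.asarray(p)
        m = np.asarray(m)
        if p.shape != m.shape:
            raise ValueError(f"patch shape mismatch: {p.shape} vs {m.shape}")
        probs.append(p.ravel())
        labs.append(m.ravel())
    return PixelPool(np.concatenate(probs), np.concatenate(labs))


def roc_auc(pool: PixelPool) -> float:
    """Trapezoidal AUC over the pooled ROC; midrank tie handling."""
    if pool.labels.min() == pool.labels.max():
        raise ValueError("AUC undefined: pool contains a single class")
    return float(skmetrics.roc_auc_score(pool.labels, pool.probabilities))


def cancer_dice(pool: PixelPool, threshold: float = 0.5) -> float:
    """Pooled (micro) Dice of the cancer class after binarizing at 0.5."""
    pred = pool.probabilities >= threshold
    lab = pool.labels.astype(bool)
    tp = int((pred & lab).sum())
    fp = int((pred & ~lab).sum())
    fn = int((~pred & lab).sum())
    if tp + fp + fn == 0:
        log.info("no positive labels or predictions: Dice defined as 1.0")
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def per_patch_dice(predictions, masks, threshold: float = 0.5) -> np.ndarray:
    """Diagnostic macro variant: one Dice per patch."""
    return np.array([cancer_dice(pool_pixels([p], [m]), threshold)
                     for p, m in zip(predictions, masks)])


def evaluate_pool(pool: PixelPool, threshold: float = 0.5) -> MetricsReport:
    return MetricsReport(auc=roc_auc(pool),
                         cancer_dice=cancer_dice(pool, threshold),
                         n_pixels=len(pool), threshold=threshold)


def aggregate_runs(reports: list[MetricsReport]):
    """mean +/- sample standard deviation (ddof=1) per metric."""
    if len(reports) < 2:
        raise ValueError("aggregation needs at least 2 run reports")
    out = {}
    for name in ("auc", "cancer_dice"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def mca_weight_summary(model) -> MCAWeightSummary:
    """Table of entrywise weight means per fusion stage.

    The reported quantity is the plain arithmetic mean over all matrix
    entries.  Note the init row is given in the 0/1/1 convention of the
    initialization (zero queries, identity keys/values); the identity
    matrix's *entrywise* mean is 1/d, so freshly initialized stages report
    1/d in the key/value columns.
    """
    from .models import DualSegModel

    if not isinstance(model, DualSegModel):
        raise ValueError("MCA weight summary requires a dual model")
    labels = ("First cross", "Second cross", "Third cross", "Fourth cross")
    stages = []
    for label, blk in zip(labels, model.mca_blocks()):
        stages.append((label,
                       float(blk.q.weight.data.mean()),
                       float(blk.k.weight.data.mean()),
                       float(blk.v.weight.data.mean())))
    return MCAWeightSummary(stages=stages)


def streaming_metrics(batches, threshold: float = 0.5) -> MetricsReport:
    """Streaming equivalent of pooling everything in memory.

    ``batches`` is a sequence of (probabilities, labels) chunks.  Chunks are
    reduced to per-distinct-probability positive/negative counts, from which
    the midrank-tie AUC and the pooled Dice are computed exactly — identical
    to :func:`evaluate_pool` on the concatenated pool, without ever holding
    the whole pool.
    """
    counts: dict[float, list[int]] = {}
    n_total = 0
    for probs, labs in batches:
        probs = np.asarray(probs, dtype=np.float64).ravel()
        labs = np.asarray(labs).ravel().astype(np.int8)
        if probs.shape != labs.shape:
            raise ValueError("chunk shape mismatch")
        n_total += probs.size
        for value, lab in ((v, l) for v, l in zip(*_chunk_counts(probs, labs))):
            c = counts.setdefault(value, [0, 0])
            c[0] += lab[0]
            c[1] += lab[1]
    if not counts:
        raise ValueError("empty prediction set")
    values = np.array(sorted(counts))
    pos = np.array([counts[v][1] for v in values], dtype=np.float64)
    neg = np.array([counts[v][0] for v in values], dtype=np.float64)
    n_pos, n_neg = pos.sum(), neg.sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: pool contains a single class")
    # midrank concordance: P(pos > neg) + 0.5 P(tie)
    neg_below = np.concatenate([[0.0], np.cumsum(neg)[:-1]])
    auc = float((pos * (neg_below + 0.5 * neg)).sum() / (n_pos * n_neg))
    pred_pos = values >= threshold
    tp = float(pos[pred_pos].sum())
    fp = float(neg[pred_pos].sum())
    fn = float(n_pos - tp)
    dice = 1.0 if tp + fp + fn == 0 else 2.0 * tp / (2.0 * tp + fp + fn)
    return MetricsReport(auc=auc, cancer_dice=dice, n_pixels=int(n_total),
                         threshold=threshold)


def _chunk_counts(probs: np.ndarray, labs: np.ndarray):
    values, inverse = np.unique(probs, return_inverse=True)
    neg = np.bincount(inverse, weights=(labs == 0), minlength=len(values))
    pos = np.bincount(inverse, weights=(labs == 1), minlength=len(values))
    return values, np.stack([neg, pos], axis=1).astype(np.int64)
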