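"""Post-hoc interpretation: input-gradient saliency and temporal attention.

Saliency is the absolute gradient of the predicted class's confidence (its
class-vector norm) with respect to the input epoch, elementwise over
channels x time — vanilla input-gradient attribution.

The architecture has exactly one normalized per-time-step weighting: the
routing couplings of a class over the T lower (per-time-step) units.  The
"temporal attention curve" of an epoch is defined as those couplings for
the predicted class at the final routing iteration; by the routing
conservation property the curve sums to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BiLSTMRoutingClassifier

__all__ = [
    "SaliencyMap", "AttentionCurve",
    "saliency_map", "temporal_attention", "aggregate_by_correctness",
]


@dataclass
class SaliencyMap:
    values: np.ndarray  # (C, T), nonnegative
    epoch_id: int
    predicted: int
    correct: bool | None = None


@dataclass
class AttentionCurve:
    values: np.ndarray  # (T,), nonnegative, sums to 1
    epoch_id: int
    correct: bool | None = None


def _check_model(model: BiLSTMRoutingClassifier) -> None:
    for name, p in model.params.items():
        if not np.all(np.isfinite(p)):
            raise ValueError(f"model parameter {name} contains non-finite values")


def saliency_map(model: BiLSTMRoutingClassifier, epoch: np.ndarray,
                 epoch_id: int = 0) -> SaliencyMap:
    """|d norm_predicted / d input| for one (C, T) epoch."""
    _check_model(model)
    if epoch.ndim != 2:
        raise ValueError("epoch must be a single (C, T) array")
    x = epoch[None, None]  # (1, 1, C, T)
    out, cache = model.forward(x, with_cache=True)
    pred = int(out.prediction[0])
    dnorms = np.zeros_like(out.class_norms)
    dnorms[0, pred] = 1.0
    _, dx = model.backward(dnorms, cache, want_input_grad=True)
    # dx is (B, T, C) -> back to (C, T)
    values = np.abs(dx[0].T)
    return SaliencyMap(values=values, epoch_id=epoch_id, predicted=pred)


def temporal_attention(model: BiLSTMRoutingClassifier, epoch: np.ndarray,
                       epoch_id: int = 0) -> AttentionCurve:
    """Final-iteration routing couplings of the predicted class over time."""
    if model.config.variant == "bilstm_only":
        raise ValueError("bilstm_only has no routing couplings; "
                         "temporal attention is undefined")
    _check_model(model)
    if epoch.ndim != 2:
        raise ValueError("epoch must be a single (C, T) array")
    out = model.forward(epoch[None, None])
    pred = int(out.prediction[0])
    values = out.routing.a[0, pred]
    return AttentionCurve(values=values, epoch_id=epoch_id)


@dataclass
class CorrectnessAggregate:
    mean_correct: np.ndarray | None
    mean_incorrect: np.ndarray | None
    n_correct: int
    n_incorrect: int


def aggregate_by_correctness(items: list[np.ndarray], predictions: np.ndarray,
                             labels: np.ndarray) -> CorrectnessAggregate:
    """Elementwise means of maps/curves within correct and incorrect groups.

    An empty group is reported as absent (None), never zero-filled.
    """
    if len(items) != len(predictions) or len(items) != len(labels):
        raise ValueError("items, predictions and labels must align")
    stack = np.stack(items)
    correct = np.asarray(predictions) == np.asarray(labels)
    mean_c = stack[correct].mean(axis=0) if correct.any() else None
    mean_i = stack[~correct].mean(axis=0) if (~correct).any() else None
    return CorrectnessAggregate(
        mean_correct=mean_c, mean_incorrect=mean_i,
        n_correct=int(correct.sum()), n_incorrect=int((~correct).sum()))
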