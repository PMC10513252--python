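"""Detection loss: weighted sum-squared error over the prediction grid.

For each grid cell the target vector is (p, x, w, c) — presence, relative
start, normalized length and the 19 one-hot class coordinates (6 domain
types + 13 lineages).  Cells that contain a domain contribute squared errors
on all coordinates with weight ``lambda_obj``; background cells contribute
only the presence error, down-weighted by ``lambda_nonobj`` because they
vastly outnumber object cells in a 50 kb window.  The returned value is the
mean over the batch of the per-window cell sums.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .. import schema as S


@dataclasses.dataclass(frozen=True)
class LossWeights:
    lambda_obj: float = 1.0
    lambda_nonobj: float = 0.06

    def __post_init__(self) -> None:
        if self.lambda_obj < 0 or self.lambda_nonobj < 0:
            raise ValueError("loss weights must be non-negative")


def _as_batch(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim == 2:
        a = a[None]
    if a.ndim != 3 or a.shape[-1] != S.N_COORDS:
        raise ValueError(f"expected (B, C, {S.N_COORDS}) grids, got shape {a.shape}")
    return a


def detection_loss(pred: np.ndarray, truth: np.ndarray,
                   weights: LossWeights = LossWeights()) -> float:
    """Weighted SSE between a predicted grid and a ground-truth grid.

    Zero iff presence matches everywhere and start/length/classes match on
    the object cells; background cells' start, length and class coordinates
    are unconstrained.
    """
    pred = _as_batch(pred)
    truth = _as_batch(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    obj = truth[..., S.IDX_PRESENCE] == 1.0          # (B, C)
    dp2 = (truth[..., S.IDX_PRESENCE] - pred[..., S.IDX_PRESENCE]) ** 2
    dxw2 = ((truth[..., 1:3] - pred[..., 1:3]) ** 2).sum(axis=-1)
    dc2 = ((truth[..., 3:] - pred[..., 3:]) ** 2).sum(axis=-1)
    per_cell = np.where(
        obj,
        weights.lambda_obj * (dp2 + dxw2 + dc2),
        weights.lambda_nonobj * dp2,
    )
    return float(per_cell.sum(axis=-1).mean())


def detection_loss_grad(pred: np.ndarray, truth: np.ndarray,
                        weights: LossWeights = LossWeights()) -> np.ndarray:
    """Gradient of :func:`detection_loss` with respect to ``pred``."""
    pred = _as_batch(pred)
    truth = _as_batch(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    B = pred.shape[0]
    obj = truth[..., S.IDX_PRESENCE] == 1.0
    grad = np.zeros_like(pred)
    diff = pred - truth
    lam_p = np.where(obj, weights.lambda_obj, weights.lambda_nonobj)
    grad[..., S.IDX_PRESENCE] = 2.0 * lam_p * diff[..., S.IDX_PRESENCE]
    grad[..., 1:] = 2.0 * weights.lambda_obj * obj[..., None] * diff[..., 1:]
    return grad / B
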