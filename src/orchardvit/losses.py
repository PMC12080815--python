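"""Cross-entropy, focal, and measured focal cross-entropy (MFCE) losses.

The MFCE loss blends cross-entropy and focal loss through a probability-
dependent softmax gate.  For a one-hot label with true-class probability
``p`` the three losses are

.. math::

    \\mathrm{CE}(p)    &= -\\log p \\\\
    \\mathrm{FL}(p)    &= -(1-p)^\\gamma \\log p \\\\
    \\mathrm{MFCE}(p)  &= -\\bigl[w_{ce}(p) + w_f(p)(1-p)^\\gamma\\bigr]\\log p

where the gate weights

.. math::

    w_{ce}(p) = \\frac{e^{(1-p)\\,dv}}{e^{p\\,dv} + e^{(1-p)\\,dv}}
              = \\sigma\\bigl((1-2p)\\,dv\\bigr), \\qquad w_f = 1 - w_{ce}

form a two-way softmax with sharpness ``dv``.  A poorly classified sample
(small ``p``) is penalised at near cross-entropy strength, while a well
classified one is down-weighted like focal loss — the property that makes
the loss useful for class-imbalanced training, where plain cross-entropy
lets majority classes dominate the objective.

Every function accepts plain numpy arrays (returning floats/arrays) or
:class:`~orchardvit.autodiff.Tensor` objects (returning a differentiable
node), so the same formulas serve unit tests and the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "LossParams",
    "cross_entropy",
    "focal_loss",
    "gate_weights",
    "mfce_loss",
    "batched_loss",
    "loss_curve",
    "LOSS_KINDS",
]

LOSS_KINDS = ("ce", "focal", "mfce")

GateConvention = Literal["multiplicative", "divisive"]


@dataclass
class LossParams:
    """Hyper-parameters of the loss family.

    Parameters
    ----------
    gamma : float
        Focusing exponent of the focal term; ``gamma=0`` reduces both the
        focal and MFCE losses to cross-entropy.  Must be >= 0.
    dv : float
        Sharpness of the MFCE gate.  ``dv=0`` fixes both gate weights at
        1/2; larger values push the gate harder toward cross-entropy for
        poorly classified samples.  Must be >= 0.
    epsilon : float
        Probabilities are clipped to ``[epsilon, 1]`` before the log.
    reduction : {"mean", "sum", "none"}
        Batch reduction used by :func:`batched_loss`.
    gate_convention : {"multiplicative", "divisive"}
        Whether the gate exponent is ``(1-p)*dv`` (default) or
        ``(1-p)/dv``.  Only the multiplicative form makes larger ``dv``
        bring the loss closer to cross-entropy near ``p=0``.
    """

    gamma: float = 2.0
    dv: float = 1.0
    epsilon: float = 1e-7
    reduction: Literal["mean", "sum", "none"] = "mean"
    gate_convention: GateConvention = "multiplicative"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.dv < 0:
            raise ValueError(f"dv must be >= 0, got {self.dv}")
        if not 0.0 < self.epsilon < 1e-3:
            raise ValueError(f"epsilon must be in (0, 1e-3), got {self.epsilon}")
        if self.reduction not in ("mean", "sum", "none"):
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if self.gate_convention == "divisive" and self.dv == 0:
            raise ValueError("divisive gate convention requires dv > 0")


def _validate_pair(Z, EP, tol: float = 1e-6):
    """Check label/probability vectors and return them as float arrays."""
    Z = np.asarray(Z, dtype=np.float64)
    EP_arr = EP.data if isinstance(EP, Tensor) else np.asarray(EP, dtype=np.float64)
    if Z.shape != EP_arr.shape:
        raise ValueError(f"label shape {Z.shape} != probability shape {EP_arr.shape}")
    if Z.shape[-1] < 2:
        raise ValueError("need at least 2 classes")
    if not np.all((Z == 0) | (Z == 1)) or not np.allclose(Z.sum(axis=-1), 1.0):
        raise ValueError("labels must be one-hot")
    if np.any(EP_arr < -tol) or np.any(EP_arr > 1 + tol):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.allclose(EP_arr.sum(axis=-1), 1.0, atol=tol):
        raise ValueError("probabilities must sum to 1 within 1e-6")
    return Z


def _as_onehot(labels, m: int) -> np.ndarray:
    """Accept integer class indices or one-hot rows; return one-hot."""
    labels = np.asarray(labels)
    if labels.ndim == 1 or (labels.ndim == 0):
        idx = np.atleast_1d(labels).astype(int)
        if np.any(idx < 0) or np.any(idx >= m):
            raise ValueError("class index out of range")
        out = np.zeros((idx.shape[0], m))
        out[np.arange(idx.shape[0]), idx] = 1.0
        return out
    return labels.astype(np.float64)


def cross_entropy(Z, EP, params: LossParams | None = None):
    """Cross-entropy of a one-hot label against a probability vector.

    Returns ``-sum_j Z_j log EP_j`` which, for one-hot ``Z``, is
    ``-log EP_s`` at the true class ``s``.
    """
    params = params or LossParams()
    Z = _validate_pair(Z, EP)
    if isinstance(EP, Tensor):
        p = ad.clip(EP, params.epsilon, 1.0)
        return -(Tensor._lift(Z) * ad.log(p)).sum(axis=-1)
    p = np.clip(np.asarray(EP, dtype=np.float64), params.epsilon, 1.0)
    return _maybe_scalar(-(Z * np.log(p)).sum(axis=-1))


def focal_loss(Z, EP, params: LossParams | None = None):
    """Focal loss: cross-entropy down-weighted by ``(1-p)**gamma``."""
    params = params or LossParams()
    Z = _validate_pair(Z, EP)
    if isinstance(EP, Tensor):
        p = ad.clip(EP, params.epsilon, 1.0)
        return -(Tensor._lift(Z) * (1.0 - p) ** params.gamma * ad.log(p)).sum(axis=-1)
    p = np.clip(np.asarray(EP, dtype=np.float64), params.epsilon, 1.0)
    return _maybe_scalar(-(Z * (1.0 - p) ** params.gamma * np.log(p)).sum(axis=-1))


def gate_weights(p, dv: float, convention: GateConvention = "multiplicative"):
    """MFCE gate weights ``(w_ce, w_f)`` at probability ``p``.

    Computed in the numerically stable logistic form
    ``w_ce = sigma((1-2p)*dv)`` (tanh-based, overflow-free), which equals
    ``exp((1-p)dv) / (exp(p dv) + exp((1-p)dv))``.  ``w_f = 1 - w_ce``
    exactly, so the pair always sums to one.
    """
    if dv < 0:
        raise ValueError("dv must be >= 0")
    scale = dv if convention == "multiplicative" else 1.0 / dv
    if isinstance(p, Tensor):
        t = (1.0 - 2.0 * p) * scale
        w_ce = 0.5 * (ad.tanh(0.5 * t) + 1.0)
        return w_ce, 1.0 - w_ce
    p_arr = np.asarray(p, dtype=np.float64)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("p must lie in [0, 1]")
    t = (1.0 - 2.0 * p_arr) * scale
    w_ce = 0.5 * (np.tanh(0.5 * t) + 1.0)
    out = (w_ce, 1.0 - w_ce)
    if p_arr.ndim == 0:
        return float(out[0]), float(out[1])
    return out


def mfce_loss(Z, EP, params: LossParams | None = None):
    """Measured focal cross-entropy: the gated CE/focal mixture.

    For every class ``j`` the per-class term is
    ``[w_ce(EP_j) + w_f(EP_j)(1-EP_j)**gamma] * (-log EP_j)``, summed
    against the one-hot label; it always lies between the focal loss and
    cross-entropy.
    """
    params = params or LossParams()
    Z = _validate_pair(Z, EP)
    if isinstance(EP, Tensor):
        p = ad.clip(EP, params.epsilon, 1.0)
        w_ce, w_f = gate_weights(p, params.dv, params.gate_convention)
        mix = w_ce + w_f * (1.0 - p) ** params.gamma
        return -(Tensor._lift(Z) * mix * ad.log(p)).sum(axis=-1)
    p = np.clip(np.asarray(EP, dtype=np.float64), params.epsilon, 1.0)
    w_ce, w_f = gate_weights(p, params.dv, params.gate_convention)
    mix = np.asarray(w_ce) + np.asarray(w_f) * (1.0 - p) ** params.gamma
    return _maybe_scalar(-(Z * mix * np.log(p)).sum(axis=-1))


def _maybe_scalar(x: np.ndarray):
    return float(x) if np.ndim(x) == 0 else x


_SCALAR_LOSS = {"ce": cross_entropy, "focal": focal_loss, "mfce": mfce_loss}


def batched_loss(loss_kind: str, labels, probs, params: LossParams | None = None):
    """Apply a loss over a batch and reduce per ``params.reduction``.

    ``labels`` may be one-hot rows or integer class indices; ``probs`` is a
    batch of probability rows (ndarray or differentiable ``Tensor``).
    """
    params = params or LossParams()
    if loss_kind not in _SCALAR_LOSS:
        raise ValueError(f"unknown loss kind {loss_kind!r}; choose from {LOSS_KINDS}")
    p_arr = probs.data if isinstance(probs, Tensor) else np.asarray(probs)
    if p_arr.ndim != 2 or p_arr.shape[0] == 0:
        raise ValueError("probs must be a non-empty batch of probability rows")
    Z = _as_onehot(labels, p_arr.shape[-1])
    per_sample = _SCALAR_LOSS[loss_kind](Z, probs, params)
    if params.reduction == "none":
        return per_sample
    if params.reduction == "sum":
        return per_sample.sum() if isinstance(per_sample, Tensor) else float(np.sum(per_sample))
    return per_sample.mean() if isinstance(per_sample, Tensor) else float(np.mean(per_sample))


def loss_curve(
    loss_kind: str,
    gamma_values: Sequence[float],
    dv_values: Sequence[float],
    grid: Sequence[float],
) -> pd.DataFrame:
    """Evaluate a loss on a grid of true-class probabilities.

    Returns a DataFrame with columns ``p, gamma, dv, loss`` — one row per
    (p, gamma, dv) combination — suitable for plotting the loss-family
    curves or feeding the ordering property tests.
    """
    grid = np.asarray(list(grid), dtype=np.float64)
    if grid.size == 0 or np.any(grid <= 0.0) or np.any(grid >= 1.0):
        raise ValueError("grid values must lie strictly inside (0, 1)")
    rows = []
    for gamma in gamma_values:
        for dv in dv_values:
            params = LossParams(gamma=gamma, dv=dv)
            for p in grid:
                # embed p as the true-class entry of a 2-class distribution
                Z = np.array([1.0, 0.0])
                EP = np.array([p, 1.0 - p])
                val = _SCALAR_LOSS[loss_kind](Z, EP, params)
                rows.append((float(p), float(gamma), float(dv), float(val)))
    return pd.DataFrame(rows, columns=["p", "gamma", "dv", "loss"])
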