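"""The masked, weighted multi-task training objective.

Classification tasks (Q8, Q3, disorder) use categorical cross entropy
averaged over non-padded positions.  Regression tasks (RSA, phi, psi) use
mean squared error, additionally masked at disordered and unknown residues
(their reference values are unreliable); for the angle tasks the squared
errors of the sine and cosine channels are summed per position before
averaging.  Each task's mean is taken over that task's own unmasked
positions; a task with no unmasked position in the batch contributes an
exact zero.  The total is the weighted sum with default weights
1, 5, 5, 100, 5, 5 for Q8, Q3, disorder, RSA, phi, psi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError
from .nn import Tensor, log_softmax


class DegenerateBatchError(ValueError):
    """Raised when a batch contains no unmasked position for any task."""


@dataclass
class LossBreakdown:
    """Per-task loss components and their weighted total."""

    q8: float
    q3: float
    disorder: float
    rsa: float
    phi: float
    psi: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "q8": self.q8, "q3": self.q3, "disorder": self.disorder,
            "rsa": self.rsa, "phi": self.phi, "psi": self.psi,
            "total": self.total,
        }


def _masked_mean(per_position: Tensor, mask: np.ndarray) -> Tensor:
    """Mean of per-position values over True mask entries; exact zero if the
    mask is empty."""
    n = int(mask.sum())
    if n == 0:
        return Tensor(0.0)
    return (per_position * Tensor(mask.astype(np.float64))).sum() * (1.0 / n)


def _cross_entropy(logits: Tensor, classes: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean categorical cross entropy over masked-in positions.

    ``classes`` may hold arbitrary values at masked-out positions; they are
    clipped for safe indexing and excluded by the mask.
    """
    n_classes = logits.shape[-1]
    safe = np.clip(classes, 0, n_classes - 1)
    onehot = np.zeros(logits.shape)
    grid = np.indices(safe.shape)
    onehot[(*grid, safe)] = 1.0
    logp = log_softmax(logits, axis=-1)
    nll = -(logp * Tensor(onehot)).sum(axis=-1)
    return _masked_mean(nll, mask)


def multitask_loss(
    outputs: dict[str, Tensor],
    targets: dict[str, np.ndarray],
    padding_mask: np.ndarray,
    weights: tuple[float, ...] = (1.0, 5.0, 5.0, 100.0, 5.0, 5.0),
) -> tuple[Tensor, LossBreakdown]:
    """Compute the weighted multi-task loss for a padded batch.

    Parameters
    ----------
    outputs
        Raw head outputs from the model: logits for ``q8`` (B, L, 8),
        ``q3`` (B, L, 3), ``disorder`` (B, L, 2); activated values for
        ``rsa`` (B, L, 1) and sine-cosine ``phi``/``psi`` (B, L, 2).
    targets
        ``q8``/``q3`` integer classes and ``disorder`` 0/1 flags (B, L);
        ``rsa`` (B, L); ``phi_sincos``/``psi_sincos`` (B, L, 2);
        ``valid_regression`` boolean (B, L).
    padding_mask
        Boolean (B, L), True at real positions.

    Returns
    -------
    A differentiable total-loss tensor and a float :class:`LossBreakdown`.

    Raises
    ------
    DegenerateBatchError
        If no position in the batch is unmasked for any task.
    """
    if len(weights) != 6:
        raise ValidationError(f"expected six loss weights, got {len(weights)}")
    pad = np.asarray(padding_mask, dtype=bool)
    if not pad.any():
        raise DegenerateBatchError("batch has no unmasked position for any task")
    reg = pad & np.asarray(targets["valid_regression"], dtype=bool)

    l_q8 = _cross_entropy(outputs["q8"], targets["q8"], pad)
    l_q3 = _cross_entropy(outputs["q3"], targets["q3"], pad)
    l_dis = _cross_entropy(outputs["disorder"], targets["disorder"], pad)

    rsa_err = (outputs["rsa"].reshape(pad.shape) - Tensor(targets["rsa"])) ** 2
    l_rsa = _masked_mean(rsa_err, reg)

    def angle_mse(pred: Tensor, target_sc: np.ndarray) -> Tensor:
        err = ((pred - Tensor(target_sc)) ** 2).sum(axis=-1)
        return _masked_mean(err, reg)

    l_phi = angle_mse(outputs["phi"], targets["phi_sincos"])
    l_psi = angle_mse(outputs["psi"], targets["psi_sincos"])

    components = (l_q8, l_q3, l_dis, l_rsa, l_phi, l_psi)
    total = components[0] * weights[0]
    for w, comp in zip(weights[1:], components[1:]):
        total = total + comp * w
    breakdown = LossBreakdown(
        q8=l_q8.item(), q3=l_q3.item(), disorder=l_dis.item(),
        rsa=l_rsa.item(), phi=l_phi.item(), psi=l_psi.item(),
        total=total.item(),
    )
    return total, breakdown
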