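"""The four training objectives and their weighted combination.

* per-modality VAE losses: sum-of-squares reconstruction error plus the
  closed-form KL divergence of the diagonal-Gaussian posterior to the
  standard normal;
* binary cross-entropy on the PD/HC prediction;
* the cross-modality alignment regulariser: the squared cosine distance
  between the two latent means.

Total = alpha * (L_S + L_A) + beta * L_C + gamma * L_D, with defaults
alpha = beta = 0.1, gamma = 1.  Each term is defined per sample and
averaged over the batch, so magnitudes are batch-size invariant.

Public functions operate on NumPy arrays and define the contract; the
``*_t`` counterparts build the identical quantities on autodiff tensors
for training and are tested to agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "recon_sse",
    "kl_to_standard_normal",
    "classification_bce",
    "cosine_distance_sq",
    "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights (alpha, beta, gamma) of the composite objective."""

    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha == self.beta == self.gamma == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class LossBreakdown:
    """Component losses and their weighted total for one step."""

    l_s: float
    l_a: float
    l_c: float
    l_d: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {"l_s": self.l_s, "l_a": self.l_a, "l_c": self.l_c, "l_d": self.l_d, "total": self.total}


def recon_sse(output: np.ndarray, target: np.ndarray, batched: bool = False) -> float:
    """Sum of squared elementwise differences.

    With ``batched=True`` the first axis indexes samples and the
    per-sample sums are averaged over the batch.
    """
    output = np.asarray(output, dtype=float)
    target = np.asarray(target, dtype=float)
    if output.shape != target.shape:
        raise ValueError(f"shape mismatch: {output.shape} vs {target.shape}")
    d = (output - target) ** 2
    if batched:
        return float(d.reshape(d.shape[0], -1).sum(axis=1).mean())
    return float(d.sum())


def kl_to_standard_normal(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL divergence of a diagonal Gaussian N(mu, diag(sigma^2)) to N(0, I).

    Closed form: 0.5 * sum(sigma^2 + mu^2 - 1 - ln sigma^2).  ``sigma``
    holds standard deviations.  Batched inputs (2-D) are averaged over
    the first axis.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    per = 0.5 * (sigma**2 + mu**2 - 1.0 - np.log(sigma**2))
    if mu.ndim == 2:
        return float(per.sum(axis=1).mean())
    return float(per.sum())


def classification_bce(y, p) -> float:
    """Binary cross-entropy -[y ln p + (1-y) ln(1-p)], batch-averaged."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def cosine_distance_sq(mu_a: np.ndarray, mu_s: np.ndarray) -> float:
    """Squared cosine distance (1 - cos(mu_a, mu_s))^2 in [0, 4].

    Batched (2-D) inputs are averaged over rows.  Zero vectors have no
    direction and raise.
    """
    mu_a = np.atleast_2d(np.asarray(mu_a, dtype=float))
    mu_s = np.atleast_2d(np.asarray(mu_s, dtype=float))
    if mu_a.shape != mu_s.shape:
        raise ValueError(f"shape mismatch: {mu_a.shape} vs {mu_s.shape}")
    na = np.linalg.norm(mu_a, axis=1)
    ns = np.linalg.norm(mu_s, axis=1)
    if np.any(na == 0) or np.any(ns == 0):
        raise ValueError("cosine distance is undefined for zero vectors")
    cos = (mu_a * mu_s).sum(axis=1) / (na * ns)
    return float(((1.0 - cos) ** 2).mean())


def total_loss(
    l_s: float, l_a: float, l_c: float, l_d: float, weights: LossWeights | None = None
) -> LossBreakdown:
    """Combine the four components into the weighted training objective."""
    weights = weights or LossWeights()
    comps = {"l_s": l_s, "l_a": l_a, "l_c": l_c, "l_d": l_d}
    for name, v in comps.items():
        if not np.isfinite(v):
            raise ValueError(f"loss component {name} is not finite: {v}")
    total = weights.alpha * (l_s + l_a) + weights.beta * l_c + weights.gamma * l_d
    return LossBreakdown(l_s=l_s, l_a=l_a, l_c=l_c, l_d=l_d, total=total)


# ---------------------------------------------------------------------------
# autodiff-tensor counterparts used inside the training loop
# ---------------------------------------------------------------------------


def recon_sse_t(output: Tensor, target: np.ndarray) -> Tensor:
    """Batch-mean per-sample sum of squared reconstruction errors."""
    d = output - Tensor(target)
    sq = d * d
    batch = target.shape[0]
    return ad.sum_(sq) * float(1.0 / batch)


def kl_to_standard_normal_t(mu: Tensor, sigma: Tensor) -> Tensor:
    """Batch-mean closed-form KL of N(mu, diag(sigma^2)) to N(0, I)."""
    s2 = sigma * sigma
    per = s2 + mu * mu - 1.0 - ad.log(s2)
    batch = mu.shape[0]
    return ad.sum_(per) * float(0.5 / batch)


def cosine_distance_sq_t(mu_a: Tensor, mu_s: Tensor, eps: float = 1e-12) -> Tensor:
    """Batch-mean squared cosine distance between rows of two matrices."""
    dot = ad.sum_(mu_a * mu_s, axis=1)
    na = ad.sum_(mu_a * mu_a, axis=1) ** 0.5
    ns = ad.sum_(mu_s * mu_s, axis=1) ** 0.5
    cos = dot * ((na * ns + eps) ** -1.0)
    one_minus = 1.0 - cos
    return ad.mean_(one_minus * one_minus)


def classification_bce_t(logits: Tensor, y: np.ndarray) -> Tensor:
    """Batch-mean BCE from logits (stable form of :func:`classification_bce`)."""
    return ad.bce_with_logits(logits, y)
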