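"""Component losses, the adversarial value function, and feedback aggregation.

The generator faces K patch discriminators.  Each contributes an adversarial
value V(D_k, G) = E[log D_k(x,y)] + lambda_k E[log(1 - D_k(G(z,x), x))] and
an assigned auxiliary segmentation loss (mean absolute error, categorical
cross-entropy, or Dice).  The feedback the generator receives is an
aggregation F (sum, average, or maximum) over the *active* discriminators —
per batch, the mode is redrawn from ``mode_probs`` and each discriminator
may be dropped with probability ``drop_prob`` (at least one always remains).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ObjectiveConfig",
    "dice_loss",
    "mae_loss",
    "cce_loss",
    "adversarial_value",
    "aggregate_feedback",
    "generator_loss",
    "one_hot",
    "EPS_DICE",
    "EPS_LOG",
]

EPS_DICE = 1e-6
EPS_LOG = 1e-12

AGGREGATION_MODES = ("sum", "average", "maximum")


@dataclass(frozen=True)
class ObjectiveConfig:
    """K discriminators, their weights, losses, and the aggregation policy."""

    K: int = 3
    lambda_k: tuple[float, ...] = (1.0, 1.0, 1.0)
    loss_assignment: tuple[str, ...] = ("mae", "cce", "dice")
    aggregation_mode: str = "sum"
    mode_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    drop_prob: float = 0.1
    aux_weights: tuple[float, ...] | None = None
    saturating: bool = False

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.lambda_k) != self.K or len(self.loss_assignment) != self.K:
            raise ValueError("lambda_k and loss_assignment must have length K")
        if any(l < 0 for l in self.lambda_k):
            raise ValueError("lambda_k must be >= 0")
        for lt in self.loss_assignment:
            if lt not in ("mae", "cce", "dice"):
                raise ValueError(f"unknown auxiliary loss {lt!r}")
        if self.aggregation_mode not in AGGREGATION_MODES:
            raise ValueError(f"unknown aggregation mode {self.aggregation_mode!r}")
        p = np.asarray(self.mode_probs, dtype=float)
        if len(p) != 3 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("mode_probs must be 3 non-negative values summing to 1")
        if not 0.0 <= self.drop_prob < 1.0:
            raise ValueError("drop_prob must be in [0, 1)")

    @classmethod
    def single(cls, loss: str = "cce", **kw) -> "ObjectiveConfig":
        """The K=1 degenerate configuration (the conditional-GAN baseline)."""
        return cls(K=1, lambda_k=(1.0,), loss_assignment=(loss,),
                   mode_probs=(1.0, 0.0, 0.0), drop_prob=0.0, **kw)


def one_hot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    """(H, W) integer mask -> (C, H, W) one-hot encoding."""
    if mask.min() < 0 or mask.max() >= n_classes:
        raise ValueError("mask values outside [0, n_classes)")
    return np.moveaxis(np.eye(n_classes)[mask], -1, 0)


def _check_simplex(pred: np.ndarray, atol: float = 1e-5) -> None:
    s = pred.sum(axis=0)
    if np.any(pred < -atol) or not np.allclose(s, 1.0, atol=atol):
        raise ValueError("pred is not a per-pixel probability simplex")


def dice_loss(pred: np.ndarray, target: np.ndarray,
              return_grad: bool = False):
    """Soft Dice loss averaged over foreground classes.

    ``1 - (2 sum(p t) + eps) / (sum p + sum t + eps)`` per foreground class
    (classes 1..C-1; for binary C=2 this is the usual foreground Dice).
    """
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    _check_simplex(pred)
    c = pred.shape[0]
    fg = list(range(1, c)) if c > 1 else [0]
    losses = []
    grad = np.zeros_like(pred) if return_grad else None
    nfg = len(fg)
    for ci in fg:
        p, t = pred[ci], target[ci]
        inter = float((p * t).sum())
        denom = float(p.sum() + t.sum()) + EPS_DICE
        num = 2.0 * inter + EPS_DICE
        losses.append(1.0 - num / denom)
        if return_grad:
            grad[ci] = -(2.0 * t * denom - num) / denom ** 2 / nfg
    loss = float(np.mean(losses))
    return (loss, grad) if return_grad else loss


def mae_loss(pred: np.ndarray, target: np.ndarray, return_grad: bool = False):
    """Elementwise mean absolute error."""
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    diff = pred - target
    loss = float(np.abs(diff).mean())
    if return_grad:
        return loss, np.sign(diff) / diff.size
    return loss


def cce_loss(pred: np.ndarray, target: np.ndarray, return_grad: bool = False):
    """Mean per-pixel categorical cross-entropy -log p(true class).

    True-class probabilities are clamped at 1e-12 (clamped pixels counted in
    the gradient path only through the clamp).
    """
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    _check_simplex(pred)
    p_true = (pred * target).sum(axis=0)
    n_pix = p_true.size
    clamped = np.maximum(p_true, EPS_LOG)
    loss = float(-np.log(clamped).mean())
    if return_grad:
        # d/dp[-log(max(p, eps))] = -1/p above the clamp, 0 below it
        grad = np.where((target > 0) & (pred > EPS_LOG),
                        -target / np.maximum(pred, EPS_LOG) / n_pix, 0.0)
        return loss, grad
    return loss


AUX_LOSSES = {"mae": mae_loss, "cce": cce_loss, "dice": dice_loss}


def adversarial_value(d_scores_real: np.ndarray, d_scores_fake: np.ndarray,
                      lambda_k: float = 1.0) -> float:
    """The value function V(D_k, G) on one batch of patch score grids.

    V = mean(log D(x,y)) + lambda_k * mean(log(1 - D(G(z,x),x))).
    Patch scores are averaged to the batch expectation.  Scores must lie in
    the open interval (0, 1).
    """
    r = np.asarray(d_scores_real, dtype=float)
    f = np.asarray(d_scores_fake, dtype=float)
    if np.any(r <= 0) or np.any(r >= 1) or np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("discriminator scores must lie in (0, 1)")
    return float(np.log(r).mean() + lambda_k * np.log1p(-f).mean())


def aggregate_feedback(values, mode: str, active_mask=None) -> float:
    """F over the active discriminators' values: sum, average, or maximum."""
    values = list(values)
    if active_mask is None:
        active_mask = [True] * len(values)
    act = [v for v, a in zip(values, active_mask) if a]
    if not act:
        raise ValueError("all discriminators dropped; at least one must remain")
    if mode == "sum":
        return float(np.sum(act)) if len(act) > 1 else float(act[0])
    if mode == "average":
        return float(np.mean(act)) if len(act) > 1 else float(act[0])
    if mode == "maximum":
        return float(np.max(act))
    raise ValueError(f"unknown aggregation mode {mode!r}")


def generator_loss(probs: np.ndarray, target_onehot: np.ndarray,
                   fake_scores: list[np.ndarray], cfg: ObjectiveConfig,
                   active_mask=None, mode: str | None = None) -> tuple[float, dict]:
    """Total generator loss and its per-term breakdown (evaluation form).

    ``fake_scores[k]`` are D_k's patch scores on the generated pair.  The
    adversarial term per discriminator is the non-saturating
    ``-lambda_k mean(log D_k(fake))`` (or the saturating
    ``lambda_k mean(log(1 - D_k(fake)))`` when ``cfg.saturating``); terms
    are aggregated by F over active discriminators, then the auxiliary
    losses assigned to active discriminators are added.
    """
    if len(fake_scores) != cfg.K:
        raise ValueError("need one fake-score grid per discriminator")
    mode = mode or cfg.aggregation_mode
    if active_mask is None:
        active_mask = [True] * cfg.K
    adv_terms = []
    breakdown: dict[str, float] = {}
    for k, (s, lam) in enumerate(zip(fake_scores, cfg.lambda_k)):
        s = np.asarray(s, dtype=float)
        if np.any(s <= 0) or np.any(s >= 1):
            raise ValueError(f"discriminator {k} scores outside (0, 1)")
        if cfg.saturating:
            term = lam * float(np.log1p(-s).mean())
        else:
            term = -lam * float(np.log(s).mean())
        if not np.isfinite(term):
            raise FloatingPointError(f"non-finite adversarial term for D{k}")
        adv_terms.append(term)
        breakdown[f"adv_{k}"] = term
    adv = aggregate_feedback(adv_terms, mode, active_mask)
    breakdown["adv_aggregated"] = adv
    total = adv
    aux_w = cfg.aux_weights or tuple(1.0 for _ in range(cfg.K))
    for k, (lt, w, a) in enumerate(zip(cfg.loss_assignment, aux_w, active_mask)):
        if not a:
            continue
        val = w * AUX_LOSSES[lt](probs, target_onehot)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite auxiliary term {lt} (D{k})")
        breakdown[f"aux_{lt}_{k}"] = val
        total += val
    breakdown["total"] = total
    return total, breakdown
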