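"""Monte-Carlo predictive moments and uncertainty-based OOD scores.

Given the configuration ensemble ``{theta_hat_i}`` (multiplicative-Gaussian
weight perturbations of the trained generator), the prediction is the first
MC moment and the uncertainty the second:

    E[y]  ~  (1/N) sum_i  y_hat(x, theta_hat_i)
    u     ~  diag(1/tau) + (1/N) sum_i y_hat^T y_hat  -  E[y]^T E[y]

per pixel, where ``tau`` holds the normalized class frequencies of the
training set.  The diag(1/tau) offset is large for rare classes — rare
classes carry intrinsically higher uncertainty — while the remaining term
is the ensemble's predictive covariance.  The per-image OOD score excludes
the constant offset so that confidently-predicted in-distribution images
score near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import DropoutConfig, NetworkParameters, sample_configuration

__all__ = [
    "ClassFrequencySpec",
    "PredictiveMoments",
    "mc_predict",
    "predictive_mean",
    "predictive_uncertainty",
    "ood_score",
    "compute_moments",
]


@dataclass(frozen=True)
class ClassFrequencySpec:
    """Normalized class frequencies tau of the training split.

    ``tau_mode="vector"`` reads tau^-1 I_C as diag(1/tau_c); ``"scalar"``
    reads it as a single precision (1/mean(tau)) * I_C.
    """

    tau: tuple[float, ...]
    tau_mode: str = "vector"

    def __post_init__(self):
        t = np.asarray(self.tau, dtype=float)
        if np.any(t <= 0):
            raise ValueError("tau must be strictly positive (a class with zero "
                             "frequency has no defined inverse frequency)")
        if not np.isclose(t.sum(), 1.0, atol=1e-6):
            raise ValueError(f"tau must sum to 1 (got {t.sum():.6f})")
        if self.tau_mode not in ("vector", "scalar"):
            raise ValueError(f"unknown tau_mode {self.tau_mode!r}")

    @property
    def C(self) -> int:
        return len(self.tau)

    def inverse_offset(self) -> np.ndarray:
        """The C x C constant offset tau^-1 I_C."""
        t = np.asarray(self.tau, dtype=float)
        if self.tau_mode == "vector":
            return np.diag(1.0 / t)
        return np.eye(self.C) / float(t.mean())

    @classmethod
    def from_masks(cls, masks, n_classes: int,
                   tau_mode: str = "vector") -> "ClassFrequencySpec":
        """Pooled pixel frequencies over a training split's masks."""
        counts = np.zeros(n_classes)
        for m in masks:
            counts += np.bincount(np.asarray(m).ravel(), minlength=n_classes)
        if np.any(counts == 0):
            missing = [i for i in range(n_classes) if counts[i] == 0]
            raise ValueError(f"classes {missing} absent from the training split")
        return cls(tau=tuple(counts / counts.sum()), tau_mode=tau_mode)


@dataclass
class PredictiveMoments:
    """First/second MC moments plus the scalar OOD score for one image."""

    mean: np.ndarray          # (C, H, W) probabilities
    u: np.ndarray             # (H, W, C, C) uncertainty matrices
    ood: float
    freq: ClassFrequencySpec


def mc_predict(generator, params: NetworkParameters, x: np.ndarray,
               z: np.ndarray, cfg: DropoutConfig,
               z_policy: str = "fixed") -> list[np.ndarray]:
    """Run the N ensemble configurations on one image.

    Returns N per-pixel probability maps ``(C, H, W)``.  ``z`` is shared
    across members by default (``z_policy="fixed"``), isolating the
    weight-noise contribution; ``"resample"`` redraws z per member from a
    stream derived from ``cfg.seed``.
    """
    if z_policy not in ("fixed", "resample"):
        raise ValueError(f"unknown z_policy {z_policy!r}")
    maps = []
    base = generator.get_parameters()
    try:
        for i in range(cfg.n_samples):
            member = sample_configuration(params, cfg, i)
            generator.set_parameters(member)
            zi = z
            if z_policy == "resample":
                zrng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 5, i])
                zi = zrng.normal(size=z.shape)
            probs = generator.forward_zx(zi, x)
            if not np.all(np.isfinite(probs)):
                raise FloatingPointError(
                    f"non-finite generator output for ensemble member {i}")
            maps.append(probs)
    finally:
        generator.set_parameters(base)
    return maps


def predictive_mean(samples: list[np.ndarray]) -> np.ndarray:
    """First MC moment: elementwise mean of the member probability maps."""
    if not samples:
        raise ValueError("need at least one sample")
    shape = samples[0].shape
    for s in samples:
        if s.shape != shape:
            raise ValueError("inconsistent sample shapes")
    return np.mean(np.stack(samples), axis=0)


def predictive_uncertainty(samples: list[np.ndarray],
                           freq: ClassFrequencySpec,
                           diagonal_only: bool = False) -> np.ndarray:
    """Second MC moment: per-pixel C x C matrix u (or its diagonal).

    u = tau^-1 I_C + (1/N) sum_i y_hat y_hat^T - E[y] E[y]^T, symmetric by
    construction; its non-constant part is the MC covariance (PSD).
    """
    if not samples:
        raise ValueError("need at least one sample")
    c = samples[0].shape[0]
    if c != freq.C:
        raise ValueError(f"sample class count {c} != freq.C {freq.C}")
    stack = np.stack(samples)                      # (N, C, H, W)
    mean = stack.mean(axis=0)                      # (C, H, W)
    offset = freq.inverse_offset()
    if diagonal_only:
        second = (stack ** 2).mean(axis=0) - mean ** 2   # (C, H, W)
        return np.moveaxis(second, 0, -1) + np.diag(offset)
    second = np.einsum("nchw,ndhw->hwcd", stack, stack) / stack.shape[0]
    mean_outer = np.einsum("chw,dhw->hwcd", mean, mean)
    return second - mean_outer + offset


def ood_score(moments_or_u, freq: ClassFrequencySpec | None = None,
              reduction: str = "mean", q: float | None = None) -> float:
    """Reduce the per-pixel total predictive variance to one scalar.

    The constant tau^-1 offset is subtracted first, so the score is the
    spatial reduction of trace(covariance): 0 for a zero-spread ensemble.
    ``reduction``: "mean", "max" or "quantile" (requires ``q``).
    """
    if isinstance(moments_or_u, PredictiveMoments):
        u = moments_or_u.u
        freq = moments_or_u.freq
    else:
        u = moments_or_u
        if freq is None:
            raise ValueError("freq is required when passing a raw u array")
    if reduction == "quantile" and q is None:
        raise ValueError("reduction='quantile' requires q")
    offset_trace = np.trace(freq.inverse_offset())
    total_var = np.trace(u, axis1=-2, axis2=-1) - offset_trace  # (H, W)
    total_var = np.maximum(total_var, 0.0)
    if reduction == "mean":
        return float(total_var.mean())
    if reduction == "max":
        return float(total_var.max())
    if reduction == "quantile":
        return float(np.quantile(total_var, q))
    raise ValueError(f"unknown reduction {reduction!r}")


def compute_moments(generator, params: NetworkParameters, x: np.ndarray,
                    z: np.ndarray, cfg: DropoutConfig,
                    freq: ClassFrequencySpec,
                    reduction: str = "mean") -> PredictiveMoments:
    """Full MC pass for one image: mean, u and OOD score."""
    maps = mc_predict(generator, params, x, z, cfg)
    mean = predictive_mean(maps)
    u = predictive_uncertainty(maps, freq)
    return PredictiveMoments(mean=mean, u=u,
                             ood=ood_score(u, freq, reduction=reduction),
                             freq=freq)
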