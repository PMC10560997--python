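"""Elementary BCE-adversarial loss/gradient primitives.

Shared by the ensemble trainer and the standalone conditional-GAN baseline
so that the K=1 degenerate case of the framework is arithmetically the
baseline, term by term.  Scores are clamped to the open unit interval
before taking logs.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def _clamp(s: np.ndarray) -> np.ndarray:
    return np.clip(s, _EPS, 1.0 - _EPS)


def bce_real(s: np.ndarray) -> tuple[float, np.ndarray]:
    """Discriminator loss on real pairs: -mean(log s); returns (loss, dL/ds)."""
    sc = _clamp(s)
    return float(-np.log(sc).mean()), -1.0 / (sc * s.size)


def bce_fake(s: np.ndarray) -> tuple[float, np.ndarray]:
    """Discriminator loss on generated pairs: -mean(log(1 - s))."""
    sc = _clamp(s)
    return float(-np.log1p(-sc).mean()), 1.0 / ((1.0 - sc) * s.size)


def g_adversarial(s: np.ndarray, lam: float,
                  saturating: bool = False) -> tuple[float, np.ndarray]:
    """Generator-side adversarial term for one discriminator's fake scores.

    Non-saturating (default): -lam * mean(log s).
    Saturating (the literal min-max form): lam * mean(log(1 - s)).
    """
    sc = _clamp(s)
    if saturating:
        return (float(lam * np.log1p(-sc).mean()),
                -lam / ((1.0 - sc) * s.size))
    return float(-lam * np.log(sc).mean()), -lam / (sc * s.size)
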