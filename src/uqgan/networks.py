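"""Generator / discriminator families and the dynamic-dropout ensemble.

The *dynamic dropout* of this framework perturbs network **weights** with
multiplicative Gaussian noise: each ensemble member is a configuration
``theta_hat_i = theta * delta_i`` with ``delta ~ N(1, sigma^2)`` drawn
elementwise.  Sampling configurations is pure — the base parameters are
never modified — and fully deterministic given ``(seed, draw_index)``.

The generator is a stacked-hourglass encoder–decoder: repeated bottom-up /
top-down stages with skip connections, so initial estimates are re-evaluated
against whole-image context.  A random vector ``z`` is injected by
concatenation at each hourglass bottleneck.  The discriminator is a
Markovian (PatchGAN-style) network scoring local patches rather than the
whole image, conditioned on the label map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "NetworkParameters",
    "DropoutConfig",
    "ConfigurationEnsemble",
    "GeneratorSpec",
    "DiscriminatorSpec",
    "sample_configuration",
    "make_ensemble",
    "build_generator",
    "build_discriminator",
    "HourglassGenerator",
    "PatchDiscriminator",
]


@dataclass
class NetworkParameters:
    """Ordered per-layer parameter arrays ``theta = {theta_1, ..., theta_d}``."""

    theta: list[np.ndarray]

    def __post_init__(self):
        if len(self.theta) < 1:
            raise ValueError("at least one parameter array is required")
        for i, a in enumerate(self.theta):
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite values in parameter array {i}")

    @property
    def d(self) -> int:
        return len(self.theta)

    def copy(self) -> "NetworkParameters":
        return NetworkParameters([a.copy() for a in self.theta])

    def __eq__(self, other) -> bool:
        return (isinstance(other, NetworkParameters)
                and len(self.theta) == len(other.theta)
                and all(np.array_equal(a, b) for a, b in zip(self.theta, other.theta)))


@dataclass(frozen=True)
class DropoutConfig:
    """Multiplicative Gaussian weight noise delta ~ N(1, sigma^2).

    ``sigma`` may follow a schedule (the "dynamic" hook): with
    ``sigma_schedule="constant"`` it is fixed; with ``"linear_decay"`` it
    decays linearly to 0 over ``schedule_steps`` draws.
    """

    sigma: float = 0.1
    n_samples: int = 5
    seed: int = 0
    sigma_schedule: str = "constant"
    schedule_steps: int = 1000

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.sigma_schedule not in ("constant", "linear_decay"):
            raise ValueError(f"unknown sigma schedule {self.sigma_schedule!r}")

    def sigma_at(self, step: int) -> float:
        if self.sigma_schedule == "constant":
            return self.sigma
        frac = min(max(step, 0), self.schedule_steps) / self.schedule_steps
        return self.sigma * (1.0 - frac)


@dataclass
class ConfigurationEnsemble:
    """The ensemble O = {theta_hat_i : i in [1, N]} of perturbed configurations."""

    members: list[NetworkParameters] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def sample_configuration(params: NetworkParameters, cfg: DropoutConfig,
                         draw_index: int, step: int = 0) -> NetworkParameters:
    """Draw one perturbed configuration ``theta_hat = theta * delta``.

    Deterministic given ``(cfg.seed, draw_index)``; the input is never
    mutated.  With ``sigma == 0`` the member equals the base parameters.
    """
    if not 0 <= draw_index < cfg.n_samples:
        raise ValueError(f"draw_index {draw_index} outside [0, {cfg.n_samples})")
    sigma = cfg.sigma_at(step)
    if sigma == 0.0:
        return params.copy()
    rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, draw_index])
    perturbed = [a * rng.normal(1.0, sigma, size=a.shape) for a in params.theta]
    return NetworkParameters(perturbed)


def make_ensemble(params: NetworkParameters, cfg: DropoutConfig,
                  step: int = 0) -> ConfigurationEnsemble:
    members = [sample_configuration(params, cfg, i, step=step)
               for i in range(cfg.n_samples)]
    return ConfigurationEnsemble(members)


@dataclass(frozen=True)
class GeneratorSpec:
    stacks: int = 2
    base_channels: int = 8
    n_classes: int = 3
    input_channels: int = 1
    noise_dim: int = 16
    n_down: int = 3
    init_std: float = 1e-3

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.stacks < 1:
            raise ValueError("stacks must be >= 1")


@dataclass(frozen=True)
class DiscriminatorSpec:
    patch_receptive_field: int = 16
    base_channels: int = 8
    loss_type: str = "cce"

    def __post_init__(self):
        if self.patch_receptive_field < 1:
            raise ValueError("patch_receptive_field must be >= 1")
        if self.loss_type not in ("mae", "cce", "dice"):
            raise ValueError(f"unknown loss_type {self.loss_type!r}")


class _Hourglass(nn.Layer):
    """One bottom-up/top-down stage with additive skips and z at the bottleneck."""

    def __init__(self, channels: int, noise_dim: int, n_down: int,
                 init_std: float, rng: np.random.Generator):
        f = channels
        self.n_down = n_down
        self.noise_dim = noise_dim
        self.downs = [nn.Conv2d(f, f, 3, stride=2, init_std=init_std, rng=rng)
                      for _ in range(n_down)]
        self.bottleneck = nn.Conv2d(f + noise_dim, f, 3, init_std=init_std, rng=rng)
        self.ups = [nn.Conv2d(f, f, 3, init_std=init_std, rng=rng)
                    for _ in range(n_down)]
        self.acts_d = [nn.LeakyReLU() for _ in range(n_down)]
        self.act_b = nn.LeakyReLU()
        self.acts_u = [nn.LeakyReLU() for _ in range(n_down)]
        self.upsamplers = [nn.Upsample2() for _ in range(n_down)]

    def _children(self):
        return self.downs + [self.bottleneck] + self.ups

    def params(self):
        return [p for l in self._children() for p in l.params()]

    def grads(self):
        return [g for l in self._children() for g in l.grads()]

    def forward_z(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for conv, act in zip(self.downs, self.acts_d):
            skips.append(h)
            h = act.forward(conv.forward(h))
        zt = np.broadcast_to(z[:, None, None], (self.noise_dim,) + h.shape[1:])
        h = self.act_b.forward(self.bottleneck.forward(np.concatenate([h, zt])))
        self._skips = skips
        for conv, act, up in zip(self.ups, self.acts_u, self.upsamplers):
            h = act.forward(conv.forward(up.forward(h)))
            h = h + skips.pop()
        return h

    def backward(self, dout):
        dskips = []
        d = dout
        for conv, act, up in zip(reversed(self.ups), reversed(self.acts_u),
                                 reversed(self.upsamplers)):
            dskips.append(d)
            d = up.backward(conv.backward(act.backward(d)))
        d = self.bottleneck.backward(self.act_b.backward(d))
        d = d[:-self.noise_dim] if self.noise_dim else d
        for conv, act, dskip in zip(reversed(self.downs), reversed(self.acts_d),
                                    reversed(dskips)):
            d = conv.backward(act.backward(d)) + dskip
        return d


class HourglassGenerator(nn.Layer):
    """Stacked-hourglass segmentation generator: (z, x) -> per-pixel class probs.

    The head sees both the refined features and the raw input (the final
    re-evaluation of the initial estimate), and ends in a per-pixel softmax,
    so the output of every configuration lies on the probability simplex.
    """

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        f = spec.base_channels
        self.stem = nn.Conv2d(spec.input_channels, f, 3,
                              init_std=spec.init_std, rng=rng)
        self.stem_act = nn.LeakyReLU()
        self.stacks = [_Hourglass(f, spec.noise_dim, spec.n_down,
                                  spec.init_std, rng)
                       for _ in range(spec.stacks)]
        self.head = nn.Conv2d(f + spec.input_channels, spec.n_classes, 1,
                              init_std=spec.init_std, rng=rng)
        self.softmax = nn.ChannelSoftmax()

    @property
    def downsample_factor(self) -> int:
        return 2 ** self.spec.n_down

    def _children(self):
        return [self.stem] + self.stacks + [self.head]

    def params(self):
        return [p for l in self._children() for p in l.params()]

    def grads(self):
        return [g for l in self._children() for g in l.grads()]

    def get_parameters(self) -> NetworkParameters:
        return NetworkParameters([p.copy() for p in self.params()])

    def set_parameters(self, params: NetworkParameters) -> None:
        own = self.params()
        if len(own) != params.d:
            raise ValueError(
                f"parameter count mismatch: network has {len(own)}, got {params.d}")
        for dst, src in zip(own, params.theta):
            if dst.shape != src.shape:
                raise ValueError("parameter shape mismatch")
            dst[...] = src

    def forward_zx(self, z: np.ndarray, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[None]
        c, h, w = x.shape
        fct = self.downsample_factor
        if h % fct or w % fct:
            raise ValueError(
                f"input {h}x{w} not divisible by downsampling factor {fct}")
        if z.shape != (self.spec.noise_dim,):
            raise ValueError(f"z must have shape ({self.spec.noise_dim},)")
        self._x = x
        feat = self.stem_act.forward(self.stem.forward(x))
        for hg in self.stacks:
            feat = feat + hg.forward_z(feat, z)
        logits = self.head.forward(np.concatenate([feat, x]))
        return self.softmax.forward(logits)

    def backward(self, dprobs: np.ndarray) -> None:
        d = self.softmax.backward(dprobs)
        d = self.head.backward(d)
        f = self.spec.base_channels
        d = d[:f]
        for hg in reversed(self.stacks):
            d = hg.backward(d) + d
        self.stem.backward(self.stem_act.backward(d))

    def zero_grad(self):
        for g in self.grads():
            g[...] = 0.0


class PatchDiscriminator(nn.Layer):
    """Markovian discriminator: (x, one-hot y) -> patch-wise scores in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec, input_channels: int,
                 n_classes: int, rng: np.random.Generator):
        self.spec = spec
        self.n_classes = n_classes
        self.input_channels = input_channels
        n_down = max(1, int(round(np.log2(max(2, spec.patch_receptive_field) / 2))))
        self.n_down = n_down
        f = spec.base_channels
        widths = [input_channels + n_classes] + [f * 2 ** i for i in range(n_down)]
        self.convs = [nn.Conv2d(widths[i], widths[i + 1], 3, stride=2, rng=rng)
                      for i in range(n_down)]
        self.acts = [nn.LeakyReLU() for _ in range(n_down)]
        self.head = nn.Conv2d(widths[-1], 1, 1, rng=rng)
        self.sigmoid = nn.Sigmoid()

    def params(self):
        return [p for l in self.convs + [self.head] for p in l.params()]

    def grads(self):
        return [g for l in self.convs + [self.head] for g in l.grads()]

    def get_parameters(self) -> NetworkParameters:
        return NetworkParameters([p.copy() for p in self.params()])

    def set_parameters(self, params: NetworkParameters) -> None:
        for dst, src in zip(self.params(), params.theta):
            dst[...] = src

    def forward_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Score an (image, label-probability-map) pair; y is (C, H, W)."""
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != y.shape[1:]:
            raise ValueError(
                f"image {x.shape[1:]} and label map {y.shape[1:]} disagree")
        h = np.concatenate([x, y])
        for conv, act in zip(self.convs, self.acts):
            h = act.forward(conv.forward(h))
        return self.sigmoid.forward(self.head.forward(h))

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return gradients w.r.t. the image and the label map inputs."""
        d = self.head.backward(self.sigmoid.backward(dout))
        for conv, act in zip(reversed(self.convs), reversed(self.acts)):
            d = conv.backward(act.backward(d))
        return d[:self.input_channels], d[self.input_channels:]

    def zero_grad(self):
        for g in self.grads():
            g[...] = 0.0


def build_generator(spec: GeneratorSpec, seed: int = 0) -> HourglassGenerator:
    """Build a generator with weights drawn from N(0, spec.init_std)."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x47454E])
    return HourglassGenerator(spec, rng)


def build_discriminator(spec: DiscriminatorSpec, input_channels: int = 1,
                        n_classes: int = 3, seed: int = 0,
                        index: int = 0) -> PatchDiscriminator:
    """Build a randomly initialized patch discriminator (He-style init)."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x444953, index])
    return PatchDiscriminator(spec, input_channels, n_classes, rng)
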