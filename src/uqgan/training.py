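"""Alternating generator / multi-discriminator optimization.

One discriminator step (every active D_k, binary cross-entropy on real and
generated pairs) alternates with one generator step per mini-batch.  The
generator's feedback is the aggregation F — redrawn per batch from
``mode_probs`` — of the active discriminators' adversarial terms, plus the
auxiliary segmentation losses assigned to the active discriminators.
Dynamic dropout perturbs the generator's weights with a fresh delta each
batch when ``sigma > 0``.  Every stochastic choice draws from its own
seed-derived stream, so runs are reproducible and the K=1, sigma=0
configuration consumes exactly the streams the conditional-GAN baseline
does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _gan_ops as ops
from .metrics import MetricReport, segmentation_report
from .networks import (DiscriminatorSpec, DropoutConfig, GeneratorSpec,
                       NetworkParameters, build_discriminator, build_generator)
from .nn import Adam
from .objectives import AUX_LOSSES, ObjectiveConfig, one_hot
from .uncertainty import ClassFrequencySpec, mc_predict, predictive_mean

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "TrainingDiverged",
    "train",
    "cross_validate",
    "evaluate",
]

AGG_MODES = ("sum", "average", "maximum")

# stream ids for the per-purpose RNGs derived from the master seed
_S_ORDER, _S_Z, _S_DROPOUT, _S_MODE, _S_DROP, _S_VALZ = 10, 11, 12, 13, 14, 15


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam, lr 2e-4, batch size 1)."""

    learning_rate: float = 2e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    weight_decay: float = 1e-4
    batch_size: int = 1
    epochs: int = 5
    seed: int = 0
    dropout: DropoutConfig = DropoutConfig()
    objective: ObjectiveConfig = ObjectiveConfig()
    lr_decay: bool = False
    dropout_in_training: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class TrainHistory:
    """Per-batch loss breakdowns and control decisions, per-epoch reports."""

    batches: list = field(default_factory=list)    # dicts: losses, mode, active
    epochs: list = field(default_factory=list)     # dicts: epoch summaries
    val_reports: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    best_epoch: int = -1

    def modes_logged(self) -> list[str]:
        return [b["mode"] for b in self.batches]


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite; carries the last good params."""

    def __init__(self, msg: str, checkpoint=None):
        super().__init__(msg)
        self.checkpoint = checkpoint


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])


def _draw_mode(rng: np.random.Generator, probs) -> str:
    return AGG_MODES[int(rng.choice(3, p=np.asarray(probs, dtype=float)))]


def _draw_active(rng: np.random.Generator, k: int, drop_prob: float) -> list[bool]:
    if drop_prob == 0.0:
        return [True] * k
    while True:
        mask = [bool(rng.random() >= drop_prob) for _ in range(k)]
        if any(mask):
            return mask


def _perturb_inplace(params: list[np.ndarray], sigma: float,
                     rng: np.random.Generator):
    """theta -> theta * delta in place; returns (base copies, deltas)."""
    base = [p.copy() for p in params]
    deltas = [rng.normal(1.0, sigma, size=p.shape) for p in params]
    for p, d in zip(params, deltas):
        p *= d
    return base, deltas


def _restore_and_scale(params, grads, base, deltas):
    """Undo the perturbation and chain grads: dL/dtheta = dL/dtheta_hat * delta."""
    for p, b in zip(params, base):
        p[...] = b
    for g, d in zip(grads, deltas):
        g *= d


def train(train_set, val_set, generator_spec: GeneratorSpec,
          discriminator_specs: list[DiscriminatorSpec],
          cfg: TrainConfig) -> tuple[NetworkParameters, TrainHistory]:
    """Train the ensemble GAN; returns (best-epoch parameters, history).

    ``discriminator_specs`` must match ``cfg.objective.K`` (their
    ``loss_type`` fields define the auxiliary-loss assignment when they
    disagree with the objective config, the objective config wins).
    """
    if not train_set:
        raise ValueError("train_set must be non-empty")
    obj = cfg.objective
    if len(discriminator_specs) != obj.K:
        raise ValueError(f"need {obj.K} discriminator specs, got "
                         f"{len(discriminator_specs)}")
    n_classes = generator_spec.n_classes
    missing = _missing_classes(train_set, n_classes)
    if missing:
        raise ValueError(f"classes {missing} absent from the training split")

    G = build_generator(generator_spec, seed=cfg.seed)
    Ds = [build_discriminator(spec, generator_spec.input_channels, n_classes,
                              seed=cfg.seed, index=k)
          for k, spec in enumerate(discriminator_specs)]
    opt_g = Adam(G.params(), lr=cfg.learning_rate, beta1=cfg.adam_beta1,
                 beta2=cfg.adam_beta2, weight_decay=cfg.weight_decay)
    opt_d = [Adam(d.params(), lr=cfg.learning_rate, beta1=cfg.adam_beta1,
                  beta2=cfg.adam_beta2, weight_decay=cfg.weight_decay)
             for d in Ds]

    order_rng = _rng(cfg.seed, _S_ORDER)
    z_rng = _rng(cfg.seed, _S_Z)
    dropout_rng = _rng(cfg.seed, _S_DROPOUT)
    mode_rng = _rng(cfg.seed, _S_MODE)
    drop_rng = _rng(cfg.seed, _S_DROP)

    history = TrainHistory(seeds={"master": cfg.seed})
    best_f1 = -1.0
    best_params = G.get_parameters()
    last_good = G.get_parameters()
    step = 0
    n = len(train_set)
    for epoch in range(cfg.epochs):
        order = order_rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [train_set[i] for i in idx]
            mode = _draw_mode(mode_rng, obj.mode_probs)
            active = _draw_active(drop_rng, obj.K, obj.drop_prob)
            sigma = cfg.dropout.sigma_at(step) if cfg.dropout_in_training else 0.0
            record = _ensemble_batch(G, Ds, opt_g, opt_d, batch, obj, mode,
                                     active, sigma, z_rng, dropout_rng,
                                     n_classes)
            record.update({"epoch": epoch, "mode": mode, "active": active,
                           "sample_ids": [s.sample_id for s in batch]})
            if not all(math.isfinite(v) for v in record["losses"].values()):
                bad = [k for k, v in record["losses"].items()
                       if not math.isfinite(v)]
                raise TrainingDiverged(
                    f"non-finite loss terms {bad} at epoch {epoch}",
                    checkpoint=last_good)
            history.batches.append(record)
            step += 1
        last_good = G.get_parameters()
        epoch_summary = _epoch_summary(history, epoch)
        if val_set:
            report = evaluate(G, last_good, val_set, cfg.dropout,
                              ClassFrequencySpec.from_masks(
                                  [s.mask for s in train_set], n_classes),
                              n_samples=1, seed=cfg.seed)
            history.val_reports.append(report)
            epoch_summary["val_f1"] = report.f1
            if report.f1 > best_f1:
                best_f1 = report.f1
                best_params = last_good
                history.best_epoch = epoch
        else:
            best_params = last_good
            history.best_epoch = epoch
        history.epochs.append(epoch_summary)
    return best_params, history


def _missing_classes(samples, n_classes: int) -> list[int]:
    counts = np.zeros(n_classes)
    for s in samples:
        counts += np.bincount(s.mask.ravel(), minlength=n_classes)
    return [c for c in range(n_classes) if counts[c] == 0]


def _epoch_summary(history: TrainHistory, epoch: int) -> dict:
    rows = [b["losses"] for b in history.batches if b["epoch"] == epoch]
    keys = sorted({k for r in rows for k in r})
    return {"epoch": epoch,
            **{f"mean_{k}": float(np.mean([r[k] for r in rows if k in r]))
               for k in keys}}


def _ensemble_batch(G, Ds, opt_g, opt_d, batch, obj: ObjectiveConfig,
                    mode: str, active: list[bool], sigma: float,
                    z_rng, dropout_rng, n_classes: int) -> dict:
    """One alternating D/G update on a mini-batch; returns the loss record."""
    K = obj.K
    bsz = len(batch)
    zs = [z_rng.normal(size=G.spec.noise_dim) for _ in batch]
    onehots = [one_hot(s.mask, n_classes) for s in batch]

    perturbed = sigma > 0.0
    if perturbed:
        base, deltas = _perturb_inplace(G.params(), sigma, dropout_rng)

    # ---- discriminator step (each active D_k on real and generated pairs)
    fakes = [G.forward_zx(z, s.image) for z, s in zip(zs, batch)]
    d_losses = {}
    for k, (d, a) in enumerate(zip(Ds, active)):
        if not a:
            continue
        d.zero_grad()
        loss_k = 0.0
        for s, onehot, fake in zip(batch, onehots, fakes):
            sr = d.forward_xy(s.image, onehot)
            lr_, gr = ops.bce_real(sr)
            d.backward(gr / bsz)
            sf = d.forward_xy(s.image, fake)
            lf_, gf = ops.bce_fake(sf)
            d.backward(gf / bsz)
            loss_k += (lr_ + lf_) / bsz
        opt_d[k].step(d.grads())
        d_losses[f"d_loss_{k}"] = loss_k

    # ---- generator step against the updated discriminators
    G.zero_grad()
    adv_terms = [0.0] * K
    aux_terms: dict[str, float] = {}
    for s, onehot, z in zip(batch, onehots, zs):
        probs = G.forward_zx(z, s.image)   # fresh caches for backward
        dprobs = np.zeros_like(probs)
        per_k = []
        for k, (d, a, lam) in enumerate(zip(Ds, active, obj.lambda_k)):
            if not a:
                per_k.append((0.0, None))
                continue
            sf = d.forward_xy(s.image, probs)
            val, ds = ops.g_adversarial(sf, lam, saturating=obj.saturating)
            per_k.append((val, ds))
            adv_terms[k] += val / bsz
        weights = _aggregation_weights([v for v, _ in per_k], mode, active)
        for k, (d, a, (val, ds)) in enumerate(zip(Ds, active, per_k)):
            if not a or weights[k] == 0.0:
                continue
            d.zero_grad()
            _, dy = d.backward(ds)
            dprobs += (weights[k] / bsz) * dy
            d.zero_grad()
        for k, (lt, a) in enumerate(zip(obj.loss_assignment, active)):
            if not a:
                continue
            w = (obj.aux_weights or (1.0,) * K)[k]
            val, g = AUX_LOSSES[lt](probs, onehot, return_grad=True)
            aux_terms[f"aux_{lt}_{k}"] = aux_terms.get(f"aux_{lt}_{k}", 0.0) \
                + w * val / bsz
            dprobs += (w / bsz) * g
        G.backward(dprobs)

    if perturbed:
        _restore_and_scale(G.params(), G.grads(), base, deltas)
    opt_g.step(G.grads())

    adv_aggregated = _aggregate(adv_terms, mode, active)
    losses = {**d_losses,
              **{f"adv_{k}": adv_terms[k] for k in range(K) if active[k]},
              "adv_aggregated": adv_aggregated, **aux_terms}
    losses["g_total"] = adv_aggregated + float(sum(aux_terms.values()))
    return {"losses": losses, "sigma": sigma}


def _aggregate(values, mode, active):
    act = [v for v, a in zip(values, active) if a]
    if mode == "sum":
        return float(act[0]) if len(act) == 1 else float(np.sum(act))
    if mode == "average":
        return float(act[0]) if len(act) == 1 else float(np.mean(act))
    return float(np.max(act))


def _aggregation_weights(values, mode, active) -> list[float]:
    """dF/dV_k for the chosen aggregation over active discriminators."""
    k = len(values)
    n_act = sum(active)
    if mode == "sum":
        return [1.0 if a else 0.0 for a in active]
    if mode == "average":
        return [1.0 / n_act if a else 0.0 for a in active]
    best, best_v = None, -np.inf
    for i, (v, a) in enumerate(zip(values, active)):
        if a and v > best_v:
            best, best_v = i, v
    return [1.0 if i == best else 0.0 for i in range(k)]


def evaluate(G, params: NetworkParameters, dataset,
             dropout: DropoutConfig, freq: ClassFrequencySpec,
             n_samples: int | None = None, seed: int = 0,
             spacing: float = 1.0) -> MetricReport:
    """Segmentation MetricReport from MC predictive-mean masks.

    ``n_samples`` overrides the dropout config's N (n=1 with the base
    parameters is the plain forward pass used for per-epoch validation).
    """
    cfg = dropout if n_samples is None else replace(dropout, n_samples=n_samples,
                                                    sigma=0.0 if n_samples == 1
                                                    else dropout.sigma)
    zr = _rng(seed, _S_VALZ)
    preds, trues = [], []
    for s in dataset:
        z = zr.normal(size=G.spec.noise_dim)
        maps = mc_predict(G, params, s.image, z, cfg)
        mean = predictive_mean(maps)
        preds.append(np.argmax(mean, axis=0))
        trues.append(s.mask)
    report = segmentation_report(preds, trues, freq.C, spacing=spacing)
    report.settings.update({"mc_samples": cfg.n_samples, "sigma": cfg.sigma,
                            "tau": list(freq.tau)})
    return report


def cross_validate(dataset, k: int, generator_spec: GeneratorSpec,
                   discriminator_specs: list[DiscriminatorSpec],
                   cfg: TrainConfig, val_fraction: float = 0.2
                   ) -> tuple[list[MetricReport], dict]:
    """k repeated seeded 80/20 train/validation splits.

    Returns the per-split reports and a mean±std summary over them.  Each
    split must contain every class in its training portion.
    """
    n = len(dataset)
    if n < k:
        raise ValueError(f"dataset of size {n} cannot support {k} splits")
    n_classes = generator_spec.n_classes
    reports = []
    for fold in range(k):
        rng = _rng(cfg.seed, 100 + fold)
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        tr = [dataset[i] for i in train_idx]
        va = [dataset[i] for i in val_idx]
        missing = _missing_classes(tr, n_classes)
        if missing:
            raise ValueError(
                f"fold {fold}: classes {missing} missing from training portion")
        fold_cfg = replace(cfg, seed=(cfg.seed * 1000 + fold) & 0x7FFFFFFF)
        params, _ = train(tr, va, generator_spec, discriminator_specs, fold_cfg)
        G = build_generator(generator_spec, seed=fold_cfg.seed)
        freq = ClassFrequencySpec.from_masks([s.mask for s in tr], n_classes)
        rep = evaluate(G, params, va, cfg.dropout, freq, seed=fold_cfg.seed)
        rep.settings["fold"] = fold
        rep.settings["split"] = "repeated random 80/20 (seeded)"
        reports.append(rep)
    summary = {}
    for name in ("assd", "f1", "precision", "recall"):
        vals = np.array([getattr(r, name) for r in reports])
        vals = vals[np.isfinite(vals)]
        if len(vals):
            summary[name] = {"mean": float(vals.mean()),
                             "std": float(vals.std(ddof=1)) if len(vals) > 1
                             else 0.0}
    return reports, summary
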