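"""Standalone conditional-GAN baseline (single discriminator, no ensemble).

A plain image-conditional GAN for segmentation: one patch discriminator
trained with binary cross-entropy on real/generated (image, mask) pairs,
and a generator trained with the non-saturating adversarial term plus one
auxiliary segmentation loss.  This is the classical single-critic model the
ensemble framework degenerates to with K=1 and sigma=0; it is kept as an
independent training loop so the degenerate case can be verified against
it rather than defined by it.
"""

from __future__ import annotations

import numpy as np

from . import _gan_ops as ops
from .networks import (DiscriminatorSpec, GeneratorSpec, NetworkParameters,
                       build_discriminator, build_generator)
from .nn import Adam
from .objectives import AUX_LOSSES, one_hot
from .training import (TrainConfig, TrainHistory, TrainingDiverged,
                       _missing_classes, _rng, _S_ORDER, _S_Z, evaluate)
from .uncertainty import ClassFrequencySpec

__all__ = ["train_cgan"]


def train_cgan(train_set, val_set, generator_spec: GeneratorSpec,
               discriminator_spec: DiscriminatorSpec, cfg: TrainConfig,
               aux_loss: str = "cce", lam: float = 1.0
               ) -> tuple[NetworkParameters, TrainHistory]:
    """Train the single-discriminator conditional GAN; mirrors `train`'s API."""
    if not train_set:
        raise ValueError("train_set must be non-empty")
    n_classes = generator_spec.n_classes
    missing = _missing_classes(train_set, n_classes)
    if missing:
        raise ValueError(f"classes {missing} absent from the training split")
    G = build_generator(generator_spec, seed=cfg.seed)
    D = build_discriminator(discriminator_spec, generator_spec.input_channels,
                            n_classes, seed=cfg.seed, index=0)
    opt_g = Adam(G.params(), lr=cfg.learning_rate, beta1=cfg.adam_beta1,
                 beta2=cfg.adam_beta2, weight_decay=cfg.weight_decay)
    opt_d = Adam(D.params(), lr=cfg.learning_rate, beta1=cfg.adam_beta1,
                 beta2=cfg.adam_beta2, weight_decay=cfg.weight_decay)
    order_rng = _rng(cfg.seed, _S_ORDER)
    z_rng = _rng(cfg.seed, _S_Z)

    history = TrainHistory(seeds={"master": cfg.seed, "model": "cgan-baseline"})
    best_f1 = -1.0
    best_params = G.get_parameters()
    n = len(train_set)
    for epoch in range(cfg.epochs):
        order = order_rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [train_set[i] for i in idx]
            bsz = len(batch)
            zs = [z_rng.normal(size=G.spec.noise_dim) for _ in batch]
            onehots = [one_hot(s.mask, n_classes) for s in batch]

            # discriminator step
            fakes = [G.forward_zx(z, s.image) for z, s in zip(zs, batch)]
            D.zero_grad()
            d_loss = 0.0
            for s, onehot, fake in zip(batch, onehots, fakes):
                sr = D.forward_xy(s.image, onehot)
                lr_, gr = ops.bce_real(sr)
                D.backward(gr / bsz)
                sf = D.forward_xy(s.image, fake)
                lf_, gf = ops.bce_fake(sf)
                D.backward(gf / bsz)
                d_loss += (lr_ + lf_) / bsz
            opt_d.step(D.grads())

            # generator step against the updated discriminator
            G.zero_grad()
            adv_term = 0.0
            aux_term = 0.0
            for s, onehot, z in zip(batch, onehots, zs):
                probs = G.forward_zx(z, s.image)
                dprobs = np.zeros_like(probs)
                sf = D.forward_xy(s.image, probs)
                val, ds = ops.g_adversarial(sf, lam)
                adv_term += val / bsz
                D.zero_grad()
                _, dy = D.backward(ds)
                dprobs += (1.0 / bsz) * dy
                D.zero_grad()
                aval, ag = AUX_LOSSES[aux_loss](probs, onehot, return_grad=True)
                aux_term += 1.0 * aval / bsz
                dprobs += (1.0 / bsz) * ag
                G.backward(dprobs)
            opt_g.step(G.grads())

            losses = {"d_loss_0": d_loss, "adv_0": adv_term,
                      "adv_aggregated": adv_term,
                      f"aux_{aux_loss}_0": aux_term,
                      "g_total": adv_term + aux_term}
            if not all(np.isfinite(v) for v in losses.values()):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}",
                                       checkpoint=best_params)
            history.batches.append({"losses": losses, "epoch": epoch,
                                    "mode": "sum", "active": [True],
                                    "sigma": 0.0,
                                    "sample_ids": [s.sample_id for s in batch]})
        params = G.get_parameters()
        if val_set:
            freq = ClassFrequencySpec.from_masks(
                [s.mask for s in train_set], n_classes)
            report = evaluate(G, params, val_set, cfg.dropout, freq,
                              n_samples=1, seed=cfg.seed)
            history.val_reports.append(report)
            if report.f1 > best_f1:
                best_f1, best_params = report.f1, params
                history.best_epoch = epoch
        else:
            best_params = params
            history.best_epoch = epoch
    return best_params, history
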