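"""Seed-deterministic adversarial training loops (desk scale).

The loops alternate critic and generator updates with one of three modes:
``wgan_clip`` (weight clipping after every critic step), ``wgan_gp``
(gradient penalty, no clipping), or ``logistic``.  Every loss component is
logged per step and a JSON manifest records the full configuration, so runs
are reproducible bit for bit from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .losses import (
    LossWeights,
    clip_weights,
    denoise_losses,
    logistic_d_loss,
    sr_losses,
    wasserstein_losses,
    wgan_gp_d_loss,
)
from .nn import Adam, Tensor, grad, no_grad


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5  # published setting; toy runs override
    batch_size: int = 2
    steps: int = 100
    seed: int = 0
    critic_updates_per_gen: int | None = None  # default: 5 clip mode, 1 GP
    gan_mode: str = "wgan_clip"  # wgan_clip | wgan_gp | logistic
    optimizer: str = "adam"

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be non-negative")
        if self.gan_mode not in ("wgan_clip", "wgan_gp", "logistic"):
            raise ValueError(f"unknown gan_mode {self.gan_mode!r}")
        if self.critic_updates_per_gen is None:
            self.critic_updates_per_gen = 5 if self.gan_mode == "wgan_clip" else 1

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "steps": self.steps,
            "seed": self.seed,
            "critic_updates_per_gen": self.critic_updates_per_gen,
            "gan_mode": self.gan_mode,
            "optimizer": self.optimizer,
        }


@dataclass
class TrainedPair:
    generator: object
    discriminator: object
    history: list = field(default_factory=list)


def _critic_step(D, d_opt, real, fake, config, weights, step_seed):
    if config.gan_mode == "wgan_gp":
        loss, _ = wgan_gp_d_loss(D, real, fake, psi=weights.gp_psi, seed=step_seed)
    elif config.gan_mode == "logistic":
        loss = logistic_d_loss(D(Tensor(real)), D(Tensor(fake)))
    else:
        d_loss, _ = wasserstein_losses(D(Tensor(real)), D(Tensor(fake)))
        loss = d_loss
    grads = grad(loss, D.parameters())
    d_opt.step(grads)
    if config.gan_mode == "wgan_clip":
        clip_weights(D, weights.clip_c)
    return float(loss.data)


def train_adversarial(
    G,
    D,
    data_stream,
    loss_fn,
    config: TrainConfig,
    weights: LossWeights | None = None,
    out_dir: str | Path | None = None,
):
    """Alternate critic and generator updates over a (input, target) stream.

    ``data_stream(rng, batch_size)`` must return (inputs, targets) numpy
    batches.  ``loss_fn(G_output, target, D)`` returns a LossBreakdown for
    the generator.  Non-finite losses abort with the last-good state kept.
    Returns a TrainedPair whose history logs every component per step.
    """
    weights = weights or LossWeights()
    rng = np.random.default_rng(config.seed)
    g_opt = Adam(G.parameters(), lr=config.learning_rate)
    d_opt = Adam(D.parameters(), lr=config.learning_rate) if D is not None else None
    history: list[dict] = []
    for step in range(config.steps):
        row: dict = {"step": step}
        inputs, targets = data_stream(rng, config.batch_size)
        if D is not None:
            with no_grad():
                fake = G(Tensor(inputs)).data
            d_losses = []
            for c in range(config.critic_updates_per_gen):
                d_losses.append(
                    _critic_step(D, d_opt, targets, fake, config, weights,
                                 step_seed=int(rng.integers(2**31)))
                )
            row["d_loss"] = float(np.mean(d_losses))
        out = G(Tensor(inputs))
        breakdown = loss_fn(out, Tensor(targets), D)
        if not np.isfinite(breakdown.total_value()):
            raise RuntimeError(f"non-finite generator loss at step {step}")
        grads = grad(breakdown.total, G.parameters())
        g_opt.step(grads)
        row["g_total"] = breakdown.total_value()
        row.update({f"g_{k}": v for k, v in breakdown.component_values().items()})
        history.append(row)
    pair = TrainedPair(generator=G, discriminator=D, history=history)
    if out_dir is not None:
        save_checkpoint(pair, config, weights, out_dir)
    return pair


def save_checkpoint(pair: TrainedPair, config: TrainConfig, weights: LossWeights,
                    out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "generator.npz", *(p.data for p in pair.generator.parameters()))
    if pair.discriminator is not None:
        np.savez(out / "discriminator.npz", *(p.data for p in pair.discriminator.parameters()))
    manifest = {
        "config": config.to_dict(),
        "loss_weights": weights.to_dict(),
        "n_steps_run": len(pair.history),
        "generator_parameters": int(pair.generator.n_parameters()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    with (out / "history.csv").open("w") as fh:
        if pair.history:
            keys = sorted({k for row in pair.history for k in row})
            fh.write(",".join(keys) + "\n")
            for row in pair.history:
                fh.write(",".join(str(row.get(k, "")) for k in keys) + "\n")
    return out


# ---------------------------------------------------------------------------
# fixture data streams (toy training)
# ---------------------------------------------------------------------------


def denoise_volume_stream(noise_sigma: float = 0.1, shape=(16, 16, 16), seed: int = 0):
    """(noisy, clean) 3-D volume batches from the smooth volume phantom."""
    from .phantoms import add_rician_noise, make_volume_phantom

    def stream(rng: np.random.Generator, batch: int):
        clean = np.stack(
            [make_volume_phantom(shape, seed=int(rng.integers(2**31))) for _ in range(batch)]
        )[:, None]
        noisy = np.stack(
            [
                add_rician_noise(v[0], noise_sigma, seed=int(rng.integers(2**31)))
                for v in clean
            ]
        )[:, None]
        return noisy, clean

    return stream


def toy_denoise_run(seed: int, steps: int = 40, noise_sigma: float = 0.1):
    """Train the width-1/4 denoiser on 16^3 fixtures; report held-out gains.

    Returns (TrainedPair, gains) where gains are the PSNR improvements of
    G(noisy) over noisy on three held-out volumes.
    """
    from .metrics import psnr
    from .networks import NetSpec, build_denoise_gan
    from .phantoms import add_rician_noise, make_volume_phantom

    G, D = build_denoise_gan(NetSpec(role="denoise_gen", width_multiplier=0.25, seed=seed))
    weights = LossWeights()
    cfg = TrainConfig(learning_rate=1e-3, batch_size=2, steps=steps, seed=seed,
                      gan_mode="wgan_gp")
    stream = denoise_volume_stream(noise_sigma=noise_sigma)

    def loss_fn(out, tgt, critic):
        return denoise_losses(out, tgt, critic=critic, extractor=None, weights=weights)

    pair = train_adversarial(G, D, stream, loss_fn, cfg, weights)
    G.eval()
    gains = []
    for s in (seed * 10 + 1001, seed * 10 + 1002, seed * 10 + 1003):
        clean = make_volume_phantom((16, 16, 16), seed=s)
        noisy = add_rician_noise(clean, noise_sigma, seed=s + 5)
        den = G(Tensor(noisy[None, None])).data[0, 0]
        gains.append(psnr(den, clean, peak=1.0) - psnr(noisy, clean, peak=1.0))
    return pair, gains


def toy_sr_run(seed: int, steps: int = 200):
    """Train the width-1/4 SR pair on DWI phantom pairs; report held-out gains.

    The baseline for each held-out case is the nearest-upsampled LR input;
    gains are PSNR(G(LR), HR) - PSNR(upsampled LR, HR).
    """
    from .metrics import psnr
    from .networks import NetSpec, build_sr_discriminator, build_sr_generator

    G = build_sr_generator(NetSpec(role="sr_gen", width_multiplier=0.25, seed=seed))
    D = build_sr_discriminator(NetSpec(role="sr_disc", width_multiplier=0.25, seed=seed + 1))
    weights = LossWeights()
    cfg = TrainConfig(learning_rate=1e-3, batch_size=2, steps=steps, seed=seed,
                      gan_mode="wgan_clip", critic_updates_per_gen=1)
    stream = sr_pair_stream(hr_size=64)

    def loss_fn(out, tgt, critic):
        return sr_losses(out, tgt, critic=critic, weights=weights)

    pair = train_adversarial(G, D, stream, loss_fn, cfg, weights)
    G.eval()
    rng = np.random.default_rng(seed + 7777)
    ins, tgt = stream(rng, 3)
    out = G(Tensor(ins)).data
    gains = []
    for i in range(3):
        up = np.repeat(np.repeat(ins[i, 0], 4, 0), 4, 1)
        gains.append(psnr(out[i, 0], tgt[i, 0], peak=1.0) - psnr(up, tgt[i, 0], peak=1.0))
    return pair, gains


def sr_pair_stream(hr_size: int = 64, factor: int = 4, blur_sigma: float = 1.0,
                   noise_sigma: float = 0.02, seed: int = 0):
    """(stacked adjacent LR frames, HR target) batches from the DWI phantom."""
    from .phantoms import DegradationSpec, PhantomSpec, degrade_to_lr, make_dwi_phantom

    deg = DegradationSpec(blur_sigma=blur_sigma, downsample_factor=factor,
                          noise_sigma=noise_sigma, noise_model="gaussian")

    def stream(rng: np.random.Generator, batch: int):
        ins, tgts = [], []
        for _ in range(batch):
            s = int(rng.integers(2**31))
            stack = make_dwi_phantom(
                PhantomSpec(name="dwi_tensor", matrix_size=hr_size, n_directions=3, seed=s)
            )
            t = 1  # middle direction is the target frame
            lr_t = degrade_to_lr(stack.images[t], deg, seed=s)
            lr_nb = degrade_to_lr(stack.images[t + 1], deg, seed=s + 1)
            ins.append(np.stack([lr_t, lr_nb]))
            tgts.append(stack.images[t][None])
        return np.stack(ins), np.stack(tgts)

    return stream
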