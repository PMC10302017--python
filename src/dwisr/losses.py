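"""Loss functions for the adversarial stages, with audited weights.

Every composite loss returns a LossBreakdown whose ``total`` is the weighted
sum of its logged components — an exact identity relied on by the tests.
Three adversarial modes are supported: ``wgan_clip`` (critic weights clipped
to +-c after each update), ``wgan_gp`` (gradient penalty), and ``logistic``
(the classic saturating GAN objective).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, grad
from .nn.autograd import cast, log, mean, scalar_like, sqrt, sum_


@dataclass
class LossWeights:
    """Every fixed scalar coefficient, in one audited record."""

    clip_c: float = 0.01  # critic weight-clipping bound
    adv_weight: float = 1e-6  # adversarial term weight in the SR composite
    rlt_weight: float = 0.001  # registration-consistency (RLT) weight
    deblur_lambda: float = 100.0  # content-loss weight in the deblur composite
    gp_psi: float = 10.0  # gradient-penalty coefficient
    denoise_deltas: tuple = (1.0, 0.1, 1e-3)  # (MSE, perceptual, adversarial)
    lipschitz_bound: float = 1.0  # absorbed into clipping; never estimated

    def __post_init__(self):
        if self.clip_c <= 0:
            raise ValueError("clip_c must be positive")
        for v in (self.adv_weight, self.rlt_weight, self.deblur_lambda, self.gp_psi,
                  *self.denoise_deltas):
            if not np.isfinite(v):
                raise ValueError("loss weights must be finite")

    def to_dict(self) -> dict:
        return {
            "clip_c": self.clip_c,
            "adv_weight": self.adv_weight,
            "rlt_weight": self.rlt_weight,
            "deblur_lambda": self.deblur_lambda,
            "gp_psi": self.gp_psi,
            "denoise_deltas": list(self.denoise_deltas),
            "lipschitz_bound": self.lipschitz_bound,
        }


@dataclass
class LossBreakdown:
    total: Tensor
    components: dict = field(default_factory=dict)  # name -> Tensor
    weights: dict = field(default_factory=dict)  # name -> float

    def component_values(self) -> dict:
        return {k: float(v.data) for k, v in self.components.items()}

    def total_value(self) -> float:
        return float(self.total.data)


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _f64(t: Tensor) -> Tensor:
    """Components are logged and accumulated in float64 so every composite
    equals the weighted sum of its logged components to machine precision."""
    return cast(t, np.float64)


# ---------------------------------------------------------------------------
# Wasserstein basics
# ---------------------------------------------------------------------------


def wasserstein_losses(critic_real, critic_fake):
    """(d_loss, g_loss): d = E[D(fake)] - E[D(real)], g = -E[D(fake)].

    Minimizing g_loss raises the critic score on generated samples;
    -d_loss estimates the Wasserstein gap between the two batches.
    """
    cr, cf = _as_t(critic_real), _as_t(critic_fake)
    if cr.size == 0 or cf.size == 0:
        raise ValueError("empty critic batch")
    d_loss = mean(cf) - mean(cr)
    g_loss = -mean(cf)
    return d_loss, g_loss


def clip_weights(network, c: float):
    """Clamp every trainable parameter of the critic to [-c, c] in place."""
    if c <= 0:
        raise ValueError("clip bound must be positive")
    for p in network.parameters():
        np.clip(p.data, -c, c, out=p.data)
    return network


def wgan_gp_d_loss(critic, real, fake, psi: float = 10.0, seed: int = 0):
    """Critic loss with a gradient penalty on random interpolates.

    x_hat = eps*real + (1-eps)*fake with eps ~ U(0,1) per sample;
    loss = E[D(fake)] - E[D(real)] + psi * E[(||grad_xhat D(x_hat)|| - 1)^2].
    The penalty's parameter gradient flows through the inner gradient
    (double backprop).
    """
    real_t, fake_t = _as_t(real), _as_t(fake)
    if real_t.shape != fake_t.shape:
        raise ValueError("real/fake batches must share a shape")
    rng = np.random.default_rng(seed)
    n = real_t.shape[0]
    eps = rng.uniform(0, 1, size=(n,) + (1,) * (real_t.ndim - 1))
    xhat = Tensor(eps * real_t.data + (1 - eps) * fake_t.data, requires_grad=True)
    d_hat = critic(xhat)
    gx, = grad(sum_(d_hat), [xhat], create_graph=True)
    axes = tuple(range(1, gx.ndim))
    norm = sqrt(sum_(gx * gx, axis=axes) + scalar_like(1e-24, gx))
    penalty = mean((norm - scalar_like(1.0, norm)) ** 2.0)
    base = mean(critic(fake_t)) - mean(critic(real_t))
    return base + scalar_like(psi, penalty) * penalty, penalty


def logistic_d_loss(critic_real, critic_fake):
    """Classic (saturating) GAN discriminator loss with a sigmoid readout."""
    from .nn.autograd import exp

    cr, cf = _as_t(critic_real), _as_t(critic_fake)

    def sig(t):
        return (scalar_like(1.0, t) + exp(-t)) ** -1.0

    eps = 1e-12
    return -mean(log(sig(cr) + scalar_like(eps, cr))) - mean(
        log(scalar_like(1.0, cf) - sig(cf) + scalar_like(eps, cf))
    )


# ---------------------------------------------------------------------------
# SR composite
# ---------------------------------------------------------------------------


def sr_losses(sr_image, hr_image, critic=None, registered_neighbors=(),
              target_frame=None, weights: LossWeights | None = None) -> LossBreakdown:
    """Pixel MSE + 1e-6 * adversarial + rho * registration-consistency.

    * MSE is averaged over the r^2*H*W HR pixels.
    * The adversarial term is mean(D(SR) - D(HR)) (Wasserstein form).
    * RLT sums ||I'_{t+i} - I_t||^2 over the registered neighbors i = +-1.
    """
    weights = weights or LossWeights()
    sr, hr = _as_t(sr_image), _as_t(hr_image)
    if sr.shape != hr.shape:
        raise ValueError("SR/HR shape mismatch")
    comps, wts = {}, {}
    l_mse = _f64(mean((hr - sr) ** 2.0))
    comps["mse"], wts["mse"] = l_mse, 1.0
    total = l_mse
    if critic is not None:
        l_gen = _f64(mean(critic(sr) - critic(hr)))
        comps["adversarial"], wts["adversarial"] = l_gen, weights.adv_weight
        total = total + scalar_like(weights.adv_weight, l_gen) * l_gen
    if registered_neighbors:
        tf = _as_t(target_frame if target_frame is not None else hr)
        rlt = None
        for nb in registered_neighbors:
            term = sum_((_as_t(nb) - tf) ** 2.0)
            rlt = term if rlt is None else rlt + term
        rlt = _f64(rlt)
        comps["rlt"], wts["rlt"] = rlt, weights.rlt_weight
        total = total + scalar_like(weights.rlt_weight, rlt) * rlt
    return LossBreakdown(total=total, components=comps, weights=wts)


# ---------------------------------------------------------------------------
# deblur composite
# ---------------------------------------------------------------------------


def deblur_loss(deblurred, sharp, critic, extractor, weights: LossWeights | None = None,
                layer: int | None = None) -> LossBreakdown:
    """Adversarial + lambda * perceptual-content loss.

    L_adv = sum_n -D(G(I_B)); L_X = mean squared feature difference
    normalized by the feature-map dimensions; total = L_adv + lambda * L_X.
    """
    weights = weights or LossWeights()
    g_out, sharp_t = _as_t(deblurred), _as_t(sharp)
    l_gan = _f64(-sum_(critic(g_out)))
    f_sharp = extractor(sharp_t, layer=layer)
    f_out = extractor(g_out, layer=layer)
    l_x = _f64(mean((f_sharp - f_out) ** 2.0))
    total = l_gan + scalar_like(weights.deblur_lambda, l_x) * l_x
    return LossBreakdown(
        total=total,
        components={"adversarial": l_gan, "content": l_x},
        weights={"adversarial": 1.0, "content": weights.deblur_lambda},
    )


# ---------------------------------------------------------------------------
# denoise composite
# ---------------------------------------------------------------------------


def denoise_losses(denoised, clean, critic=None, extractor=None,
                   weights: LossWeights | None = None) -> LossBreakdown:
    """delta1 * MSE + delta2 * perceptual + delta3 * adversarial (generator).

    MSE is normalized by the o*p*r voxel count; the perceptual term is a
    squared Frobenius feature distance normalized by the feature-map size.
    """
    weights = weights or LossWeights()
    d1, d2, d3 = weights.denoise_deltas
    g_out, clean_t = _as_t(denoised), _as_t(clean)
    if g_out.shape != clean_t.shape:
        raise ValueError("volume shape mismatch")
    comps, wts = {}, {}
    l_mse = _f64(mean((g_out - clean_t) ** 2.0))
    comps["mse"], wts["mse"] = l_mse, d1
    total = scalar_like(d1, l_mse) * l_mse
    if extractor is not None:
        f_out = extractor(g_out)
        f_clean = extractor(clean_t)
        l_perc = _f64(mean((f_out - f_clean) ** 2.0))
        comps["perceptual"], wts["perceptual"] = l_perc, d2
        total = total + scalar_like(d2, l_perc) * l_perc
    if critic is not None:
        l_adv = _f64(-mean(critic(g_out)))
        comps["adversarial"], wts["adversarial"] = l_adv, d3
        total = total + scalar_like(d3, l_adv) * l_adv
    return LossBreakdown(total=total, components=comps, weights=wts)
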