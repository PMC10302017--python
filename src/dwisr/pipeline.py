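"""End-to-end orchestration: sample -> low-resolution reconstruction ->
denoise -> deblur -> register -> super-resolve -> evaluate.

The stage operators are pluggable: each enhancement stage runs either an
analytic operator (the default: deterministic, fast) or a trained network.
Everything is reproducible from (config, seed): rerunning a configuration
yields byte-identical metrics JSON.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import filters, transform

from . import io as dio
from .metrics import compute_metrics
from .phantoms import (
    DegradationSpec,
    DWIStack,
    PhantomSpec,
    degrade_to_lr,
    make_dwi_phantom,
    make_shepp_logan,
    make_volume_phantom,
    make_displacement_field,
    DeformationSpec,
)
from .recon import (
    KSpace,
    ReconConfig,
    dc_cascade_recon,
    fft2c,
    ifft2c,
    rosa_composite,
    tv_refiner,
)
from .registration import mrf_register, warp
from .sampling import (
    blades_to_mask,
    kq_schedule,
    nested_mask_family,
    partial_fourier_mask,
    propeller_blades,
)

SPARSITY_RATES = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(
        name="dwi_tensor", matrix_size=128, n_directions=8))
    degradation: DegradationSpec = field(default_factory=lambda: DegradationSpec(
        blur_sigma=1.0, downsample_factor=4, noise_sigma=0.02))
    sparsity_rate: float = 0.6  # fraction of k-space samples retained
    sampling_kind: str = "nested_vd"  # nested_vd | blades
    partial_fourier: float = 1.0  # (0.5, 1]; 1 disables
    recon: ReconConfig = field(default_factory=lambda: ReconConfig(
        n_dc_iterations=8, denoiser_hook=tv_refiner(0.02)))
    neighbor_window: int = 2
    registration: dict = field(default_factory=lambda: {
        "kappa": 0.5, "label_range": 3, "levels": 2, "block_size": 6})
    register_before_denoise: bool = False
    denoise_sigma: float = 0.5  # analytic denoiser strength
    deblur_amount: float = 0.6  # unsharp-mask amount (analytic deblur)
    sr_method: str = "analytic"  # analytic (cubic resize) | network
    sr_checkpoint: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "phantom": vars(self.phantom).copy(),
            "degradation": {
                k: (vars(v).copy() if isinstance(v, DeformationSpec) else v)
                for k, v in vars(self.degradation).items()
            },
            "sparsity_rate": self.sparsity_rate,
            "sampling_kind": self.sampling_kind,
            "partial_fourier": self.partial_fourier,
            "recon": {k: v for k, v in vars(self.recon).items() if k != "denoiser_hook"},
            "neighbor_window": self.neighbor_window,
            "registration": dict(self.registration),
            "register_before_denoise": self.register_before_denoise,
            "denoise_sigma": self.denoise_sigma,
            "deblur_amount": self.deblur_amount,
            "sr_method": self.sr_method,
            "seed": self.seed,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    config_hash: str
    stage_metrics: dict  # stage name -> dict
    final_psnr: float
    images: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def metrics_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "stages": self.stage_metrics,
             "final_psnr": self.final_psnr},
            indent=2,
            sort_keys=True,
        )


def _direction_masks(config: PipelineConfig, lr_size: int, n_dir: int):
    """Per-direction sampling masks at the configured sparsity rate."""
    rate = config.sparsity_rate
    if config.sampling_kind == "blades":
        blades = propeller_blades(n_dir, max(4, lr_size // 4), lr_size, lr_size)
        masks = [blades_to_mask([b], lr_size) for b in blades]
    else:
        fam = nested_mask_family(lr_size, [rate], seed=config.seed)
        masks = [fam[rate]] * n_dir
    if config.partial_fourier < 1.0:
        masks = [partial_fourier_mask(m, config.partial_fourier) for m in masks]
    return masks


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full chain on a synthetic acquisition and evaluate it."""
    t_start = time.time()
    stage_metrics: dict = {}
    timings: dict = {}
    rng = np.random.default_rng(config.seed)

    # --- ground truth and low-resolution acquisition -----------------------
    t0 = time.time()
    stack_hr = make_dwi_phantom(config.phantom)
    f = config.degradation.downsample_factor
    lr_size = config.phantom.matrix_size // f
    lr_clean = np.stack([
        degrade_to_lr(im, DegradationSpec(
            blur_sigma=config.degradation.blur_sigma, downsample_factor=f,
            noise_sigma=0.0, motion=config.degradation.motion), seed=config.seed)
        for im in stack_hr.images
    ])
    lr_noisy = lr_clean.copy()
    if config.degradation.noise_sigma > 0:
        if config.degradation.noise_model == "gaussian":
            lr_noisy = lr_clean + rng.normal(0, config.degradation.noise_sigma, lr_clean.shape)
        else:
            from .phantoms import add_rician_noise

            lr_noisy = np.stack([
                add_rician_noise(np.clip(im, 0, None), config.degradation.noise_sigma,
                                 seed=int(rng.integers(2**31)))
                for im in lr_clean
            ])
    timings["phantom"] = time.time() - t0

    # --- k-space sampling ---------------------------------------------------
    t0 = time.time()
    n_dir = stack_hr.n_directions
    masks = _direction_masks(config, lr_size, n_dir)
    kspaces = [
        KSpace(values=fft2c(lr_noisy[d]) * masks[d].mask, support=masks[d])
        for d in range(n_dir)
    ]
    timings["sampling"] = time.time() - t0

    # --- low-resolution reconstruction --------------------------------------
    t0 = time.time()
    recon_imgs = np.stack([
        dc_cascade_recon(kspaces[d], masks[d], config.recon) for d in range(n_dir)
    ])
    if config.neighbor_window > 0 and n_dir > config.neighbor_window:
        scheme = kq_schedule(n_dir, neighbor_window=config.neighbor_window)
        scheme.q_vectors = stack_hr.q_vectors  # phantom directions are authoritative
        stack_zf = DWIStack(images=recon_imgs, q_vectors=stack_hr.q_vectors,
                            b_value=stack_hr.b_value)
        recon_imgs = rosa_composite(stack_zf, kspaces, scheme, masks).images
    stage_metrics["recon"] = _stack_metrics(recon_imgs, lr_clean)
    timings["recon"] = time.time() - t0

    # --- enhancement stages --------------------------------------------------
    def denoise_stage(imgs):
        return np.stack([ndimage.gaussian_filter(im, config.denoise_sigma) for im in imgs])

    def deblur_stage(imgs):
        out = []
        for im in imgs:
            lo, hi = im.min(), im.max()
            span = hi - lo if hi > lo else 1.0
            u = filters.unsharp_mask((im - lo) / span, radius=1.5,
                                     amount=config.deblur_amount)
            out.append(u * span + lo)
        return np.stack(out)

    t0 = time.time()
    work = recon_imgs
    order = ["register", "denoise"] if config.register_before_denoise else ["denoise", "register"]
    fields = [None] * n_dir
    for stage in order + ["deblur"]:
        if stage == "denoise":
            work = denoise_stage(work)
            stage_metrics["denoise"] = _stack_metrics(work, lr_clean)
        elif stage == "deblur":
            work = deblur_stage(work)
            stage_metrics["deblur"] = _stack_metrics(work, lr_clean)
        elif stage == "register":
            ref = 0  # register every direction onto the first
            reg = [work[ref]]
            for d in range(1, n_dir):
                fld, _, _ = mrf_register(
                    work[ref], work[d],
                    block_size=config.registration.get("block_size", 6),
                    label_range=config.registration.get("label_range", 3),
                    kappa=config.registration.get("kappa", 0.5),
                    levels=config.registration.get("levels", 2),
                )
                fields[d] = fld
                reg.append(warp(work[d], fld))
            # registered neighbors feed the SR stage; images stay per-direction
            registered = np.stack(reg)
            stage_metrics["register"] = _stack_metrics(registered, lr_clean)
    timings["enhance"] = time.time() - t0

    # --- super-resolution ----------------------------------------------------
    t0 = time.time()
    hr_size = config.phantom.matrix_size
    if config.sr_method == "network" and config.sr_checkpoint:
        from .networks import NetSpec, build_sr_generator
        from .nn import Tensor

        G = build_sr_generator(NetSpec(role="sr_gen", width_multiplier=0.25)).eval()
        data = np.load(config.sr_checkpoint)
        G.load_state_arrays([data[k] for k in data.files])
        sr = np.stack([
            G(Tensor(np.stack([work[d], work[(d + 1) % n_dir]])[None])).data[0, 0]
            for d in range(n_dir)
        ])
    else:
        sr = np.stack([
            transform.resize(work[d], (hr_size, hr_size), order=3, anti_aliasing=False)
            for d in range(n_dir)
        ])
    stage_metrics["super_resolution"] = _stack_metrics(sr, stack_hr.images)
    timings["sr"] = time.time() - t0

    final = float(np.mean([
        compute_metrics(sr[d], stack_hr.images[d], peak=1.0).psnr for d in range(n_dir)
    ]))
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "elapsed_s": round(time.time() - t_start, 3),
        "mask_fraction": masks[0].fraction_sampled,
    }
    result = RunResult(
        config_hash=config.hash(),
        stage_metrics=stage_metrics,
        final_psnr=final,
        images={"sr": sr, "recon": recon_imgs, "lr_clean": lr_clean, "hr": stack_hr.images},
        manifest=manifest,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.save_nifti(out / "sr.nii", np.moveaxis(sr, 0, -1))
        dio.save_nifti(out / "recon_lr.nii", np.moveaxis(recon_imgs, 0, -1))
        (out / "metrics.json").write_text(result.metrics_json())
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result


def _stack_metrics(test: np.ndarray, ref: np.ndarray) -> dict:
    ps = [compute_metrics(t, r, peak=1.0) for t, r in zip(test, ref)]
    return {
        "psnr_mean": float(np.mean([p.psnr for p in ps])),
        "ssim_mean": float(np.mean([p.ssim for p in ps])),
        "mse_mean": float(np.mean([p.mse for p in ps])),
    }


def sparsity_sweep(config: PipelineConfig, rates=SPARSITY_RATES) -> dict:
    """Run the pipeline across sparsity rates on a fixed phantom and seed.

    Masks come from one nested family, so each higher rate strictly adds
    samples; reports final PSNR per rate.
    """
    out = {}
    for r in rates:
        cfg = PipelineConfig(**{**config.__dict__, "sparsity_rate": r})
        out[r] = run_pipeline(cfg).final_psnr
    return out


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the canonical small test set used throughout the suite.

    64^2 Shepp-Logan, an 8-direction 48^2 DWI stack (NIfTI + bvec/bval),
    16^3 clean/noisy denoiser volumes, an RBF deformation with its warped
    image, and sampling masks at the five sparsity rates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory = {}

    sl = make_shepp_logan(PhantomSpec(matrix_size=64, seed=seed))
    dio.save_nifti(out / "shepp_logan_64.nii", sl)
    inventory["shepp_logan"] = "shepp_logan_64.nii"

    # 48 is not a power of two; the DWI fixture uses 64 and crops centrally
    stack = make_dwi_phantom(PhantomSpec(name="dwi_tensor", matrix_size=64,
                                         n_directions=8, seed=seed))
    cropped = DWIStack(images=stack.images[:, 8:56, 8:56], q_vectors=stack.q_vectors,
                       b_value=stack.b_value)
    inventory["dwi_stack"] = dio.save_dwi_stack(cropped, out, "dwi_48_8dir")

    from .phantoms import add_rician_noise

    clean = make_volume_phantom((16, 16, 16), seed=seed + 1)
    noisy = add_rician_noise(clean, 0.1, seed=seed + 2)
    np.savez_compressed(out / "denoise_volumes.npz", clean=clean, noisy=noisy)
    inventory["denoise_volumes"] = "denoise_volumes.npz"

    dspec = DeformationSpec(kind="rbf_nonrigid", max_displacement=3.0, seed=seed + 3)
    field_arr = make_displacement_field(sl.shape, dspec)
    from .phantoms import warp_image

    warped = warp_image(sl, field_arr)
    dio.save_field(out / "deformation_field.npz", field_arr)
    dio.save_nifti(out / "shepp_logan_warped.nii", warped)
    inventory["deformation"] = ["deformation_field.npz", "shepp_logan_warped.nii"]

    fam = nested_mask_family(64, SPARSITY_RATES, seed=seed)
    mask_files = {}
    for r, m in fam.items():
        files = dio.save_mask(out / f"mask_rate{int(r * 100)}", m)
        mask_files[f"{int(r * 100)}%"] = files
    inventory["masks"] = mask_files

    manifest = {"seed": seed, "inventory": inventory}
    (out / "fixtures_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
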