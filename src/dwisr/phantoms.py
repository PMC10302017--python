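"""Synthetic test objects: Shepp–Logan, diffusion-tensor DWI stacks, and the
degradations (motion, blur, decimation, Gaussian/Rician noise) used to build
low-resolution inputs.

The DWI phantom follows the mono-exponential tensor model
``S(g) = S0 * exp(-b g^T D g)`` with a spatially varying tensor field over a
few tissue classes, so that images from nearby q-space directions are highly
correlated while distant directions decorrelate — the redundancy that
neighbor-direction sharing exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    name: str = "shepp_logan"  # or "dwi_tensor"
    matrix_size: int = 64
    n_directions: int = 8
    b_value: float = 1000.0  # s/mm^2
    seed: int = 0

    def __post_init__(self):
        if self.name not in ("shepp_logan", "dwi_tensor"):
            raise ValueError(f"unknown phantom {self.name!r}")
        n = int(self.matrix_size)
        if n < 16 or (n & (n - 1)) != 0:
            raise ValueError("matrix_size must be a power of two >= 16")
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        if self.b_value < 0:
            raise ValueError("b_value must be non-negative")


@dataclass
class DeformationSpec:
    kind: str = "rbf_nonrigid"  # or "affine"
    max_displacement: float = 3.0  # voxels
    rotation_deg: float = 0.0
    subpixel_shift: float = 0.0
    control_points: int = 4
    seed: int = 0
    max_gradient: float = 0.5  # smoothness bound on finite differences

    def __post_init__(self):
        if self.kind not in ("affine", "rbf_nonrigid"):
            raise ValueError(f"unknown deformation kind {self.kind!r}")


@dataclass
class DegradationSpec:
    blur_sigma: float = 1.0  # pixels
    downsample_factor: int = 4
    noise_sigma: float = 25.0 / 255.0  # on the internal [0, 1] scale
    noise_model: str = "gaussian"  # or "rician"
    motion: DeformationSpec | None = None

    def __post_init__(self):
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class DWIStack:
    """Registered magnitude DW images with their q-space metadata."""

    images: np.ndarray  # (n_directions, H, W)
    q_vectors: np.ndarray  # (n_directions, 3), unit norm
    b_value: float
    s0: np.ndarray | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.q_vectors = np.asarray(self.q_vectors, dtype=float)
        if self.images.shape[0] != self.q_vectors.shape[0]:
            raise ValueError("one q-vector per direction required")

    @property
    def n_directions(self) -> int:
        return self.images.shape[0]


# ---------------------------------------------------------------------------
# Shepp–Logan
# ---------------------------------------------------------------------------

# (intensity delta, a, b, x0, y0, phi_deg) — modified (unit-intensity) variant,
# so summed intensities stay in [0, 1].
SHEPP_LOGAN_ELLIPSES = [
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.874, 0.0, -0.0184, 0.0),
    (-0.2, 0.11, 0.31, 0.22, 0.0, -18.0),
    (-0.2, 0.16, 0.41, -0.22, 0.0, 18.0),
    (0.1, 0.21, 0.25, 0.0, 0.35, 0.0),
    (0.1, 0.046, 0.046, 0.0, 0.1, 0.0),
    (0.1, 0.046, 0.046, 0.0, -0.1, 0.0),
    (0.1, 0.046, 0.023, -0.08, -0.605, 0.0),
    (0.1, 0.023, 0.023, 0.0, -0.606, 0.0),
    (0.1, 0.023, 0.046, 0.06, -0.605, 0.0),
]


def shepp_logan_value(x: float, y: float) -> float:
    """Closed-form phantom intensity at normalized coordinates (x, y)."""
    val = 0.0
    for a0, a, b, x0, y0, phi in SHEPP_LOGAN_ELLIPSES:
        c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
        xr = (x - x0) * c + (y - y0) * s
        yr = -(x - x0) * s + (y - y0) * c
        if (xr / a) ** 2 + (yr / b) ** 2 <= 1.0:
            val += a0
    return val


def make_shepp_logan(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the analytic 10-ellipse head phantom on spec.matrix_size."""
    if spec.name != "shepp_logan":
        raise ValueError("spec.name must be 'shepp_logan'")
    n = spec.matrix_size
    # pixel n//2 sits exactly at the origin, matching the centered-FFT grid
    coords = (np.arange(n) - n // 2) / (n / 2)
    x, y = np.meshgrid(coords, -coords, indexing="xy")
    img = np.zeros((n, n), dtype=float)
    for a0, a, b, x0, y0, phi in SHEPP_LOGAN_ELLIPSES:
        c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
        xr = (x - x0) * c + (y - y0) * s
        yr = -(x - x0) * s + (y - y0) * c
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += a0
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# DWI tensor phantom
# ---------------------------------------------------------------------------


def uniform_sphere_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors (golden-spiral) on the upper hemisphere.

    Diffusion encoding is antipodally symmetric, so the hemisphere suffices.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n) + 0.5
    # z in (0, 1): hemisphere
    z = i / n
    phi = np.pi * (1 + 5**0.5) * i
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    g = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def _tensor_field(n: int, rng: np.random.Generator):
    """Diffusion tensors (mm^2/s) on an n x n grid: 3 tissue classes.

    Class 0: background (no signal).  Class 1: isotropic "CSF-like".
    Class 2: anisotropic "fiber" region with smoothly rotating principal axis.
    """
    base = make_shepp_logan(PhantomSpec(matrix_size=n))
    s0 = np.where(base > 0, 0.2 + 0.8 * base, 0.0)
    iso = (base > 0) & (base < 0.25)
    fiber = base >= 0.25
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    # in-plane fiber angle varies smoothly across the image
    theta = 2.0 * np.pi * (xx + yy) / (2.0 * n) + rng.uniform(0, np.pi)
    d_iso = 2.5e-3
    lam_par, lam_perp = 1.8e-3, 0.3e-3
    D = np.zeros((n, n, 3, 3))
    D[iso] = d_iso * np.eye(3)
    ct, st = np.cos(theta), np.sin(theta)
    e1 = np.stack([ct, st, np.zeros_like(ct)], axis=-1)  # (n,n,3)
    outer = e1[..., :, None] * e1[..., None, :]
    aniso = lam_perp * np.eye(3) + (lam_par - lam_perp) * outer
    D[fiber] = aniso[fiber]
    return s0, D


def make_dwi_phantom(spec: PhantomSpec, noise_sigma: float = 0.0) -> DWIStack:
    """Multi-direction DW magnitude stack from a tensor-field phantom.

    Adjacent q-space directions produce highly correlated images; the
    correlation decays with angular distance (the premise of blade sharing).
    Optional Rician magnitude noise with std ``noise_sigma``.
    """
    if spec.b_value < 0:
        raise ValueError("b_value must be non-negative")
    rng = np.random.default_rng(spec.seed)
    n = spec.matrix_size
    s0, D = _tensor_field(n, rng)
    g = uniform_sphere_directions(spec.n_directions)
    # ADC per direction: g^T D g, shape (n_dir, n, n)
    adc = np.einsum("di,xyij,dj->dxy", g, D, g)
    images = s0[None] * np.exp(-spec.b_value * adc)
    if noise_sigma > 0:
        images = np.stack(
            [add_rician_noise(im, noise_sigma, seed=int(rng.integers(2**31))) for im in images]
        )
    return DWIStack(images=images, q_vectors=g, b_value=spec.b_value, s0=s0)


# ---------------------------------------------------------------------------
# deformations
# ---------------------------------------------------------------------------


def make_displacement_field(shape, spec: DeformationSpec) -> np.ndarray:
    """Ground-truth displacement field, shape (2, H, W), in voxels.

    Backward-warping convention: ``warped(p) = image(p + field(p))``.
    """
    h, w = shape
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    if spec.kind == "affine":
        th = np.deg2rad(spec.rotation_deg)
        cy, cx = (h - 1) / 2, (w - 1) / 2
        dy = (np.cos(th) - 1) * (yy - cy) - np.sin(th) * (xx - cx) + spec.subpixel_shift
        dx = np.sin(th) * (yy - cy) + (np.cos(th) - 1) * (xx - cx) + spec.subpixel_shift
        field = np.stack([dy, dx])
    else:
        field = np.zeros((2, h, w))
        sigma = max(h, w) / 4.0
        for _ in range(spec.control_points):
            cy = rng.uniform(0, h - 1)
            cx = rng.uniform(0, w - 1)
            amp = rng.uniform(-1, 1, size=2)
            rbf = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
            field[0] += amp[0] * rbf
            field[1] += amp[1] * rbf
        peak = np.abs(field).max()
        if peak > 0:
            field *= spec.max_displacement / peak
        field[0] += spec.subpixel_shift
        field[1] += spec.subpixel_shift
    gmax = max(
        np.abs(np.diff(field, axis=1)).max(initial=0.0),
        np.abs(np.diff(field, axis=2)).max(initial=0.0),
    )
    if gmax > spec.max_gradient + 1e-9:
        raise ValueError(
            f"generated field is not smooth enough (max finite-difference {gmax:.3f} "
            f"> bound {spec.max_gradient})"
        )
    return field


def warp_image(image: np.ndarray, field: np.ndarray, order: int = 3) -> np.ndarray:
    """Backward-warp ``image`` by a dense displacement field (2, H, W)."""
    h, w = image.shape
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return ndimage.map_coordinates(
        image, [yy + field[0], xx + field[1]], order=order, mode="reflect"
    )


def apply_deformation(image: np.ndarray, spec: DeformationSpec):
    """Warp an image by a generated deformation; returns (warped, field)."""
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    field = make_displacement_field(image.shape, spec)
    if np.abs(field).max() > min(image.shape):
        raise ValueError("displacement exceeds image extent")
    if not np.any(field):
        return image.copy(), field
    return warp_image(image, field), field


# ---------------------------------------------------------------------------
# degradations
# ---------------------------------------------------------------------------


def add_rician_noise(image: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Magnitude of (image + n1) + i*n2 with iid Gaussian n1, n2 of std sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("Rician noise applies to non-negative magnitude images")
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0, sigma, image.shape)
    n2 = rng.normal(0, sigma, image.shape)
    return np.sqrt((image + n1) ** 2 + n2**2)


def block_average(image: np.ndarray, factor: int) -> np.ndarray:
    h, w = image.shape
    if h % factor or w % factor:
        raise ValueError("downsample_factor must divide the image size")
    return image.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def degrade_to_lr(image: np.ndarray, deg: DegradationSpec, seed: int = 0) -> np.ndarray:
    """Low-resolution formation: (motion) -> blur -> decimate -> noise."""
    out = np.asarray(image, dtype=float)
    if deg.motion is not None:
        out, _ = apply_deformation(out, deg.motion)
    if deg.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, deg.blur_sigma, mode="reflect")
    if deg.downsample_factor > 1:
        out = block_average(out, deg.downsample_factor)
    if deg.noise_sigma > 0:
        if deg.noise_model == "gaussian":
            rng = np.random.default_rng(seed)
            out = out + rng.normal(0, deg.noise_sigma, out.shape)
        else:
            out = add_rician_noise(out, deg.noise_sigma, seed=seed)
    return out


def make_volume_phantom(shape, seed: int = 0, n_blobs: int = 6) -> np.ndarray:
    """Smooth 3-D magnitude volume in [0, 1] for denoiser fixtures."""
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    for _ in range(n_blobs):
        c = [rng.uniform(0, s - 1) for s in shape]
        s2 = rng.uniform(2, max(shape) / 2) ** 2
        vol += rng.uniform(0.3, 1.0) * np.exp(
            -((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) / (2 * s2)
        )
    vol -= vol.min()
    m = vol.max()
    return vol / m if m > 0 else vol
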