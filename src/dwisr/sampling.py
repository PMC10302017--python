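"""k-q sampling pattern generation.

Covers PROPELLER blade trajectories, Poisson-disc subsampling with a
variable-density profile, Hermitian ("halved") partial-Fourier masks, radial
masks, and the one-blade-per-direction schedule with q-space neighbor lists.

Conventions: k-space coordinates live in cycles/FOV within the half-open
Nyquist box [-0.5, 0.5); Cartesian grids are 0-based with DC at index N//2
(centered layout); the conjugate mirror of index i is (-i) mod N in the
unshifted layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .phantoms import uniform_sphere_directions


@dataclass
class Trajectory:
    """Off-grid k-space sample locations with density-compensation weights."""

    coords: np.ndarray  # (M, 2) (kx, ky) in cycles/FOV
    density_weights: np.ndarray  # (M,)
    grid_size: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (M, 2)")
        if np.any(self.coords < -0.5) or np.any(self.coords >= 0.5):
            raise ValueError("coords must lie in the half-open Nyquist box [-0.5, 0.5)")
        if self.density_weights is None:
            self.density_weights = np.ones(len(self.coords))
        self.density_weights = np.asarray(self.density_weights, dtype=float)
        if np.any(self.density_weights <= 0):
            raise ValueError("density weights must be positive")


@dataclass
class SamplingMask:
    """Binary Cartesian mask in centered layout (DC at N//2)."""

    mask: np.ndarray
    hermitian_half: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def fraction_sampled(self) -> float:
        return float(self.mask.mean())

    @property
    def grid_size(self):
        return self.mask.shape


@dataclass
class QScheme:
    """One blade angle per diffusion direction plus q-space neighbor lists."""

    q_vectors: np.ndarray  # (D, 3)
    blade_angles: np.ndarray  # degrees, in [0, 180)
    neighbor_window: int
    neighbors: list = field(default_factory=list)  # per-direction index lists

    @property
    def n_directions(self) -> int:
        return len(self.q_vectors)


# ---------------------------------------------------------------------------
# PROPELLER blades
# ---------------------------------------------------------------------------


def propeller_blades(
    n_blades: int, lines_per_blade: int, samples_per_line: int, grid_size: int
) -> list[Trajectory]:
    """Rotated rectangular strips of parallel lines through the k-space center.

    Blade ``b`` is the axis-aligned strip rotated by ``b * 180 / n_blades``
    degrees (180-degree coverage: Cartesian lines are undirected).  Samples
    falling outside the Nyquist box after rotation are dropped.
    """
    if n_blades < 1:
        raise ValueError("n_blades must be >= 1")
    if lines_per_blade > grid_size:
        raise ValueError("lines_per_blade exceeds grid size")
    ky = (np.arange(lines_per_blade) - lines_per_blade // 2) / grid_size
    kx = (np.arange(samples_per_line) - samples_per_line // 2) / samples_per_line
    kxg, kyg = np.meshgrid(kx, ky, indexing="xy")
    base = np.stack([kxg.ravel(), kyg.ravel()], axis=1)
    blades = []
    for b in range(n_blades):
        th = np.deg2rad(b * 180.0 / n_blades)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = base @ rot.T
        keep = np.all((pts >= -0.5) & (pts < 0.5), axis=1)
        pts = pts[keep]
        # analytic ramp weights: density of parallel-line strips is flat, so
        # weights default to 1; rosette/radial-style |k| ramps do not apply.
        blades.append(
            Trajectory(coords=pts, density_weights=np.ones(len(pts)), grid_size=grid_size)
        )
    return blades


def trajectory_to_mask(traj: Trajectory, grid_size: int | None = None) -> SamplingMask:
    """Rasterize trajectory samples to the nearest Cartesian grid cell."""
    n = grid_size or traj.grid_size
    idx = np.rint(traj.coords * n).astype(int) + n // 2
    idx = np.clip(idx, 0, n - 1)
    mask = np.zeros((n, n), dtype=bool)
    # coords are (kx, ky): kx -> column, ky -> row
    mask[idx[:, 1], idx[:, 0]] = True
    return SamplingMask(mask=mask)


def blades_to_mask(blades: Sequence[Trajectory], grid_size: int) -> SamplingMask:
    mask = np.zeros((grid_size, grid_size), dtype=bool)
    for b in blades:
        mask |= trajectory_to_mask(b, grid_size).mask
    return SamplingMask(mask=mask)


# ---------------------------------------------------------------------------
# Poisson-disc subsampling
# ---------------------------------------------------------------------------


def default_density_profile(core_radius: float = 0.08, hf_boost: float = 2.0) -> Callable:
    """Relative sampling rate vs |k|/k_max.

    A fully sampled low-frequency core (rate -> inf below ``core_radius``)
    and a boosted high-frequency band; the exact high-frequency law is a
    configuration choice, default linear in radius.
    """

    def profile(rho: np.ndarray) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        rate = 1.0 + (hf_boost - 1.0) * rho
        return np.where(rho < core_radius, np.inf, rate)

    return profile


class InfeasibleSampling(ValueError):
    pass


def poisson_subsample(
    support,
    target_fraction: float,
    r_min: float,
    density_profile: Callable | None = None,
    seed: int = 0,
    max_attempts: int = 20,
) -> SamplingMask:
    """Poisson-disc (dart-throwing) subsampling of a Cartesian support.

    ``support`` is a SamplingMask or a square grid size.  Retained samples are
    pairwise separated by at least ``r_min`` in the density-warped metric
    (locally ``r_min / sqrt(rate)``); with a uniform profile this is the plain
    Euclidean minimum distance.  The achieved fraction must land within 10 %
    of ``target_fraction`` (relative), else InfeasibleSampling is raised.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if isinstance(support, SamplingMask):
        base = support.mask
    else:
        base = np.ones((int(support), int(support)), dtype=bool)
    n = base.shape[0]
    ys, xs = np.nonzero(base)
    total = len(ys)
    target_n = target_fraction * total
    if target_fraction == 1.0 and r_min <= 0:
        return SamplingMask(mask=base.copy())
    rho = np.hypot(ys - n // 2, xs - n // 2) / (n / 2)
    rate = (
        np.ones(total) if density_profile is None else np.asarray(density_profile(rho), dtype=float)
    )
    local_r = np.where(np.isinf(rate), 0.0, r_min / np.sqrt(np.maximum(rate, 1e-12)))
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        order = rng.permutation(total)
        kept_y: list[int] = []
        kept_x: list[int] = []
        kept_r: list[float] = []
        for j in order:
            if len(kept_y) >= int(np.ceil(target_n)):
                break
            y, x, r = ys[j], xs[j], local_r[j]
            if kept_y:
                d2 = (np.array(kept_y) - y) ** 2 + (np.array(kept_x) - x) ** 2
                rr = np.maximum(np.array(kept_r), r)
                if np.any(d2 < rr**2):
                    continue
            kept_y.append(y)
            kept_x.append(x)
            kept_r.append(r)
        if len(kept_y) >= 0.9 * target_n:
            mask = np.zeros_like(base)
            mask[kept_y, kept_x] = True
            return SamplingMask(mask=mask)
    raise InfeasibleSampling(
        f"cannot reach fraction {target_fraction} with r_min={r_min} "
        f"(best {len(kept_y) / total:.3f} of support)"
    )


def min_pairwise_distance(mask: SamplingMask) -> float:
    """Exhaustive O(n^2) minimum Euclidean distance between sampled points."""
    ys, xs = np.nonzero(mask.mask)
    if len(ys) < 2:
        return np.inf
    pts = np.stack([ys, xs], axis=1).astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    return float(np.sqrt(d2.min()))


# ---------------------------------------------------------------------------
# partial Fourier
# ---------------------------------------------------------------------------


def _kept_rows(n: int, fraction: float) -> np.ndarray:
    """Row selector (centered layout) for an asymmetric-echo acquisition.

    Keeps ceil(fraction * n) rows: the self-conjugate extreme row (centered
    coordinate -n/2), plus centered coordinates [-(m), n/2 - 1] where
    m = kept - n/2 - 1.  Every removed row's conjugate mirror is kept.
    """
    kept = int(np.ceil(fraction * n))
    m = kept - n // 2 - 1
    c = np.arange(n) - n // 2  # centered coordinate per row index
    sel = (c >= -m) | (c == -(n // 2))
    return sel


def partial_fourier_mask(mask: SamplingMask, fraction: float) -> SamplingMask:
    """Restrict a mask to the asymmetric-echo (partial Fourier) region.

    Keeps a full symmetric center band plus one half-plane of rows so that
    the conjugate mirror of every removed point remains in the kept region.
    """
    if not 0.5 < fraction <= 1.0:
        raise ValueError("partial Fourier fraction must be in (0.5, 1]")
    if fraction == 1.0:
        return SamplingMask(mask=mask.mask.copy(), hermitian_half=mask.hermitian_half)
    n = mask.mask.shape[0]
    rows = _kept_rows(n, fraction)
    out = mask.mask & rows[:, None]
    return SamplingMask(mask=out, hermitian_half=True)


def mirror_centered(i: np.ndarray, n: int) -> np.ndarray:
    """Mirror of centered-layout indices under conjugate symmetry."""
    # unshifted index u = (i - n//2) mod n ; mirror (-u) mod n ; back to centered
    u = (np.asarray(i) - n // 2) % n
    return ((-u) % n + n // 2) % n


# ---------------------------------------------------------------------------
# radial masks
# ---------------------------------------------------------------------------


def radial_mask(n_lines: int, aperture_deg: float, grid_size: int) -> SamplingMask:
    """n equally spaced diameters through DC within the given aperture."""
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if not 0 < aperture_deg <= 180:
        raise ValueError("aperture must be in (0, 180] degrees")
    n = grid_size
    mask = np.zeros((n, n), dtype=bool)
    c = n // 2
    t = np.linspace(-1, 1, 4 * n)
    rmax = n // 2 - 1
    for i in range(n_lines):
        th = np.deg2rad(i * aperture_deg / n_lines)
        rows = np.rint(c + t * rmax * np.sin(th)).astype(int)
        cols = np.rint(c + t * rmax * np.cos(th)).astype(int)
        ok = (rows >= 0) & (rows < n) & (cols >= 0) & (cols < n)
        mask[rows[ok], cols[ok]] = True
    return SamplingMask(mask=mask)


# ---------------------------------------------------------------------------
# k-q schedule
# ---------------------------------------------------------------------------


def kq_schedule(n_directions: int, n_blades: int | None = None, neighbor_window: int = 2) -> QScheme:
    """One blade per diffusion direction plus angular neighbor lists.

    Direction d gets blade angle (d * 180 / n_directions) mod 180.  Neighbor
    lists hold the ``neighbor_window`` nearest directions by angular distance
    on the (antipodally symmetric) q-sphere; ties break to the lowest index.
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    if neighbor_window >= n_directions:
        raise ValueError("neighbor_window must be smaller than n_directions")
    g = uniform_sphere_directions(n_directions)
    angles = (np.arange(n_directions) * 180.0 / n_directions) % 180.0
    dots = np.clip(np.abs(g @ g.T), 0, 1)
    ang = np.arccos(dots)
    neighbors = []
    for d in range(n_directions):
        others = [(ang[d, j], j) for j in range(n_directions) if j != d]
        others.sort()  # ties broken by the lower index
        neighbors.append([j for _, j in others[:neighbor_window]])
    return QScheme(
        q_vectors=g, blade_angles=angles, neighbor_window=neighbor_window, neighbors=neighbors
    )


# ---------------------------------------------------------------------------
# nested variable-density mask family (sparsity-rate sweeps)
# ---------------------------------------------------------------------------


def nested_mask_family(grid_size: int, fractions: Sequence[float], seed: int = 0) -> dict:
    """Masks at several sparsity rates, nested by construction.

    Grid points are ranked by a variable-density priority (center-out radius
    plus a seeded random jitter); rate f keeps the top f fraction.  Because
    the ranking is shared, a lower-rate mask is always a subset of a
    higher-rate mask, which makes quality trends across rates well posed.
    """
    n = grid_size
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    rho = np.hypot(yy - n // 2, xx - n // 2) / (n / 2)
    priority = rho + 0.7 * rng.random((n, n))
    order = np.argsort(priority, axis=None)
    out = {}
    for f in fractions:
        k = int(round(f * n * n))
        mask = np.zeros(n * n, dtype=bool)
        mask[order[:k]] = True
        out[f] = SamplingMask(mask=mask.reshape(n, n))
    return out
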