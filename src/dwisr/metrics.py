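"""Image-quality metrics (MSE, PSNR, SSIM) with repeat aggregation."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity


@dataclass
class MetricsReport:
    mse: float
    psnr: float  # dB; math.inf for identical images
    ssim: float
    peak: float
    n_repeats: int = 1
    psnr_mean: float | None = None
    psnr_std: float | None = None

    def to_dict(self) -> dict:
        d = {
            "mse": self.mse,
            "psnr": None if math.isinf(self.psnr) else self.psnr,
            "psnr_infinite": math.isinf(self.psnr),
            "ssim": self.ssim,
            "peak": self.peak,
            "n_repeats": self.n_repeats,
        }
        if self.psnr_mean is not None:
            d["psnr_mean"] = self.psnr_mean
            d["psnr_std"] = self.psnr_std
        return d


def psnr(test: np.ndarray, reference: np.ndarray, peak: float | None = None) -> float:
    """10 log10(peak^2 / MSE); infinite for identical inputs."""
    test, reference = np.asarray(test, float), np.asarray(reference, float)
    if test.shape != reference.shape:
        raise ValueError("shape mismatch")
    if peak is None:
        peak = float(reference.max())
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((test - reference) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(peak * peak / mse)


def compute_metrics(test: np.ndarray, reference: np.ndarray, peak: float | None = None,
                    n_repeats: int = 1) -> MetricsReport:
    """PSNR/SSIM/MSE between a reconstruction and its reference.

    ``peak`` defaults to the reference maximum.  SSIM uses the standard
    7-pixel window with constants derived from ``peak``.
    """
    test, reference = np.asarray(test, float), np.asarray(reference, float)
    if test.size == 0:
        raise ValueError("empty input")
    if test.shape != reference.shape:
        raise ValueError("shape mismatch")
    if peak is None:
        peak = float(reference.max())
    mse = float(np.mean((test - reference) ** 2))
    p = psnr(test, reference, peak)
    ssim = float(
        structural_similarity(reference, test, win_size=7, data_range=peak)
    )
    return MetricsReport(mse=mse, psnr=p, ssim=ssim, peak=peak, n_repeats=n_repeats)


def aggregate(reports: list[MetricsReport]) -> MetricsReport:
    """Mean/std of PSNR over repeated evaluations (std 0 for one repeat)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    ps = [r.psnr for r in reports if not math.isinf(r.psnr)]
    rep = reports[0]
    out = MetricsReport(
        mse=float(np.mean([r.mse for r in reports])),
        psnr=rep.psnr if len(reports) == 1 else float(np.mean(ps)) if ps else math.inf,
        ssim=float(np.mean([r.ssim for r in reports])),
        peak=rep.peak,
        n_repeats=len(reports),
    )
    out.psnr_mean = float(np.mean(ps)) if ps else None
    out.psnr_std = 0.0 if len(reports) == 1 else (float(np.std(ps)) if ps else None)
    return out
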