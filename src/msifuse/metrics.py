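"""Checkpoint and result evaluation: PSNR, SSIM, and the edge loss as a metric.

PSNR and SSIM score the fused image against the interpolated ion target (the
chemical reference); the edge perceptual loss scores it against the microscopy
luminance (the morphological reference).  Both pairings are recorded because
the two metric families diverge during training: the chemical metrics keep
"improving" as the model memorizes the interpolated target, while the edge
loss turns once the image starts to fuzz.

SSIM follows the canonical published defaults: 11x11 Gaussian window with
sigma 1.5, C1 = (0.01 L)^2, C2 = (0.03 L)^2, data range L = 1 on normalized
images, sample statistics from Gaussian-weighted local moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .losses import EdgeKernel, edge_perceptual_loss
from .preprocess import RegisteredPair, to_luminance

__all__ = [
    "MetricReport",
    "psnr",
    "ssim",
    "evaluate_checkpoints",
    "register_feature_extractor",
    "feature_loss",
]

_GAUSS = {"sigma": 1.5, "truncate": 3.5, "mode": "reflect"}  # 11x11 window
_PAD = 5  # (11 - 1) / 2 border crop, as in the reference formulation


@dataclass
class MetricReport:
    """One checkpoint's scores against its references."""

    psnr_db: float
    ssim: float
    edge_loss: float
    reference_name: str = "ion_interp"
    epoch: int | None = None
    missing: bool = False


def psnr(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10 log10(L^2 / MSE) in dB.

    Identical inputs return ``inf`` (the zero-MSE sentinel).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Mean local structural similarity with an 11x11 Gaussian window.

    Requires min(H, W) >= 11 so at least one full window fits.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise ValueError(f"image {a.shape} smaller than the 11x11 SSIM window")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_a = gaussian_filter(a, **_GAUSS)
    mu_b = gaussian_filter(b, **_GAUSS)
    var_a = gaussian_filter(a * a, **_GAUSS) - mu_a * mu_a
    var_b = gaussian_filter(b * b, **_GAUSS) - mu_b * mu_b
    cov = gaussian_filter(a * b, **_GAUSS) - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    s = num / den
    return float(s[_PAD:-_PAD, _PAD:-_PAD].mean())


# ---------------------------------------------------------------------------
# Feature-extractor hook (perceptual-loss-style metric, no weights shipped)
# ---------------------------------------------------------------------------

_FEATURE_EXTRACTORS: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def register_feature_extractor(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a callable mapping an image to a feature grid.

    Any registered extractor can back a perceptual-loss-style metric via
    :func:`feature_loss`; none is shipped by default.
    """
    _FEATURE_EXTRACTORS[name] = fn


def feature_loss(a: np.ndarray, b: np.ndarray, name: str) -> float:
    """MSE between the registered extractor's features of two images."""
    if name not in _FEATURE_EXTRACTORS:
        raise KeyError(f"no feature extractor registered under {name!r}")
    fn = _FEATURE_EXTRACTORS[name]
    fa, fb = np.asarray(fn(a)), np.asarray(fn(b))
    if fa.shape != fb.shape:
        raise ValueError("feature extractor returned mismatching shapes")
    return float(np.mean((fa - fb) ** 2))


# ---------------------------------------------------------------------------
# Checkpoint evaluation
# ---------------------------------------------------------------------------

def evaluate_checkpoints(
    checkpoints: Sequence[str | Path],
    pair: RegisteredPair,
    kernel: EdgeKernel | None = None,
    truth: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score each checkpoint against the pair's references.

    For every loadable checkpoint: PSNR and SSIM of the (clipped) output
    against the interpolated ion target, and the edge perceptual loss against
    the microscopy luminance.  With a ground-truth grid (phantom runs) a
    truth-referenced SSIM/PSNR column pair is added.  Missing or unreadable
    checkpoints are listed as absent and the run continues.  Rows are ordered
    by epoch, independent of the on-disk ordering of ``checkpoints``.
    """
    from .trainer import rebuild_model_from_checkpoint  # local: avoids cycle

    kernel = kernel or EdgeKernel()
    lum = to_luminance(pair.microscopy)
    x = np.ascontiguousarray(pair.microscopy.values.transpose(2, 0, 1))
    rows = []
    for path in checkpoints:
        path = Path(path)
        try:
            model, ckpt = rebuild_model_from_checkpoint(path)
        except Exception:  # noqa: BLE001 - absent/corrupt -> recorded, not fatal
            rows.append({"checkpoint": path.name, "epoch": -1, "missing": True,
                         "psnr_db": np.nan, "ssim": np.nan, "edge_loss": np.nan})
            continue
        y = np.clip(model.forward(x), 0.0, 1.0)
        row = {
            "checkpoint": path.name,
            "epoch": int(ckpt["header"]["epoch"]),
            "missing": False,
            "psnr_db": psnr(y, pair.ion_interp),
            "ssim": ssim(y, pair.ion_interp),
            "edge_loss": edge_perceptual_loss(y, lum, kernel),
        }
        if truth is not None:
            row["psnr_truth_db"] = psnr(y, truth)
            row["ssim_truth"] = ssim(y, truth)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("epoch", kind="stable").reset_index(drop=True)
    return df
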