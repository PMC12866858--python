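"""Deterministic plumbing between raw inputs and the training pair.

Covers min-max normalization (both loss terms must share the [0,1] scale),
bilinear magnification of the ion image with half-pixel-center alignment (the
convention of OpenCV ``INTER_LINEAR``), the registration shape contract, and
Rec. 601 luminance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, RegistrationError
from .io_formats import IonImage, MicroscopyImage

__all__ = [
    "RegisteredPair",
    "minmax_normalize",
    "upscale_bilinear",
    "validate_registration",
    "to_luminance",
]

#: Rec. 601 luma coefficients.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class RegisteredPair:
    """A validated microscopy / interpolated-ion training pair.

    ``microscopy.values`` is H x W x 3 and ``ion_interp`` is H x W, both
    min-max normalized to [0, 1], with H = h x magnification and
    W = w x magnification for the native ion shape (h, w).
    """

    microscopy: MicroscopyImage
    ion_interp: np.ndarray
    magnification: int
    ion_native_shape: tuple[int, int]

    def __post_init__(self) -> None:
        h, w = self.ion_native_shape
        expected = (h * self.magnification, w * self.magnification)
        if self.microscopy.spatial_shape != expected:
            raise RegistrationError(
                f"microscopy shape {self.microscopy.spatial_shape} != "
                f"ion shape x magnification {expected}"
            )
        if self.ion_interp.shape != expected:
            raise RegistrationError(
                f"interpolated ion shape {self.ion_interp.shape} != {expected}"
            )


def minmax_normalize(grid: np.ndarray, return_bounds: bool = False):
    """Rescale a finite grid to [0, 1] by (x - min) / (max - min).

    A constant grid maps to all-zeros.  With ``return_bounds`` the original
    (min, max) is returned as well, for back-scaling outputs to native units.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if not np.all(np.isfinite(grid)):
        raise DataError("cannot normalize a grid with non-finite values")
    lo, hi = float(grid.min()), float(grid.max())
    if hi == lo:
        out = np.zeros_like(grid)
    else:
        out = (grid - lo) / (hi - lo)
    return (out, (lo, hi)) if return_bounds else out


def upscale_bilinear(ion: IonImage | np.ndarray, magnification: int):
    """Bilinearly enlarge a grid by an integer factor.

    Uses half-pixel-center alignment: output pixel ``I`` samples the input at
    ``(I + 0.5) / magnification - 0.5``, clamped at the borders — identical to
    the common image-library linear resize.  Magnification 1 is the identity.

    An :class:`IonImage` input yields an :class:`IonImage` whose pixel pitch
    is divided by the factor; a bare array yields an array.
    """
    if isinstance(ion, IonImage):
        out = upscale_bilinear(ion.values, magnification)
        return IonImage(
            values=out,
            pixel_pitch_um=ion.pixel_pitch_um / int(magnification),
            mz_center=ion.mz_center,
            mz_tolerance_ppm=ion.mz_tolerance_ppm,
        )
    values = np.asarray(ion, dtype=np.float64)
    m = int(magnification)
    if m < 1:
        raise ValueError("magnification must be >= 1")
    if m == 1:
        return values.copy()
    h, w = values.shape

    def _axis_coords(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        src = (np.arange(n * m) + 0.5) / m - 0.5
        src = np.clip(src, 0.0, n - 1.0)
        i0 = np.floor(src).astype(np.intp)
        i0 = np.minimum(i0, n - 2) if n > 1 else np.zeros_like(i0)
        frac = src - i0
        return i0, i0 + 1 if n > 1 else i0, frac

    r0, r1, fr = _axis_coords(h)
    c0, c1, fc = _axis_coords(w)
    fr = fr[:, None]
    fc = fc[None, :]
    top = values[np.ix_(r0, c0)] * (1 - fc) + values[np.ix_(r0, c1)] * fc
    bot = values[np.ix_(r1, c0)] * (1 - fc) + values[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr


def to_luminance(img: MicroscopyImage | np.ndarray) -> np.ndarray:
    """Rec. 601 luminance 0.299 R + 0.587 G + 0.114 B of a 3-channel image."""
    values = img.values if isinstance(img, MicroscopyImage) else np.asarray(img)
    if values.ndim != 3 or values.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    return values @ LUMA_WEIGHTS


def validate_registration(
    microscopy: MicroscopyImage,
    ion: IonImage,
    magnification: int,
) -> RegisteredPair:
    """Enforce the registration contract and build the training pair.

    The microscopy grid must equal the ion grid times ``magnification``
    exactly — no silent crop or pad; external registration tools can export
    off-by-a-crop images, and that must fail loudly here.  The ion image is
    bilinearly upscaled and then min-max normalized (so the [0,1] invariant is
    exact); the microscopy channels are jointly min-max normalized.
    """
    m = int(magnification)
    if m < 1:
        raise ValueError("magnification must be >= 1")
    h, w = ion.shape
    expected = (h * m, w * m)
    if microscopy.spatial_shape != expected:
        raise RegistrationError(
            f"registration contract violated: microscopy is "
            f"{microscopy.spatial_shape}, expected {expected} "
            f"(= ion {ion.shape} x magnification {m})"
        )
    ion_interp = minmax_normalize(upscale_bilinear(ion.values, m))
    micro_norm = MicroscopyImage(
        values=minmax_normalize(microscopy.values),
        provenance=microscopy.provenance,
    )
    return RegisteredPair(
        microscopy=micro_norm,
        ion_interp=ion_interp,
        magnification=m,
        ion_native_shape=(h, w),
    )
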