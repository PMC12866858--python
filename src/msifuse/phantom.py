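"""Seeded synthetic plant-tissue phantoms.

A phantom triplet stands in for a registered microscopy / MSI pair with known
ground truth: a Voronoi tessellation plays the role of the cell mosaic, dark
1-2 px cell walls separate the regions, concentric ring classes mimic
epidermis / mesophyll / vascular zones, and ion abundance follows region
class.  The low-resolution ion image is the block-mean of the high-resolution
truth (the MSI laser spot integrates over its footprint) plus Gaussian noise.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import IonImage, MicroscopyImage

__all__ = ["PhantomSpec", "PhantomTriplet", "generate_phantom", "degrade"]

#: ring class -> mean relative ion abundance; inner rings (vascular tissue)
#: accumulate most of the metabolite in this phantom.
DEFAULT_ABUNDANCE_PROFILE: dict[str, float] = {
    "vascular": 0.9,
    "mesophyll": 0.5,
    "epidermis": 0.2,
}

#: ring class -> base RGB color of the mock bright-field stain.
_CLASS_COLORS: dict[str, tuple[float, float, float]] = {
    "vascular": (0.80, 0.62, 0.35),
    "mesophyll": (0.55, 0.75, 0.40),
    "epidermis": (0.75, 0.80, 0.55),
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tissue phantom."""

    hr_shape: tuple[int, int] = (256, 256)
    magnification: int = 8
    n_cells: int = 40
    wall_darkness: float = 0.6
    abundance_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ABUNDANCE_PROFILE)
    )
    abundance_jitter: float = 0.10
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.hr_shape
        if self.magnification < 1:
            raise ValueError("magnification must be a positive integer")
        if rows % self.magnification or cols % self.magnification:
            raise ValueError(
                f"hr_shape {self.hr_shape} not divisible by magnification "
                f"{self.magnification}"
            )
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if not 0.0 <= self.wall_darkness <= 1.0:
            raise ValueError("wall_darkness must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.abundance_jitter < 0:
            raise ValueError("abundance_jitter must be non-negative")


@dataclass
class PhantomTriplet:
    """Microscopy, high-resolution ion truth, and degraded low-resolution ion."""

    microscopy: MicroscopyImage
    ion_truth_hr: np.ndarray
    ion_lr: IonImage
    boundary_mask: np.ndarray
    region_labels: np.ndarray

    def __post_init__(self) -> None:
        hr = self.ion_truth_hr.shape
        lr = self.ion_lr.shape
        m = hr[0] // lr[0]
        if (lr[0] * m, lr[1] * m) != hr:
            raise ValueError("ion_lr shape x magnification must equal hr_shape")


def degrade(
    ion_truth_hr: np.ndarray,
    magnification: int,
    noise_sd: float,
    seed: int,
    pixel_pitch_um: float = 1.0,
) -> IonImage:
    """Block-mean downsample by ``magnification``, add seeded Gaussian noise,
    clip at zero.

    This is the forward model mapping the high-resolution abundance map to the
    MSI raster: each low-resolution pixel averages its ``m x m`` footprint.
    """
    grid = np.asarray(ion_truth_hr, dtype=np.float64)
    m = int(magnification)
    if m < 1:
        raise ValueError("magnification must be a positive integer")
    rows, cols = grid.shape
    if rows % m or cols % m:
        raise ValueError(f"grid shape {grid.shape} not divisible by magnification {m}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    lr = grid.reshape(rows // m, m, cols // m, m).mean(axis=(1, 3))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        lr = lr + rng.normal(0.0, noise_sd, size=lr.shape)
    lr = np.clip(lr, 0.0, None)
    return IonImage(values=lr, pixel_pitch_um=pixel_pitch_um * m)


def _ring_class(radius_norm: np.ndarray) -> np.ndarray:
    """Assign ring classes by normalized distance of the Voronoi site from the
    image center: inner third -> vascular, outer shell -> epidermis."""
    classes = np.full(radius_norm.shape, "mesophyll", dtype=object)
    classes[radius_norm < 0.45] = "vascular"
    classes[radius_norm >= 0.80] = "epidermis"
    return classes


def generate_phantom(spec: PhantomSpec) -> PhantomTriplet:
    """Generate one seeded phantom triplet.

    The same seed always yields a bit-identical triplet: all randomness flows
    through one ``numpy`` Generator in a fixed call order.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.hr_shape

    sites = rng.uniform(0, 1, size=(spec.n_cells, 2)) * np.array([rows, cols])
    rr, cc = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5])
    _, labels = cKDTree(sites).query(pts)
    labels = labels.reshape(rows, cols)

    # boundary = pixels whose 4-neighborhood crosses a region border (1-2 px)
    boundary = np.zeros((rows, cols), dtype=bool)
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    boundary[1:, :] |= labels[1:, :] != labels[:-1, :]
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary[:, 1:] |= labels[:, 1:] != labels[:, :-1]

    center = np.array([rows / 2, cols / 2])
    site_r = np.linalg.norm(sites - center, axis=1) / np.linalg.norm(center)
    classes = _ring_class(site_r)

    # per-region abundance: class mean with mild seeded cell-to-cell variation
    jitter = 1.0 + spec.abundance_jitter * rng.standard_normal(spec.n_cells)
    abundance = np.array(
        [max(spec.abundance_profile[cls] * j, 0.0) for cls, j in zip(classes, jitter)]
    )
    ion_truth_hr = abundance[labels]
    if spec.wall_darkness > 0:
        ion_truth_hr = np.where(
            boundary, ion_truth_hr * (1.0 - spec.wall_darkness), ion_truth_hr
        )

    color_jitter = 1.0 + 0.08 * rng.standard_normal((spec.n_cells, 3))
    base = np.array([_CLASS_COLORS[c] for c in classes]) * color_jitter
    micro = np.clip(base[labels], 0.0, 1.0)
    micro = np.where(boundary[:, :, None], micro * (1.0 - spec.wall_darkness), micro)

    noise_seed = int(rng.integers(0, 2**31 - 1))
    ion_lr = degrade(ion_truth_hr, spec.magnification, spec.noise_sd, noise_seed)

    return PhantomTriplet(
        microscopy=MicroscopyImage(values=micro, provenance=f"phantom(seed={spec.seed})"),
        ion_truth_hr=ion_truth_hr,
        ion_lr=ion_lr,
        boundary_mask=boundary,
        region_labels=labels,
    )
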