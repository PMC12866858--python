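"""Reading and writing every external representation the pipeline touches.

MSI rasters arrive either as imzML/ibd pairs (the instrument export) or as a
per-ion CSV intensity grid (the shinyCardinal export path); microscopy arrives
as a registered RGB TIFF/PNG; fused outputs leave as 16-bit grayscale TIFF with
a lossless float sidecar.

The single internal convention is: 0-based (row, col) coordinates, origin
top-left, row-major.  imzML 1-based pixel indices are shifted on read.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

from .errors import DataError, FormatError, IntegrityError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "MSIDataset",
    "IonImage",
    "MicroscopyImage",
    "read_imzml",
    "write_imzml",
    "extract_ion_image",
    "read_ion_csv",
    "write_ion_csv",
    "read_microscopy",
    "write_fused",
    "read_fused_sidecar",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MSIDataset:
    """A raster of mass spectra.

    ``spectra`` is a list of ``((row, col), mz_array, intensity_array)`` with
    0-based coordinates; ``grid_shape`` is ``(n_rows, n_cols)``;
    ``pixel_pitch_um`` is the physical raster pitch in micrometres.
    """

    spectra: list[tuple[tuple[int, int], np.ndarray, np.ndarray]]
    grid_shape: tuple[int, int]
    pixel_pitch_um: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        n_rows, n_cols = self.grid_shape
        for (r, c), mz, inten in self.spectra:
            if not (0 <= r < n_rows and 0 <= c < n_cols):
                raise IntegrityError(
                    f"spectrum coordinate ({r}, {c}) outside grid {self.grid_shape}"
                )
            if len(mz) != len(inten):
                raise IntegrityError("m/z and intensity arrays differ in length")
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise IntegrityError(f"m/z array not strictly increasing at ({r}, {c})")


@dataclass
class IonImage:
    """Low-resolution 2D intensity grid of one m/z window."""

    values: np.ndarray
    pixel_pitch_um: float = 1.0
    mz_center: float | None = None
    mz_tolerance_ppm: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ion image must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise DataError("ion image contains non-finite values")
        if np.any(self.values < 0):
            raise DataError("ion image contains negative intensities")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class MicroscopyImage:
    """Registered high-resolution 3-channel image, values in [0, 1]."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("microscopy image must be H x W x 3")
        if not np.all(np.isfinite(self.values)):
            raise DataError("microscopy image contains non-finite values")
        if self.values.min() < 0 or self.values.max() > 1:
            raise DataError("microscopy values must lie in [0, 1]")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

def read_imzml(path: str | Path, pixel_pitch_um: float = 1.0) -> MSIDataset:
    """Read a continuous- or processed-mode imzML/ibd pair into an MSIDataset.

    Coordinates are converted from the standard's 1-based (x, y) indexing to
    0-based (row, col); the grid shape is the maximum coordinate extent + 1.

    Raises
    ------
    FormatError
        if the ``.ibd`` companion is missing or the XML is unreadable.
    IntegrityError
        if a spectrum coordinate exceeds the declared pixel counts.
    """
    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FormatError(f"missing .ibd companion for {path}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise FormatError(f"could not parse imzML file {path}: {exc}") from exc

    max_x = parser.imzmldict.get("max count of pixels x")
    max_y = parser.imzmldict.get("max count of pixels y")
    spectra = []
    max_r = max_c = 0
    for i, (x, y, _z) in enumerate(parser.coordinates):
        r, c = int(y) - 1, int(x) - 1
        if max_x is not None and x > max_x or max_y is not None and y > max_y:
            raise IntegrityError(
                f"spectrum {i} at (x={x}, y={y}) exceeds declared "
                f"max counts ({max_x}, {max_y})"
            )
        mz, inten = parser.getspectrum(i)
        spectra.append(
            ((r, c), np.asarray(mz, dtype=np.float64), np.asarray(inten, dtype=np.float64))
        )
        max_r, max_c = max(max_r, r), max(max_c, c)
    return MSIDataset(
        spectra=spectra,
        grid_shape=(max_r + 1, max_c + 1),
        pixel_pitch_um=pixel_pitch_um,
    )


def write_imzml(path: str | Path, ds: MSIDataset) -> None:
    """Write an MSIDataset as a processed-mode imzML/ibd pair.

    Fixture-grade writer: intended for tests and round-trip checks, not for
    production export.  0-based (row, col) become 1-based (x=col+1, y=row+1).
    """
    with ImzMLWriter(str(path), mz_dtype=np.float64,
                     intensity_dtype=np.float64) as writer:
        for (r, c), mz, inten in ds.spectra:
            writer.addSpectrum(mz, inten, (c + 1, r + 1, 1))


def extract_ion_image(ds: MSIDataset, mz: float, tol_ppm: float = 5.0) -> IonImage:
    """Sum, per pixel, the intensities of all peaks within ``tol_ppm`` of ``mz``.

    Pixels with no spectrum (or no matching peak) are 0.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    grid = np.zeros(ds.grid_shape, dtype=np.float64)
    half_width = mz * tol_ppm * 1e-6
    for (r, c), mzs, intens in ds.spectra:
        mask = np.abs(mzs - mz) <= half_width
        if mask.any():
            grid[r, c] += float(intens[mask].sum())
    return IonImage(
        values=grid,
        pixel_pitch_um=ds.pixel_pitch_um,
        mz_center=mz,
        mz_tolerance_ppm=tol_ppm,
    )


# ---------------------------------------------------------------------------
# CSV ion-image grids
# ---------------------------------------------------------------------------

def read_ion_csv(
    path: str | Path,
    has_header: bool = False,
    pixel_pitch_um: float = 1.0,
) -> IonImage:
    """Read a rectangular CSV of intensities (top image row first)."""
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for i, raw in enumerate(reader):
            if has_header and i == 0:
                continue
            if not raw:
                continue
            parsed = []
            for j, cell in enumerate(raw):
                try:
                    parsed.append(float(cell))
                except ValueError as exc:
                    raise ParseError(
                        f"non-numeric cell {cell!r} at row {i}, col {j} of {path}",
                        row=i,
                        col=j,
                    ) from exc
            rows.append(parsed)
    if not rows:
        raise FormatError(f"empty CSV file {path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"ragged CSV rows in {path}: widths {sorted(widths)}")
    return IonImage(values=np.array(rows, dtype=np.float64), pixel_pitch_um=pixel_pitch_um)


def write_ion_csv(path: str | Path, ion: IonImage | np.ndarray) -> None:
    """Write an ion-image grid as plain CSV, full float precision."""
    values = ion.values if isinstance(ion, IonImage) else np.asarray(ion)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in values:
            writer.writerow([repr(float(v)) for v in row])


# ---------------------------------------------------------------------------
# Microscopy and fused-image files
# ---------------------------------------------------------------------------

def _dtype_max(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 1.0


def read_microscopy(path: str | Path, provenance: str | None = None) -> MicroscopyImage:
    """Load an 8/16-bit RGB or grayscale image, rescaled to [0, 1].

    Grayscale is replicated to 3 channels; an alpha channel is dropped with a
    logged warning.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    scale = _dtype_max(arr)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("dropping alpha channel of %s", path)
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"unsupported channel layout {arr.shape} in {path}")
    arr = np.clip(arr / scale, 0.0, 1.0)
    return MicroscopyImage(values=arr, provenance=provenance or str(path))


def write_fused(path: str | Path, values: np.ndarray, clip: bool = True) -> Path:
    """Write a fused image as 16-bit grayscale TIFF plus a float sidecar.

    The TIFF holds the [0,1]-clipped image quantized to uint16; the ``.npy``
    sidecar next to it holds the float64 grid losslessly.  Returns the sidecar
    path.
    """
    path = Path(path)
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("fused image must be 2-D")
    out = np.clip(values, 0.0, 1.0) if clip else values
    tifffile.imwrite(path, np.round(out * 65535.0).astype(np.uint16))
    sidecar = path.with_suffix(path.suffix + ".npy")
    np.save(sidecar, values)
    return sidecar


def read_fused_sidecar(path: str | Path) -> np.ndarray:
    """Load the lossless float sidecar written by :func:`write_fused`."""
    return np.load(Path(path))
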