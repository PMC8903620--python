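"""Image containers and grayscale radiograph I/O.

Coordinate convention used throughout the package: 0-based, ``x`` is the
column index, ``y`` the row index, origin at the top-left corner, pixel
centers at integer coordinates.  Physical lengths are always millimetres,
obtained via the isotropic ``pixel_spacing`` (mm per pixel).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, SizeError

__all__ = [
    "TextureField",
    "Radiograph",
    "read_radiograph",
    "write_radiograph",
    "qc_flag_exposure",
]


@dataclass
class TextureField:
    """A square (or rectangular) patch of intensity values.

    The raw signal the fractal analysis reads: either a synthetic
    fractional-Brownian surface with a known Hurst exponent, or a block
    extracted from a radiograph ROI.

    Parameters
    ----------
    pixels
        2-D array of intensities (arbitrary units, finite).
    pixel_spacing
        Isotropic physical spacing in mm per pixel, > 0.
    hurst_true
        Ground-truth Hurst exponent for synthetic fields, else ``None``.
    seed
        Seed used to synthesise the field, else ``None``.
    """

    pixels: np.ndarray
    pixel_spacing: float
    hurst_true: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ParameterError("pixels must be a 2-D grid")
        if min(self.pixels.shape) < 16:
            raise SizeError(
                f"grid dimensions must be at least 16x16, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("pixels must be finite")
        if not self.pixel_spacing > 0:
            raise ParameterError("pixel_spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Radiograph:
    """A grayscale knee radiograph with physical spacing and QC metadata."""

    pixels: np.ndarray
    pixel_spacing: float
    modality: str = "CR"  # CR = computed radiography, RG = digitized film
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ParameterError("radiograph must be a 2-D grayscale image")
        if not self.pixel_spacing > 0:
            raise ParameterError("pixel_spacing must be > 0")
        if self.modality not in ("CR", "RG"):
            raise ParameterError(f"modality must be CR or RG, got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def intensity_max(self) -> float:
        """Saturation level: dtype maximum for integer images, observed
        maximum for float images (overridable through metadata)."""
        if "intensity_max" in self.metadata:
            return float(self.metadata["intensity_max"])
        if np.issubdtype(self.pixels.dtype, np.integer):
            return float(np.iinfo(self.pixels.dtype).max)
        return float(self.pixels.max())


def qc_flag_exposure(
    radiograph: Radiograph, saturation_fraction_threshold: float = 0.05
) -> bool:
    """Flag a radiograph whose saturated-pixel fraction exceeds a threshold.

    A pixel counts as saturated when it reaches >= 99% of the saturation
    level.  Operationalizes the exposure-problem exclusion applied to the
    quality-controlled cohort subsets.
    """
    if radiograph.pixels.size == 0:
        raise ParameterError("empty image")
    level = radiograph.intensity_max
    frac = float(np.mean(np.asarray(radiograph.pixels, dtype=float) >= 0.99 * level))
    return frac > saturation_fraction_threshold


def write_radiograph(path: str | Path, radiograph: Radiograph) -> None:
    """Write a radiograph as 16-bit PNG/TIFF plus a YAML sidecar with the
    pixel spacing and modality."""
    import imageio.v3 as iio
    import yaml

    path = Path(path)
    arr = np.asarray(radiograph.pixels)
    if not np.issubdtype(arr.dtype, np.integer):
        arr = np.clip(arr, 0, 65535).astype(np.uint16)
    iio.imwrite(path, arr.astype(np.uint16))
    sidecar = {
        "pixel_spacing_mm": float(radiograph.pixel_spacing),
        "modality": radiograph.modality,
        **{k: v for k, v in radiograph.metadata.items() if _yaml_safe(v)},
    }
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_radiograph(path: str | Path, pixel_spacing: float | None = None) -> Radiograph:
    """Read a grayscale radiograph from PNG/TIFF (+YAML sidecar) or DICOM.

    Pixel spacing is taken from, in order: the explicit argument, the DICOM
    PixelSpacing tag, or the ``<file>.yaml`` sidecar.
    """
    path = Path(path)
    metadata: dict = {}
    modality = "CR"
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if pixel_spacing is None and "PixelSpacing" in ds:
            pixel_spacing = float(ds.PixelSpacing[0])
        modality = str(getattr(ds, "Modality", "CR"))
        if modality not in ("CR", "RG"):
            modality = "CR"
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse accidental channel axis
            arr = arr[..., 0]
        sidecar = Path(str(path) + ".yaml")
        if sidecar.exists():
            import yaml

            meta = yaml.safe_load(sidecar.read_text()) or {}
            if pixel_spacing is None:
                pixel_spacing = meta.get("pixel_spacing_mm")
            modality = meta.get("modality", modality)
            metadata.update(
                {k: v for k, v in meta.items() if k not in ("pixel_spacing_mm", "modality")}
            )
    if pixel_spacing is None:
        raise ParameterError(f"no pixel spacing available for {path}")
    return Radiograph(arr, float(pixel_spacing), modality=modality, metadata=metadata)


def _yaml_safe(v) -> bool:
    return isinstance(v, (str, int, float, bool, type(None)))
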