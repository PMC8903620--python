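"""Directional variograms and two-band fractal texture descriptors.

For a texture block I the directional empirical variogram at pixel lag d is
the mean squared increment

    V(d) = mean over p of (I(p + d e_dir) - I(p))^2,

the quadratic-variation statistic.  For a fractional Brownian surface with
Hurst exponent H, V(d) ∝ d^(2H), so an ordinary least-squares fit of
log2 V on log2 d estimates H = slope / 2, and the fractal dimension is
FD = fd_offset - H (surface convention fd_offset = 3).

Descriptors are fitted on two disjoint scale bands of the lag axis:

* micro band (μFD): lags strictly under 0.4 mm — the fine trabecular scale;
* milli band (mFD): lags strictly above 0.6 mm, capped at min(2.5 mm,
  side/4) so every retained lag keeps a large pair count.

Four values per ROI (two directions x two bands) over the 16 ROIs give the
64-descriptor vector per knee.  Fits that cannot be performed (too few
in-band lags, flat texture) are carried as explicitly invalid slots, never
silently filled.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateTextureError,
    GeometryError,
    InsufficientScaleError,
    OutOfBoundsError,
    ParameterError,
)
from .geometry import ROIPatchwork, extract_roi_pixels
from .image import Radiograph, TextureField

__all__ = [
    "Variogram",
    "FDFit",
    "FractalConfig",
    "TBTDescriptors",
    "DESCRIPTOR_NAMES",
    "directional_variogram",
    "fit_fd",
    "compute_tbt_descriptors",
]

DIRECTIONS = ("h", "v")
BANDS = ("micro", "milli")

#: canonical descriptor slot order: ROI 1..16 (row-major, medial→lateral),
#: direction h|v, band micro|milli
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(
    f"roi{i:02d}_{d}_{b}_fd" for i in range(1, 17) for d in DIRECTIONS for b in BANDS
)


@dataclass
class Variogram:
    """Directional empirical variogram of a texture block."""

    direction: str
    lags_px: np.ndarray
    lags_mm: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        self.lags_px = np.asarray(self.lags_px)
        self.lags_mm = np.asarray(self.lags_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if np.any(np.diff(self.lags_mm) <= 0):
            raise ParameterError("lags must be strictly increasing")
        if np.any(self.values < 0):
            raise ParameterError("variogram values must be >= 0")
        if np.any(self.n_pairs < 1):
            raise ParameterError("each retained lag needs at least one pair")


@dataclass
class FDFit:
    """Result of fitting H (and FD) on one scale band of a variogram."""

    hurst: float
    fd: float
    scale_band: str
    band_limits_mm: tuple[float, float]
    n_lags_used: int
    r2: float
    clipped: bool = False
    fd_offset: float = 3.0


@dataclass
class FractalConfig:
    """Tunable knobs of the fractal stage.

    Band limits are open intervals in mm of lag; the milli upper limit is
    additionally capped at ``milli_cap_fraction`` of the ROI side.
    ``increment_order`` 1 gives plain quadratic variations; 2 the
    second-order generalized variations.
    """

    micro_band: tuple[float, float] = (0.0, 0.4)
    milli_band: tuple[float, float] = (0.6, 2.5)
    milli_cap_fraction: float = 0.25
    increment_order: int = 1
    fd_offset: float = 3.0

    def __post_init__(self) -> None:
        if self.increment_order not in (1, 2):
            raise ParameterError("increment_order must be 1 or 2")
        for lo, hi in (self.micro_band, self.milli_band):
            if not (0 <= lo < hi):
                raise ParameterError("band limits must satisfy 0 <= low < high")
        if self.micro_band[1] > self.milli_band[0]:
            raise ParameterError("micro and milli bands must be disjoint")


def directional_variogram(
    block: TextureField | np.ndarray,
    direction: str,
    max_lag_px: int,
    pixel_spacing: float | None = None,
    increment_order: int = 1,
) -> Variogram:
    """Empirical variogram of ``block`` along one image axis.

    ``direction`` is ``"horizontal"``/``"h"`` (along x, i.e. across
    columns) or ``"vertical"``/``"v"``.  All in-block pairs at each integer
    lag 1..max_lag_px contribute.
    """
    if isinstance(block, TextureField):
        pixels = block.pixels
        if pixel_spacing is None:
            pixel_spacing = block.pixel_spacing
    else:
        pixels = np.asarray(block, dtype=float)
        if pixel_spacing is None:
            raise ParameterError("pixel_spacing required for raw arrays")
    d = direction.lower()
    if d in ("h", "horizontal"):
        axis, dname = 1, "h"
    elif d in ("v", "vertical"):
        axis, dname = 0, "v"
    else:
        raise ParameterError(f"direction must be horizontal|vertical, got {direction!r}")
    extent = pixels.shape[axis]
    if extent < 2:
        raise GeometryError("block must span at least 2 px along the variogram direction")
    if max_lag_px < 1:
        raise ParameterError("max_lag_px must be >= 1")
    if max_lag_px * increment_order >= extent:
        raise GeometryError(
            f"block extent {extent} px too small for max lag {max_lag_px} "
            f"(increment order {increment_order})"
        )
    arr = pixels if axis == 1 else pixels.T
    lags, values, n_pairs = [], [], []
    for lag in range(1, max_lag_px + 1):
        if increment_order == 1:
            diff = arr[:, lag:] - arr[:, :-lag]
        else:
            if 2 * lag >= arr.shape[1]:
                break
            diff = arr[:, 2 * lag :] - 2.0 * arr[:, lag:-lag] + arr[:, : -2 * lag]
        lags.append(lag)
        values.append(float(np.mean(diff * diff)))
        n_pairs.append(diff.size)
    lags = np.array(lags)
    return Variogram(
        direction=dname,
        lags_px=lags,
        lags_mm=lags * pixel_spacing,
        values=np.array(values),
        n_pairs=np.array(n_pairs),
        pixel_spacing=float(pixel_spacing),
    )


def fit_fd(
    variogram: Variogram,
    band_limits_mm: tuple[float, float],
    fd_offset: float = 3.0,
    scale_band: str = "",
) -> FDFit:
    """OLS fit of log2 V(d) on log2 d restricted to an open lag band.

    hurst = slope / 2, clipped to [0, 1.5] (flagged when clipping occurs);
    fd = fd_offset - hurst.
    """
    lo, hi = band_limits_mm
    sel = (variogram.lags_mm > lo) & (variogram.lags_mm < hi)
    n_used = int(sel.sum())
    if n_used < 2:
        raise InsufficientScaleError(
            f"only {n_used} lag(s) inside band ({lo}, {hi}) mm at spacing "
            f"{variogram.pixel_spacing} mm; need >= 2"
        )
    v = variogram.values[sel]
    if np.any(v == 0):
        raise DegenerateTextureError("zero variogram value inside the fitting band")
    x = np.log2(variogram.lags_mm[sel])
    y = np.log2(v)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    hurst = slope / 2.0
    clipped = not (0.0 <= hurst <= 1.5)
    hurst = float(np.clip(hurst, 0.0, 1.5))
    return FDFit(
        hurst=hurst,
        fd=float(fd_offset - hurst),
        scale_band=scale_band,
        band_limits_mm=(float(lo), float(hi)),
        n_lags_used=n_used,
        r2=r2,
        clipped=clipped,
        fd_offset=fd_offset,
    )


@dataclass
class TBTDescriptors:
    """The 64 trabecular-bone-texture descriptors of one knee.

    ``values[name]`` is the fitted FD (NaN when invalid); ``valid[name]``
    the per-slot validity flag; ``reasons`` records why a slot is invalid.
    """

    values: dict[str, float] = field(default_factory=dict)
    valid: dict[str, bool] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in DESCRIPTOR_NAMES:
            self.values.setdefault(name, float("nan"))
            self.valid.setdefault(name, False)
        extra = set(self.values) - set(DESCRIPTOR_NAMES)
        if extra:
            raise ParameterError(f"unknown descriptor slots: {sorted(extra)}")

    def __len__(self) -> int:
        return len(DESCRIPTOR_NAMES)

    def to_series(self):
        import pandas as pd

        return pd.Series({n: self.values[n] for n in DESCRIPTOR_NAMES})

    @property
    def n_valid(self) -> int:
        return sum(self.valid.values())


def compute_tbt_descriptors(
    radiograph: Radiograph,
    patchwork: ROIPatchwork,
    config: FractalConfig | None = None,
) -> TBTDescriptors:
    """Compute the full 64-descriptor vector for one knee.

    Per-ROI geometry or degenerate-texture failures invalidate only the
    affected slots; the remaining ROIs are still processed.
    """
    config = config or FractalConfig()
    desc = TBTDescriptors()
    spacing = radiograph.pixel_spacing
    for roi in patchwork:
        slot = lambda d, b: f"roi{roi.index:02d}_{d}_{b}_fd"  # noqa: E731
        try:
            block = extract_roi_pixels(radiograph, roi)
        except (OutOfBoundsError, GeometryError) as exc:
            for d in DIRECTIONS:
                for b in BANDS:
                    desc.reasons[slot(d, b)] = f"geometry: {exc}"
            continue
        milli_hi = min(config.milli_band[1], roi.side_mm * config.milli_cap_fraction)
        max_lag = max(int(np.floor(milli_hi / spacing)), 1)
        max_lag = min(max_lag, roi.side_px // (config.increment_order + 1) - 1)
        for d, dirname in (("h", "horizontal"), ("v", "vertical")):
            try:
                vg = directional_variogram(
                    block, dirname, max_lag, increment_order=config.increment_order
                )
            except (GeometryError, ParameterError) as exc:
                for b in BANDS:
                    desc.reasons[slot(d, b)] = f"variogram: {exc}"
                continue
            for b, limits in (
                ("micro", config.micro_band),
                ("milli", (config.milli_band[0], milli_hi)),
            ):
                name = slot(d, b)
                try:
                    fit = fit_fd(vg, limits, fd_offset=config.fd_offset, scale_band=b)
                except (InsufficientScaleError, DegenerateTextureError) as exc:
                    desc.reasons[name] = str(exc)
                    continue
                desc.values[name] = fit.fd
                desc.valid[name] = True
    return desc
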