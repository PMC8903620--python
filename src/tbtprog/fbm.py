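"""Synthesis of 2-D fractional Brownian (fBm) texture fields.

An isotropic fractional Brownian surface with Hurst exponent H in (0, 1)
has a power spectral density proportional to f^-(2H+2) and a variogram
(mean squared increment) growing as d^(2H); its log2-log2 variogram slope
is therefore 2H, the quantity the fractal estimators in
:mod:`tbtprog.fractal` recover.

Synthesis is spectral: Gaussian white noise is shaped in the Fourier
domain and transformed back.  Two discretization effects are handled
explicitly:

* a *sampled* fBm surface is not band-limited — its grid spectrum is the
  continuous spectrum folded over all aliases.  The shaping amplitude
  therefore sums |f + k|^-(2H+2) over integer alias offsets k (truncated
  at ``alias_range``); without this fold the smallest-lag variogram slope
  is badly biased toward smoothness for low H;
* the FFT field is periodic, so the surface is synthesised on a grid
  ``oversample`` times larger than requested and cropped, suppressing
  wrap-around correlation at the lags used for estimation.

An independent midpoint-displacement generator is used as cross-check in
the test-suite, never here.
"""
from __future__ import annotations

import numpy as np

from .errors import ParameterError, SizeError
from .image import TextureField

__all__ = ["generate_fbm_field"]


def generate_fbm_field(
    size: int,
    hurst: float,
    pixel_spacing: float = 0.1,
    seed: int | None = None,
    oversample: int = 2,
    alias_range: int = 6,
) -> TextureField:
    """Generate a square fractional-Brownian texture field.

    Parameters
    ----------
    size
        Side length in pixels (>= 16).
    hurst
        Hurst exponent, strictly inside (0, 1).
    pixel_spacing
        Physical spacing in mm per pixel.
    seed
        Seed for bit-reproducible output.
    oversample
        Synthesis-grid factor (>= 1); the field is cropped back to ``size``.
    alias_range
        Spectrum-folding truncation: aliases with |k| <= alias_range per
        axis enter the shaping amplitude.

    Returns
    -------
    TextureField
        Zero-mean, unit-variance field carrying ``hurst_true`` and ``seed``.
    """
    if not (0.0 < hurst < 1.0):
        raise ParameterError(f"hurst must be in (0, 1), got {hurst}")
    if size < 16:
        raise SizeError(f"size must be >= 16, got {size}")
    if oversample < 1:
        raise ParameterError("oversample must be >= 1")

    n = int(size) * int(oversample)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, n))
    spectrum = np.fft.fft2(noise)

    fx = np.fft.fftfreq(n)[None, :]
    fy = np.fft.fftfreq(n)[:, None]
    power = np.zeros((n, n))
    K = int(alias_range)
    for kx in range(-K, K + 1):
        for ky in range(-K, K + 1):
            r2 = (fx + kx) ** 2 + (fy + ky) ** 2
            with np.errstate(divide="ignore"):
                term = r2 ** -(hurst + 1.0)
            power += np.where(r2 > 0, term, 0.0)

    field = np.real(np.fft.ifft2(spectrum * np.sqrt(power)))[:size, :size]
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    return TextureField(field, pixel_spacing, hurst_true=float(hurst), seed=seed)
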