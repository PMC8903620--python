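"""Synthetic landmark sets and knee radiographs.

The landmark generator produces a stylized tibia/femur contour scaled by
the knee width.  Only the point count (148) and the tibial extremity index
convention are contractual; the remaining points are a plausible smooth
contour, since real landmark geometry varies per subject and scanner.

The image synthesizer plants 16 known texture fields into the patchwork
cells of a blank radiograph so that geometry extraction and QC flagging
can be validated round-trip against ground truth.  With the default
jitter-free geometry the ROI sampling grids fall exactly on pixel centers,
making the round-trip exact up to intensity quantization.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import GeometryError, ParameterError
from .geometry import (
    PatchworkConfig,
    build_patchwork,
    fit_subchondral_baseline,
    roi_sampling_grid,
)
from .image import Radiograph, TextureField
from .landmarks import N_LANDMARKS, TIBIAL_EXTREMITY_INDICES, LandmarkSet

__all__ = ["generate_landmarks", "synthesize_knee_image"]


def generate_landmarks(
    knee_width_mm: float = 75.0,
    laterality: str = "left",
    jitter_mm: float = 0.0,
    seed: int | None = None,
    pixel_spacing: float = 0.1,
    margin_px: float = 16.0,
) -> LandmarkSet:
    """Generate a 148-point contour with the extremity landmarks separated
    by ``knee_width_mm`` (± jitter).

    The two tibial extremities sit at half-integer pixel coordinates so
    that, for even knee widths in pixels, the derived patchwork sampling
    grids land exactly on pixel centers.
    """
    if not knee_width_mm > 0:
        raise ParameterError(f"knee_width_mm must be > 0, got {knee_width_mm}")
    if laterality not in ("left", "right"):
        raise ParameterError(f"laterality must be left|right, got {laterality!r}")
    width_px = knee_width_mm / pixel_spacing
    y_base = np.floor(0.3 * width_px) + 0.5
    xa = np.floor(margin_px) + 0.5
    xb = xa + width_px
    # lateral compartment on the image left for left knees (PA convention)
    if laterality == "left":
        x_lat, x_med = xa, xb
    else:
        x_med, x_lat = xa, xb
    i_lat, i_med = TIBIAL_EXTREMITY_INDICES[laterality]

    pts = _template_contour(width_px, y_base, (xa + xb) / 2.0)
    lo, hi = sorted((i_lat, i_med))
    pts[i_lat] = (x_lat, y_base)
    pts[i_med] = (x_med, y_base)
    # tibial plateau edge between the extremities: straight run with a
    # shallow central dip (tibial spines region is ignored on purpose)
    span = hi - lo
    for k in range(lo + 1, hi):
        t = (k - lo) / span
        x = pts[lo][0] + t * (pts[hi][0] - pts[lo][0])
        y = y_base + 0.03 * width_px * np.sin(np.pi * t)
        pts[k] = (x, y)

    if jitter_mm > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, jitter_mm / pixel_spacing, size=pts.shape)
    pts[:, 0] = np.maximum(pts[:, 0], 0.5)
    pts[:, 1] = np.maximum(pts[:, 1], 0.5)
    return LandmarkSet(pts, laterality, pixel_spacing)


def _template_contour(width_px: float, y_base: float, cx: float) -> np.ndarray:
    """Closed stylized knee outline: an ellipse around the joint, femoral
    half above the subchondral baseline, tibial half below."""
    t = np.linspace(0.0, 2.0 * np.pi, N_LANDMARKS, endpoint=False)
    rx, ry = 0.55 * width_px, 0.28 * width_px
    x = cx + rx * np.cos(t)
    y = (y_base + 0.05 * width_px) + ry * np.sin(t)
    return np.column_stack([x, y])


def synthesize_knee_image(
    landmarks: LandmarkSet,
    roi_fields: Sequence[TextureField],
    background: float = 25000.0,
    artifact: str = "none",
    gain: float = 5000.0,
    saturation_fraction: float = 0.08,
    patchwork_config: PatchworkConfig | None = None,
    modality: str = "CR",
    margin_px: int = 16,
) -> Radiograph:
    """Render a 16-bit radiograph whose patchwork cells contain the given
    texture fields.

    ``artifact`` is one of ``none`` | ``overexposure`` (saturates at least
    ``saturation_fraction`` of the pixels at the dtype maximum) |
    ``material`` (a uniform max-intensity blob inside the subchondral
    zone, overlapping the patchwork).
    """
    if artifact not in ("none", "overexposure", "material"):
        raise ParameterError(f"unknown artifact {artifact!r}")
    if len(roi_fields) != 16:
        raise GeometryError(f"expected 16 texture fields, got {len(roi_fields)}")
    baseline = fit_subchondral_baseline(landmarks)
    patchwork = build_patchwork(baseline, landmarks.pixel_spacing, patchwork_config)
    n = patchwork.side_px
    for i, f in enumerate(roi_fields):
        if f.shape != (n, n):
            raise GeometryError(
                f"texture field {i} has shape {f.shape}, patchwork ROI side is {n} px"
            )

    grids = [roi_sampling_grid(roi) for roi in patchwork]
    xmax = max(landmarks.points[:, 0].max(), max(g[0].max() for g in grids))
    ymax = max(landmarks.points[:, 1].max(), max(g[1].max() for g in grids))
    shape = (int(np.ceil(ymax)) + margin_px, int(np.ceil(xmax)) + margin_px)
    canvas = np.full(shape, float(background))

    for roi, field, (xs, ys) in zip(patchwork, roi_fields, grids):
        xi = np.rint(xs).astype(int)
        yi = np.rint(ys).astype(int)
        canvas[yi, xi] = background + gain * field.pixels

    metadata: dict = {"artifact": artifact}
    if artifact == "overexposure":
        n_sat = int(np.ceil(saturation_fraction * canvas.size))
        rows = int(np.ceil(n_sat / shape[1]))
        canvas[:rows, :] = 65535.0
        metadata["saturated_fraction"] = rows * shape[1] / canvas.size
    elif artifact == "material":
        blob_roi = patchwork.rois[2]  # subchondral row, lateral-third column
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        r = 0.6 * n
        mask = (xx - blob_roi.center[0]) ** 2 + (yy - blob_roi.center[1]) ** 2 <= r * r
        canvas[mask] = 65535.0
        metadata["material_center"] = (float(blob_roi.center[0]), float(blob_roi.center[1]))
        metadata["material_radius_px"] = float(r)

    pixels = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)
    return Radiograph(pixels, landmarks.pixel_spacing, modality=modality, metadata=metadata)
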