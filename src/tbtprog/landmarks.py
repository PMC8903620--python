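"""148-point bone-contour landmark sets.

The contour convention follows BoneFinder-style point lists: 148 ordered
(x, y) pixel coordinates outlining the tibial and femoral edges.  Only the
point count and the tibial extremity indices are contractual:

* left knee:  point 48 = lateral tibial extremity, point 64 = medial;
* right knee: point 122 = lateral tibial extremity, point 138 = medial.

The right-knee lateral/medial assignment is a convention adopted by this
package (the two indices are fixed; which is lateral is configurable
nowhere because every downstream quantity depends only on the
medial→lateral ordering, which is recovered from the laterality).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError

__all__ = [
    "N_LANDMARKS",
    "TIBIAL_EXTREMITY_INDICES",
    "LandmarkSet",
    "read_landmarks",
    "write_landmarks",
]

N_LANDMARKS = 148

#: laterality -> (lateral extremity index, medial extremity index)
TIBIAL_EXTREMITY_INDICES: dict[str, tuple[int, int]] = {
    "left": (48, 64),
    "right": (122, 138),
}


@dataclass
class LandmarkSet:
    """An ordered set of 148 contour points in pixel coordinates."""

    points: np.ndarray
    laterality: str
    pixel_spacing: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ParameterError(
                f"landmark set must have shape ({N_LANDMARKS}, 2), got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("landmark coordinates must be finite")
        if self.laterality not in ("left", "right"):
            raise ParameterError(f"laterality must be left|right, got {self.laterality!r}")
        if not self.pixel_spacing > 0:
            raise ParameterError("pixel_spacing must be > 0")

    @property
    def extremity_indices(self) -> tuple[int, int]:
        """(lateral, medial) tibial extremity indices for this laterality."""
        return TIBIAL_EXTREMITY_INDICES[self.laterality]

    def translated(self, dx: float, dy: float) -> "LandmarkSet":
        return LandmarkSet(self.points + np.array([dx, dy]), self.laterality, self.pixel_spacing)


def write_landmarks(path: str | Path, landmarks: LandmarkSet) -> None:
    """Write a landmark set as a whitespace-delimited x y point file with a
    one-line header naming the laterality."""
    lines = [f"# laterality {landmarks.laterality} pixel_spacing {landmarks.pixel_spacing}"]
    lines += [f"{x:.6f} {y:.6f}" for x, y in landmarks.points]
    Path(path).write_text("\n".join(lines) + "\n")


def read_landmarks(path: str | Path, pixel_spacing: float | None = None) -> LandmarkSet:
    """Read a landmark point file written by :func:`write_landmarks`."""
    raw = Path(path).read_text().strip().splitlines()
    if not raw:
        raise ParameterError(f"empty landmark file {path}")
    header = raw[0]
    laterality = "left"
    if header.lstrip().startswith("#"):
        toks = header.replace("#", "").split()
        for key, val in zip(toks, toks[1:]):
            if key == "laterality":
                laterality = val
            elif key == "pixel_spacing" and pixel_spacing is None:
                pixel_spacing = float(val)
        body = raw[1:]
    else:
        body = raw
    pts = np.array([[float(t) for t in line.split()[:2]] for line in body if line.strip()])
    if pixel_spacing is None:
        raise ParameterError(f"no pixel spacing available for {path}")
    return LandmarkSet(pts, laterality, float(pixel_spacing))
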