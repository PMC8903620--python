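import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from tbtprog import (
    PatchworkConfig,
    build_patchwork,
    fit_subchondral_baseline,
    generate_fbm_field,
    generate_landmarks,
    synthesize_knee_image,
)


@pytest.fixture(scope="session")
def planted_knee():
    """A jitter-free left knee with 16 planted H=0.5 fBm textures.

    Width 80 mm at 0.1 mm spacing gives an 800-px knee, 100-px ROIs and
    pixel-center-aligned sampling grids, so extraction is exact.
    """
    lm = generate_landmarks(knee_width_mm=80.0, laterality="left", jitter_mm=0.0, seed=7)
    baseline = fit_subchondral_baseline(lm)
    patchwork = build_patchwork(baseline, lm.pixel_spacing)
    fields = [
        generate_fbm_field(patchwork.side_px, 0.5, seed=300 + i) for i in range(16)
    ]
    image = synthesize_knee_image(lm, fields, artifact="none")
    return {
        "landmarks": lm,
        "baseline": baseline,
        "patchwork": patchwork,
        "fields": fields,
        "image": image,
        "background": 25000.0,
        "gain": 5000.0,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
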