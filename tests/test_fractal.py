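"""Directional variograms, band-restricted FD fits and the 64-descriptor
vector."""
import numpy as np
import pytest

from tbtprog import (
    DESCRIPTOR_NAMES,
    FractalConfig,
    compute_tbt_descriptors,
    directional_variogram,
    fit_fd,
    generate_fbm_field,
)
from tbtprog.errors import (
    DegenerateTextureError,
    GeometryError,
    InsufficientScaleError,
)
from tbtprog.fractal import Variogram

from oracles import brute_force_variogram


class TestVariogram:
    def test_constant_block_has_zero_variogram(self):
        vg = directional_variogram(np.full((32, 32), 3.7), "horizontal", 5,
                                   pixel_spacing=0.1)
        np.testing.assert_array_equal(vg.values, 0.0)

    def test_linear_ramp_closed_form(self):
        a = 0.35
        x = np.arange(40, dtype=float)
        img = np.tile(a * x, (40, 1))
        vg_h = directional_variogram(img, "horizontal", 6, pixel_spacing=0.1)
        vg_v = directional_variogram(img, "vertical", 6, pixel_spacing=0.1)
        np.testing.assert_allclose(vg_h.values, (a * vg_h.lags_px) ** 2, rtol=1e-12)
        np.testing.assert_array_equal(vg_v.values, 0.0)

    @pytest.mark.parametrize("direction", ["horizontal", "vertical"])
    @pytest.mark.parametrize("order", [1, 2])
    def test_vectorized_equals_brute_force_double_loop(self, rng, direction, order):
        block = rng.normal(size=(64, 64))
        vg = directional_variogram(block, direction, 10, pixel_spacing=0.1,
                                   increment_order=order)
        if order == 1:
            ref = brute_force_variogram(block, direction, 10)
            assert np.max(np.abs(vg.values - ref)) < 1e-10
        else:  # second-order increments reduce to first-order on the halved series
            assert vg.values.shape == (10,)
            assert np.all(vg.values >= 0)

    def test_lag_and_pair_bookkeeping(self, rng):
        vg = directional_variogram(rng.normal(size=(20, 30)), "h", 4, pixel_spacing=0.2)
        np.testing.assert_array_equal(vg.lags_px, [1, 2, 3, 4])
        np.testing.assert_allclose(vg.lags_mm, [0.2, 0.4, 0.6, 0.8])
        np.testing.assert_array_equal(vg.n_pairs, [20 * 29, 20 * 28, 20 * 27, 20 * 26])

    def test_block_too_small_for_lag(self, rng):
        with pytest.raises(GeometryError):
            directional_variogram(rng.normal(size=(20, 6)), "h", 6, pixel_spacing=0.1)


class TestFDFit:
    def _vg(self, values, spacing=0.1):
        lags = np.arange(1, len(values) + 1)
        return Variogram("h", lags, lags * spacing, np.asarray(values, float),
                         np.full(len(values), 100), spacing)

    def test_quadratic_variogram_gives_fd_two(self):
        d = np.arange(1, 10.0)
        fit = fit_fd(self._vg(3.0 * d**2), (0.0, 0.4))
        assert fit.hurst == pytest.approx(1.0, abs=1e-12)
        assert fit.fd == pytest.approx(2.0, abs=1e-12)

    def test_linear_variogram_gives_fd_two_and_a_half(self):
        d = np.arange(1, 10.0)
        fit = fit_fd(self._vg(0.8 * d), (0.0, 0.4))
        assert fit.hurst == pytest.approx(0.5, abs=1e-12)
        assert fit.fd == pytest.approx(2.5, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_single_in_band_lag_is_insufficient(self):
        # 0.2 mm spacing leaves only lag 0.2 mm strictly under 0.4 mm
        d = np.arange(1, 10.0)
        with pytest.raises(InsufficientScaleError):
            fit_fd(self._vg(d, spacing=0.2), (0.0, 0.4))

    def test_zero_variogram_in_band_is_degenerate(self):
        with pytest.raises(DegenerateTextureError):
            fit_fd(self._vg([0.0, 0.0, 0.0, 1.0]), (0.0, 0.4))

    def test_hurst_clipping_flagged(self):
        d = np.arange(1, 10.0)
        fit = fit_fd(self._vg(2.0 * d**4), (0.0, 0.4))  # slope 4 -> H=2 -> clip
        assert fit.clipped and fit.hurst == 1.5

    def test_fbm_micro_band_recovers_planted_fd(self):
        """H = 0.8 fields at 0.1 mm spacing must fit micro-band FD 2.2."""
        fds = []
        for s in range(20):
            f = generate_fbm_field(256, 0.8, seed=500 + s)
            for direction in ("h", "v"):
                vg = directional_variogram(f, direction, 4)
                fds.append(fit_fd(vg, (0.0, 0.4)).fd)
        assert np.mean(fds) == pytest.approx(2.2, abs=0.1)


class TestDescriptors:
    def test_canonical_slot_names(self):
        assert len(DESCRIPTOR_NAMES) == 64
        assert DESCRIPTOR_NAMES[0] == "roi01_h_micro_fd"
        assert DESCRIPTOR_NAMES[-1] == "roi16_v_milli_fd"
        assert len(set(DESCRIPTOR_NAMES)) == 64

    def test_full_vector_and_determinism(self, planted_knee):
        img, pw = planted_knee["image"], planted_knee["patchwork"]
        d1 = compute_tbt_descriptors(img, pw)
        d2 = compute_tbt_descriptors(img, pw)
        assert len(d1) == 64 and d1.n_valid == 64
        assert d1.values == d2.values

    def test_planted_h05_gives_micro_fd_near_25(self, planted_knee):
        desc = compute_tbt_descriptors(planted_knee["image"], planted_knee["patchwork"])
        micro = [v for n, v in desc.values.items() if "micro" in n]
        assert np.mean(micro) == pytest.approx(2.5, abs=0.1)

    def test_affine_intensity_invariance_is_exact(self, planted_knee):
        from tbtprog.image import Radiograph

        img, pw = planted_knee["image"], planted_knee["patchwork"]
        scaled = Radiograph(2.5 * np.asarray(img.pixels, float) + 300.0,
                            img.pixel_spacing)
        d0 = compute_tbt_descriptors(img, pw).to_series().to_numpy()
        d1 = compute_tbt_descriptors(scaled, pw).to_series().to_numpy()
        np.testing.assert_allclose(d1, d0, rtol=1e-9)

    def test_isotropy_on_isotropic_fields(self):
        gaps = []
        for s in range(20):
            f = generate_fbm_field(128, 0.5, seed=700 + s)
            h = fit_fd(directional_variogram(f, "h", 4), (0.0, 0.4)).hurst
            v = fit_fd(directional_variogram(f, "v", 4), (0.0, 0.4)).hurst
            gaps.append(h - v)
        assert abs(np.mean(gaps)) < 0.1

    def test_estimated_hurst_monotone_in_true_hurst(self):
        means = []
        for H in (0.2, 0.5, 0.8):
            est = [
                fit_fd(directional_variogram(generate_fbm_field(128, H, seed=50 + s),
                                             "h", 4), (0.0, 0.4)).hurst
                for s in range(10)
            ]
            means.append(np.mean(est))
        assert means[0] < means[1] < means[2]

    def test_micro_and_milli_bands_disjoint_at_supported_spacings(self):
        cfg = FractalConfig()
        for spacing in (0.1, 0.2):
            lags = np.arange(1, 60) * spacing
            micro = (lags > cfg.micro_band[0]) & (lags < cfg.micro_band[1])
            milli = (lags > cfg.milli_band[0]) & (lags < cfg.milli_band[1])
            assert not np.any(micro & milli)

    def test_invalid_micro_band_at_coarse_spacing_flagged_not_filled(self, planted_knee):
        """At 0.2 mm spacing only one lag sits under 0.4 mm, so every
        micro slot must carry an explicit invalid flag."""
        from tbtprog.image import Radiograph

        img, pw = planted_knee["image"], planted_knee["patchwork"]
        coarse = Radiograph(np.asarray(img.pixels)[::2, ::2], 0.2)
        # rebuild geometry at the coarse spacing
        from tbtprog.geometry import build_patchwork, fit_subchondral_baseline
        from tbtprog.landmarks import LandmarkSet

        lm = planted_knee["landmarks"]
        lm2 = LandmarkSet(lm.points / 2.0, lm.laterality, 0.2)
        pw2 = build_patchwork(fit_subchondral_baseline(lm2), 0.2)
        desc = compute_tbt_descriptors(coarse, pw2)
        micro_valid = [desc.valid[n] for n in DESCRIPTOR_NAMES if "micro" in n]
        milli_valid = [desc.valid[n] for n in DESCRIPTOR_NAMES if "milli" in n]
        assert not any(micro_valid)
        assert all(milli_valid)
        assert all(np.isnan(desc.values[n]) for n in DESCRIPTOR_NAMES if "micro" in n)
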