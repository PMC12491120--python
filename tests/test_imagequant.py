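import numpy as np
import pytest
from scipy.integrate import quad

from psmadyn.core import FrameSchedule, TimeActivityCurve
from psmadyn.imagequant import (
    ONE_ML_SPHERE_RADIUS_MM,
    DynamicImage,
    Injection,
    VOIMask,
    decay_correct,
    decay_correction_factors,
    extract_tac,
    segment_lesion_40pct,
    suv_convert,
    suv_peak,
)

GA68 = 67.71
VOX = (2.0, 2.0, 2.0)


def brute_force_segment(img, voxel_size, seed, radius_mm, frac=0.40):
    """Independent oracle: explicit threshold + 6-neighbour flood fill."""
    shape = img.shape
    idx = np.indices(shape)
    d2 = sum(((idx[a] - seed[a]) * voxel_size[a]) ** 2 for a in range(3))
    sphere = d2 <= radius_mm**2
    masked = np.where(sphere, img, -np.inf)
    peak = np.unravel_index(np.argmax(masked), shape)
    thr = frac * img[peak]
    supra = (img >= thr) & sphere
    out = np.zeros(shape, bool)
    stack = [peak]
    out[peak] = True
    while stack:
        x, y, z = stack.pop()
        for dx, dy, dz in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
            p = (x+dx, y+dy, z+dz)
            if all(0 <= p[a] < shape[a] for a in range(3)) and supra[p] and not out[p]:
                out[p] = True
                stack.append(p)
    return out


def brute_force_suvpeak(img, voxel_size, mask, inj, radius_mm):
    """Independent oracle: exhaustive sphere means at every mask voxel."""
    suv = img / (inj.dose_Bq / inj.weight_g)
    best = -np.inf
    coords = np.argwhere(np.ones_like(img, bool))
    for c in np.argwhere(mask):
        d2 = sum(((coords[:, a] - c[a]) * voxel_size[a]) ** 2 for a in range(3))
        sel = coords[d2 <= radius_mm**2]
        best = max(best, suv[sel[:, 0], sel[:, 1], sel[:, 2]].mean())
    return best


class TestDecayCorrection:
    def test_instantaneous_frame_at_one_half_life_doubles(self):
        # a vanishingly short frame starting at t = T1/2 is corrected by x2
        sched = FrameSchedule(np.array([0.0, GA68 * 60.0]), np.array([GA68 * 60.0, 1e-4]))
        f = decay_correction_factors(sched, GA68)
        assert np.isclose(f[1], 2.0, rtol=1e-6)

    def test_factor_tends_to_one_at_time_zero(self):
        sched = FrameSchedule(np.array([0.0]), np.array([1e-6]))
        assert np.isclose(decay_correction_factors(sched, GA68)[0], 1.0, rtol=1e-9)

    def test_factor_matches_quadrature_oracle(self):
        sched = FrameSchedule.dynamic_55frame()
        f = decay_correction_factors(sched, GA68)
        lam = np.log(2) / (GA68 * 60.0)
        for i in (0, 20, 54):
            t0, dt = sched.start_times[i], sched.durations[i]
            oracle = dt / quad(lambda t: np.exp(-lam * t), t0, t0 + dt)[0]
            assert abs(f[i] - oracle) < 1e-10

    def test_double_correction_rejected(self, schedule):
        inj = Injection(1e8, 8e4)
        img = DynamicImage(np.ones((2, 2, 2, 55)), VOX, schedule, inj)
        once = decay_correct(img)
        with pytest.raises(ValueError):
            decay_correct(once)

    def test_correct_then_invert_is_identity(self, schedule):
        tac = TimeActivityCurve.from_schedule(schedule, np.linspace(10, 500, 55))
        corr = decay_correct(tac, half_life_min=GA68)
        lam = np.log(2) / GA68
        t0 = corr.t_min - 0.5 * corr.dt_min
        f = np.exp(lam * t0) * lam * corr.dt_min / (1 - np.exp(-lam * corr.dt_min))
        assert np.allclose(corr.conc / f, tac.conc, rtol=1e-12)


class TestSegmentation:
    def test_binary_lesion_recovered_exactly(self):
        img = np.zeros((20, 20, 10))
        img[8:12, 8:12, 4:6] = 100.0
        voi = segment_lesion_40pct(img, VOX, (10, 10, 5), 15.0)
        assert np.array_equal(voi.mask, img > 0)
        assert voi.method == "adaptive40"

    def test_connectivity_excludes_disjoint_blob(self):
        img = np.zeros((30, 20, 10))
        img[5:8, 8:11, 4:6] = 100.0   # blob A (global max region)
        img[20:23, 8:11, 4:6] = 80.0  # blob B, supra-threshold but disjoint
        voi = segment_lesion_40pct(img, VOX, (6, 9, 5), 60.0)
        assert voi.mask[6, 9, 5] and not voi.mask[21, 9, 5]

    def test_gaussian_blob_matches_brute_force_oracle(self):
        x, y, z = np.meshgrid(*[np.arange(n) for n in (24, 24, 12)], indexing="ij")
        img = 100 * np.exp(-(((x - 12) ** 2 + (y - 12) ** 2 + (z - 6) ** 2) / 18.0))
        voi = segment_lesion_40pct(img, VOX, (11, 12, 6), 14.0)
        oracle = brute_force_segment(img, VOX, (11, 12, 6), 14.0)
        assert np.array_equal(voi.mask, oracle)

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(2)
        img = rng.random((16, 16, 8))
        img[8, 8, 4] = 5.0
        a = segment_lesion_40pct(img, VOX, (8, 8, 4), 10.0)
        b = segment_lesion_40pct(7.3 * img, VOX, (8, 8, 4), 10.0)
        assert np.array_equal(a.mask, b.mask)

    def test_all_zero_region_rejected(self):
        with pytest.raises(ValueError, match="signal"):
            segment_lesion_40pct(np.zeros((10, 10, 10)), VOX, (5, 5, 5), 8.0)


class TestExtractTac:
    def _image(self, schedule, fill):
        inj = Injection(1.6e8, 8e4)
        return DynamicImage(fill, VOX, schedule, inj, decay_corrected=True)

    def test_uniform_image_gives_constant_tac(self, schedule):
        img = self._image(schedule, np.full((4, 4, 4, 55), 123.0))
        mask = VOIMask(np.ones((4, 4, 4), bool))
        tac = extract_tac(img, mask)
        assert np.allclose(tac.conc, 123.0)

    def test_single_voxel_mask_returns_that_series(self, schedule):
        rng = np.random.default_rng(0)
        vol = rng.random((4, 4, 4, 55))
        img = self._image(schedule, vol)
        m = np.zeros((4, 4, 4), bool)
        m[1, 2, 3] = True
        tac = extract_tac(img, VOIMask(m))
        assert np.array_equal(tac.conc, vol[1, 2, 3])

    def test_linearity_in_image_scale(self, schedule):
        rng = np.random.default_rng(1)
        vol = rng.random((4, 4, 4, 55)) + 0.5
        m = VOIMask(rng.random((4, 4, 4)) > 0.5)
        t1 = extract_tac(self._image(schedule, vol), m)
        t3 = extract_tac(self._image(schedule, 3.0 * vol), m)
        assert np.allclose(t3.conc, 3.0 * t1.conc, rtol=1e-12)


class TestSuv:
    INJ = Injection(dose_Bq=160e6, weight_g=80e3)  # 2 MBq/kg at 80 kg

    def test_definition(self):
        assert np.isclose(suv_convert(self.INJ.dose_Bq / self.INJ.weight_g, self.INJ), 1.0)
        assert suv_convert(0.0, self.INJ) == 0.0
        # 4000 Bq/ml at 2 MBq/kg dosing -> SUV 2
        assert np.isclose(suv_convert(4000.0, self.INJ), 2.0)

    def test_invalid_injection_rejected(self):
        with pytest.raises(ValueError):
            Injection(dose_Bq=0.0, weight_g=80e3)

    def test_uniform_region_peak_equals_value(self):
        img = np.full((14, 14, 14), 4000.0)
        mask = VOIMask(np.ones_like(img, bool))
        assert np.isclose(suv_peak(img, VOX, mask, self.INJ), 2.0)

    def test_peak_bounded_by_max_voxel(self):
        rng = np.random.default_rng(3)
        img = 1000 + 3000 * rng.random((10, 10, 10))
        mask = VOIMask(rng.random((10, 10, 10)) > 0.6)
        pk = suv_peak(img, VOX, mask, self.INJ)
        assert pk <= suv_convert(img.max(), self.INJ) + 1e-12

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        img = 500 + 2000 * rng.random((8, 8, 8))
        m = np.zeros((8, 8, 8), bool)
        m[3:6, 3:6, 3:6] = True
        mine = suv_peak(img, VOX, VOIMask(m), self.INJ)
        oracle = brute_force_suvpeak(img, VOX, m, self.INJ, ONE_ML_SPHERE_RADIUS_MM)
        assert np.isclose(mine, oracle, rtol=1e-12)

    def test_monotone_under_nonnegative_increment(self):
        rng = np.random.default_rng(5)
        img = 1000 * rng.random((8, 8, 8))
        inc = 500 * rng.random((8, 8, 8))
        m = VOIMask(rng.random((8, 8, 8)) > 0.5)
        assert suv_peak(img + inc, VOX, m, self.INJ) >= suv_peak(img, VOX, m, self.INJ)
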