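import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import two_pass_mean_sd
from mriq.io import RoiCenter, VoxelGrid
from mriq.metrics import (
    DegenerateRoiError,
    RoiSample,
    cnr,
    extract_cube,
    extract_cube_volume_matched,
    normalize_ratio,
    snr_cn_pooled,
    snr_region,
)


def grid_of(data, voxel=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(data, dtype=float), voxel)


@pytest.fixture
def sequential_grid():
    """A 5^3 grid whose central 3x3x3 neighbourhood holds 1..27."""
    data = np.zeros((5, 5, 5))
    data[1:4, 1:4, 1:4] = np.arange(1, 28, dtype=float).reshape(3, 3, 3)
    return grid_of(data)


class TestExtractCube:
    def test_constant_field(self):
        g = grid_of(np.full((7, 7, 7), 7.0))
        s = extract_cube(g, RoiCenter("CC", (3, 3, 3)))
        assert (s.n, s.mu, s.sigma) == (27, 7.0, 0.0)

    def test_sequential_values_match_two_pass_oracle(self, sequential_grid):
        s = extract_cube(sequential_grid, RoiCenter("CC", (2, 2, 2)))
        mean, sd = two_pass_mean_sd(range(1, 28))
        assert s.mu == pytest.approx(mean, abs=1e-12)
        assert s.mu == 14.0
        assert s.sigma == pytest.approx(sd, abs=1e-12)
        assert sorted(s.values) == list(map(float, range(1, 28)))

    @pytest.mark.parametrize("center", [(0, 3, 3), (3, 0, 3), (3, 3, 6)])
    def test_boundary_centre_rejected(self, center):
        g = grid_of(np.zeros((7, 7, 7)))
        with pytest.raises(ValueError, match="exceeds grid bounds"):
            extract_cube(g, RoiCenter("CC", center))


class TestVolumeMatched:
    def test_equal_dims_reduces_to_contiguous(self, sequential_grid):
        c = RoiCenter("CC", (2, 2, 2))
        a = extract_cube(sequential_grid, c)
        b = extract_cube_volume_matched(sequential_grid, c, (1.0, 1.0, 1.0))
        assert np.array_equal(np.sort(a.values), np.sort(b.values))
        assert b.n == 27

    def test_half_voxel_grid_gets_seven_wide_cube(self, rng):
        g = grid_of(rng.normal(size=(9, 9, 9)), voxel=(0.5, 0.5, 0.5))
        s = extract_cube_volume_matched(g, RoiCenter("CC", (4, 4, 4)), (1.0, 1.0, 1.0))
        # 3 * 1.0/0.5 = 6, forced odd upward to 7 per axis
        assert s.n == 343

    def test_coarse_reference_equal_to_grid(self, rng):
        g = grid_of(rng.normal(size=(9, 9, 9)), voxel=(1.2, 1.2, 1.2))
        s = extract_cube_volume_matched(g, RoiCenter("CC", (4, 4, 4)), (1.2, 1.2, 1.2))
        assert s.n == 27

    def test_reference_smaller_than_grid_rejected(self, rng):
        g = grid_of(rng.normal(size=(9, 9, 9)), voxel=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="reference voxel size"):
            extract_cube_volume_matched(g, RoiCenter("CC", (4, 4, 4)), (0.5, 1.0, 1.0))

    def test_oversized_cube_rejected(self, rng):
        g = grid_of(rng.normal(size=(9, 9, 9)), voxel=(0.25, 0.25, 0.25))
        with pytest.raises(ValueError, match="exceeds grid bounds"):
            extract_cube_volume_matched(g, RoiCenter("CC", (4, 4, 4)), (1.2, 1.2, 1.2))


class TestSnr:
    def test_direct_arithmetic(self):
        s = RoiSample("CC", np.array([95.0, 105.0] * 14)[:27])
        assert snr_region(s) == pytest.approx(s.mu / s.sigma, abs=1e-14)

    def test_known_mean_and_sd(self):
        values = np.array([100.0 - 5.0, 100.0 + 5.0] * 2)  # mu=100, sd known
        s = RoiSample("CC", values)
        mean, sd = two_pass_mean_sd(values)
        assert snr_region(s) == pytest.approx(mean / sd, abs=1e-12)

    def test_degenerate_roi_rejected(self):
        with pytest.raises(DegenerateRoiError, match="zero intensity SD"):
            snr_region(RoiSample("CC", np.full(27, 3.0)))

    def test_monte_carlo_matches_generating_parameters(self, rng):
        # 1000 noise-only cubes at mean 50, SD 2: mean SNR within 5% of 25
        snrs = [
            snr_region(RoiSample("CC", rng.normal(50.0, 2.0, 27))) for _ in range(1000)
        ]
        assert np.mean(snrs) == pytest.approx(25.0, rel=0.05)

    def test_per_cube_mean_carries_known_small_sample_bias(self, rng):
        # E[mu_hat/s] = (mu/sigma) * E[sigma/s] with s chi-distributed on
        # nu = 26 df; the closed-form bias factor is sqrt(nu/2)*G((nu-1)/2)/G(nu/2)
        from scipy.special import gammaln

        nu = 26
        factor = math.sqrt(nu / 2.0) * math.exp(gammaln((nu - 1) / 2.0) - gammaln(nu / 2.0))
        snrs = np.array(
            [snr_region(RoiSample("CC", rng.normal(100.0, 5.0, 27))) for _ in range(20_000)]
        )
        expected = 20.0 * factor  # ~ +1% above the true ratio
        assert factor > 1.005
        se = snrs.std(ddof=1) / math.sqrt(snrs.size)
        assert abs(snrs.mean() - expected) < 4 * se


class TestPooledCn:
    def test_symmetric_sides_close_to_each_side(self, rng):
        left = RoiSample("LCN", rng.normal(10, 1, 27))
        right = RoiSample("RCN", rng.normal(10, 1, 27))
        _, pooled_snr = snr_cn_pooled(left, right)
        assert pooled_snr == pytest.approx(snr_region(left), rel=0.2)

    def test_bruteforce_concatenation_oracle(self, rng):
        left = RoiSample("LCN", rng.normal(10, 1, 27))
        right = RoiSample("RCN", rng.normal(20, 1, 27))
        pooled, pooled_snr = snr_cn_pooled(left, right)
        both = np.concatenate([left.values, right.values])
        mean, sd = two_pass_mean_sd(both)
        assert pooled.n == 54
        assert pooled_snr == pytest.approx(mean / sd, abs=1e-10)
        # between-side spread inflates the pooled SD below the per-side mean SNR
        assert pooled_snr < 0.5 * (snr_region(left) + snr_region(right))

    def test_sum_pooling_scales_by_count(self, rng):
        left = RoiSample("LCN", rng.normal(10, 1, 27))
        right = RoiSample("RCN", rng.normal(12, 1, 27))
        _, by_mean = snr_cn_pooled(left, right, pooling="mean")
        _, by_sum = snr_cn_pooled(left, right, pooling="sum")
        assert by_sum == pytest.approx(54 * by_mean, abs=1e-10)

    def test_mismatched_sizes_rejected(self, rng):
        left = RoiSample("LCN", rng.normal(10, 1, 27))
        right = RoiSample("RCN", rng.normal(10, 1, 26))
        with pytest.raises(ValueError, match="match in size"):
            snr_cn_pooled(left, right)


class TestCnr:
    def test_zero_contrast(self, rng):
        a = RoiSample("CC", rng.normal(0, 3, 27) + 90.0)
        b = RoiSample("CN_pooled", a.values.copy())
        assert cnr(a, b) == 0.0

    def test_formula_value(self):
        # mu 110 vs 90, both SD 10: 20/sqrt(200)
        a = _sample_with("CC", mu=110.0, sigma=10.0)
        b = _sample_with("CN_pooled", mu=90.0, sigma=10.0)
        assert cnr(a, b) == pytest.approx(20.0 / math.sqrt(200.0), rel=1e-12)

    def test_antisymmetry(self, rng):
        a = RoiSample("CC", rng.normal(110, 9, 27))
        b = RoiSample("CN_pooled", rng.normal(88, 7, 54))
        assert cnr(a, b) == pytest.approx(-cnr(b, a), abs=1e-14)

    def test_both_sigmas_zero_rejected(self):
        a = RoiSample("CC", np.full(27, 1.0))
        b = RoiSample("CN_pooled", np.full(54, 2.0))
        with pytest.raises(DegenerateRoiError, match="both ROI SDs are zero"):
            cnr(a, b)

    def test_monte_carlo_matches_closed_form(self, rng):
        # contrast 20, SD 5 in both regions: E[CNR] ~ 20/(5*sqrt(2))
        vals = [
            cnr(
                RoiSample("CC", rng.normal(100, 5, 27)),
                RoiSample("CN_pooled", rng.normal(80, 5, 54)),
            )
            for _ in range(1000)
        ]
        assert np.mean(vals) == pytest.approx(20.0 / (5.0 * math.sqrt(2.0)), rel=0.05)


def _sample_with(region, mu, sigma):
    """Build a sample with exactly the requested mean and sample SD."""
    base = np.arange(27, dtype=float)
    base = (base - base.mean()) / base.std(ddof=1)
    return RoiSample(region, mu + sigma * base)


class TestNormalize:
    def test_unit_voxel_is_identity(self):
        assert normalize_ratio(10.0, (1.0, 1.0, 1.0)) == 10.0

    def test_half_millimetre_voxel(self):
        assert normalize_ratio(10.0, (0.5, 0.5, 0.5)) == pytest.approx(80.0, abs=1e-12)

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            normalize_ratio(1.0, (1.0, -1.0, 1.0))


class TestScaleInvariance:
    @settings(max_examples=30, derandomize=True)
    @given(scale=st.floats(0.01, 100.0), offset=st.floats(-50.0, 50.0), seed=st.integers(0, 10_000))
    def test_snr_scale_and_cnr_offset_invariance(self, scale, offset, seed):
        rng = np.random.default_rng(seed)
        cc = rng.normal(100, 5, 27)
        cn = rng.normal(80, 5, 54)
        s0 = snr_region(RoiSample("CC", cc))
        c0 = cnr(RoiSample("CC", cc), RoiSample("CN_pooled", cn))
        # global positive scaling leaves both ratios unchanged
        s1 = snr_region(RoiSample("CC", cc * scale))
        c1 = cnr(RoiSample("CC", cc * scale), RoiSample("CN_pooled", cn * scale))
        assert s1 == pytest.approx(s0, rel=1e-9)
        assert c1 == pytest.approx(c0, rel=1e-9)
        # a global offset leaves CNR unchanged but shifts SNR
        c2 = cnr(RoiSample("CC", cc + offset), RoiSample("CN_pooled", cn + offset))
        s2 = snr_region(RoiSample("CC", cc + offset))
        assert c2 == pytest.approx(c0, rel=1e-9)
        if abs(offset) > 1e-6:
            assert s2 != pytest.approx(s0, rel=1e-12)


def test_quantitative_contrasts_reported_raw(small_config, rng):
    from dataclasses import replace

    from mriq.metrics import measure_scan
    from mriq.phantoms import generate_volume

    grid, truth = generate_volume(small_config, 0, 40.0, rng)
    from mriq.io import ScanRecord

    rec_q = ScanRecord("db00", "s0", "qT1", grid.voxel_mm)
    rows = measure_scan(grid, truth.centers, rec_q)
    for r in rows:
        assert r.snr_normalized == r.snr_raw
    rec_w = replace(rec_q, contrast="T1w")
    rows_w = measure_scan(grid, truth.centers, rec_w)
    vol = grid.voxel_volume_mm3
    for r in rows_w:
        assert r.snr_normalized == pytest.approx(r.snr_raw / vol, rel=1e-12)
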