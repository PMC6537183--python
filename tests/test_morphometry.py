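"""Per-fiber measurements, section scores and their invariants."""

import numpy as np
import pytest

from musclemorph import (FiberRecord, atrophy_factor, circularity,
                         hypertrophy_factor, measure_fiber,
                         normalized_fiber_count, summarize_section)
from musclemorph.morphometry import ATROPHY_BINS, HYPERTROPHY_BINS


def disk_mask(radius, pad=5):
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


class TestMeasureFiber:
    def test_single_pixel_csa_is_calibration_squared(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        rec = measure_fiber(mask, 0.647)
        assert rec.csa_um2 == pytest.approx(0.418609, abs=1e-9)

    def test_disk_is_round_and_right_sized(self):
        rec = measure_fiber(disk_mask(30), 0.647)
        assert rec.csa_um2 == pytest.approx(np.pi * 30**2 * 0.647**2, rel=0.02)
        assert rec.circularity >= 0.95
        assert abs(rec.major_diameter_um - rec.minor_diameter_um) \
            <= 0.02 * rec.major_diameter_um

    def test_rectangle_axis_ratio(self):
        mask = np.zeros((60, 60), bool)
        mask[10:20, 10:50] = True            # 10 x 40 rectangle
        rec = measure_fiber(mask, 1.0)
        assert rec.major_diameter_um / rec.minor_diameter_um == pytest.approx(4.0, rel=0.02)

    def test_scale_equivariance(self):
        mask = disk_mask(12)
        a = measure_fiber(mask, 0.5)
        b = measure_fiber(mask, 1.0)
        assert b.csa_um2 == pytest.approx(4 * a.csa_um2)
        assert b.perimeter_um == pytest.approx(2 * a.perimeter_um)
        assert b.major_diameter_um == pytest.approx(2 * a.major_diameter_um)
        assert b.minor_diameter_um == pytest.approx(2 * a.minor_diameter_um)

    def test_stored_circularity_is_self_consistent(self, rng):
        mask = rng.random((40, 40)) > 0.5
        from scipy import ndimage
        lab, n = ndimage.label(mask)
        big = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        rec = measure_fiber(lab == big, 0.647)
        expect = min(1.0, 4 * np.pi * rec.csa_um2 / rec.perimeter_um**2)
        assert rec.circularity == pytest.approx(expect, abs=1e-6)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            measure_fiber(np.zeros((5, 5), bool), 0.647)


class TestCircularity:
    def test_circle_is_one(self):
        assert circularity(np.pi, 2 * np.pi) == pytest.approx(1.0)

    def test_unit_square(self):
        assert circularity(1.0, 4.0) == pytest.approx(np.pi / 4, abs=1e-12)

    def test_capped_at_one(self):
        assert circularity(100.0, 1.0) == 1.0

    @pytest.mark.parametrize("csa,per", [(0, 10), (-1, 10), (10, 0), (10, -2)])
    def test_nonpositive_inputs_error(self, csa, per):
        with pytest.raises(ValueError):
            circularity(csa, per)


class TestNormalizedCount:
    @pytest.mark.parametrize("n,area,expect", [
        (100, 1e7, 100.0),        # identity at exactly 10 mm^2
        (500, 2.5e6, 2000.0),
        (0, 5e6, 0.0),
        (1, 1.0, 1e7),
    ])
    def test_values(self, n, area, expect):
        assert normalized_fiber_count(n, area) == pytest.approx(expect)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            normalized_fiber_count(10, 0.0)


def oracle_atrophy_score(csa):
    if csa <= 500:
        return 20
    if csa <= 1000:
        return 10
    if csa <= 1500:
        return 5
    if csa <= 2000:
        return 1
    return 0


def oracle_hypertrophy_score(csa):
    if csa <= 4500:
        return 0
    if csa <= 5500:
        return 1
    if csa <= 6500:
        return 5
    if csa <= 7500:
        return 10
    if csa <= 8500:
        return 20
    return 30


class TestScoreFactors:
    def test_all_fibers_in_top_atrophy_bin(self):
        assert atrophy_factor([300, 300]) == 20.0

    def test_all_fibers_above_atrophy_range(self):
        assert atrophy_factor([2500, 2500, 2500]) == 0.0

    def test_atrophy_mixed_hand_case(self):
        assert atrophy_factor([400, 800, 1200, 1800, 2500]) == pytest.approx(7.2)

    def test_hypertrophy_single_fiber(self):
        assert hypertrophy_factor([5000]) == 1.0

    def test_hypertrophy_extremes(self):
        assert hypertrophy_factor([9000, 9000]) == 30.0

    def test_hypertrophy_mixed_hand_case(self):
        vals = [4600, 6000, 7000, 8000, 9000, 2000]
        assert hypertrophy_factor(vals) == pytest.approx(11.0)

    def test_matches_hand_oracle_on_random_csas(self, rng):
        csas = rng.uniform(50, 12000, 200)
        expect_a = np.mean([oracle_atrophy_score(c) for c in csas])
        expect_h = np.mean([oracle_hypertrophy_score(c) for c in csas])
        assert atrophy_factor(csas) == pytest.approx(expect_a)
        assert hypertrophy_factor(csas) == pytest.approx(expect_h)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            atrophy_factor([])
        with pytest.raises(ValueError):
            hypertrophy_factor([])

    def test_atrophy_monotone_across_bin_boundary(self):
        base = [1200.0, 3000.0, 800.0]
        lowered = [1200.0, 3000.0, 400.0]   # one fiber crosses down a bin edge
        assert atrophy_factor(lowered) >= atrophy_factor(base)

    def test_hypertrophy_monotone_across_bin_boundary(self):
        base = [5000.0, 3000.0]
        raised = [5600.0, 3000.0]
        assert hypertrophy_factor(raised) >= hypertrophy_factor(base)

    def test_bin_edges_inclusive_above(self):
        # printed integer edges: 500 belongs to score 20, 501..1000 to 10
        assert ATROPHY_BINS.score(500.0) == 20
        assert ATROPHY_BINS.score(500.5) == 10
        assert HYPERTROPHY_BINS.score(4500.0) == 0
        assert HYPERTROPHY_BINS.score(4500.5) == 1


def rec(fid, csa, ftype, per=100.0):
    return FiberRecord(fiber_id=fid, csa_um2=csa, perimeter_um=per,
                       major_diameter_um=50.0, minor_diameter_um=40.0,
                       circularity=0.8, fiber_type=ftype)


class TestSummarize:
    def test_counts_and_percentages(self):
        records = [rec(i, 2000.0, "II" if i <= 6 else "I") for i in range(1, 11)]
        s = summarize_section(records, 1e6)
        assert (s.n_total, s.n_type1, s.n_type2) == (10, 4, 6)
        assert s.pct_type1 == pytest.approx(40.0)
        assert s.pct_type2 == pytest.approx(60.0)
        assert s.pct_type1 + s.pct_type2 == pytest.approx(100.0)

    def test_identical_csas_mean_and_zero_sem(self):
        records = [rec(i, 1234.0, "I") for i in range(1, 6)]
        s = summarize_section(records, 1e6)
        mean, sem = s.means["all"]["csa_um2"]
        assert mean == pytest.approx(1234.0)
        assert sem == 0.0

    def test_zero_fibers_reported_missing(self):
        s = summarize_section([], 5e5)
        assert s.n_total == 0
        assert s.atrophy_factor_all is None
        assert s.hypertrophy_factor_2 is None
        assert s.pct_type1 is None

    def test_untyped_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_section([rec(1, 1000.0, None)], 1e6)

    def test_synthetic_means_near_generator_truth(self, clean_section, clean_result):
        _, _, truth = clean_section
        from musclemorph import truth_table
        tt = truth_table(truth)
        mean, sem = clean_result.summary.means["all"]["csa_um2"]
        # detected means should sit within 2 SEM + small segmentation bias
        assert mean == pytest.approx(tt["csa_um2"].mean(), rel=0.05)
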