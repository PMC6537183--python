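"""Membrane binarization, gap closing, fiber labeling, exclusion filters."""

import numpy as np
import pytest
from scipy import ndimage

from musclemorph import (ExclusionParams, IntensityImage,
                         apply_exclusion_filters, binarize_membrane,
                         close_membrane_gaps, compute_tissue_area,
                         label_fibers, otsu_threshold)
from musclemorph.morphometry import FiberRecord

FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def exhaustive_otsu(values):
    """Independent oracle: try every threshold, maximize between-class variance."""
    values = np.asarray(values, dtype=np.int64).ravel()
    best_t, best_var = None, -1.0
    for t in range(values.min(), values.max()):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-9:
            best_var, best_t = var, t
    return best_t


class TestBinarize:
    def test_two_valued_image_splits_exactly(self):
        px = np.full((30, 30), 100, dtype=np.uint16)
        px[10:20, 10:20] = 3000
        mask = binarize_membrane(IntensityImage(px))
        assert np.array_equal(mask, px == 3000)

    def test_threshold_matches_exhaustive_oracle(self, rng):
        # bimodal Gaussian mixture
        lo = rng.normal(300, 60, 2500)
        hi = rng.normal(2800, 200, 900)
        values = np.clip(np.rint(np.concatenate([lo, hi])), 0, 4095).astype(np.uint16)
        assert otsu_threshold(values) == exhaustive_otsu(values)

    @pytest.mark.parametrize("case", ["uniform", "skewed", "narrow"])
    def test_oracle_equivalence_more_distributions(self, case, rng):
        if case == "uniform":
            values = rng.integers(0, 256, 4000).astype(np.uint16)
        elif case == "skewed":
            values = np.clip(np.rint(rng.gamma(2.0, 150.0, 4000)), 0, 4095).astype(np.uint16)
        else:
            values = np.clip(np.rint(rng.normal(500, 5, 4000)), 0, 4095).astype(np.uint16)
        assert otsu_threshold(values) == exhaustive_otsu(values)

    def test_all_zero_image_empty_mask(self, caplog):
        mask = binarize_membrane(IntensityImage(np.zeros((10, 10), np.uint16)))
        assert not mask.any()


def ring_mask(shape=(40, 40), thickness=6, break_px=0):
    """Square membrane ring; optional break of given width in the top edge."""
    m = np.zeros(shape, dtype=bool)
    m[8:32, 8:32] = True
    m[8 + thickness:32 - thickness, 8 + thickness:32 - thickness] = False
    if break_px:
        m[8:8 + thickness, 19:19 + break_px] = False
    return m


class TestCloseGaps:
    def test_seals_small_break_in_ring(self):
        broken = ring_mask(break_px=3)
        closed = close_membrane_gaps(broken, 2)
        # interior becomes a single enclosed hole again
        filled = ndimage.binary_fill_holes(closed)
        assert (filled & ~closed).sum() > 0
        n_outside = ndimage.label(~filled, structure=FOUR)[1]
        assert n_outside == 1  # only the exterior remains outside

    def test_extensive(self, rng):
        mask = rng.random((50, 50)) > 0.7
        closed = close_membrane_gaps(mask, 2)
        assert (closed & mask).sum() == mask.sum()   # output superset of input

    def test_idempotent_on_closed_ring(self):
        ring = ring_mask()
        once = close_membrane_gaps(ring, 2)
        twice = close_membrane_gaps(once, 2)
        assert np.array_equal(once, twice)
        # hole count preserved
        assert ndimage.label(~once, structure=FOUR)[1] == \
            ndimage.label(~ring, structure=FOUR)[1]


class TestLabelFibers:
    def test_grid_inside_frame_gives_four_cells(self):
        m = np.zeros((41, 41), dtype=bool)
        for x in (4, 20, 36):
            m[x, 4:37] = True
            m[4:37, x] = True
        labels, n = label_fibers(m)
        assert n == 4
        # raster-scan label order: top-left cell is label 1
        assert labels[10, 10] == 1 and labels[10, 30] == 2
        assert labels[30, 10] == 3 and labels[30, 30] == 4

    def test_cells_touching_edge_are_dropped(self):
        m = np.zeros((41, 41), dtype=bool)
        m[20, :] = True
        m[:, 20] = True          # four quadrants all touch the border
        labels, n = label_fibers(m)
        assert n == 0

    def test_interior_holes_filled(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5, 5:25] = m[24, 5:25] = m[5:25, 5] = m[5:25, 24] = True
        m[14:16, 14:16] = True   # speck inside the cell
        labels, n = label_fibers(m)
        assert n == 1
        assert labels[14, 14] == 1   # speck absorbed into the fiber

    def test_synthetic_section_counts_match_truth(self, clean_section, clean_result):
        _, _, truth = clean_section
        assert clean_result.summary.n_total == truth.n_fibers

    def test_labels_disjoint_and_consecutive(self, clean_result):
        labels = clean_result.labels
        n = labels.max()
        present = np.unique(labels)
        assert np.array_equal(present[present > 0], np.arange(1, n + 1))


def make_record(fid, csa=1000.0, circ=0.8, minor=30.0):
    return FiberRecord(fiber_id=fid, csa_um2=csa, perimeter_um=100.0,
                       major_diameter_um=50.0, minor_diameter_um=minor,
                       circularity=circ)


class TestExclusionFilters:
    def test_paper_rule_small_area(self):
        labels = np.zeros((5, 5), np.int32)
        labels[1, 1] = 1
        recs = [make_record(1, csa=150.0)]
        _, kept, removed = apply_exclusion_filters(labels, recs, ExclusionParams())
        assert kept == [] and removed == [1]

    def test_paper_rule_low_circularity(self):
        labels = np.zeros((5, 5), np.int32)
        labels[1, 1] = 1
        recs = [make_record(1, csa=1000.0, circ=0.39, minor=30.0)]
        _, kept, removed = apply_exclusion_filters(labels, recs, ExclusionParams())
        assert kept == [] and removed == [1]

    def test_ties_at_bounds_survive(self):
        labels = np.zeros((4, 8), np.int32)
        labels[1, 1], labels[1, 3], labels[1, 5] = 1, 2, 3
        recs = [make_record(1, csa=200.0), make_record(2, circ=0.4),
                make_record(3, minor=1.5)]
        _, kept, removed = apply_exclusion_filters(labels, recs, ExclusionParams())
        assert len(kept) == 3 and removed == []

    def test_fifty_fibers_five_single_rule_violators(self):
        # 45 compliant + one violator of each rule (plus one extra large-CSA)
        recs = [make_record(i) for i in range(1, 46)]
        recs.append(make_record(46, csa=150.0))           # too small
        recs.append(make_record(47, csa=14000.0))         # too large
        recs.append(make_record(48, circ=0.39))           # not round enough
        recs.append(make_record(49, minor=1.0))           # too thin
        recs.append(make_record(50, csa=13500.0))         # too large again
        labels = np.zeros((1, 51), np.int32)
        labels[0, 1:51] = np.arange(1, 51)
        new_labels, kept, removed = apply_exclusion_filters(
            labels, recs, ExclusionParams())
        assert len(kept) == 45
        assert sorted(removed) == [46, 47, 48, 49, 50]
        # survivors renumbered consecutively
        assert [r.fiber_id for r in kept] == list(range(1, 46))
        assert new_labels.max() == 45

    @pytest.mark.parametrize("relax", ["min_area_um2", "max_area_um2",
                                       "min_circularity", "min_minor_diameter_um"])
    def test_relaxing_any_bound_is_monotone(self, relax, rng):
        csas = rng.uniform(50, 15000, 60)
        circs = rng.uniform(0.1, 1.0, 60)
        minors = rng.uniform(0.5, 80, 60)
        recs = [make_record(i + 1, csa=csas[i], circ=circs[i], minor=minors[i])
                for i in range(60)]
        labels = np.zeros((1, 61), np.int32)
        labels[0, 1:61] = np.arange(1, 61)
        tight = ExclusionParams()
        relaxed_kwargs = dict(min_area_um2=200.0, max_area_um2=13000.0,
                              min_circularity=0.4, min_minor_diameter_um=1.5)
        relaxed_kwargs[relax] = {"min_area_um2": 50.0, "max_area_um2": 20000.0,
                                 "min_circularity": 0.2,
                                 "min_minor_diameter_um": 0.5}[relax]
        loose = ExclusionParams(**relaxed_kwargs)
        import copy
        n_tight = len(apply_exclusion_filters(labels, copy.deepcopy(recs), tight)[1])
        n_loose = len(apply_exclusion_filters(labels, copy.deepcopy(recs), loose)[1])
        assert n_loose >= n_tight


class TestTissueArea:
    def test_empty_inputs_zero(self):
        area = compute_tissue_area(np.zeros((10, 10), bool),
                                   np.zeros((10, 10), np.int32), 0.647)
        assert area == 0.0

    def test_solid_block_arithmetic(self):
        mask = np.ones((1000, 1000), dtype=bool)
        labels = np.zeros((1000, 1000), np.int32)
        area = compute_tissue_area(mask, labels, 0.647, tissue_close_radius_px=0)
        assert area == pytest.approx(0.647**2 * 1e6)
        assert round(area) == 418609

    def test_synthetic_section_within_5pct_of_truth(self, clean_section, clean_result):
        _, _, truth = clean_section
        measured = compute_tissue_area(
            clean_result.membrane_mask, clean_result.labels, truth.pixel_size_um,
            tissue_mask=clean_result.tissue_mask)
        assert measured == pytest.approx(truth.tissue_area_um2, rel=0.05)

    def test_area_at_least_sum_of_fibers(self, clean_result):
        fiber_area = (clean_result.labels > 0).sum() * 0.647**2
        assert clean_result.summary.tissue_area_um2 >= fiber_area
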