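"""Tests for ROI extraction against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camvol.errors import ConfigurationError, DomainError
from camvol.extraction import (ProbabilityMap, compute_woap, extract_rois,
                               image_positive, match_rois_to_nodules,
                               threshold_mask)


def flood_fill_rois(values, spacing, cutoff=0.2):
    """Independent oracle: 8-connected flood fill plus per-pixel accumulation."""
    mask = values > cutoff
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    nrow, ncol = mask.shape
    for r0 in range(nrow):
        for c0 in range(ncol):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack, pix = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                pix.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < nrow and 0 <= cc < ncol
                                and mask[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            p = np.array([values[r, c] for r, c in pix])
            comps.append(dict(
                pixel_count=len(pix),
                area=len(pix) * spacing ** 2,
                woap=p.sum() * spacing ** 2,
                mean=p.mean(), median=np.median(p), pmax=p.max(),
                centroid=(np.mean([r for r, _ in pix]),
                          np.mean([c for _, c in pix]))))
    comps.sort(key=lambda d: (-d["area"], -d["pmax"], d["centroid"]))
    return comps


class TestMapValidation:
    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            ProbabilityMap(values=np.full((4, 4), 1.2), pixel_spacing_mm=1.0)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ConfigurationError):
            ProbabilityMap(values=np.zeros((4, 4)), pixel_spacing_mm=0.0)


class TestImagePositivity:
    @pytest.mark.parametrize("fill,expected", [
        (0.10, False),
        (0.15, True),   # boundary: >= convention
        (0.50, True),
    ])
    def test_uniform_maps(self, fill, expected):
        pmap = ProbabilityMap(values=np.full((8, 8), fill), pixel_spacing_mm=1.0)
        assert image_positive(pmap) is expected

    def test_single_hot_pixel(self):
        v = np.zeros((8, 8))
        v[3, 3] = 0.5
        assert image_positive(ProbabilityMap(values=v, pixel_spacing_mm=1.0))


class TestThresholdMask:
    def test_all_zero_map_empty(self):
        pmap = ProbabilityMap(values=np.zeros((5, 5)), pixel_spacing_mm=1.0)
        assert not threshold_mask(pmap).any()

    def test_uniform_cutoff_map_empty_strict(self):
        pmap = ProbabilityMap(values=np.full((5, 5), 0.2), pixel_spacing_mm=1.0)
        assert not threshold_mask(pmap).any()

    def test_uniform_above_cutoff_full(self):
        pmap = ProbabilityMap(values=np.full((5, 5), 0.21), pixel_spacing_mm=1.0)
        assert threshold_mask(pmap).all()

    def test_invalid_cutoff_rejected(self):
        pmap = ProbabilityMap(values=np.zeros((5, 5)), pixel_spacing_mm=1.0)
        with pytest.raises(ConfigurationError):
            threshold_mask(pmap, cutoff=1.5)


class TestWoap:
    def test_uniform_half_probability(self):
        assert compute_woap([0.5] * 4, 1.0) == pytest.approx(2.0)

    def test_single_pixel_with_spacing(self):
        assert compute_woap([1.0], 2.0) == pytest.approx(4.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(DomainError):
            compute_woap([], 1.0)

    def test_matches_direct_sum(self, rng):
        p = rng.uniform(0.2, 1.0, size=20)
        assert compute_woap(p, 0.7) == pytest.approx(float(p.sum()) * 0.49)


class TestExtractRois:
    def test_all_zero_map_no_rois(self):
        pmap = ProbabilityMap(values=np.zeros((6, 6)), pixel_spacing_mm=1.0)
        assert extract_rois(pmap) == []

    def test_uniform_map_single_roi(self):
        pmap = ProbabilityMap(values=np.ones((10, 10)), pixel_spacing_mm=1.0)
        rois = extract_rois(pmap)
        assert len(rois) == 1
        roi = rois[0]
        assert roi.pixel_count == 100
        assert roi.area_mm2 == pytest.approx(100.0)
        assert roi.woap == pytest.approx(100.0)
        assert roi.prob_mean == roi.prob_median == roi.prob_max == 1.0

    def test_two_blobs_match_flood_fill_oracle(self):
        v = np.zeros((6, 6))
        v[0:2, 0:2] = 0.5
        v[4:6, 4:6] = 0.9
        pmap = ProbabilityMap(values=v, pixel_spacing_mm=2.0)
        rois = extract_rois(pmap)
        oracle = flood_fill_rois(v, 2.0)
        assert len(rois) == len(oracle) == 2
        for roi, exp in zip(rois, oracle):
            assert roi.area_mm2 == pytest.approx(exp["area"])
            assert roi.area_mm2 == pytest.approx(16.0)
            assert roi.woap == pytest.approx(exp["woap"])
            assert roi.prob_mean == pytest.approx(exp["mean"])
            assert roi.centroid == pytest.approx(exp["centroid"])

    @pytest.mark.parametrize("seed", range(20))
    def test_random_maps_match_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(900 + seed)
        v = np.where(rng.uniform(size=(32, 32)) < 0.25,
                     rng.uniform(0.2, 1.0, size=(32, 32)), 0.0)
        pmap = ProbabilityMap(values=v, pixel_spacing_mm=0.7)
        rois = extract_rois(pmap, max_rois=10_000)
        oracle = flood_fill_rois(v, 0.7)
        assert len(rois) == len(oracle)
        for roi, exp in zip(rois, oracle):
            assert roi.pixel_count == exp["pixel_count"]
            assert roi.woap == pytest.approx(exp["woap"])
            assert roi.prob_mean == pytest.approx(exp["mean"])
            assert roi.prob_median == pytest.approx(exp["median"])
            assert roi.prob_max == pytest.approx(exp["pmax"])

    def test_truncation_to_max_rois_keeps_largest(self):
        v = np.zeros((20, 20))
        v[0:4, 0:4] = 0.5      # 16 px
        v[0:3, 10:13] = 0.5    # 9 px
        v[10:12, 0:2] = 0.5    # 4 px
        v[15:16, 15:16] = 0.5  # 1 px
        pmap = ProbabilityMap(values=v, pixel_spacing_mm=1.0)
        rois = extract_rois(pmap, max_rois=3)
        assert [r.pixel_count for r in rois] == [16, 9, 4]
        assert [r.roi_id for r in rois] == [0, 1, 2]

    def test_total_pixels_bounded_by_mask(self, rng):
        v = np.where(rng.uniform(size=(24, 24)) < 0.3,
                     rng.uniform(0.2, 1.0, size=(24, 24)), 0.0)
        pmap = ProbabilityMap(values=v, pixel_spacing_mm=1.0)
        rois = extract_rois(pmap, max_rois=3)
        assert sum(r.pixel_count for r in rois) <= int((v > 0.2).sum())

    def test_downsampling_robustness(self):
        """2x downsampling changes the area of a large ROI by < 10%."""
        yy, xx = np.mgrid[0:64, 0:64]
        blob = 0.9 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 8.0 ** 2))
        full = ProbabilityMap(values=blob, pixel_spacing_mm=1.0)
        down = ProbabilityMap(values=blob[::2, ::2], pixel_spacing_mm=2.0)
        a_full = extract_rois(full)[0].area_mm2
        a_down = extract_rois(down)[0].area_mm2
        assert extract_rois(full)[0].pixel_count >= 100
        assert abs(a_down - a_full) / a_full < 0.10


class TestRoiInvariants:
    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_parameters_invariant_to_pixel_order(self, seed):
        """Descriptors do not depend on pixel visitation order."""
        rng = np.random.default_rng(seed)
        v = np.where(rng.uniform(size=(16, 16)) < 0.4,
                     rng.uniform(0.25, 1.0, size=(16, 16)), 0.0)
        pmap = ProbabilityMap(values=v, pixel_spacing_mm=1.0)
        rois = extract_rois(pmap, max_rois=100)
        # flipping the map relabels components but must preserve the
        # multiset of descriptors
        flipped = ProbabilityMap(values=v[::-1, ::-1].copy(), pixel_spacing_mm=1.0)
        rois_f = extract_rois(flipped, max_rois=100)
        key = lambda rs: sorted((r.pixel_count, round(r.woap, 9),
                                 round(r.prob_mean, 9)) for r in rs)
        assert key(rois) == key(rois_f)


class TestMatching:
    def test_empty_inputs(self):
        assert match_rois_to_nodules([], [], []) == {}

    def test_single_centered_match(self):
        pmap = ProbabilityMap(values=np.pad(np.full((3, 3), 0.9), 3),
                              pixel_spacing_mm=1.0)
        rois = extract_rois(pmap)
        mapping = match_rois_to_nodules(rois, [(4.0, 4.0)], ["nod1"])
        assert mapping == {0: "nod1"}

    def test_crossed_distances_match_exhaustive_assignment(self):
        """Greedy nearest-centroid equals the brute-force minimum-total-
        distance assignment on a crossed 2x2 configuration."""
        from camvol.extraction import RoiParams

        r0 = RoiParams(roi_id=0, pixel_count=1, area_mm2=1, woap=0.5,
                       prob_mean=0.5, prob_median=0.5, prob_max=0.5,
                       centroid=(0.0, 0.0))
        r1 = RoiParams(roi_id=1, pixel_count=1, area_mm2=1, woap=0.5,
                       prob_mean=0.5, prob_median=0.5, prob_max=0.5,
                       centroid=(0.0, 10.0))
        centers = [(0.0, 2.0), (0.0, 9.0)]
        # exhaustive: {0->a, 1->b}: 2+1=3 vs {0->b, 1->a}: 9+8=17
        mapping = match_rois_to_nodules([r0, r1], centers, ["a", "b"])
        assert mapping == {0: "a", 1: "b"}

    def test_distance_gate_leaves_roi_unmatched(self):
        from camvol.extraction import RoiParams

        roi = RoiParams(roi_id=0, pixel_count=1, area_mm2=1, woap=0.5,
                        prob_mean=0.5, prob_median=0.5, prob_max=0.5,
                        centroid=(0.0, 0.0))
        mapping = match_rois_to_nodules([roi], [(0.0, 50.0)], ["far"],
                                        max_distance_px=[10.0])
        assert mapping == {0: None}
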