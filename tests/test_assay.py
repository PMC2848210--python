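import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_compartments, pixel_set
from transloc.assay import (
    Bounds,
    CellFeatures,
    CompartmentParams,
    GateSpec,
    apply_gates,
    calibrate_gates,
    classify_field,
    define_compartments,
    extract_features,
    ratio_distribution,
    segment_nuclei,
    well_percentage,
)
from transloc.synthetic import FieldSpec, generate_field


def disk_labels(radius: float, size: int = 32, center=None, label: int = 1) -> np.ndarray:
    c = (size // 2, size // 2) if center is None else center
    yy, xx = np.mgrid[0:size, 0:size]
    return (((xx - c[1]) ** 2 + (yy - c[0]) ** 2) <= radius**2).astype(np.int32) * label


class TestSegmentNuclei:
    def test_two_disks_two_labels(self):
        img = np.zeros((64, 64))
        img[10:20, 10:20] = 100.0
        img[40:50, 40:50] = 100.0
        labels = segment_nuclei(img, min_area_px=10)
        assert labels.max() == 2
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_uniform_image_no_labels(self):
        labels = segment_nuclei(np.full((32, 32), 7.0))
        assert labels.max() == 0

    def test_nonfinite_rejected(self):
        img = np.zeros((8, 8))
        img[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            segment_nuclei(img)

    def test_min_area_filter(self):
        img = np.zeros((32, 32))
        img[5, 5] = 100.0  # 1-px speck
        img[15:25, 15:25] = 100.0
        labels = segment_nuclei(img, min_area_px=10)
        assert labels.max() == 1

    def test_synthetic_field_recovers_truth_centroids(self, clean_field):
        spec, fld = clean_field
        labels = segment_nuclei(fld.stain_channel, min_area_px=20)
        assert labels.max() == spec.n_cells
        from scipy import ndimage

        centroids = ndimage.center_of_mass(labels > 0, labels, range(1, labels.max() + 1))
        truth = {(round(c.y), round(c.x)) for c in fld.truth}
        for cy, cx in centroids:
            nearest = min(np.hypot(cy - ty, cx - tx) for ty, tx in truth)
            assert nearest <= 2.0


class TestDefineCompartments:
    def test_single_disk_matches_exhaustive_oracle(self):
        labels = disk_labels(6)
        cm = define_compartments(labels, 2, 1, 1)
        eroded_o, rings_o = brute_force_compartments(labels, 2, 1, 1)
        assert pixel_set(cm.nuclear_masks[1]) == eroded_o[1]
        assert pixel_set(cm.ring_masks[1]) == rings_o[1]

    @pytest.mark.parametrize(
        "erosion,dist,width", [(0, 0, 1), (1, 1, 1), (2, 1, 1), (3, 2, 1), (2, 0, 2)]
    )
    def test_fixture_shapes_match_oracle(self, erosion, dist, width):
        # hand-built 32x32 masks: disk, ellipse, square, two close disks,
        # off-center blob
        yy, xx = np.mgrid[0:32, 0:32]
        shapes = [
            disk_labels(6),
            ((((xx - 16) / 8.0) ** 2 + ((yy - 16) / 5.0) ** 2) <= 1).astype(np.int32),
            (np.logical_and(abs(xx - 16) <= 5, abs(yy - 16) <= 5)).astype(np.int32),
            (((xx - 9) ** 2 + (yy - 16) ** 2) <= 25).astype(np.int32)
            + 2 * (((xx - 23) ** 2 + (yy - 16) ** 2) <= 25).astype(np.int32),
            (((xx - 8) ** 2 + (yy - 8) ** 2) <= 16).astype(np.int32),
        ]
        for labels in shapes:
            cm = define_compartments(labels, erosion, dist, width)
            eroded_o, rings_o = brute_force_compartments(labels, erosion, dist, width)
            for lab in cm.nuclear_masks:
                assert pixel_set(cm.nuclear_masks[lab]) == eroded_o[lab]
                assert pixel_set(cm.ring_masks[lab]) == rings_o[lab]
            surviving = {lab for lab, s in eroded_o.items() if s}
            assert set(cm.nuclear_masks) == surviving

    def test_ring_is_contour_with_zero_params(self):
        labels = disk_labels(5)
        cm = define_compartments(labels, 0, 0, 1)
        ring = pixel_set(cm.ring_masks[1])
        # 4-adjacent background pixels of the disk (Euclidean distance 1)
        expected = set()
        fg = set(zip(*np.nonzero(labels)))
        for y, x in fg:
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if (y + dy, x + dx) not in fg:
                    expected.add((y + dy, x + dx))
        assert ring == expected

    def test_small_disk_erased_by_erosion(self):
        labels = disk_labels(2)
        cm = define_compartments(labels, 3, 1, 1)
        assert 1 not in cm.nuclear_masks
        assert cm.excluded[1] == "erased_by_erosion"

    def test_disjointness_and_unique_assignment(self):
        # two nearby nuclei: rings must not overlap each other or any nucleus
        labels = disk_labels(5, center=(16, 9)) + 2 * disk_labels(5, center=(16, 23))
        cm = define_compartments(labels, 2, 1, 2)
        ring1, ring2 = pixel_set(cm.ring_masks[1]), pixel_set(cm.ring_masks[2])
        assert ring1.isdisjoint(ring2)
        nuclei = set(zip(*np.nonzero(labels)))
        assert ring1.isdisjoint(nuclei) and ring2.isdisjoint(nuclei)
        for lab in (1, 2):
            assert pixel_set(cm.nuclear_masks[lab]).isdisjoint(pixel_set(cm.ring_masks[lab]))


class TestExtractFeatures:
    def test_disk_circularity_band(self):
        # rasterized disk of radius 10; band fixed from the Crofton estimator
        labels = disk_labels(10, size=64)
        cm = define_compartments(labels, 2, 1, 1)
        feats, _ = extract_features(cm, np.ones((64, 64)))
        assert len(feats) == 1
        assert 0.85 <= feats[0].circularity <= 1.1

    def test_uniform_gfp(self):
        labels = disk_labels(6)
        cm = define_compartments(labels, 2, 1, 1)
        feats, _ = extract_features(cm, np.full((32, 32), 5.0))
        f = feats[0]
        assert f.sd_gfp == 0.0
        assert f.nc_ratio == pytest.approx(1.0)

    def test_clean_field_ratio_recovery(self, clean_field):
        spec, fld = clean_field
        labels = segment_nuclei(fld.stain_channel, min_area_px=20)
        cm = define_compartments(labels, 2, 1, 1)
        feats, _ = extract_features(cm, fld.gfp_channel)
        states = {}
        for f in feats:
            from scipy import ndimage

            cy, cx = ndimage.center_of_mass(labels == f.cell_id)
            truth = min(fld.truth, key=lambda c: np.hypot(c.y - cy, c.x - cx))
            states[f.cell_id] = truth.state
            expected = (
                spec.intensity.ratio_nuclear_state
                if truth.state == "nuclear"
                else spec.intensity.ratio_cytoplasmic_state
            )
            assert f.nc_ratio == pytest.approx(expected, rel=0.02)

    def test_border_cell_excluded(self):
        labels = disk_labels(6, size=32, center=(3, 16))
        cm = define_compartments(labels, 2, 1, 1)
        feats, excluded = extract_features(cm, np.ones((32, 32)))
        assert feats == []
        assert excluded[1] == "touches_border"

    def test_shape_mismatch(self):
        cm = define_compartments(disk_labels(6), 2, 1, 1)
        with pytest.raises(ValueError, match="dimensions"):
            extract_features(cm, np.ones((8, 8)))


def make_cell(**kw) -> CellFeatures:
    base = dict(
        cell_id=1,
        nucleus_area_px=100,
        perimeter_px=35.0,
        circularity=0.95,
        mean_nuc_gfp=400.0,
        mean_cyt_gfp=100.0,
        sd_gfp=50.0,
        nc_ratio=4.0,
    )
    base.update(kw)
    return CellFeatures(**base)


class TestApplyGates:
    def test_high_ratio_is_nuclear(self):
        gates = GateSpec(theta_nc=1.0)
        assert apply_gates([make_cell()], gates)[1] == "nuclear"

    def test_low_circularity_excluded_regardless_of_intensity(self):
        gates = GateSpec(r01_circularity=Bounds(0.5, 1.1), theta_nc=1.0)
        cell = make_cell(circularity=0.2, mean_nuc_gfp=1e6)
        assert apply_gates([cell], gates)[1] == "excluded"

    def test_boundary_rule(self):
        gates = GateSpec(theta_nc=1.5, intercept=0.0)
        above = make_cell(cell_id=1, mean_nuc_gfp=151.0, mean_cyt_gfp=100.0)
        on_boundary = make_cell(cell_id=2, mean_nuc_gfp=150.0, mean_cyt_gfp=100.0)
        out = apply_gates([above, on_boundary], gates)
        assert out[1] == "nuclear"
        assert out[2] == "cytoplasmic"  # strict inequality: boundary is not nuclear

    def test_classification_matches_truth_on_clean_field(self, clean_field):
        spec, fld = clean_field
        feats, classes, dropped = classify_field(
            fld.stain_channel, fld.gfp_channel, GateSpec(theta_nc=1.5)
        )
        from scipy import ndimage

        labels = segment_nuclei(fld.stain_channel, min_area_px=20)
        mismatches = 0
        for f in feats:
            cy, cx = ndimage.center_of_mass(labels == f.cell_id)
            truth = min(fld.truth, key=lambda c: np.hypot(c.y - cy, c.x - cx))
            if classes[f.cell_id] != truth.state:
                mismatches += 1
        assert mismatches == 0

    @given(theta_lo=st.floats(0.5, 3.0), delta=st.floats(0.01, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_raising_threshold_never_adds_nuclear_cells(self, theta_lo, delta):
        rng = np.random.default_rng(0)
        cells = [
            make_cell(
                cell_id=i,
                mean_nuc_gfp=float(rng.uniform(10, 500)),
                mean_cyt_gfp=float(rng.uniform(10, 500)),
            )
            for i in range(40)
        ]
        lo = apply_gates(cells, GateSpec(theta_nc=theta_lo))
        hi = apply_gates(cells, GateSpec(theta_nc=theta_lo + delta))
        n_lo = sum(1 for v in lo.values() if v == "nuclear")
        n_hi = sum(1 for v in hi.values() if v == "nuclear")
        assert n_hi <= n_lo


class TestCalibrateGates:
    def test_control_population_passes_its_own_gates(self):
        rng = np.random.default_rng(1)
        cells = [
            make_cell(
                cell_id=i,
                perimeter_px=float(rng.uniform(30, 40)),
                circularity=float(rng.uniform(0.85, 1.0)),
                sd_gfp=float(rng.uniform(10, 60)),
            )
            for i in range(200)
        ]
        gates = calibrate_gates(cells)
        out = apply_gates(cells, gates)
        frac_excluded = sum(1 for v in out.values() if v == "excluded") / len(cells)
        assert frac_excluded <= 0.1  # only percentile tails get cut

    def test_outlier_rejected_by_calibrated_gates(self):
        cells = [make_cell(cell_id=i) for i in range(100)]
        gates = calibrate_gates(cells)
        blob = make_cell(cell_id=999, circularity=0.3, perimeter_px=200.0)
        assert apply_gates([blob], gates)[999] == "excluded"

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            calibrate_gates([])


class TestWellPercentage:
    def test_printed_formula(self):
        res = well_percentage({"A1": ["nuclear"] * 30 + ["cytoplasmic"] * 70})[0]
        assert res.pct_nuclear == 30.0

    def test_zero_nuclear(self):
        res = well_percentage({"A1": ["cytoplasmic"] * 50})[0]
        assert res.pct_nuclear == 0.0

    def test_excluded_not_in_denominator(self):
        res = well_percentage({"A1": ["nuclear"] * 10 + ["excluded"] * 5})[0]
        assert res.pct_nuclear == 100.0
        assert res.n_excluded == 5

    def test_no_classified_cells_is_missing_not_zero(self):
        res = well_percentage({"A1": ["excluded"] * 3})[0]
        assert res.pct_nuclear is None

    @given(
        n_nuc=st.integers(0, 200), n_cyt=st.integers(0, 200), n_exc=st.integers(0, 50)
    )
    @settings(max_examples=50, deadline=None)
    def test_percentages_sum_to_100(self, n_nuc, n_cyt, n_exc):
        classes = ["nuclear"] * n_nuc + ["cytoplasmic"] * n_cyt + ["excluded"] * n_exc
        res = well_percentage({"A1": classes})[0]
        if n_nuc + n_cyt == 0:
            assert res.pct_nuclear is None
        else:
            assert res.pct_nuclear + res.pct_cytoplasmic == 100.0


class TestRatioDistribution:
    def test_identical_cells_single_bin(self):
        counts, _ = ratio_distribution([make_cell(cell_id=i) for i in range(10)], bins=5)
        assert counts.sum() == 10
        assert (counts > 0).sum() == 1

    def test_single_bin_holds_all(self):
        cells = [make_cell(cell_id=i, nc_ratio=float(r)) for i, r in enumerate([1, 2, 3])]
        counts, _ = ratio_distribution(cells, bins=1)
        assert counts.tolist() == [3]

    def test_bimodal_mixture_two_modes(self, clean_field):
        spec, fld = clean_field
        labels = segment_nuclei(fld.stain_channel, min_area_px=20)
        cm = define_compartments(labels, 2, 1, 1)
        feats, _ = extract_features(cm, fld.gfp_channel)
        counts, edges = ratio_distribution(feats, bins=12)
        assert counts.sum() == len(feats)
        # the generator mixes ratios near 0.5 and 4.0: both extremes occupied,
        # intermediate bins empty
        centers = 0.5 * (edges[:-1] + edges[1:])
        occupied = centers[counts > 0]
        assert occupied.min() < 1.0 < 2.5 < occupied.max()
        assert np.any(counts[(centers > 1.0) & (centers < 2.5)] == 0)
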