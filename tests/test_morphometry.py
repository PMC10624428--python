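import numpy as np
import pytest
from scipy.spatial.distance import pdist

import sarcquant as sq
from sarcquant import phantoms as ph
from sarcquant.morphometry import measure_length, measure_orientation


class TestLabeling:
    def test_empty_mask(self, cal01):
        assert sq.label_structures(np.zeros((10, 10), dtype=bool), cal01) == []

    def test_two_disjoint_squares(self, cal01):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        structs = sq.label_structures(mask, cal01)
        assert len(structs) == 2
        for s in structs:
            assert s.area_um2 == pytest.approx(9 * 0.1**2)
        # deterministic id order: top-most first
        assert structs[0].centroid[1] > structs[1].centroid[1]

    def test_corner_touching_squares_are_one_component(self, cal01):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:4, 2:4] = True
        mask[4:6, 4:6] = True  # touches only at corner (3,3)-(4,4)
        structs = sq.label_structures(mask, cal01)
        assert len(structs) == 1
        assert structs[0].pixel_count == 8

    def test_pixel_count_conservation(self, cal01):
        rng = np.random.default_rng(11)
        mask = rng.random((60, 60)) > 0.6
        structs = sq.label_structures(mask, cal01)
        assert sum(s.pixel_count for s in structs) == int(mask.sum())


class TestMeasureLength:
    def test_single_pixel(self, cal01):
        assert measure_length(np.array([[5, 5]]), cal01) == 0.0

    def test_rectangle_matches_brute_force(self, cal01):
        rr, cc = np.mgrid[0:4, 0:30]
        pix = np.column_stack([rr.ravel(), cc.ravel()])
        got = measure_length(pix, cal01)
        assert got == pytest.approx(np.hypot(29, 3) * 0.1)
        assert got == pytest.approx(pdist(pix.astype(float)).max() * 0.1)

    def test_diagonal_run(self, cal01):
        pix = np.array([[k, k] for k in range(15)])
        got = measure_length(pix, cal01)
        assert got == pytest.approx(14 * np.sqrt(2) * 0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sets_match_pairwise_max(self, seed, cal01):
        rng = np.random.default_rng(seed)
        pix = rng.integers(0, 40, size=(rng.integers(2, 60), 2))
        got = measure_length(pix, cal01)
        assert got == pytest.approx(pdist(np.unique(pix, axis=0).astype(float)).max() * 0.1)


class TestOrientation:
    def test_horizontal_bar(self):
        pix = np.column_stack([np.ones(20, dtype=int), np.arange(20)])
        ang, degen = measure_orientation(pix)
        assert not degen
        assert ang == pytest.approx(0.0, abs=1e-9)

    def test_vertical_bar(self):
        pix = np.column_stack([np.arange(20), np.ones(20, dtype=int)])
        ang, degen = measure_orientation(pix)
        assert ang == pytest.approx(90.0, abs=1e-9)

    def test_single_pixel_degenerate(self):
        ang, degen = measure_orientation(np.array([[3, 3]]))
        assert degen and ang == 0.0

    @pytest.mark.parametrize("nominal", [10.0, 30.0, 55.0, 120.0, 170.0])
    def test_rendered_bar_angle(self, nominal):
        spec = ph.single_bar_phantom(2.0, cal_um_per_px=0.02, width_um=0.2,
                                     angle_deg=nominal)
        # widen the canvas so rotated bars stay inside
        spec = ph.PhantomSpec(
            shape_px=(261, 261), cal=spec.cal,
            elements={"actinin": [ph.Bar((2.6, -2.6), 2.0, 0.2, nominal)]},
        )
        masks, _ = ph.render(spec)
        s = sq.label_structures(masks["actinin"], spec.cal)[0]
        diff = abs(s.orientation_deg - nominal)
        assert min(diff, 180 - diff) < 2.0

    def test_length_rotation_consistency(self):
        # rendered bar's Feret length within 1 px·sqrt(2)·cal of nominal
        cal = 0.02
        for ang in range(0, 180, 15):
            spec = ph.PhantomSpec(
                shape_px=(261, 261), cal=sq.PixelCalibration(cal),
                elements={"actinin": [ph.Bar((2.6, -2.6), 2.0, 0.2, float(ang))]},
            )
            masks, _ = ph.render(spec)
            s = sq.label_structures(masks["actinin"], spec.cal)[0]
            # Feret of a finite-width bar can exceed nominal length by the diagonal
            assert abs(s.length_um - 2.0) <= np.hypot(2.0, 0.2) - 2.0 + np.sqrt(2) * cal


class TestClassification:
    @pytest.mark.parametrize(
        "length,stain,expected",
        [
            (1.5, "actinin", "candidate_line"),
            (1.4, "actinin", "candidate_body"),
            (1.39, "actinin", "candidate_body"),
            (1.7, "titin", "candidate_body"),
            (1.71, "titin", "candidate_line"),
            (1.4, "myomesin", "candidate_body"),
            (1.41, "myomesin", "candidate_line"),
        ],
    )
    def test_strict_threshold(self, length, stain, expected, default_params):
        s = sq.Structure(
            id=1, centroid=(0, 0), length_um=length, orientation_deg=0.0,
            orientation_degenerate=False, area_um2=0.5, aspect_ratio=5.0,
            has_hole=False, filled_area_um2=0.5, pixel_count=50,
        )
        assert sq.classify_structure(s, default_params, stain) == expected

    def test_titin_ring_precedence(self, default_params):
        s = sq.Structure(
            id=1, centroid=(0, 0), length_um=2.0, orientation_deg=0.0,
            orientation_degenerate=False, area_um2=1.0, aspect_ratio=1.1,
            has_hole=True, filled_area_um2=2.0, pixel_count=100,
        )
        assert sq.classify_structure(s, default_params, "titin") == "candidate_ring"
        # same structure without the hole is a line
        s.has_hole = False
        assert sq.classify_structure(s, default_params, "titin") == "candidate_line"

    def test_monotone_in_length(self, default_params):
        lengths = np.linspace(0.5, 3.0, 100)
        classes = []
        for L in lengths:
            s = sq.Structure(
                id=1, centroid=(0, 0), length_um=float(L), orientation_deg=0.0,
                orientation_degenerate=False, area_um2=0.5, aspect_ratio=5.0,
                has_hole=False, filled_area_um2=0.5, pixel_count=50,
            )
            classes.append(sq.classify_structure(s, default_params, "actinin"))
        first_line = classes.index("candidate_line")
        assert all(c == "candidate_line" for c in classes[first_line:])


class TestHoleTopology:
    def test_annulus_has_hole(self, cal01):
        spec = ph.PhantomSpec(
            shape_px=(61, 61), cal=cal01,
            elements={"titin": [ph.RingElement((3.0, -3.0), (2.0, 2.0), 0.4)]},
        )
        masks, _ = ph.render(spec)
        s = sq.label_structures(masks["titin"], cal01)[0]
        assert s.has_hole
        assert s.filled_area_um2 > s.area_um2

    def test_solid_disk_has_no_hole(self, cal01):
        spec = ph.PhantomSpec(
            shape_px=(41, 41), cal=cal01,
            elements={"actinin": [ph.Disk((2.0, -2.0), 2.0)]},
        )
        masks, _ = ph.render(spec)
        s = sq.label_structures(masks["actinin"], cal01)[0]
        assert not s.has_hole
        assert s.filled_area_um2 == pytest.approx(s.area_um2)
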