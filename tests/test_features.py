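import numpy as np
import pytest

from leaftooth import (
    PipelineConfig,
    aggregate_tooth_shape,
    classify_flank_shape,
    classify_sinus_shape,
    count_orders,
    extract_features,
    load_config,
    normalize_lengths,
    save_config,
    spacing_regularity,
)
from leaftooth.css import CSSParams, detect_corners
from leaftooth.features import _point_line_distance, analyze_mask, segment
from leaftooth.preprocess import extract_contour
from leaftooth.synthetic import SyntheticLeafSpec, generate_leaf

# the eight published mean sinus curvatures with their class labels
SINUS_REFERENCE = [
    (0.087059, "angular"),
    (0.078781, "angular"),
    (0.065193, "angular"),
    (0.061088, "angular"),
    (0.043190, "rounded"),
    (0.025086, "rounded"),
    (0.016129, "rounded"),
    (0.009013, "rounded"),
]


class TestToothLengthGeometry:
    def test_point_line_distance(self):
        # apex (0,10) against the chord through (-5,0) and (5,0): length 10
        assert _point_line_distance((0, 10), (-5, 0), (5, 0)) == pytest.approx(10)
        assert _point_line_distance((0, 0), (-5, 0), (5, 0)) == 0


class TestNormalizeLengths:
    @pytest.mark.parametrize(
        "lengths, expected",
        [
            ([10, 10, 10, 50], [1, 1, 1]),          # 50 > 2*mean, removed
            ([8, 4], [1.0, 0.5]),
            ([10, 10, 10, 20], [0.5, 0.5, 0.5, 1.0]),  # 20 == 2*mean, kept
        ],
    )
    def test_outlier_rule_and_scaling(self, lengths, expected):
        assert normalize_lengths(lengths) == pytest.approx(expected)


class TestCountOrders:
    @pytest.mark.parametrize(
        "normalized, expected",
        [
            ([1.0, 0.4, 0.4, 0.4, 0.9, 0.4], 2),   # 4 of 6 short
            ([1.0, 0.9, 0.95, 0.4, 0.45, 0.42], 1),  # tie at n/2 -> one order
            ([1.0], 1),
        ],
    )
    def test_order_rule(self, normalized, expected):
        n_orders, orders = count_orders(normalized)
        assert n_orders == expected
        if expected == 2:
            assert orders == [1 if v >= 0.5 else 2 for v in normalized]


class TestSpacingRegularity:
    @pytest.mark.parametrize(
        "distances, expected",
        [
            ([5, 6, 8], "regular"),       # 5 > 4.8
            ([3, 8], "irregular"),
            ([6, 10], "irregular"),       # exactly 0.6*max -> irregular
        ],
    )
    def test_rule(self, distances, expected):
        assert spacing_regularity(distances) == expected


class TestSinusShape:
    @pytest.mark.parametrize("value, label", SINUS_REFERENCE)
    def test_published_reference_labels(self, value, label):
        assert classify_sinus_shape(value) == label

    def test_boundary_is_rounded(self):
        assert classify_sinus_shape(0.05) == "rounded"


class TestAggregateToothShape:
    @pytest.mark.parametrize(
        "labels, expected",
        [(["cv", "cv", "st"], "cv"), (["st"], "st"), (["cv", "cc"], "cv"),
         (["rt", "fl"], "fl"), (["cc", "cc", "fl"], "cc")],
    )
    def test_majority_and_precedence(self, labels, expected):
        assert aggregate_tooth_shape(labels) == expected


class TestFlankShape:
    def _tooth_points(self, img):
        mask = segment(img)
        record, contour, curve, corners, tps = analyze_mask(mask)
        return mask, contour, tps

    def test_straight_flanks_classified_st(self, simple_leaf):
        _, img, _ = simple_leaf
        rec = extract_features(img)
        assert rec.tooth_shape == "st"

    def test_arc_end_swap_exchanges_fl_and_rt(self):
        """The S labels are anchored to which arc end is the apex."""
        spec = SyntheticLeafSpec(
            n_teeth=7, flank_style="rt", sinus_style="rounded",
            tooth_amplitude=65.0, seed=5,
        )
        img, _ = generate_leaf(spec)
        mask, contour, tps = self._tooth_points(img)
        checked = 0
        for k in range(tps.n_teeth):
            apex = tps.apices[k]
            sinus = tps.sinuses[k]
            if sinus is None:
                continue
            forward = classify_flank_shape(sinus, apex, contour, mask)
            if forward != "rt":
                continue
            swapped = classify_flank_shape(apex, sinus, contour, mask)
            assert swapped == "fl"
            checked += 1
        assert checked >= 3

    def test_mirroring_image_fixes_labels(self):
        """The region rule is apex-anchored, so mirroring changes nothing."""
        for style in ("rt", "cv"):
            spec = SyntheticLeafSpec(
                n_teeth=7 if style == "rt" else 10,
                flank_style=style,
                sinus_style="rounded" if style == "rt" else "angular",
                tooth_amplitude=65.0 if style == "rt" else 56.0,
                seed=9,
            )
            img, _ = generate_leaf(spec)
            rec = extract_features(img)
            rec_mirror = extract_features(np.fliplr(img).copy())
            assert rec.tooth_shape == style
            assert rec_mirror.tooth_shape == style


class TestFullPipeline:
    def test_synthetic_leaf_record_matches_spec(self, simple_leaf,
                                                simple_leaf_record):
        spec, _, gt = simple_leaf
        rec = simple_leaf_record
        assert rec.n_teeth == spec.n_teeth
        assert rec.n_orders == 1
        assert rec.spacing == "regular"
        assert rec.sinus_shape == "angular"
        assert rec.tooth_shape == "st"

    def test_two_order_leaf(self):
        spec = SyntheticLeafSpec(
            n_teeth=12, n_orders=2, order2_ratio=0.42, tooth_amplitude=62.0,
            blade_axes=(215.0, 185.0), seed=13,
        )
        img, gt = generate_leaf(spec)
        rec = extract_features(img)
        assert rec.n_orders == 2
        orders = [t.order for t in rec.per_tooth]
        assert orders.count(1) == len(gt.orders) - sum(o == 2 for o in gt.orders)

    def test_toothless_ellipse_image(self):
        img, gt = generate_leaf(SyntheticLeafSpec(n_teeth=0, seed=2))
        rec = extract_features(img)
        assert rec.n_teeth == 0
        assert rec.status == "toothless"
        assert rec.sinus_shape is None and rec.spacing is None

    def test_rotation_preserves_all_characters(self, simple_leaf,
                                               simple_leaf_record):
        _, img, _ = simple_leaf
        rec = simple_leaf_record
        rot = extract_features(np.rot90(img).copy())
        assert rot.n_teeth == rec.n_teeth
        assert rot.n_orders == rec.n_orders
        assert rot.spacing == rec.spacing
        assert rot.sinus_shape == rec.sinus_shape
        assert rot.tooth_shape == rec.tooth_shape


class TestConfig:
    def test_round_trip(self, tmp_path):
        cfg = PipelineConfig(
            css=CSSParams(delta=5.0, C=1.7, t_angle=150.0, gap_size=4.0),
            disk_radius=9, st_tol_factor=0.2, sinus_threshold=0.04,
            spacing_factor=0.55, normalize_size=480, polarity="dark",
            close_radius=3,
        )
        path = tmp_path / "params.cfg"
        save_config(cfg, path)
        loaded = load_config(path)
        assert loaded == cfg

    def test_defaults_round_trip(self, tmp_path):
        path = tmp_path / "params.cfg"
        save_config(PipelineConfig(), path)
        assert load_config(path) == PipelineConfig()
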