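import numpy as np
import pytest
from shapely.geometry import LineString

from monkeyhab.habitat_quality import (
    QUALITY_GRADE_LABELS,
    ThreatLayer,
    build_threat_layers,
    decay_influence,
    degradation,
    grade_quality,
    percent_of_grades,
    quality,
    rasterize_lines,
)
from monkeyhab.params import THREAT_NAMES, default_params
from monkeyhab.raster import Raster


def _lulc(codes, px=100.0):
    codes = np.asarray(codes)
    return Raster(codes, x_origin=0.0, y_origin=codes.shape[0] * px, pixel_size=px)


def _single_threat(presence, weight=0.7, d_max=1000.0, decay="exponential"):
    return [ThreatLayer(name="t", max_distance=d_max, weight=weight,
                        decay=decay, presence=np.asarray(presence, dtype=bool))]


class TestDecayInfluence:
    def test_zero_distance_is_one(self):
        assert decay_influence(0.0, 2000.0, "linear") == 1.0
        assert decay_influence(0.0, 2000.0, "exponential") == 1.0

    def test_linear_zero_at_max_distance(self):
        assert decay_influence(2000.0, 2000.0, "linear") == 0.0

    def test_exponential_at_max_distance(self):
        assert decay_influence(2000.0, 2000.0, "exponential") == pytest.approx(
            np.exp(-2.99), abs=1e-12
        )

    def test_zero_beyond_max_distance(self):
        assert decay_influence(2000.1, 2000.0, "exponential") == 0.0
        assert decay_influence(5000.0, 2000.0, "linear") == 0.0

    def test_vectorized_and_bounded(self, rng):
        d = rng.uniform(0, 5000, 1000)
        for decay in ("linear", "exponential"):
            infl = decay_influence(d, 2000.0, decay)
            assert np.all((infl >= 0) & (infl <= 1))

    def test_monotone_nonincreasing(self):
        d = np.linspace(0, 3000, 500)
        for decay in ("linear", "exponential"):
            infl = decay_influence(d, 2000.0, decay)
            assert np.all(np.diff(infl) <= 1e-15)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            decay_influence(-1.0, 100.0, "linear")

    def test_bad_dmax_and_decay_rejected(self):
        with pytest.raises(ValueError):
            decay_influence(1.0, 0.0, "linear")
        with pytest.raises(ValueError):
            decay_influence(1.0, 100.0, "gaussian")


class TestBuildThreatLayers:
    def _scene(self, small_scene):
        from monkeyhab.synthetic_data import INDICATOR_CODES
        from monkeyhab.village_development import (
            comprehensive_score, fit_pca, grade_villages, standardize_indicators,
        )

        v = small_scene.villages
        z = comprehensive_score(
            fit_pca(standardize_indicators(v[list(INDICATOR_CODES)]), min_retain=1)
        )
        return v[["x", "y"]].to_numpy(), grade_villages(z)

    def test_twelve_layers_in_canonical_order(self, small_scene):
        xy, grades = self._scene(small_scene)
        layers = build_threat_layers(xy, grades, small_scene.roads, small_scene.lulc)
        assert [l.name for l in layers] == list(THREAT_NAMES)
        for l in layers:
            assert l.presence.shape == small_scene.lulc.shape

    def test_absent_grade_gives_all_zero_layer(self, small_scene):
        xy, grades = self._scene(small_scene)
        grades = np.full_like(grades, "II")  # nothing in grade VII
        layers = build_threat_layers(xy, grades, [], small_scene.lulc)
        vii = next(l for l in layers if l.name == "village_vii")
        assert not vii.presence.any()
        ii = next(l for l in layers if l.name == "village_ii")
        assert ii.presence.any()

    def test_uniform_cropland_presence_everywhere(self):
        lulc = _lulc(np.full((10, 10), 7))
        layers = build_threat_layers(np.empty((0, 2)), np.array([], dtype=object),
                                     [], lulc)
        crop = next(l for l in layers if l.name == "cropland")
        assert crop.presence.all()

    def test_landcover_threat_source_codes(self):
        data = np.full((4, 4), 11)
        data[0, 0], data[1, 1], data[2, 2], data[3, 3] = 1, 8, 7, 14
        layers = build_threat_layers(np.empty((0, 2)), np.array([], dtype=object),
                                     [], _lulc(data))
        by_name = {l.name: l for l in layers}
        assert by_name["other_nonforest"].presence[0, 0]
        assert by_name["economic_forest"].presence[1, 1]
        assert by_name["cropland"].presence[2, 2]
        assert by_name["artificial_construction"].presence[3, 3]
        assert by_name["other_nonforest"].presence.sum() == 1

    def test_invalid_grade_rejected(self, small_scene):
        xy, grades = self._scene(small_scene)
        grades = grades.astype(object)
        grades[0] = "VIII"
        with pytest.raises(ValueError, match="I-VII"):
            build_threat_layers(xy, grades, [], small_scene.lulc)

    def test_table5_distances_and_decays(self, small_scene):
        xy, grades = self._scene(small_scene)
        layers = build_threat_layers(xy, grades, [], small_scene.lulc)
        by_name = {l.name: l for l in layers}
        assert by_name["village_road"].max_distance == 4000.0
        assert by_name["village_road"].decay == "linear"
        assert by_name["village_i"].max_distance == 2000.0
        assert by_name["cropland"].max_distance == 1000.0

    def test_road_rasterization_marks_traversed_pixels(self):
        lulc = _lulc(np.full((10, 10), 11))
        road = LineString([(50.0, 950.0), (950.0, 950.0)])  # along the top row
        mask = rasterize_lines([road], lulc)
        assert mask[0, :].all()
        assert mask.sum() == 10


class TestDegradation:
    def test_no_presence_gives_zero(self):
        lulc = _lulc(np.full((8, 8), 4))
        d = degradation(lulc, _single_threat(np.zeros((8, 8))))
        assert np.all(d.data == 0.0)

    def test_insensitive_class_gives_zero(self):
        lulc = _lulc(np.full((8, 8), 7))  # cropland: zero sensitivity to all
        pres = np.zeros((8, 8), dtype=bool)
        pres[4, 4] = True
        layers = build_threat_layers(np.empty((0, 2)), np.array([], dtype=object),
                                     [], lulc)
        d = degradation(lulc, layers)
        assert np.all(d.data == 0.0)

    def test_single_threat_on_source_pixel(self):
        # sole threat => w/sum_w = 1; on-source influence = 1; S = 0.9
        params = default_params()
        lulc = _lulc(np.full((5, 5), 4))
        pres = np.zeros((5, 5), dtype=bool)
        pres[2, 2] = True
        layers = _single_threat(pres, weight=0.7, d_max=1000.0)
        params["landcover"][4]["sensitivity"] = [0.9] * 12
        d = degradation(lulc, layers, params)
        assert d.data[2, 2] == pytest.approx(0.9)

    def test_bounded_zero_one(self, small_scene):
        from monkeyhab.synthetic_data import INDICATOR_CODES
        from monkeyhab.village_development import (
            comprehensive_score, fit_pca, grade_villages, standardize_indicators,
        )

        v = small_scene.villages
        z = comprehensive_score(
            fit_pca(standardize_indicators(v[list(INDICATOR_CODES)]), min_retain=1)
        )
        layers = build_threat_layers(
            v[["x", "y"]].to_numpy(), grade_villages(z),
            small_scene.roads, small_scene.lulc,
        )
        d = degradation(small_scene.lulc, layers)
        assert np.nanmin(d.data) >= 0.0
        assert np.nanmax(d.data) <= 1.0

    def test_grid_mismatch_rejected(self):
        lulc = _lulc(np.full((8, 8), 4))
        with pytest.raises(ValueError, match="mismatch"):
            degradation(lulc, _single_threat(np.zeros((5, 5))))

    def test_unknown_code_rejected(self):
        lulc = _lulc(np.full((4, 4), 99))
        with pytest.raises(ValueError, match="unknown land-cover"):
            degradation(lulc, _single_threat(np.zeros((4, 4))))

    def test_matches_bruteforce_nearest_source(self, rng):
        # oracle equivalence on random small scenes, exact
        params = default_params()
        for _ in range(25):
            codes = rng.integers(1, 15, size=(15, 15))
            lulc = _lulc(codes)
            pres = rng.random((15, 15)) < 0.1
            d_max = float(rng.choice([500.0, 1000.0, 2000.0]))
            decay = str(rng.choice(["linear", "exponential"]))
            layers = _single_threat(pres, d_max=d_max, decay=decay)
            got = degradation(lulc, layers, params)
            expected = _bruteforce_degradation(lulc, layers[0], params)
            assert np.array_equal(got.data, expected)


def _bruteforce_degradation(lulc, layer, params):
    """Literal per-pixel nearest-source search (test oracle)."""
    rows, cols = lulc.shape
    px = lulc.pixel_size
    sens = {c: spec["sensitivity"][0] for c, spec in params["landcover"].items()}
    # a single-threat list: normalized weight is 1
    src = np.argwhere(layer.presence)
    out = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            if src.size:
                dmin = np.inf
                for sr, sc in src:
                    dd = np.sqrt(((r - sr) * px) ** 2 + ((c - sc) * px) ** 2)
                    dmin = min(dmin, dd)
                infl = decay_influence(dmin, layer.max_distance, layer.decay)
            else:
                infl = 0.0
            out[r, c] = infl * sens[int(lulc.data[r, c])]
    return out


class TestQuality:
    def test_no_degradation_gives_suitability(self):
        lulc = _lulc(np.full((6, 6), 4))
        d = lulc.like(np.zeros((6, 6)))
        q = quality(d, lulc)
        assert np.all(q.data == 1.0)

    def test_zero_suitability_gives_zero(self):
        lulc = _lulc(np.full((6, 6), 7))
        d = lulc.like(np.full((6, 6), 0.8))
        q = quality(d, lulc)
        assert np.all(q.data == 0.0)

    def test_half_saturation_identity(self):
        lulc = _lulc(np.full((4, 4), 11))  # H = 1
        d = lulc.like(np.full((4, 4), 0.5))  # D = k
        q = quality(d, lulc)
        assert np.allclose(q.data, 0.5, atol=1e-12)

    def test_bounded_by_suitability(self, rng):
        codes = rng.integers(1, 15, size=(12, 12))
        lulc = _lulc(codes)
        d = lulc.like(rng.uniform(0, 1, size=(12, 12)))
        q = quality(d, lulc)
        lut = {c: s["suitability"] for c, s in default_params()["landcover"].items()}
        h = np.vectorize(lut.get)(codes)
        assert np.all(q.data <= h + 1e-12)
        assert np.all(q.data >= 0)

    def test_invalid_k_rejected(self):
        lulc = _lulc(np.full((3, 3), 4))
        with pytest.raises(ValueError, match="positive"):
            quality(lulc.like(np.zeros((3, 3))), lulc, k=0.0)

    def test_grid_mismatch_rejected(self):
        lulc = _lulc(np.full((3, 3), 4))
        other = _lulc(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="grid"):
            quality(other, lulc)


class TestGradeQuality:
    @pytest.mark.parametrize("q,label", [
        (0.0, "very poor"), (0.19, "very poor"), (0.2, "poor"),
        (0.4679, "medium"), (0.6, "good"), (0.8, "excellent"), (1.0, "excellent"),
    ])
    def test_interval_assignment(self, q, label):
        lulc = _lulc(np.full((2, 2), 4))
        grades, table, _ = grade_quality(lulc.like(np.full((2, 2), q)))
        code = int(grades.data[0, 0])
        assert QUALITY_GRADE_LABELS[code - 1] == label

    def test_percentages_sum_to_100(self, rng):
        lulc = _lulc(np.zeros((20, 20)))
        q = lulc.like(rng.uniform(0, 1, size=(20, 20)))
        _, table, _ = grade_quality(q)
        assert table["percent"].sum() == pytest.approx(100.0, abs=0.01)

    def test_area_arithmetic(self):
        lulc = _lulc(np.zeros((10, 10)), px=1000.0)  # 1 km pixels
        q = lulc.like(np.full((10, 10), 0.9))
        _, table, mean_q = grade_quality(q)
        excellent = table.set_index("label").loc["excellent"]
        assert excellent["area_km2"] == pytest.approx(100.0)
        assert excellent["percent"] == pytest.approx(100.0)
        assert mean_q == pytest.approx(0.9)

    def test_out_of_range_rejected(self):
        lulc = _lulc(np.zeros((2, 2)))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            grade_quality(lulc.like(np.full((2, 2), 1.5)))

    def test_nodata_excluded(self):
        lulc = _lulc(np.zeros((2, 2)))
        data = np.array([[0.9, np.nan], [np.nan, 0.1]])
        _, table, mean_q = grade_quality(lulc.like(data))
        assert table["percent"].sum() == pytest.approx(100.0)
        assert mean_q == pytest.approx(0.5)

    def test_percent_of_grades_helper(self):
        import pandas as pd

        table = pd.DataFrame({
            "label": ["very poor", "poor", "medium", "good", "excellent"],
            "percent": [51.94, 3.08, 15.13, 13.24, 16.60],
        })
        assert percent_of_grades(table, ["good", "excellent"]) == pytest.approx(29.84)
        with pytest.raises(KeyError):
            percent_of_grades(table, ["amazing"])


class TestMonotonicity:
    def _quality_for(self, lulc, presences, d_max=2000.0, weight=0.7):
        layers = _single_threat(presences, weight=weight, d_max=d_max)
        d = degradation(lulc, layers)
        return quality(d, lulc)

    def test_adding_threat_pixel_never_increases_quality(self, rng):
        for _ in range(20):
            codes = rng.integers(1, 15, size=(15, 15))
            lulc = _lulc(codes)
            pres = rng.random((15, 15)) < 0.05
            q0 = self._quality_for(lulc, pres)
            pres2 = pres.copy()
            free = np.argwhere(~pres2)
            r, c = free[rng.integers(len(free))]
            pres2[r, c] = True
            q1 = self._quality_for(lulc, pres2)
            assert np.all(q1.data <= q0.data + 1e-12)

    def test_locality_beyond_max_distance(self, rng):
        codes = rng.integers(1, 15, size=(30, 30))
        lulc = _lulc(codes)  # 100 m pixels
        pres = np.zeros((30, 30), dtype=bool)
        pres[0, 0] = True
        q0 = self._quality_for(lulc, pres, d_max=500.0)
        pres2 = pres.copy()
        pres2[1, 1] = True
        q1 = self._quality_for(lulc, pres2, d_max=500.0)
        xs, ys = lulc.cell_centers()
        changed_x = lulc.x_origin + 1.5 * lulc.pixel_size
        changed_y = lulc.y_origin - 1.5 * lulc.pixel_size
        dist = np.hypot(xs - changed_x, ys - changed_y)
        far = dist > 500.0
        assert np.array_equal(q0.data[far], q1.data[far])

    def test_village_upgrade_weakly_decreases_quality(self, rng):
        # one village upgraded I -> VII: weight 0.4 -> 0.95
        codes = rng.integers(1, 15, size=(20, 20))
        lulc = _lulc(codes)
        xy = np.array([[1050.0, 950.0]])
        for before, after in [("I", "VII")]:
            layers_lo = build_threat_layers(xy, np.array([before], dtype=object), [], lulc)
            layers_hi = build_threat_layers(xy, np.array([after], dtype=object), [], lulc)
            q_lo = quality(degradation(lulc, layers_lo), lulc)
            q_hi = quality(degradation(lulc, layers_hi), lulc)
        assert np.all(q_hi.data <= q_lo.data + 1e-12)
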