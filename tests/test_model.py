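import json
import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from nerveseg import (Contour, DistributionSpec, PackingError,
                      TissueConductivity, Trajectory, build_geometry,
                      generate_db_nerve, recruitment_curve, titrate,
                      titration_search)
from nerveseg.contours import ContourSet
from nerveseg.model import (DEFAULT_CONDUCTIVITIES, export_geometry_json,
                            read_conductivity_config,
                            write_conductivity_config)


def circle_contour(r, cx=0.0, cy=0.0, n=360, cls="axon", cid=1) -> Contour:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)]),
                   tissue_class=cls, id=cid)


class TestBuildGeometry:
    def test_single_axon_sweeps_along_one_cm(self):
        cs = {"axon": ContourSet([circle_contour(10.0)])}
        geom = build_geometry(cs, pixel_size_um=0.1)
        assert len(geom.features) == 1
        assert len(geom.fiber_splines) == 1
        spline = geom.fiber_splines[0]
        assert geom.trajectory.length_um == pytest.approx(10_000.0)
        assert np.linalg.norm(spline.path_um[-1] - spline.path_um[0]) == (
            pytest.approx(10_000.0))

    def test_umf_cap_at_one_micron(self):
        # perimeter-based diameter 1.5 um -> exported at exactly 1 um
        c = circle_contour(7.5, cls="umf")
        geom = build_geometry({"umf": ContourSet([c])}, pixel_size_um=0.1)
        assert geom.fiber_splines[0].diameter_um == 1.0

    def test_small_umf_not_touched(self):
        c = circle_contour(4.0, cls="umf")  # diameter 0.8 um at 0.1 um/px
        geom = build_geometry({"umf": ContourSet([c])}, pixel_size_um=0.1)
        assert geom.fiber_splines[0].diameter_um == pytest.approx(0.8, rel=1e-3)

    def test_endoneurium_gets_table_conductivity(self):
        c = circle_contour(50.0, cls="endoneurium")
        geom = build_geometry({"endoneurium": ContourSet([c])}, 0.1)
        assert geom.features[0].conductivity_s_per_m == 0.2651

    def test_missing_conductivity_raises(self):
        c = circle_contour(5.0, cls="mystery tissue")
        with pytest.raises(ValueError):
            build_geometry({"mystery tissue": ContourSet([c])}, 0.1)

    def test_class_conserving_and_cap_never_increases(self):
        rng = np.random.default_rng(0)
        sets = {}
        for cls in ("axon", "umf", "endoneurium"):
            contours = [circle_contour(rng.uniform(3, 12), cx=40.0 * i,
                                       cls=cls, cid=i + 1)
                        for i in range(4)]
            sets[cls] = ContourSet(contours)
        geom = build_geometry(sets, pixel_size_um=0.1)
        from nerveseg import estimate_diameter

        per_class = {}
        for f in geom.features:
            per_class[f.tissue_class] = per_class.get(f.tissue_class, 0) + 1
        assert per_class == {"axon": 4, "umf": 4, "endoneurium": 4}
        for cls, cs in sets.items():
            splines = [s for s in geom.fiber_splines if s.tissue_class == cls]
            for c, s in zip(cs.contours, splines):
                raw = estimate_diameter(c, 0.1)
                assert s.diameter_um <= raw + 1e-9

    def test_export_roundtrip(self, tmp_path):
        geom = build_geometry({"axon": ContourSet([circle_contour(10.0)])}, 0.1)
        export_geometry_json(geom, tmp_path / "scene.json")
        with open(tmp_path / "scene.json") as fh:
            payload = json.load(fh)
        assert payload["trajectory_length_um"] == pytest.approx(10_000.0)
        assert payload["electrode"]["wire_diameter_um"] == 0.127
        assert {"biphasic_250us", "biphasic_1000us"} <= set(
            payload["pulse_presets"])


class TestConductivityConfig:
    def test_defaults_roundtrip(self, tmp_path):
        cond = TissueConductivity()
        write_conductivity_config(cond, tmp_path / "cond.cfg")
        back = read_conductivity_config(tmp_path / "cond.cfg")
        assert back.values == DEFAULT_CONDUCTIVITIES

    def test_override_and_positivity(self, tmp_path):
        (tmp_path / "c.cfg").write_text("fat = 0.05\n# comment\n")
        assert read_conductivity_config(tmp_path / "c.cfg")["fat"] == 0.05
        with pytest.raises(ValueError):
            TissueConductivity({"fat": -1.0})


class TestGenerateDbNerve:
    def test_zero_fibers_gives_only_boundaries(self):
        sets = generate_db_nerve(DistributionSpec(seed=1))
        assert sets["myelinated fiber"].contours == []
        assert sets["unmyelinated fiber"].contours == []
        assert len(sets["endoneurium"].top_level()) == 1

    def test_oversized_fiber_raises_packing_error(self):
        spec = DistributionSpec(n_unmyelinated=1,
                                unmyelinated_diameter_mean_um=50.0,
                                unmyelinated_diameter_sd_um=0.0,
                                max_attempts=50, seed=0)
        with pytest.raises(PackingError):
            generate_db_nerve(spec)

    def test_statistics_containment_overlap_and_determinism(self):
        spec = DistributionSpec(n_myelinated=100, n_unmyelinated=100,
                                myelinated_diameter_mean_um=2.0,
                                myelinated_diameter_sd_um=0.5,
                                unmyelinated_diameter_mean_um=1.0,
                                unmyelinated_diameter_sd_um=0.3, seed=3)
        sets = generate_db_nerve(spec)
        my = sets["myelinated fiber"].top_level()
        um = sets["unmyelinated fiber"].top_level()
        assert len(my) == 100 and len(um) == 100
        d = np.array([c.perimeter / math.pi for c in my])
        se = 0.5 / math.sqrt(100)
        assert abs(d.mean() - 2.0) < 3 * se
        # exhaustive overlap / containment checks
        endo = Polygon(sets["endoneurium"].top_level()[0].points)
        discs = [(c.centroid(), c.perimeter / (2 * math.pi)) for c in my + um]
        for (c, r) in discs:
            assert endo.contains(Point(c).buffer(0.999 * r, quad_segs=8))
        for i in range(len(discs)):
            for j in range(i + 1, len(discs)):
                (x1, y1), r1 = discs[i]
                (x2, y2), r2 = discs[j]
                assert (x1 - x2) ** 2 + (y1 - y2) ** 2 > (r1 + r2) ** 2 * 0.999
        rerun = generate_db_nerve(spec)
        for cls in sets:
            for a, b in zip(sets[cls].contours, rerun[cls].contours):
                assert np.array_equal(a.points, b.points)

    def test_myelinated_fibers_carry_inner_circle(self):
        sets = generate_db_nerve(DistributionSpec(n_myelinated=5, seed=2))
        cs = sets["myelinated fiber"]
        outers = cs.top_level()
        assert len(outers) == 5
        for o in outers:
            holes = cs.holes_of(o.id)
            assert len(holes) == 1
            g = holes[0].perimeter / o.perimeter
            assert 0.05 <= g <= 0.95

    def test_dbc_variant_uses_equal_area_circles(self):
        sq = np.array([[0, 0], [40.0, 0], [40.0, 40.0], [0, 40.0]])
        spec = DistributionSpec(endoneurium_um=sq * 0.8 + 4.0,
                                epineurium_um=sq,
                                circular_boundaries=True, seed=0)
        sets = generate_db_nerve(spec)
        endo = sets["endoneurium"].top_level()[0]
        from nerveseg import circularity

        assert circularity(endo) > 0.99
        assert Polygon(endo.points).area == pytest.approx((40 * 0.8) ** 2,
                                                          rel=0.01)


class TestTitration:
    def test_pointwise_product(self):
        assert titrate(2.0, 3.0, 0.5) == pytest.approx(3.0)
        assert np.all(titrate(np.ones(5), 0.0, np.ones(5)) == 0.0)
        phi = np.array([1.0, -2.0, 0.5])
        assert np.allclose(titrate(phi, 1.0, np.ones(3)), phi)
        with pytest.raises(ValueError):
            titrate(1.0, -0.1, 1.0)

    @pytest.mark.parametrize("threshold", [0.003, 0.7, 2.0, 9.9])
    def test_search_recovers_step_threshold(self, threshold):
        t = titration_search(lambda T: T >= threshold, T_max=10.0, tol=0.01)
        assert t >= threshold
        assert (t - threshold) / threshold <= 0.011

    def test_search_agrees_with_linear_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            thr = rng.uniform(0.05, 9.5)
            t = titration_search(lambda T: T >= thr, T_max=10.0, tol=0.01)
            grid = np.arange(0.001 * 10.0, 10.0, 0.001 * 10.0)
            oracle = grid[grid >= thr][0]
            assert abs(t - oracle) <= 0.011 * max(t, oracle) + 0.01

    def test_never_fires_returns_infinity(self):
        assert titration_search(lambda T: False, 10.0) == math.inf

    def test_always_fires_returns_near_zero(self):
        assert titration_search(lambda T: True, 10.0) <= 0.01 * 10.0

    def test_non_monotone_predicate_detected(self):
        # fires at low scales but not at T_max: violates the contract
        with pytest.raises(RuntimeError):
            titration_search(lambda T: T < 6.0, T_max=10.0)


class TestRecruitmentCurve:
    def test_counting_fractions(self):
        res = recruitment_curve([1, 2, 4], 100.0, [100, 200, 400])
        assert np.allclose(res.fractions, [1 / 3, 2 / 3, 1.0])

    def test_step_when_all_equal(self):
        res = recruitment_curve([2, 2, 2], 100.0, [150, 199, 200, 300])
        assert res.fractions.tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_grid_below_thresholds_is_zero(self):
        res = recruitment_curve([5, 6], 100.0, [10, 20, 30])
        assert not res.fractions.any()

    def test_monotone_bounded_and_saturates(self):
        rng = np.random.default_rng(1)
        T = rng.lognormal(0, 0.5, 50)
        grid = np.linspace(0, 110 * T.max(), 300)
        res = recruitment_curve(T, 100.0, grid, kde=True)
        assert np.all(np.diff(res.fractions) >= 0)
        assert res.fractions[0] >= 0.0 and res.fractions[-1] == 1.0
        assert res.density is not None and np.all(res.density >= 0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            recruitment_curve([], 100.0, [1.0])
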