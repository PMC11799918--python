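"""Functional metrics: hand-computable oracles, phantom parameter recovery,
rotation equivariance."""

import numpy as np
import pytest

from lvdose import metrics as mx
from lvdose import phantom as ph
from lvdose.views import PlanarView, estimate_long_axis, resample_views
from lvdose.volumes import Grid, LabelVolume


def make_ring_view(r_endo_mm, r_epi_mm, n=160, spacing=1.0, center=(0.0, 0.0)):
    """Synthetic SAX view: circular cavity of radius r_endo inside a ring."""
    c = (n - 1) / 2.0
    ii, jj = np.mgrid[:n, :n]
    rr = np.hypot((ii - c) * spacing - center[0], (jj - c) * spacing - center[1])
    labels = np.zeros((n, n), np.uint8)
    labels[rr <= r_epi_mm] = 1
    labels[rr <= r_endo_mm] = 2
    masks = np.stack([
        np.clip(rr - r_epi_mm + 0.5, 0, 1),
        np.clip(r_epi_mm - rr + 0.5, 0, 1) * np.clip(rr - r_endo_mm + 0.5, 0, 1),
        np.clip(r_endo_mm - rr + 0.5, 0, 1),
    ]).astype(np.float32)
    return PlanarView(key="SAX_test", center=np.zeros(3),
                      axes=np.array([[1.0, 0, 0], [0, 1.0, 0]]),
                      normal=np.array([0, 0, 1.0]), spacing=spacing,
                      labels=labels, masks=masks)


class TestDice:
    def _cube(self, offset=0):
        grid = Grid((6, 6, 6), (1, 1, 1))
        arr = np.zeros(grid.shape, np.uint8)
        arr[1 + offset:3 + offset, 1:3, 1:3] = 2
        return LabelVolume(array=arr, grid=grid)

    def test_identical_masks(self):
        a = self._cube()
        assert mx.dice(a, a, 2) == 1.0

    def test_disjoint_masks(self):
        assert mx.dice(self._cube(), self._cube(offset=3), 2) == 0.0

    def test_offset_cubes_give_half(self):
        # 2x2x2 cubes offset by one voxel: |A|=|B|=8, overlap 4 -> 0.5
        assert mx.dice(self._cube(), self._cube(offset=1), 2) == 0.5

    def test_symmetry_and_empty_convention(self):
        a, b = self._cube(), self._cube(offset=1)
        assert mx.dice(a, b, 2) == mx.dice(b, a, 2)
        assert mx.dice(a, b, 1) == 1.0  # class 1 absent from both

    def test_grid_mismatch_rejected(self):
        a = self._cube()
        other = LabelVolume(array=np.zeros((6, 6, 6), np.uint8), grid=Grid((6, 6, 6), (2, 2, 2)))
        with pytest.raises(ValueError, match="grid"):
            mx.dice(a, other, 2)


class TestEjectionFraction:
    def test_arithmetic_on_known_volumes(self):
        grid = Grid((24, 20, 20), (2.5, 2.5, 2.5))  # 15.625 uL voxels
        ed = np.zeros(grid.shape, np.uint8)
        es = np.zeros(grid.shape, np.uint8)
        ed.ravel()[:9600] = 2   # EDV = 150 mL
        es.ravel()[:3840] = 2   # ESV = 60 mL
        ef = mx.ejection_fraction(LabelVolume(array=ed, grid=grid),
                                  LabelVolume(array=es, grid=grid))
        assert ef == pytest.approx(60.0)

    def test_identical_phases_give_zero(self, default_phases):
        labels = default_phases["ED"][0]
        assert mx.ejection_fraction(labels, labels) == 0.0

    def test_empty_edv_rejected(self):
        grid = Grid((4, 4, 4), (1, 1, 1))
        empty = LabelVolume(array=np.zeros(grid.shape, np.uint8), grid=grid)
        with pytest.raises(ValueError, match="EDV"):
            mx.ejection_fraction(empty, empty)

    def test_phantom_ef_recovers_analytic_value(self, default_spec, default_phases):
        ef = mx.ejection_fraction(default_phases["ED"][0], default_phases["ES"][0])
        gt = ph.analytic_ground_truth(default_spec)
        assert ef == pytest.approx(gt.ef_pct, abs=1.0)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert mx.pearson(x, x) == pytest.approx(1.0)
        assert mx.pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        # brute force: cov = mean(xy) - mean x mean y = 7.0 - 6.25 = 0.75
        # sd_x = sd_y = sqrt(1.25) -> rho = 0.75/1.25 = 0.6
        assert mx.pearson(x, y) == pytest.approx(0.6, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mx.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSyntheticViews:
    def test_circular_cavity_cs_scales_with_radius(self):
        ed = make_ring_view(25.0, 35.0)
        es = make_ring_view(20.0, 32.0)
        assert mx.circumferential_strain(ed, es) == pytest.approx(-20.0, abs=0.5)

    def test_identical_views_zero_cs_and_wt(self):
        v = make_ring_view(25.0, 35.0)
        assert mx.circumferential_strain(v, v) == 0.0
        spokes, avg = mx.wall_thickening(v, v)
        assert avg == pytest.approx(0.0, abs=0.5)

    def test_obliterated_cavity_flags_minus_100(self):
        ed = make_ring_view(25.0, 35.0)
        es = make_ring_view(25.0, 35.0)
        es.masks[2][...] = 0.0
        assert mx.circumferential_strain(ed, es) == mx.OBLITERATION_CS

    def test_uniform_ring_thickening_forty_percent(self):
        ed = make_ring_view(25.0, 35.0)   # t = 10 mm
        es = make_ring_view(21.0, 35.0)   # t = 14 mm
        spokes, avg = mx.wall_thickening(ed, es)
        assert len(spokes) == 16
        assert np.nanmax(np.abs(spokes - 40.0)) < 3.0
        assert avg == pytest.approx(40.0, abs=1.5)

    def test_wall_thickness_profile_in_mm(self):
        v = make_ring_view(25.0, 35.0)
        t = mx.wall_thickness_profile(v)
        assert t.shape == (16,)
        assert np.allclose(t, 10.0, atol=0.8)


class TestGLS:
    def test_phantom_long_scale_recovered(self, fine_grid):
        spec = ph.PhantomSpec(es_long_scale=0.85, es_radial_scale=0.8)
        edl, _ = ph.voxelize_phase(spec, "ED", fine_grid)
        esl, _ = ph.voxelize_phase(spec, "ES", fine_grid)
        axis = estimate_long_axis(edl)
        g = mx.gls(resample_views(edl, None, axis), resample_views(esl, None, axis))
        assert g == pytest.approx(-15.0, abs=1.0)

    def test_identical_views_zero(self, default_phases):
        labels = default_phases["ED"][0]
        axis = estimate_long_axis(labels)
        views = resample_views(labels, None, axis)
        assert mx.gls(views, views) == 0.0


class TestComputeAll:
    def test_identity_deformation_all_metrics_near_zero(self, fine_grid):
        spec = ph.PhantomSpec(es_radial_scale=1.0, es_long_scale=1.0)
        edl, _ = ph.voxelize_phase(spec, "ED", fine_grid)
        esl, _ = ph.voxelize_phase(spec, "ES", fine_grid)
        fm = mx.compute_all(edl, esl)
        assert abs(fm.ef_pct) <= 1.0
        assert abs(fm.gls_pct) <= 1.0
        assert all(abs(v) <= 1.0 for v in fm.cs_pct.values())
        assert all(abs(v) <= 1.0 for v in fm.wt_avg_pct.values())

    def test_default_phantom_recovers_analytic_ground_truth(
            self, default_spec, default_phases):
        fm = mx.compute_all(default_phases["ED"][0], default_phases["ES"][0])
        gt = ph.analytic_ground_truth(default_spec)
        assert fm.ef_pct == pytest.approx(gt.ef_pct, abs=1.0)
        assert fm.gls_pct == pytest.approx(gt.gls_pct, abs=1.0)
        for lvl in ("basal", "middle", "apical"):
            assert fm.cs_pct[lvl] == pytest.approx(gt.cs_pct[lvl], abs=1.0)
            assert fm.wt_avg_pct[lvl] == pytest.approx(gt.wt_pct[lvl], abs=2.0)
        assert all(len(v) == 16 for v in fm.wt_spokes_pct.values())

    def test_rotation_equivariance(self, default_spec, fine_grid):
        """Metrics of the same anatomy measured in two generic orientations
        agree within the per-metric resampling tolerances (1 pp; 2 pp for
        wall thickening).  Generic poses are compared because the canonical
        axis-aligned pose carries a grid-alignment quantisation bias of its
        own that a rotation test would otherwise conflate with orientation
        dependence."""
        def rotation(seed):
            rng = np.random.default_rng(seed)
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            return [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y),
                    2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x),
                    2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]

        results = {}
        for tag, seed in (("A", 17), ("B", 18)):
            spec = ph.PhantomSpec.from_dict(
                {**default_spec.to_dict(), "orientation": rotation(seed)})
            edl, _ = ph.voxelize_phase(spec, "ED", fine_grid)
            esl, _ = ph.voxelize_phase(spec, "ES", fine_grid)
            results[tag] = mx.compute_all(edl, esl).as_flat_dict()
        for key in results["A"]:
            tol = 2.0 if key.startswith("wt") else 1.0
            assert results["B"][key] == pytest.approx(results["A"][key], abs=tol), key
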