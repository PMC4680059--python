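"""Thickness measurement and CDI computation against analytic phantoms."""

import numpy as np
import pytest

from cdi import coords, measure, synthetic
from cdi.measure import CdiResult, ThicknessMeasurement, compute_cdi
from cdi.synthetic import LesionSpec, PhantomSpec
from tests.conftest import make_locset

SMALL = dict(n_slices=40, in_plane_shape=(96, 120))

# posterior measurement sites: the oblique-interface region the informative
# locations live in (the condylar apex is a documented resolution limit)
POSTERIOR_SITES = [(u, v) for u in (0.55, 0.65, 0.75, 0.85) for v in (0.3, 0.5, 0.7)]


class TestMeasureThickness:
    def test_uniform_phantom_posterior_accuracy(self, femur_phantom, femur_frame):
        for loc in POSTERIOR_SITES:
            m = measure.measure_thickness(femur_phantom.volume, femur_frame, loc)
            assert m.thickness_mm == pytest.approx(2.0, abs=0.15)

    def test_uniform_phantom_tibia_accuracy(self, tibia_phantom, tibia_frame):
        for u in (0.15, 0.3, 0.5, 0.7, 0.85):
            for v in (0.25, 0.5, 0.75):
                m = measure.measure_thickness(tibia_phantom.volume, tibia_frame, (u, v))
                assert m.thickness_mm == pytest.approx(1.8, abs=0.15)

    def test_uniform_phantom_global_bound(self, femur_phantom, femur_frame):
        """Everywhere (incl. the flat apex) error stays below one row voxel."""
        for u in np.linspace(0.1, 0.9, 9):
            for v in (0.3, 0.5, 0.7):
                m = measure.measure_thickness(femur_phantom.volume, femur_frame, (u, v))
                assert abs(m.thickness_mm - 2.0) < femur_phantom.volume.dy

    def test_full_thickness_lesion_reads_zero(self):
        lesion = LesionSpec(center_uv=(0.7, 0.5), extent_uv=(0.2, 0.2))
        res = synthetic.rasterize_phantom(
            PhantomSpec(surface="tibia", base_thickness_mm=1.8, lesions=(lesion,), **SMALL)
        )
        frame = coords.build_surface_frame(res.volume, "tibia")
        m = measure.measure_thickness(res.volume, frame, (0.7, 0.5))
        assert m.thickness_mm == 0.0

    def test_linear_wedge_field(self):
        """t(u) = 1 + 2u sampled at u = 0.7 reads 2.4 mm."""
        res = synthetic.rasterize_phantom(
            PhantomSpec(
                surface="tibia",
                thickness_field=lambda u, v: 1.0 + 2.0 * u,
                **SMALL,
            )
        )
        frame = coords.build_surface_frame(res.volume, "tibia")
        m = measure.measure_thickness(res.volume, frame, (0.7, 0.5))
        assert m.thickness_mm == pytest.approx(2.4, abs=0.15)

    def test_off_surface_location_raises(self, femur_phantom):
        frame = coords.SurfaceFrame(surface="femur", medial_slice=0, lateral_slice=1)
        with pytest.raises(coords.OffSurfaceError):
            measure.measure_thickness(femur_phantom.volume, frame, (0.5, 0.5))


def _measurement(surface, t, L, ml=0.7):
    return ThicknessMeasurement(
        surface=surface, location=(0.5, 0.5), slice_index=0,
        thickness_mm=t, ap_length_mm=L, ml_factor_mm=ml,
    )


class TestComputeCdi:
    def test_single_location_arithmetic(self):
        """t=2 mm, L=10 mm, ml=0.7 mm, height 1.70 m -> 2*10*0.7/1.70."""
        res = compute_cdi(
            [_measurement("femur", 2.0, 10.0), _measurement("tibia", 0.0, 0.0)],
            height_m=1.70,
        )
        assert res.femur_cdi == pytest.approx(2 * 10 * 0.7 / 1.70)
        assert res.femur_cdi == pytest.approx(8.2353, abs=1e-4)
        assert res.total_cdi == res.femur_cdi

    def test_all_zero_thickness_gives_zero(self):
        res = compute_cdi(
            [_measurement("femur", 0.0, 5.0), _measurement("tibia", 0.0, 5.0)],
            height_m=1.6,
        )
        assert res.femur_cdi == res.tibia_cdi == res.total_cdi == 0.0

    def test_doubling_thickness_doubles_cdi(self):
        ms1 = [_measurement("femur", 1.5, 8.0), _measurement("tibia", 1.1, 6.0)]
        ms2 = [_measurement(m.surface, 2 * m.thickness_mm, m.ap_length_mm) for m in ms1]
        r1, r2 = compute_cdi(ms1, 1.7), compute_cdi(ms2, 1.7)
        assert r2.femur_cdi == pytest.approx(2 * r1.femur_cdi)
        assert r2.tibia_cdi == pytest.approx(2 * r1.tibia_cdi)

    def test_height_scaling_exact(self):
        ms = [_measurement("femur", 2.0, 10.0), _measurement("tibia", 1.5, 8.0)]
        c = 1.25
        r1, r2 = compute_cdi(ms, 1.6), compute_cdi(ms, 1.6 * c)
        assert r2.total_cdi == pytest.approx(r1.total_cdi / c)

    def test_invalid_height_raises(self):
        with pytest.raises(ValueError):
            compute_cdi([_measurement("femur", 1, 1), _measurement("tibia", 1, 1)], 0.0)

    def test_missing_surface_raises(self):
        with pytest.raises(ValueError):
            compute_cdi([_measurement("femur", 1, 1)], 1.7)

    def test_total_is_sum_invariant(self):
        res = CdiResult(femur_cdi=3.0, tibia_cdi=2.0, height_m=1.7)
        assert res.total_cdi == 5.0


class TestCdiOracle:
    def closed_form_cdi(self, truth, locset, thickness, ml, height, volume):
        """Independent closed form: sum over cells of t x L x ml / h with L
        counted from the phantom's known rectangular column domain."""
        c0, c1 = truth.domain_cols
        cols = np.arange(c0, c1 + 1)
        u_cols = (cols - c0) / (c1 - c0)
        total = 0.0
        for (u, v), (cu0, _cv0, cdu, _cdv) in zip(locset.locations, locset.cells):
            in_cell = (u_cols >= cu0) & (u_cols < cu0 + cdu)
            L = in_cell.sum() * volume.dx
            total += thickness * L * ml / height
        return total

    @pytest.mark.parametrize("surface,thickness", [("femur", 2.0), ("tibia", 1.8)])
    def test_cdi_matches_closed_form(self, surface, thickness, posterior_locsets,
                                     femur_phantom, tibia_phantom):
        phantom = femur_phantom if surface == "femur" else tibia_phantom
        frame = coords.build_surface_frame(phantom.volume, surface)
        ms = measure.measure_at_locations(phantom.volume, frame, posterior_locsets[surface])
        got = sum(m.contribution_mm3 for m in ms) / 1.70
        expected = self.closed_form_cdi(
            phantom.truth, posterior_locsets[surface], thickness, 0.7, 1.70,
            phantom.volume,
        )
        assert got == pytest.approx(expected, rel=0.05)

    def test_zero_thickness_phantom_gives_exact_zero(self, posterior_locsets):
        res = synthetic.rasterize_phantom(
            PhantomSpec(surface="tibia", base_thickness_mm=0.0, **SMALL)
        )
        frame = coords.build_surface_frame(res.volume, "tibia")
        ms = measure.measure_at_locations(res.volume, frame, posterior_locsets["tibia"])
        assert all(m.thickness_mm == 0.0 for m in ms)
        assert sum(m.contribution_mm3 for m in ms) == 0.0


class TestLesionSensitivity:
    def test_identical_volumes_zero_change(self, tibia_phantom, femur_phantom,
                                           posterior_locsets):
        vols = {"femur": femur_phantom.volume, "tibia": tibia_phantom.volume}
        base, follow, change = measure.cdi_for_pair(vols, vols, posterior_locsets, 1.70)
        assert change == {"femur": 0.0, "tibia": 0.0, "total": 0.0}
        assert base.total_cdi == follow.total_cdi > 0

    def test_lesion_on_location_removes_its_contribution(self, femur_phantom,
                                                         posterior_locsets):
        locset = posterior_locsets["femur"]
        cell = locset.cells[4]  # center location's cell
        lesion = LesionSpec(
            center_uv=(cell[0] + cell[2] / 2, cell[1] + cell[3] / 2),
            extent_uv=(cell[2], cell[3]),
        )
        lesioned = synthetic.rasterize_phantom(
            PhantomSpec(surface="femur", base_thickness_mm=2.0, lesions=(lesion,), **SMALL)
        )
        frame_b = coords.build_surface_frame(femur_phantom.volume, "femur")
        ms_b = measure.measure_at_locations(femur_phantom.volume, frame_b, locset)
        frame_f = coords.build_surface_frame(lesioned.volume, "femur")
        ms_f = measure.measure_at_locations(lesioned.volume, frame_f, locset)
        height = 1.70
        change = (
            sum(m.contribution_mm3 for m in ms_f) - sum(m.contribution_mm3 for m in ms_b)
        ) / height
        contribution = ms_b[4].contribution_mm3 / height
        # thickness tolerance propagated through the contribution formula
        tol = (0.15 * ms_b[4].ap_length_mm * 0.7) / height + 0.15 * contribution
        assert change < 0
        assert change == pytest.approx(-contribution, abs=tol)

    def test_disjoint_lesion_is_a_blind_spot(self, femur_phantom, posterior_locsets):
        """A lesion outside every location cell leaves the CDI unchanged:
        the method's designed blind spot."""
        locset = posterior_locsets["femur"]
        lesion = LesionSpec(center_uv=(0.15, 0.5), extent_uv=(0.1, 0.2))
        lesioned = synthetic.rasterize_phantom(
            PhantomSpec(surface="femur", base_thickness_mm=2.0, lesions=(lesion,), **SMALL)
        )
        frame_b = coords.build_surface_frame(femur_phantom.volume, "femur")
        frame_f = coords.build_surface_frame(lesioned.volume, "femur")
        cdi_b = sum(
            m.contribution_mm3
            for m in measure.measure_at_locations(femur_phantom.volume, frame_b, locset)
        )
        cdi_f = sum(
            m.contribution_mm3
            for m in measure.measure_at_locations(lesioned.volume, frame_f, locset)
        )
        assert cdi_f == pytest.approx(cdi_b, rel=0.01)


class TestFastMode:
    def test_fast_measurement_matches_grid(self, posterior_locsets):
        cohort = synthetic.generate_cohort(synthetic.CohortSpec(n_per_grade=2, seed=0))
        rec = cohort.baseline()[0]
        res = measure.measure_record(rec, posterior_locsets)
        for m in res.measurements:
            u, v = m.location
            assert m.thickness_mm == rec.models[m.surface].thickness_at(u, v)

    def test_noise_floor_keeps_denuded_zero(self, posterior_locsets, rng):
        spec = synthetic.CohortSpec(
            n_per_grade=2, lesion_prob_by_grade=(1.0, 1.0, 1.0, 1.0), seed=1
        )
        cohort = synthetic.generate_cohort(spec)
        for rec in cohort.baseline():
            res = measure.measure_record(rec, posterior_locsets, rng=rng, noise_sd=0.5)
            for m in res.measurements:
                u, v = m.location
                if rec.models[m.surface].thickness_at(u, v) == 0.0:
                    assert m.thickness_mm == 0.0
                assert m.thickness_mm >= 0.0
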