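import numpy as np
import pytest

from transitqa.plan_perturbation import (
    Beam,
    ControlPoint,
    PlanError,
    central_pair_indices,
    make_fixture_plan,
    perturb_plan,
    project_aperture,
    read_rtplan,
    write_rtplan,
)


def plans_equal(a, b) -> bool:
    for ba, bb in zip(a.beams, b.beams):
        if ba.collimator_angle_deg != bb.collimator_angle_deg or ba.mu != bb.mu:
            return False
        for ca, cb in zip(ba.control_points, bb.control_points):
            if not (np.array_equal(ca.bank_a_mm, cb.bank_a_mm)
                    and np.array_equal(ca.bank_b_mm, cb.bank_b_mm)
                    and ca.jaw_x_mm == cb.jaw_x_mm and ca.jaw_y_mm == cb.jaw_y_mm):
                return False
    return True


class TestModelValidation:
    def test_bank_order_enforced(self):
        with pytest.raises(PlanError):
            ControlPoint(np.array([5.0]), np.array([-5.0]), (-10, 10), (-10, 10))

    def test_jaw_order_enforced(self):
        with pytest.raises(PlanError):
            ControlPoint(np.array([-5.0]), np.array([5.0]), (10, -10), (-10, 10))

    def test_leaf_count_consistency(self):
        cp1 = ControlPoint(np.full(4, -5.0), np.full(4, 5.0), (-10, 10), (-10, 10))
        cp2 = ControlPoint(np.full(5, -5.0), np.full(5, 5.0), (-10, 10), (-10, 10))
        with pytest.raises(PlanError):
            Beam(0.0, 100.0, [cp1, cp2])


class TestDicomRoundTrip:
    def test_fixture_roundtrips_bitwise_on_modeled_fields(self, tmp_path):
        plan = make_fixture_plan(n_pairs=10, n_control_points=2,
                                 collimator_angle_deg=15.0, mu=123.5)
        path = str(tmp_path / "plan.dcm")
        write_rtplan(plan, path)
        assert plans_equal(read_rtplan(path), plan)

    def test_perturb_write_read_shows_exact_deltas(self, tmp_path):
        plan = make_fixture_plan(n_pairs=10)
        perturbed = perturb_plan(plan, "mlc_gap_mm", 1.5)
        path = str(tmp_path / "perturbed.dcm")
        write_rtplan(perturbed, path)
        back = read_rtplan(path)
        cp0, cpb = plan.beams[0].control_points[0], back.beams[0].control_points[0]
        np.testing.assert_allclose(cpb.bank_a_mm, cp0.bank_a_mm - 0.75)
        np.testing.assert_allclose(cpb.bank_b_mm, cp0.bank_b_mm + 0.75)

    def test_template_passthrough_preserves_extra_attributes(self, tmp_path):
        import pydicom

        plan = make_fixture_plan()
        path = str(tmp_path / "orig.dcm")
        write_rtplan(plan, path)
        ds = pydicom.dcmread(path)
        ds.RTPlanLabel = "my-special-label"
        ds.save_as(path, little_endian=True, implicit_vr=False)
        out = str(tmp_path / "modified.dcm")
        write_rtplan(perturb_plan(plan, "mu_pct", 2.0), out, template=path)
        assert pydicom.dcmread(out).RTPlanLabel == "my-special-label"

    def test_missing_mlc_is_format_error(self, tmp_path):
        import pydicom

        plan = make_fixture_plan()
        path = str(tmp_path / "plan.dcm")
        write_rtplan(plan, path)
        ds = pydicom.dcmread(path)
        ds.BeamSequence[0].BeamLimitingDeviceSequence = \
            ds.BeamSequence[0].BeamLimitingDeviceSequence[:2]
        bad = str(tmp_path / "bad.dcm")
        ds.save_as(bad, little_endian=True, implicit_vr=False)
        with pytest.raises(PlanError, match="MLC"):
            read_rtplan(bad)


class TestPerturbations:
    def test_mu_scaling_exact(self):
        plan = make_fixture_plan(mu=100.0)
        assert perturb_plan(plan, "mu_pct", 2.0).beams[0].mu == 102.0
        assert perturb_plan(plan, "mu_pct", -2.0).beams[0].mu == 98.0

    def test_symmetric_gap_split(self):
        plan = make_fixture_plan(gap_mm=20.0)  # pairs at (-10, +10)
        out = perturb_plan(plan, "mlc_gap_mm", 1.5)
        cp = out.beams[0].control_points[0]
        assert cp.bank_a_mm[0] == -10.75 and cp.bank_b_mm[0] == 10.75

    def test_central_variant_touches_middle_third_only(self):
        plan = make_fixture_plan(n_pairs=9, gap_mm=20.0)
        out = perturb_plan(plan, "mlc_gap_central_mm", 5.0)
        gaps = out.beams[0].control_points[0].gaps()
        assert np.count_nonzero(gaps > 20.0) == 3
        np.testing.assert_array_equal(np.nonzero(gaps > 20.0)[0], [3, 4, 5])

    def test_gap_involution_without_clamping(self):
        plan = make_fixture_plan(gap_mm=20.0)
        back = perturb_plan(perturb_plan(plan, "mlc_gap_mm", 3.0), "mlc_gap_mm", -3.0)
        assert plans_equal(back, plan)

    def test_independent_errors_commute(self):
        plan = make_fixture_plan()
        ab = perturb_plan(perturb_plan(plan, "mu_pct", 2.0), "collimator_deg", 1.0)
        ba = perturb_plan(perturb_plan(plan, "collimator_deg", 1.0), "mu_pct", 2.0)
        assert plans_equal(ab, ba)

    def test_erosion_clamps_narrow_pairs_and_warns(self):
        from transitqa.plan_perturbation import Beam, ControlPoint, PlanModel

        a = np.array([-2.0, -2.0, -2.0, -10.0, -10.0, -10.0, -10.0])
        b = -a
        plan = PlanModel([Beam(0.0, 100.0, [ControlPoint(a, b, (-30, 30), (-30, 30))])])
        with pytest.warns(UserWarning, match="clamped"):
            out = perturb_plan(plan, "mlc_gap_mm", -6.0)
        gaps = out.beams[0].control_points[0].gaps()
        np.testing.assert_allclose(gaps[:3], 0.0, atol=1e-12)  # 4 mm pairs close
        np.testing.assert_allclose(gaps[3:], 14.0)  # 20 mm pairs erode to 14

    def test_erosion_closing_every_pair_is_an_error(self):
        plan = make_fixture_plan(gap_mm=4.0)
        with pytest.raises(PlanError, match="closed every"):
            perturb_plan(plan, "mlc_gap_mm", -6.0)

    def test_closed_pairs_not_moved(self):
        plan = make_fixture_plan(gap_mm=0.2)  # below the closed-pair threshold
        out = perturb_plan(plan, "mlc_gap_mm", 2.0)
        assert plans_equal(out, plan)

    def test_retract_exposes_jaw_rectangle(self):
        # leaf stack spans the jaws, so the retracted aperture is the jaw box
        plan = make_fixture_plan(n_pairs=14, gap_mm=20.0, jaw_half_mm=30.0)
        out = perturb_plan(plan, "retract_mlc")
        mask = project_aperture(out.beams[0], shape=(101, 101))
        assert abs(mask.sum() - 60.0 * 60.0) < 1.0
        base = project_aperture(plan.beams[0], shape=(101, 101))
        assert np.all(mask >= base - 1e-12)


class TestApertureProjection:
    def test_rectangle_area_is_leaf_jaw_intersection(self):
        # leaves open to +-20 in x, jaws clip y to +-25: area = 40 x 50
        plan = make_fixture_plan(n_pairs=14, gap_mm=40.0, jaw_half_mm=25.0)
        mask = project_aperture(plan.beams[0], shape=(101, 101))
        assert abs(mask.sum() - 40.0 * 50.0) < 0.5

    def test_subpixel_edges_weighted(self):
        plan = make_fixture_plan(gap_mm=21.0)  # edges at +-10.5 between pixel centers
        mask = project_aperture(plan.beams[0], shape=(101, 101))
        assert np.any((mask > 0.0) & (mask < 1.0))
        assert abs(mask.sum() - 21.0 * 50.0) < 0.5

    def test_one_degree_rotation_preserves_area(self):
        plan = make_fixture_plan(n_pairs=14, gap_mm=30.0, jaw_half_mm=35.0)
        base = project_aperture(plan.beams[0], shape=(121, 121))
        rot = perturb_plan(plan, "collimator_deg", 1.0)
        rotated = project_aperture(rot.beams[0], shape=(121, 121), supersample=8)
        assert abs(rotated.sum() - base.sum()) / base.sum() < 0.005

    def test_closed_plan_gives_empty_mask(self):
        plan = make_fixture_plan(gap_mm=0.0001)
        mask = project_aperture(plan.beams[0], shape=(101, 101))
        assert mask.sum() < 0.1


class TestCentralBand:
    def test_middle_third_of_open_pairs(self):
        open_mask = np.array([False, True, True, True, True, True, True, False])
        np.testing.assert_array_equal(central_pair_indices(open_mask), [3, 4])

    def test_at_least_one_pair(self):
        open_mask = np.array([False, True, False])
        np.testing.assert_array_equal(central_pair_indices(open_mask), [1])
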