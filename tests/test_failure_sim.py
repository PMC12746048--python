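import numpy as np
import pytest

from transitqa import DoseImage
from transitqa.failure_sim import (
    BeamModel,
    DegenerateScenarioError,
    PatientModel,
    SuiteConfig,
    apply_anatomy_error,
    apply_linac_error,
    export_suite,
    generate_suite,
    load_suite,
    lung_patient,
    random_breast_patient,
    surrogate_ptv_dmean,
    sub_seed,
    transit_dose,
)
from transitqa.plan_perturbation import make_fixture_plan


def slab_patient(thickness: float, n: int = 64) -> PatientModel:
    ptv = np.zeros((n, n), dtype=bool)
    ptv[n // 2 - 5:n // 2 + 5, n // 2 - 5:n // 2 + 5] = True
    return PatientModel(np.full((n, n), float(thickness)), ptv)


def open_beam(**kwargs) -> BeamModel:
    geom = make_fixture_plan(n_pairs=14, gap_mm=50.0, jaw_half_mm=30.0).beams[0]
    defaults = dict(mu=1.0, output_per_mu=10.0, penumbra_sigma_mm=1.0,
                    mu_atten_per_mm=0.005)
    defaults.update(kwargs)
    return BeamModel(geom, **defaults)


class TestForwardModel:
    def test_zero_thickness_gives_open_air_output(self):
        beam = open_beam(penumbra_sigma_mm=0.5)
        dose = transit_dose(slab_patient(0.0), beam)
        center = dose.values[32, 32]
        np.testing.assert_allclose(center, beam.output_per_mu * beam.mu, rtol=1e-3)

    def test_uniform_slab_attenuates_exponentially(self):
        beam = open_beam(penumbra_sigma_mm=0.5)
        dose = transit_dose(slab_patient(200.0), beam)  # mu * t = 1
        np.testing.assert_allclose(dose.values[32, 32],
                                   beam.output_per_mu * np.exp(-1.0), rtol=1e-3)

    def test_linear_in_mu(self):
        patient = slab_patient(120.0)
        d1 = transit_dose(patient, open_beam(mu=1.0))
        d2 = transit_dose(patient, open_beam(mu=2.0))
        np.testing.assert_allclose(d2.values, 2.0 * d1.values, rtol=1e-12)

    def test_retracted_mlc_dose_dominates_base(self):
        patient = slab_patient(150.0)
        base = open_beam()
        retracted = apply_linac_error(base, "mlc_retracted")
        d0 = transit_dose(patient, base).values
        d1 = transit_dose(patient, retracted).values
        assert np.all(d1 >= d0 - 1e-12)


class TestSurrogateLabel:
    def test_identity_gives_zero_delta(self):
        patient, beam = slab_patient(100.0), open_beam()
        d = surrogate_ptv_dmean(patient, beam)
        assert d > 0
        assert surrogate_ptv_dmean(patient, beam) == d

    def test_mu_scaling_is_exact(self):
        patient, beam = slab_patient(100.0), open_beam()
        base = surrogate_ptv_dmean(patient, beam)
        err = surrogate_ptv_dmean(patient, apply_linac_error(beam, "mu_scale", 2.0))
        np.testing.assert_allclose(100.0 * (err - base) / base, 2.0, atol=1e-9)

    def test_bolus_removal_closed_form(self):
        # removing 10 mm of unit-density bolus halves at mid-depth:
        # dose ratio = exp(+mu * 5 mm)
        patient = slab_patient(100.0)
        patient.region_masks["bolus"] = np.ones(patient.shape, dtype=bool)
        beam = open_beam()
        base = surrogate_ptv_dmean(patient, beam)
        removed = apply_anatomy_error(patient, "bolus_removed", {"thickness_mm": 10.0})
        err = surrogate_ptv_dmean(removed, beam)
        np.testing.assert_allclose(err / base, np.exp(0.005 * 5.0), rtol=1e-9)

    def test_no_overlap_is_degenerate(self):
        patient = slab_patient(100.0)
        patient.ptv_mask[:] = False
        patient.ptv_mask[0, 0] = True  # far outside the aperture
        with pytest.raises(DegenerateScenarioError):
            surrogate_ptv_dmean(patient, open_beam(penumbra_sigma_mm=0.5))


class TestAnatomyErrors:
    def test_bolus_removal_is_involutive(self):
        patient = random_breast_patient(5, with_bolus=True)
        removed = apply_anatomy_error(patient, "bolus_removed", {"thickness_mm": 10.0})
        restored = apply_anatomy_error(removed, "bolus_removed", {"thickness_mm": -10.0})
        np.testing.assert_allclose(restored.thickness_map, patient.thickness_map,
                                   atol=1e-12)

    def test_zero_breath_shift_is_identity(self):
        patient = lung_patient(0.0)
        shifted = apply_anatomy_error(patient, "breath_shift", {"displacement_mm": 0.0})
        np.testing.assert_array_equal(shifted.region_masks["lung"],
                                      patient.region_masks["lung"])
        np.testing.assert_array_equal(shifted.region_masks["gtv"],
                                      patient.region_masks["gtv"])

    def test_breath_shift_off_grid_raises(self):
        patient = lung_patient(0.0)
        with pytest.raises(ValueError, match="GTV"):
            apply_anatomy_error(patient, "breath_shift", {"displacement_mm": 400.0})

    def test_fluid_change_toggles_density(self):
        from transitqa.failure_sim import effusion_patient

        wet = effusion_patient(True)
        dry = apply_anatomy_error(wet, "fluid_change", {"region": "fluid", "density": 0.30})
        assert dry.densities["fluid"] == 0.30
        assert np.all(dry.effective_thickness() <= wet.effective_thickness() + 1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            apply_anatomy_error(lung_patient(), "teleportation", {})


class TestBreathingSigns:
    def test_expiration_planned_inspiration_delivered_raises_transit_dose(self):
        # soft-tissue GTV moves out from under the planning PTV: the beam is
        # less attenuated there, so the delivered transit dose is higher
        cfg = SuiteConfig(modes=("breathing",))
        suite = {s.scenario_id: s for s in generate_suite(cfg, seed=2)}
        sc = suite["breath_exp_to_insp"]
        amp = sc.parameters["amplitude_mm"]
        planned = lung_patient(amp)
        delivered = lung_patient(0.0)
        vacated = planned.region_masks["gtv"] & ~delivered.region_masks["gtv"]
        assert vacated.any()
        assert sc.evaluated.values[vacated].mean() > sc.reference.values[vacated].mean()
        # converse pairing: soft tissue newly replaces lung where the GTV
        # arrives, so the delivered transit dose is lower there
        sc2 = suite["breath_insp_to_exp"]
        planned2 = lung_patient(0.0)
        delivered2 = lung_patient(amp)
        newly2 = delivered2.region_masks["gtv"] & ~planned2.region_masks["gtv"]
        assert newly2.any()
        assert sc2.evaluated.values[newly2].mean() < sc2.reference.values[newly2].mean()


class TestSuite:
    def test_sub_seed_stable(self):
        assert sub_seed(1, "a") == sub_seed(1, "a")
        assert sub_seed(1, "a") != sub_seed(2, "a")
        assert 0 <= sub_seed(123, "anything") < 2**31

    def test_subset_counts(self):
        assert len(generate_suite(SuiteConfig(modes=("breathing",)), 0)) == 6
        assert len(generate_suite(SuiteConfig(modes=("patient_id",)), 0)) == 2

    def test_determinism_bitwise(self):
        cfg = SuiteConfig(modes=("bolus", "patient_id"))
        a = generate_suite(cfg, seed=9)
        b = generate_suite(cfg, seed=9)
        for sa, sb in zip(a, b):
            assert sa.scenario_id == sb.scenario_id
            np.testing.assert_array_equal(sa.reference.values, sb.reference.values)
            np.testing.assert_array_equal(sa.evaluated.values, sb.evaluated.values)
            assert sa.delta_dmean_pct == sb.delta_dmean_pct

    def test_mu_scenarios_have_exact_labels(self):
        cfg = SuiteConfig(modes=("linac_hardware",),
                          linac_errors=(("mu_scale", 2.0), ("mu_scale", -2.0)))
        suite = generate_suite(cfg, seed=4)
        deltas = sorted(s.delta_dmean_pct for s in suite)
        np.testing.assert_allclose(deltas, [-2.0, 2.0], atol=1e-9)

    def test_export_reload_roundtrip(self, tmp_path):
        cfg = SuiteConfig(modes=("bolus",))
        suite = generate_suite(cfg, seed=11)
        export_suite(suite, str(tmp_path))
        back = load_suite(str(tmp_path))
        assert len(back) == len(suite) == 1
        np.testing.assert_allclose(back[0].reference.values, suite[0].reference.values,
                                   rtol=1e-6, atol=1e-4)
        assert back[0].failure_mode == "bolus"
        assert back[0].delta_dmean_pct == pytest.approx(suite[0].delta_dmean_pct)


class TestMonotoneDetectability:
    def test_growing_mlc_error_never_raises_passing_rate(self):
        from transitqa.failure_sim import head_neck_patient, head_neck_plan, _calibrated_beam
        from transitqa.gamma import GammaCriterion, compute_gamma

        cfg = SuiteConfig()
        patient = head_neck_patient()
        base = _calibrated_beam(head_neck_plan(sub_seed(3, "hn_plan")), patient, cfg)
        ref = transit_dose(patient, base)
        rates = []
        for mag in (1.0, 2.0, 4.0, 8.0):
            err = apply_linac_error(base, "mlc_shift", mag)
            res = compute_gamma(ref, transit_dose(patient, err), GammaCriterion(10, 1))
            rates.append(res.passing_rate_pct)
        assert all(a >= b - 1e-9 for a, b in zip(rates, rates[1:]))
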