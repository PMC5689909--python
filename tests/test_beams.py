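"""SOBP construction: flatness, clinical landmarks, wheel invariants."""
from dataclasses import replace

import numpy as np
import pytest

import rmwcal as rc
from rmwcal.beams import ModulatorWheel, WheelStep

from conftest import BEAM_CONFIGS


@pytest.mark.parametrize("key", list(BEAM_CONFIGS))
class TestPaperBeams:
    def test_plateau_flat_within_two_percent(self, beams, key):
        assert rc.plateau_flatness(beams[key]) <= 0.02

    def test_distal_range_within_clinical_tolerance(self, beams, key):
        beam = beams[key]
        d90 = rc.distal_range(rc.sobp_depth_dose(beam))
        err_mm = (d90 - beam.prescribed_range_cm) * 10
        assert -2.0 <= err_mm <= 1.0  # clinical +1/-2 mm range tolerance

    def test_modulation_width_within_3mm(self, beams, key):
        beam = beams[key]
        mw = rc.modulation_width(rc.sobp_depth_dose(beam))
        assert abs(mw - beam.modulation_cm) * 10 <= 3.0

    def test_dwell_fractions_conserve_period(self, beams, key):
        assert beams[key].wheel.dwell_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weights_decrease_with_pullback(self, beams, key):
        # decreasing from the full-range step through the wheel body; the
        # last (shallowest) steps may ring slightly to build the proximal
        # shoulder of the plateau
        w = beams[key].wheel.dwell_fractions
        assert (np.diff(w[:-3]) <= 1e-9).all()
        assert w[0] == w.max()

    def test_overshoot_rule(self, beams, key):
        beam = beams[key]
        assert beam.prescribed_range_cm == pytest.approx(
            BEAM_CONFIGS[key]["wepl"] + 1.0
        )


class TestSolveStepWeights:
    def test_single_step_is_degenerate_pristine_wheel(self):
        wheel = rc.solve_step_weights(10.0, 9.9, n_steps=1)
        assert wheel.n_steps == 1
        assert wheel.steps[0].dwell_fraction == 1.0
        assert wheel.steps[0].pullback_cm == 0.0

    def test_few_steps_rejected(self):
        with pytest.raises(ValueError):
            rc.solve_step_weights(10.0, 9.9, n_steps=3)

    def test_modulation_larger_than_range_rejected(self):
        with pytest.raises(ValueError):
            rc.solve_step_weights(10.0, 10.5)


class TestSobpDepthDose:
    def test_single_step_reduces_to_pristine(self):
        from rmwcal.bragg import PristinePeak, pristine_dose

        wheel = rc.solve_step_weights(8.0, 5.0, n_steps=1)
        peak = PristinePeak(8.0)
        beam = rc.ScoutBeam(
            prescribed_range_cm=8.0, modulation_cm=5.0, wheel=wheel, base_peak=peak
        )
        z = np.arange(0.0, 9.0, 0.05)
        curve = rc.sobp_depth_dose(beam, z, normalize=False)
        np.testing.assert_allclose(curve.doses, pristine_dose(z, peak), rtol=1e-12)

    def test_bcm_scaling_leaves_normalized_curve_unchanged(self, beam10):
        z = np.arange(0.0, 11.0, 0.02)
        ref = rc.sobp_depth_dose(beam10, z)
        scaled_steps = [
            replace(s, bcm_factor=2.0 * s.bcm_factor) for s in beam10.wheel.steps
        ]
        scaled = replace(
            beam10,
            wheel=ModulatorWheel(steps=scaled_steps, period_ms=beam10.wheel.period_ms),
        )
        got = rc.sobp_depth_dose(scaled, z)
        np.testing.assert_allclose(got.doses, ref.doses, rtol=1e-12)

    def test_range_minus_modulation_consistent(self, beam10):
        curve = rc.sobp_depth_dose(beam10)
        d90 = rc.distal_range(curve)
        mw = rc.modulation_width(curve)
        assert abs((d90 - mw) - (10.0 - 9.9)) <= 0.3


class TestModulationWidth:
    @staticmethod
    def _trapezoid_curve():
        # flat top of width 5 between linear ramps
        z = np.linspace(0, 10, 2001)
        d = np.interp(z, [0, 2, 2.5, 7.5, 8, 10], [0, 0, 1, 1, 0, 0])
        return rc.DepthDoseCurve(z, d)

    def test_rectangle_width_recovered(self):
        curve = self._trapezoid_curve()
        # proximal 98% at 2.49, distal 90% at 7.55: width 5 + edge interp
        assert rc.modulation_width(curve) == pytest.approx(5.06, abs=0.02)

    def test_pristine_peak_gives_small_width(self):
        from rmwcal.bragg import PristinePeak, pristine_dose

        peak = PristinePeak(10.0)
        z = np.arange(0.0, 12.0, 0.01)
        curve = rc.DepthDoseCurve(z, pristine_dose(z, peak))
        assert rc.modulation_width(curve) < 1.5  # of the order of the peak width


class TestRefineBcm:
    def test_already_flat_beam_keeps_unit_bcm(self, beams):
        refined = rc.refine_bcm(beams["15/14"])
        np.testing.assert_allclose(refined.wheel.bcm_factors, 1.0, atol=1e-6)

    def test_refinement_never_worsens_flatness(self, beam10):
        assert rc.plateau_flatness(rc.refine_bcm(beam10)) <= rc.plateau_flatness(
            beam10
        ) + 1e-12

    def test_perturbed_dwell_restored_by_refinement(self, beam10):
        dwell = beam10.wheel.dwell_fractions.copy()
        dwell[len(dwell) // 2] *= 1.10
        dwell /= dwell.sum()
        steps = [
            replace(s, dwell_fraction=float(d), bcm_factor=1.0)
            for s, d in zip(beam10.wheel.steps, dwell)
        ]
        perturbed = replace(beam10, wheel=ModulatorWheel(steps=steps))
        assert rc.plateau_flatness(perturbed) > rc.plateau_flatness(beam10)
        restored = rc.refine_bcm(perturbed)
        assert rc.plateau_flatness(restored) <= 0.02
        assert rc.plateau_flatness(restored) <= rc.plateau_flatness(perturbed)


class TestDesignScoutBeam:
    def test_modulation_exceeding_range_rejected(self):
        with pytest.raises(ValueError, match="modulation"):
            rc.design_scout_beam(5.0, 7.0)

    def test_nonpositive_wepl_rejected(self):
        with pytest.raises(ValueError):
            rc.design_scout_beam(-1.0, 2.0)


class TestWheelValidation:
    def test_dwell_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ModulatorWheel(steps=[WheelStep(0, 0.0, 0.4), WheelStep(1, 1.0, 0.4)])

    def test_pullbacks_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            ModulatorWheel(steps=[WheelStep(0, 1.0, 0.5), WheelStep(1, 0.5, 0.5)])

    def test_json_round_trip(self, beam10, tmp_path):
        path = tmp_path / "beam.json"
        beam10.to_json(path)
        loaded = rc.ScoutBeam.from_json(path)
        assert loaded.prescribed_range_cm == beam10.prescribed_range_cm
        np.testing.assert_allclose(
            loaded.wheel.dwell_fractions, beam10.wheel.dwell_fractions
        )
        np.testing.assert_allclose(loaded.wheel.bcm_factors, beam10.wheel.bcm_factors)
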