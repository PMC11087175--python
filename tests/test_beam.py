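"""Synthetic beam generator: range calibration, Bragg curves, spot fields,
SOBP design, and perturbation injection."""

import numpy as np
import pytest

from protonqa.beam import (
    MAJOR_ENERGIES,
    RS_VERIFICATION_ENERGIES,
    BeamModel,
    GridSpec,
    Layer,
    Perturbation,
    PlanSpec,
    apply_perturbation,
    compute_plan_dose,
    energy_to_range,
    generate_sobp_plan,
    generate_spot_field,
    plan_axis_dose,
    pristine_depth_dose,
    range_to_energy,
)
from protonqa.depthdose import analyze_depth_dose
from protonqa.exceptions import ConfigurationError, DomainError


class TestRangeCalibration:
    def test_clinical_endpoints_exact(self, model):
        assert energy_to_range(62.4, model) == pytest.approx(30.0, abs=1e-9)
        assert energy_to_range(252.7, model) == pytest.approx(380.0, abs=1e-9)

    def test_monotone_over_major_energies(self, model):
        ranges = [energy_to_range(e, model) for e in MAJOR_ENERGIES]
        assert np.all(np.diff(ranges) > 0)

    def test_inverse_round_trip(self, model):
        for e in (70.0, 148.2, 230.0):
            assert range_to_energy(energy_to_range(e, model), model) == pytest.approx(e)

    def test_out_of_range_energy_rejected(self, model):
        with pytest.raises(DomainError):
            energy_to_range(61.0, model)
        with pytest.raises(DomainError):
            energy_to_range(260.0, model)


class TestPristineDepthDose:
    @pytest.mark.parametrize("energy", [62.4, 148.2, 252.7])
    def test_r80_matches_calibration(self, model, energy):
        """Dense-grid root finding recovers the calibrated R80 within 0.05 mm."""
        from oracles import r80_dense_resample

        target = energy_to_range(energy, model)
        depths = np.arange(0.0, target + 15, 0.05)
        prof = pristine_depth_dose(energy, depths, model)
        assert r80_dense_resample(prof.positions, prof.values) == pytest.approx(target, abs=0.05)

    def test_single_peak_nonnegative_peak_proximal_to_r80(self, model):
        depths = np.arange(0.0, 160, 0.1)
        prof = pristine_depth_dose(148.2, depths, model)
        assert np.all(prof.values >= 0)
        m = analyze_depth_dose(prof)
        assert m.peak_depth < m.r80

    @pytest.mark.parametrize("energy", RS_VERIFICATION_ENERGIES)
    def test_range_shifter_shifts_r80_by_its_wet(self, model, energy):
        depths = np.arange(0.0, 260, 0.1)
        open_m = analyze_depth_dose(pristine_depth_dose(energy, depths, model))
        rs_m = analyze_depth_dose(pristine_depth_dose(energy, depths, model, rs_inserted=True))
        assert open_m.r80 - rs_m.r80 == pytest.approx(model.rs_wet, abs=0.02)

    def test_too_shallow_effective_range_rejected(self, model):
        with pytest.raises(ConfigurationError):
            pristine_depth_dose(62.4, np.arange(0, 10, 0.1), model, rs_inserted=True)


class TestSpotFields:
    def test_central_spot_centered_at_any_plane(self, model):
        from protonqa.spots import analyze_spot

        plan = PlanSpec((Layer(148.2, [[0.0, 0.0, 1.0]]),), isd_cm=50.0)
        spec = GridSpec(origin=(-25, -25, 0), spacing=(0.68, 0.68, 5.0), shape=(74, 74, 4))
        g = generate_spot_field(plan, model, spec)
        for iz in range(4):
            sm = analyze_spot(g.values[:, :, iz], g.axis_coords(0), g.axis_coords(1))
            assert sm.centroid[0] == pytest.approx(0.0, abs=0.02)
            assert sm.centroid[1] == pytest.approx(0.0, abs=0.02)

    def test_vsad_projection_similar_triangles(self, model):
        """A 50 mm nominal spot observed 500 mm upstream of isocenter lands at
        50*(VSAD-500)/VSAD per axis."""
        from protonqa.spots import analyze_spot

        plan = PlanSpec((Layer(148.2, [[50.0, 0.0, 1.0]]),), isd_cm=50.0)
        spec = GridSpec(origin=(17, -20, 0), spacing=(0.68, 0.68, 1.0), shape=(60, 60, 2))
        g = generate_spot_field(plan, model, spec)
        sm = analyze_spot(g.values[:, :, 0], g.axis_coords(0), g.axis_coords(1))
        assert sm.centroid[0] == pytest.approx(50 * (model.vsad_x - 500) / model.vsad_x, abs=0.02)

    def test_linear_in_weights(self, model):
        layer1 = Layer(120.0, [[0.0, 0.0, 1.0], [5.0, -3.0, 2.0]])
        layer2 = Layer(120.0, [[0.0, 0.0, 2.0], [5.0, -3.0, 4.0]])
        spec = GridSpec(origin=(-30, -30, 0), spacing=(2, 2, 2), shape=(31, 31, 50))
        g1 = generate_spot_field(PlanSpec((layer1,)), model, spec)
        g2 = generate_spot_field(PlanSpec((layer2,)), model, spec)
        np.testing.assert_allclose(g2.values, 2.0 * g1.values, rtol=1e-12)

    def test_plan_dose_additive_over_layers(self, model):
        spec = GridSpec(origin=(-20, -20, 0), spacing=(2, 2, 2), shape=(21, 21, 60))
        la = Layer(110.0, [[0.0, 0.0, 1.0]])
        lb = Layer(130.0, [[4.0, 4.0, 2.0]])
        ga = compute_plan_dose(PlanSpec((la,)), model, spec)
        gb = compute_plan_dose(PlanSpec((lb,)), model, spec)
        gab = compute_plan_dose(PlanSpec((la, lb)), model, spec)
        np.testing.assert_allclose(gab.values, ga.values + gb.values, rtol=1e-12, atol=1e-15)

    def test_spot_outside_grid_warns(self, model):
        plan = PlanSpec((Layer(120.0, [[80.0, 0.0, 1.0]]),))
        spec = GridSpec(origin=(-20, -20, 0), spacing=(2, 2, 5), shape=(21, 21, 10))
        with pytest.warns(UserWarning, match="outside the lateral grid"):
            generate_spot_field(plan, model, spec)

    def test_monoenergetic_comb_flat_against_quadrature_oracle(self, model):
        """A 12x12 cm^2, 2 mm-spaced field is laterally flat within 1% over
        the central 8 cm; the oracle is the continuous-fluence limit of the
        Gaussian comb."""
        energy = 148.2
        coords = np.arange(-60.0, 60.001, 2.0)
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        spots = np.column_stack([xx.ravel(), yy.ravel(), np.ones(xx.size)])
        plan = PlanSpec((Layer(energy, spots),), isd_cm=0.0)
        depth = 20.0
        xs = np.linspace(-40, 40, 33)
        dose = np.array([plan_axis_dose(plan, model, [depth], x=x).values[0] for x in xs])
        # continuous limit: fluence 1/(s_x s_y k_x k_y) times the depth dose
        d = -depth  # plane beyond isocenter at ISD0
        kx = (model.vsad_x - d) / model.vsad_x
        ky = (model.vsad_y - d) / model.vsad_y
        idd = pristine_depth_dose(energy, [depth], model).values[0]
        oracle = idd / (2.0 * 2.0 * kx * ky)
        np.testing.assert_allclose(dose, oracle, rtol=0.01)
        assert dose.max() / dose.min() - 1 < 0.01


class TestSobp:
    def test_box_flat_at_target_dose(self, model):
        """80 mm cube centered at 150 mm WED: central 80% of the SOBP flat
        within 2% of the target dose."""
        plan = generate_sobp_plan((80.0, 80.0, 80.0), 150.0, 2.0, model, spot_spacing=4.0)
        assert not plan.rs_inserted
        z = np.arange(150 - 32.0, 150 + 32.0, 1.0)
        prof = plan_axis_dose(plan, model, z)
        np.testing.assert_allclose(prof.values, 2.0, rtol=0.02)

    def test_box_distal_r80_matches_geometry(self, model):
        plan = generate_sobp_plan((80.0, 80.0, 80.0), 150.0, 2.0, model, spot_spacing=4.0)
        prof = plan_axis_dose(plan, model, np.arange(0.0, 215.0, 0.5))
        m = analyze_depth_dose(prof)
        assert m.r80 == pytest.approx(190.0, abs=1.5)

    def test_all_weights_nonnegative(self, model):
        plan = generate_sobp_plan((40.0, 40.0, 40.0), 100.0, 1.0, model, spot_spacing=5.0)
        for layer in plan.layers:
            assert np.all(layer.spots[:, 2] >= 0)

    def test_shallow_box_gets_range_shifter(self, model):
        plan = generate_sobp_plan((60.0, 60.0, 60.0), 50.0, 2.0, model, spot_spacing=5.0)
        assert plan.rs_inserted

    def test_box_above_surface_rejected(self, model):
        with pytest.raises(ConfigurationError):
            generate_sobp_plan((60.0, 60.0, 60.0), 20.0, 2.0, model)


class TestPerturbations:
    def test_range_shift_moves_r80_exactly(self, model):
        plan = PlanSpec((Layer(148.2, [[0.0, 0.0, 1.0]]),))
        shifted = apply_perturbation(plan, Perturbation("range_shift_mm", 2.0))
        z = np.arange(100.0, 160.0, 0.1)
        m0 = analyze_depth_dose(plan_axis_dose(plan, model, z))
        m1 = analyze_depth_dose(plan_axis_dose(shifted, model, z))
        assert m1.r80 - m0.r80 == pytest.approx(2.0, abs=0.02)

    def test_output_scale_multiplies_every_voxel(self, model, rng):
        from protonqa.grids import DoseGrid3D

        g = DoseGrid3D((0, 0, 0), (1, 1, 1), rng.uniform(0.1, 1, (4, 4, 4)))
        out = apply_perturbation(g, Perturbation("output_scale", 1.018))
        np.testing.assert_allclose(out.values / g.values, 1.018, rtol=1e-12)

    def test_zero_magnitude_is_identity(self, model):
        plan = PlanSpec((Layer(148.2, [[0.0, 0.0, 1.0]]),))
        same = apply_perturbation(plan, Perturbation("range_shift_mm", 0.0))
        spec = GridSpec(origin=(-15, -15, 0), spacing=(2, 2, 2), shape=(16, 16, 80))
        np.testing.assert_array_equal(
            compute_plan_dose(plan, model, spec).values,
            compute_plan_dose(same, model, spec).values,
        )

    def test_noise_is_seeded_and_deterministic(self, model, rng):
        from protonqa.grids import DoseGrid3D

        g = DoseGrid3D((0, 0, 0), (1, 1, 1), rng.uniform(0.1, 1, (5, 5, 5)))
        p = Perturbation("noise_pct", 2.0)
        a = apply_perturbation(g, p, seed=11)
        b = apply_perturbation(g, p, seed=11)
        c = apply_perturbation(g, p, seed=12)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)
        with pytest.raises(ConfigurationError):
            apply_perturbation(g, p)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            Perturbation("wrong_kind", 1.0)
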