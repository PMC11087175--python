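"""R80/BPW80 extraction, IRPD integration, and reference point doses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protonqa.beam import GridSpec, Layer, PlanSpec, generate_spot_field, pristine_depth_dose
from protonqa.depthdose import analyze_depth_dose, integrate_depth_dose, reference_point_dose
from protonqa.exceptions import AnalysisError, DomainError
from protonqa.grids import DoseGrid3D, Profile1D


class TestAnalyzeDepthDose:
    def test_plateau_then_linear_falloff(self):
        """100% plateau to 30 mm then linear to zero at 32 mm: the distal 80%
        crossing sits at 30.4 mm."""
        z = np.concatenate([np.arange(0, 30.5, 1.0), [31.0, 32.0]])
        v = np.where(z <= 30.0, 100.0, 100.0 * (32.0 - z) / 2.0)
        v[0] = 50.0  # entrance ramp so a proximal crossing exists
        m = analyze_depth_dose(Profile1D(z, v))
        assert m.r80 == pytest.approx(30.4, abs=1e-9)

    def test_triangle_peak_width(self):
        """Triangle 0→100% over 0–10 mm, back to 0 at 12 mm: proximal 80% at
        8.0 mm, distal at 10.4 mm, BPW80 = 2.4 mm."""
        z = np.concatenate([np.arange(0.0, 10.5, 1.0), [11.0, 12.0]])
        v = np.where(z <= 10.0, 10.0 * z, 100.0 * (12.0 - z) / 2.0)
        m = analyze_depth_dose(Profile1D(z, v))
        assert m.bpw80 == pytest.approx(2.4, abs=1e-9)
        assert m.r80 == pytest.approx(10.4, abs=1e-9)
        assert m.peak_depth == pytest.approx(10.0)

    def test_agrees_with_dense_resampling_oracle(self, model):
        from oracles import bpw_dense_resample, r80_dense_resample

        z = np.arange(0.0, 160.0, 0.2)
        prof = pristine_depth_dose(148.2, z, model)
        m = analyze_depth_dose(prof)
        assert m.sampling_ok
        assert m.r80 == pytest.approx(r80_dense_resample(z, prof.values), abs=0.05)
        assert m.bpw80 == pytest.approx(bpw_dense_resample(z, prof.values), abs=0.05)

    def test_low_energy_under_sampling_flagged(self, model):
        """The lowest-energy Bragg peak is narrower than twice a 2 mm (CT
        slice) sampling step and must be flagged; sub-peak-width sampling
        recovers R80 to the calibrated range within 0.05 mm."""
        from protonqa.beam import energy_to_range

        coarse = analyze_depth_dose(
            pristine_depth_dose(62.4, np.arange(0, 40, 2.0), model)
        )
        assert not coarse.sampling_ok
        assert coarse.bpw80 < 4.0
        fine = analyze_depth_dose(
            pristine_depth_dose(62.4, np.arange(0, 40, 0.1), model)
        )
        assert fine.sampling_ok
        assert fine.r80 == pytest.approx(energy_to_range(62.4, model), abs=0.05)

    def test_truncated_curve_rejected(self, model):
        z = np.arange(0.0, 140.0, 0.2)  # ends before the 148.2 MeV fall-off
        with pytest.raises(AnalysisError, match="truncated"):
            analyze_depth_dose(pristine_depth_dose(148.2, z, model))

    def test_distal_gradient_reported_in_pct_per_mm(self, model):
        z = np.arange(0.0, 40.0, 0.05)
        m = analyze_depth_dose(pristine_depth_dose(62.4, z, model))
        depth, grad = m.distal_gradient_at
        assert depth == pytest.approx(m.r80)
        assert grad < -2.0  # steep distal fall-off at the lowest energy

    @settings(max_examples=30, deadline=None)
    @given(delta=st.floats(-20.0, 50.0))
    def test_translation_equivariance(self, model, delta):
        z = np.arange(0.0, 120.0, 0.2)
        prof = pristine_depth_dose(111.6, z, model)
        m0 = analyze_depth_dose(prof)
        m1 = analyze_depth_dose(Profile1D(z + delta, prof.values))
        assert m1.r80 - m0.r80 == pytest.approx(delta, abs=1e-9)
        assert m1.peak_depth - m0.peak_depth == pytest.approx(delta, abs=1e-9)
        assert m1.bpw80 == pytest.approx(m0.bpw80, abs=1e-9)


class TestIrpd:
    def test_single_spot_irpd_sigma_independent(self, model):
        """The laterally integrated profile of a single pencil beam equals the
        pristine curve times the weight, independent of spot sigma."""
        spec = GridSpec(origin=(-40, -40, 0), spacing=(1.0, 1.0, 2.0), shape=(81, 81, 70))
        z = spec.coords(2)
        idd = pristine_depth_dose(124.7, z, model).values
        for isd in (0.0, 50.0):  # different ISD -> different sigma
            g = generate_spot_field(
                PlanSpec((Layer(124.7, [[0.0, 0.0, 3.0]]),), isd_cm=isd), model, spec
            )
            p = integrate_depth_dose(g)
            np.testing.assert_allclose(p.values, 3.0 * idd, rtol=2e-3, atol=1e-6)

    def test_uniform_cube_flat_inside(self):
        vals = np.zeros((4, 4, 10))
        vals[:, :, 2:5] = 1.0
        g = DoseGrid3D((0, 0, 0), (2, 2, 1), vals)
        p = integrate_depth_dose(g)
        np.testing.assert_allclose(p.values[2:5], 16 * 4.0)
        np.testing.assert_allclose(p.values[:2], 0.0)

    def test_irpd_peak_depth_matches_1d_model(self, model):
        spec = GridSpec(origin=(-30, -30, 0), spacing=(1.5, 1.5, 0.5), shape=(41, 41, 160))
        g = generate_spot_field(PlanSpec((Layer(97.4, [[0.0, 0.0, 1.0]]),)), model, spec)
        m3d = analyze_depth_dose(integrate_depth_dose(g))
        dense = np.arange(0.0, 80.0, 0.01)
        m1d = analyze_depth_dose(pristine_depth_dose(97.4, dense, model))
        assert abs(m3d.peak_depth - m1d.peak_depth) <= spec.spacing[2]

    def test_irpd_conservation(self, rng):
        g = DoseGrid3D((0, 0, 0), (1.5, 2.0, 2.5), rng.uniform(0, 1, (5, 6, 7)))
        p = integrate_depth_dose(g)
        assert (p.values * g.spacing[2]).sum() == pytest.approx(
            g.values.sum() * g.voxel_volume, rel=1e-12
        )


class TestReferencePointDose:
    def test_uniform_field_independent_of_diameter(self):
        g = DoseGrid3D((-50, -50, 0), (2, 2, 2), np.full((51, 51, 20), 1.7))
        for dia in (10.0, 40.0):
            dose, _ = reference_point_dose(g, 15.0, averaging_diameter=dia)
            assert dose == pytest.approx(1.7, rel=1e-12)

    def test_monoenergetic_field_dose_vs_quadrature_oracle(self, model):
        """Central dose of a 12x12 comb at 14 mm depth vs the continuous
        Gaussian-comb limit, within 0.2%."""
        energy = 148.2
        s = 2.0
        coords = np.arange(-60.0, 60.001, s)
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        spots = np.column_stack([xx.ravel(), yy.ravel(), np.ones(xx.size)])
        plan = PlanSpec((Layer(energy, spots),), isd_cm=0.0)
        spec = GridSpec(origin=(-80, -80, 10), spacing=(2.0, 2.0, 1.0), shape=(81, 81, 10))
        g = generate_spot_field(plan, model, spec)
        dose, _ = reference_point_dose(g, 14.0, averaging_diameter=40.0)
        depth = 14.0
        kx = (model.vsad_x + depth) / model.vsad_x
        ky = (model.vsad_y + depth) / model.vsad_y
        oracle = pristine_depth_dose(energy, [depth], model).values[0] / (s * s * kx * ky)
        assert dose == pytest.approx(oracle, rel=2e-3)

    def test_low_energy_gradient_exceeds_1pct_per_mm(self, model):
        """Near the end of range of the lowest energy, the local depth
        gradient at a shallow measurement point exceeds 1 %/mm — the driver
        of positioning uncertainty for low-energy reference dosimetry."""
        coords = np.arange(-40.0, 40.001, 2.0)
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        spots = np.column_stack([xx.ravel(), yy.ravel(), np.ones(xx.size)])
        plan = PlanSpec((Layer(62.4, spots),))
        spec = GridSpec(origin=(-50, -50, 14), spacing=(2.0, 2.0, 0.5), shape=(51, 51, 24))
        g = generate_spot_field(plan, model, spec)
        _, grad = reference_point_dose(g, 20.0, averaging_diameter=30.0)
        assert abs(grad) > 1.0

    def test_disc_exceeding_grid_rejected(self):
        g = DoseGrid3D((-10, -10, 0), (2, 2, 2), np.ones((11, 11, 5)))
        with pytest.raises(DomainError):
            reference_point_dose(g, 4.0, averaging_diameter=40.0)
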