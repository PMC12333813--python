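"""Synthetic-data generator: ARF scaling, stiffness surrogate, RF speckle."""

import numpy as np
import pytest

from visrsim.config import StudyConfig
from visrsim.materials import make_incompressible_material
from visrsim.msd import forward_displacement
from visrsim.synth import (
    AcquisitionGeometry,
    ARFField,
    ScattererPhantom,
    effective_stiffness,
    force_from_intensity,
    generate_ensemble,
    make_phantom,
    msd_params_for_stiffness,
    synthesize_rf,
)


class TestForceFromIntensity:
    def test_zero_intensity_zero_force(self):
        assert force_from_intensity(0.0, 0.5, 4.21, 1540.0) == 0.0

    def test_linear_in_intensity(self):
        f1 = force_from_intensity(2500.0, 0.5, 4.21, 1540.0)
        f2 = force_from_intensity(5000.0, 0.5, 4.21, 1540.0)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)

    def test_unit_conversion_oracle(self):
        # alpha = 0.5*4.21 dB/cm = 2.105/8.686 Np/cm = 24.235 Np/m; I = 5e7 W/m^2
        f = force_from_intensity(5000.0, 0.5, 4.21, 1540.0)
        assert f == pytest.approx(1.574e6, rel=1e-3)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            force_from_intensity(5000.0, -0.5, 4.21, 1540.0)
        with pytest.raises(ValueError):
            force_from_intensity(5000.0, 0.5, 0.0, 1540.0)

    def test_arf_field_consistency_enforced(self):
        fld = ARFField(peak_intensity=5000.0, alpha_db=0.5, push_freq=4.21, c_sound=1540.0)
        assert fld.force_density == pytest.approx(1.574e6, rel=1e-3)
        with pytest.raises(ValueError, match="inconsistent"):
            ARFField(
                peak_intensity=5000.0, alpha_db=0.5, push_freq=4.21,
                c_sound=1540.0, force_density=1.0,
            )


class TestEffectiveStiffness:
    def test_normal_incidence_reflects_shear_only(self):
        mat = make_incompressible_material(ET=13e3, EL=60e3, muL=16.2e3)
        geom = AcquisitionGeometry.from_incidence("longitudinal", 90.0)
        assert effective_stiffness(mat, geom) == pytest.approx(16.2e3, rel=1e-12)

    @pytest.mark.parametrize("incidence", [90.0, 78.0, 46.0])
    def test_plane_of_isotropy_angle_independent(self, incidence):
        mat = make_incompressible_material(ET=13.55e3, EL=60e3, muL=16.2e3)
        geom = AcquisitionGeometry.from_incidence("transverse", incidence)
        assert effective_stiffness(mat, geom) == pytest.approx(mat.muT, rel=1e-12)

    def test_hand_worked_surrogate_value(self):
        mat = make_incompressible_material(ET=12e3, EL=48e3, muL=4.8e3)
        geom = AcquisitionGeometry.from_incidence("longitudinal", 46.0)
        # 4.8 + 0.05*48*sin^2(44 deg) kPa
        assert effective_stiffness(mat, geom, c_E=0.05) == pytest.approx(5.958e3, rel=1e-3)

    def test_monotone_in_deviation(self):
        mat = make_incompressible_material(ET=12e3, EL=48e3, muL=4.8e3)
        vals = [
            effective_stiffness(mat, AcquisitionGeometry.from_incidence("longitudinal", a))
            for a in (90.0, 78.0, 66.0, 46.0)
        ]
        assert np.all(np.diff(vals) > 0)


class TestGeometry:
    def test_tilts_compose_to_incidence(self):
        g = AcquisitionGeometry("longitudinal", beam_tilt_deg=20.0, material_tilt_deg=24.0)
        assert g.delta_deg == pytest.approx(44.0)
        assert g.incidence_deg == pytest.approx(46.0)
        g = AcquisitionGeometry("longitudinal", beam_tilt_deg=-20.0, material_tilt_deg=24.0)
        assert g.incidence_deg == pytest.approx(86.0)

    def test_out_of_range_incidence_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionGeometry("longitudinal", beam_tilt_deg=90.0, material_tilt_deg=20.0)
        with pytest.raises(ValueError):
            AcquisitionGeometry("sideways")


class TestDisplacementMode:
    def test_noise_free_equals_forward_model(self, cfg, seq, panel):
        cfg0 = StudyConfig(disp_noise_rel=0.0)
        mat = panel[0]
        geom = AcquisitionGeometry.from_incidence("longitudinal", 66.0)
        profiles = generate_ensemble(mat, geom, seq, cfg0, "displacement", seed=3)
        mu_eff = effective_stiffness(mat, geom, cfg0.c_E)
        expected = forward_displacement(
            msd_params_for_stiffness(mu_eff, cfg0, mu_base=mat.muL), seq
        ).z
        for p in profiles:
            np.testing.assert_array_equal(p.z, expected)

    def test_seed_determinism(self, cfg, seq, panel):
        a = generate_ensemble(panel[0], AcquisitionGeometry.from_incidence("longitudinal", 78.0), seq, cfg, "displacement", seed=9)
        b = generate_ensemble(panel[0], AcquisitionGeometry.from_incidence("longitudinal", 78.0), seq, cfg, "displacement", seed=9)
        c = generate_ensemble(panel[0], AcquisitionGeometry.from_incidence("longitudinal", 78.0), seq, cfg, "displacement", seed=10)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.z, pb.z)
        assert not np.array_equal(a[0].z, c[0].z)

    def test_unknown_mode_rejected(self, cfg, seq, panel):
        with pytest.raises(ValueError, match="mode"):
            generate_ensemble(panel[0], AcquisitionGeometry.from_incidence("longitudinal", 90.0), seq, cfg, "fem", seed=0)


class TestRFSynthesis:
    def test_zero_displacement_noise_off_lines_identical(self, cfg, seq):
        roi = (0.019, 0.021)
        ph = make_phantom(cfg, (roi[0] - 2.5e-3, roi[1] + 2.5e-3), seed=5)
        d = np.zeros_like(seq.sample_times)
        ens = synthesize_rf(ph, d, seq.sample_times, cfg, roi, seed=6, snr_db=np.inf)
        for k in range(1, ens.rf.shape[1]):
            np.testing.assert_array_equal(ens.rf[:, k], ens.rf[:, 0])

    def test_ensemble_snr_matches_contract(self, cfg, seq):
        roi = (0.019, 0.021)
        ph = make_phantom(cfg, (roi[0] - 2.5e-3, roi[1] + 2.5e-3), seed=5)
        d = np.full(seq.sample_times.shape, 3e-6)
        d[0] = 0.0
        noisy = synthesize_rf(ph, d, seq.sample_times, cfg, roi, seed=6)
        clean = synthesize_rf(ph, d, seq.sample_times, cfg, roi, seed=6, snr_db=np.inf)
        noise = noisy.rf - clean.rf
        snr = 10.0 * np.log10(np.mean(clean.rf**2) / np.mean(noise**2))
        assert snr == pytest.approx(40.0, abs=0.5)

    def test_displacement_beyond_span_rejected(self, cfg, seq):
        roi = (0.019, 0.021)
        ph = make_phantom(cfg, (roi[0] - 2.5e-3, roi[1] + 2.5e-3), seed=5)
        d = np.full(seq.sample_times.shape, 5e-3)
        with pytest.raises(ValueError, match="span"):
            synthesize_rf(ph, d, seq.sample_times, cfg, roi, seed=6)

    def test_sparse_phantom_rejected(self):
        with pytest.raises(ValueError, match="density"):
            ScattererPhantom(
                positions=np.array([0.02]),
                amplitudes=np.array([1.0]),
                density_per_cell=2.0,
                seed=0,
                span=(0.019, 0.021),
            )

    def test_stiffer_angle_gives_smaller_peak_displacement(self, cfg, seq, panel):
        """rf mode, low muL/EL material: deviation from normal incidence stiffens."""
        from visrsim.tracking import ncc_track

        mat = panel[0]  # lowest muL with large EL/muL
        peaks = []
        for angle in (90.0, 46.0):
            geom = AcquisitionGeometry.from_incidence("longitudinal", angle)
            ens = generate_ensemble(mat, geom, seq, cfg, "rf", seed=21)
            tracked = ncc_track(ens)
            peaks.append(np.median(np.max(tracked.disp, axis=1)))
        assert peaks[1] < peaks[0]
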