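"""Lateral pressure profile pipeline and membrane property measures."""

import numpy as np
import pytest

from gpcrmech import membrane, synthdata
from gpcrmech.membrane import (
    area_per_lipid,
    bilayer_thickness,
    instantaneous_lateral_pressure,
    order_parameter,
    pressure_profile,
    read_pressure_tsv,
    smooth3,
    surface_tension_check,
    write_pressure_tsv,
)
from gpcrmech.synthdata import GeneratorSpec, ground_truth_pi, synthetic_pressure_series


class TestInstantaneousPressure:
    @pytest.mark.parametrize(
        "pxx,pyy,pzz,expected",
        [(100, 100, 100, 0), (300, 100, 0, 200), (0, 0, 500, -500)],
    )
    def test_definition(self, pxx, pyy, pzz, expected):
        assert instantaneous_lateral_pressure(pxx, pyy, pzz) == expected


class TestSmooth3:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3], [1.5, 2, 2.5]),
            ([5, 5, 5, 5], [5, 5, 5, 5]),
            ([0, 3, 0], [1.5, 1, 1.5]),
        ],
    )
    def test_stencil(self, values, expected):
        np.testing.assert_allclose(smooth3(values), expected)

    def test_idempotent_on_constants(self):
        c = np.full(11, 3.7)
        np.testing.assert_allclose(smooth3(smooth3(c)), c, atol=1e-12)

    def test_interior_mean_preserved_for_constant_extension(self):
        v = np.concatenate([[2.0], np.linspace(2, 4, 20), [4.0]])
        v[0], v[-1] = v[1], v[-2]
        assert smooth3(v)[1:-1].mean() == pytest.approx(v[1:-1].mean(), abs=1e-12)


class TestPressureProfile:
    def test_noise_free_recovery(self, default_spec):
        series = synthetic_pressure_series(default_spec.with_(pressure_noise=0.0))
        prof = pressure_profile(series)
        expected = smooth3(ground_truth_pi(default_spec, prof.z))
        peak = default_spec.head_peak_height
        assert np.max(np.abs(prof.pi - expected)) < 0.01 * peak

    def test_unsmoothed_equals_time_mean(self, default_spec):
        series = synthetic_pressure_series(default_spec.with_(pressure_noise=25.0))
        prof = pressure_profile(series, smooth=False)
        mask = series.times >= 20.0
        manual = instantaneous_lateral_pressure(
            series.pxx[mask], series.pyy[mask], series.pzz[mask]
        ).mean(axis=0)
        np.testing.assert_allclose(prof.pi, manual, atol=1e-9)

    def test_drift_correction_within_2_percent_of_peak(self, default_spec):
        still = pressure_profile(
            synthetic_pressure_series(default_spec.with_(pressure_noise=0.0))
        )
        drifted = pressure_profile(
            synthetic_pressure_series(
                default_spec.with_(pressure_noise=0.0, drift_rate=0.05)
            )
        )
        peak = default_spec.head_peak_height
        interior = slice(5, -5)
        assert np.max(np.abs(drifted.pi[interior] - still.pi[interior])) < 0.02 * peak

    def test_noisy_peak_positions_within_one_slab(self, default_spec):
        spec = default_spec.with_(pressure_noise=50.0, pressure_n_times=2000, seed=7)
        prof = pressure_profile(synthetic_pressure_series(spec))
        dz = prof.z[1] - prof.z[0]
        upper = prof.z > 0
        peak_z = prof.z[upper][np.argmax(prof.pi[upper])]
        assert abs(peak_z - spec.head_peak_z) <= dz
        trough_z = prof.z[upper][np.argmin(prof.pi[upper])]
        assert abs(trough_z - spec.interface_peak_z) <= dz

    def test_tmin_beyond_series_rejected(self, default_spec):
        series = synthetic_pressure_series(default_spec)
        with pytest.raises(ValueError, match="t_min"):
            pressure_profile(series, t_min=1e4)

    def test_tsv_round_trip(self, tmp_path, default_spec):
        series = synthetic_pressure_series(default_spec.with_(pressure_n_times=20))
        path = tmp_path / "p.tsv"
        write_pressure_tsv(str(path), series)
        back = read_pressure_tsv(str(path))
        np.testing.assert_allclose(back.pxx, series.pxx, rtol=1e-9)
        np.testing.assert_allclose(back.z, series.z, atol=1e-4)
        np.testing.assert_allclose(back.z_p, series.z_p, atol=1e-9)


class TestThickness:
    def test_narrow_leaflets_peak_to_peak(self, rng):
        z = np.concatenate(
            [rng.normal(-19.4, 0.3, 4000), rng.normal(19.4, 0.3, 4000)]
        )
        assert bilayer_thickness(z) == pytest.approx(38.8, abs=0.5)

    def test_stretched_bilayer(self, rng):
        z = np.concatenate(
            [rng.normal(-18.15, 0.3, 4000), rng.normal(18.15, 0.3, 4000)]
        )
        assert bilayer_thickness(z) == pytest.approx(36.3, abs=0.5)

    def test_recovery_within_one_bin_for_moderate_spread(self, rng):
        for sigma in (0.5, 1.0, 2.0):
            z = np.concatenate(
                [rng.normal(-19.4, sigma, 20000), rng.normal(19.4, sigma, 20000)]
            )
            assert bilayer_thickness(z, bin_width=0.5) == pytest.approx(38.8, abs=0.5)

    def test_unimodal_rejected(self):
        with pytest.raises(ValueError, match="unimodal"):
            bilayer_thickness(np.full(100, 5.0))

    def test_generator_round_trip(self, default_spec):
        frame = synthdata.synthetic_bilayer(default_spec)
        pz = frame.coords[frame.atom_name == "P", 2]
        assert bilayer_thickness(pz) == pytest.approx(
            default_spec.leaflet_separation, abs=1.0
        )


class TestAreaPerLipid:
    @pytest.mark.parametrize(
        "cell,prot,n,expected", [(4900, 1300, 60, 60), (4900, 0, 70, 70)]
    )
    def test_arithmetic(self, cell, prot, n, expected):
        assert area_per_lipid(cell, prot, n) == pytest.approx(expected)

    def test_nonpositive_free_area_rejected(self):
        with pytest.raises(ValueError):
            area_per_lipid(1000, 1200, 60)


class TestOrderParameter:
    def test_aligned_vectors(self):
        assert order_parameter(np.tile([0.0, 0, 1], (10, 1))) == pytest.approx(1.0)

    def test_in_plane_vectors(self):
        assert order_parameter(np.tile([1.0, 0, 0], (10, 1))) == pytest.approx(-0.5)

    def test_magic_angle(self):
        theta = np.radians(54.7356)
        v = np.tile([np.sin(theta), 0.0, np.cos(theta)], (5, 1))
        assert order_parameter(v) == pytest.approx(0.0, abs=1e-4)

    def test_isotropic_sample_near_zero(self):
        rng = np.random.default_rng(99)
        v = rng.standard_normal((100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert order_parameter(v) == pytest.approx(0.0, abs=0.01)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            order_parameter(np.zeros((3, 3)))


class TestSurfaceTension:
    def test_isotropic_pressure_gives_zero(self):
        assert surface_tension_check(100.0, 100.0, 80.0) == 0.0

    def test_unit_conversion(self):
        # 20 bar over 100 A -> 2000 bar*A = 2000e-5 N/m = 20 dyn/cm
        assert surface_tension_check(21.0, 1.0, 100.0) == pytest.approx(20.0)

    def test_slab_integrated_tension_from_generator(self):
        # calibrate the profile integral to -2000 bar*A so the applied
        # tension evaluates to the study value, 20 dyn/cm
        spec = GeneratorSpec(pressure_noise=0.0)
        target_integral = -2000.0
        head_term = spec.head_peak_height * spec.head_peak_width
        h_int = (
            target_integral / (2.0 * np.sqrt(2.0 * np.pi)) - head_term
        ) / spec.interface_peak_width
        spec = spec.with_(interface_peak_height=h_int)
        series = synthetic_pressure_series(spec)
        pt = np.mean((series.pxx[0] + series.pyy[0]) / 2.0)
        pz = np.mean(series.pzz[0])
        gamma = surface_tension_check(pz, pt, spec.lz)
        assert gamma == pytest.approx(20.0, rel=0.01)
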