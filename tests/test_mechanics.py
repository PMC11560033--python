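"""Cross-section area profiles and the work against lateral pressure."""

import numpy as np
import pytest

from gpcrmech.mechanics import (
    AreaProfile,
    cross_section_profile,
    delta_area,
    disk_union_area,
    enclosed_volume,
    mean_area_range,
    pressure_work,
)
from gpcrmech.membrane import LateralPressureProfile
from gpcrmech.structure import MolecularFrame
from gpcrmech.units import BAR_A3_TO_KCAL_PER_MOL


def frame_of_spheres(coords) -> MolecularFrame:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return MolecularFrame(
        time=0.0,
        res_id=np.arange(1, n + 1),
        res_name=np.array(["ALA"] * n),
        atom_name=np.array(["CA"] * n),
        chain=np.array(["A"] * n),
        coords=coords,
    )


def constant_profile(value: float, z_lo=0.0, z_hi=20.0, dz=0.2) -> AreaProfile:
    z = np.arange(z_lo, z_hi + dz / 2, dz)
    return AreaProfile(z=z, area=np.full_like(z, value))


def mc_disk_union(centers, radii, n_samples, seed) -> float:
    """Monte-Carlo oracle for the union-of-disks area."""
    rng = np.random.default_rng(seed)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    pts = rng.uniform(lo, hi, (n_samples, 2))
    inside = np.zeros(n_samples, dtype=bool)
    for c, r in zip(centers, radii):
        inside |= ((pts - c) ** 2).sum(axis=1) <= r**2
    return inside.mean() * np.prod(hi - lo)


class TestCrossSection:
    def test_single_sphere_disk_area(self):
        frame = frame_of_spheres([[0.0, 0.0, 0.0]])
        prof = cross_section_profile(frame, atom_radii={"C": 2.0}, grid_resolution=0.1)
        i = np.argmin(np.abs(prof.z))
        assert prof.area[i] == pytest.approx(np.pi * 4.0, rel=0.02)

    def test_cylinder_interior_slabs(self):
        # a radius-10 cylinder: overlapping radius-10 spheres stacked densely
        column = [(0.0, 0.0, z) for z in np.arange(-4.0, 4.25, 0.5)]
        frame = frame_of_spheres(column)
        prof = cross_section_profile(
            frame, atom_radii={"C": 10.0}, grid_resolution=0.1
        )
        mid = np.abs(prof.z) < 2.0
        assert np.all(np.abs(prof.area[mid] - np.pi * 100.0) / (np.pi * 100.0) < 0.02)

    def test_slab_above_protein_is_zero(self):
        frame = frame_of_spheres([[0.0, 0.0, 0.0]])
        prof = cross_section_profile(
            frame, atom_radii={"C": 2.0}, z_range=(-6.0, 6.0)
        )
        assert prof.area[np.abs(prof.z) > 2.0].max() == 0.0

    def test_unknown_element_rejected(self):
        frame = frame_of_spheres([[0.0, 0.0, 0.0]])
        with pytest.raises(KeyError, match="radius"):
            cross_section_profile(frame, atom_radii={"N": 1.55})

    def test_grid_matches_monte_carlo_oracle(self, rng):
        for trial in range(20):
            n = rng.integers(2, 20)
            centers = rng.uniform(-5, 5, (n, 2))
            radii = rng.uniform(1.2, 2.0, n)
            grid = disk_union_area(centers, radii, resolution=0.05)
            mc = mc_disk_union(centers, radii, n_samples=300_000, seed=trial)
            assert grid == pytest.approx(mc, rel=0.01)

    def test_resolution_convergence_toward_oracle(self):
        centers = np.array([[0.0, 0.0], [1.5, 0.5], [-1.0, 1.0]])
        radii = np.array([1.7, 1.7, 1.7])
        exact = mc_disk_union(centers, radii, n_samples=2_000_000, seed=0)
        errors = [
            abs(disk_union_area(centers, radii, resolution=res) - exact)
            for res in (0.5, 0.2, 0.1)
        ]
        assert errors[-1] < errors[0]


class TestAreaProfileOps:
    def test_mean_area_constant_and_ramp(self):
        assert mean_area_range(constant_profile(200.0), 0, 20) == pytest.approx(200.0)
        z = np.arange(0, 20.2, 0.2)
        ramp = AreaProfile(z=z, area=100.0 * z / 20.0)
        assert mean_area_range(ramp, 0, 20) == pytest.approx(50.0)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            mean_area_range(constant_profile(1.0), 30, 40)

    def test_delta_identical_profiles_zero(self):
        p = constant_profile(250.0)
        assert np.all(delta_area(p, p).area == 0.0)

    def test_delta_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delta_area(constant_profile(1.0), constant_profile(1.0, z_hi=10.0))

    def test_constant_50_difference_integrates_to_1000(self):
        delta = delta_area(constant_profile(250.0), constant_profile(200.0))
        assert enclosed_volume(delta, 0.0, 20.0) == pytest.approx(1000.0, rel=1e-9)

    def test_triangular_delta_volume(self):
        z = np.arange(0, 20.2, 0.2)
        tri = AreaProfile(z=z, area=100.0 * (1.0 - np.abs(z - 10.0) / 10.0))
        assert enclosed_volume(tri, 0, 20) == pytest.approx(1000.0, rel=1e-6)


class TestPressureWork:
    def test_zero_delta_zero_work(self):
        delta = constant_profile(0.0)
        prof = LateralPressureProfile(z=delta.z, pi=np.full_like(delta.z, 300.0))
        assert pressure_work(delta, prof, 0, 20) == 0.0

    def test_constant_product_closed_form(self):
        delta = constant_profile(50.0)
        prof = LateralPressureProfile(z=delta.z, pi=np.full_like(delta.z, 100.0))
        w = pressure_work(delta, prof, 0, 20)
        assert w == pytest.approx(1e5 * BAR_A3_TO_KCAL_PER_MOL, rel=1e-9)
        assert w == pytest.approx(1.4393, abs=1e-4)

    def test_sign_follows_pressure(self):
        delta = constant_profile(50.0)
        prof = LateralPressureProfile(z=delta.z, pi=np.full_like(delta.z, -100.0))
        assert pressure_work(delta, prof, 0, 20) == pytest.approx(-1.4393, abs=1e-4)

    def test_bilinearity(self, rng):
        z = np.arange(0, 20.2, 0.2)
        da = rng.uniform(-50, 50, len(z))
        pi = rng.uniform(-500, 500, len(z))
        delta = AreaProfile(z=z, area=da)
        delta2 = AreaProfile(z=z, area=2 * da)
        prof = LateralPressureProfile(z=z, pi=pi)
        prof2 = LateralPressureProfile(z=z, pi=2 * pi)
        w = pressure_work(delta, prof, 0, 20)
        assert pressure_work(delta2, prof, 0, 20) == pytest.approx(2 * w, abs=1e-12)
        assert pressure_work(delta, prof2, 0, 20) == pytest.approx(2 * w, abs=1e-12)

    def test_non_overlapping_grids_rejected(self):
        delta = constant_profile(50.0)
        prof = LateralPressureProfile(z=delta.z + 100.0, pi=np.zeros_like(delta.z))
        with pytest.raises(ValueError):
            pressure_work(delta, prof, 0, 20)

    def test_realistic_magnitude_low_kcal_range(self, default_spec):
        # the study's 1000 A^3 geometry against profiles with few-hundred-bar
        # peaks lands in the low-kcal/mol range (order of magnitude check)
        from gpcrmech.synthdata import ground_truth_pi

        delta = constant_profile(50.0)
        pi = ground_truth_pi(default_spec, delta.z)
        prof = LateralPressureProfile(z=delta.z, pi=pi)
        w = abs(pressure_work(delta, prof, 0, 20))
        assert 0.1 < w < 10.0
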