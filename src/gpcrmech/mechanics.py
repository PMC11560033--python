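"""Protein cross-section area profiles and the work against lateral pressure.

The protein is sliced into thin slabs along the membrane normal (0.2 Å by
default); in each slab the cross-section area A(z) is the area of the
union of disks obtained by cutting the atomic van der Waals spheres at the
slab-center plane, evaluated on a 2-D occupancy grid.

For a conformational change with area difference δA(z), the mechanical
work against the membrane lateral pressure profile π(z) is

    W = ∫ δA(z) π(z) dz      [bar·Å³ → kcal/mol]

Constant offsets in the area definition (radii set, slab assignment)
cancel in δA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gpcrmech.membrane import LateralPressureProfile
from gpcrmech.structure import MolecularFrame
from gpcrmech.units import BAR_A3_TO_KCAL_PER_MOL

#: Van der Waals radii (Å) used to slice atoms into disks.
DEFAULT_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}

DEFAULT_SLAB_WIDTH = 0.2  # Å
DEFAULT_GRID_RESOLUTION = 0.1  # Å, 2-D occupancy grid


@dataclass
class AreaProfile:
    """Cross-section area A(z) (Ų) on a regular z grid (Å)."""

    z: np.ndarray
    area: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if len(self.z) != len(self.area):
            raise ValueError("z and area must have equal length")
        dz = np.diff(self.z)
        if len(dz) and not np.allclose(dz, dz[0]):
            raise ValueError("z grid must be regular")


def _element_of(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name.lstrip("0123456789")
    return name[0].upper()


def disk_union_area(
    centers_xy: np.ndarray, radii: np.ndarray, resolution: float
) -> float:
    """Area of a union of disks via a 2-D occupancy grid (Ų)."""
    if len(centers_xy) == 0:
        return 0.0
    rmax = radii.max()
    lo = centers_xy.min(axis=0) - rmax - resolution
    hi = centers_xy.max(axis=0) + rmax + resolution
    xs = np.arange(lo[0], hi[0] + resolution, resolution)
    ys = np.arange(lo[1], hi[1] + resolution, resolution)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    occupied = np.zeros(gx.shape, dtype=bool)
    for (cx, cy), r in zip(centers_xy, radii):
        occupied |= (gx - cx) ** 2 + (gy - cy) ** 2 <= r**2
    return float(occupied.sum()) * resolution**2


def cross_section_profile(
    frame: MolecularFrame,
    atom_radii: dict[str, float] | None = None,
    slab_width: float = DEFAULT_SLAB_WIDTH,
    grid_resolution: float = DEFAULT_GRID_RESOLUTION,
    z_range: tuple[float, float] | None = None,
) -> AreaProfile:
    """Per-slab union-of-disks cross-section areas of the protein.

    Each atomic sphere contributes, in a slab whose center plane it
    intersects, a disk of radius sqrt(r² − dz²) where dz is the distance
    from the atom center to the slab-center plane.
    """
    radii_map = dict(DEFAULT_RADII if atom_radii is None else atom_radii)
    mask = frame.protein_mask()
    if not np.any(mask):
        raise ValueError("empty protein selection")
    coords = frame.coords[mask]
    elements = [_element_of(a) for a in frame.atom_name[mask]]
    unknown = sorted({e for e in elements if e not in radii_map})
    if unknown:
        raise KeyError(f"no van der Waals radius for element(s) {unknown}")
    radii = np.array([radii_map[e] for e in elements])
    if z_range is None:
        z_lo = np.floor((coords[:, 2] - radii).min() / slab_width) * slab_width
        z_hi = np.ceil((coords[:, 2] + radii).max() / slab_width) * slab_width
    else:
        z_lo, z_hi = z_range
    z_grid = np.arange(z_lo, z_hi + slab_width / 2, slab_width)
    areas = np.empty(len(z_grid))
    for i, zc in enumerate(z_grid):
        dz = coords[:, 2] - zc
        cut = np.abs(dz) < radii
        if not np.any(cut):
            areas[i] = 0.0
            continue
        disk_r = np.sqrt(radii[cut] ** 2 - dz[cut] ** 2)
        areas[i] = disk_union_area(coords[cut, :2], disk_r, grid_resolution)
    return AreaProfile(
        z=z_grid,
        area=areas,
        provenance={"slab_width": slab_width, "grid_resolution": grid_resolution},
    )


def average_profiles(profiles: list[AreaProfile]) -> AreaProfile:
    """Frame average of area profiles sharing one grid."""
    z0 = profiles[0].z
    for p in profiles[1:]:
        if len(p.z) != len(z0) or not np.allclose(p.z, z0):
            raise ValueError("area profiles must share the same z grid")
    return AreaProfile(
        z=z0.copy(),
        area=np.mean([p.area for p in profiles], axis=0),
        provenance={"frames_averaged": len(profiles)},
    )


def mean_area_range(profile: AreaProfile, z_lo: float, z_hi: float) -> float:
    """Mean A(z) over slabs with z_lo ≤ z ≤ z_hi (Ų)."""
    mask = (profile.z >= z_lo - 1e-9) & (profile.z <= z_hi + 1e-9)
    if not np.any(mask):
        raise ValueError(f"range [{z_lo}, {z_hi}] contains no grid points")
    return float(profile.area[mask].mean())


def delta_area(profile_a: AreaProfile, profile_b: AreaProfile) -> AreaProfile:
    """Pointwise area difference a − b (may be negative)."""
    if len(profile_a.z) != len(profile_b.z) or not np.allclose(profile_a.z, profile_b.z):
        raise ValueError("area profiles must share the same z grid")
    return AreaProfile(
        z=profile_a.z.copy(),
        area=profile_a.area - profile_b.area,
        provenance={"difference": True},
    )


def enclosed_volume(delta: AreaProfile, z_lo: float, z_hi: float) -> float:
    """Trapezoidal integral of δA(z) over [z_lo, z_hi] (Å³)."""
    mask = (delta.z >= z_lo - 1e-9) & (delta.z <= z_hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"range [{z_lo}, {z_hi}] spans fewer than two grid points")
    return float(np.trapezoid(delta.area[mask], delta.z[mask]))


def pressure_work(
    delta: AreaProfile,
    profile: LateralPressureProfile,
    z_lo: float,
    z_hi: float,
) -> float:
    """W = ∫ δA(z)·π(z) dz over [z_lo, z_hi], in kcal/mol.

    π(z) is linearly resampled onto the area grid; the grids must overlap
    the requested range.
    """
    mask = (delta.z >= z_lo - 1e-9) & (delta.z <= z_hi + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"range [{z_lo}, {z_hi}] spans fewer than two grid points")
    z = delta.z[mask]
    if z[0] < profile.z[0] - 1e-9 or z[-1] > profile.z[-1] + 1e-9:
        raise ValueError("pressure profile does not cover the requested z range")
    pi = np.interp(z, profile.z, profile.pi)
    w_bar_a3 = np.trapezoid(delta.area[mask] * pi, z)
    return float(w_bar_a3 * BAR_A3_TO_KCAL_PER_MOL)
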