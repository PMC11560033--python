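"""Synthetic inputs with known ground truth.

Generators for every input the analysis pipeline consumes:

* an ideal α-helix and a toy 7-TM receptor bundle with Ballesteros–
  Weinstein numbering whose marker distances (d36, d37) are set exactly;
* opening trajectories in which the TM6 segment 6.32–6.48 rotates by a
  scheduled angle and TM7 follows an inward/outward/static scenario;
* two-leaflet bilayers of PC/PG head-group pseudo-atoms with controllable
  thickness, composition and internal-lipid placement;
* per-slab pressure-tensor series built from a known π(z) (two positive
  head-group peaks, two negative interface peaks) plus white noise and
  leaflet drift;
* H-bond donor/hydrogen/acceptor scenes at a requested distance and angle.

Every generator is deterministic under a fixed seed.  The geometry is
statistical/geometric only — no force-field energetics, no acyl chains —
which is exactly what the downstream measurements consume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from gpcrmech.contacts import HBondGeometry
from gpcrmech.membrane import PressureSlabSeries
from gpcrmech.structure import BWScheme, MolecularFrame, Trajectory

#: Helix direction along z per helix number: odd helices run
#: extracellular (−z) → intracellular (+z), even helices the reverse.
HELIX_DIRECTION = {1: 1, 2: -1, 3: 1, 4: -1, 5: 1, 6: -1, 7: 1}

#: TM6 moving segment (BW positions) driven by the opening schedule.
TM6_SEGMENT = (32, 48)


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth parameters for all synthetic generators.

    Defaults mirror the study conditions: a 35° TM6 opening scheduled over
    20 ns followed by 70 ns of relaxation and sampled as 12 equidistant
    snapshots; an initial TM3–TM7 distance of 20 Å (the inactive value);
    a 38.8 Å-thick bilayer; a 9:1 PC:PG head-group mix; 100 pressure
    slabs with head-group peaks of a few hundred bar.
    """

    seed: int = 0
    # receptor geometry
    n_helices: int = 7  # the bundle is a 7-TM fold; other counts are rejected
    bundle_radius: float = 11.0  # Å, helix centers on this circle
    helix_halfspan: int = 13  # residues kept either side of each x.50 anchor
    marker_z: float = 12.0  # Å, z of the intracellular marker Cα atoms
    d36: float = 8.0  # Å, initial Cα 3.50-6.34 distance
    d37: float = 20.0  # Å, initial Cα 3.50-7.55 distance (inactive: 20 ± 1)
    with_donors: bool = True  # add side-chain N-H atoms at 7.58/7.59/7.61/7.62
    # TM6 opening schedule
    tm6_target_angle: float = 35.0  # degrees
    pull_ns: float = 20.0
    relax_ns: float = 70.0
    n_frames: int = 12
    # TM7 scenario
    tm7_scenario: str = "static"  # "inward" | "outward" | "static"
    tm7_target_d37: float | None = None  # Å, endpoint of the d37 ramp
    tm7_ramp_ns: float = 60.0  # d37 reaches the target here, then holds
    noise_sigma: float = 0.0  # Å, per-atom Gaussian jitter per frame
    # bilayer
    leaflet_separation: float = 38.8  # Å, P-to-P distance
    n_lipids_per_leaflet: int = 30  # reduced scale (study systems used 60)
    pc_fraction: float = 0.9  # PC:PG = 9:1 MIX composition
    lipid_jitter_z: float = 1.0  # Å, leaflet roughness
    lipid_exclusion_radius: float = 20.0  # Å, annulus keeping lipids off the bundle
    internal_fraction: float = 0.0  # fraction of frames with an internal lipid
    # pressure profile ground truth (bar, Å)
    n_slabs: int = 100
    lz: float = 100.0
    head_peak_height: float = 500.0
    head_peak_z: float = 19.4
    head_peak_width: float = 2.5
    interface_peak_height: float = -400.0
    interface_peak_z: float = 12.0
    interface_peak_width: float = 3.0
    pressure_baseline: float = 1.0  # bar, pzz
    pressure_noise: float = 50.0  # bar, white noise on pxx/pyy
    drift_rate: float = 0.0  # Å/ns, linear leaflet drift
    pressure_n_times: int = 200
    pressure_dt_ns: float = 0.5

    def with_(self, **kw) -> "GeneratorSpec":
        return replace(self, **kw)

    @property
    def frame_dt(self) -> float:
        return (self.pull_ns + self.relax_ns) / self.n_frames

    @property
    def scheme(self) -> BWScheme:
        return BWScheme()


def ideal_helix(
    n_res: int, rise: float = 1.5, twist: float = 100.0, radius: float = 2.3
) -> np.ndarray:
    """Cα coordinates of an ideal α-helix along +z (3.6 residues/turn)."""
    if n_res < 2:
        raise ValueError("a helix needs at least 2 residues")
    i = np.arange(n_res)
    phi = np.radians(i * twist)
    return np.column_stack([radius * np.cos(phi), radius * np.sin(phi), i * rise])


def _helix_residue_range(scheme: BWScheme, helix: int, halfspan: int) -> range:
    anchor = scheme.anchors[helix]
    lo = halfspan if helix != 6 else 50 - TM6_SEGMENT[0]  # TM6 reaches down to 6.32
    hi = halfspan if helix != 7 else 12  # helix 7 extends into H8 (up to 7.62)
    return range(anchor - lo, anchor + hi + 1)


def _build_bundle(spec: GeneratorSpec) -> dict:
    """Helix Cα coordinates keyed by helix number, plus residue numbers."""
    scheme = spec.scheme
    bundle = {}
    for h in range(1, 8):
        residues = list(_helix_residue_range(scheme, h, spec.helix_halfspan))
        coords = ideal_helix(len(residues))
        if HELIX_DIRECTION[h] < 0:
            coords = coords[:, [0, 1, 2]] * np.array([1.0, -1.0, -1.0])
        # place the marker residue's z at spec.marker_z; markers are the
        # intracellular-side reference Cα of each helix (x.50 for TM3-like
        # mid-anchors is shifted so 3.50 / 6.34 / 7.55 share one z plane)
        marker_bw = {3: 50, 6: 34, 7: 55}.get(h, 50)
        marker_res = scheme.anchors[h] + (marker_bw - 50)
        k = residues.index(marker_res)
        coords = coords - coords[k] * np.array([0.0, 0.0, 1.0]) + np.array(
            [0.0, 0.0, spec.marker_z]
        )
        angle = 2.0 * np.pi * (h - 1) / 7.0
        center = spec.bundle_radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        coords = coords + np.array([center[0], center[1], 0.0])
        bundle[h] = {"residues": residues, "coords": coords, "marker_res": marker_res}
    return bundle


def _marker_xyz(bundle: dict, helix: int) -> np.ndarray:
    info = bundle[helix]
    return info["coords"][info["residues"].index(info["marker_res"])]


def _place_helix_at_distance(bundle: dict, helix: int, target: float) -> None:
    """Rigidly translate a helix in xy so its marker sits ``target`` Å from
    the TM3 marker (markers share one z plane, so the xy distance is the
    full distance)."""
    ref = _marker_xyz(bundle, 3)
    cur = _marker_xyz(bundle, helix)
    direction = cur[:2] - ref[:2]
    d = np.linalg.norm(direction)
    if d < 1e-9:
        direction, d = np.array([1.0, 0.0]), 1.0
    shift2d = (target - d) * direction / d
    bundle[helix]["coords"][:, :2] += shift2d


def toy_receptor(spec: GeneratorSpec) -> MolecularFrame:
    """A 7-helix bundle with BW numbering and exact marker distances.

    Marker distances d36 (Cα 3.50–6.34) and d37 (Cα 3.50–7.55) equal the
    spec's values by construction.  Side-chain donor pseudo-atoms (NZ/HZ1
    for Lys, NE/HE for Arg) are attached at the C-terminal positions when
    ``with_donors`` is set.
    """
    if spec.n_helices != 7:
        raise ValueError("the toy receptor models a 7-TM bundle; n_helices must be 7")
    if not 0 < spec.d36 < 4 * spec.bundle_radius or not 0 < spec.d37 < 4 * spec.bundle_radius:
        raise ValueError("marker distance targets incompatible with bundle radius")
    scheme = spec.scheme
    bundle = _build_bundle(spec)
    _place_helix_at_distance(bundle, 6, spec.d36)
    _place_helix_at_distance(bundle, 7, spec.d37)

    res_id, res_name, atom_name, chain, coords = [], [], [], [], []
    donor_res = {
        scheme.resolve("7.58"): ("LYS", "NZ", "HZ1"),
        scheme.resolve("7.59"): ("LYS", "NZ", "HZ1"),
        scheme.resolve("7.61"): ("LYS", "NZ", "HZ1"),
        scheme.resolve("7.62"): ("ARG", "NE", "HE"),
    }
    center_xy = np.zeros(2)
    for h in range(1, 8):
        info = bundle[h]
        for res, xyz in zip(info["residues"], info["coords"]):
            rname = donor_res.get(res, ("ALA",))[0] if spec.with_donors else "ALA"
            res_id.append(res)
            res_name.append(rname)
            atom_name.append("CA")
            chain.append("A")
            coords.append(xyz)
            if spec.with_donors and res in donor_res:
                _, n_name, h_name = donor_res[res]
                out = xyz[:2] - center_xy
                out = out / np.linalg.norm(out)
                n_xyz = xyz + np.array([out[0] * 3.0, out[1] * 3.0, 0.5])
                h_xyz = n_xyz + np.array([out[0], out[1], 0.0])
                for name, pos in ((n_name, n_xyz), (h_name, h_xyz)):
                    res_id.append(res)
                    res_name.append(rname)
                    atom_name.append(name)
                    chain.append("A")
                    coords.append(pos)
    return MolecularFrame(
        time=0.0,
        res_id=np.array(res_id),
        res_name=np.array(res_name),
        atom_name=np.array(atom_name),
        chain=np.array(chain),
        coords=np.array(coords),
        box=(spec.lz, spec.lz, spec.lz),
    )


def _tm6_rotation(spec: GeneratorSpec, frame0: MolecularFrame, theta_deg: float):
    """Rotation (matrix, pivot) tilting the TM6 segment outward by theta."""
    scheme = spec.scheme
    seg = [scheme.resolve(f"6.{p}") for p in range(TM6_SEGMENT[0], TM6_SEGMENT[1] + 1)]
    sel = np.isin(frame0.res_id, seg) & (frame0.atom_name == "CA")
    pts = frame0.coords[sel]
    # helix axis ≈ z; tilt about the in-plane direction perpendicular to
    # the radial direction, so the segment swings away from the bundle
    radial = pts.mean(axis=0)[:2]
    radial = radial / np.linalg.norm(radial)
    axis = np.array([-radial[1], radial[0], 0.0])
    theta = np.radians(theta_deg)
    k = axis
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
    pivot_res = scheme.resolve(f"6.{TM6_SEGMENT[1]}")
    pivot = frame0.coords[
        (frame0.res_id == pivot_res) & (frame0.atom_name == "CA")
    ][0]
    return np.isin(frame0.res_id, seg), rot, pivot


def theta_schedule(spec: GeneratorSpec, t: float) -> float:
    """Programmed TM6 opening angle at time t: linear ramp then hold."""
    if spec.pull_ns <= 0:
        return 0.0
    return spec.tm6_target_angle * min(t / spec.pull_ns, 1.0)


def d37_schedule(spec: GeneratorSpec, t: float) -> float:
    """Programmed TM3–TM7 distance at time t under the TM7 scenario."""
    if spec.tm7_scenario == "static" or spec.tm7_target_d37 is None:
        return spec.d37
    frac = min(t / spec.tm7_ramp_ns, 1.0) if spec.tm7_ramp_ns > 0 else 1.0
    return spec.d37 + (spec.tm7_target_d37 - spec.d37) * frac


def opening_trajectory(spec: GeneratorSpec, include_bilayer: bool = False) -> Trajectory:
    """Snapshots of the scheduled TM6 opening with the TM7 scenario applied.

    Measuring the TM6 segment axis per frame with the helix-geometry module
    recovers the programmed θ(t); measuring marker distances recovers the
    programmed d37(t).
    """
    if spec.tm7_scenario not in ("inward", "outward", "static"):
        raise ValueError(f"unknown TM7 scenario {spec.tm7_scenario!r}")
    if spec.tm6_target_angle != 0 and spec.pull_ns > spec.pull_ns + spec.relax_ns:
        raise ValueError("schedule longer than the trajectory")
    rng = np.random.default_rng(spec.seed)
    base = toy_receptor(spec)
    if include_bilayer:
        base = synthetic_bilayer(spec, base)
    seg_mask, _, pivot = _tm6_rotation(spec, base, 0.0)
    scheme = spec.scheme
    helix7_res = list(_helix_residue_range(scheme, 7, spec.helix_halfspan))
    h7_mask = np.isin(base.res_id, helix7_res) & (base.chain == "A")
    marker3 = base.coords[
        (base.res_id == scheme.resolve("3.50")) & (base.atom_name == "CA")
    ][0]
    marker7 = base.coords[
        (base.res_id == scheme.resolve("7.55")) & (base.atom_name == "CA")
    ][0]
    d37_dir = (marker7[:2] - marker3[:2]) / np.linalg.norm(marker7[:2] - marker3[:2])

    n_internal_frames = int(round(spec.internal_fraction * spec.n_frames))
    frames = []
    for i in range(spec.n_frames):
        t = i * spec.frame_dt
        coords = base.coords.copy()
        # TM6 segment: rigid rotation about the hinge at 6.48
        _, rot, _ = _tm6_rotation(spec, base, theta_schedule(spec, t))
        coords[seg_mask] = (coords[seg_mask] - pivot) @ rot.T + pivot
        # TM7: rigid in-plane translation realizing the d37 schedule
        coords[h7_mask, :2] += d37_dir * (d37_schedule(spec, t) - spec.d37)
        if include_bilayer and spec.internal_fraction > 0:
            coords = _apply_internal_program(
                spec, base, coords, internal=(i < n_internal_frames)
            )
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
        frames.append(
            MolecularFrame(
                time=t,
                res_id=base.res_id,
                res_name=base.res_name,
                atom_name=base.atom_name,
                chain=base.chain,
                coords=coords,
                box=base.box,
            )
        )
    return Trajectory(
        frames=frames,
        metadata={
            "seed": spec.seed,
            "tm6_target_angle": spec.tm6_target_angle,
            "tm7_scenario": spec.tm7_scenario,
            "tm7_target_d37": spec.tm7_target_d37,
        },
    )


#: residue id given to the lipid whose head follows the internal program
INTERNAL_LIPID_RESID = 9000


def _apply_internal_program(
    spec: GeneratorSpec, base: MolecularFrame, coords: np.ndarray, internal: bool
) -> np.ndarray:
    """Move the programmed lipid inside (cavity midpoint) or far outside."""
    scheme = spec.scheme
    ca3 = base.coords[(base.res_id == scheme.resolve("3.50")) & (base.atom_name == "CA")][0]
    ca7 = base.coords[(base.res_id == scheme.resolve("7.56")) & (base.atom_name == "CA")][0]
    target = (ca3 + ca7) / 2.0 if internal else np.array([45.0, 45.0, spec.leaflet_separation / 2])
    lip = base.res_id == INTERNAL_LIPID_RESID
    p_idx = np.where(lip & (base.atom_name == "P"))[0]
    shift = target - coords[p_idx[0]]
    coords[lip] = coords[lip] + shift
    return coords


def synthetic_bilayer(spec: GeneratorSpec, frame: MolecularFrame | None = None) -> MolecularFrame:
    """Append two leaflets of PC/PG head-group pseudo-atoms to a frame.

    Heads (P plus two acceptor oxygens O11/O12) sit at ±separation/2 with
    Gaussian z jitter, on a ring lattice outside the receptor footprint.
    Head types follow the PC fraction (largest-remainder rounding).  When
    an internal-lipid program is active, one intracellular-leaflet lipid
    (residue id 9000) is reserved for it.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_lipids_per_leaflet
    n_pc = int(round(spec.pc_fraction * n))
    res_id, res_name, atom_name, chain, coords = [], [], [], [], []
    next_res = 1001
    for leaflet_sign in (1, -1):
        z0 = leaflet_sign * spec.leaflet_separation / 2.0
        placed = 0
        ring = 0
        while placed < n:
            r = spec.lipid_exclusion_radius + 8.0 * ring
            n_on_ring = max(int(2 * np.pi * r / 8.0), 1)
            for j in range(n_on_ring):
                if placed >= n:
                    break
                ang = 2 * np.pi * j / n_on_ring + 0.1 * ring
                x, y = r * np.cos(ang), r * np.sin(ang)
                z = z0 + rng.normal(0.0, spec.lipid_jitter_z)
                rname = ("POPC" if placed < n_pc else "DOPG")
                is_program = (
                    leaflet_sign == 1 and placed == n - 1 and spec.internal_fraction > 0
                )
                rid = INTERNAL_LIPID_RESID if is_program else next_res
                if is_program:
                    rname = "DOPG" if spec.pc_fraction < 1 else "POPC"
                for name, off in (
                    ("P", (0.0, 0.0, 0.0)),
                    ("O11", (1.2, 0.0, 0.6)),
                    ("O12", (-1.2, 0.0, 0.6)),
                ):
                    res_id.append(rid)
                    res_name.append(rname)
                    atom_name.append(name)
                    chain.append("L")
                    coords.append((x + off[0], y + off[1], z + off[2]))
                if not is_program:
                    next_res += 1
                placed += 1
            ring += 1
    lipids = MolecularFrame(
        time=0.0 if frame is None else frame.time,
        res_id=np.array(res_id),
        res_name=np.array(res_name),
        atom_name=np.array(atom_name),
        chain=np.array(chain),
        coords=np.array(coords),
        box=None if frame is None else frame.box,
    )
    if frame is None:
        return lipids
    return MolecularFrame(
        time=frame.time,
        res_id=np.concatenate([frame.res_id, lipids.res_id]),
        res_name=np.concatenate([frame.res_name, lipids.res_name]),
        atom_name=np.concatenate([frame.atom_name, lipids.atom_name]),
        chain=np.concatenate([frame.chain, lipids.chain]),
        coords=np.vstack([frame.coords, lipids.coords]),
        box=frame.box,
    )


def ground_truth_pi(spec: GeneratorSpec, z: np.ndarray) -> np.ndarray:
    """The generator's π(z): two positive head peaks, two negative
    interface peaks (symmetric Gaussian pairs), in bar."""

    def gauss(z0, h, w):
        return h * np.exp(-((z - z0) ** 2) / (2 * w**2))

    return (
        gauss(+spec.head_peak_z, spec.head_peak_height, spec.head_peak_width)
        + gauss(-spec.head_peak_z, spec.head_peak_height, spec.head_peak_width)
        + gauss(+spec.interface_peak_z, spec.interface_peak_height, spec.interface_peak_width)
        + gauss(-spec.interface_peak_z, spec.interface_peak_height, spec.interface_peak_width)
    )


def synthetic_pressure_series(spec: GeneratorSpec) -> PressureSlabSeries:
    """Per-slab pressure tensors realizing a known π(z) plus noise/drift.

    pzz is a flat baseline; pxx = pyy = pzz + π(z − drift(t)) + noise, so
    (pxx+pyy)/2 − pzz recovers the drift-shifted ground truth.  The drift
    is recorded in the z_P (phosphorus barycenter) sidecar channel exactly
    as the profile pipeline expects.
    """
    if spec.head_peak_width > spec.lz or spec.interface_peak_width > spec.lz:
        raise ValueError("peak widths exceed the box")
    rng = np.random.default_rng(spec.seed + 2)
    z = (np.arange(spec.n_slabs) + 0.5) * spec.lz / spec.n_slabs - spec.lz / 2.0
    times = np.arange(spec.pressure_n_times) * spec.pressure_dt_ns
    pzz = np.full((len(times), len(z)), spec.pressure_baseline)
    pxx = np.empty_like(pzz)
    for i, t in enumerate(times):
        shift = spec.drift_rate * t
        pi_t = ground_truth_pi(spec, z - shift)
        pxx[i] = spec.pressure_baseline + pi_t
    noise_x = rng.normal(0.0, spec.pressure_noise, pzz.shape) if spec.pressure_noise else 0.0
    noise_y = rng.normal(0.0, spec.pressure_noise, pzz.shape) if spec.pressure_noise else 0.0
    return PressureSlabSeries(
        times=times,
        z=z,
        pxx=pxx + noise_x,
        pyy=pxx + noise_y,
        pzz=pzz,
        lz=np.full(len(times), spec.lz),
        z_p=spec.drift_rate * times,
        metadata={"seed": spec.seed, "ground_truth": "four-gaussian"},
    )


def contact_scene(
    spec: GeneratorSpec, scene: list[tuple[str, float, float]]
) -> MolecularFrame:
    """Receptor frame with lipid acceptors placed at programmed geometries.

    ``scene`` lists (BW position, donor-acceptor distance Å, H-D-A angle
    degrees); one single-oxygen lipid head is appended per entry, so the
    H-bond verdict at each position is known by construction.
    """
    frame = toy_receptor(spec.with_(with_donors=True))
    res_id = list(frame.res_id)
    res_name = list(frame.res_name)
    atom_name = list(frame.atom_name)
    chain = list(frame.chain)
    coords = list(frame.coords)
    scheme = spec.scheme
    next_res = 8000
    for pos, distance, angle in scene:
        res = scheme.resolve(pos)
        sel = frame.res_id == res
        names = frame.atom_name[sel]
        n_mask = np.isin(names, ("NZ", "NE"))
        h_mask = np.isin(names, ("HZ1", "HE"))
        if not n_mask.any() or not h_mask.any():
            raise ValueError(f"no donor atoms at BW {pos}; build with with_donors=True")
        n_xyz = frame.coords[sel][n_mask][0]
        h_xyz = frame.coords[sel][h_mask][0]
        dh = (h_xyz - n_xyz) / np.linalg.norm(h_xyz - n_xyz)
        # rotate D->H by the requested angle within the plane spanned by
        # the D->H direction and z
        perp = np.array([0.0, 0.0, 1.0]) - (np.array([0.0, 0.0, 1.0]) @ dh) * dh
        perp /= np.linalg.norm(perp)
        a = np.radians(angle)
        direction = np.cos(a) * dh + np.sin(a) * perp
        acceptor = n_xyz + distance * direction
        for name, xyz in (("O11", acceptor), ("P", acceptor + np.array([0.0, 0.0, 4.0]))):
            res_id.append(next_res)
            res_name.append("POPC")
            atom_name.append(name)
            chain.append("L")
            coords.append(xyz)
        next_res += 1
    return MolecularFrame(
        time=0.0,
        res_id=np.array(res_id),
        res_name=np.array(res_name),
        atom_name=np.array(atom_name),
        chain=np.array(chain),
        coords=np.array(coords),
        box=frame.box,
    )


def hbond_scene(distance: float, angle: float) -> HBondGeometry:
    """Donor at the origin, H at 1 Å along x, acceptor at the requested
    donor–acceptor distance and donor-centered H–D–A angle (degrees)."""
    if distance <= 1.2:
        raise ValueError("donor-acceptor distance must exceed the D-H bond length")
    if not 0.0 <= angle <= 180.0:
        raise ValueError("angle must lie in [0, 180] degrees")
    a = np.radians(angle)
    return HBondGeometry(
        donor=np.zeros(3),
        hydrogen=np.array([1.0, 0.0, 0.0]),
        acceptor=np.array([distance * np.cos(a), distance * np.sin(a), 0.0]),
    )
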