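"""Lipid–receptor H-bond detection and the internal-lipid criterion.

An H-bond between a donor heavy atom D (with bonded hydrogen H) and an
acceptor heavy atom A is counted when

    d(D, A) ≤ 3.5 Å   and   angle(H−D−A) ≤ 30°

(the angle between the D→H and D→A directions).  H-bonds are tallied
between lipid head-group oxygens and the side-chain N–H donors of the
basic C-terminal residues at BW positions 7.58, 7.59, 7.61 and 7.62.

A lipid of the intracellular leaflet is *internal* — its head group sits
inside the receptor's intracellular cavity — when its phosphorus P obeys
all four strict inequalities

    d(P, Cα3.50) < 15 Å,  d(P, Cα7.56) < 12 Å,
    d(P, Cα3.50) < d(Cα3.50, Cα7.56),  d(P, Cα7.56) < d(Cα3.50, Cα7.56)

the last two excluding external lipids near the TM5–TM6 cleft.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from gpcrmech.structure import BWScheme, MolecularFrame, Trajectory, select_calpha

HBOND_DISTANCE_CUTOFF = 3.5  # Å, donor-acceptor heavy atoms
HBOND_ANGLE_CUTOFF = 30.0  # degrees, H-D-A
DH_BOND_MAX = 1.2  # Å, hydrogen counted as bonded to its donor

INTERNAL_D3_MAX = 15.0  # Å, P to Cα 3.50
INTERNAL_D7_MAX = 12.0  # Å, P to Cα 7.56

#: C-terminal BW positions probed for lipid H-bonds (Lys/Arg side chains).
CTERM_POSITIONS = ("7.58", "7.59", "7.61", "7.62")

#: Side-chain donor nitrogen names (Lys NZ; Arg NE/NH1/NH2).
DONOR_N_NAMES = ("NZ", "NE", "NH1", "NH2")
#: Lipid head-group acceptor oxygens (phosphate + glycerol/ester).
ACCEPTOR_O_NAMES = ("O11", "O12", "O13", "O14", "O21", "O22", "O31", "O32", "OC2", "OC3")


@dataclass(frozen=True)
class HBondGeometry:
    """Donor / hydrogen / acceptor coordinates of one candidate H-bond."""

    donor: np.ndarray
    hydrogen: np.ndarray
    acceptor: np.ndarray
    donor_id: str = ""
    acceptor_id: str = ""

    def __post_init__(self) -> None:
        for name in ("donor", "hydrogen", "acceptor"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.linalg.norm(self.hydrogen - self.donor) > DH_BOND_MAX:
            raise ValueError(
                f"hydrogen is {np.linalg.norm(self.hydrogen - self.donor):.2f} A "
                f"from its donor; not a bonded pair (max {DH_BOND_MAX} A)"
            )


@dataclass
class ContactRecord:
    """Per-frame H-bond counts by BW position plus internal-lipid flags."""

    time: float
    hbond_counts: dict[str, int]
    internal_flags: dict[int, bool] = field(default_factory=dict)

    @property
    def total_hbonds(self) -> int:
        return sum(self.hbond_counts.values())

    @property
    def has_internal(self) -> bool:
        return any(self.internal_flags.values())


def is_hbond(geom: HBondGeometry) -> bool:
    """Apply the distance (≤3.5 Å) and angle (≤30°) cutoffs."""
    eps = 1e-9  # keep exact-boundary geometries on the inclusive side
    da = geom.acceptor - geom.donor
    dh = geom.hydrogen - geom.donor
    dist = np.linalg.norm(da)
    if dist > HBOND_DISTANCE_CUTOFF + eps:
        return False
    cosang = (da @ dh) / (np.linalg.norm(da) * np.linalg.norm(dh))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return bool(angle <= HBOND_ANGLE_CUTOFF + eps)


def _position_donors(frame: MolecularFrame, res: int):
    """(N coordinate, [H coordinates]) pairs of one residue's side chain."""
    donors = []
    sel = frame.res_id == res
    names = frame.atom_name[sel]
    coords = frame.coords[sel]
    for n_name in DONOR_N_NAMES:
        n_hit = names == n_name
        if not np.any(n_hit):
            continue
        n_xyz = coords[n_hit][0]
        h_mask = np.char.startswith(names.astype(str), "H")
        h_near = coords[h_mask][
            np.linalg.norm(coords[h_mask] - n_xyz, axis=1) <= DH_BOND_MAX
        ]
        if len(h_near):
            donors.append((n_xyz, h_near))
    return donors


def cterm_hbond_counts(frame: MolecularFrame, scheme: BWScheme) -> dict[str, int]:
    """H-bond count per C-terminal BW position (atom-pair counting).

    A position with no resolvable side-chain donor is skipped with a
    warning rather than failing, so partially stripped rosters remain
    analyzable.
    """
    lipid = frame.lipid_mask()
    acc_mask = lipid & np.isin(frame.atom_name, ACCEPTOR_O_NAMES)
    acceptors = frame.coords[acc_mask]
    counts: dict[str, int] = {}
    for pos in CTERM_POSITIONS:
        res = scheme.resolve(pos)
        donors = _position_donors(frame, res)
        if not donors:
            warnings.warn(f"no side-chain donor atoms for BW {pos} (residue {res})")
            counts[pos] = 0
            continue
        n = 0
        for n_xyz, h_list in donors:
            for acc in acceptors:
                for h_xyz in h_list:
                    if is_hbond(HBondGeometry(n_xyz, h_xyz, acc)):
                        n += 1
                        break  # one bond per donor-acceptor atom pair
        counts[pos] = n
    return counts


def internal_lipid_flags(frame: MolecularFrame, scheme: BWScheme) -> dict[int, bool]:
    """Internal-lipid verdict per intracellular-leaflet lipid phosphorus."""
    markers = select_calpha(frame, [scheme.resolve("3.50"), scheme.resolve("7.56")])
    ca3, ca7 = markers
    d_ref = float(np.linalg.norm(ca3 - ca7))
    lipid = frame.lipid_mask()
    p_mask = lipid & (frame.atom_name == "P") & (frame.leaflet() == 1)
    flags: dict[int, bool] = {}
    for res, xyz in zip(frame.res_id[p_mask], frame.coords[p_mask]):
        d3 = float(np.linalg.norm(xyz - ca3))
        d7 = float(np.linalg.norm(xyz - ca7))
        flags[int(res)] = (
            d3 < INTERNAL_D3_MAX and d7 < INTERNAL_D7_MAX and d3 < d_ref and d7 < d_ref
        )
    return flags


def internal_fraction(traj: Trajectory, scheme: BWScheme) -> float:
    """Fraction of frames with at least one internal lipid."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    hits = sum(
        1 for f in traj if any(internal_lipid_flags(f, scheme).values())
    )
    return hits / len(traj)


def contact_records(traj: Trajectory, scheme: BWScheme) -> list[ContactRecord]:
    """Per-frame H-bond counts and internal flags for a trajectory."""
    return [
        ContactRecord(
            time=f.time,
            hbond_counts=cterm_hbond_counts(f, scheme),
            internal_flags=internal_lipid_flags(f, scheme),
        )
        for f in traj
    ]
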