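"""H-bond detection and the internal-lipid criterion."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpcrmech import synthdata
from gpcrmech.contacts import (
    HBondGeometry,
    cterm_hbond_counts,
    internal_fraction,
    internal_lipid_flags,
    is_hbond,
)
from gpcrmech.synthdata import GeneratorSpec, contact_scene, hbond_scene


class TestIsHbond:
    @pytest.mark.parametrize(
        "distance,angle,expected",
        [
            (2.9, 15.0, True),
            (3.6, 5.0, False),  # distance fails
            (3.0, 35.0, False),  # angle fails
            (3.5, 30.0, True),  # boundary: cutoffs are inclusive
            (3.51, 0.0, False),
        ],
    )
    def test_cutoff_rules(self, distance, angle, expected):
        assert is_hbond(hbond_scene(distance, angle)) is expected

    def test_rigid_motion_invariance(self, rng):
        geom = hbond_scene(3.2, 20.0)
        for _ in range(100):
            q = rng.standard_normal(4)
            rot = Rotation.from_quat(q / np.linalg.norm(q))
            shift = rng.uniform(-50, 50, 3)
            moved = HBondGeometry(
                donor=rot.apply(geom.donor) + shift,
                hydrogen=rot.apply(geom.hydrogen) + shift,
                acceptor=rot.apply(geom.acceptor) + shift,
            )
            assert is_hbond(moved) == is_hbond(geom)

    def test_detached_hydrogen_rejected(self):
        with pytest.raises(ValueError, match="donor"):
            HBondGeometry(
                donor=np.zeros(3),
                hydrogen=np.array([2.0, 0, 0]),
                acceptor=np.array([3.0, 0, 0]),
            )


class TestCtermCounts:
    def test_programmed_scene_counts(self, default_spec, scheme):
        frame = contact_scene(
            default_spec,
            [("7.58", 2.9, 15.0), ("7.58", 3.0, 10.0), ("7.59", 3.6, 5.0)],
        )
        # brute-force oracle: re-evaluate every donor/acceptor pair
        counts = cterm_hbond_counts(frame, scheme)
        assert counts == {"7.58": 2, "7.59": 0, "7.61": 0, "7.62": 0}

    def test_boundary_pair_counting(self, default_spec, scheme):
        frame = contact_scene(
            default_spec, [("7.61", 3.4, 29.0), ("7.61", 3.6, 10.0)]
        )
        counts = cterm_hbond_counts(frame, scheme)
        assert sum(counts.values()) == 1

    def test_no_lipids_all_zero(self, receptor_frame, scheme):
        counts = cterm_hbond_counts(receptor_frame, scheme)
        assert counts == {p: 0 for p in ("7.58", "7.59", "7.61", "7.62")}

    def test_counts_monotone_under_added_contact(self, default_spec, scheme):
        base = cterm_hbond_counts(
            contact_scene(default_spec, [("7.59", 3.0, 5.0)]), scheme
        )
        more = cterm_hbond_counts(
            contact_scene(
                default_spec, [("7.59", 3.0, 5.0), ("7.62", 2.8, 12.0)]
            ),
            scheme,
        )
        assert all(more[p] >= base[p] for p in base)

    def test_missing_donor_warns_not_fails(self, default_spec, scheme):
        frame = synthdata.toy_receptor(default_spec.with_(with_donors=False))
        with pytest.warns(UserWarning, match="donor"):
            counts = cterm_hbond_counts(frame, scheme)
        assert sum(counts.values()) == 0


def flags_oracle(p, ca3, ca7):
    """Direct re-evaluation of the four internal-lipid inequalities."""
    d3 = np.linalg.norm(p - ca3)
    d7 = np.linalg.norm(p - ca7)
    d_ref = np.linalg.norm(ca3 - ca7)
    return d3 < 15.0 and d7 < 12.0 and d3 < d_ref and d7 < d_ref


class TestInternalLipids:
    def make_frame(self, p_xyz, scheme, default_spec):
        frame = synthdata.toy_receptor(default_spec)
        return synthdata_frame_with_lipid(frame, p_xyz)

    def test_midpoint_lipid_is_internal(self, default_spec, scheme):
        frame = synthdata.toy_receptor(default_spec)
        ca3 = frame.coords[(frame.res_id == scheme.resolve("3.50")) & (frame.atom_name == "CA")][0]
        ca7 = frame.coords[(frame.res_id == scheme.resolve("7.56")) & (frame.atom_name == "CA")][0]
        mid = (ca3 + ca7) / 2.0
        flags = internal_lipid_flags(
            synthdata_frame_with_lipid(frame, mid), scheme
        )
        assert flags == {5000: True}

    def test_far_lipid_is_external(self, default_spec, scheme):
        frame = synthdata.toy_receptor(default_spec)
        flags = internal_lipid_flags(
            synthdata_frame_with_lipid(frame, np.array([40.0, 40.0, 20.0])), scheme
        )
        assert flags == {5000: False}

    def test_truth_table_against_oracle(self, default_spec, scheme, rng):
        frame = synthdata.toy_receptor(default_spec)
        ca3 = frame.coords[(frame.res_id == scheme.resolve("3.50")) & (frame.atom_name == "CA")][0]
        ca7 = frame.coords[(frame.res_id == scheme.resolve("7.56")) & (frame.atom_name == "CA")][0]
        # positions probing every region of the four-condition truth table
        probes = [(ca3 + ca7) / 2.0]
        for _ in range(60):
            probes.append(
                (ca3 + ca7) / 2.0 + rng.uniform(-20, 20, 3) * np.array([1, 1, 0.2])
            )
        for p in probes:
            p = p.copy()
            p[2] = max(p[2], 1.0)  # keep in the intracellular leaflet
            flags = internal_lipid_flags(
                synthdata_frame_with_lipid(frame, p), scheme
            )
            assert flags[5000] == flags_oracle(p, ca3, ca7)

    def test_extracellular_leaflet_excluded(self, default_spec, scheme):
        frame = synthdata.toy_receptor(default_spec)
        flags = internal_lipid_flags(
            synthdata_frame_with_lipid(frame, np.array([0.0, 0.0, -19.0])), scheme
        )
        assert flags == {}  # only intracellular-leaflet phosphorus considered


class TestInternalFraction:
    def test_programmed_fraction_recovered(self, scheme):
        spec = GeneratorSpec(internal_fraction=0.3, n_frames=10)
        traj = synthdata.opening_trajectory(spec, include_bilayer=True)
        assert internal_fraction(traj, scheme) == pytest.approx(0.3, abs=0.1)

    def test_no_lipids_gives_zero(self, scheme, default_spec):
        traj = synthdata.opening_trajectory(default_spec.with_(n_frames=3))
        assert internal_fraction(traj, scheme) == 0.0


def synthdata_frame_with_lipid(frame, p_xyz):
    """Append a single one-phosphorus lipid (residue 5000) to a frame."""
    from gpcrmech.structure import MolecularFrame

    return MolecularFrame(
        time=frame.time,
        res_id=np.concatenate([frame.res_id, [5000]]),
        res_name=np.concatenate([frame.res_name, ["DOPG"]]),
        atom_name=np.concatenate([frame.atom_name, ["P"]]),
        chain=np.concatenate([frame.chain, ["L"]]),
        coords=np.vstack([frame.coords, [p_xyz]]),
    )
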