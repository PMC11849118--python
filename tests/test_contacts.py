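"""Contact fractions: hand-enumerated toys, cutoff monotonicity, oracle equality."""

import numpy as np
import pandas as pd
import pytest

from fccs.contacts import (
    ContactSceneSpec,
    LabeledTrajectory,
    binding_regions,
    contact_fraction,
    synth_trajectory,
)


def two_particle_traj(res_z, box=None):
    """One residue particle above one TAG bead at the origin; res_z per frame."""
    n = len(res_z)
    coords = np.zeros((n, 2, 3))
    coords[:, 0, 2] = res_z
    return LabeledTrajectory(
        coords=coords,
        residue_index=np.array([0, -1]),
        lipid_class=np.array(["", "TAG"], dtype=object),
        box=box,
    )


class TestContactFraction:
    def test_hand_enumerated_half_fraction(self):
        # contact (2 A) in frames 1 and 3 of 4; far (100 A) otherwise
        traj = two_particle_traj([100.0, 2.0, 100.0, 2.0])
        frac = contact_fraction(traj, cutoff=6.0, classes=["TAG"])
        assert frac.loc[0, "TAG"] == 0.5

    def test_all_far_gives_zero(self):
        traj = two_particle_traj([50.0, 60.0])
        assert contact_fraction(traj, cutoff=6.0, classes=["TAG"]).loc[0, "TAG"] == 0.0

    def test_infinite_cutoff_gives_one(self):
        traj = two_particle_traj([50.0, 60.0])
        assert contact_fraction(traj, cutoff=1e12, classes=["TAG"]).loc[0, "TAG"] == 1.0

    def test_monotone_in_cutoff(self):
        spec = ContactSceneSpec(n_residues=6, n_frames=10, jitter_sd=1.0,
                                planted={1: ("TAG", 0.5), 4: ("POPC", 0.8)})
        traj, _ = synth_trajectory(spec, seed=5)
        prev = None
        for cutoff in (1.0, 3.0, 6.0, 12.0, 30.0):
            frac = contact_fraction(traj, cutoff=cutoff)
            if prev is not None:
                assert (frac.to_numpy() >= prev.to_numpy() - 1e-12).all()
            prev = frac

    def test_tree_equals_brute_force(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 60, size=(5, 200, 3))
        res = np.repeat(np.arange(20), 5)
        traj = LabeledTrajectory(
            coords=coords,
            residue_index=np.concatenate([res, -np.ones(100, dtype=int)]),
            lipid_class=np.array([""] * 100 + ["POPC"] * 50 + ["TAG"] * 50,
                                 dtype=object),
        )
        tree = contact_fraction(traj, cutoff=8.0, classes=["POPC", "TAG"], method="tree")
        brute = contact_fraction(traj, cutoff=8.0, classes=["POPC", "TAG"], method="brute")
        pd.testing.assert_frame_equal(tree, brute)

    def test_minimum_image_contact_across_boundary(self):
        # residue at z=9.5, lipid at z=0 in a 10 A box: wrapped distance 0.5
        box = np.tile([10.0, 10.0, 10.0], (1, 1))
        traj = two_particle_traj([9.5], box=box)
        assert contact_fraction(traj, cutoff=1.0, classes=["TAG"]).loc[0, "TAG"] == 1.0
        no_box = two_particle_traj([9.5])
        assert contact_fraction(no_box, cutoff=1.0, classes=["TAG"]).loc[0, "TAG"] == 0.0

    def test_rigid_motion_invariance(self):
        spec = ContactSceneSpec(n_residues=5, n_frames=6, jitter_sd=0.5,
                                planted={2: ("DOPE", 0.5)})
        traj, _ = synth_trajectory(spec, seed=9)
        base = contact_fraction(traj, cutoff=6.0)
        # rotate about z by 30 degrees, then translate
        th = np.pi / 6
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0],
                        [0, 0, 1.0]])
        moved = LabeledTrajectory(
            coords=traj.coords @ rot.T + np.array([100.0, -50.0, 7.0]),
            residue_index=traj.residue_index,
            lipid_class=traj.lipid_class,
        )
        pd.testing.assert_frame_equal(contact_fraction(moved, cutoff=6.0), base)

    def test_unknown_class_rejected_empty_class_warns(self):
        traj = two_particle_traj([2.0])
        with pytest.raises(ValueError, match="unknown lipid class"):
            contact_fraction(traj, cutoff=6.0, classes=["CHOL"])
        with pytest.warns(UserWarning, match="SAPI"):
            frac = contact_fraction(traj, cutoff=6.0, classes=["TAG", "SAPI"])
        assert frac.loc[0, "SAPI"] == 0.0


class TestBindingRegions:
    def test_all_zero_gives_empty(self):
        frac = pd.DataFrame(0.0, index=range(10), columns=["TAG"])
        assert binding_regions(frac, threshold=0.5, min_run=3) == []

    def test_single_block(self):
        frac = pd.DataFrame(0.0, index=range(1, 13), columns=["TAG"])
        frac.loc[5:9, "TAG"] = 1.0
        assert binding_regions(frac, threshold=0.5, min_run=3) == [(5, 9)]

    def test_min_run_filters_short_runs(self):
        frac = pd.DataFrame(0.0, index=range(10), columns=["TAG"])
        frac.loc[2:3, "TAG"] = 1.0
        assert binding_regions(frac, threshold=0.5, min_run=3) == []

    def test_multiple_regions_and_max_over_classes(self):
        frac = pd.DataFrame(0.0, index=range(1, 21), columns=["POPC", "TAG"])
        frac.loc[3:6, "POPC"] = 0.8
        frac.loc[12:20, "TAG"] = 0.6
        assert binding_regions(frac, threshold=0.5, min_run=4) == [(3, 6), (12, 20)]


class TestSynthTrajectory:
    def test_identical_seeds_identical_output(self):
        spec = ContactSceneSpec(jitter_sd=0.3, planted={0: ("TAG", 0.5)})
        t1, _ = synth_trajectory(spec, seed=4)
        t2, _ = synth_trajectory(spec, seed=4)
        np.testing.assert_array_equal(t1.coords, t2.coords)

    def test_planted_contacts_recovered_exactly_noise_free(self):
        spec = ContactSceneSpec(n_residues=8, n_frames=10,
                                planted={2: ("SAPI", 0.3), 6: ("TAG", 0.7)})
        traj, truth = synth_trajectory(spec, seed=0)
        frac = contact_fraction(traj, cutoff=6.0)
        pd.testing.assert_frame_equal(frac, truth, check_like=True)

    def test_jittered_contacts_within_one_frame_unit(self):
        spec = ContactSceneSpec(n_residues=6, n_frames=10, jitter_sd=0.3,
                                planted={1: ("POPC", 0.5)})
        traj, truth = synth_trajectory(spec, seed=8)
        frac = contact_fraction(traj, cutoff=6.0)
        assert abs(frac.loc[1, "POPC"] - truth.loc[1, "POPC"]) <= 1.0 / spec.n_frames

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            ContactSceneSpec(planted={99: ("TAG", 0.5)})
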