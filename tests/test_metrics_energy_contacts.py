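"""Interaction energies, contact frequencies, and persistence counting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from proteomicelle import SelectionSpec
from proteomicelle.metrics import (
    COULOMB_CONSTANT,
    contact_frequency,
    interaction_energy,
    ligand_contact_delta,
    persistent_interhelical_contacts,
)
from conftest import make_ensemble


def _charged_pair(r, q1=1.0, q2=1.0, eps=0.0, sig=0.3):
    return make_ensemble(
        np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        roles=["protein", "ligand"],
        charges=[q1, q2],
        lj_eps=[eps, eps],
        lj_sig=[sig, sig],
    )


class TestInteractionEnergy:
    def test_unit_charges_at_one_nm(self):
        ens = _charged_pair(1.0)
        eb = interaction_energy(ens, [0], [1])
        assert eb.e_coul == pytest.approx(COULOMB_CONSTANT, abs=1e-9)
        assert eb.e_total == eb.e_lj + eb.e_coul

    def test_lj_minimum_at_sigma_two_to_sixth(self):
        sig, eps = 0.34, 0.8
        r = 2 ** (1 / 6) * sig
        ens = _charged_pair(r, q1=0.0, q2=0.0, eps=eps, sig=sig)
        eb = interaction_energy(ens, [0], [1])
        assert eb.e_lj == pytest.approx(-eps, rel=1e-12)
        assert eb.e_coul == 0.0

    def test_pair_just_beyond_cutoff_contributes_nothing(self):
        ens = _charged_pair(1.2 + 1e-6)
        eb = interaction_energy(ens, [0], [1], cutoff_nm=1.2)
        assert eb.e_coul == 0.0 and eb.e_lj == 0.0

    def test_lorentz_berthelot_combination(self):
        ens = make_ensemble(
            np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]),
            roles=["protein", "ligand"],
            charges=[0.0, 0.0],
            lj_eps=[0.2, 0.8],
            lj_sig=[0.30, 0.40],
        )
        eb = interaction_energy(ens, [0], [1])
        eps = np.sqrt(0.2 * 0.8)
        sig = 0.35
        expected = 4 * eps * ((sig / 0.5) ** 12 - (sig / 0.5) ** 6)
        assert eb.e_lj == pytest.approx(expected, rel=1e-12)

    def test_symmetric_and_additive_over_partitions(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(12, 3)) * 0.4
        ens = make_ensemble(
            coords,
            roles=["protein"] * 6 + ["ligand"] * 6,
            charges=rng.normal(size=12) * 0.3,
            lj_eps=np.full(12, 0.4),
            lj_sig=np.full(12, 0.32),
        )
        a = list(range(6))
        b = list(range(6, 12))
        e_ab = interaction_energy(ens, a, b)
        e_ba = interaction_energy(ens, b, a)
        assert e_ab.e_total == pytest.approx(e_ba.e_total, rel=1e-12)
        e_b1 = interaction_energy(ens, a, b[:3])
        e_b2 = interaction_energy(ens, a, b[3:])
        assert e_ab.e_total == pytest.approx(e_b1.e_total + e_b2.e_total,
                                             rel=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(10, 3)) * 0.4
        R = Rotation.from_euler("zyx", [1.0, 0.4, -0.7]).as_matrix()
        moved = coords @ R.T + np.array([3.0, -1.0, 2.0])
        kwargs = dict(
            roles=["protein"] * 5 + ["ligand"] * 5,
            charges=rng.normal(size=10) * 0.2,
            lj_eps=np.full(10, 0.3),
            lj_sig=np.full(10, 0.33),
        )
        e1 = interaction_energy(make_ensemble(coords, **kwargs), range(5),
                                range(5, 10))
        e2 = interaction_energy(make_ensemble(moved, **kwargs), range(5),
                                range(5, 10))
        assert e1.e_total == pytest.approx(e2.e_total, rel=1e-9)

    def test_missing_parameters_refused(self):
        ens = make_ensemble(
            np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]),
            roles=["protein", "ligand"],
        )
        with pytest.raises(ValueError, match="lacking"):
            interaction_energy(ens, [0], [1])

    def test_overlapping_groups_rejected(self):
        ens = _charged_pair(1.0)
        with pytest.raises(ValueError, match="disjoint"):
            interaction_energy(ens, [0, 1], [1])


class TestContactFrequency:
    def _scripted(self):
        """Two single-atom molecules within 0.3 nm in 3 of 5 frames."""
        frames = []
        for near in (True, False, True, False, True):
            d = 0.3 if near else 2.0
            frames.append([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        return make_ensemble(np.array(frames), roles=["protein", "ligand"],
                             residue_ids=[1, 2])

    def test_scripted_three_of_five(self):
        ens = self._scripted()
        table = contact_frequency(ens, [0], [1], cutoff_nm=0.45)
        assert table.frequency_of(1, 2) == pytest.approx(0.6)

    def test_always_within_cutoff_gives_one(self, micelle):
        ens = self._scripted()
        table = contact_frequency(ens, [0], [1], cutoff_nm=2.5)
        assert table.frequency_of(1, 2) == 1.0

    def test_distance_exactly_at_cutoff_counts(self):
        ens = make_ensemble(
            np.array([[[0.0, 0.0, 0.0], [0.45, 0.0, 0.0]]]),
            roles=["protein", "ligand"], residue_ids=[1, 2],
        )
        table = contact_frequency(ens, [0], [1], cutoff_nm=0.45)
        assert table.frequency_of(1, 2) == 1.0

    def test_filter_threshold_is_strict(self):
        frames = []
        for near in (True, True, False, False, False):
            frames.append([[0.0, 0.0, 0.0], [0.3 if near else 2.0, 0.0, 0.0]])
        ens = make_ensemble(np.array(frames), roles=["protein", "ligand"],
                            residue_ids=[1, 2])
        table = contact_frequency(ens, [0], [1], cutoff_nm=0.45)
        assert table.frequency_of(1, 2) == pytest.approx(0.4)
        assert len(table.filter(0.4, strict=True)) == 0
        assert len(table.filter(0.4, strict=False)) == 1


class TestLigandContactDelta:
    def test_table_against_itself_is_zero(self):
        ens = TestContactFrequency()._scripted()
        t = contact_frequency(ens, [0], [1], cutoff_nm=0.45)
        d = ligand_contact_delta(t, t)
        assert (d["delta"] == 0).all()

    def test_pair_only_in_first_table(self):
        ens_a = TestContactFrequency()._scripted()
        t_a = contact_frequency(ens_a, [0], [1], cutoff_nm=0.45)
        ens_b = make_ensemble(
            np.array([[[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]]),
            roles=["protein", "ligand"], residue_ids=[1, 2],
        )
        t_b = contact_frequency(ens_b, [0], [1], cutoff_nm=0.45)
        d = ligand_contact_delta(t_a, t_b)
        assert len(d) == 1
        assert d["delta"].iloc[0] == pytest.approx(0.6)

    def test_antisymmetry(self, micelle):
        ens, _ = micelle
        prot = ens.indices_by_role("protein")
        det = ens.indices_by_role("detergent_tail")
        head = ens.indices_by_role("detergent_head")
        t1 = contact_frequency(ens, prot, det, cutoff_nm=2.0)
        t2 = contact_frequency(ens, prot, head, cutoff_nm=2.0)
        assert len(t1) and len(t2)
        d12 = ligand_contact_delta(t1, t2)
        d21 = ligand_contact_delta(t2, t1)
        assert len(d12) == len(d21)
        np.testing.assert_allclose(
            d12["delta"].to_numpy(dtype=float),
            -d21["delta"].to_numpy(dtype=float), atol=1e-12,
        )

    def test_granularity_mismatch_rejected(self):
        ens = TestContactFrequency()._scripted()
        t_res = contact_frequency(ens, [0], [1], granularity="residue")
        t_atom = contact_frequency(ens, [0], [1], granularity="atom")
        with pytest.raises(ValueError, match="granularity"):
            ligand_contact_delta(t_res, t_atom)


class TestInterhelicalContacts:
    def _hbond_system(self, angle_deg, n_frames=5):
        """N-H donor on helix 1 facing an O acceptor on helix 2.

        The hydrogen sits at the given H-D-A angle from the donor-acceptor
        axis; donor-acceptor distance 0.29 nm.
        """
        d_da = 0.29
        theta = np.radians(angle_deg)
        h = 0.10 * np.array([np.cos(theta), np.sin(theta), 0.0])
        coords = np.array([
            [0.0, 0.0, 0.0],          # donor N (res 1, helix 1)
            h,                        # its hydrogen
            [d_da, 0.0, 0.0],         # acceptor O (res 11, helix 2)
        ])
        frames = np.repeat(coords[None], n_frames, axis=0)
        return make_ensemble(
            frames,
            elements=["N", "H", "O"],
            atom_names=["N", "H", "O"],
            residue_ids=[1, 1, 11],
            roles=["protein"] * 3,
        )

    SPEC = SelectionSpec(name="tm", residue_ranges=[(1, 5), (10, 15)])

    def test_ideal_geometry_counts_one_hbond(self):
        ens = self._hbond_system(angle_deg=5.0)
        n, table = persistent_interhelical_contacts(ens, self.SPEC,
                                                    kind="hbond",
                                                    threshold=0.4)
        assert n == 1
        assert table.table["frequency"].iloc[0] == 1.0

    def test_bent_geometry_falls_back_to_vdw(self):
        ens = self._hbond_system(angle_deg=45.0)
        n_hb, _ = persistent_interhelical_contacts(ens, self.SPEC,
                                                   kind="hbond", threshold=0.4)
        n_vdw, _ = persistent_interhelical_contacts(ens, self.SPEC,
                                                    kind="vdw", threshold=0.4)
        assert n_hb == 0
        assert n_vdw >= 1

    def test_strict_threshold_excludes_exact_forty_percent(self):
        # in contact (hbond geometry) in exactly 2 of 5 frames
        good = self._hbond_system(angle_deg=5.0, n_frames=1).coords[0]
        apart = good.copy()
        apart[2, 0] = 2.0
        frames = np.stack([good, apart, good, apart, apart])
        ens = make_ensemble(
            frames, elements=["N", "H", "O"], atom_names=["N", "H", "O"],
            residue_ids=[1, 1, 11], roles=["protein"] * 3,
        )
        n, table = persistent_interhelical_contacts(ens, self.SPEC,
                                                    kind="hbond",
                                                    threshold=0.4)
        assert n == 0  # frequency 0.4 is not > 0.4
        full = table.table
        assert len(full) == 0

    def test_same_helix_pairs_excluded(self):
        coords = np.array([
            [0.0, 0.0, 0.0],
            [0.1, 0.0, 0.0],
            [0.29, 0.0, 0.0],
        ])
        ens = make_ensemble(
            coords[None], elements=["N", "H", "O"],
            atom_names=["N", "H", "O"], residue_ids=[1, 1, 3],
        )
        spec = SelectionSpec(name="tm", residue_ranges=[(1, 5)])
        n, _ = persistent_interhelical_contacts(ens, spec, kind="hbond",
                                                threshold=0.0)
        assert n == 0

    def test_hbond_without_hydrogens_suggests_vdw(self, bundle):
        ens, tm_spec = bundle  # backbone-only bundle has no hydrogens
        with pytest.raises(ValueError, match="vdw"):
            persistent_interhelical_contacts(ens, tm_spec, kind="hbond")

    def test_count_non_increasing_in_threshold(self, bundle):
        ens, tm_spec = bundle
        counts = [
            persistent_interhelical_contacts(ens, tm_spec, kind="vdw",
                                             threshold=th)[0]
            for th in (0.0, 0.4, 0.8)
        ]
        assert counts[0] >= counts[1] >= counts[2]
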