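"""RMSD/RMSF, micelle shape, RDF, occupancy, and helicity metrics."""

import numpy as np
import pytest

from proteomicelle import MicelleSimSpec, SelectionSpec, gen_proteomicelle
from proteomicelle.metrics import (
    helicity_fraction,
    helicity_vs_rmsd,
    micelle_shape,
    rdf_from_core,
    rmsd,
    rmsf,
    spatial_occupancy,
)
from conftest import make_ensemble


class TestRMSD:
    def test_identical_frames_zero(self, bundle):
        x = bundle.ensemble.coords[0]
        assert rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_superposed_away(self, bundle):
        x = bundle.ensemble.coords[0]
        assert rmsd(x + np.array([1.0, -2.0, 0.5]), x) < 1e-9

    def test_single_displacement_closed_form(self):
        n = 16
        rng = np.random.default_rng(0)
        x = rng.normal(size=(n, 3))
        y = x.copy()
        d = 0.37
        y[3, 0] += d
        assert rmsd(y, x, superpose_first=False) == pytest.approx(
            d / np.sqrt(n), abs=1e-12
        )

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRMSF:
    def test_static_ensemble_all_zero(self):
        x = np.random.default_rng(1).normal(size=(10, 3))
        ens = make_ensemble(np.repeat(x[None], 4, axis=0))
        assert rmsf(ens).max() < 1e-12

    def test_alternating_atom_closed_form(self):
        # four anchor atoms pin the superposition; one atom oscillates +-d
        d = 0.25
        base = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [2.0, 2.0, 2.0]],
            dtype=float,
        )
        frames = []
        for k in range(6):
            f = base.copy()
            f[4, 2] += d if k % 2 == 0 else -d
            frames.append(f)
        ens = make_ensemble(np.stack(frames))
        vals = rmsf(ens, superpose_first=False)
        assert vals[4] == pytest.approx(d, abs=1e-12)
        assert vals[:4].max() < 1e-12

    def test_matches_two_pass_variance_oracle(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(5, 8, 3))
        ens = make_ensemble(coords)
        vals = rmsf(ens, superpose_first=False)
        mean = coords.mean(axis=0)
        oracle = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(vals, oracle, atol=1e-12)

    def test_single_frame_rejected(self):
        ens = make_ensemble(np.zeros((1, 5, 3)))
        with pytest.raises(ValueError):
            rmsf(ens)


class TestMicelleShape:
    def _sphere(self, n=10_000, seed=0):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def test_spherical_shell_eccentricity_one(self):
        ecc = micelle_shape(self._sphere()).eccentricity
        assert ecc == pytest.approx(1.0, abs=0.02)

    def test_two_to_one_ellipsoid_gives_half(self):
        pts = self._sphere()
        pts[:, 0] *= 2.0
        ecc = micelle_shape(pts).eccentricity
        assert ecc == pytest.approx(0.5, abs=0.02)

    def test_collinear_points_degenerate(self):
        pts = np.outer(np.linspace(0, 1, 30), np.array([1.0, 2.0, -1.0]))
        res = micelle_shape(pts)
        assert res.eccentricity == 0.0
        assert res.degenerate

    def test_eigen_oracle_on_constructed_set(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(500, 3)) * np.array([3.0, 2.0, 1.0])
        res = micelle_shape(pts)
        d = pts - pts.mean(axis=0)
        gyr = d.T @ d / len(pts)
        ev = np.sort(np.linalg.eigvalsh(gyr))[::-1]
        np.testing.assert_allclose(res.eigenvalues, ev, rtol=1e-10)
        assert res.eccentricity == pytest.approx(np.sqrt(ev[2] / ev[0]), rel=1e-10)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        pts = np.random.default_rng(8).normal(size=(400, 3)) * [2.0, 1.0, 0.7]
        e1 = micelle_shape(pts).eccentricity
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.2]).as_matrix()
        e2 = micelle_shape(pts @ R.T + np.array([5.0, -3.0, 1.0])).eccentricity
        assert e1 == pytest.approx(e2, rel=1e-9)


class TestRDF:
    def _uniform_ensemble(self, n=30_000, r_sphere=3.0, seed=0):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v * (rng.random(n) ** (1 / 3))[:, None] * r_sphere
        coords = np.vstack([[[0.0, 0.0, 0.0]], pts])
        return make_ensemble(
            coords, roles=["protein"] + ["solvent"] * n
        )

    def test_uniform_filling_gives_unity(self):
        ens = self._uniform_ensemble()
        res = rdf_from_core(ens, [0], np.arange(1, ens.n_atoms), bin_nm=0.1,
                            r_max=3.0)
        # skip the innermost bins where counts are tiny
        sel = res.r > 0.5
        assert np.abs(res.g[sel] - 1.0).mean() < 0.05

    def test_single_radius_matches_hand_count(self):
        # all shell atoms at a bin-center radius -> one bin, exact count
        n = 200
        rng = np.random.default_rng(2)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        coords = np.vstack([[[0.0, 0.0, 0.0]], v * 1.55])
        ens = make_ensemble(coords, roles=["protein"] + ["solvent"] * n)
        res = rdf_from_core(ens, [0], np.arange(1, n + 1), bin_nm=0.1,
                            r_max=3.0)
        nonzero = np.flatnonzero(res.counts)
        assert nonzero.size == 1
        assert res.counts[nonzero[0]] == n
        assert res.r[nonzero[0]] == pytest.approx(1.55, abs=1e-12)

    def test_doubling_count_leaves_g_unchanged(self):
        rng = np.random.default_rng(3)
        n = 8000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = v * (rng.random(n) ** (1 / 3))[:, None] * 3.0
        ens1 = make_ensemble(np.vstack([[[0.0, 0.0, 0.0]], pts]),
                             roles=["protein"] + ["solvent"] * n)
        ens2 = make_ensemble(np.vstack([[[0.0, 0.0, 0.0]], pts, pts]),
                             roles=["protein"] + ["solvent"] * (2 * n))
        r1 = rdf_from_core(ens1, [0], np.arange(1, ens1.n_atoms), 0.1, 3.0)
        r2 = rdf_from_core(ens2, [0], np.arange(1, ens2.n_atoms), 0.1, 3.0)
        np.testing.assert_allclose(r1.g, r2.g, atol=1e-10)
        assert r2.counts.sum() == 2 * r1.counts.sum()

    def test_empty_selection_rejected(self, micelle):
        with pytest.raises(ValueError):
            rdf_from_core(micelle.ensemble, [], [1, 2], 0.02, 3.0)


class TestOccupancy:
    def test_static_molecule_counts_all_frames(self):
        x = np.array([[0.05, 0.05, 0.05], [1.55, 0.05, 0.05]])
        ens = make_ensemble(np.repeat(x[None], 7, axis=0),
                            roles=["ligand", "ligand"])
        grid = spatial_occupancy(ens, [0, 1], voxel_nm=0.1)
        assert grid.counts.max() == 7
        assert (grid.counts[grid.counts > 0] == 7).all()

    def test_total_occupancy_bounded(self, micelle):
        ens, _ = micelle
        det = ens.indices_by_role("detergent_tail")
        grid = spatial_occupancy(ens, det, voxel_nm=0.25)
        assert grid.total_occupancy <= ens.n_frames * det.size

    def test_mobile_molecule_occupies_more_voxels(self):
        occupied = []
        for sd in (0.0, 0.05):
            spec = MicelleSimSpec(n_helices=4, helix_length=12, n_detergent=10,
                                  n_frames=10, mobility_sd=sd, seed=6)
            ens, _ = gen_proteomicelle(spec)
            det = ens.indices_by_role("detergent_head", "detergent_tail")
            occupied.append(
                spatial_occupancy(ens, det, voxel_nm=0.1).occupied_voxels
            )
        assert occupied[1] > occupied[0]


class TestHelicity:
    def test_extended_chain_scores_zero(self):
        # phi = psi = 180: a straight zig-zag built from trans geometry
        from proteomicelle.synthetic import _ideal_helix

        ext = _ideal_helix(12, phi=180.0, psi=180.0)
        coords, names, rids = [], [], []
        for i in range(12):
            for nm in ("N", "CA", "C"):
                coords.append(ext[nm][i])
                names.append(nm)
                rids.append(i + 1)
        ens = make_ensemble(np.asarray(coords), atom_names=names,
                            residue_ids=rids)
        spec = SelectionSpec(name="seg", residue_ranges=[(1, 12)])
        assert helicity_fraction(ens, spec)[0] == 0.0

    def test_short_helical_island_filtered_by_run_rule(self):
        # 3 helical residues sandwiched in an extended chain: below the
        # 4-residue run threshold, so the fraction stays 0
        from proteomicelle.synthetic import _ideal_helix

        n = 14
        coords, names, rids = [], [], []
        chain = _ideal_helix(n, phi=180.0, psi=180.0)
        helical = _ideal_helix(n, phi=-63.0, psi=-42.0)
        for i in range(n):
            src = helical if 5 <= i <= 7 else chain
            for nm in ("N", "CA", "C"):
                # splice helical coordinates locally; geometry between the
                # segments is irrelevant to per-residue dihedrals inside them
                coords.append(src[nm][i] + (0 if 5 <= i <= 7 else 50.0))
                names.append(nm)
                rids.append(i + 1)
        ens = make_ensemble(np.asarray(coords), atom_names=names,
                            residue_ids=rids)
        spec = SelectionSpec(name="seg", residue_ranges=[(1, n)])
        assert helicity_fraction(ens, spec)[0] == 0.0

    def test_missing_backbone_reported(self, bundle):
        ens, _ = bundle
        spec = SelectionSpec(name="oob", residue_ranges=[(1, 200)])
        with pytest.raises(ValueError, match="backbone"):
            helicity_fraction(ens, spec)


class TestHelicityVsRmsd:
    def test_static_ensemble_identical_rows(self, bundle):
        ens0, tm_spec = bundle
        coords = np.repeat(ens0.coords, 4, axis=0)
        ens = make_ensemble(
            coords,
            roles=list(ens0.atoms["role"]),
            atom_names=list(ens0.atoms["atom_name"]),
            residue_ids=list(ens0.atoms["residue_id"]),
            residue_names=list(ens0.atoms["residue_name"]),
        )
        df = helicity_vs_rmsd(ens, tm_spec)
        assert len(df) == 4
        assert df["helicity"].nunique() == 1
        assert df["rmsd_nm"].max() < 1e-9

    def test_components_agree_with_standalone_ops(self, micelle):
        from proteomicelle.ensemble import resolve_selection

        ens, tm_spec = micelle
        df = helicity_vs_rmsd(ens, tm_spec)
        assert len(df) == ens.n_frames
        hel = helicity_fraction(ens, tm_spec)
        np.testing.assert_allclose(df["helicity"], hel, atol=1e-12)
        sel = resolve_selection(ens, tm_spec)
        r3 = rmsd(ens.coords[3], ens.coords[0], sel=sel)
        assert df["rmsd_nm"].iloc[3] == pytest.approx(r3, abs=1e-12)
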