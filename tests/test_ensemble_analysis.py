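import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allosite import (
    Atom,
    ConformerEnsemble,
    FitError,
    InsufficientDataError,
    Structure,
    ValidationError,
    chi1_series,
    cluster_conformers,
    dihedral,
    find_invariant_core,
    fit_pca,
    pairwise_rmsd,
    select_representatives,
    superpose,
)
from allosite.ensemble_analysis import apply_transform, coord_rmsd

from conftest import make_ca_structure


def rotation_grid_rmsd_oracle(mobile, reference, coarse=0.1, fine=0.01):
    """Independent minimum RMSD by coarse-to-fine grid search over SO(3).

    With the rotation fixed, the optimal translation matches the centroids,
    so only rotations are searched.
    """
    x0 = mobile - mobile.mean(axis=0)
    y0 = reference - reference.mean(axis=0)

    def best_around(center_euler, half_width, step):
        axes = [np.arange(-half_width, half_width + step / 2, step) + c for c in center_euler]
        ga, gb, gc = np.meshgrid(*axes, indexing="ij")
        eulers = np.column_stack([ga.ravel(), gb.ravel(), gc.ravel()])
        mats = Rotation.from_euler("zyx", eulers).as_matrix()
        moved = np.einsum("kij,nj->kni", mats, x0)
        errs = np.mean(np.sum((moved - y0) ** 2, axis=2), axis=1)
        i = int(np.argmin(errs))
        return eulers[i], float(np.sqrt(errs[i]))

    center, _ = best_around(np.zeros(3), np.pi, coarse)
    center, rmsd = best_around(center, 2 * coarse, fine)
    return rmsd


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        _, _, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(6, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot.T + np.array([5.0, -2.0, 1.0])
        r, t, rmsd = superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(apply_transform(mobile, r, t), ref, atol=1e-8)

    def test_scaled_triangle_matches_grid_search_oracle(self):
        tri = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        doubled = 2.0 * tri
        _, _, rmsd = superpose(tri, doubled)
        oracle = rotation_grid_rmsd_oracle(tri, doubled)
        assert rmsd <= oracle + 1e-6
        assert rmsd == pytest.approx(oracle, abs=0.02)

    def test_rmsd_invariant_under_rigid_motion_of_mobile(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(8, 3))
        mobile = ref + rng.normal(scale=0.3, size=(8, 3))
        _, _, rmsd0 = superpose(mobile, ref)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = mobile @ rot.T + np.array([1.0, 2.0, 3.0])
        _, _, rmsd1 = superpose(moved, ref)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)

    def test_too_few_points_rejected(self):
        pts = np.zeros((2, 3))
        with pytest.raises(FitError):
            superpose(pts, pts)

    def test_collinear_geometry_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(FitError):
            superpose(line, line)


def build_ensemble(coord_list, ids=None, align=False):
    """Ensemble from raw Cα coordinate sets.

    With ``align=False`` the given coordinates are used verbatim (handy when
    a test plants an exact displacement that superposition would partially
    absorb); ``align=True`` goes through the normal superposing constructor.
    """
    structures = [
        make_ca_structure(c, structure_id=(ids[i] if ids else f"s{i}"))
        for i, c in enumerate(coord_list)
    ]
    if align:
        return ConformerEnsemble.from_structures(structures)
    from allosite import ResidueId

    n = len(coord_list[0])
    emap = [{i: ResidueId("A", i + 1) for i in range(n)} for _ in structures]
    return ConformerEnsemble(
        structures=structures, coords=np.asarray(coord_list, float), equiv_map=emap
    )


def spread_base(n=8, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, 20, size=(n, 3))


class TestInvariantCore:
    def test_single_mobile_position_excluded(self):
        base = spread_base(10, seed=4)
        rng = np.random.default_rng(5)
        confs = []
        for _ in range(6):
            c = base.copy()
            c[5] += rng.normal(scale=2.0, size=3)  # 3-D scatter at residue 5
            confs.append(c)
        ens = build_ensemble(confs)
        core = find_invariant_core(ens, volume_threshold=0.5)
        assert 5 not in core
        assert set(core) >= set(range(10)) - {5}

    def test_identical_conformers_keep_everything(self):
        base = spread_base(7, seed=6)
        ens = build_ensemble([base.copy() for _ in range(4)])
        core = find_invariant_core(ens, volume_threshold=0.5)
        assert set(core) == set(range(7))

    def test_rotating_domain_excluded(self):
        # two domains: residues 0-5 static, 6-11 wobbling under independent
        # random rotations per conformer, so the mobile scatter is truly 3-D
        static = spread_base(6, seed=7) + np.array([30.0, 0, 0])
        arm = spread_base(6, seed=8)
        rng = np.random.default_rng(9)
        confs = []
        for _ in range(6):
            rot = Rotation.from_euler(
                "zyx", rng.uniform(-25.0, 25.0, size=3), degrees=True
            ).as_matrix()
            confs.append(np.vstack([static, arm @ rot.T]))
        ens = build_ensemble(confs)
        core = find_invariant_core(ens, volume_threshold=0.5, min_fraction=0.3)
        assert set(core) <= set(range(6))


class TestPCA:
    def test_rank_one_motion_single_eigenvalue(self):
        base = spread_base(5, seed=9)
        confs = []
        for dx in (-1.0, 0.0, 1.0):
            c = base.copy()
            c[2, 0] += dx
            confs.append(c)
        ens = build_ensemble(confs)
        model = fit_pca(ens)
        assert model.eigenvalues[0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(model.eigenvalues[1:] < 1e-8)

    def test_variance_conservation_and_orthonormality(self):
        rng = np.random.default_rng(10)
        confs = [spread_base(6, seed=11) + rng.normal(scale=0.5, size=(6, 3)) for _ in range(5)]
        ens = build_ensemble(confs)
        model = fit_pca(ens)
        x = ens.coords2d - ens.coords2d.mean(axis=0)
        trace = np.trace(x.T @ x / (len(confs) - 1))
        assert np.sum(model.eigenvalues) == pytest.approx(trace, rel=1e-6)
        gram = model.eigenvectors.T @ model.eigenvectors
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_reconstruction_completeness(self):
        rng = np.random.default_rng(12)
        confs = [spread_base(4, seed=13) + rng.normal(scale=0.4, size=(4, 3)) for _ in range(4)]
        ens = build_ensemble(confs)
        model = fit_pca(ens)
        centered = ens.coords2d - model.mean
        recon = (centered @ model.eigenvectors) @ model.eigenvectors.T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_mean_projects_to_zero_and_unit_displacement(self):
        rng = np.random.default_rng(14)
        confs = [spread_base(5, seed=15) + rng.normal(scale=0.5, size=(5, 3)) for _ in range(4)]
        ens = build_ensemble(confs)
        model = fit_pca(ens)
        np.testing.assert_allclose(model.project(model.mean), 0.0, atol=1e-8)
        displaced = model.mean + 2.0 * model.eigenvectors[:, 0]
        scores = model.project(displaced, k=3)[0]
        assert scores[0] == pytest.approx(2.0, abs=1e-8)
        np.testing.assert_allclose(scores[1:], 0.0, atol=1e-8)

    def test_projection_matches_dense_oracle(self):
        rng = np.random.default_rng(16)
        confs = [spread_base(5, seed=17) + rng.normal(scale=0.5, size=(5, 3)) for _ in range(5)]
        ens = build_ensemble(confs)
        model = fit_pca(ens)
        new = ens.coords2d[2] + 0.3 * rng.normal(size=15)
        expected = model.eigenvectors[:, :3].T @ (new - model.mean)
        np.testing.assert_allclose(model.project(new, k=3)[0], expected, atol=1e-10)

    def test_single_conformer_rejected(self):
        ens = build_ensemble([spread_base(4, seed=18)])
        with pytest.raises(InsufficientDataError):
            fit_pca(ens)


class TestPairwiseRmsd:
    def test_matches_composed_superpose_calls(self):
        rng = np.random.default_rng(19)
        confs = [spread_base(6, seed=20) + rng.normal(scale=0.5, size=(6, 3)) for _ in range(3)]
        ens = build_ensemble(confs)
        mat = pairwise_rmsd(ens)
        assert np.allclose(mat, mat.T, atol=1e-6)
        assert np.allclose(np.diag(mat), 0.0, atol=1e-8)
        for i in range(3):
            for j in range(3):
                if i != j:
                    _, _, r = superpose(ens.coords[j], ens.coords[i], ens.core)
                    assert mat[i, j] == pytest.approx(r, abs=1e-10)


class TestClustering:
    def test_planted_two_group_recovery(self):
        rng = np.random.default_rng(21)
        scores = np.vstack(
            [rng.normal(0.0, 0.3, size=(5, 3)), rng.normal(10.0, 0.3, size=(5, 3))]
        )
        res = cluster_conformers(scores, k=2)
        assert set(np.unique(res.labels[:5])) != set(np.unique(res.labels[5:]))
        assert len(np.unique(res.labels[:5])) == 1
        assert len(np.unique(res.labels[5:])) == 1

    def test_k_equals_n_gives_singletons(self):
        scores = np.arange(12.0).reshape(4, 3)
        res = cluster_conformers(scores, k=4)
        assert sorted(res.populations) == [1, 1, 1, 1]

    def test_average_linkage_heights_match_manual_upgma(self):
        # 4 points on a line: 0, 1, 5, 7
        pts = np.array([0.0, 1.0, 5.0, 7.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = cluster_conformers(d, k=1)
        heights = sorted(res.linkage[:, 2])
        # manual UPGMA: merge (0,1) at 1; merge (2,3) at 2;
        # final merge at mean cross distance: (5+7+4+6)/4 = 5.5
        assert heights == pytest.approx([1.0, 2.0, 5.5])

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            cluster_conformers(np.zeros((3, 3)), k=4)


class TestRepresentatives:
    def test_singleton_cluster_is_its_own_representative(self):
        confs = [spread_base(4, seed=22) + i * 5.0 for i in range(3)]
        ens = build_ensemble(confs)
        res = cluster_conformers(np.arange(3.0).reshape(-1, 1) * 100, k=3)
        reps = select_representatives(ens, res)
        assert sorted(reps.values()) == sorted(ens.ids)

    def test_symmetric_triplet_picks_middle(self):
        base = spread_base(5, seed=23)
        mode = np.zeros((5, 3))
        mode[1, 0] = 1.0
        confs = [base + a * mode for a in (-1.0, 0.0, 1.0)]
        ens = build_ensemble(confs)
        res = cluster_conformers(np.zeros((3, 1)), k=1)
        reps = select_representatives(ens, res)
        assert reps[0] == "s1"

    def test_representative_verified_by_exhaustive_scan(self):
        rng = np.random.default_rng(24)
        confs = [spread_base(6, seed=25) + rng.normal(scale=0.8, size=(6, 3)) for _ in range(5)]
        ens = build_ensemble(confs)
        res = cluster_conformers(np.zeros((5, 1)), k=1)
        reps = select_representatives(ens, res)
        mean = ens.coords.mean(axis=0)
        dists = [coord_rmsd(ens.coords[i], mean) for i in range(5)]
        assert reps[0] == ens.ids[int(np.argmin(dists))]


def dihedral_oracle(p0, p1, p2, p3):
    """Alternative dihedral construction: angle between plane normals with
    sign from the scalar triple product."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


class TestChi1:
    def _residue_structure(self, n, ca, cb, cg, structure_id="s0"):
        names = ["N", "CA", "CB", "CG"]
        coords = [n, ca, cb, cg]
        atoms = [
            Atom(
                serial=i + 1,
                name=names[i],
                element=names[i][0] if names[i][0] != "C" else "C",
                resname="TYR",
                resid=71,
                chain="A",
                coord=tuple(coords[i]),
            )
            for i in range(4)
        ]
        return Structure(id=structure_id, atoms=atoms)

    def test_planar_cis_is_zero(self):
        s = self._residue_structure(
            (1.0, 1.0, 0.0), (0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.5, 1.0, 0.0)
        )
        angles, _ = chi1_series([s], "A", 71)
        assert angles[0] == pytest.approx(0.0, abs=1e-6)

    def test_anti_is_180(self):
        s = self._residue_structure(
            (1.0, 1.0, 0.0), (0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.5, -1.0, 0.0)
        )
        angles, _ = chi1_series([s], "A", 71)
        assert abs(angles[0]) == pytest.approx(180.0, abs=1e-6)

    def test_tetrahedral_matches_independent_formula(self):
        rng = np.random.default_rng(26)
        pts = rng.normal(size=(4, 3)) * 2.0
        expected = dihedral_oracle(*pts)
        assert dihedral(*pts) == pytest.approx(expected, abs=1e-8)
        s = self._residue_structure(*[tuple(p) for p in pts])
        angles, _ = chi1_series([s], "A", 71)
        assert angles[0] == pytest.approx(expected, abs=1e-8)

    def test_missing_atom_yields_nan_with_warning(self):
        s = self._residue_structure(
            (1.0, 1.0, 0.0), (0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.5, 1.0, 0.0)
        )
        s.atoms = s.atoms[:3]  # drop CG
        with pytest.warns(UserWarning):
            angles, (edges, density) = chi1_series([s], "A", 71)
        assert np.isnan(angles[0])
        assert len(edges) == 37  # 10-degree bins over 360 degrees
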