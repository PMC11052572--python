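"""Geometry operators against independent oracles and invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_point_structure, random_rigid_transform
from fusescreen.geometry import (
    RejectionEmptiedError,
    buried_surface_area,
    find_disulfides,
    kabsch,
    match_residues,
    max_extent,
    mean_plddt,
    shrake_rupley_sasa,
    superpose_with_rejection,
    transform_structure,
)
from fusescreen.synthetic import ChainPlan, ToyComplexSpec, build_toy_structure
from fusescreen.types import Atom, Chain, Correspondence, Residue, Structure


def chain_from_coords(cid, coords, resname="ALA", start=1, bfactors=None):
    residues = []
    for i, pos in enumerate(coords):
        b = 0.0 if bfactors is None else bfactors[i]
        residues.append(
            Residue(start + i, resname, [Atom("CA", "C", np.asarray(pos, float), b)])
        )
    return Chain(cid, residues)


def correspondence(A, B):
    return Correspondence(A, B, [(("A", i), ("A", i)) for i in range(len(A))])


class TestMatchResidues:
    def test_structure_vs_itself_pairs_everything(self, toy_structure):
        corr = match_residues(toy_structure, toy_structure)
        assert len(corr) == sum(len(c) for c in toy_structure.chains)

    def test_missing_residues_shrink_correspondence(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(40, 3)) * 10
        a = Structure("a", [chain_from_coords("A", coords)])
        keep = [r for r in chain_from_coords("A", coords).residues if not (10 <= r.seq_id < 20)]
        b = Structure("b", [Chain("A", keep)])
        corr = match_residues(a, b, method="author-number")
        assert len(corr) == 30

    def test_sequence_align_survives_renumbering(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(30, 3)) * 10
        names = ["ALA", "GLY", "SER", "THR", "VAL", "LEU"] * 5
        res_a = [Residue(i + 1, names[i], [Atom("CA", "C", coords[i])]) for i in range(30)]
        res_b = [Residue(i + 101, names[i], [Atom("CA", "C", coords[i])]) for i in range(30)]
        a = Structure("a", [Chain("A", res_a)])
        b = Structure("b", [Chain("A", res_b)])
        corr = match_residues(a, b, method="sequence-align")
        assert len(corr) == 30

    def test_no_overlap_raises(self):
        a = Structure("a", [chain_from_coords("A", [[0, 0, 0]], start=1)])
        b = Structure("b", [chain_from_coords("A", [[0, 0, 0]], start=500)])
        with pytest.raises(ValueError, match="empty correspondence"):
            match_residues(a, b, method="author-number")


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(20, 3)) * 10
        res = kabsch(correspondence(A, A))
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_copy_gives_zero(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(50, 3)) * 10
        Q, t = random_rigid_transform(rng)
        res = kabsch(correspondence(A, A @ Q.T + t))
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_rmsd_invariant_under_rigid_transform_of_input(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(40, 3)) * 10
        B = A + rng.normal(scale=1.0, size=A.shape)
        base = kabsch(correspondence(A, B)).rmsd
        Q, t = random_rigid_transform(rng)
        moved = kabsch(correspondence(A @ Q.T + t, B)).rmsd
        assert moved == pytest.approx(base, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_independent_least_squares(self, seed):
        """scipy's align_vectors solves the same weighted least-squares
        rotation problem by an independent route."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(30, 3)) * 10
        B = A @ Rotation.random(random_state=seed).as_matrix().T + rng.normal(
            scale=2.0, size=A.shape
        )
        res = kabsch(correspondence(A, B))
        rot, rssd = Rotation.align_vectors(B - B.mean(0), A - A.mean(0))
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(A)), abs=1e-6)
        np.testing.assert_allclose(res.rotation, rot.as_matrix(), atol=1e-6)

    def test_displaced_point_matches_closed_form(self):
        # 3 anchor points fit exactly; 4th displaced by 2 Å contributes
        # all residual error less what the optimal fit redistributes
        rng = np.random.default_rng(3)
        A = rng.normal(size=(40, 3)) * 10
        B = A.copy()
        B[0] += np.array([2.0, 0, 0])
        res = kabsch(correspondence(A, B))
        rot, rssd = Rotation.align_vectors(B - B.mean(0), A - A.mean(0))
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(A)), abs=1e-9)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            kabsch(correspondence(np.zeros((2, 3)), np.zeros((2, 3))))

    def test_collinear_points_raise(self):
        A = np.array([[float(i), 0, 0] for i in range(10)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(correspondence(A, A))


class TestRejection:
    def test_clean_copy_no_rejection(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(60, 3)) * 10
        Q, t = random_rigid_transform(rng)
        res = superpose_with_rejection(correspondence(A, A @ Q.T + t))
        assert res.n_rejected == 0
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_ten_displaced_points_rejected(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(100, 3)) * 10
        B = A.copy()
        B[:10] += rng.normal(size=(10, 3)) * 10 + 5.0
        res = superpose_with_rejection(correspondence(A, B))
        assert res.n_rejected == 10
        assert res.n_used == 90
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        assert res.n_used + res.n_rejected == 100

    @pytest.mark.parametrize("seed", range(5))
    def test_rejection_never_raises_rmsd(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(80, 3)) * 10
        B = A + rng.normal(scale=1.5, size=A.shape)
        before = kabsch(correspondence(A, B))
        after = superpose_with_rejection(correspondence(A, B))
        assert after.rmsd <= before.rmsd + 1e-12

    def test_emptied_set_reports_last_fit(self):
        # two clusters of exact fits pulling apart: aggressive sigma
        # trims until too few pairs remain
        rng = np.random.default_rng(6)
        A = rng.normal(size=(6, 3)) * 10
        B = A + rng.normal(scale=5.0, size=A.shape)
        with pytest.raises(RejectionEmptiedError) as err:
            superpose_with_rejection(correspondence(A, B), sigma_cutoff=0.5, max_cycles=50)
        assert err.value.last_result.rmsd >= 0


class TestBuriedSurfaceArea:
    def test_far_groups_bury_nothing(self):
        st = make_point_structure([[0, 0, 0], [100.0, 0, 0]])
        rep = buried_surface_area(st, ["C0"], ["C1"])
        assert rep.buried_area == pytest.approx(0.0, abs=1e-6)
        assert rep.interface_residues == {"a": [], "b": []}

    @pytest.mark.parametrize("separation", [2.0, 3.0, 4.5])
    def test_two_spheres_match_spherical_cap_formula(self, separation):
        """For two identical single-atom chains the buried area per side
        is the spherical cap 2*pi*R*h cut by the midplane, with
        R = r_vdw + probe and h = R - d/2."""
        st = make_point_structure([[0, 0, 0], [separation, 0, 0]])
        rep = buried_surface_area(st, ["C0"], ["C1"], n_points=2000)
        R = 1.70 + 1.4
        cap = 2 * np.pi * R * (R - separation / 2.0)
        assert rep.buried_area == pytest.approx(cap, rel=0.02)

    def test_symmetric_under_group_swap(self, toy_structure):
        ab = buried_surface_area(toy_structure, ["A"], ["B"], n_points=240)
        ba = buried_surface_area(toy_structure, ["B"], ["A"], n_points=240)
        assert ab.buried_area == pytest.approx(ba.buried_area, abs=1e-9)
        assert ab.interface_residues["a"] == ba.interface_residues["b"]

    def test_agrees_with_biotite_sampler(self):
        """Independent Shrake-Rupley implementation (biotite) with the
        same radii and probe should give near-identical per-atom areas."""
        biotite_struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 12, size=(30, 3))
        radii = np.full(30, 1.7)
        mine = shrake_rupley_sasa(coords, radii, probe=1.4, n_points=2000)
        arr = biotite_struc.AtomArray(30)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 30)
        arr.atom_name = np.array(["CA"] * 30)
        arr.res_name = np.array(["ALA"] * 30)
        arr.res_id = np.arange(1, 31)
        arr.chain_id = np.array(["A"] * 30)
        theirs = biotite_struc.sasa(
            arr, probe_radius=1.4, vdw_radii=radii, point_number=2000
        )
        np.testing.assert_allclose(mine, theirs, rtol=0.03, atol=0.5)

    def test_empty_group_rejected(self, toy_structure):
        with pytest.raises(KeyError):
            buried_surface_area(toy_structure, ["A"], ["Z"])


class TestMaxExtent:
    def test_single_atom_zero(self):
        st = make_point_structure([[1.0, 2.0, 3.0]])
        assert max_extent(st) == 0.0

    def test_two_atoms(self):
        st = make_point_structure([[0, 0, 0], [10.0, 0, 0]])
        assert max_extent(st) == pytest.approx(10.0)

    def test_matches_brute_force_on_cloud(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(500, 3)) * 40
        st = make_point_structure(pts)
        ref = max(
            np.linalg.norm(pts[i] - pts[j])
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        )
        assert max_extent(st) == pytest.approx(ref, abs=1e-9)

    def test_rigid_invariance(self, toy_structure):
        rng = np.random.default_rng(9)
        Q, t = random_rigid_transform(rng)
        from fusescreen.types import SuperpositionResult

        moved = transform_structure(
            toy_structure, SuperpositionResult(Q, t, 0.0, 1)
        )
        assert max_extent(moved) == pytest.approx(max_extent(toy_structure), abs=1e-6)

    def test_empty_selection_raises(self, toy_structure):
        with pytest.raises(ValueError):
            max_extent(toy_structure, atom_filter="OXT")


def cys(cid, seq_id, sg_pos):
    return Residue(
        seq_id, "CYS",
        [Atom("CA", "C", np.asarray(sg_pos) + [1.5, 0, 0]), Atom("SG", "S", sg_pos)],
    )


class TestDisulfides:
    def test_no_cysteines(self, toy_structure):
        assert find_disulfides(toy_structure) == []

    def test_canonical_bond_detected(self):
        st = Structure("s", [Chain("A", [cys("A", 1, [0, 0, 0]), cys("A", 10, [2.05, 0, 0])])])
        assert find_disulfides(st) == [(("A", 1), ("A", 10))]

    def test_triple_cluster_pairs_nearest_and_warns(self):
        st = Structure(
            "s",
            [Chain("A", [
                cys("A", 1, [0, 0, 0]),
                cys("A", 10, [2.0, 0, 0]),
                cys("A", 20, [0, 2.2, 0]),
            ])],
        )
        with pytest.warns(UserWarning, match="already-bonded"):
            bonds = find_disulfides(st)
        assert bonds == [(("A", 1), ("A", 10))]

    def test_symmetric_in_input_order(self):
        r1, r2 = cys("A", 1, [0, 0, 0]), cys("A", 5, [2.05, 0, 0])
        st_fwd = Structure("s", [Chain("A", [r1, r2])])
        st_rev = Structure(
            "s",
            [Chain("A", [cys("A", 1, [2.05, 0, 0]), cys("A", 5, [0, 0, 0])])],
        )
        assert find_disulfides(st_fwd) == find_disulfides(st_rev)


class TestMeanPlddt:
    def test_uniform_value(self):
        st = build_toy_structure(
            ToyComplexSpec(seed=0, chains=[ChainPlan("A", 10, plddt=90.0)])
        )
        assert mean_plddt(st, "A", (1, 10)) == pytest.approx(90.0)

    def test_two_residue_average(self):
        ch = chain_from_coords("A", [[0, 0, 0], [3.8, 0, 0]], bfactors=[80.0, 100.0])
        st = Structure("s", [ch])
        assert mean_plddt(st, "A", (1, 2)) == pytest.approx(90.0)

    def test_planted_profile_recovered(self):
        rng = np.random.default_rng(10)
        profile = rng.uniform(40, 100, size=30)
        st = build_toy_structure(
            ToyComplexSpec(seed=0, chains=[ChainPlan("A", 30, plddt=list(profile))])
        )
        assert mean_plddt(st, "A", (5, 20)) == pytest.approx(
            float(np.mean(profile[4:20])), abs=1e-9
        )

    def test_empty_range_raises(self, toy_structure):
        with pytest.raises(ValueError):
            mean_plddt(toy_structure, "A", (500, 600))
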