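import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pmhc.structio import (AtomSelection, Ensemble, StructureModel,
                           backbone_dihedrals, clash_score, contact_residues,
                           dihedral_angle, ensemble_rmsd_summary, kabsch,
                           parse_selection, per_atom_rmsf,
                           ramachandran_classify, read_model_ensemble, rmsd,
                           superpose, wrap_angle, write_pdb)
from pmhc.synth import make_chain, make_complex


def random_rotation(rng):
    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()


def simple_model(xyz, names=None, chain="X", model_id=0, elements=None,
                 res_numbers=None, chains=None):
    n = len(xyz)
    names = names or [f"C{i}" for i in range(n)]
    return StructureModel(
        model_id=model_id,
        chain_ids=np.array(chains or [chain] * n, dtype=object),
        res_numbers=np.array(res_numbers or list(range(1, n + 1)), dtype=int),
        icodes=np.array([""] * n, dtype=object),
        res_names=np.array(["ALA"] * n, dtype=object),
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements or ["C"] * n, dtype=object),
        xyz=np.asarray(xyz, dtype=float),
    )


class TestModel:
    def test_duplicate_atom_identity_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            simple_model([[0, 0, 0], [1, 0, 0]], names=["CA", "CA"],
                         res_numbers=[1, 1])

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            simple_model([[0, 0, 0], [np.nan, 0, 0]])

    def test_shared_topology_mismatch_rejected(self, peptide_chain):
        other = peptide_chain.subset(np.arange(peptide_chain.n_atoms - 1))
        with pytest.raises(ValueError, match="shared_topology"):
            Ensemble([peptide_chain, other], shared_topology=True)

    def test_selection_classes(self, complex_model):
        bb = AtomSelection(chain="C", atom_class="backbone-no-O")
        assert sorted(set(
            complex_model.atom_names[bb.mask(complex_model)])) == \
            ["C", "CA", "N"]
        ca = AtomSelection(chain="C", atom_class="CA")
        assert ca.indices(complex_model).size == 10
        rng_sel = AtomSelection(chain="C", res_min=57, res_max=59)
        assert set(complex_model.res_numbers[
            rng_sel.mask(complex_model)]) == {57, 58, 59}

    def test_parse_selection(self):
        s = parse_selection("A:150-155:backbone")
        assert (s.chain, s.res_min, s.res_max, s.atom_class) == \
            ("A", 150, 155, "backbone-no-O")
        assert parse_selection("*:ca").atom_class == "CA"
        with pytest.raises(ValueError):
            parse_selection("A:bogusclass")


class TestIO:
    def test_multi_model_round_trip(self, tmp_path):
        models = [make_complex() for _ in range(10)]
        for i, m in enumerate(models):
            m.model_id = i
        path = tmp_path / "ens.pdb"
        write_pdb(Ensemble(models), path)
        ens = read_model_ensemble(path, shared_topology=True)
        assert len(ens) == 10
        assert all(m.n_atoms == models[0].n_atoms for m in ens)
        assert np.allclose(ens[0].xyz, models[0].xyz, atol=1e-3)

    def test_single_model_file(self, tmp_path, peptide_chain):
        path = tmp_path / "one.pdb"
        write_pdb(peptide_chain, path)
        ens = read_model_ensemble(path)
        assert len(ens) == 1
        assert list(ens[0].atom_names) == list(peptide_chain.atom_names)

    def test_mismatched_models_rejected_when_shared(self, tmp_path,
                                                    peptide_chain):
        short = peptide_chain.subset(np.arange(peptide_chain.n_atoms - 1))
        short.model_id = 1
        path = tmp_path / "bad.pdb"
        write_pdb(Ensemble([peptide_chain, short]), path)
        with pytest.raises(ValueError):
            read_model_ensemble(path, shared_topology=True)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_model_ensemble("/nonexistent/file.pdb")


class TestSuperpose:
    def test_identical_models(self, peptide_chain):
        sel = AtomSelection(chain="C")
        tr, r = superpose(peptide_chain, peptide_chain, sel)
        assert r == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-8)

    def test_rigid_motion_recovered(self, peptide_chain):
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = peptide_chain.with_xyz(
            peptide_chain.xyz @ rot.T + np.array([5.0, -3.0, 2.0]))
        _, r = superpose(moved, peptide_chain, AtomSelection(chain="C"))
        assert r == pytest.approx(0.0, abs=1e-8)

    def test_proper_rotation_even_for_reflected_input(self, rng):
        pts = rng.normal(size=(20, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        tr = kabsch(mirrored, pts)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0)

    def test_too_few_atoms(self, rng):
        pts = rng.normal(size=(2, 3))
        with pytest.raises(ValueError, match="at least 3"):
            kabsch(pts, pts)

    def test_collinear_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line)

    def test_against_rotation_grid_oracle(self, rng):
        """50 random 20-atom instances vs an exhaustive rotation-grid
        oracle refined by direct numerical minimization (no SVD)."""
        grid = Rotation.from_euler(
            "zyz",
            [[a, b, c]
             for a in range(0, 360, 24)
             for b in range(0, 181, 20)
             for c in range(0, 360, 24)],
            degrees=True).as_matrix()

        def oracle_rmsd(a, b):
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)
            rotated = np.einsum("rij,nj->rni", grid, ac)
            costs = np.sqrt(((rotated - bc) ** 2).sum(axis=2).mean(axis=1))
            starts = np.argsort(costs)[:8]

            def cost(v):
                r = Rotation.from_rotvec(v).as_matrix()
                return np.sqrt(((ac @ r.T - bc) ** 2).sum(axis=1).mean())

            best = np.inf
            for s in starts:
                e0 = Rotation.from_matrix(grid[s]).as_rotvec()
                res = minimize(cost, e0, method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-13,
                                        "maxiter": 5000})
                best = min(best, res.fun)
            return best

        for _ in range(50):
            a = rng.normal(size=(20, 3)) * 3.0
            b = a @ random_rotation(rng).T + rng.normal(size=(20, 3)) * 0.4
            ma, mb = simple_model(a), simple_model(b)
            _, fitted = superpose(ma, mb, AtomSelection())
            assert fitted == pytest.approx(oracle_rmsd(a, b), abs=1e-3)


class TestRmsd:
    def test_self_zero(self, peptide_chain):
        assert rmsd(peptide_chain, peptide_chain,
                    AtomSelection()) == pytest.approx(0.0)

    def test_hand_value_single_displacement(self):
        a = simple_model([[0, 0, 0], [3, 0, 0], [0, 3, 1.0]])
        xyz = a.xyz.copy()
        xyz[0, 0] += 1.0
        b = a.with_xyz(xyz)
        assert rmsd(a, b, AtomSelection()) == \
            pytest.approx(np.sqrt(1.0 / 3.0), abs=1e-12)

    def test_symmetry(self, rng):
        a = simple_model(rng.normal(size=(8, 3)))
        b = a.with_xyz(a.xyz + rng.normal(size=(8, 3)))
        sel = AtomSelection()
        assert rmsd(a, b, sel) == pytest.approx(rmsd(b, a, sel))

    def test_nonnegative_zero_iff_equal(self, rng):
        a = simple_model(rng.normal(size=(6, 3)))
        b = a.with_xyz(a.xyz + 0.01)
        assert rmsd(a, b, AtomSelection()) > 0

    def test_empty_selection(self, peptide_chain):
        with pytest.raises(ValueError, match="empty"):
            rmsd(peptide_chain, peptide_chain, AtomSelection(chain="Z"))


class TestEnsembleSummary:
    def test_identical_models(self, complex_model):
        models = []
        for i in range(3):
            m = complex_model.with_xyz(complex_model.xyz)
            m.model_id = i
            models.append(m)
        ens = Ensemble(models, shared_topology=True)
        bb, hv = ensemble_rmsd_summary(
            ens, AtomSelection(chain="A", atom_class="backbone-no-O"),
            AtomSelection(chain="C", atom_class="backbone-no-O"),
            AtomSelection(chain="C", atom_class="all-heavy"))
        assert bb == pytest.approx(0.0, abs=1e-8)
        assert hv == pytest.approx(0.0, abs=1e-8)

    def test_known_displacements_mean(self, complex_model):
        """Mean over models matches averaging the per-model rmsd op."""
        pep = complex_model.chain_ids == "C"
        models = [complex_model]
        for i, dy in enumerate((0.5, 1.0), start=1):
            xyz = complex_model.xyz.copy()
            xyz[pep, 1] += dy
            m = complex_model.with_xyz(xyz)
            m.model_id = i
            models.append(m)
        ens = Ensemble(models, shared_topology=True)
        fit = AtomSelection(chain="A", atom_class="backbone-no-O")
        rep_bb = AtomSelection(chain="C", atom_class="backbone-no-O")
        rep_hv = AtomSelection(chain="C", atom_class="all-heavy")
        bb, hv = ensemble_rmsd_summary(ens, fit, rep_bb, rep_hv)
        # receptor is identical across models so the fit is the identity
        expect_bb = np.mean([rmsd(m, models[0], rep_bb) for m in models[1:]])
        expect_hv = np.mean([rmsd(m, models[0], rep_hv) for m in models[1:]])
        assert bb == pytest.approx(expect_bb, abs=1e-8)
        assert hv == pytest.approx(expect_hv, abs=1e-8)

    def test_requires_two_models(self, complex_model):
        ens = Ensemble([complex_model], shared_topology=True)
        sel = AtomSelection()
        with pytest.raises(ValueError, match="at least 2"):
            ensemble_rmsd_summary(ens, sel, sel, sel)


class TestRmsf:
    @staticmethod
    def _ensemble_with_oscillation(base, amplitude=0.5, n=8):
        models = []
        for t in range(n):
            xyz = base.xyz.copy()
            xyz[0, 0] += amplitude * (1 if t % 2 == 0 else -1)
            m = base.with_xyz(xyz)
            m.model_id = t
            models.append(m)
        return Ensemble(models, shared_topology=True)

    def test_static_ensemble_zero(self, complex_model):
        models = []
        for i in range(4):
            m = complex_model.with_xyz(complex_model.xyz)
            m.model_id = i
            models.append(m)
        prof = per_atom_rmsf(Ensemble(models, shared_topology=True),
                             AtomSelection(chain="A"),
                             AtomSelection(chain="C"))
        assert np.allclose(prof.rmsf, 0.0, atol=1e-10)

    def test_oscillating_atom_closed_form(self, complex_model):
        ens = self._ensemble_with_oscillation(complex_model)
        prof = per_atom_rmsf(ens, AtomSelection(chain="C"),
                             AtomSelection())
        # atom 0 (receptor) oscillates +/-0.5 about its mean -> RMSF 0.5;
        # the fit uses the static peptide so frames stay put
        assert prof.rmsf[0] == pytest.approx(0.5, abs=1e-10)
        assert np.allclose(prof.rmsf[1:], 0.0, atol=1e-10)

    def test_rigid_motion_invariance(self, complex_model, rng):
        models = []
        for t in range(5):
            xyz = complex_model.xyz + rng.normal(scale=0.1,
                                                 size=complex_model.xyz.shape)
            m = complex_model.with_xyz(xyz)
            m.model_id = t
            models.append(m)
        ens = Ensemble(models, shared_topology=True)
        fit = AtomSelection(chain="A")
        rep = AtomSelection(chain="C")
        base = per_atom_rmsf(ens, fit, rep).rmsf
        rot = Rotation.from_euler("xyz", [30, -40, 10],
                                  degrees=True).as_matrix()
        moved = [m.with_xyz(m.xyz @ rot.T + np.array([4.0, 5, -6]))
                 for m in models]
        again = per_atom_rmsf(Ensemble(moved, shared_topology=True),
                              fit, rep).rmsf
        assert np.allclose(base, again, atol=1e-8)

    def test_frame_order_permutation_invariant(self, complex_model, rng):
        models = []
        for t in range(6):
            m = complex_model.with_xyz(
                complex_model.xyz + rng.normal(scale=0.2,
                                               size=complex_model.xyz.shape))
            m.model_id = t
            models.append(m)
        fit = AtomSelection(chain="A")
        rep = AtomSelection(chain="C")
        a = per_atom_rmsf(Ensemble(models, shared_topology=True), fit,
                          rep).rmsf
        shuffled = [models[i] for i in rng.permutation(6)]
        b = per_atom_rmsf(Ensemble(shuffled, shared_topology=True), fit,
                          rep).rmsf
        assert np.allclose(a, b, atol=1e-10)


def _dihedral_oracle(p0, p1, p2, p3):
    """Independent vector-algebra torsion: signed angle between the two
    bond planes measured around b1 with an explicit sign via the scalar
    triple product."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    # IUPAC orientation: positive when b2 is clockwise of b0 looking
    # from atom 1 to atom 2, i.e. det[n1, b1, n2] > 0
    sign = np.sign(np.linalg.det(np.stack([n1, b1, n2])))
    return ang * (sign if sign != 0 else 1.0)


def _four_atoms_with_torsion(angle_deg):
    """Place C(i-1)-N-CA-C with the given torsion by explicit rotation."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.46, 0.0, 0.0])
    prev_c = np.array([-0.5, 1.3, 0.0])
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.array([-1.0, 0, 0]))
    # start from the cis (0 degree) position of C relative to prev_c
    cis_dir = np.array([0.0, 1.0, 0.0])
    c = ca + 1.52 * rot.apply(cis_dir)
    return prev_c, n, ca, c


class TestDihedrals:
    @pytest.mark.parametrize("angle", [180.0, 0.0, 60.0, -60.0, 135.0])
    def test_constructed_torsion(self, angle):
        p = _four_atoms_with_torsion(angle)
        got = dihedral_angle(*p)
        assert got == pytest.approx(wrap_angle(angle), abs=1e-8)
        assert got == pytest.approx(wrap_angle(_dihedral_oracle(*p)),
                                    abs=1e-8)

    def test_trans_is_180(self):
        got = dihedral_angle(*_four_atoms_with_torsion(180.0))
        assert abs(got) == pytest.approx(180.0, abs=1e-8)

    def test_cis_is_0(self):
        assert dihedral_angle(*_four_atoms_with_torsion(0.0)) == \
            pytest.approx(0.0, abs=1e-8)

    def test_two_residue_chain_one_phi_one_psi(self):
        chain = make_chain("C", 2)
        series = backbone_dihedrals(chain, "C")
        names = [(s.res_number, s.angle_name) for s in series]
        assert names == [(1, "psi"), (2, "phi")]

    def test_unknown_chain(self, peptide_chain):
        with pytest.raises(KeyError):
            backbone_dihedrals(peptide_chain, "Z")

    def test_wrap_angle_principal_interval(self):
        assert wrap_angle(270.0) == pytest.approx(-90.0)
        assert wrap_angle(-180.0) == pytest.approx(180.0)
        assert wrap_angle(180.0) == pytest.approx(180.0)


class TestRamachandran:
    def test_alpha_point_favored(self):
        assert ramachandran_classify(-63, -43, "general") == "favored"

    def test_beta_point_favored(self):
        assert ramachandran_classify(-120, 130, "general") == "favored"

    def test_periodicity(self):
        for phi, psi in [(-63, -43), (-120, 130), (60, -120), (10, 10)]:
            assert ramachandran_classify(phi, psi, "general") == \
                ramachandran_classify(phi - 360, psi, "general") == \
                ramachandran_classify(phi, psi + 360, "general")

    @given(st.floats(-180, 180), st.floats(-180, 180),
           st.sampled_from(["general", "glycine", "proline", "pre-proline"]))
    @settings(max_examples=200, deadline=None)
    def test_partitions_the_torus(self, phi, psi, cls):
        assert ramachandran_classify(phi, psi, cls) in \
            {"favored", "allowed", "outlier"}

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            ramachandran_classify(0, 0, "bogus")


class TestContacts:
    @staticmethod
    def _two_chain_model(distance):
        xyz = [[0, 0, 0], [-5, 0, 0], [0, -5, 1.0],
               [distance, 0, 0], [distance + 5, 0, 0],
               [distance, 5, 1.0]]
        return simple_model(
            xyz, names=["CA", "CB", "CG", "CA", "CB", "CG"],
            res_numbers=[1, 1, 1, 1, 1, 1],
            chains=["A", "A", "A", "C", "C", "C"])

    def test_boundary_included(self):
        m = self._two_chain_model(3.4)
        assert len(contact_residues(m, "C", "A", cutoff=3.5)) == 1

    def test_beyond_cutoff_excluded(self):
        m = self._two_chain_model(3.6)
        assert contact_residues(m, "C", "A", cutoff=3.5) == []

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            n_rec, n_pep = 5, 3
            coords, chains, resnums, names = [], [], [], []
            for r in range(n_rec):
                for a in range(3):
                    coords.append(rng.uniform(0, 12, 3))
                    chains.append("A")
                    resnums.append(r + 1)
                    names.append(f"C{a}")
            for r in range(n_pep):
                for a in range(2):
                    coords.append(rng.uniform(0, 12, 3))
                    chains.append("C")
                    resnums.append(r + 1)
                    names.append(f"C{a}")
            m = simple_model(coords, names=names, res_numbers=resnums,
                             chains=chains)
            got = {k[1] for k in contact_residues(m, "C", "A", cutoff=4.0)}
            # O(N^2) oracle
            expect = set()
            pep_xyz = m.xyz[m.chain_ids == "C"]
            for i in range(m.n_atoms):
                if m.chain_ids[i] != "A":
                    continue
                for p in pep_xyz:
                    if np.linalg.norm(m.xyz[i] - p) <= 4.0:
                        expect.add(int(m.res_numbers[i]))
            assert got == expect

    def test_unknown_chain(self, complex_model):
        with pytest.raises(KeyError):
            contact_residues(complex_model, "Z", "A")


class TestClashScore:
    def test_two_carbons_overlap(self):
        m = self._pair_model(3.0)
        score, pairs = clash_score(m, return_pairs=True)
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(0.4, abs=1e-9)

    def test_just_under_threshold(self):
        m = self._pair_model(3.41)
        assert clash_score(m) == 0.0

    @staticmethod
    def _pair_model(d):
        return simple_model([[0, 0, 0], [d, 0, 0]], names=["CA", "CA"],
                            res_numbers=[1, 1], chains=["A", "B"])

    def test_normalization_per_1000(self):
        """2000 atoms, 3 engineered clashes -> 1.5 per 1000."""
        coords, chains, resnums, names = [], [], [], []
        for i in range(1994):  # far-apart background atoms
            coords.append([10.0 * i, 0.0, 0.0])
            chains.append("Z")
            resnums.append(i + 1)
            names.append("CA")
        base = 1994
        for j in range(3):  # clash pairs, 3.0 Å apart (overlap 0.4)
            y = 100.0 * (j + 1)
            coords += [[0.0, y, 50.0], [3.0, y, 50.0]]
            chains += ["A", "B"]
            resnums += [base + 2 * j + 1, base + 2 * j + 2]
            names += ["CA", "CA"]
        m = simple_model(coords, names=names, res_numbers=resnums,
                         chains=chains)
        assert m.n_atoms == 2000
        assert clash_score(m) == pytest.approx(1.5)

    def test_unknown_element(self):
        m = simple_model([[0, 0, 0], [1, 0, 0]], elements=["C", "XX"])
        with pytest.raises(KeyError, match="XX"):
            clash_score(m)

    def test_same_residue_excluded(self):
        m = simple_model([[0, 0, 0], [1.0, 0, 0]], names=["CA", "CB"],
                         res_numbers=[1, 1])
        assert clash_score(m) == 0.0
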