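"""Coulomb/LJ/GB primitives, Born radii, rotamer selection, table building."""

import numpy as np
import pytest

from pottsbind.energies import (COULOMB_K, EnergyModel, ForceField, ParamAtoms,
                                RotamerLibrary, born_radii, coulomb_energy,
                                gb_pair_energy, gb_self_energy, lj_energy,
                                _f_gb)
from pottsbind.potts import Alphabet, PottsModel, potts_score
from pottsbind.structure import align_slab_to_z
from pottsbind.synthetic import make_toy_system


def atoms_at(coords, charge=0.0, eps=0.1, rmin_half=1.7, gb=1.5):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    m = len(coords)
    return ParamAtoms(coords, np.full(m, charge), np.full(m, eps),
                      np.full(m, rmin_half), np.full(m, gb))


class TestCoulomb:
    def test_unit_charges_at_one_angstrom(self):
        a = atoms_at([[0, 0, 0]], charge=1.0)
        b = atoms_at([[1, 0, 0]], charge=1.0)
        assert coulomb_energy(a, b) == pytest.approx(COULOMB_K, rel=1e-12)

    def test_opposite_charges_flip_sign(self):
        a = atoms_at([[0, 0, 0]], charge=1.0)
        b = atoms_at([[1, 0, 0]], charge=-1.0)
        assert coulomb_energy(a, b) == pytest.approx(-COULOMB_K, rel=1e-12)

    def test_inverse_distance_law(self):
        a = atoms_at([[0, 0, 0]], charge=1.0)
        assert coulomb_energy(a, atoms_at([[2, 0, 0]], charge=1.0)) == pytest.approx(
            0.5 * coulomb_energy(a, atoms_at([[1, 0, 0]], charge=1.0)), rel=1e-12)

    def test_zero_distance_raises(self):
        a = atoms_at([[0, 0, 0]], charge=1.0)
        with pytest.raises(ValueError):
            coulomb_energy(a, atoms_at([[0, 0, 0]], charge=1.0))


class TestLennardJones:
    def test_minimum_at_rmin(self):
        a = atoms_at([[0, 0, 0]], eps=0.25, rmin_half=1.6)
        b = atoms_at([[3.2, 0, 0]], eps=0.25, rmin_half=1.6)
        assert lj_energy(a, b) == pytest.approx(-0.25, rel=1e-12)

    def test_vanishes_at_long_range(self):
        a = atoms_at([[0, 0, 0]], eps=0.25)
        b = atoms_at([[500.0, 0, 0]], eps=0.25)
        assert abs(lj_energy(a, b)) < 1e-12

    def test_matches_brute_force_sum_on_fixture(self):
        """Vectorized set-set LJ equals an explicit double loop (10 atoms)."""
        rng = np.random.default_rng(5)
        ca = rng.uniform(0, 5, (5, 3))
        cb = rng.uniform(6, 11, (5, 3))
        ea, eb = rng.uniform(0.05, 0.3, 5), rng.uniform(0.05, 0.3, 5)
        ra, rb = rng.uniform(1.2, 2.0, 5), rng.uniform(1.2, 2.0, 5)
        A = ParamAtoms(ca, np.zeros(5), ea, ra, np.full(5, 1.5))
        B = ParamAtoms(cb, np.zeros(5), eb, rb, np.full(5, 1.5))
        expected = 0.0
        for i in range(5):
            for j in range(5):
                r = np.linalg.norm(ca[i] - cb[j])
                eps = np.sqrt(ea[i] * eb[j])
                rmin = ra[i] + rb[j]
                expected += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert lj_energy(A, B) == pytest.approx(expected, rel=1e-9)


class TestBornRadii:
    def test_isolated_atom_keeps_intrinsic_radius(self):
        a = atoms_at([[0, 0, 0]], gb=1.5)
        assert born_radii(a)[0] == pytest.approx(1.5, rel=1e-12)

    def test_buried_atom_radius_grows(self):
        center = [[0.0, 0.0, 0.0]]
        cage = [[x, y, z] for x in (-3, 3) for y in (-3, 3) for z in (-3, 3)]
        a = atoms_at(center + cage, gb=1.5)
        radii = born_radii(a)
        assert radii[0] > 1.5

    def test_matches_volume_integral_oracle(self):
        """HCT descreening vs Monte Carlo integration of 1/(4 pi r^4) over
        the neighbour spheres (non-overlapping geometry), within 5%."""
        rng = np.random.default_rng(11)
        centers = np.array([[0.0, 0.0, 0.0], [4.0, 0, 0], [0, 4.5, 0],
                            [-4.2, 0, 1.0], [0, 0, -5.0]])
        rho = np.array([1.5, 1.4, 1.6, 1.3, 1.7])
        a = ParamAtoms(centers, np.zeros(5), np.zeros(5), np.ones(5), rho)
        got = born_radii(a)[0]
        # oracle: 1/R0 = 1/rho0 - sum_j MC integral over sphere j
        integral = 0.0
        for j in range(1, 5):
            pts = rng.uniform(-1, 1, (200_000, 3))
            pts = pts[np.linalg.norm(pts, axis=1) <= 1.0] * rho[j] + centers[j]
            vol = 4.0 / 3.0 * np.pi * rho[j] ** 3
            r = np.linalg.norm(pts, axis=1)
            integrand = 1.0 / (4.0 * np.pi * r ** 4)
            integral += vol * integrand.mean()
        oracle = 1.0 / (1.0 / rho[0] - integral)
        assert got == pytest.approx(oracle, rel=0.05)

    def test_overlapping_centers_raise(self):
        a = atoms_at([[0, 0, 0], [0, 0, 0]], gb=1.5)
        with pytest.raises(ValueError):
            born_radii(a)


class TestGeneralizedBorn:
    def test_self_limit_at_zero_separation(self):
        a = atoms_at([[0, 0, 0]], charge=1.0, gb=2.0)
        b = atoms_at([[0, 0, 0]], charge=1.0, gb=2.0)
        e = gb_pair_energy(a, b, np.array([2.0]), np.array([2.0]))
        assert e == pytest.approx(-COULOMB_K * (1 - 1 / 78.5) / 2.0, rel=1e-12)

    def test_vanishes_when_dielectrics_match(self):
        a = atoms_at([[0, 0, 0]], charge=1.0)
        b = atoms_at([[3, 0, 0]], charge=1.0)
        assert gb_pair_energy(a, b, np.array([1.5]), np.array([1.5]),
                              eps_in=78.5, eps_out=78.5) == 0.0

    def test_three_atom_hand_computed_oracle(self):
        """f_GB and the pair sum recomputed by hand for three atoms."""
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 4.0, 0]])
        q = np.array([1.0, -0.5, 0.25])
        R = np.array([1.5, 2.0, 1.8])
        a = ParamAtoms(coords, q, np.zeros(3), np.ones(3), R)
        expected = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                r2 = np.sum((coords[i] - coords[j]) ** 2)
                f = np.sqrt(r2 + R[i] * R[j] * np.exp(-r2 / (4 * R[i] * R[j])))
                expected += -COULOMB_K * (1 - 1 / 78.5) * q[i] * q[j] / f
        got = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                ai = ParamAtoms(coords[i], q[i], 0.0, 1.0, R[i])
                aj = ParamAtoms(coords[j], q[j], 0.0, 1.0, R[j])
                got += gb_pair_energy(ai, aj, R[i:i + 1], R[j:j + 1])
        assert got == pytest.approx(expected, rel=1e-9)

    def test_fgb_approaches_r_for_small_radii(self):
        d = np.array([[5.0]])
        for radius in (1e-2, 1e-3, 1e-4):
            f = _f_gb(d, np.array([radius]), np.array([radius]))[0, 0]
            assert f == pytest.approx(5.0, rel=radius)

    def test_self_energy_negative_for_charged_atom(self):
        a = atoms_at([[0, 0, 0]], charge=1.0, gb=2.0)
        e = gb_self_energy(a, np.array([2.0]))
        assert e == pytest.approx(-COULOMB_K / 2 * (1 - 1 / 78.5) / 2.0, rel=1e-12)


class TestRotamerSelection:
    def test_single_rotamer_library_returns_it(self, tiny_energy_setup):
        conf, _, _ = tiny_energy_setup
        lib = RotamerLibrary(rotamers={"S": [(-60.0,)]})
        em = EnergyModel(conf, library=lib, alphabet=Alphabet("S"))
        chis, _ = em.select_rotamer(0, "S")
        # refinement may shift by multiples of 10 degrees around -60
        assert chis[0] == pytest.approx(-60.0, abs=2 * em.chi_refine_sweeps * 10.0)

    def test_clashing_rotamer_rejected(self, tiny_energy_setup):
        conf, em, _ = tiny_energy_setup
        # evaluate lysine one-body for each library rotamer: the selected one
        # must have the lowest refined energy among all candidates
        chis, e = em.select_rotamer(1, "K")
        for cand in em.library.for_aa("K"):
            assert e <= em.one_body_breakdown(1, "K", tuple(cand)).total + 1e-9

    def test_no_chi_amino_acids(self, tiny_energy_setup):
        _, em, _ = tiny_energy_setup
        chis_a, e_a = em.select_rotamer(0, "A")
        assert chis_a == ()
        assert np.isfinite(e_a)
        lib = RotamerLibrary.default()
        assert lib.for_aa("G") == [()]

    def test_missing_amino_acid_raises(self):
        lib = RotamerLibrary(rotamers={"A": [()]})
        with pytest.raises(KeyError):
            lib.for_aa("W")


class TestOneBody:
    def test_breakdown_components_sum(self, tiny_energy_setup):
        _, em, _ = tiny_energy_setup
        bd = em.one_body_breakdown(0, "K", (180.0, 180.0))
        assert bd.total == pytest.approx(bd.elec + bd.lj + bd.gb, abs=1e-9)

    def test_far_slab_contribution_decays(self):
        """A neutral residue >50 A above the slab has negligible direct
        plastic interaction."""
        conf = align_slab_to_z(make_toy_system(2, slab_nx=4, slab_ny=4,
                                               slab_layers=1, com_height=55.0,
                                               seed=2))
        em = EnergyModel(conf, alphabet=Alphabet("AL"))
        sc = em.build_sidechain(0, "L", (180.0, 180.0))
        assert abs(lj_energy(sc, em._plastic)) < 1e-3
        assert abs(coulomb_energy(sc, em._plastic)) < 1e-3

    def test_glycine_one_body_is_zero(self, tiny_energy_setup):
        conf, _, _ = tiny_energy_setup
        em = EnergyModel(conf, alphabet=Alphabet("G"))
        assert em.one_body_energy(0, "G") == 0.0


class TestTwoBody:
    def test_symmetry_under_swap(self, tiny_energy_setup):
        _, em, _ = tiny_energy_setup
        assert em.two_body_energy(0, "K", 2, "S") == pytest.approx(
            em.two_body_energy(2, "S", 0, "K"), rel=1e-12)

    def test_same_residue_rejected(self, tiny_energy_setup):
        _, em, _ = tiny_energy_setup
        with pytest.raises(ValueError):
            em.two_body_energy(1, "A", 1, "C")

    def test_neutral_pair_decays_with_distance(self):
        conf = align_slab_to_z(make_toy_system(2, slab_nx=4, slab_ny=4,
                                               slab_layers=1, seed=2))
        em = EnergyModel(conf, alphabet=Alphabet("AL"))
        # residues 0 and 1 are 3.8 A apart; move residue 1's side chain far
        # away by scoring against a distant duplicate instead: use the direct
        # cross terms on translated copies of the cached rotamer atoms
        em.select_rotamer(0, "L")
        em.select_rotamer(1, "L")
        si = em._selected[(0, "L")]
        sj = em._selected[(1, "L")]
        far = ParamAtoms(sj["atoms"].coords + np.array([60.0, 0, 0]),
                         sj["atoms"].charge, sj["atoms"].eps,
                         sj["atoms"].rmin_half, sj["atoms"].gb_radius)
        e = (coulomb_energy(si["atoms"], far)
             + lj_energy(si["atoms"], far)
             + gb_pair_energy(si["atoms"], far, si["radii"], sj["radii"]))
        assert abs(e) < 1e-3

    def test_matches_atom_pair_brute_force(self, tiny_energy_setup):
        """Cross energy equals the explicit per-pair Coulomb+LJ+GB sum."""
        _, em, _ = tiny_energy_setup
        e = em.two_body_energy(0, "K", 2, "C")
        si = em._selected[(0, "K")]
        sj = em._selected[(2, "C")]
        expected = 0.0
        ai, aj = si["atoms"], sj["atoms"]
        for p in range(len(ai)):
            for r in range(len(aj)):
                dist = np.linalg.norm(ai.coords[p] - aj.coords[r])
                expected += COULOMB_K * ai.charge[p] * aj.charge[r] / dist
                eps = np.sqrt(ai.eps[p] * aj.eps[r])
                rmin = ai.rmin_half[p] + aj.rmin_half[r]
                expected += eps * ((rmin / dist) ** 12 - 2 * (rmin / dist) ** 6)
                f = np.sqrt(dist ** 2 + si["radii"][p] * sj["radii"][r]
                            * np.exp(-dist ** 2 / (4 * si["radii"][p] * sj["radii"][r])))
                expected += -COULOMB_K * (1 - 1 / 78.5) * ai.charge[p] * aj.charge[r] / f
        assert e == pytest.approx(expected, rel=1e-9)


class TestBuildTables:
    def test_entry_counts(self, tiny_energy_setup):
        _, _, tables = tiny_energy_setup
        assert tables.one_body.shape == (3, 4)          # 12 one-body entries
        filled = [(i, j) for i in range(3) for j in range(3)
                  if np.any(tables.two_body[i, j] != 0)]
        assert set(filled) <= {(0, 1), (0, 2), (1, 2)}  # 3 pairs x 16 entries

    def test_rebuild_is_byte_identical(self, tiny_energy_setup, tmp_path):
        conf, _, tables = tiny_energy_setup
        t2 = EnergyModel(conf, alphabet=Alphabet("ACKS")).build_tables()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        tables.to_csv(p1)
        t2.to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_table_score_equals_direct_recomputation(self, tiny_energy_setup):
        conf, em, tables = tiny_energy_setup
        model = PottsModel(tables=tables)
        rng = np.random.default_rng(17)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACKS"), 3))
            direct = sum(em.one_body_energy(i, seq[i]) for i in range(3))
            direct += model.lam * sum(em.two_body_energy(i, seq[i], j, seq[j])
                                      for i in range(3) for j in range(i + 1, 3))
            assert potts_score(model, seq) == pytest.approx(direct, rel=1e-9, abs=1e-9)

    def test_translation_invariance(self, tiny_energy_setup):
        conf, _, tables = tiny_energy_setup
        shifted = conf.transformed(np.eye(3), np.array([3.0, -2.0, 5.0]))
        t2 = EnergyModel(shifted, alphabet=Alphabet("ACKS")).build_tables()
        np.testing.assert_allclose(t2.one_body, tables.one_body, atol=1e-8)
        np.testing.assert_allclose(t2.two_body, tables.two_body, atol=1e-8)


class TestCoarseGrainingConsistency:
    def test_mutation_energy_vs_full_system_oracle(self, tiny_energy_setup):
        """Finite-difference check of the coarse-graining approximation.

        The table predicts the energy change of mutating one residue; the
        oracle recomputes both full-system energies with every side chain
        explicit (no CG spheres) and identical Born-radius context.  The
        two agree up to the CG approximation error, which for these small
        systems stays within 1 kcal/mol or 15% of the change.
        """
        conf, em, tables = tiny_energy_setup
        model = PottsModel(tables=tables)

        def full_energy(seq):
            scs, radii_list = [], []
            sel = [em._selected[(i, seq[i])] for i in range(3)]
            atom_sets = [s["atoms"] for s in sel]
            stack = ParamAtoms.concat(atom_sets + [em._backbone, em._plastic])
            radii = born_radii(stack)
            offsets = np.cumsum([0] + [len(s) for s in atom_sets])
            nb = len(em._backbone)
            bb_radii = radii[offsets[-1]:offsets[-1] + nb]
            pl_radii = radii[offsets[-1] + nb:]
            total = 0.0
            for i in range(3):
                sc, rr = atom_sets[i], radii[offsets[i]:offsets[i + 1]]
                if len(sc) == 0:
                    continue
                scale = em._bonded_scale(i, len(sc))
                total += coulomb_energy(sc, em._plastic) + lj_energy(sc, em._plastic)
                total += coulomb_energy(sc, em._backbone, scale=scale)
                total += lj_energy(sc, em._backbone, scale=scale)
                total += gb_pair_energy(sc, em._plastic, rr, pl_radii)
                total += gb_pair_energy(sc, em._backbone, rr, bb_radii)
                total += gb_self_energy(sc, rr)
            for i in range(3):
                for j in range(i + 1, 3):
                    si, sj = atom_sets[i], atom_sets[j]
                    if len(si) == 0 or len(sj) == 0:
                        continue
                    ri = radii[offsets[i]:offsets[i + 1]]
                    rj = radii[offsets[j]:offsets[j + 1]]
                    total += model.lam * (coulomb_energy(si, sj) + lj_energy(si, sj)
                                          + gb_pair_energy(si, sj, ri, rj))
            return total

        base, mutant = "AKS", "CKS"
        d_table = potts_score(model, mutant) - potts_score(model, base)
        d_full = full_energy(mutant) - full_energy(base)
        assert d_table == pytest.approx(d_full, rel=0.15, abs=1.0)
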