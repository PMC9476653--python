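"""Multipole interactions, Ewald summation and Lennard-Jones."""

import math

import numpy as np
import pytest

from gpwater import electrostatics as es
from gpwater.units import COULOMB

from conftest import random_multipoles


def null_net_moment_cluster(seed=0):
    """Two distorted waters plus a compensating central site whose dipole and
    quadrupole cancel the cluster's net moments; its periodic images then
    couple only at octupole order, so Ewald and open-boundary sums agree."""
    rng = np.random.default_rng(seed)
    pos = np.array([[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0],
                    [3.0, 0.2, 0.1], [3.8, 0.5, 0.0], [2.6, 0.9, 0.4]], float)
    q = np.array([-0.8, 0.4, 0.4, -0.8, 0.4, 0.4])
    _, mu, th = random_multipoles(rng, 6)
    mol = np.array([0, 0, 0, 1, 1, 1])
    center = pos.mean(axis=0)
    _, M, T = es.net_moments(pos, q, mu, th, origin=center)
    pos = np.vstack([pos, center])
    q = np.append(q, 0.0)
    mu = np.vstack([mu, -M])
    th = np.concatenate([th, -T[None]])
    mol = np.append(mol, 2)
    return pos - center, q, mu, th, mol


class TestPairInteractions:
    def test_unit_charges_at_one_angstrom(self):
        e, _ = es.pair_multipole_energy(es.MultipoleSet(q=1.0),
                                        es.MultipoleSet(q=-1.0),
                                        [1.0, 0.0, 0.0], lprime=0)
        assert e == pytest.approx(-1389.35, abs=0.01)
        assert e == pytest.approx(-COULOMB, rel=1e-12)

    @pytest.mark.parametrize("lprime", [0, 1, 2])
    def test_zero_moments_give_zero_energy(self, lprime):
        e, g = es.pair_multipole_energy(es.MultipoleSet(), es.MultipoleSet(),
                                        [2.0, 1.0, 0.5], lprime=lprime)
        assert e == 0.0 and np.all(g == 0.0)

    def test_zero_separation_raises(self):
        with pytest.raises(ZeroDivisionError):
            es.pair_multipole_energy(es.MultipoleSet(q=1.0),
                                     es.MultipoleSet(q=1.0), [0, 0, 0])

    def test_dipole_tensor_formula_matches_shrinking_point_charges(self):
        muA = np.array([0.3, -0.2, 0.5])
        muB = np.array([-0.1, 0.4, 0.2])
        rAB = np.array([2.0, 1.0, -0.5])
        e_ref, _ = es.pair_multipole_energy(es.MultipoleSet(mu=muA),
                                            es.MultipoleSet(mu=muB), rAB)

        def brute(d):
            pts, chg = [], []
            for mu, c in ((muA, np.zeros(3)), (muB, rAB)):
                mh = mu / np.linalg.norm(mu)
                pts += [c + d * mh, c - d * mh]
                chg += [np.linalg.norm(mu) / (2 * d), -np.linalg.norm(mu) / (2 * d)]
            e = 0.0
            for i in range(2):
                for j in range(2, 4):
                    e += COULOMB * chg[i] * chg[j] / np.linalg.norm(pts[i] - pts[j])
            return e

        errs = [abs(brute(d) - e_ref) for d in (0.02, 0.01)]
        assert errs[1] < errs[0] / 1.9          # order >= 1 in spacing
        assert errs[1] < 1e-4 * abs(e_ref)

    def test_quadrupole_tensor_formula_matches_shrinking_point_charges(self):
        # linear quadrupole (+q, -2q, +q) along a unit vector n:
        # traceless moment theta = q d^2 (3 n n - I)
        n = np.array([0.6, 0.64, 0.48]); n /= np.linalg.norm(n)
        rAB = np.array([1.5, -2.0, 1.0])
        qB = 0.7
        # shrinking array keeps q d^2 = 0.5 fixed, so theta is d-independent
        theta = 0.5 * (3.0 * np.outer(n, n) - np.eye(3))

        def brute(d):
            qs = 0.5 / d ** 2
            pts = [d * n, -d * n, np.zeros(3)]
            chg = [qs, qs, -2 * qs]
            return sum(COULOMB * c * qB / np.linalg.norm(p - rAB)
                       for c, p in zip(chg, pts))

        e_ref, _ = es.pair_multipole_energy(
            es.MultipoleSet(theta=theta), es.MultipoleSet(q=qB), rAB)
        errs = [abs(brute(d) - e_ref) for d in (0.05, 0.025)]
        assert errs[1] < errs[0] / 1.9
        assert errs[1] < 1e-3 * max(abs(e_ref), 1e-3)

    def test_pair_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        q, mu, th = random_multipoles(rng, 2, neutral=False)
        mA = es.MultipoleSet(q=q[0], mu=mu[0], theta=th[0])
        mB = es.MultipoleSet(q=q[1], mu=mu[1], theta=th[1])
        rAB = np.array([1.8, 1.1, -0.7])
        e0, g = es.pair_multipole_energy(mA, mB, rAB)
        h = 1e-6
        for k in range(3):
            dr = np.zeros(3); dr[k] = h
            num = (es.pair_multipole_energy(mA, mB, rAB + dr)[0]
                   - es.pair_multipole_energy(mA, mB, rAB - dr)[0]) / (2 * h)
            assert num == pytest.approx(g[k], rel=1e-6, abs=1e-9)

    def test_truncation_refinement_ordering_at_long_range(self):
        # multipole convergence: the L'=2 correction decays faster than the
        # L'=1 correction with separation
        rng = np.random.default_rng(4)
        q, mu, th = random_multipoles(rng, 2, neutral=False)
        mA = es.MultipoleSet(q=q[0], mu=mu[0], theta=th[0])
        mB = es.MultipoleSet(q=q[1], mu=mu[1], theta=th[1])
        direction = np.array([0.3, 0.5, 0.81])
        d21_over_d10 = []
        for r in (8.0, 16.0):
            e = [es.pair_multipole_energy(mA, mB, r * direction, lprime=lp)[0]
                 for lp in (0, 1, 2)]
            d21_over_d10.append(abs(e[2] - e[1]) / abs(e[1] - e[0]))
        assert d21_over_d10[1] < d21_over_d10[0] / 1.5


class TestEwald:
    def test_matches_direct_sum_on_isolated_cluster(self):
        pos, q, mu, th, mol = null_net_moment_cluster()
        e_direct, _, _ = es.direct_sum(pos, q, mu, th, exclusions=mol)
        cfg = es.ElectrostaticsConfig(precision=1e-7, rcut=14.0)
        res = es.ewald_sum(pos + 45.0, q, mu, th, 90.0, cfg, molecule=mol)
        assert abs(res.energy - e_direct) <= 1e-7

    def test_energy_invariant_to_splitting_parameter(self):
        pos, q, mu, th, mol = null_net_moment_cluster(seed=1)
        cfg0 = es.ElectrostaticsConfig(precision=1e-7, rcut=9.0)
        base = es.Ewald(30.0, cfg0)
        energies = []
        for fac in (0.8, 1.0, 1.2):
            cfg = es.ElectrostaticsConfig(precision=1e-7, rcut=9.0,
                                          alpha=base.alpha * fac)
            energies.append(es.ewald_sum(pos + 15.0, q, mu, th, 30.0, cfg,
                                         molecule=mol).energy)
        assert max(energies) - min(energies) < 1e-7

    def test_rock_salt_madelung_constant(self):
        lat = np.array([[i, j, k] for i in range(2) for j in range(2)
                        for k in range(2)], float)
        qs = np.array([(-1.0) ** (i + j + k) for i in range(2)
                       for j in range(2) for k in range(2)])
        cfg = es.ElectrostaticsConfig(precision=1e-8, rcut=1.0, lprime=0)
        res = es.ewald_sum(lat, qs, np.zeros((8, 3)), np.zeros((8, 3, 3)),
                           2.0, cfg)
        madelung = -res.energy * 2.0 / (8.0 * COULOMB)
        assert madelung == pytest.approx(1.747565, abs=1e-5)

    def test_invariant_under_lattice_translation(self):
        pos, q, mu, th, mol = null_net_moment_cluster(seed=2)
        cfg = es.ElectrostaticsConfig(precision=1e-7, rcut=6.0)
        L = 20.0
        r1 = es.ewald_sum(pos + 10.0, q, mu, th, L, cfg, molecule=mol)
        shifted = pos + 10.0
        shifted[3] += np.array([L, -2 * L, L])   # integer lattice translation
        r2 = es.ewald_sum(shifted, q, mu, th, L, cfg, molecule=mol)
        assert r2.energy == pytest.approx(r1.energy, abs=1e-7)
        assert np.abs(r1.forces - r2.forces).max() < 1e-6

    def test_non_neutral_system_reports_net_charge(self):
        pos = np.array([[1.0, 1, 1], [3.0, 3, 3]])
        with pytest.raises(es.NonNeutralError, match="0.5"):
            es.ewald_sum(pos, np.array([1.0, -0.5]), np.zeros((2, 3)),
                         np.zeros((2, 3, 3)), 12.0,
                         es.ElectrostaticsConfig(rcut=5.0))

    def test_forces_match_finite_differences(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 10.0, (6, 3))
        q, mu, th = random_multipoles(rng, 6)
        cfg = es.ElectrostaticsConfig(precision=1e-8, rcut=5.0)
        ew = es.Ewald(10.0, cfg)
        res = ew.compute(pos, q, mu, th)
        h = 1e-5
        for a, x in ((0, 0), (2, 1), (5, 2)):
            pp = pos.copy(); pp[a, x] += h
            pm = pos.copy(); pm[a, x] -= h
            num = -(ew.compute(pp, q, mu, th).energy
                    - ew.compute(pm, q, mu, th).energy) / (2 * h)
            assert num == pytest.approx(res.forces[a, x], rel=1e-5, abs=1e-7)

    def test_newtons_third_law(self):
        rng = np.random.default_rng(9)
        pos = rng.uniform(0, 12.0, (9, 3))
        q, mu, th = random_multipoles(rng, 9)
        res = es.ewald_sum(pos, q, mu, th, 12.0,
                           es.ElectrostaticsConfig(precision=1e-7, rcut=6.0))
        assert np.abs(res.forces.sum(axis=0)).max() < 1e-9

    def test_self_interaction_constant(self):
        assert es.self_interaction_constant() == pytest.approx(2.837297, abs=1e-6)


class TestFlexibleMoments:
    def test_rigid_moments_contribute_nothing(self):
        phi = es.PhiDerivs.zeros(6)
        phi.p0[:] = 1.3
        phi.p1[:] = 0.7
        phi.p2[:] = -0.2
        mol_index = np.array([[0, 1, 2], [3, 4, 5]])
        zeros = {"dq": np.zeros((2, 3, 3, 3)), "dmu": np.zeros((2, 3, 3, 3, 3)),
                 "dth": np.zeros((2, 3, 3, 3, 3, 3))}
        f = es.assemble_flexible_forces(phi, mol_index, zeros["dq"],
                                        zeros["dmu"], zeros["dth"])
        assert np.all(f == 0.0)

    def test_total_flexible_force_sums_to_zero(self, small_box):
        sim = small_box()
        f = sim.compute_forces()
        assert np.abs(f.forces.sum(axis=0)).max() < 1e-9


class TestLennardJones:
    def setup_method(self):
        self.p = es.LJParams()

    def _pair(self, r, shift=False):
        pos = np.array([[0.0, 0, 0], [r, 0, 0]])
        e, f, _ = es.lj_energy_forces(pos, np.array(["O", "O"]),
                                      np.array([0, 1]), self.p, rcut=10.0,
                                      shift=shift)
        return e, f

    def test_zero_at_sigma(self):
        e, _ = self._pair(self.p.sigma_oo)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_minimum_depth_matches_epsilon(self):
        e, f = self._pair(2 ** (1 / 6) * self.p.sigma_oo)
        assert e == pytest.approx(-0.763, abs=1e-10)
        assert np.abs(f).max() < 1e-10

    def test_hh_pairs_have_no_lj_term(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        e, f, _ = es.lj_energy_forces(pos, np.array(["H", "H"]),
                                      np.array([0, 1]), self.p, rcut=10.0)
        assert e == 0.0 and np.all(f == 0.0)

    def test_intramolecular_pairs_skipped(self):
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        e, _, _ = es.lj_energy_forces(pos, np.array(["O", "O"]),
                                      np.array([0, 0]), self.p, rcut=10.0)
        assert e == 0.0

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="species"):
            es.lj_energy_forces(np.zeros((2, 3)), np.array(["O", "X"]),
                                np.array([0, 1]), self.p, rcut=5.0)

    def test_forces_match_finite_differences_in_random_box(self):
        # random but non-overlapping configuration (lattice + jitter); with
        # overlapping atoms the r^-12 wall makes any FD oracle meaningless
        from gpwater import md
        rng = np.random.default_rng(1)
        n_mol = 10
        state = md.build_water_box(n_mol, 12.0, seed=2)
        pos = state.positions + rng.normal(0, 0.1, (3 * n_mol, 3))
        species = np.array(["O", "H", "H"] * n_mol)
        mol = np.repeat(np.arange(n_mol), 3)
        e0, f, _ = es.lj_energy_forces(pos, species, mol, self.p, rcut=5.0,
                                       box_length=12.0)
        h = 1e-6
        for a, x in ((0, 0), (7, 1), (20, 2)):
            pp = pos.copy(); pp[a, x] += h
            pm = pos.copy(); pm[a, x] -= h
            ep = es.lj_energy_forces(pp, species, mol, self.p, 5.0, 12.0)[0]
            em = es.lj_energy_forces(pm, species, mol, self.p, 5.0, 12.0)[0]
            num = -(ep - em) / (2 * h)
            assert num == pytest.approx(f[a, x], rel=1e-6, abs=1e-7)

    def test_minimum_image_matches_brute_force_images(self):
        # cutoff bookkeeping against an explicit 27-image enumeration
        rng = np.random.default_rng(5)
        L, rc = 8.0, 3.5
        n_mol = 6
        pos = rng.uniform(0, L, (n_mol, 3))
        species = np.array(["O"] * n_mol)
        mol = np.arange(n_mol)
        e_mi, _, _ = es.lj_energy_forces(pos, species, mol, self.p, rc, L)
        e_brute = 0.0
        for i in range(n_mol):
            for j in range(i + 1, n_mol):
                best = np.inf
                for sx in (-1, 0, 1):
                    for sy in (-1, 0, 1):
                        for sz in (-1, 0, 1):
                            d = pos[i] - pos[j] + L * np.array([sx, sy, sz])
                            best = min(best, np.linalg.norm(d))
                if best <= rc:
                    s6 = (self.p.sigma_oo / best) ** 6
                    sc6 = (self.p.sigma_oo / rc) ** 6
                    e_brute += 4 * self.p.eps_oo * (s6 * s6 - s6) \
                        - 4 * self.p.eps_oo * (sc6 * sc6 - sc6)
        assert e_mi == pytest.approx(e_brute, rel=1e-12)

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            es.lj_energy_forces(np.zeros((1, 3)), np.array(["O"]),
                                np.array([0]), self.p, rcut=-1.0)
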