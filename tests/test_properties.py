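"""Bulk-property estimators against closed-form and simulation oracles."""

import math

import numpy as np
import pytest

from gpwater import md, properties
from gpwater.electrostatics import self_interaction_constant
from gpwater.units import COULOMB, KB

KB_SI = 1.380649e-23


class TestRDF:
    def test_ideal_gas_is_flat_within_counting_noise(self):
        rng = np.random.default_rng(0)
        L, n_o, n_frames = 10.0, 40, 60
        frames = rng.uniform(0, L, (n_frames, n_o, 3))
        elements = np.array(["O"] * n_o)
        molecules = np.arange(n_o)[:, None]
        r, g = properties.rdf(frames, elements, molecules, "OO", L,
                              bin_width=0.25)
        # counting statistics per bin: N ~ Poisson(mean), 3 sigma bands
        shell = 4 * np.pi * r ** 2 * 0.25
        npairs = n_o * (n_o - 1) / 2
        mean_counts = npairs * shell / L ** 3 * n_frames
        sel = mean_counts > 30
        z = (g[sel] - 1.0) * np.sqrt(mean_counts[sel])
        assert np.abs(z).max() < 4.0
        assert abs(np.mean(g[sel]) - 1.0) < 0.05

    def test_single_frozen_pair_occupies_one_bin(self):
        d = 2.13
        frames = np.array([[[0.0, 0, 0], [d, 0, 0]]])
        elements = np.array(["O", "O"])
        molecules = np.array([[0], [1]])
        r, g = properties.rdf(frames, elements, molecules, "OO", 10.0,
                              bin_width=0.1)
        occupied = np.flatnonzero(g > 0)
        assert len(occupied) == 1
        assert abs(r[occupied[0]] - d) <= 0.05

    def test_intramolecular_peak_present_by_default(self):
        mol = np.array([[[0.0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]]])
        elements = np.array(["O", "H", "H"])
        molecules = np.array([[0, 1, 2]])
        r, g = properties.rdf(mol, elements, molecules, "OH", 8.0,
                              bin_width=0.05)
        assert g[np.argmin(np.abs(r - 0.96))] > 0
        _, g2 = properties.rdf(mol, elements, molecules, "OH", 8.0,
                               bin_width=0.05, include_intramolecular=False)
        assert np.all(g2 == 0)

    def test_rmax_beyond_half_box_rejected(self):
        with pytest.raises(ValueError, match="half box"):
            properties.rdf(np.zeros((1, 2, 3)), np.array(["O", "O"]),
                           np.array([[0], [1]]), "OO", 10.0, r_max=6.0)


class TestDiffusion:
    def test_seeded_lattice_random_walk_recovers_known_coefficient(self):
        # walkers hop +-a along a random axis each step:
        # MSD(t) = a^2 t/dt -> D = a^2/(6 dt)
        rng = np.random.default_rng(1)
        n_steps, n_walkers, a, dt = 10_000, 60, 1.0, 1.0
        axes = rng.integers(0, 3, (n_steps, n_walkers))
        signs = rng.choice([-1.0, 1.0], (n_steps, n_walkers))
        steps = np.zeros((n_steps, n_walkers, 3))
        idx = np.arange(n_walkers)
        for t in range(n_steps):
            steps[t, idx, axes[t]] = signs[t]
        centers = np.cumsum(steps, axis=0) * a
        res = properties.diffusion_einstein(centers[::10], dt * 10,
                                            fit_start=5, fit_stop=50)
        d_true = a ** 2 / (6 * dt)
        assert res.D == pytest.approx(d_true, rel=0.05)
        assert not res.nonlinear

    def test_ballistic_motion_flagged_nonlinear(self):
        t = np.arange(400, dtype=float)
        v = np.array([[0.3, 0.1, -0.2]])
        centers = t[:, None, None] * v[None]
        res = properties.diffusion_einstein(centers, 1.0, fit_start=10,
                                            fit_stop=150)
        assert res.nonlinear

    def test_static_configuration_has_zero_diffusion(self):
        centers = np.ones((200, 5, 3)) * 2.5
        res = properties.diffusion_einstein(centers, 1.0, fit_start=5,
                                            fit_stop=80)
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_wrapped_coordinates_detected(self):
        centers = np.zeros((10, 1, 3))
        centers[5, 0, 0] = 9.0      # jump larger than L/2
        with pytest.raises(ValueError, match="unwrapped"):
            properties.diffusion_einstein(centers, 1.0, 1, 4, box_length=10.0)


class TestYehHummer:
    def test_infinite_viscosity_leaves_d_unchanged(self):
        assert properties.yeh_hummer_correct(1.5e-9, 2e-9, 298.0, 1e12) \
            == pytest.approx(1.5e-9, rel=1e-10)

    def test_xi_constant_reproduced_by_lattice_summation(self):
        assert self_interaction_constant() == pytest.approx(
            properties.XI_CUBIC, abs=1e-6)

    def test_consistent_with_one_over_L_extrapolation(self):
        # synthetic D(L) = D_true - c/L with the hydrodynamic coefficient:
        # correcting either box size must agree with the 1/L intercept
        T, eta = 298.0, 0.896e-3
        d_true = 1.93e-9
        c = KB_SI * T * properties.XI_CUBIC / (6 * math.pi * eta)
        Ls = np.array([18.64e-10, 23.47e-10, 40.0e-10])
        dL = d_true - c / Ls
        intercept = np.polyfit(1.0 / Ls, dL, 1)[1]
        for L, d in zip(Ls, dL):
            corrected = properties.yeh_hummer_correct(d, L, T, eta)
            assert corrected == pytest.approx(intercept, rel=0.01)

    def test_nonpositive_viscosity_rejected(self):
        with pytest.raises(ValueError):
            properties.yeh_hummer_correct(1e-9, 2e-9, 298.0, 0.0)


class TestTemperatureFits:
    def test_exact_cubic_maximum_recovered(self):
        # cubic constructed to peak at exactly 285.9 K inside the data range
        der = 1e-4 * np.poly([285.9, 350.0])     # derivative with max at 285.9
        coeffs = np.polyint(der)                 # the cubic itself
        T = np.linspace(250.0, 340.0, 10)
        rho = np.polyval(coeffs, T) + 997.0
        res = properties.rho_max(T, rho)
        assert res.T_extremum == pytest.approx(285.9, abs=1e-6)

    def test_monotone_data_yields_no_interior_maximum(self):
        T = np.linspace(250.0, 340.0, 8)
        res = properties.rho_max(T, 0.5 * T + 3.0)
        assert res.T_extremum is None and res.kind == "none"

    def test_symmetric_parabola_peaks_at_centre(self):
        T = np.linspace(270.0, 310.0, 9)
        res = properties.rho_max(T, -(T - 290.0) ** 2)
        assert res.T_extremum == pytest.approx(290.0, abs=1e-9)

    def test_too_few_temperatures_rejected(self):
        with pytest.raises(ValueError):
            properties.rho_max([1, 2, 3], [1, 2, 3])


class TestThermalExpansion:
    def test_constant_volume_gives_zero(self):
        T = np.linspace(250, 340, 8)
        alpha, _ = properties.thermal_expansion(T, np.full_like(T, 30.0))
        assert np.abs(alpha).max() < 1e-14

    def test_linear_volume_gives_exact_closed_form(self):
        T = np.linspace(250, 340, 8)
        a, v0 = 2.5e-4, 18.0
        V = v0 * (1 + a * T)
        alpha, _ = properties.thermal_expansion(T, V)
        assert np.allclose(alpha, a / (1 + a * T), rtol=1e-10)

    def test_decreasing_volume_gives_negative_alpha(self):
        T = np.linspace(250, 340, 8)
        alpha, _ = properties.thermal_expansion(T, 30.0 - 0.01 * T)
        assert np.all(alpha < 0)


class TestEnthalpy:
    def test_equal_phases_vaporise_for_free(self):
        T = np.array([280.0, 300.0])
        H = np.array([-40.0, -39.0])
        assert np.all(properties.enthalpy_vaporization(T, H, T, H) == 0.0)

    def test_known_difference_exact(self):
        T = np.array([298.0])
        dh = properties.enthalpy_vaporization(T, [2.0], T, [-42.0])
        assert dh[0] == 44.0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            properties.enthalpy_vaporization([280.0], [1.0], [300.0], [2.0])

    def test_gas_enthalpy_stationary_over_monomer_run(self, water_models):
        # reduced-length analog of averaging monomer-run enthalpies: block
        # means of a single NVT monomer trajectory agree within 2 sigma
        state = md.gas_monomer_state(temperature=298.0, seed=2)
        sim = md.Simulation(state, water_models,
                            md.IntegratorConfig(ensemble="nvt",
                                                temperature=298.0),
                            lj_enabled=False)
        for _ in range(500):
            sim.nvt_step()
        e = []
        for _ in range(3000):
            sim.nvt_step()
            f = sim._ensure_cached()
            e.append(f.e_pot + sim.state.kinetic_energy())
        e = np.array(e)
        blocks = e.reshape(6, -1).mean(axis=1)
        sem = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(blocks[:3].mean() - blocks[3:].mean()) < 4 * sem * np.sqrt(2)


class TestHeatCapacity:
    def test_exact_quadratic_differentiated_exactly(self):
        T = np.linspace(260, 340, 9)
        a, b, c = 0.02, -3.0, 500.0
        H = a * T ** 2 + b * T + c
        cp, _ = properties.heat_capacity(T, H)
        assert np.allclose(cp, 2 * a * T + b, rtol=1e-10)

    def test_linear_enthalpy_gives_constant_cp(self):
        T = np.linspace(260, 340, 9)
        cp, _ = properties.heat_capacity(T, 75.0 * T + 3.0)
        assert np.allclose(cp, 75.0, rtol=1e-10)

    def test_noisy_quadratic_recovered_within_standard_errors(self):
        rng = np.random.default_rng(7)
        T = np.linspace(250, 350, 21)
        a, b = 0.05, -10.0
        sigma = 0.5
        H = a * T ** 2 + b * T + rng.normal(0, sigma, T.size)
        _, coeffs = properties.heat_capacity(T, H)
        # standard errors from the normal equations of the quadratic fit
        A = np.vander(T, 3)
        cov = sigma ** 2 * np.linalg.inv(A.T @ A)
        assert abs(coeffs[0] - a) < 3 * math.sqrt(cov[0, 0])
        assert abs(coeffs[1] - b) < 3 * math.sqrt(cov[1, 1])

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            properties.heat_capacity([300.0, 300.0, 300.0], [1.0, 2.0, 3.0])


class TestIRSpectrum:
    def test_constant_dipole_has_no_finite_frequency_intensity(self):
        M = np.ones((2048, 3)) * 0.7
        w, i = properties.ir_spectrum(M, 1.0)
        assert np.abs(i[1:]).max() == pytest.approx(0.0, abs=1e-10)

    def test_cosine_dipole_peaks_in_the_right_bin(self):
        # 100 THz = 100/ps -> ~3336 cm^-1
        dt_fs, n = 1.0, 4096
        t = np.arange(n) * dt_fs * 1e-3
        M = np.zeros((n, 3))
        M[:, 0] = np.cos(2 * np.pi * 100.0 * t)
        w, i = properties.ir_spectrum(M, dt_fs)
        peak_wn = w[np.argmax(i)]
        expected = 100.0 / properties.C_CM_PER_PS
        assert expected == pytest.approx(3335.6, abs=1.0)
        bin_width = w[1] - w[0]
        assert abs(peak_wn - expected) <= bin_width

    def test_two_frequencies_keep_intensity_ordering(self):
        dt_fs, n = 1.0, 4096
        t = np.arange(n) * dt_fs * 1e-3
        M = np.zeros((n, 3))
        M[:, 0] = 1.0 * np.cos(2 * np.pi * 30.0 * t) \
            + 0.4 * np.cos(2 * np.pi * 80.0 * t)
        w, i = properties.ir_spectrum(M, dt_fs, correction="none")
        w1 = i[np.argmin(np.abs(w - 30.0 / properties.C_CM_PER_PS))]
        w2 = i[np.argmin(np.abs(w - 80.0 / properties.C_CM_PER_PS))]
        assert w1 > w2 > 0.05

    def test_normalised_to_unit_maximum(self):
        rng = np.random.default_rng(0)
        w, i = properties.ir_spectrum(rng.normal(0, 1, (1024, 3)), 1.0)
        assert i.max() == pytest.approx(1.0)

    def test_quantum_correction_options(self):
        omega = np.linspace(0, 500, 64)
        for kind in ("none", "harmonic", "standard", "schofield"):
            f = properties.quantum_correction(kind, omega, 298.0)
            assert np.all(np.isfinite(f)) and f[0] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            properties.quantum_correction("bogus", omega, 298.0)

    def test_bad_input_shapes_rejected(self):
        with pytest.raises(ValueError):
            properties.ir_spectrum(np.zeros((10, 2)), 1.0)


class TestPermittivity:
    def test_constant_dipole_gives_unity(self):
        res = properties.relative_permittivity(np.ones((500, 3)), 1000.0, 298.0)
        assert res.eps_r == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_fluctuations_match_closed_form(self):
        rng = np.random.default_rng(11)
        sigma, V, T = 0.8, 8000.0, 298.0
        n = 200_000
        M = rng.normal(0, sigma, (n, 3))
        res = properties.relative_permittivity(M, V, T)
        expected = 1.0 + 4 * math.pi * COULOMB * 3 * sigma ** 2 / (3 * V * KB * T)
        # Monte-Carlo error of the variance estimate: rel ~ sqrt(2/(3n))
        tol = 4 * math.sqrt(2.0 / (3 * n)) * (expected - 1.0)
        assert abs(res.eps_r - expected) < tol

    def test_dipole_scaling_scales_the_fluctuation_quadratically(self):
        rng = np.random.default_rng(3)
        M = rng.normal(0, 0.5, (5000, 3))
        base = properties.relative_permittivity(M, 5000.0, 298.0)
        scaled = properties.relative_permittivity(1.9 * M, 5000.0, 298.0)
        assert scaled.eps_r - 1.0 == pytest.approx(
            1.9 ** 2 * (base.eps_r - 1.0), rel=1e-10)

    def test_short_series_warns_in_metadata(self):
        res = properties.relative_permittivity(np.ones((10, 3)), 100.0, 298.0)
        assert res.warning is not None


class TestUncertainties:
    def test_identical_trajectories_have_zero_uncertainty(self):
        assert properties.loo_uncertainty([3.3, 3.3, 3.3, 3.3]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_estimates_hand_case(self):
        # estimates {1, 3}: leave-one-out means {3, 1}, total mean 2 -> RMS 1
        assert properties.loo_uncertainty([1.0, 3.0]) == pytest.approx(1.0)

    def test_three_estimates_hand_case(self):
        # {0,0,6}: loo means {3,3,0}, total 2 -> RMS sqrt((1+1+4)/3)
        assert properties.loo_uncertainty([0.0, 0.0, 6.0]) == pytest.approx(
            math.sqrt(2.0))

    def test_single_trajectory_rejected(self):
        with pytest.raises(ValueError):
            properties.loo_uncertainty([1.0])

    def test_ensemble_spread_hand_case(self):
        # per-box values {1, 2, 3} about mean 2 -> RMS deviation sqrt(2/3)
        assert properties.ensemble_spread(2.0, [1.0, 2.0, 3.0]) == \
            pytest.approx(math.sqrt(2.0 / 3.0))
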