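"""Target construction, system assembly and the regularized LS solve,
cross-checked against an independent iterative minimizer."""

import numpy as np
import pytest

from mwfocus import (
    DesiredField,
    SystemMatrix,
    assemble_system,
    choose_alpha,
    gaussian_target,
    solve_rls,
    spherical_array,
    steer,
)
from mwfocus.dipole_fields import MagneticDipole, superpose


def cube_grid(half, spacing):
    n = int(round(half / spacing))
    ax = spacing * np.arange(-n, n + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def ball_grid(radius, spacing):
    pts = cube_grid(radius, spacing)
    return pts[np.linalg.norm(pts, axis=1) <= radius]


class TestGaussianTarget:
    def test_peak_at_center(self):
        grid = cube_grid(0.03, 0.005)
        t = gaussian_target(grid, [0, 0, 0], 0.01, 0.01, [0, 0, 1])
        amp = np.linalg.norm(t.E_d.reshape(-1, 3), axis=1)
        assert amp.max() == pytest.approx(0.01)
        assert amp[np.argmax(amp)] == amp[np.all(grid == 0, axis=1)][0]

    def test_value_at_one_sigma(self):
        grid = np.array([[0.0, 0.0, 0.0], [0.01, 0.0, 0.0]])
        t = gaussian_target(grid, [0, 0, 0], 0.01, 0.01, [0, 0, 1])
        amp = np.linalg.norm(t.E_d.reshape(-1, 3), axis=1)
        assert amp[1] == pytest.approx(0.01 * np.exp(-0.5))

    def test_no_transverse_components(self):
        grid = cube_grid(0.02, 0.01)
        t = gaussian_target(grid, [0, 0, 0], 0.01, 0.01, [0, 0, 1])
        E = t.E_d.reshape(-1, 3)
        assert np.all(E[:, 0] == 0) and np.all(E[:, 1] == 0)

    def test_profile_fwhm_identity(self):
        """FWHM of the amplitude profile is 2 sqrt(2 ln 2) sigma ≈ 2.355 cm
        for sigma = 1 cm."""
        x = np.linspace(-0.05, 0.05, 10001)
        amp = 0.01 * np.exp(-(x**2) / (2 * 0.01**2))
        above = x[amp >= amp.max() / 2]
        assert above[-1] - above[0] == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 0.01, abs=2e-5)

    def test_center_outside_grid_warns(self):
        grid = cube_grid(0.02, 0.01)
        with pytest.warns(UserWarning, match="outside"):
            gaussian_target(grid, [0.2, 0, 0], 0.01, 0.01, [0, 0, 1])

    def test_non_unit_polarization_rejected(self):
        with pytest.raises(ValueError):
            gaussian_target(cube_grid(0.02, 0.01), [0, 0, 0], 0.01, 0.01, [0, 0, 2])


class TestAssembleSystem:
    def test_shape_3nd_by_3nt(self, brain_medium):
        layout = spherical_array(0.06, 4)
        grid = cube_grid(0.01, 0.01)
        system = assemble_system(brain_medium, layout, grid)
        assert system.G_E.shape == (3 * grid.shape[0], 12)

    def test_columns_are_unit_moment_fields(self, brain_medium):
        from mwfocus.dipole_fields import dipole_E

        layout = spherical_array(0.06, 4)
        grid = cube_grid(0.01, 0.01)
        system = assemble_system(brain_medium, layout, grid)
        n, j = 2, 1
        m = np.zeros(3, complex)
        m[j] = 1.0
        col = dipole_E(MagneticDipole(layout.positions[n], m), grid, brain_medium).reshape(-1)
        np.testing.assert_allclose(system.G_E[:, 3 * n + j], col, rtol=1e-12)

    def test_matrix_action_equals_superposition(self, brain_medium, rng):
        layout = spherical_array(0.06, 4)
        grid = cube_grid(0.01, 0.01)
        system = assemble_system(brain_medium, layout, grid)
        m = rng.normal(size=12) + 1j * rng.normal(size=12)
        dipoles = [MagneticDipole(p, mm) for p, mm in zip(layout.positions, m.reshape(4, 3))]
        direct = superpose(dipoles, grid, brain_medium).E.reshape(-1)
        np.testing.assert_allclose(system.G_E @ m, direct, rtol=1e-10)

    def test_numeric_mode_matches_analytic_on_zero_contrast(self, air_medium):
        """System matrices from the analytic path and from a zero-contrast
        Green's table agree (cross-mode equivalence)."""
        from mwfocus import VoxelPhantom, build_greens_table

        ph = VoxelPhantom(
            np.zeros(3), 0.005, (8, 8, 8),
            np.ones((8, 8, 8)), np.zeros((8, 8, 8)), air_medium,
        )
        layout = spherical_array(0.05, 2)
        table = build_greens_table(ph, layout, 1e9, tol=1e-8)
        pts = ph.voxel_centers()
        sub = pts[::37]
        sys_num = assemble_system(table, layout, sub)
        sys_ana = assemble_system(air_medium, layout, sub)
        scale = np.max(np.abs(sys_ana.G_E))
        assert np.max(np.abs(sys_num.G_E - sys_ana.G_E)) / scale < 1e-8


def random_system(rng, nd=4, nt=2):
    G = rng.normal(size=(3 * nd, 3 * nt)) + 1j * rng.normal(size=(3 * nd, 3 * nt))
    grid = rng.normal(size=(nd, 3))
    layout = spherical_array(0.06, nt)
    system = SystemMatrix(G_E=G, grid=grid, layout=layout, frequency=1e9)
    E_d = rng.normal(size=3 * nd) + 1j * rng.normal(size=3 * nd)
    target = DesiredField(grid=grid, E_d=E_d, description={"profile": "raw"})
    return system, target


def iterative_minimizer(G, E_d, alpha, tol=1e-10, max_iter=200000):
    """Independent oracle: projected gradient descent on
    ΔE = ||GM − E_d||² + α||M||² (Wirtinger gradient Gᴴ(GM−E_d) + αM)."""
    L = np.linalg.norm(G, 2) ** 2 + alpha
    M = np.zeros(G.shape[1], complex)
    for _ in range(max_iter):
        g = G.conj().T @ (G @ M - E_d) + alpha * M
        M_new = M - g / L
        if np.linalg.norm(M_new - M) <= tol * max(np.linalg.norm(M), 1e-30):
            return M_new
        M = M_new
    return M


class TestSolveRLS:
    def test_matches_iterative_minimizer(self, rng):
        """Closed-form normal-equation solution equals an independent
        gradient-descent minimizer of the objective to 1e-8 relative on
        random 12x6 complex systems."""
        for _ in range(3):
            system, target = random_system(rng, nd=4, nt=2)  # 12 x 6
            alpha = 0.1 * np.linalg.norm(system.G_E, 2) ** 2
            sol = solve_rls(system, target, alpha)
            M_it = iterative_minimizer(system.G_E, target.E_d, alpha)
            assert np.linalg.norm(sol.M_opt - M_it) / np.linalg.norm(M_it) < 1e-8

    def test_square_well_conditioned_interpolates(self, rng):
        system, target = random_system(rng, nd=2, nt=2)  # 6 x 6 square
        sol = solve_rls(system, target, 0.0)
        np.testing.assert_allclose(sol.E_mod, target.E_d, rtol=1e-8)

    def test_huge_alpha_kills_solution(self, rng):
        system, target = random_system(rng)
        alpha = 1e6 * np.linalg.norm(system.G_E, 2) ** 2
        sol = solve_rls(system, target, alpha)
        assert np.linalg.norm(sol.M_opt) < 1e-5 * np.linalg.norm(target.E_d)
        assert np.linalg.norm(sol.E_mod) < 1e-4 * np.linalg.norm(target.E_d)

    def test_normal_equation_residual_tiny(self, rng):
        system, target = random_system(rng, nd=6, nt=3)
        alpha = 1e-3 * np.linalg.norm(system.G_E, 2) ** 2
        sol = solve_rls(system, target, alpha)
        G = system.G_E
        lhs = (G.conj().T @ G + alpha * np.eye(G.shape[1])) @ sol.M_opt
        rhs = G.conj().T @ target.E_d
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-10

    def test_alpha_monotonicity(self, rng):
        """Misfit non-decreasing and ||M|| non-increasing in alpha."""
        system, target = random_system(rng, nd=6, nt=3)
        s2 = np.linalg.norm(system.G_E, 2) ** 2
        misfits, norms = [], []
        for alpha in s2 * np.logspace(-6, 1, 12):
            sol = solve_rls(system, target, alpha)
            misfits.append(sol.misfit)
            norms.append(sol.moment_norm)
        assert np.all(np.diff(misfits) >= -1e-12 * misfits[-1])
        assert np.all(np.diff(norms) <= 1e-12 * norms[0])

    def test_scale_equivariance(self, rng):
        """Scaling E_d by c scales M_opt by c exactly (linearity: antenna
        amplitudes scale proportionately with the desired peak)."""
        system, target = random_system(rng)
        alpha = 0.01 * np.linalg.norm(system.G_E, 2) ** 2
        sol1 = solve_rls(system, target, alpha)
        target2 = DesiredField(grid=target.grid, E_d=3.5 * target.E_d, description={})
        sol2 = solve_rls(system, target2, alpha)
        np.testing.assert_allclose(sol2.M_opt, 3.5 * sol1.M_opt, rtol=1e-10)

    def test_rank_deficient_alpha_zero_rejected(self, rng):
        system, target = random_system(rng, nd=4, nt=2)
        system.G_E[:, 3] = system.G_E[:, 2]  # duplicate column
        with pytest.raises(np.linalg.LinAlgError, match="regulariz"):
            solve_rls(system, target, 0.0)

    def test_negative_alpha_rejected(self, rng):
        system, target = random_system(rng)
        with pytest.raises(ValueError):
            solve_rls(system, target, -1.0)


class TestSteer:
    @pytest.fixture(scope="class")
    def focus_setup(self, brain_medium):
        layout = spherical_array(0.06, 64)
        grid = ball_grid(0.045, 0.0075)
        system = assemble_system(brain_medium, layout, grid)
        template = gaussian_target(grid, [0, 0, 0], 0.01, 0.01, [0, 0, 1])
        alpha = choose_alpha(system, tau=1e-3)
        return system, template, alpha

    def test_identity_steer_reproduces_solution(self, focus_setup):
        system, template, alpha = focus_setup
        sol0 = solve_rls(system, template, alpha)
        sol1 = steer(system, template, [0, 0, 0], alpha)
        np.testing.assert_array_equal(sol0.M_opt, sol1.M_opt)

    def test_mirrored_targets_have_matching_peaks(self, focus_setup):
        """±d targets along the diagonal of a symmetric problem realize
        peak magnitudes within 5%."""
        system, template, alpha = focus_setup
        peaks = []
        for s in (+1, -1):
            sol = steer(system, template, [s * 0.01] * 3, alpha)
            peaks.append(np.max(np.abs(sol.E_mod)))
        assert abs(peaks[0] - peaks[1]) / peaks[1] < 0.05

    def test_three_target_sweep_peaks_at_own_targets(self, focus_setup):
        system, template, alpha = focus_setup
        for c in ([-0.01] * 3, [0.0] * 3, [0.01] * 3):
            sol = steer(system, template, c, alpha)
            amp = np.linalg.norm(sol.E_mod.reshape(-1, 3), axis=1)
            peak_pt = system.grid[np.argmax(amp)]
            assert np.linalg.norm(peak_pt - np.asarray(c)) < 0.012

    def test_center_outside_region_rejected(self, focus_setup):
        system, template, alpha = focus_setup
        with pytest.raises(ValueError, match="outside"):
            steer(system, template, [0.2, 0, 0], alpha)


class TestChooseAlpha:
    def test_fixed_relative_scale_equivariance(self, rng):
        system, target = random_system(rng)
        a1 = choose_alpha(system, target, "fixed-relative", tau=1e-3)
        system2 = SystemMatrix(
            G_E=3.0 * system.G_E, grid=system.grid, layout=system.layout, frequency=1e9
        )
        a2 = choose_alpha(system2, target, "fixed-relative", tau=1e-3)
        assert a2 == pytest.approx(9.0 * a1, rel=1e-9)

    def test_tau_zero_passthrough(self, rng):
        system, target = random_system(rng)
        assert choose_alpha(system, target, "fixed-relative", tau=0.0) == 0.0

    def test_lcurve_lands_in_tradeoff_plateau(self, rng):
        """On a synthetic ill-posed system (geometric singular-value decay
        over 4 decades plus noise), the l-curve corner falls strictly
        between the extreme singular values squared."""
        n = 24
        U, _ = np.linalg.qr(rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n)))
        V, _ = np.linalg.qr(rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n)))
        s = np.logspace(0, -4, n)
        G = U @ np.diag(s) @ V.conj().T
        x_true = rng.normal(size=n) + 1j * rng.normal(size=n)
        b = G @ x_true + 1e-3 * (rng.normal(size=n) + 1j * rng.normal(size=n))
        layout = spherical_array(0.06, n // 3)
        system = SystemMatrix(G_E=G, grid=rng.normal(size=(n // 3, 3)), layout=layout, frequency=1e9)
        target = DesiredField(grid=system.grid, E_d=b, description={})
        alpha = choose_alpha(system, target, "l-curve")
        assert s[-1] ** 2 < alpha < s[0] ** 2
        # and it actually trades off: moment norm well below the alpha->0 norm
        sol_small = solve_rls(system, target, s[-1] ** 2 * 1e-2)
        sol_corner = solve_rls(system, target, alpha)
        assert sol_corner.moment_norm < 0.5 * sol_small.moment_norm
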