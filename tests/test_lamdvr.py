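"""Sinc-DVR eigensolver and thermal averaging along the inversion motion."""

import numpy as np
import pytest
from scipy.linalg import eig_banded

from nitroxkit import hcc, lamdvr, synthdata
from nitroxkit.constants import HBAR2_OVER_2_CM1_AMU_A2, KB_CM1_PER_K
from nitroxkit.errors import InputError
from nitroxkit.lamdvr import DVRGridSpec
from nitroxkit.pes import QuarticDoubleWell

INERTIA = 26.2  # amu*A^2, oxygen mass on an NO-length arm


def harmonic_potential(omega, inertia):
    """V(theta_deg) = k theta^2 / 2 with k set so the analytic spacing is omega."""
    f = HBAR2_OVER_2_CM1_AMU_A2 / inertia
    k = omega**2 / (2.0 * f)
    return lambda deg: 0.5 * k * np.radians(deg) ** 2


def fd_oracle(vfun, inertia, npoints, lo, hi, nlevels=10):
    """Fourth-order finite-difference diagonalization on a dense uniform grid:
    an independent route to the same Hamiltonian."""
    grid = np.linspace(lo, hi, npoints)
    dx = np.radians(grid[1] - grid[0])
    f = HBAR2_OVER_2_CM1_AMU_A2 / inertia
    v = np.asarray(vfun(grid), dtype=float)
    bands = np.zeros((3, npoints))
    bands[0] = v + f * 2.5 / dx**2
    bands[1] = -f * (4.0 / 3.0) / dx**2
    bands[2] = f * (1.0 / 12.0) / dx**2
    return eig_banded(bands, lower=True, eigvals_only=True,
                      select="i", select_range=(0, nlevels - 1))


class TestSolve:
    def test_harmonic_ladder(self):
        sol = lamdvr.solve(harmonic_potential(500.0, INERTIA), INERTIA,
                           DVRGridSpec(npoints=257, range=(-40.0, 40.0)))
        spacings = np.diff(sol.eigenvalues[:6])
        np.testing.assert_allclose(spacings, 500.0, atol=0.01)
        assert sol.eigenvalues[0] == pytest.approx(250.0, abs=0.01)

    def test_quartic_against_finite_difference_oracle(self):
        well = QuarticDoubleWell(B=334.0, theta_eq=25.7)
        sol = lamdvr.solve(well, INERTIA,
                           DVRGridSpec(npoints=257, range=(-65.0, 65.0)))
        oracle = fd_oracle(well.evaluate, INERTIA, 4001, -65.0, 65.0)
        assert np.max(np.abs(sol.eigenvalues[:10] - oracle)) < 0.05

    def test_deep_well_doublet_degeneracy(self):
        shallow = QuarticDoubleWell(B=334.0, theta_eq=25.7)
        deep = QuarticDoubleWell(B=334.0 * 100.0, theta_eq=25.7)
        spec = DVRGridSpec(npoints=385, range=(-50.0, 50.0))
        sol = lamdvr.solve(deep, INERTIA, spec)
        splitting = sol.eigenvalues[1] - sol.eigenvalues[0]
        spacing = sol.eigenvalues[2] - sol.eigenvalues[0]
        assert splitting < 1e-3 * spacing

    def test_tunneling_splitting_decreases_with_barrier_and_inertia(self):
        spec = DVRGridSpec(npoints=257, range=(-60.0, 60.0))

        def splitting(B, inertia):
            sol = lamdvr.solve(QuarticDoubleWell(B=B, theta_eq=25.7), inertia, spec)
            return sol.eigenvalues[1] - sol.eigenvalues[0]

        s_barriers = [splitting(B, INERTIA) for B in (200.0, 334.0, 600.0)]
        assert s_barriers[0] > s_barriers[1] > s_barriers[2] > 0
        s_inertias = [splitting(334.0, i) for i in (10.0, 26.2, 60.0)]
        assert s_inertias[0] > s_inertias[1] > s_inertias[2] > 0

    def test_variational_stability_under_refinement(self):
        """Eigenvalues settle as the grid is refined (non-increasing within
        numerical slack in the converged regime)."""
        well = QuarticDoubleWell(B=334.0, theta_eq=25.7)
        prev = None
        for npts in (129, 257, 513):
            sol = lamdvr.solve(well, INERTIA,
                               DVRGridSpec(npoints=npts, range=(-65.0, 65.0)))
            if prev is not None:
                assert np.all(sol.eigenvalues[:10] <= prev + 1e-6)
            prev = sol.eigenvalues[:10]

    def test_auto_extend_converges(self):
        well = QuarticDoubleWell(B=334.0, theta_eq=25.7)
        spec = DVRGridSpec(npoints=65, range=(-65.0, 65.0), auto_extend=True)
        sol = lamdvr.solve(well, INERTIA, spec)
        oracle = fd_oracle(well.evaluate, INERTIA, 4001, -65.0, 65.0)
        assert np.max(np.abs(sol.eigenvalues[:10] - oracle)) < 0.05

    def test_eigenvectors_orthonormal(self):
        sol = lamdvr.solve(QuarticDoubleWell(B=334.0, theta_eq=25.7), INERTIA,
                           DVRGridSpec(npoints=129, range=(-60.0, 60.0)))
        gram = sol.eigenvectors.T @ sol.eigenvectors
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_scan_input_clips_grid_to_scan_range(self):
        scan = synthdata.gen_scan(334.0, 25.7, npts=41)
        sol = lamdvr.solve(scan, INERTIA, DVRGridSpec(npoints=129, range=(-90, 90)))
        assert sol.grid[0] >= scan.coord[0] - 1e-9
        assert sol.grid[-1] <= scan.coord[-1] + 1e-9

    def test_bad_inputs(self):
        well = QuarticDoubleWell(B=334.0, theta_eq=25.7)
        with pytest.raises(InputError):
            lamdvr.solve(well, -1.0)
        with pytest.raises(InputError):
            DVRGridSpec(npoints=8)
        with pytest.raises(InputError):
            DVRGridSpec(npoints=64, range=(10.0, -10.0))


@pytest.fixture(scope="module")
def quartic_solution():
    well = QuarticDoubleWell(B=334.0, theta_eq=25.7)
    sol = lamdvr.solve(well, INERTIA, DVRGridSpec(npoints=257, range=(-65.0, 65.0)))
    return well, sol


class TestPopulations:
    def test_ground_state_only_at_low_temperature(self, quartic_solution):
        _, sol = quartic_solution
        ens = lamdvr.populations(sol, T=1.0)
        # the tunneling doublet is quasi-degenerate, so compare to the
        # doublet-resolved Boltzmann weight rather than assuming p0 = 1
        gap = sol.eigenvalues[1] - sol.eigenvalues[0]
        expected = 1.0 / (1.0 + np.exp(-gap / KB_CM1_PER_K))
        assert ens.populations[0] == pytest.approx(expected, abs=1e-6)
        assert ens.populations[2:].max() < 1e-12

    def test_two_level_ratio_at_kt_splitting(self):
        # levels split by exactly kB*T populate in the ratio e^-1
        omega = KB_CM1_PER_K * 300.0
        sol = lamdvr.solve(harmonic_potential(omega, INERTIA), INERTIA,
                           DVRGridSpec(npoints=257, range=(-60.0, 60.0)))
        ens = lamdvr.populations(sol, T=300.0)
        assert ens.populations[1] / ens.populations[0] == pytest.approx(
            np.exp(-1.0), rel=1e-6)

    def test_harmonic_retained_count_matches_geometric_series(self):
        """Closed-form oracle: for a 500 cm^-1 ladder at 300 K the level
        populations are (1-q) q^n with q = exp(-500/kT); count those >= 0.5%."""
        omega = 500.0
        q = np.exp(-omega / (KB_CM1_PER_K * 300.0))
        expected = [n for n in range(50) if (1 - q) * q**n >= 0.005]
        sol = lamdvr.solve(harmonic_potential(omega, INERTIA), INERTIA,
                           DVRGridSpec(npoints=257, range=(-60.0, 60.0)))
        ens = lamdvr.populations(sol, T=300.0)
        assert list(ens.retained) == expected

    def test_populations_sum_to_one(self, quartic_solution):
        _, sol = quartic_solution
        ens = lamdvr.populations(sol, T=300.0)
        assert ens.populations.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(ens.populations >= 0)

    def test_nonpositive_temperature_rejected(self, quartic_solution):
        _, sol = quartic_solution
        with pytest.raises(InputError):
            lamdvr.populations(sol, T=0.0)


class TestThermalAverage:
    def test_constant_property_is_exact(self, quartic_solution):
        _, sol = quartic_solution
        ens = lamdvr.populations(sol, T=300.0)
        assert lamdvr.thermal_average(sol, ens, lambda th: 0 * th + 3.7) == (
            pytest.approx(3.7, abs=1e-10))

    def test_linear_property_in_offset_harmonic_well(self):
        theta0 = 10.0
        f = HBAR2_OVER_2_CM1_AMU_A2 / INERTIA
        k = 500.0**2 / (2.0 * f)
        vfun = lambda deg: 0.5 * k * np.radians(deg - theta0) ** 2
        sol = lamdvr.solve(vfun, INERTIA, DVRGridSpec(npoints=257, range=(-50, 70)))
        ens = lamdvr.populations(sol, T=300.0)
        assert lamdvr.thermal_average(sol, ens, lambda th: th) == pytest.approx(
            theta0, abs=1e-6)

    def test_bounded_by_property_range_and_linear(self, quartic_solution):
        _, sol = quartic_solution
        ens = lamdvr.populations(sol, T=300.0)
        p1 = lamdvr.thermal_average(sol, ens, np.abs)
        p2 = lamdvr.thermal_average(sol, ens, lambda th: np.cos(np.radians(th)))
        combo = lamdvr.thermal_average(
            sol, ens, lambda th: 2.0 * np.abs(th) - 0.5 * np.cos(np.radians(th)))
        assert combo == pytest.approx(2.0 * p1 - 0.5 * p2, abs=1e-9)
        assert 0.0 <= p1 <= np.abs(sol.grid).max()

    def test_zero_point_delocalization_pulls_theta_inward(self, quartic_solution):
        """At T -> 0 the averaged |theta| sits below theta_eq: the ground state
        leaks toward the barrier.  Cross-checked against explicit quadrature
        with the dense-grid FD ground state."""
        well, sol = quartic_solution
        ens = lamdvr.populations(sol, T=1.0)
        avg = lamdvr.thermal_average(sol, ens, np.abs)
        assert avg < well.theta_eq
        # independent quadrature oracle on the ground doublet
        psi0 = sol.eigenvectors[:, 0]
        psi1 = sol.eigenvectors[:, 1]
        w0 = ens.populations[0]
        w1 = ens.populations[1]
        oracle = (w0 * np.sum(psi0**2 * np.abs(sol.grid))
                  + w1 * np.sum(psi1**2 * np.abs(sol.grid)))
        assert avg == pytest.approx(oracle, abs=1e-10)


class TestVibrationalCorrection:
    def test_constant_property_gives_zero(self, quartic_solution):
        well, sol = quartic_solution
        ens = lamdvr.populations(sol, T=300.0)
        corr = lamdvr.vibrational_correction(
            sol, ens, lambda th: np.full_like(np.asarray(th, dtype=float), 5.0),
            well.theta_eq)
        assert corr == pytest.approx(0.0, abs=1e-10)

    def test_matches_dense_grid_quadrature(self, quartic_solution):
        well, sol = quartic_solution
        ens = lamdvr.populations(sol, T=300.0)
        prop = lambda th: hcc.an_of_theta(hcc.B2_MODEL, th)
        corr = lamdvr.vibrational_correction(sol, ens, prop, well.theta_eq)
        pk = prop(sol.grid)
        oracle = float(ens.populations @ ((sol.eigenvectors**2).T @ pk)) - prop(
            well.theta_eq)
        assert corr == pytest.approx(oracle, abs=1e-12)

    def test_magnitude_order_for_template_molecule_setup(self, quartic_solution):
        """With the double well matched to the template molecule's barrier and
        a physically plausible inertia, the aN averaging correction at 300 K
        is of order 1 MHz."""
        well, sol = quartic_solution
        ens = lamdvr.populations(sol, T=300.0)
        corr = lamdvr.vibrational_correction(
            sol, ens, lambda th: hcc.an_of_theta(hcc.B2_MODEL, th), well.theta_eq)
        assert 0.5 <= abs(corr) <= 5.0
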