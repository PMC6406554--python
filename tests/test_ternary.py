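"""Thermodynamics: free energy, stability criterion, spinodal/binodal,
crowding sweep."""

import numpy as np
import pytest

from llpskit.ternary import (
    TernaryModel, binary_critical_point, binodal_at_crowder, crowding_sweep,
    depletion_layer_ratio, free_energy_density, mu_derivative,
    spinodal_at_crowder,
)


class TestFreeEnergy:
    def test_ideal_ternary_entropy(self):
        m = TernaryModel()
        f = free_energy_density(m, 1 / 3, 1 / 3)
        assert f == pytest.approx(-np.log(3.0), rel=1e-12)

    def test_binary_limit(self):
        m = TernaryModel(chi_ps=1.5)
        phi = 0.3
        f = free_energy_density(m, phi, 0.0)
        expected = phi * np.log(phi) + (1 - phi) * np.log(1 - phi) \
            + 1.5 * phi * (1 - phi)
        assert f == pytest.approx(expected, rel=1e-12)

    def test_protein_crowder_swap_symmetry(self):
        m = TernaryModel(n_protein=3, n_crowder=7, chi_ps=0.8, chi_cs=0.3,
                         chi_pc=0.5)
        m_swapped = TernaryModel(n_protein=7, n_crowder=3, chi_ps=0.3,
                                 chi_cs=0.8, chi_pc=0.5)
        assert free_energy_density(m, 0.2, 0.35) == pytest.approx(
            free_energy_density(m_swapped, 0.35, 0.2), rel=1e-12)

    def test_boundary_composition_rejected(self):
        with pytest.raises(ValueError):
            free_energy_density(TernaryModel(), 0.0, 0.2)
        with pytest.raises(ValueError):
            free_energy_density(TernaryModel(), 0.6, 0.4)


class TestMuDerivative:
    def test_ideal_mixture_value_and_stability(self):
        m = TernaryModel()
        phi_p, phi_c = 0.25, 0.15
        val = mu_derivative(m, phi_p, phi_c)
        assert val == pytest.approx(1 / phi_p + 1 / (1 - phi_p - phi_c),
                                    rel=1e-12)
        assert val > 0

    def test_matches_central_difference_oracle_on_grid(self):
        """Analytic curvature equals central differences of the free energy
        to <= 1e-6 relative, across parameter sets on a 20x20 interior
        grid."""
        models = [
            TernaryModel(),
            TernaryModel(n_protein=10, chi_ps=1.2, chi_cs=0.2, chi_pc=0.6),
            TernaryModel(n_protein=5, n_crowder=20, chi_ps=2.0, chi_dep=4.0),
        ]
        def central(m, phi_p, phi_c, h):
            return (free_energy_density(m, phi_p + h, phi_c)
                    - 2 * free_energy_density(m, phi_p, phi_c)
                    + free_energy_density(m, phi_p - h, phi_c)) / h ** 2

        h = 1e-4
        pp = np.linspace(0.05, 0.45, 20)
        cc = np.linspace(0.0, 0.35, 20)
        for m in models:
            for phi_c in cc:
                for phi_p in pp:
                    # Richardson-extrapolated central difference, O(h^4)
                    fd = (4 * central(m, phi_p, phi_c, h)
                          - central(m, phi_p, phi_c, 2 * h)) / 3
                    assert mu_derivative(m, phi_p, phi_c) == pytest.approx(
                        fd, rel=1e-6, abs=1e-6)

    def test_binary_critical_point_closed_form(self):
        for n in (1, 10, 100):
            chi_c, phi_crit = binary_critical_point(n)
            m = TernaryModel(n_protein=n, chi_ps=chi_c)
            # at the critical point the curvature vanishes at phi_crit
            assert mu_derivative(m, phi_crit, 0.0) == pytest.approx(
                0.0, abs=1e-9)
            # and is nonnegative everywhere (marginal stability)
            grid = np.linspace(1e-4, 1 - 1e-4, 2000)
            assert np.min(mu_derivative(m, grid, np.zeros_like(grid))) \
                > -1e-9

    def test_decreases_with_crowding_under_depletion(self):
        """The stability margin decreases monotonically with crowder volume
        fraction when the depletion coupling dominates the solvent entropy
        (2 chi_dep phi_s^2 > 1)."""
        m = TernaryModel(n_protein=5, chi_ps=1.2, chi_dep=5.6)
        for phi_p in np.linspace(0.05, 0.4, 8):
            vals = [mu_derivative(m, phi_p, pc)
                    for pc in np.linspace(0.0, 0.2, 9)]
            assert np.all(np.diff(vals) < 0)


class TestSpinodal:
    def test_subcritical_stable_everywhere(self):
        m = TernaryModel(chi_ps=1.5)
        assert spinodal_at_crowder(m, 0.0).stable_everywhere

    def test_binary_roots_match_quadratic_oracle(self):
        # 1/phi + 1/(1-phi) = 2 chi  =>  phi^2 - phi + 1/(2 chi) = 0
        chi = 2.2
        disc = np.sqrt(1 - 2 / chi)
        expected = ((1 - disc) / 2, (1 + disc) / 2)
        sp = spinodal_at_crowder(TernaryModel(chi_ps=chi), 0.0)
        assert sp.spinodal_phi[0] == pytest.approx(expected[0], rel=1e-9)
        assert sp.spinodal_phi[1] == pytest.approx(expected[1], rel=1e-9)

    def test_crowding_induced_instability(self):
        m = TernaryModel(chi_ps=1.9, chi_dep=4.0)  # sub-critical alone
        assert spinodal_at_crowder(m, 0.0).stable_everywhere
        sp = spinodal_at_crowder(m, 0.2)
        assert not sp.stable_everywhere
        lo, hi = sp.spinodal_phi
        assert lo < hi


class TestBinodal:
    def test_symmetric_binary_coexistence(self):
        m = TernaryModel(chi_ps=2.2)
        b = binodal_at_crowder(m, 0.0)
        assert b.phi_dilute == pytest.approx(1 - b.phi_dense, abs=1e-8)

    def test_binodal_brackets_spinodal(self):
        m = TernaryModel(n_protein=5, chi_ps=1.2, chi_pc=0.8)
        for phi_c in (0.0, 0.1):
            sp = spinodal_at_crowder(m, phi_c)
            b = binodal_at_crowder(m, phi_c)
            assert b.phi_dilute < sp.spinodal_phi[0]
            assert sp.spinodal_phi[1] < b.phi_dense

    def test_common_tangent_residuals(self):
        b = binodal_at_crowder(TernaryModel(n_protein=5, chi_ps=1.2,
                                            chi_pc=0.8), 0.1)
        assert b.mu_residual <= 1e-8
        assert b.omega_residual <= 1e-8

    def test_no_coexistence_when_stable(self):
        with pytest.raises(ValueError, match="no spinodal"):
            binodal_at_crowder(TernaryModel(chi_ps=1.0), 0.0)


class TestCrowdingSweep:
    def test_depletion_lowers_csat_and_raises_partition(self):
        m = TernaryModel(n_protein=5, chi_ps=1.2, chi_pc=0.8)
        df = crowding_sweep(m, [0.0, 0.05, 0.1, 0.15, 0.2])
        assert df["error"].isna().all()
        assert df.attrs["csat_decreasing"]
        assert df.attrs["partition_increasing"]

    def test_inert_crowder_leaves_csat_nearly_constant(self):
        """With no protein-crowder coupling the boundary moves only through
        the (small) solvent-displacement term; drift stays within 5% over a
        dilute crowder range."""
        m = TernaryModel(chi_ps=2.2, chi_pc=0.0, chi_cs=0.0)
        df = crowding_sweep(m, [0.0, 0.005, 0.01])
        csat = df["csat"].to_numpy()
        assert np.all(np.isfinite(csat))
        assert np.max(np.abs(csat - csat[0])) / csat[0] <= 0.05

    def test_failed_levels_reported_not_raised(self):
        m = TernaryModel(chi_ps=1.9, chi_dep=4.0)
        df = crowding_sweep(m, [0.0, 0.2])   # stable at 0, demixed at 0.2
        assert df["error"].iloc[0] is not None
        assert np.isfinite(df["csat"].iloc[1])


class TestDepletionGeometry:
    def test_layer_proportional_to_crowder_radius(self):
        assert depletion_layer_ratio(5.0, 2.0).layer_thickness == 2.0
        assert depletion_layer_ratio(5.0, 4.0).layer_thickness == 4.0

    def test_overlap_factor_equal_radii(self):
        assert depletion_layer_ratio(3.0, 3.0).overlap_factor == \
            pytest.approx(7.0)

    def test_overlap_factor_vanishes_for_small_crowder(self):
        assert depletion_layer_ratio(5.0, 1e-9).overlap_factor == \
            pytest.approx(0.0, abs=1e-6)
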