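"""Free-energy functionals, mass-action solutions and the enumeration oracle."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from phasefus import (ModelParams, ProteinSpec, SystemComposition,
                      exact_association_oracle, f_binding_atp,
                      f_binding_pure, f_reference, f_reference_atp, f_total,
                      mu_atp_reservoir, mu_protein, solve_internal,
                      solve_p_pure)
from phasefus.meanfield import _solve_pq


def _composition_at(phi, n_p, params, lam=0.0):
    """Molecule counts hitting the requested phi (and lam) as closely as
    integer counts allow."""
    n1, n2 = params.protein.n1, params.n2
    n_atp = round(lam * n_p * n1)
    n_s = round((n_p * n1 * (1 - phi) / phi - n_atp) / n2)
    return SystemComposition(n_p=n_p, n_s=n_s, n_atp=n_atp)


class TestReferenceFreeEnergy:
    def test_hand_value(self, fus):
        # (0.5/526) ln 0.5 + (0.5/65) ln 0.5
        assert f_reference(0.5, fus) == pytest.approx(-5.9908e-3, rel=1e-4)

    def test_boundary_limits_are_zero(self, fus):
        assert f_reference(0.0, fus) == 0.0
        assert f_reference(1.0, fus) == 0.0

    def test_domain_error(self, fus):
        with pytest.raises(ValueError):
            f_reference(1.2, fus)
        with pytest.raises(ValueError):
            f_reference(-0.1, fus)


class TestPureBinding:
    def test_no_bonds_no_free_energy(self, fus):
        assert f_binding_pure(0.37, 0.0, fus) == 0.0

    def test_binding_switched_off(self, fus):
        weak = replace(fus, beta_eps1=+400.0)
        p = solve_p_pure(0.1, weak)
        assert p < 1e-10
        assert f_binding_pure(0.1, p, weak) == pytest.approx(0.0, abs=1e-12)

    def test_mass_action_value(self, fus):
        # independent check: direct 1-D minimisation of the functional
        p = solve_p_pure(0.1, fus)
        assert p == pytest.approx(0.0436, abs=2e-4)
        res = minimize_scalar(lambda x: f_binding_pure(0.1, x, fus),
                              bounds=(1e-12, 1 - 1e-12), method="bounded",
                              options={"xatol": 1e-12})
        assert p == pytest.approx(res.x, abs=1e-8)

    @given(st.floats(1e-5, 0.95))
    @settings(max_examples=40, deadline=None)
    def test_mass_action_residual(self, phi):
        params = ModelParams()
        p = solve_p_pure(phi, params)
        m1, m2, n1 = 34, 34, 526
        lhs = p / ((1 - p) * (1 - p * m1 / m2))
        rhs = (m2 * phi / n1) * math.exp(-params.beta_eps1)
        assert lhs == pytest.approx(rhs, rel=1e-12)
        assert 0 < p < 1

    def test_asymmetric_p_cap(self):
        # with m1 > m2 the bond fraction saturates below m2/m1
        params = ModelParams(protein=ProteinSpec(n1=526, m1=34, m2=11),
                             beta_eps1=-12.0)
        p = solve_p_pure(0.5, params)
        assert 0 < p < 11 / 34

    def test_arg_budget_domain_error(self):
        params = ModelParams(protein=ProteinSpec(n1=526, m1=34, m2=11))
        with pytest.raises(ValueError):
            f_binding_pure(0.1, 0.9, params)   # p m1/m2 > 1


class TestReservoir:
    def test_hand_value(self, fus):
        assert mu_atp_reservoir(0.1, fus) == pytest.approx(-2.27635,
                                                           abs=1e-4)

    def test_symmetric_ideal_case(self):
        params = ModelParams(n2=1, chi=0.0)
        assert mu_atp_reservoir(0.5, params) == pytest.approx(0.0, abs=1e-14)

    def test_monotone_in_reservoir_fraction(self, fus):
        grid = np.linspace(1e-3, 0.4, 80)
        mus = [mu_atp_reservoir(x, fus) for x in grid]
        assert np.all(np.diff(mus) > 0)

    def test_domain_error(self, fus):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                mu_atp_reservoir(bad, fus)


class TestAtpFreeEnergies:
    def test_lam_zero_reduces_to_reference(self, fus):
        for phi in (1e-4, 0.1, 0.6):
            assert f_reference_atp(phi, 0.0, fus) == f_reference(phi, fus)

    def test_reference_term_by_term(self):
        params = ModelParams(atp_reservoir_phi=0.05)
        phi, lam = 0.1, 0.5
        mu = mu_atp_reservoir(0.05, params)
        psi = 1 - phi - lam * phi
        expected = (phi / 526 * math.log(phi)
                    + psi / 65 * math.log(psi)
                    + lam * phi * math.log(lam * phi)
                    + params.chi * lam * phi * psi
                    - lam * phi * mu)
        assert f_reference_atp(phi, lam, params) == pytest.approx(
            expected, rel=1e-14)

    def test_overfilled_box_rejected(self, fus):
        with pytest.raises(ValueError):
            f_reference_atp(0.4, 2.0, fus)

    def test_atp_decoupled_limit(self, fus):
        p = solve_p_pure(0.2, fus)
        assert f_binding_atp(0.2, 0.0, p, 0.0, fus) == \
            f_binding_pure(0.2, p, fus)

    def test_no_bonds_vanish(self, fus):
        assert f_binding_atp(0.2, 0.0, 0.0, 0.0, fus) == 0.0

    def test_arg_budget_error(self, fus):
        with pytest.raises(ValueError):
            f_binding_atp(0.2, 1.0, 0.5, 0.9, fus)


class TestSolveInternal:
    def test_empty_reservoir_recovers_pure_solution(self, fus):
        st_ = solve_internal(0.1, fus)
        assert st_.lam == 0.0 and st_.q == 0.0
        assert st_.p == solve_p_pure(0.1, fus)

    def test_atp_binding_switched_off(self, fus):
        params = replace(fus, beta_eps2=+400.0, atp_reservoir_phi=1e-3)
        st_ = solve_internal(0.1, params)
        assert st_.q < 1e-10
        assert st_.lam > 0  # free ATP still partitions into the solution
        assert st_.p == pytest.approx(solve_p_pure(0.1, fus), rel=1e-6)

    def test_stationarity_of_lambda(self, fus):
        params = fus.with_reservoir_molar(1e-3)
        phi = 0.05
        st_ = solve_internal(phi, params)
        f0 = f_reference_atp(phi, st_.lam, params) + \
            f_binding_atp(phi, st_.lam, st_.p, st_.q, params)
        for h in (1e-6, -1e-6):
            lam = st_.lam * (1 + h)
            p, q, _ = _solve_pq(phi, lam, params)
            f1 = f_reference_atp(phi, lam, params) + \
                f_binding_atp(phi, lam, p, q, params)
            assert f1 >= f0 - 1e-12

    def test_is_a_minimum(self, fus):
        params = fus.with_reservoir_molar(1e-3)
        for phi in (0.01, 0.2):
            solve_internal(phi, params, check_minimum=True)

    def test_constraints_hold(self, fus):
        params = replace(fus, valence=3).with_reservoir_molar(5e-3)
        for phi in np.geomspace(1e-6, 0.85, 25):
            st_ = solve_internal(phi, params)
            assert st_.sigma(params) >= 0
            assert st_.lam * phi + phi <= 1
            assert 0 <= st_.p <= 1 and 0 <= st_.q <= 1

    def test_higher_valence_binds_more_arg_per_atp(self, fus):
        c = 1e-5
        g = {}
        for L in (1, 2):
            params = replace(fus, valence=L,
                             beta_eps2=-8.0).with_reservoir_molar(c)
            st_ = solve_internal(0.1, params)
            g[L] = st_.bound_arg_per_atp(params)
        assert g[2] > g[1]


class TestTotalFreeEnergy:
    def test_matches_pure_model_without_atp(self, fus):
        for phi in np.geomspace(1e-5, 0.9, 20):
            f, st_ = f_total(phi, fus, return_state=True)
            expected = f_reference(phi, fus) + \
                f_binding_pure(phi, solve_p_pure(phi, fus), fus)
            assert f == pytest.approx(expected, rel=1e-14, abs=1e-18)

    @pytest.mark.parametrize("reservoir_molar", [0.0, 1e-4, 5e-3])
    def test_envelope_derivative(self, fus, reservoir_molar):
        params = (fus.with_reservoir_molar(reservoir_molar)
                  if reservoir_molar else fus)
        for phi in (1e-3, 0.05, 0.3, 0.6):
            h = 1e-6 * phi
            fd = (f_total(phi + h, params) - f_total(phi - h, params)) / (2 * h)
            assert mu_protein(phi, params) == pytest.approx(fd, rel=1e-6)

    def test_smooth_along_phi(self, fus):
        params = replace(fus, valence=2).with_reservoir_molar(1e-3)
        phis = np.geomspace(1e-6, 0.9, 150)
        f = np.array([f_total(p, params) for p in phis])
        assert np.all(np.isfinite(f))
        assert np.max(np.abs(np.diff(f))) < 0.02


class TestEnumerationOracle:
    def test_single_bond_closed_form(self):
        params = ModelParams(protein=ProteinSpec(n1=4, m1=1, m2=1), n2=1)
        comp = SystemComposition(n_p=1, n_s=6, n_atp=0)
        v_over_V = 1 / comp.total_sites(params)
        expected = -v_over_V * math.log(
            1 + v_over_V * math.exp(-params.beta_eps1))
        assert exact_association_oracle(comp, params) == pytest.approx(
            expected, rel=1e-14)

    def test_infinite_energy_kills_binding(self, fus):
        params = replace(fus, beta_eps1=+500.0, beta_eps2=+500.0)
        comp = _composition_at(0.1, 1, params)
        assert exact_association_oracle(comp, params) == pytest.approx(
            0.0, abs=1e-15)

    def test_term_guard(self, fus):
        comp = SystemComposition(n_p=10, n_s=100, n_atp=10**6)
        with pytest.raises(ValueError):
            exact_association_oracle(comp, fus, max_terms=1000)

    def test_stirling_converges_to_oracle_pure(self, fus):
        gaps = []
        for n_p in (2, 20, 200):
            comp = _composition_at(0.1, n_p, fus)
            phi = comp.phi(fus)
            f_exact = exact_association_oracle(comp, fus)
            f_stirling = f_binding_pure(phi, solve_p_pure(phi, fus), fus)
            gaps.append(abs(f_stirling - f_exact) / abs(f_exact))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[1] < 1e-2 and gaps[2] < 1e-4

    def test_stirling_converges_to_oracle_with_atp(self):
        params = ModelParams(protein=ProteinSpec(n1=20, m1=2, m2=2),
                             n2=5, valence=2, beta_eps2=-3.0,
                             atp_reservoir_phi=1e-3)
        gaps = []
        for scale in (1, 10, 100):
            comp = _composition_at(0.2, 2 * scale, params, lam=0.05)
            phi, lam = comp.phi(params), comp.lam(params)
            f_exact = exact_association_oracle(comp, params)
            p, q, _ = _solve_pq(phi, lam, params)
            f_stirling = f_binding_atp(phi, lam, p, q, params)
            gaps.append(abs(f_stirling - f_exact) / abs(f_exact))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-2


class TestParamValidation:
    def test_protein_invariants(self):
        with pytest.raises(ValueError):
            ProteinSpec(n1=10, m1=8, m2=8)
        with pytest.raises(ValueError):
            ProteinSpec(n1=0)

    def test_model_invariants(self):
        with pytest.raises(ValueError):
            ModelParams(valence=4)
        with pytest.raises(ValueError):
            ModelParams(atp_reservoir_phi=1.0)

    def test_per_valence_eps2_defaults(self):
        assert ModelParams(valence=2).eps2 == -8.0
        assert ModelParams(valence=1).eps2 < ModelParams(valence=2).eps2 \
            < ModelParams(valence=3).eps2
        assert ModelParams(valence=3, beta_eps2=-7.5).eps2 == -7.5
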