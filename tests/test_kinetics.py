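import numpy as np
import pytest

from oracles import superoperator_propagate, superoperator_yields
from triospin.hamiltonian import FieldSpec, zeeman_term
from triospin.kinetics_yields import (
    InitialState,
    KineticsError,
    ReactionScheme,
    effective_hamiltonian,
    initial_density,
    yields_by_integration,
    yields_by_resolvent,
)
from triospin.spin_core import SpinSystemLayout, singlet_projector, triplet_projector

from conftest import random_spin_system

K_F = 1.0 / 3e-6


class TestScheme:
    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            ReactionScheme(k_f=-1.0)

    def test_scavenging_forbids_recombination(self):
        # the scavenging scheme purposefully neglects primary recombination
        with pytest.raises(ValueError, match="recombination"):
            ReactionScheme(k_f=K_F, k_x=1e6, k_b=1e5, kind="scavenging")

    def test_r3m_bystander_is_inert(self):
        with pytest.raises(ValueError, match="inert"):
            ReactionScheme(k_f=K_F, k_x=1e6, kind="R3M")

    def test_unknown_initial_state_rejected(self):
        with pytest.raises(ValueError, match="unknown initial state"):
            InitialState("doublet")


class TestInitialDensity:
    @pytest.mark.parametrize("kind", ["singlet_born", "triplet_born", "F_pair"])
    def test_unit_trace_hermitian_psd(self, kind, trio_layout):
        rho = initial_density(trio_layout, InitialState(kind))
        assert np.trace(rho).real == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(rho, rho.conj().T, atol=1e-14)
        assert np.linalg.eigvalsh(rho).min() > -1e-14

    def test_uncorrelated_scavenger_singlet_probabilities(self, trio_layout):
        # geminate pair fully correlated; scavenger pairs at the random 1/4
        rho_s = initial_density(trio_layout, InitialState("singlet_born"))
        rho_t = initial_density(trio_layout, InitialState("triplet_born"))
        p12 = singlet_projector(trio_layout, (1, 2))
        p13 = singlet_projector(trio_layout, (1, 3))
        assert np.trace(p12 @ rho_s).real == pytest.approx(1.0, abs=1e-12)
        assert np.trace(p13 @ rho_s).real == pytest.approx(0.25, abs=1e-12)
        t12 = triplet_projector(trio_layout, (1, 2))
        assert np.trace(t12 @ rho_t).real == pytest.approx(1.0, abs=1e-12)
        assert np.trace(p13 @ rho_t).real == pytest.approx(0.25, abs=1e-12)

    def test_f_pair_is_maximally_mixed(self, trio_layout):
        rho = initial_density(trio_layout, InitialState("F_pair"))
        p12 = singlet_projector(trio_layout, (1, 2))
        assert np.trace(p12 @ rho).real == pytest.approx(0.25, abs=1e-12)


class TestEffectiveHamiltonian:
    def test_zero_rates_reduce_to_hamiltonian(self, trio_layout):
        h = np.diag(np.arange(8.0)).astype(complex)
        scheme = ReactionScheme(k_f=0.0)
        np.testing.assert_allclose(effective_hamiltonian(h, trio_layout, scheme), h)

    def test_pure_escape_eigenvalues(self, trio_layout):
        h_eff = effective_hamiltonian(
            np.zeros((8, 8), complex), trio_layout, ReactionScheme(k_f=K_F)
        )
        np.testing.assert_allclose(np.linalg.eigvals(h_eff), -0.5j * K_F * np.ones(8))

    def test_anti_hermitian_part_negative_semidefinite(self, trio_layout):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        h_eff = effective_hamiltonian(
            (a + a.conj().T), trio_layout,
            ReactionScheme(k_f=K_F, k_x=5e6, scavenged_pair=(1, 3)),
        )
        gamma = (h_eff - h_eff.conj().T) / 2j
        assert np.linalg.eigvalsh(gamma).max() <= 1e-12

    def test_propagation_matches_superoperator_exponential(self, trio_layout):
        """exp(-i H_eff t) rho exp(+i H_eff^dag t) equals the full Liouvillian flow."""
        from scipy.linalg import expm

        rng = np.random.default_rng(7)
        a = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        h = (a + a.conj().T) * K_F
        scheme = ReactionScheme(k_f=K_F, k_x=2 * K_F, scavenged_pair=(2, 3))
        rho0 = initial_density(trio_layout, InitialState("singlet_born"))
        t = 0.7 / K_F
        h_eff = effective_hamiltonian(h, trio_layout, scheme)
        u = expm(-1j * h_eff * t)
        rho_fast = u @ rho0 @ u.conj().T
        rho_oracle = superoperator_propagate(h, trio_layout, scheme, rho0, t)
        np.testing.assert_allclose(rho_fast, rho_oracle, atol=1e-8)


class TestClosedForms:
    def test_escape_only_forward_yield_is_one(self, trio_layout):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        h = (a + a.conj().T) * K_F
        rho0 = initial_density(trio_layout, InitialState("singlet_born"))
        res = yields_by_resolvent(h, trio_layout, ReactionScheme(k_f=K_F), rho0)
        assert res.phi_f == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("ratio", [0.3, 1.0, 4.0])
    def test_zero_hamiltonian_scavenging_yield(self, trio_layout, ratio):
        # Tr[P_S^13 rho0] = 1/4 is stationary: Phi_X = (1/4) k_X/(k_f + k_X)
        k_x = ratio * K_F
        scheme = ReactionScheme(k_f=K_F, k_x=k_x, scavenged_pair=(1, 3))
        rho0 = initial_density(trio_layout, InitialState("triplet_born"))
        res = yields_by_resolvent(np.zeros((8, 8), complex), trio_layout, scheme, rho0)
        assert res.phi_x == pytest.approx(0.25 * k_x / (K_F + k_x), rel=1e-10)
        assert res.total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("b0", [0.0, 50e-6, 500e-6])
    def test_rpm_singlet_stationary_under_uniform_field(self, pair_layout, b0):
        # singlet is an eigenstate of the Zeeman term: Phi_b = k_b/(k_b + k_f)
        k_b = 2.5e5
        h = zeeman_term(pair_layout, FieldSpec(b0=b0))
        scheme = ReactionScheme(k_f=K_F, k_b=k_b, kind="RPM")
        rho0 = initial_density(pair_layout, InitialState("singlet_born"))
        res = yields_by_resolvent(h, pair_layout, scheme, rho0)
        assert res.phi_b == pytest.approx(k_b / (k_b + K_F), rel=1e-9)


class TestSolverAgreement:
    def test_resolvent_matches_superoperator_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            layout, h, scheme = random_spin_system(rng)
            rho0 = initial_density(layout, InitialState("singlet_born"))
            res = yields_by_resolvent(h, layout, scheme, rho0)
            oracle = superoperator_yields(h, layout, scheme, rho0)
            assert res.phi_f == pytest.approx(oracle["forward"], abs=1e-8)
            assert res.phi_x == pytest.approx(oracle.get("scavenging", 0.0), abs=1e-8)
            assert res.phi_b == pytest.approx(oracle.get("recombination", 0.0), abs=1e-8)

    def test_integration_matches_resolvent(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            layout, h, scheme = random_spin_system(rng, max_nuclei=0)
            rho0 = initial_density(layout, InitialState("triplet_born"))
            res_r = yields_by_resolvent(h, layout, scheme, rho0)
            res_i = yields_by_integration(h, layout, scheme, rho0)
            assert res_i.phi_f == pytest.approx(res_r.phi_f, abs=1e-6)
            assert res_i.phi_x == pytest.approx(res_r.phi_x, abs=1e-6)

    def test_conservation_across_rate_magnitudes(self):
        # rates spanning six orders of magnitude relative to the couplings
        rng = np.random.default_rng(13)
        layout = SpinSystemLayout((1, 2, 3), ((1, 0.5),))
        a = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        h = (a + a.conj().T) * 1e6
        rho0 = initial_density(layout, InitialState("singlet_born"))
        for exp in range(3, 10):
            scheme = ReactionScheme(k_f=10.0**exp, k_x=10.0 ** (12 - exp), scavenged_pair=(2, 3))
            res = yields_by_resolvent(h, layout, scheme, rho0)
            assert res.total == pytest.approx(1.0, abs=1e-6)
            assert -1e-9 <= res.phi_f <= 1 + 1e-9
            assert -1e-9 <= res.phi_x <= 1 + 1e-9

    def test_yields_linear_in_initial_state(self, trio_layout):
        rng = np.random.default_rng(14)
        a = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        h = (a + a.conj().T) * K_F
        scheme = ReactionScheme(k_f=K_F, k_x=K_F, scavenged_pair=(1, 3))
        rho_s = initial_density(trio_layout, InitialState("singlet_born"))
        rho_t = initial_density(trio_layout, InitialState("triplet_born"))
        w = 0.3
        mix = w * rho_s + (1 - w) * rho_t
        res_mix = yields_by_resolvent(h, trio_layout, scheme, mix)
        res_s = yields_by_resolvent(h, trio_layout, scheme, rho_s)
        res_t = yields_by_resolvent(h, trio_layout, scheme, rho_t)
        assert res_mix.phi_x == pytest.approx(w * res_s.phi_x + (1 - w) * res_t.phi_x, abs=1e-12)


class TestErrorPaths:
    def test_integration_reports_unconverged_residual(self, trio_layout):
        rho0 = initial_density(trio_layout, InitialState("singlet_born"))
        with pytest.raises(KineticsError, match="residual"):
            yields_by_integration(
                np.zeros((8, 8), complex), trio_layout,
                ReactionScheme(k_f=K_F), rho0, t_max=0.1 / K_F,
            )

    def test_resolvent_flags_ill_conditioned_eigenbasis(self, trio_layout):
        rho0 = initial_density(trio_layout, InitialState("singlet_born"))
        with pytest.raises(KineticsError, match="condition"):
            yields_by_resolvent(
                np.zeros((8, 8), complex), trio_layout,
                ReactionScheme(k_f=K_F), rho0, cond_limit=0.5,
            )

    def test_resolvent_requires_decay(self, trio_layout):
        rho0 = initial_density(trio_layout, InitialState("singlet_born"))
        with pytest.raises(KineticsError):
            yields_by_resolvent(np.zeros((8, 8), complex), trio_layout,
                                ReactionScheme(k_f=0.0), rho0)
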