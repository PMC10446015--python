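"""FSSH engine: integrators, hop machinery, decoherence, full trajectories."""

import math

import numpy as np
import pytest

import bahop
from bahop.fssh_engine import _substep_unitary
from bahop.model_potentials import Polynomial
from bahop.units import FS_TO_AU


def harmonic_model(omega=0.01, mass=1.0):
    """Single-state harmonic surface V = 1/2 w^2 Q^2 (mass-weighted)."""
    pot = Polynomial((0.5 * omega**2,), ((2,),))
    return bahop.DiabaticModel(1, 1, np.array([mass]), ((pot,),))


def make_state(model, R, v, active=0, c=None):
    point = bahop.adiabatize(model, R)
    n = model.n_states
    cc = np.zeros(n, dtype=complex)
    if c is None:
        cc[active] = 1.0
    else:
        cc[:] = c
    from bahop.tdba_coupling import GapHistory

    history = GapHistory(n_states=n, max_len=4)
    history.push(point.E)
    return bahop.TrajectoryState(
        t=0.0, R=np.asarray(R, float), v=np.asarray(v, float),
        masses=model.masses, active=active, c=cc, point=point,
        rng=np.random.default_rng(0), gap_history=history,
        sigma_drive=np.zeros((n, n)),
    )


class TestVelocityVerlet:
    def test_energy_drift_harmonic_1000_steps(self):
        m = harmonic_model(omega=0.01)
        state = make_state(m, [1.0], [0.0])
        e0 = state.total_energy()
        for _ in range(1000):
            bahop.velocity_verlet_step(state, m, dt=1.0)
        assert abs(state.total_energy() - e0) < 1e-8

    def test_zero_force_advances_linearly(self):
        flat = bahop.DiabaticModel(
            1, 1, np.array([1.0]), ((Polynomial.constant(0.3, 1),),)
        )
        state = make_state(flat, [0.0], [0.25])
        for _ in range(10):
            bahop.velocity_verlet_step(flat and flat, flat, dt=0.5) if False else None
            bahop.velocity_verlet_step(state, flat, dt=0.5)
        assert state.R[0] == pytest.approx(0.25 * 5.0, abs=1e-12)
        assert state.v[0] == pytest.approx(0.25)

    def test_quadratic_convergence_to_reference(self):
        # Richardson-style check: global position error scales as dt^2
        m = harmonic_model(omega=0.05)
        T = 200.0

        def final_q(dt):
            state = make_state(m, [1.0], [0.0])
            for _ in range(int(T / dt)):
                bahop.velocity_verlet_step(state, m, dt=dt)
            return state.R[0]

        exact = math.cos(0.05 * T)
        e1 = abs(final_q(0.5) - exact)
        e2 = abs(final_q(0.25) - exact)
        assert e1 / e2 == pytest.approx(4.0, rel=0.1)


class TestPropagateQuantum:
    def test_zero_coupling_rotates_phases_only(self):
        E = np.array([0.1, 0.3])
        c0 = np.array([0.6, 0.8], dtype=complex)
        c1 = bahop.propagate_quantum(
            c0, E, E, np.zeros((2, 2)), np.zeros((2, 2)), dtau=0.05, dt=1.0
        )
        expected = c0 * np.exp(-1j * E * 1.0)
        assert c1 == pytest.approx(expected, abs=1e-10)

    def test_constant_coupling_rabi_rotation(self):
        # degenerate two-level with constant sigma: |c0|^2 = cos^2(s t)
        s = 0.3
        sigma = np.array([[0.0, s], [-s, 0.0]])
        c = np.array([1.0, 0.0], dtype=complex)
        dt = 2.0
        c = bahop.propagate_quantum(
            c, np.zeros(2), np.zeros(2), sigma, sigma, dtau=0.01, dt=dt
        )
        assert abs(c[0]) ** 2 == pytest.approx(math.cos(s * dt) ** 2, abs=1e-6)

    def test_norm_conserved_with_random_coupling(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=3) + 1j * rng.normal(size=3)
        c /= np.linalg.norm(c)
        for _ in range(50):
            E0, E1 = np.sort(rng.normal(size=3)), np.sort(rng.normal(size=3))
            a = rng.normal(size=(3, 3))
            s0, s1 = a - a.T, (a - a.T) * rng.normal()
            c = bahop.propagate_quantum(c, E0, E1, s0, s1, dtau=0.1, dt=1.0)
            assert np.sum(np.abs(c) ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_unitary_matches_expm(self):
        from scipy.linalg import expm

        rng = np.random.default_rng(2)
        for _ in range(5):
            E = np.sort(rng.normal(size=2))
            s = rng.normal()
            sigma = np.array([[0.0, s], [-s, 0.0]])
            U = _substep_unitary(E, sigma, 0.3)
            G = -(1j * np.diag(E) + sigma)
            assert U == pytest.approx(expm(G * 0.3), abs=1e-12)


class TestHopMachinery:
    def test_probability_hand_value(self):
        # |c_L|^2 = 0.8, Re(c_J c_L*) = 0.4, sigma_JL = -1, dtau = 0.2
        c = np.array([math.sqrt(0.8), math.sqrt(0.2)], dtype=complex)
        sigma = np.array([[0.0, 1.0], [-1.0, 0.0]])  # sigma[1, 0] = -1
        p = bahop.hop_probability(c, sigma, L=0, J=1, dtau=0.2)
        assert p == pytest.approx(0.2)

    def test_probability_zero_for_empty_target(self):
        c = np.array([1.0, 0.0], dtype=complex)
        sigma = np.array([[0.0, 1.0], [-1.0, 0.0]])
        assert bahop.hop_probability(c, sigma, 0, 1, 0.1) == 0.0

    def test_probability_sign_screen(self):
        # inward flux (sigma_JL * Re > 0) must give zero
        c = np.array([math.sqrt(0.8), math.sqrt(0.2)], dtype=complex)
        sigma = np.array([[0.0, -1.0], [1.0, 0.0]])
        assert bahop.hop_probability(c, sigma, 0, 1, 0.2) == 0.0

    def test_attempt_hop_none_when_all_zero(self):
        rng = np.random.default_rng(0)
        assert bahop.attempt_hop(0, {1: 0.0, 2: 0.0}, rng) is None

    def test_attempt_hop_multinomial_statistics(self):
        rng = np.random.default_rng(42)
        probs = {1: 0.15, 2: 0.25, 3: 0.05}
        n = 100_000
        counts = {1: 0, 2: 0, 3: 0, None: 0}
        for _ in range(n):
            t = bahop.attempt_hop(0, probs, rng)
            counts[t] += 1
        for J, p in probs.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[J] / n - p) < 3 * se

    def test_rescale_p_hand_value(self):
        v, ok = bahop.rescale_velocity_p(
            np.array([2.0]), np.array([1.0]), E_from=1.5, E_to=0.0
        )
        assert ok and v[0] == pytest.approx(math.sqrt(7.0))

    def test_rescale_p_conserves_energy_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            v0 = rng.normal(size=3)
            m = rng.uniform(1, 2000, size=3)
            e_from, e_to = rng.normal(), rng.normal()
            v1, ok = bahop.rescale_velocity_p(v0, m, e_from, e_to)
            ke0, ke1 = 0.5 * np.sum(m * v0**2), 0.5 * np.sum(m * v1**2)
            if ok:
                assert ke1 + e_to == pytest.approx(ke0 + e_from, abs=1e-12)
            else:
                assert np.array_equal(v1, v0)

    def test_rescale_p_frustrated_upward(self):
        v, ok = bahop.rescale_velocity_p(
            np.array([1.0]), np.array([1.0]), E_from=0.0, E_to=1.0
        )
        assert not ok and v[0] == 1.0

    def test_rescale_h_conserves_energy_exactly(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            v0 = rng.normal(size=2)
            m = rng.uniform(100, 2000, size=2)
            h = rng.normal(size=2)
            e_from, e_to = 0.1, 0.05
            v1, ok = bahop.rescale_velocity_h(v0, m, h, e_from, e_to)
            assert ok
            assert 0.5 * np.sum(m * v1**2) + e_to == pytest.approx(
                0.5 * np.sum(m * v0**2) + e_from, abs=1e-12
            )


class TestDecoherence:
    def test_decay_factor_hand_value(self):
        # tau = (1/0.1)(1 + 0.1/0.1) = 20 au; factor exp(-4.134/20)
        c = np.array([math.sqrt(0.5), math.sqrt(0.5)], dtype=complex)
        E = np.array([0.0, 0.1])
        out = bahop.apply_decoherence(c, active=1, E=E, kinetic_energy=0.1,
                                      dt=4.134, alpha=0.1)
        assert abs(out[0]) == pytest.approx(
            math.sqrt(0.5) * math.exp(-4.134 / 20.0), rel=1e-12
        )

    def test_degenerate_state_does_not_decay(self):
        c = np.array([0.6, 0.8], dtype=complex)
        out = bahop.apply_decoherence(c, 1, np.array([0.2, 0.2]), 0.5, 1.0)
        assert out == pytest.approx(c)

    def test_norm_restored(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=3) + 1j * rng.normal(size=3)
        c /= np.linalg.norm(c)
        out = bahop.apply_decoherence(c, 0, np.array([0.0, 0.1, 0.4]), 0.2, 10.0)
        assert np.sum(np.abs(out) ** 2) == pytest.approx(1.0, abs=1e-12)


class TestRunTrajectory:
    def test_single_state_model_conserves_and_never_hops(self):
        m = harmonic_model(omega=0.005, mass=2000.0)
        s = bahop.FsshSettings(t_max_fs=50.0, coupling_source="exact")
        log = bahop.run_trajectory(m, [0.5], [0.0], 0, s, seed=0)
        assert not log.hops
        assert np.ptp(log.total_energy) < 1e-8
        assert np.all(log.active == 0)

    def test_identical_seeds_are_bit_identical(self, ba_model):
        s = bahop.FsshSettings(coupling_source="exact", t_max_fs=5.0)
        a = bahop.run_trajectory(ba_model, [-1.0], [0.02], 0, s, seed=123)
        b = bahop.run_trajectory(ba_model, [-1.0], [0.02], 0, s, seed=123)
        assert np.array_equal(a.active, b.active)
        assert np.array_equal(a.coeff_pops, b.coeff_pops)
        assert np.array_equal(a.total_energy, b.total_energy)

    def test_norm_conserved_along_trajectory(self, ba_model):
        s = bahop.FsshSettings(coupling_source="exact", t_max_fs=10.0)
        log = bahop.run_trajectory(ba_model, [-1.0], [0.02], 0, s, seed=5)
        norms = log.coeff_pops.sum(axis=1)
        assert np.max(np.abs(norms - 1.0)) < 1e-8

    def test_frustrated_hops_change_nothing(self):
        # crossing passed with kinetic energy far below the upward gap:
        # every attempted hop must be frustrated and leave the state alone
        m = bahop.ba_model_1d(0.1, 0.02, mass=2000.0)
        s = bahop.FsshSettings(coupling_source="exact", t_max_fs=10.0,
                               decoherence_alpha=None)
        gap_rise = 0.5 * (math.sqrt(4 * 0.01 * 0.25 + 4e-4) - 0.02)
        v0 = math.sqrt(2 * (0.005 + gap_rise) / 2000.0)
        ics = [([-0.5], [v0], 0)] * 15
        logs = bahop.run_ensemble(m, ics, s, master_seed=6)
        outcomes = [h.outcome for log in logs for h in log.hops]
        assert outcomes and set(outcomes) == {"frustrated"}
        assert all(np.all(log.active == 0) for log in logs)

    def test_tdba_run_logs_both_coupling_series(self, ba_model):
        s = bahop.FsshSettings(coupling_source="tdba", t_max_fs=5.0)
        log = bahop.run_trajectory(ba_model, [-1.0], [0.02], 0, s, seed=2)
        assert log.sigma_tdba.shape == log.sigma_exact.shape
        assert np.isfinite(log.sigma_tdba).all()
        # exact oracle logged opportunistically alongside
        assert np.isfinite(log.sigma_exact[5:]).all()

    def test_warmup_forbids_hops_with_tdba(self, ba_model):
        s = bahop.FsshSettings(coupling_source="tdba", t_max_fs=1.0)
        log = bahop.run_trajectory(ba_model, [-1.0], [0.02], 0, s, seed=0)
        assert np.all(log.sigma_tdba[:3] == 0.0)


class TestEnsemble:
    def test_split_run_reproduces_single_run(self, ba_model):
        s = bahop.FsshSettings(coupling_source="exact", t_max_fs=2.0)
        ics = [([-1.0], [0.02], 0)] * 4
        full = bahop.run_ensemble(ba_model, ics, s, master_seed=9)
        first = bahop.run_ensemble(ba_model, ics[:2], s, master_seed=9)
        second = bahop.run_ensemble(ba_model, ics[2:], s, master_seed=9,
                                    index_offset=2)
        for a, b in zip(full, first + second):
            assert np.array_equal(a.active, b.active)
            assert np.array_equal(a.coeff_pops, b.coeff_pops)

    def test_internal_consistency_fast_crossing(self, ba_model):
        # without decoherence, the fraction of trajectories on each surface
        # must track the mean |c|^2 within Monte-Carlo error
        s = bahop.FsshSettings(
            coupling_source="exact", t_max_fs=5.0, dt_fs=0.02, dtau_fs=0.002,
            decoherence_alpha=None,
        )
        v0 = math.sqrt(2 * 1.0 / 2000.0)
        ics = [([-1.0], [v0], 0)] * 120
        stop = lambda st: abs(st.R[0]) > 1.0
        logs = bahop.run_ensemble(ba_model, ics, s, master_seed=17,
                                  stop_condition=stop)
        frac_up = np.mean([log.active[-1] == 1 for log in logs])
        mean_pop = np.mean([log.coeff_pops[-1, 1] for log in logs])
        se = math.sqrt(mean_pop * (1 - mean_pop) / len(logs))
        assert abs(frac_up - mean_pop) < 3 * se
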