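import numpy as np
import pytest

import bahop


@pytest.fixture
def ba_model():
    """Reference linear-crossing model: kappa=0.1, Delta_c=0.02, Qc=0."""
    return bahop.ba_model_1d(0.1, 0.02, qc=0.0, mass=2000.0)


@pytest.fixture
def gap_fn():
    """Analytic adiabatic gap of the reference linear-crossing model."""

    def f(q):
        return np.sqrt(4 * 0.1**2 * np.asarray(q, dtype=float) ** 2 + 0.02**2)

    return f


def make_exponential_ensemble(tau_fs, n_traj, t_end_fs, dt_fs, seed):
    """Synthetic ensemble of step-decay trajectories with Exp(tau) lifetimes.

    Each trajectory sits on state 1 until its lifetime, then drops to state 0
    for good — the idealized single-passage internal-conversion picture the
    exponential-fit analysis assumes.
    """
    rng = np.random.default_rng(seed)
    time_fs = np.arange(0.0, t_end_fs + dt_fs / 2, dt_fs)
    lifetimes = rng.exponential(tau_fs, size=n_traj)
    logs = []
    for T in lifetimes:
        active = (time_fs < T).astype(int)
        nt = len(time_fs)
        logs.append(
            bahop.TrajectoryLog(
                time_fs=time_fs,
                energies=np.zeros((nt, 2)),
                active=active,
                coeff_pops=np.zeros((nt, 2)),
                sigma_tdba=np.zeros((nt, 1)),
                sigma_exact=np.zeros((nt, 1)),
                total_energy=np.zeros(nt),
                pair_order=[(1, 0)],
                hops=[],
                flagged=False,
                n_states=2,
            )
        )
    return logs
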