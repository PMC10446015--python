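"""Decoherence-corrected fewest-switches surface hopping (DC-FSSH).

Nuclei follow classical velocity-Verlet dynamics on one adiabatic surface of
an analytic diabatic model; complex electronic coefficients obey the locally
approximated time-dependent Schroedinger equation

    dc_J/dt = - sum_K ( (i/hbar) E_J delta_JK + sigma_JK ) c_K

integrated in substeps ``dtau`` with energies and couplings interpolated
across the classical step ``dt``.  At every substep the active state L may
hop to J with the fewest-switches probability

    P_{L->J} = max[ 0, -(2 dtau / |c_L|^2) sigma_LJ Re(c_J c_L*) ]

Time-derivative couplings ``sigma`` come either from the TD-BA estimator
(:mod:`bahop.tdba_coupling`) or from the exact oracle ``v . h_JL`` of the
model.  After an accepted hop the velocity is rescaled along the linear
momentum (the **h** direction being unknown to TD-BA); rescaling along the
exact **h** vector is available for oracle runs.  Hops without enough kinetic
energy are frustrated and change nothing.  Over-coherence is damped once per
classical step by the simplified-decay-of-mixing correction with the
standard 0.1 au parameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .units import FS_TO_AU, HARTREE_TO_EV, HBAR
from .model_potentials import (
    DegeneracyError,
    DiabaticModel,
    ElectronicPoint,
    adiabatize,
)
from .tdba_coupling import (
    CouplingEstimate,
    GapHistory,
    Provenance,
    Scheme,
    TdbaSettings,
    estimate_couplings,
)

__all__ = [
    "FsshSettings",
    "TrajectoryState",
    "HopEvent",
    "TrajectoryLog",
    "velocity_verlet_step",
    "propagate_quantum",
    "hop_probability",
    "attempt_hop",
    "rescale_velocity_p",
    "rescale_velocity_h",
    "apply_decoherence",
    "run_trajectory",
    "run_ensemble",
    "derive_rng",
]

logger = logging.getLogger(__name__)

#: allowed drift of the total energy between hops before a trajectory is flagged
ENERGY_DRIFT_TOL = 1e-3
#: allowed deviation of sum |c|^2 from 1 at any classical step
NORM_TOL = 1e-8


@dataclass
class FsshSettings:
    """Dynamics parameters (production defaults).

    ``dt_fs`` and ``dtau_fs`` are the classical and quantum timesteps; their
    ratio must be a positive integer.  ``decoherence_alpha`` is the
    decay-of-mixing energy parameter (hartree); ``None`` disables the
    correction.  ``coupling_source`` selects the TD-BA estimator or the exact
    oracle; ``rescale_direction`` is "p" (linear momentum, the only choice
    available to TD-BA) or "h" (exact coupling vector, oracle runs only).
    """

    dt_fs: float = 0.1
    dtau_fs: float = 0.005
    t_max_fs: float = 200.0
    decoherence_alpha: float | None = 0.1
    coupling_source: str = "tdba"  # "tdba" | "exact"
    rescale_direction: str = "p"  # "p" | "h"
    tdba: TdbaSettings = field(default_factory=TdbaSettings)

    def __post_init__(self) -> None:
        if self.dt_fs <= 0 or self.dtau_fs <= 0 or self.t_max_fs <= 0:
            raise ValueError("all timesteps and t_max must be positive")
        ratio = self.dt_fs / self.dtau_fs
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"dt/dtau = {ratio} must be a positive integer "
                f"(dt={self.dt_fs} fs, dtau={self.dtau_fs} fs)"
            )
        if self.coupling_source not in ("tdba", "exact"):
            raise ValueError("coupling_source must be 'tdba' or 'exact'")
        if self.rescale_direction not in ("p", "h"):
            raise ValueError("rescale_direction must be 'p' or 'h'")
        if self.rescale_direction == "h" and self.coupling_source != "exact":
            raise ValueError("h-direction rescaling needs the exact coupling vector")

    @property
    def n_substeps(self) -> int:
        return round(self.dt_fs / self.dtau_fs)

    @property
    def dt_au(self) -> float:
        return self.dt_fs * FS_TO_AU

    @property
    def dtau_au(self) -> float:
        return self.dtau_fs * FS_TO_AU


@dataclass
class TrajectoryState:
    """Mutable state of one trajectory."""

    t: float  # atomic time units
    R: np.ndarray
    v: np.ndarray
    masses: np.ndarray
    active: int
    c: np.ndarray  # complex coefficients
    point: ElectronicPoint  # electronic structure at R
    rng: np.random.Generator
    gap_history: GapHistory
    sigma_drive: np.ndarray  # coupling matrix the dynamics currently uses
    tdba_previous: CouplingEstimate | None = None

    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.masses * self.v**2))

    def total_energy(self) -> float:
        return self.kinetic_energy() + float(self.point.E[self.active])


@dataclass
class HopEvent:
    """One attempted surface switch."""

    time_fs: float
    from_state: int
    to_state: int
    gap_ev: float  # |E_to - E_from| at the hop
    outcome: str  # "accepted" | "frustrated"
    R: np.ndarray


@dataclass
class TrajectoryLog:
    """Per-classical-step time series of one trajectory.

    ``sigma_tdba`` and ``sigma_exact`` carry one column per state pair in
    ``pair_order``; exact entries are NaN where the oracle hit a degeneracy.
    """

    time_fs: np.ndarray
    energies: np.ndarray  # (n_steps, n_states) hartree
    active: np.ndarray  # (n_steps,) int
    coeff_pops: np.ndarray  # (n_steps, n_states) |c|^2
    sigma_tdba: np.ndarray  # (n_steps, n_pairs)
    sigma_exact: np.ndarray  # (n_steps, n_pairs)
    total_energy: np.ndarray  # (n_steps,) hartree
    pair_order: list[tuple[int, int]]
    hops: list[HopEvent]
    flagged: bool
    n_states: int
    seed_label: str = ""


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def velocity_verlet_step(
    state: TrajectoryState, model: DiabaticModel, dt: float, with_nac: bool = True
) -> ElectronicPoint:
    """Advance nuclei one classical step on the active surface.

    Standard velocity Verlet with the Hellmann-Feynman force of the active
    adiabatic state; updates ``state.R``, ``state.v`` and ``state.point`` in
    place and returns the new :class:`ElectronicPoint`.  If the new geometry
    is too close to a degeneracy for the exact-coupling oracle, the point is
    returned without ``h_exact`` (energies and forces are still well defined).
    """
    a0 = -state.point.grad[state.active] / state.masses
    state.R = state.R + state.v * dt + 0.5 * a0 * dt**2
    try:
        new_point = adiabatize(
            model, state.R, prev_eigvecs=state.point.eigvecs, with_nac=with_nac
        )
    except DegeneracyError:
        new_point = adiabatize(
            model, state.R, prev_eigvecs=state.point.eigvecs, with_nac=False
        )
    if not np.all(np.isfinite(new_point.grad)):
        raise FloatingPointError(f"non-finite force at R={state.R}")
    a1 = -new_point.grad[state.active] / state.masses
    state.v = state.v + 0.5 * (a0 + a1) * dt
    state.point = new_point
    state.t += dt
    return new_point


def _substep_unitary(E: np.ndarray, sigma: np.ndarray, dtau: float) -> np.ndarray:
    """Propagator exp(-(i diag(E)/hbar + sigma) dtau) for one substep.

    The generator is anti-Hermitian (real antisymmetric sigma, imaginary
    diagonal), so the propagator is exactly unitary.  Two states use a closed
    form; larger systems go through the eigendecomposition of the Hermitian
    matrix H = diag(E) - i hbar sigma.
    """
    n = E.shape[0]
    if n == 2:
        ebar = 0.5 * (E[0] + E[1]) / HBAR
        delta = 0.5 * (E[0] - E[1]) / HBAR
        s = sigma[0, 1]
        omega = math.hypot(delta, s)
        phase = complex(math.cos(ebar * dtau), -math.sin(ebar * dtau))
        if omega == 0.0:
            return phase * np.eye(2, dtype=complex)
        cw = math.cos(omega * dtau)
        sw = math.sin(omega * dtau) / omega
        # H - ebar = delta*sz + s*sy  (Pauli decomposition)
        return phase * np.array(
            [[cw - 1j * sw * delta, -sw * s], [sw * s, cw + 1j * sw * delta]],
            dtype=complex,
        )
    H = np.diag(E.astype(complex) / HBAR) - 1j * sigma
    w, V = np.linalg.eigh(H)
    return (V * np.exp(-1j * w * dtau)) @ V.conj().T


def propagate_quantum(
    c: np.ndarray,
    E_start: np.ndarray,
    E_end: np.ndarray,
    sigma_start: np.ndarray,
    sigma_end: np.ndarray,
    dtau: float,
    dt: float,
) -> np.ndarray:
    """Integrate the electronic coefficients over one classical step.

    Energies and couplings are interpolated linearly to each substep
    midpoint; each substep applies the exactly unitary propagator of the
    frozen interpolated generator, so the norm is conserved to rounding.
    """
    n_sub = round(dt / dtau)
    if n_sub < 1 or abs(dt / dtau - n_sub) > 1e-9:
        raise ValueError("dt/dtau must be a positive integer")
    c = np.asarray(c, dtype=complex).copy()
    for k in range(n_sub):
        f = (k + 0.5) / n_sub
        E = E_start + (E_end - E_start) * f
        sigma = sigma_start + (sigma_end - sigma_start) * f
        c = _substep_unitary(E, sigma, dtau) @ c
    return c


def hop_probability(
    c: np.ndarray, sigma: np.ndarray, L: int, J: int, dtau: float
) -> float:
    """Fewest-switches probability of hopping from active L to J at one substep.

    ``P = max[0, -(2 dtau / |c_L|^2) sigma_JL Re(c_J c_L*)]``, the
    coefficient-flux form: under the propagation equation the population flux
    out of the active state L into J is ``-2 sigma_JL Re(c_J c_L*) |...``, so
    P equals the fraction of the active population leaving toward J during
    the substep (clamped to [0, 1]).
    """
    pop_L = abs(c[L]) ** 2
    if pop_L < 1e-12:
        logger.warning("active-state population below 1e-12; hop probability set to 0")
        return 0.0
    p = -(2.0 * dtau / pop_L) * sigma[J, L] * (c[J] * np.conj(c[L])).real
    return min(max(p, 0.0), 1.0)


def attempt_hop(
    active: int, probabilities: dict[int, float], rng: np.random.Generator
) -> int | None:
    """Select a hop target from one uniform draw over cumulative intervals.

    Targets are examined in ascending state index; returns the selected
    target or None.  If the probabilities sum above 1 they are renormalized
    (with a warning) before the draw.
    """
    total = sum(probabilities.values())
    scale = 1.0
    if total > 1.0:
        logger.warning("hop probabilities sum to %.3f > 1; renormalizing", total)
        scale = 1.0 / total
    r = rng.random()
    acc = 0.0
    for J in sorted(probabilities):
        acc += probabilities[J] * scale
        if r < acc:
            return J
    return None


def rescale_velocity_p(
    v: np.ndarray, masses: np.ndarray, E_from: float, E_to: float
) -> tuple[np.ndarray, bool]:
    """Rescale the velocity along the linear momentum after a hop.

    ``v' = gamma v`` with ``gamma = sqrt(1 + 2 (E_from - E_to) / sum(m v^2))``
    conserves total energy exactly.  A negative radicand (not enough kinetic
    energy for an upward hop) frustrates the hop: ``(v, False)`` is returned
    unchanged.
    """
    two_ke = float(np.sum(masses * v**2))
    dE = E_from - E_to
    if dE == 0.0:
        return v, True
    if two_ke <= 0.0:
        return v, False
    radicand = 1.0 + 2.0 * dE / two_ke
    if radicand < 0.0:
        return v, False
    return math.sqrt(radicand) * v, True


def rescale_velocity_h(
    v: np.ndarray,
    masses: np.ndarray,
    h_vec: np.ndarray,
    E_from: float,
    E_to: float,
) -> tuple[np.ndarray, bool]:
    """Rescale the velocity along an exact coupling vector after a hop.

    Solves ``v' = v + gamma h/m`` with gamma from exact energy conservation,
    taking the root of smaller magnitude; only available to oracle runs,
    since TD-BA never produces the **h** direction.
    """
    a = 0.5 * float(np.sum(h_vec**2 / masses))
    b = float(np.sum(v * h_vec))
    dE = E_from - E_to
    if a == 0.0:
        return (v, True) if dE == 0.0 else (v, False)
    disc = b * b + 4.0 * a * dE
    if disc < 0.0:
        return v, False
    root = math.sqrt(disc)
    g1 = (-b + root) / (2 * a)
    g2 = (-b - root) / (2 * a)
    gamma = g1 if abs(g1) <= abs(g2) else g2
    return v + gamma * h_vec / masses, True


def apply_decoherence(
    c: np.ndarray,
    active: int,
    E: np.ndarray,
    kinetic_energy: float,
    dt: float,
    alpha: float = 0.1,
) -> np.ndarray:
    """Simplified decay of mixing.

    Inactive coefficients decay as ``exp(-dt/tau_J)`` with
    ``tau_J = (hbar/|E_J - E_M|) (1 + alpha/E_kin)``; the active coefficient
    is rescaled to restore the norm.  Zero kinetic energy means an infinite
    decay time (no decay, with a warning); a degenerate pair never decays.
    """
    c = np.asarray(c, dtype=complex).copy()
    if kinetic_energy <= 0.0:
        logger.warning("zero kinetic energy: decoherence times infinite, no decay")
        return c
    factor = 1.0 + alpha / kinetic_energy
    for J in range(len(c)):
        if J == active:
            continue
        gap = abs(E[J] - E[active])
        if gap == 0.0:
            continue
        tau = HBAR / gap * factor
        c[J] *= math.exp(-dt / tau)
    inactive = sum(abs(c[J]) ** 2 for J in range(len(c)) if J != active)
    pop_M = abs(c[active]) ** 2
    if pop_M < 1e-300:
        norm = math.sqrt(inactive + pop_M)
        return c / norm
    c[active] *= math.sqrt(max(1.0 - inactive, 0.0) / pop_M)
    return c


# ---------------------------------------------------------------------------
# trajectory driver
# ---------------------------------------------------------------------------

def _pair_order(n_states: int) -> list[tuple[int, int]]:
    return [(j, l) for j in range(n_states) for l in range(j)]


def _exact_sigma(point: ElectronicPoint, v: np.ndarray, n: int) -> np.ndarray:
    """Exact time-derivative couplings v.h, NaN-filled on degeneracy."""
    if point.h_exact is None:
        return np.full((n, n), np.nan)
    return np.einsum("jld,d->jl", point.h_exact, v)


def run_trajectory(
    model: DiabaticModel,
    R0: np.ndarray,
    v0: np.ndarray,
    active0: int,
    settings: FsshSettings,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    c0: np.ndarray | None = None,
    stop_condition=None,
) -> TrajectoryLog:
    """Propagate one DC-FSSH trajectory.

    Per classical step: velocity-Verlet nuclear update, new electronic point,
    coupling evaluation (TD-BA estimate and, when the oracle permits, exact
    ``v . h``), quantum substeps with a per-substep hop test, then the
    decoherence correction.  Identical (model, initial conditions, settings,
    seed) give bit-identical logs.

    ``stop_condition(state)`` may end the trajectory early (e.g. once a
    scattering trajectory leaves the interaction region).  A total-energy
    drift beyond 1e-3 hartree between hops flags the trajectory rather than
    silently keeping it.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    n = model.n_states
    dt, dtau, n_sub = settings.dt_au, settings.dtau_au, settings.n_substeps
    use_exact = settings.coupling_source == "exact"

    R0 = np.asarray(R0, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    if c0 is None:
        c = np.zeros(n, dtype=complex)
        c[active0] = 1.0
    else:
        c = np.asarray(c0, dtype=complex).copy()
        c /= math.sqrt(float(np.sum(np.abs(c) ** 2)))

    try:
        point = adiabatize(model, R0, with_nac=True)
        exact_ok = True
    except DegeneracyError:
        point = adiabatize(model, R0, with_nac=False)
        exact_ok = False
        if use_exact:
            raise

    tdba_window = (
        settings.tdba.n_points(dt)
        if settings.tdba.scheme is Scheme.QUADRATIC_REGRESSION
        else 4
    )
    history = GapHistory(n_states=n, max_len=max(4, tdba_window))
    # gaps accumulate from the first classical step on: the coupling is null
    # during the first two steps and is first computed at the third

    state = TrajectoryState(
        t=0.0, R=R0.copy(), v=v0.copy(), masses=model.masses, active=active0,
        c=c, point=point, rng=rng, gap_history=history,
        sigma_drive=np.zeros((n, n)),
    )

    n_steps = int(round(settings.t_max_fs * FS_TO_AU / dt))
    pairs = _pair_order(n)

    times, energies, actives, pops = [], [], [], []
    sig_tdba_rows, sig_exact_rows, etot_rows = [], [], []
    hops: list[HopEvent] = []
    flagged = False

    def log_row(sig_tdba: np.ndarray, sig_exact: np.ndarray) -> None:
        times.append(state.t / FS_TO_AU)
        energies.append(state.point.E.copy())
        actives.append(state.active)
        pops.append(np.abs(state.c) ** 2)
        sig_tdba_rows.append([sig_tdba[p] for p in pairs])
        sig_exact_rows.append([sig_exact[p] for p in pairs])
        etot_rows.append(state.total_energy())

    sigma_exact_now = _exact_sigma(state.point, state.v, n) if exact_ok else np.full((n, n), np.nan)
    log_row(np.zeros((n, n)), sigma_exact_now)
    e_ref = state.total_energy()

    for _ in range(n_steps):
        E_old = state.point.E.copy()
        sigma_old = state.sigma_drive.copy()
        velocity_verlet_step(state, model, dt, with_nac=True)
        exact_ok = state.point.h_exact is not None
        if use_exact and not exact_ok:
            raise DegeneracyError(
                f"exact-coupling run hit a degeneracy at R={state.R}"
            )

        state.gap_history.push(state.point.E)
        tdba_est = estimate_couplings(
            state.gap_history, settings.tdba, dt, state.tdba_previous
        )
        state.tdba_previous = tdba_est
        sigma_exact_new = (
            _exact_sigma(state.point, state.v, n) if exact_ok else np.full((n, n), np.nan)
        )
        if use_exact:
            sigma_new = np.nan_to_num(sigma_exact_new)
        else:
            sigma_new = tdba_est.sigma
        E_new = state.point.E

        # quantum substeps with per-substep hop tests
        k = 0
        while k < n_sub:
            f = (k + 0.5) / n_sub
            E_k = E_old + (E_new - E_old) * f
            sigma_k = sigma_old + (sigma_new - sigma_old) * f
            state.c = _substep_unitary(E_k, sigma_k, dtau) @ state.c
            probs = {
                J: hop_probability(state.c, sigma_k, state.active, J, dtau)
                for J in range(n)
                if J != state.active
            }
            target = attempt_hop(state.active, probs, state.rng)
            if target is not None:
                # rescale against the surfaces at the actual current geometry,
                # so the switch conserves total energy exactly
                e_from = float(E_new[state.active])
                e_to = float(E_new[target])
                if settings.rescale_direction == "h":
                    h_vec = state.point.h_exact[state.active, target]
                    v_new, ok = rescale_velocity_h(
                        state.v, state.masses, h_vec, e_from, e_to
                    )
                else:
                    v_new, ok = rescale_velocity_p(
                        state.v, state.masses, e_from, e_to
                    )
                hops.append(
                    HopEvent(
                        time_fs=state.t / FS_TO_AU,
                        from_state=state.active,
                        to_state=target,
                        gap_ev=abs(e_to - e_from) * HARTREE_TO_EV,
                        outcome="accepted" if ok else "frustrated",
                        R=state.R.copy(),
                    )
                )
                if ok:
                    state.v = v_new
                    state.active = target
                    # TD-BA restarts from scratch after any hop
                    state.gap_history.reset()
                    state.tdba_previous = None
                    if use_exact:
                        sigma_exact_new = _exact_sigma(state.point, state.v, n)
                        sigma_new = np.nan_to_num(sigma_exact_new)
                        sigma_old = sigma_new.copy()
                    else:
                        sigma_new = np.zeros((n, n))
                        sigma_old = np.zeros((n, n))
                        tdba_est = CouplingEstimate.zeros(n, Provenance.ZEROED_WARMUP)
                    e_ref = state.total_energy()
            k += 1

        if settings.decoherence_alpha is not None:
            state.c = apply_decoherence(
                state.c, state.active, E_new, state.kinetic_energy(), dt,
                settings.decoherence_alpha,
            )
        norm = float(np.sum(np.abs(state.c) ** 2))
        if abs(norm - 1.0) > NORM_TOL:
            raise FloatingPointError(
                f"electronic norm drifted to {norm} at t={state.t / FS_TO_AU:.3f} fs"
            )

        state.sigma_drive = sigma_new
        log_row(tdba_est.sigma, sigma_exact_new)

        if abs(state.total_energy() - e_ref) > ENERGY_DRIFT_TOL:
            flagged = True
            logger.warning(
                "total energy drifted by %.2e hartree at t=%.2f fs; trajectory flagged",
                state.total_energy() - e_ref, state.t / FS_TO_AU,
            )
        if stop_condition is not None and stop_condition(state):
            break

    def pair_cols(rows):
        return np.array(rows).reshape(len(rows), len(pairs))

    return TrajectoryLog(
        time_fs=np.array(times),
        energies=np.array(energies),
        active=np.array(actives, dtype=int),
        coeff_pops=np.array(pops),
        sigma_tdba=pair_cols(sig_tdba_rows),
        sigma_exact=pair_cols(sig_exact_rows),
        total_energy=np.array(etot_rows),
        pair_order=pairs,
        hops=hops,
        flagged=flagged,
        n_states=n,
    )


def run_adiabatic_trajectory(
    model: DiabaticModel,
    R0: np.ndarray,
    v0: np.ndarray,
    surface: int,
    dt_fs: float,
    n_steps: int,
    tdba: TdbaSettings | None = None,
) -> dict:
    """Classical trajectory pinned to one adiabatic surface (no hopping).

    A diagnostic driver for coupling studies: nuclei follow velocity Verlet
    on ``surface`` while the TD-BA estimate and the exact ``v . h`` are
    recorded side by side at every classical step.  Returns a dict of arrays
    ``time_fs, R, v, E, sigma_tdba, sigma_exact`` (couplings for each ordered
    pair, columns in ``pair_order``).
    """
    if tdba is None:
        tdba = TdbaSettings()
    dt = dt_fs * FS_TO_AU
    n = model.n_states
    point = adiabatize(model, np.asarray(R0, dtype=float))
    window = tdba.n_points(dt) if tdba.scheme is Scheme.QUADRATIC_REGRESSION else 4
    history = GapHistory(n_states=n, max_len=max(4, window))
    state = TrajectoryState(
        t=0.0, R=np.asarray(R0, dtype=float).copy(),
        v=np.asarray(v0, dtype=float).copy(), masses=model.masses,
        active=surface, c=np.eye(n, dtype=complex)[surface], point=point,
        rng=np.random.default_rng(0), gap_history=history,
        sigma_drive=np.zeros((n, n)),
    )
    pairs = _pair_order(n)
    rows = {k: [] for k in ("time_fs", "R", "v", "E", "sigma_tdba", "sigma_exact")}
    previous: CouplingEstimate | None = None

    def log() -> None:
        est = estimate_couplings(history, tdba, dt, previous)
        sig_ex = _exact_sigma(state.point, state.v, n)
        rows["time_fs"].append(state.t / FS_TO_AU)
        rows["R"].append(state.R.copy())
        rows["v"].append(state.v.copy())
        rows["E"].append(state.point.E.copy())
        rows["sigma_tdba"].append([est.sigma[p] for p in pairs])
        rows["sigma_exact"].append([sig_ex[p] for p in pairs])
        return est

    previous = log()
    for _ in range(n_steps):
        velocity_verlet_step(state, model, dt)
        history.push(state.point.E)
        previous = log()
    out = {k: np.asarray(v) for k, v in rows.items()}
    out["pair_order"] = pairs
    return out


def derive_rng(master_seed: int, index: int) -> np.random.Generator:
    """Deterministic per-trajectory RNG stream.

    Built from ``SeedSequence((master_seed, index))`` — a stable hash of the
    master seed and the global trajectory index, so split runs that preserve
    indices reproduce a single larger run exactly.
    """
    return np.random.default_rng(np.random.SeedSequence((master_seed, index)))


def run_ensemble(
    model: DiabaticModel,
    initial_conditions,
    settings: FsshSettings,
    master_seed: int,
    index_offset: int = 0,
    stop_condition=None,
) -> list[TrajectoryLog]:
    """Run one trajectory per initial condition with derived seeds.

    ``initial_conditions`` is an iterable of ``(R0, v0, active0)`` tuples;
    trajectory ``i`` uses the RNG stream ``derive_rng(master_seed,
    index_offset + i)``.
    """
    logs = []
    for i, (R0, v0, active0) in enumerate(initial_conditions):
        rng = derive_rng(master_seed, index_offset + i)
        log = run_trajectory(
            model, R0, v0, active0, settings, seed=rng,
            stop_condition=stop_condition,
        )
        log.seed_label = f"{master_seed}:{index_offset + i}"
        logs.append(log)
    return logs
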