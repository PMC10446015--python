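"""Time-dependent Baeck-An (TD-BA) coupling estimator.

The TD-BA approximation rewrites the Baeck-An spatial coupling model in the
time domain: along a trajectory the only inputs are the adiabatic energy gap
``dE_JL(t) = E_J - E_L`` and its second time derivative, and the
time-derivative coupling is

    sigma_JL = sgn(dE) * (1/2) * sqrt( (1/dE) d2(dE)/dt2 )   if the argument > 0
    sigma_JL = 0                                             otherwise

All references to the (unknown) coupling coordinate cancel, which is what
makes the estimator usable with any electronic-structure method that yields
energies.  The second time derivative can be taken by backward finite
differences — an O(dt) three-point stencil at the third step, an O(dt^2)
four-point stencil from the fourth step on — or analytically as ``2a`` from a
quadratic regression ``dE ~= a t^2 + b t + c`` over a sliding window ``dT``.

Raw estimates pass through three optional "cleaning" conditions that damp
artifacts of small discontinuities in the potential surfaces:

1. rate limit ``deta``  — if ``(|sigma(t)| - |sigma(t-dt)|)/dt > deta``, keep
   the previous coupling;
2. gap ceiling ``deps`` — zero the coupling when ``|dE| > deps``;
3. product ceiling ``dpi`` — zero it when ``|dE * d2|`` is anomalously large.

During the first two classical steps of a trajectory and after every accepted
hop the coupling is defined to be null while the gap buffer refills.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .units import EV_TO_HARTREE, FS_TO_AU
from .model_potentials import DegeneracyError

__all__ = [
    "Scheme",
    "Provenance",
    "TdbaSettings",
    "GapHistory",
    "CouplingEstimate",
    "InsufficientHistoryError",
    "second_time_derivative",
    "tdba_sigma",
    "apply_cleaning",
    "estimate_couplings",
    "couplings_from_table",
]


class Scheme(str, enum.Enum):
    """Second-time-derivative scheme."""

    FD_FIRST_ORDER = "fd_first_order"
    FD_SECOND_ORDER = "fd_second_order"
    QUADRATIC_REGRESSION = "quadratic_regression"


class Provenance(str, enum.Enum):
    """How one pair's coupling at one step was obtained."""

    COMPUTED = "computed"
    ZEROED_NEGATIVE_ARGUMENT = "zeroed_negative_argument"
    ZEROED_WARMUP = "zeroed_warmup"
    HELD_PREVIOUS = "held_previous"
    ZEROED_GAP = "zeroed_gap"
    ZEROED_PRODUCT = "zeroed_product"


class InsufficientHistoryError(RuntimeError):
    """Signals that the gap buffer is still warming up."""


@dataclass
class TdbaSettings:
    """TD-BA estimator parameters.

    Defaults mirror the production setup: quadratic regression over
    ``dT = 0.4 fs`` with the rate limit ``deta = 0.1 au`` enabled and the gap
    and product conditions disabled.  ``deps`` is stored in eV (the natural
    unit for electronic gaps) and converted internally; ``deta`` and ``dpi``
    are atomic-unit quantities.
    """

    scheme: Scheme = Scheme.QUADRATIC_REGRESSION
    dT_fs: float = 0.4  # regression window (fs)
    deta: float = 0.1  # max |sigma| growth rate (1/t^2, atomic units)
    deps_ev: float = 12.0  # max gap for nonzero coupling (eV)
    dpi: float = 0.01  # max |dE * d2(dE)/dt2| (atomic units)
    eta_enabled: bool = True
    eps_enabled: bool = False
    pi_enabled: bool = False

    def __post_init__(self) -> None:
        self.scheme = Scheme(self.scheme)
        if self.eta_enabled and self.deta <= 0:
            raise ValueError("deta must be positive when the rate condition is on")
        if self.eps_enabled and self.deps_ev <= 0:
            raise ValueError("deps_ev must be positive when the gap condition is on")
        if self.pi_enabled and self.dpi <= 0:
            raise ValueError("dpi must be positive when the product condition is on")
        if self.scheme is Scheme.QUADRATIC_REGRESSION and self.dT_fs <= 0:
            raise ValueError("dT_fs must be positive for quadratic regression")

    def n_points(self, dt_au: float) -> int:
        """Regression window length N_p = dT/dt, at least 3 points."""
        np_ = int(round(self.dT_fs * FS_TO_AU / dt_au))
        if self.scheme is Scheme.QUADRATIC_REGRESSION and np_ < 3:
            raise ValueError(
                f"regression window dT={self.dT_fs} fs holds fewer than 3 points "
                f"at dt={dt_au / FS_TO_AU} fs"
            )
        return np_

    @property
    def deps_au(self) -> float:
        return self.deps_ev * EV_TO_HARTREE


@dataclass
class GapHistory:
    """Ring buffer of signed energy gaps per ordered state pair (J > L).

    One gap is pushed per classical step at uniform spacing ``dt``; the
    buffer is cleared at trajectory start and at every accepted hop, which
    restarts the TD-BA warmup.
    """

    n_states: int
    max_len: int
    _gaps: dict[tuple[int, int], list[float]] = field(default_factory=dict)
    steps: int = 0  # gaps pushed since last reset

    def __post_init__(self) -> None:
        self.reset()

    def pairs(self) -> list[tuple[int, int]]:
        return [(j, l) for j in range(self.n_states) for l in range(j)]

    def reset(self) -> None:
        self._gaps = {p: [] for p in self.pairs()}
        self.steps = 0

    def push(self, energies: np.ndarray) -> None:
        for (j, l), buf in self._gaps.items():
            buf.append(float(energies[j] - energies[l]))
            if len(buf) > self.max_len:
                del buf[0]
        self.steps += 1

    def gaps(self, pair: tuple[int, int]) -> list[float]:
        """Stored gaps for a pair, oldest first."""
        return self._gaps[pair]


@dataclass
class CouplingEstimate:
    """Antisymmetric coupling matrix plus per-pair provenance."""

    sigma: np.ndarray  # (n_states, n_states), sigma[J, L] = -sigma[L, J]
    flags: dict[tuple[int, int], Provenance]  # keyed by (J, L) with J > L
    d2: dict[tuple[int, int], float] = field(default_factory=dict)

    @staticmethod
    def zeros(n_states: int, flag: Provenance) -> "CouplingEstimate":
        flags = {(j, l): flag for j in range(n_states) for l in range(j)}
        return CouplingEstimate(np.zeros((n_states, n_states)), flags)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def second_time_derivative(
    gaps: list[float] | np.ndarray,
    scheme: Scheme,
    dt: float,
    n_points: int | None = None,
) -> float:
    """Second time derivative of a gap series sampled at spacing ``dt``.

    ``gaps`` is ordered oldest to newest; the derivative refers to the newest
    point.  Backward stencils:

    * ``fd_first_order`` (3 points):  ``[dE(t) - 2 dE(t-dt) + dE(t-2dt)] / dt^2``
    * ``fd_second_order`` (4 points): ``[2 dE(t) - 5 dE(t-dt) + 4 dE(t-2dt) - dE(t-3dt)] / dt^2``
    * ``quadratic_regression``: ``2a`` from the least-squares quadratic over
      the last ``n_points`` points (fewer are used while the buffer grows,
      with a minimum of 3).

    Raises :class:`InsufficientHistoryError` while the buffer is too short —
    the caller must treat the coupling as null during this warmup.
    """
    scheme = Scheme(scheme)
    g = np.asarray(gaps, dtype=float)
    n = g.shape[0]
    if scheme is Scheme.FD_FIRST_ORDER:
        if n < 3:
            raise InsufficientHistoryError("need 3 gap points")
        return (g[-1] - 2 * g[-2] + g[-3]) / dt**2
    if scheme is Scheme.FD_SECOND_ORDER:
        if n < 4:
            raise InsufficientHistoryError("need 4 gap points")
        return (2 * g[-1] - 5 * g[-2] + 4 * g[-3] - g[-4]) / dt**2
    # quadratic regression
    if n_points is None:
        n_points = n
    use = min(n, n_points)
    if use < 3:
        raise InsufficientHistoryError("need at least 3 gap points for regression")
    y = g[-use:]
    # time origin at the newest point: 2a is invariant, conditioning is not
    t = dt * np.arange(-use + 1, 1)
    a = np.polynomial.polynomial.polyfit(t, y, 2)[2]
    return 2.0 * a


def tdba_sigma(dE: float, d2: float) -> float:
    """TD-BA time-derivative coupling from a gap and its second derivative.

    ``sigma = sgn(dE) * 0.5 * sqrt(d2 / dE)`` when the square-root argument is
    positive (the signature of an approach to a gap minimum); zero otherwise.
    """
    if dE == 0.0:
        raise DegeneracyError("TD-BA coupling undefined at zero energy gap")
    arg = d2 / dE
    if arg > 0.0:
        return math.copysign(0.5 * math.sqrt(arg), dE)
    return 0.0


def apply_cleaning(
    sigma_raw: float,
    sigma_prev: float,
    dE: float,
    d2: float,
    settings: TdbaSettings,
    dt: float,
) -> tuple[float, Provenance]:
    """Apply the enabled cleaning conditions to one raw coupling.

    Conditions are tested in order — rate limit, gap ceiling, product
    ceiling — and the first one triggered wins.  ``sigma_prev`` is the
    previous *cleaned* value (the one the dynamics actually consumed); the
    output is always one of ``sigma_raw``, ``sigma_prev`` or 0.
    """
    if settings.eta_enabled and (abs(sigma_raw) - abs(sigma_prev)) / dt > settings.deta:
        return sigma_prev, Provenance.HELD_PREVIOUS
    if settings.eps_enabled and abs(dE) > settings.deps_au:
        return 0.0, Provenance.ZEROED_GAP
    if settings.pi_enabled and abs(dE * d2) > settings.dpi:
        return 0.0, Provenance.ZEROED_PRODUCT
    flag = (
        Provenance.COMPUTED if sigma_raw != 0.0 else Provenance.ZEROED_NEGATIVE_ARGUMENT
    )
    return sigma_raw, flag


def estimate_couplings(
    history: GapHistory,
    settings: TdbaSettings,
    dt: float,
    previous: CouplingEstimate | None = None,
) -> CouplingEstimate:
    """Full TD-BA coupling matrix for the current classical step.

    Dispatches the derivative scheme per pair, applies the sign/zero rule and
    the cleaning conditions, and completes the matrix antisymmetrically.
    While fewer than three gaps are buffered (trajectory start or just after
    a hop) every pair is zero with the ``zeroed_warmup`` flag.  With the
    finite-difference schemes the stencil escalates: the O(dt) three-point
    formula at the third step, the O(dt^2) four-point formula from the fourth
    step on.
    """
    n = history.n_states
    if history.steps < 3:
        return CouplingEstimate.zeros(n, Provenance.ZEROED_WARMUP)

    n_points = (
        settings.n_points(dt)
        if settings.scheme is Scheme.QUADRATIC_REGRESSION
        else None
    )
    sigma = np.zeros((n, n))
    flags: dict[tuple[int, int], Provenance] = {}
    d2s: dict[tuple[int, int], float] = {}
    for pair in history.pairs():
        gaps = history.gaps(pair)
        dE = gaps[-1]
        scheme = settings.scheme
        if scheme is Scheme.FD_SECOND_ORDER and history.steps == 3:
            scheme = Scheme.FD_FIRST_ORDER  # four-point stencil needs a 4th step
        d2 = second_time_derivative(gaps, scheme, dt, n_points)
        raw = tdba_sigma(dE, d2)
        prev = 0.0 if previous is None else float(previous.sigma[pair])
        val, flag = apply_cleaning(raw, prev, dE, d2, settings, dt)
        j, l = pair
        sigma[j, l] = val
        sigma[l, j] = -val
        flags[pair] = flag
        d2s[pair] = d2
    return CouplingEstimate(sigma, flags, d2s)


# ---------------------------------------------------------------------------
# standalone post-processor
# ---------------------------------------------------------------------------

def couplings_from_table(
    times_fs: np.ndarray,
    energies: np.ndarray,
    settings: TdbaSettings | None = None,
):
    """TD-BA couplings for a logged (time, energies) table.

    ``times_fs`` is a uniform grid in fs; ``energies`` has one column per
    state (hartree).  Returns a :class:`pandas.DataFrame` with, per state
    pair, the signed coupling ``sigma_J_L`` (1/atomic-time) and its
    provenance flag.  Hop times are unknown to the post-processor, so only
    the start-of-series warmup applies.
    """
    import pandas as pd

    if settings is None:
        settings = TdbaSettings()
    times_fs = np.asarray(times_fs, dtype=float)
    energies = np.atleast_2d(np.asarray(energies, dtype=float))
    if energies.shape[0] != times_fs.shape[0]:
        raise ValueError("times and energies must have the same number of rows")
    steps = np.diff(times_fs)
    if steps.size == 0:
        raise ValueError("need at least two time points")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
        raise ValueError("time grid must be uniform")
    dt = steps[0] * FS_TO_AU

    n_states = energies.shape[1]
    max_len = max(4, settings.n_points(dt) if settings.scheme is Scheme.QUADRATIC_REGRESSION else 4)
    history = GapHistory(n_states=n_states, max_len=max_len)
    rows = []
    previous: CouplingEstimate | None = None
    for k in range(times_fs.shape[0]):
        history.push(energies[k])
        est = estimate_couplings(history, settings, dt, previous)
        previous = est
        row: dict[str, float | str] = {"time_fs": times_fs[k]}
        for (j, l) in history.pairs():
            row[f"sigma_{j}_{l}"] = est.sigma[j, l]
            row[f"flag_{j}_{l}"] = est.flags[(j, l)].value
        rows.append(row)
    return pd.DataFrame(rows)
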