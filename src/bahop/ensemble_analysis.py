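"""Ensemble reduction: populations, lifetimes, hop statistics, coupling RMSD,
overlap scores and geometric hop classification.

The observables mirror standard surface-hopping analysis practice:

* classical adiabatic populations — the fraction of trajectories on each
  active surface per time point (mean ``|c_J|^2`` is also available as an
  internal-consistency diagnostic);
* excited-state lifetimes from exponential fits, with 95% confidence
  intervals from a percentile bootstrap over trajectories;
* per-transition hop counts and energy-gap statistics;
* the pooled RMSD between estimated and exact coupling magnitudes,
  ``sqrt( (1/N) sum_traj sum_t (|sigma| - |sigma_hat|)^2 )``;
* the overlap score ``lambda`` between two (mean, 95% CI) observables — the
  product of each Gaussian's probability mass over the intersection of the
  two confidence intervals, normalized by the squared confidence level — and
  its ensemble mean ``Lambda``;
* the mean torsional angle around an exocyclic C-CH2 bond and the
  Planar / Twisted-stretched / Twisted-shrunk classification of hop
  geometries on the crossing seam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fssh_engine import HopEvent, TrajectoryLog

__all__ = [
    "Observable",
    "PopulationCurve",
    "populations",
    "coefficient_populations",
    "fit_decay",
    "bootstrap_ci",
    "rmsd_couplings",
    "hop_statistics",
    "overlap_score",
    "mean_overlap",
    "read_xyz",
    "dihedral_angle",
    "mean_torsion",
    "classify_hop_region",
]


@dataclass
class Observable:
    """A scalar observable with the halfwidth of its 95% confidence interval."""

    name: str
    mean: float
    halfwidth: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.halfwidth < 0:
            raise ValueError("CI halfwidth must be non-negative")


@dataclass
class PopulationCurve:
    """Per-state fraction of trajectories on each surface over time."""

    time_fs: np.ndarray
    fractions: np.ndarray  # (n_times, n_states), rows sum to 1
    ci_halfwidth: np.ndarray | None = None


def _active_matrix(logs: Sequence[TrajectoryLog]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-trajectory active-state series on the common time grid.

    Trajectories of different length are truncated explicitly to the
    shortest grid.
    """
    if not logs:
        raise ValueError("empty ensemble")
    n_t = min(len(log.time_fs) for log in logs)
    time_fs = logs[0].time_fs[:n_t]
    active = np.stack([log.active[:n_t] for log in logs])
    return time_fs, active


def populations(logs: Sequence[TrajectoryLog]) -> PopulationCurve:
    """Classical adiabatic populations: fraction of trajectories per surface."""
    time_fs, active = _active_matrix(logs)
    n_states = max(log.n_states for log in logs)
    fractions = np.stack(
        [np.mean(active == s, axis=0) for s in range(n_states)], axis=1
    )
    return PopulationCurve(time_fs=time_fs, fractions=fractions)


def coefficient_populations(logs: Sequence[TrajectoryLog]) -> PopulationCurve:
    """Mean ``|c_J|^2`` — the internal-consistency companion to `populations`."""
    if not logs:
        raise ValueError("empty ensemble")
    n_t = min(len(log.time_fs) for log in logs)
    pops = np.mean(np.stack([log.coeff_pops[:n_t] for log in logs]), axis=0)
    return PopulationCurve(time_fs=logs[0].time_fs[:n_t], fractions=pops)


def _fit_tau(
    time_fs: np.ndarray, p: np.ndarray, fit_amplitude: bool, tau0: float
) -> float:
    if fit_amplitude:
        popt, _ = optimize.curve_fit(
            lambda t, tau, a: a * np.exp(-t / tau), time_fs, p,
            p0=(tau0, max(p[0], 1e-3)), maxfev=10000,
        )
    else:
        popt, _ = optimize.curve_fit(
            lambda t, tau: np.exp(-t / tau), time_fs, p, p0=(tau0,), maxfev=10000,
        )
    return float(popt[0])


def fit_decay(
    logs: Sequence[TrajectoryLog],
    state: int,
    fit_amplitude: bool = False,
    n_boot: int = 10_000,
    seed: int = 0,
    confidence: float = 0.95,
) -> Observable:
    """Exponential lifetime of a state's classical population.

    Least-squares fit of ``p(t) = exp(-t/tau)`` (optionally with a fitted
    amplitude) starting at t = 0; the confidence interval comes from a
    percentile bootstrap over trajectories, refitting each resample.
    """
    time_fs, active = _active_matrix(logs)
    p = np.mean(active == state, axis=0)
    if p[-1] >= p[0] or p[0] <= 0:
        raise RuntimeError(f"population of state {state} does not decay; no fit")
    tau0 = max(time_fs[-1] / 3.0, time_fs[1] if len(time_fs) > 1 else 1.0)
    tau = _fit_tau(time_fs, p, fit_amplitude, tau0)

    rng = np.random.default_rng(seed)
    n_traj = active.shape[0]
    taus = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_traj, size=n_traj)
        pb = np.mean(active[idx] == state, axis=0)
        try:
            taus[b] = _fit_tau(time_fs, pb, fit_amplitude, tau)
        except RuntimeError:
            taus[b] = np.nan
    lo, hi = np.nanpercentile(
        taus, [50 * (1 - confidence), 50 * (1 + confidence)]
    )
    return Observable(
        name=f"tau_state_{state}", mean=tau, halfwidth=float((hi - lo) / 2.0),
        units="fs",
    )


def bootstrap_ci(
    values: np.ndarray,
    statistic=np.mean,
    n_rep: int = 10_000,
    seed: int = 0,
    confidence: float = 0.95,
) -> float:
    """Percentile-bootstrap CI halfwidth of a per-trajectory statistic."""
    values = np.asarray(values)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 observations to bootstrap")
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    reps = np.empty(n_rep)
    for b in range(n_rep):
        reps[b] = statistic(values[rng.integers(0, n, size=n)])
    lo, hi = np.percentile(reps, [50 * (1 - confidence), 50 * (1 + confidence)])
    return float((hi - lo) / 2.0)


def rmsd_couplings(
    sigma_series: Sequence[np.ndarray], sigma_hat_series: Sequence[np.ndarray]
) -> float:
    """Pooled RMSD between estimated and reference coupling magnitudes.

    ``sqrt( (1/N) sum_traj sum_t (|sigma| - |sigma_hat|)^2 )`` with N the
    total number of timesteps over all trajectories.
    """
    if len(sigma_series) != len(sigma_hat_series):
        raise ValueError("need one reference series per estimated series")
    total = 0.0
    n = 0
    for s, sh in zip(sigma_series, sigma_hat_series):
        s = np.asarray(s, dtype=float)
        sh = np.asarray(sh, dtype=float)
        if s.shape != sh.shape:
            raise ValueError("misaligned coupling series")
        total += float(np.sum((np.abs(s) - np.abs(sh)) ** 2))
        n += s.size
    if n == 0:
        raise ValueError("empty coupling series")
    return math.sqrt(total / n)


def hop_statistics(events: Sequence[HopEvent]) -> pd.DataFrame:
    """Per-transition count and |energy gap| statistics of accepted hops.

    One row per ordered (from, to) pair — upward and downward transitions are
    distinct — with the count, mean absolute gap and population standard
    deviation in eV.
    """
    rows = [
        {"from": e.from_state, "to": e.to_state, "gap_ev": e.gap_ev}
        for e in events
        if e.outcome == "accepted"
    ]
    if not rows:
        return pd.DataFrame(columns=["from", "to", "count", "mean_ev", "std_ev"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["from", "to"], as_index=False)["gap_ev"]
        .agg(count="size", mean_ev="mean", std_ev=lambda g: g.std(ddof=0))
        .sort_values(["from", "to"], ignore_index=True)
    )
    return out


# ---------------------------------------------------------------------------
# overlap scores
# ---------------------------------------------------------------------------

def overlap_score(a: Observable, b: Observable, confidence: float = 0.95) -> float:
    """Probability-of-agreement score lambda between two observables.

    The overlap interval is the intersection of the two confidence intervals
    ``mean +- halfwidth`` (empty intersection gives 0).  Each observable is
    modelled as a Gaussian whose sigma makes its CI carry exactly
    ``confidence`` probability; lambda is the product of the two Gaussian
    masses over the overlap interval, normalized by ``confidence**2`` (the
    largest product the confidence level allows), so identical observables
    score exactly 1.  A zero-halfwidth observable is a point mass: it scores
    1 if its mean lies inside the other's interval and 0 otherwise.
    """
    if a.units != b.units:
        raise ValueError(f"unit mismatch: {a.units!r} vs {b.units!r}")
    # a zero-halfwidth observable is a point mass: agreement is containment
    if a.halfwidth == 0.0 or b.halfwidth == 0.0:
        return float(abs(a.mean - b.mean) <= max(a.halfwidth, b.halfwidth))
    lo = max(a.mean - a.halfwidth, b.mean - b.halfwidth)
    hi = min(a.mean + a.halfwidth, b.mean + b.halfwidth)
    if hi < lo:
        return 0.0
    z = stats.norm.ppf(0.5 + confidence / 2.0)

    def mass(obs: Observable) -> float:
        sigma = obs.halfwidth / z
        return float(
            stats.norm.cdf(hi, obs.mean, sigma) - stats.norm.cdf(lo, obs.mean, sigma)
        )

    return mass(a) * mass(b) / confidence**2


def mean_overlap(
    a: Sequence[Observable], b: Sequence[Observable], confidence: float = 0.95
) -> float:
    """Mean overlap score Lambda over paired observables."""
    if len(a) != len(b) or not a:
        raise ValueError("need equally many observables in both summaries")
    return float(np.mean([overlap_score(x, y, confidence) for x, y in zip(a, b)]))


# ---------------------------------------------------------------------------
# geometric analysis
# ---------------------------------------------------------------------------

def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Read a standard XYZ file; returns (element symbols, coordinates in angstrom)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # element-guessing chatter
        import MDAnalysis as mda

        u = mda.Universe(str(path))
        return list(u.atoms.names), u.atoms.positions.astype(float)


def dihedral_angle(coords: np.ndarray, atoms: Sequence[int]) -> float:
    """Signed dihedral (degrees, in (-180, 180]) for four 0-based atom indices."""
    from MDAnalysis.lib.distances import calc_dihedrals

    i, j, k, l = atoms
    phi = math.degrees(
        float(calc_dihedrals(coords[i], coords[j], coords[k], coords[l]))
    )
    if math.isnan(phi):
        raise ValueError(f"undefined dihedral for atoms {atoms} (collinear?)")
    return _fold_deg(phi)


def _fold_deg(angle: float) -> float:
    """Fold an angle in degrees to (-180, 180]."""
    a = math.fmod(angle, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def mean_torsion(
    coords: np.ndarray, dihedral_specs: Sequence[Sequence[int]]
) -> float:
    """Mean torsional angle around an exocyclic C=CH2 bond (degrees).

    ``phi = (1/4) [ |phi_cis1| + |phi_cis2| + |180 - phi_trans1|
    + |180 - phi_trans2| ]`` over four dihedrals given as 0-based 4-atom
    index tuples in the order (cis1, cis2, trans1, trans2); each ``180 -
    phi`` is folded back to (-180, 180] before taking the absolute value.
    Planar geometries give 0, a 90-degree twist gives 90.
    """
    if len(dihedral_specs) != 4:
        raise ValueError("need exactly four dihedral specs (cis1, cis2, trans1, trans2)")
    phis = [dihedral_angle(coords, spec) for spec in dihedral_specs]
    return 0.25 * (
        abs(phis[0])
        + abs(phis[1])
        + abs(_fold_deg(180.0 - phis[2]))
        + abs(_fold_deg(180.0 - phis[3]))
    )


def classify_hop_region(phi_deg: float, d_angstrom: float) -> str:
    """Classify a hop geometry on the torsion x C-CH2-distance plane.

    Planar: mean torsion < 30 degrees.  Twisted-stretched: torsion >= 30 and
    distance >= 1.55 angstrom.  Twisted-shrunk: torsion >= 30 and distance
    < 1.55 angstrom.  Boundary values fall on the twisted / stretched side.
    """
    if not 0.0 <= phi_deg <= 90.0:
        raise ValueError("mean torsion must lie in [0, 90] degrees")
    if d_angstrom <= 0:
        raise ValueError("distance must be positive")
    if phi_deg < 30.0:
        return "Planar"
    return "Twisted-stretched" if d_angstrom >= 1.55 else "Twisted-shrunk"
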