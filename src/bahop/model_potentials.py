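"""Analytic diabatic model potentials and the exact-coupling oracle.

A :class:`DiabaticModel` is a symmetric matrix of multivariate polynomials
``V(R)`` (hartree, coordinates in bohr) together with per-coordinate masses.
Diagonalizing ``V(R)`` yields adiabatic energies, Hellmann-Feynman gradients
and — through ``<J|dV/dR|L> / (E_L - E_J)`` — the exact first-order
nonadiabatic coupling vectors ``h_JL``.  Projected on a nuclear velocity these
give the exact time-derivative couplings ``sigma_JL = v . h_JL``, which serve
as the validation oracle for the time-dependent Baeck-An estimator.

Two constructors cover the analytic systems used throughout:

* :func:`ba_model_1d` — a one-dimensional linear crossing (diabats
  ``+-kappa (Q - Qc)`` coupled by a constant ``Delta_c / 2``) whose exact
  coupling is, by construction, a Lorentzian of half-gap ``Delta_c / 2`` and
  slope ``kappa``, peaking at ``kappa / Delta_c``.
* :func:`lvc_model` — a linear vibronic coupling model: harmonic diagonal
  plus linear tuning terms, linear off-diagonal coupling terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DegeneracyError",
    "InvalidModelError",
    "Polynomial",
    "DiabaticModel",
    "ElectronicPoint",
    "adiabatize",
    "exact_nac",
    "ba_model_1d",
    "ba_lorentzian",
    "spatial_ba_coupling",
    "lvc_model",
]

#: adiabatic gap (hartree) below which exact couplings are refused
DEGENERACY_TOL = 1e-10


class DegeneracyError(ValueError):
    """Raised when an adiabatic gap is below the degeneracy tolerance."""


class InvalidModelError(ValueError):
    """Raised for malformed model definitions or non-finite potentials."""


@dataclass(frozen=True)
class Polynomial:
    """Multivariate polynomial: sum of ``coeff * prod_i Q_i**powers[i]``.

    Values and gradients are analytic, so adiabatic gradients carry no
    finite-difference error into energy-conservation checks.
    """

    coefficients: tuple[float, ...]
    powers: tuple[tuple[int, ...], ...]  # one exponent tuple per term

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.powers):
            raise InvalidModelError("one exponent tuple required per coefficient")
        ndims = {len(p) for p in self.powers}
        if len(ndims) > 1:
            raise InvalidModelError("inconsistent dimensionality across terms")

    @property
    def n_dims(self) -> int:
        return len(self.powers[0]) if self.powers else 0

    def value(self, R: np.ndarray) -> float:
        total = 0.0
        for c, pw in zip(self.coefficients, self.powers):
            term = c
            for x, p in zip(R, pw):
                if p:
                    term *= x**p
            total += term
        return total

    def gradient(self, R: np.ndarray) -> np.ndarray:
        g = np.zeros(len(R))
        for c, pw in zip(self.coefficients, self.powers):
            for d, p in enumerate(pw):
                if p == 0:
                    continue
                term = c * p * R[d] ** (p - 1)
                for dd, q in enumerate(pw):
                    if dd != d and q:
                        term *= R[dd] ** q
                g[d] += term
        return g

    @staticmethod
    def zero(n_dims: int) -> "Polynomial":
        return Polynomial((), ())

    @staticmethod
    def constant(value: float, n_dims: int) -> "Polynomial":
        return Polynomial((value,), ((0,) * n_dims,))


@dataclass(frozen=True)
class DiabaticModel:
    """Symmetric matrix of polynomial diabatic potentials plus masses."""

    n_states: int
    n_dims: int
    masses: np.ndarray
    V_spec: tuple[tuple[Polynomial, ...], ...]  # (n_states, n_states), symmetric

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.n_dims < 1:
            raise InvalidModelError("n_states and n_dims must be positive")
        m = np.asarray(self.masses, dtype=float)
        if m.shape != (self.n_dims,) or np.any(m <= 0):
            raise InvalidModelError("masses must be positive, one per coordinate")
        object.__setattr__(self, "masses", m)
        if len(self.V_spec) != self.n_states or any(
            len(row) != self.n_states for row in self.V_spec
        ):
            raise InvalidModelError("V_spec must be n_states x n_states")
        for j in range(self.n_states):
            for l in range(j):
                if self.V_spec[j][l] is not self.V_spec[l][j]:
                    raise InvalidModelError("V_spec must be symmetric (share elements)")

    def V(self, R: np.ndarray) -> np.ndarray:
        """Diabatic potential matrix at R (hartree)."""
        R = np.asarray(R, dtype=float)
        out = np.empty((self.n_states, self.n_states))
        for j in range(self.n_states):
            for l in range(j + 1):
                out[j, l] = out[l, j] = self.V_spec[j][l].value(R)
        if not np.all(np.isfinite(out)):
            raise InvalidModelError(f"non-finite diabatic potential at R={R}")
        return out

    def dV(self, R: np.ndarray) -> np.ndarray:
        """Gradient of the diabatic matrix, shape (n_states, n_states, n_dims)."""
        R = np.asarray(R, dtype=float)
        out = np.empty((self.n_states, self.n_states, self.n_dims))
        for j in range(self.n_states):
            for l in range(j + 1):
                g = self.V_spec[j][l].gradient(R)
                out[j, l] = out[l, j] = g
        return out


@dataclass
class ElectronicPoint:
    """Adiabatic electronic structure at one geometry.

    ``h_exact[J, L]`` is the exact coupling vector (1/bohr), antisymmetric in
    (J, L) with zero diagonal.  ``sigma_exact`` (1/atomic-time) is filled only
    when a velocity was supplied to :func:`adiabatize`.
    """

    R: np.ndarray
    E: np.ndarray  # (n_states,), ascending
    grad: np.ndarray  # (n_states, n_dims)
    eigvecs: np.ndarray  # columns are adiabatic states in the diabatic basis
    h_exact: np.ndarray | None = None  # (n_states, n_states, n_dims)
    sigma_exact: np.ndarray | None = None  # (n_states, n_states)

    @property
    def n_states(self) -> int:
        return len(self.E)


def adiabatize(
    model: DiabaticModel,
    R: Sequence[float] | np.ndarray,
    prev_eigvecs: np.ndarray | None = None,
    velocity: Sequence[float] | np.ndarray | None = None,
    with_nac: bool = True,
) -> ElectronicPoint:
    """Diagonalize the diabatic matrix at ``R``.

    Energies come out ascending; gradients are Hellmann-Feynman expectation
    values of ``dV/dR``; eigenvector signs are fixed to have non-negative
    overlap with ``prev_eigvecs`` (identity convention on the first call),
    which keeps exact coupling time series smooth along a trajectory.

    With ``with_nac`` the exact coupling vectors are computed as well; this
    raises :class:`DegeneracyError` at near-degenerate geometries, so it can
    be switched off when only energies and gradients are needed.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (model.n_dims,):
        raise InvalidModelError(f"R must have {model.n_dims} entries, got {R.shape}")
    V = model.V(R)
    E, U = np.linalg.eigh(V)  # ascending by construction

    if prev_eigvecs is None:
        prev_eigvecs = np.eye(model.n_states)
    # sign continuity: flip columns whose overlap with the predecessor is negative
    overlaps = np.einsum("ij,ij->j", prev_eigvecs, U)
    U = U * np.where(overlaps < 0, -1.0, 1.0)

    dV = model.dV(R)
    # <J| dV |L> for all pairs, shape (n_states, n_states, n_dims)
    F = np.einsum("ij,jkd,kl->ild", U.T, dV, U)
    grad = np.einsum("jjd->jd", F).copy()

    point = ElectronicPoint(R=R, E=E, grad=grad, eigvecs=U)
    if with_nac:
        n = model.n_states
        h = np.zeros((n, n, model.n_dims))
        for j in range(n):
            for l in range(j + 1, n):
                gap = E[l] - E[j]
                if abs(gap) < DEGENERACY_TOL:
                    raise DegeneracyError(
                        f"states {j} and {l} degenerate at R={R} "
                        f"(gap {gap:.3e} hartree below {DEGENERACY_TOL:.0e})"
                    )
                h[j, l] = F[j, l] / gap
                h[l, j] = -h[j, l]
        point.h_exact = h
        if velocity is not None:
            v = np.asarray(velocity, dtype=float)
            point.sigma_exact = np.einsum("jld,d->jl", h, v)
    return point


def exact_nac(model: DiabaticModel, R: Sequence[float] | np.ndarray,
              prev_eigvecs: np.ndarray | None = None) -> np.ndarray:
    """Exact nonadiabatic coupling vectors ``h_JL`` at ``R`` (1/bohr).

    ``h_JL = <J| dV/dR |L> / (E_L - E_J)`` in the adiabatic basis; the result
    is antisymmetric in (J, L).  Raises :class:`DegeneracyError` when any
    adiabatic gap is below the degeneracy tolerance.
    """
    return adiabatize(model, R, prev_eigvecs=prev_eigvecs).h_exact


# ---------------------------------------------------------------------------
# model constructors
# ---------------------------------------------------------------------------

def ba_model_1d(kappa: float, delta_c: float, qc: float = 0.0,
                mass: float = 2000.0) -> DiabaticModel:
    """One-dimensional linear-crossing model behind the Baeck-An derivation.

    Diabats ``-+ kappa (Q - Qc)`` with constant diabatic coupling
    ``Delta_c / 2``.  By construction the adiabatic gap is
    ``sqrt(4 kappa^2 (Q - Qc)^2 + Delta_c^2)`` (so the gap at the crossing
    point equals ``Delta_c``, twice the diabatic coupling) and the exact
    coupling is the Lorentzian of :func:`ba_lorentzian`, with maximum
    ``kappa / Delta_c``.

    Parameters
    ----------
    kappa : slope of the diabats (hartree/bohr), > 0.
    delta_c : adiabatic gap at the crossing (hartree), > 0.
    qc : crossing position (bohr).
    mass : nuclear mass (atomic units); a free parameter of the dynamics,
        defaulting to a nuclear-scale 2000 m_e.
    """
    if kappa <= 0 or delta_c <= 0:
        raise InvalidModelError("kappa and delta_c must be positive")
    # -kappa*(Q - qc) = -kappa*Q + kappa*qc
    lower = Polynomial((-kappa, kappa * qc), ((1,), (0,)))
    upper = Polynomial((kappa, -kappa * qc), ((1,), (0,)))
    w = Polynomial.constant(delta_c / 2.0, 1)
    return DiabaticModel(
        n_states=2, n_dims=1, masses=np.array([mass]),
        V_spec=((lower, w), (w, upper)),
    )


def ba_lorentzian(kappa: float, delta_c: float, qc: float,
                  Q: np.ndarray | float) -> np.ndarray | float:
    """Closed-form coupling of the linear-crossing model (1/bohr).

    ``h(Q) = (1/2) kappa (Delta_c/2) / ((Delta_c/2)^2 + kappa^2 (Q-Qc)^2)``
    — the Lorentzian the Baeck-An model posits, used as an independent check
    on :func:`exact_nac`.
    """
    half = delta_c / 2.0
    return 0.5 * kappa * half / (half**2 + kappa**2 * (np.asarray(Q) - qc) ** 2)


def spatial_ba_coupling(gap_fn, Q: np.ndarray | float, dq: float = 1e-3) -> np.ndarray:
    """Spatial Baeck-An coupling estimate from an energy-gap profile.

    ``h(Q) ~= sgn(dE) * (1/2) sqrt( (1/dE) d2(dE)/dQ2 )`` with the second
    derivative of ``gap_fn`` taken by a local central finite-difference
    stencil of spacing ``dq``; points where the square-root argument is
    non-positive give 0.
    """
    Q = np.asarray(Q, dtype=float)
    g = np.asarray(gap_fn(Q), dtype=float)
    # O(dq^4) central stencil keeps truncation and roundoff both small
    d2 = (
        -gap_fn(Q + 2 * dq) + 16 * gap_fn(Q + dq) - 30 * g
        + 16 * gap_fn(Q - dq) - gap_fn(Q - 2 * dq)
    ) / (12 * dq**2)
    arg = d2 / g
    return np.where(arg > 0, 0.5 * np.sqrt(np.where(arg > 0, arg, 0.0)) * np.sign(g), 0.0)


def lvc_model(
    frequencies: Sequence[float],
    gradients: Sequence[Sequence[float]],
    couplings: Sequence[float],
    energies: Sequence[float],
    masses: Sequence[float] | None = None,
) -> DiabaticModel:
    """Linear vibronic coupling model.

    ``V_JJ = E0_J + sum_i (1/2) w_i^2 Q_i^2 + sum_i g_{J,i} Q_i`` and
    ``V_JL = sum_i lambda_i Q_i`` for J != L (one shared set of coupling
    constants; states couple pairwise identically).  Coordinates are
    mass-weighted normal modes, so masses default to 1.

    Parameters
    ----------
    frequencies : mode frequencies w_i (atomic units), > 0.
    gradients : tuning constants g_{J,i}, shape (n_states, n_modes).
    couplings : coupling constants lambda_i, shape (n_modes,).
    energies : vertical energies E0_J, shape (n_states,).
    """
    w = np.asarray(frequencies, dtype=float)
    g = np.asarray(gradients, dtype=float)
    lam = np.asarray(couplings, dtype=float)
    e0 = np.asarray(energies, dtype=float)
    n_modes = w.shape[0]
    n_states = e0.shape[0]
    if w.ndim != 1 or np.any(w <= 0):
        raise InvalidModelError("frequencies must be a 1-D array of positive values")
    if g.shape != (n_states, n_modes):
        raise InvalidModelError(
            f"gradients must have shape {(n_states, n_modes)}, got {g.shape}"
        )
    if lam.shape != (n_modes,):
        raise InvalidModelError(f"couplings must have shape {(n_modes,)}")
    if masses is None:
        masses = np.ones(n_modes)

    lin_pows = tuple(
        tuple(1 if d == i else 0 for d in range(n_modes)) for i in range(n_modes)
    )
    quad_pows = tuple(
        tuple(2 if d == i else 0 for d in range(n_modes)) for i in range(n_modes)
    )

    rows: list[list[Polynomial]] = [
        [None] * n_states for _ in range(n_states)  # type: ignore[list-item]
    ]
    off = Polynomial(tuple(lam), lin_pows)
    for j in range(n_states):
        coeffs = (e0[j],) + tuple(0.5 * w**2) + tuple(g[j])
        pows = ((0,) * n_modes,) + quad_pows + lin_pows
        rows[j][j] = Polynomial(coeffs, pows)
        for l in range(j):
            rows[j][l] = rows[l][j] = off
    return DiabaticModel(
        n_states=n_states, n_dims=n_modes, masses=np.asarray(masses, dtype=float),
        V_spec=tuple(tuple(r) for r in rows),
    )
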