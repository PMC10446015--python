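"""Wigner sampling of initial conditions and excitation-window filtering.

Initial nuclear phase-space points are drawn from the ground-state harmonic
Wigner distribution: per mode, position and momentum are independent
zero-mean Gaussians with variances ``hbar/(2 mu w)`` and ``hbar mu w / 2`` —
the minimum-uncertainty product ``sigma_Q sigma_P = hbar/2``.  Samples are
then restricted to a vertical-excitation energy window
``|dE_{0,target} - E_center| <= E_halfwidth`` and started on the target
surface, emulating a narrow-band excitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .units import HARTREE_TO_EV, HBAR
from .model_potentials import DiabaticModel, adiabatize

__all__ = [
    "WignerSamples",
    "EmptyEnsembleError",
    "sample_wigner",
    "filter_window",
    "write_samples",
    "read_samples",
]


class EmptyEnsembleError(RuntimeError):
    """No sample survived the excitation-window filter."""


@dataclass
class WignerSamples:
    """Phase-space samples with optional vertical gaps and target surface."""

    R: np.ndarray  # (n, n_dims) positions (bohr), relative to the well minimum
    v: np.ndarray  # (n, n_dims) velocities (bohr / atomic time)
    gaps_ev: np.ndarray | None = None  # (n,) vertical dE_{0,target} (eV)
    target_state: int | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return self.R.shape[0]


def sample_wigner(
    frequencies: Sequence[float],
    masses: Sequence[float],
    n: int,
    seed: int | np.random.Generator = 0,
    center: Sequence[float] | None = None,
) -> WignerSamples:
    """Draw ``n`` phase-space points from the ground-state harmonic Wigner
    distribution of the given modes.

    Positions have variance ``hbar/(2 mu w)``, momenta ``hbar mu w / 2``;
    velocities are momenta divided by the mode mass.  ``center`` shifts the
    position marginals to a non-origin well minimum.
    """
    w = np.asarray(frequencies, dtype=float)
    mu = np.asarray(masses, dtype=float)
    if np.any(w <= 0):
        raise ValueError("all frequencies must be positive")
    if w.shape != mu.shape:
        raise ValueError("frequencies and masses must have the same shape")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_q = np.sqrt(HBAR / (2.0 * mu * w))
    sigma_p = np.sqrt(HBAR * mu * w / 2.0)
    R = rng.normal(0.0, 1.0, size=(n, w.shape[0])) * sigma_q
    P = rng.normal(0.0, 1.0, size=(n, w.shape[0])) * sigma_p
    if center is not None:
        R = R + np.asarray(center, dtype=float)
    return WignerSamples(R=R, v=P / mu, seed=seed if isinstance(seed, int) else None)


def filter_window(
    samples: WignerSamples,
    model: DiabaticModel,
    e_center_ev: float,
    e_halfwidth_ev: float,
    target_state: int,
) -> tuple[WignerSamples, float]:
    """Keep samples whose vertical gap to ``target_state`` falls in the window.

    Returns the filtered samples (annotated with their gaps and the target
    surface) and the acceptance fraction.  Raises
    :class:`EmptyEnsembleError` when nothing survives.
    """
    if not 0 < target_state < model.n_states:
        raise ValueError("target_state must be an excited state of the model")
    gaps = np.empty(len(samples))
    for i in range(len(samples)):
        point = adiabatize(model, samples.R[i], with_nac=False)
        gaps[i] = (point.E[target_state] - point.E[0]) * HARTREE_TO_EV
    keep = np.abs(gaps - e_center_ev) <= e_halfwidth_ev
    if not np.any(keep):
        raise EmptyEnsembleError(
            f"no sample inside the {e_center_ev} +- {e_halfwidth_ev} eV window "
            f"(gap range {gaps.min():.2f}-{gaps.max():.2f} eV)"
        )
    filtered = WignerSamples(
        R=samples.R[keep], v=samples.v[keep], gaps_ev=gaps[keep],
        target_state=target_state, seed=samples.seed,
    )
    return filtered, float(np.mean(keep))


def write_samples(samples: WignerSamples, path) -> None:
    """Persist samples as a self-describing whitespace table."""
    n_dims = samples.R.shape[1]
    header = [
        "initial conditions: harmonic Wigner samples",
        f"seed: {samples.seed}",
        f"target_state: {samples.target_state}",
        "columns: "
        + " ".join(f"R{d}(bohr)" for d in range(n_dims))
        + " "
        + " ".join(f"v{d}(bohr/au_t)" for d in range(n_dims))
        + (" gap(eV)" if samples.gaps_ev is not None else ""),
    ]
    cols = [samples.R, samples.v]
    if samples.gaps_ev is not None:
        cols.append(samples.gaps_ev[:, None])
    np.savetxt(path, np.hstack(cols), header="\n".join(header))


def read_samples(path) -> WignerSamples:
    """Read samples written by :func:`write_samples`."""
    import re

    seed = target = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.match(r"#\s*seed:\s*(\S+)", line)
            if m and m.group(1) != "None":
                seed = int(m.group(1))
            m = re.match(r"#\s*target_state:\s*(\S+)", line)
            if m and m.group(1) != "None":
                target = int(m.group(1))
    data = np.atleast_2d(np.loadtxt(path))
    n_cols = data.shape[1]
    has_gap = n_cols % 2 == 1
    n_dims = (n_cols - (1 if has_gap else 0)) // 2
    return WignerSamples(
        R=data[:, :n_dims],
        v=data[:, n_dims : 2 * n_dims],
        gaps_ev=data[:, -1] if has_gap else None,
        target_state=target,
        seed=seed,
    )
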