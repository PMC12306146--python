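"""Nonnegative tensor component analysis of hidden-layer activity.

Smoothed spiking activity arranged as a (neurons x time x trials) tensor is
decomposed by rank-R nonnegative canonical polyadic (CP) decomposition

    X ~= sum_r  neuron_r (o) time_r (o) trial_r ,   all factors >= 0.

Each component couples a *neuron factor* (how strongly each unit loads on
the component), a *time factor* (the component's within-trial time course)
and a *trial factor* (its activation across trials, which for this task
tracks the stimulus IPD).  The decomposition is computed by hierarchical
alternating least squares (HALS): cyclic exact minimisation over factor
columns with projection onto the nonnegative orthant, which makes the
reconstruction error non-increasing over sweeps.  Several random restarts
guard against local minima; the best fit by reconstruction error is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["TCAFactors", "tca_decompose"]

_EPS = 1e-12


@dataclass
class TCAFactors:
    """Rank-R nonnegative CP factors of a (neurons, time, trials) tensor.

    Neuron and time columns are scaled to unit L2 norm with the scale
    absorbed into the trial factor.
    """

    rank: int
    neuron_factor: np.ndarray   # (N, R)
    time_factor: np.ndarray     # (T, R)
    trial_factor: np.ndarray    # (K, R)
    rec_error: float            # relative Frobenius reconstruction error

    def reconstruct(self) -> np.ndarray:
        return np.einsum("nr,tr,kr->ntk", self.neuron_factor,
                         self.time_factor, self.trial_factor)


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def _hals_sweep(x_unf, factors, mode: int) -> None:
    """One in-place HALS pass over the columns of ``factors[mode]``."""
    others = [factors[m] for m in range(3) if m != mode]
    # column order of the Khatri-Rao product must match the unfolding:
    # unfold(mode) has the remaining modes in ascending order.
    kr = _khatri_rao(others[0], others[1])
    w = x_unf @ kr                                   # (dim, R)
    gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
    a = factors[mode]
    for r in range(a.shape[1]):
        denom = gram[r, r]
        if denom < _EPS:
            continue
        update = a[:, r] + (w[:, r] - a @ gram[:, r]) / denom
        a[:, r] = np.maximum(update, 0.0)


def _rec_error(x: np.ndarray, factors) -> float:
    rec = np.einsum("nr,tr,kr->ntk", *factors)
    return float(np.linalg.norm(x - rec) / max(np.linalg.norm(x), _EPS))


def tca_decompose(tensor: np.ndarray, rank: int,
                  rng: Optional[np.random.Generator] = None,
                  restarts: int = 5, max_sweeps: int = 500,
                  tol: float = 1e-6) -> TCAFactors:
    """Nonnegative CP decomposition of a (neurons, time, trials) tensor.

    Best of ``restarts`` seeded uniform initialisations by reconstruction
    error; each run sweeps HALS updates until the relative error change
    drops below ``tol`` or ``max_sweeps`` is reached.
    """
    x = np.asarray(tensor, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("tensor must be 3-way (neurons, time, trials)")
    if np.any(x < 0):
        raise ValueError("tensor must be nonnegative")
    if rank < 1 or rank > min(x.shape):
        raise ValueError(
            f"rank must be in [1, {min(x.shape)}] for tensor shape {x.shape}")
    if rng is None:
        rng = np.random.default_rng(0)

    unfoldings = [_unfold(x, m) for m in range(3)]
    scale = x.mean() ** (1 / 3) + _EPS
    best = None
    for _ in range(max(restarts, 1)):
        factors = [rng.uniform(0.1, 1.0, size=(dim, rank)) * scale
                   for dim in x.shape]
        prev = np.inf
        for _sweep in range(max_sweeps):
            for mode in range(3):
                _hals_sweep(unfoldings[mode], factors, mode)
            err = _rec_error(x, factors)
            if prev - err < tol:
                break
            prev = err
        if best is None or err < best[0]:
            best = (err, [f.copy() for f in factors])

    err, (neuron, time, trial) = best
    # unit-norm neuron/time columns, scale absorbed into the trial factor
    for f in (neuron, time):
        norms = np.linalg.norm(f, axis=0)
        norms[norms < _EPS] = 1.0
        f /= norms
        trial *= norms
    return TCAFactors(rank=rank, neuron_factor=neuron, time_factor=time,
                      trial_factor=trial, rec_error=err)
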