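"""The IPD estimation task: binaural stimuli and Poisson spike coding.

A pure tone of frequency ``f`` arrives at the two ears with an interaural
phase difference (IPD) ``alpha`` drawn uniformly from [-pi/2, pi/2] (frontal
plane).  Each ear is represented by a population of ``n_psi`` input neurons
whose members carry an additional fixed phase delay ``psi_j`` uniformly
spaced over [0, pi/2], so that comparing a left and a right unit can realise
any phase difference in (-pi/2, pi/2).  Unit ``j`` of ear ``i`` (0 = left,
1 = right, only the right ear carries ``alpha``) sees phase

    theta_ij(t) = 2 pi f t + i * alpha + psi_j

and fires as an inhomogeneous Poisson process with intensity

    R_ij(t) = R_max * ((1 + sin theta_ij(t)) / 2) ** 2

realised in discrete time as independent Bernoulli draws with p = R * dt.

The IPD range is partitioned into ``n_classes`` equal intervals
I_k = [-pi/2 + k pi/N_c, -pi/2 + (k+1) pi/N_c); a network reports the class
index, decoded back to an angle as the interval midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "TaskConfig", "SpikeBatch", "phase_delays", "sample_ipds", "input_rates",
    "generate_spikes", "ipd_to_class", "class_to_midpoint", "make_batch",
    "batch_rates",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the IPD task.

    Parameters
    ----------
    f : float
        Tone frequency in Hz.
    n_psi : int
        Input neurons per ear.
    n_classes : int
        Number of IPD classes N_c.
    rate_max : float
        Maximum input firing rate R_max in spikes/s.
    duration : float
        Stimulus length in seconds.
    dt : float
        Simulation time step in seconds.
    ipd_min, ipd_max : float
        IPD support in radians (the frontal plane, [-pi/2, pi/2]).
    """

    f: float = 50.0
    n_psi: int = 100
    n_classes: int = 12
    rate_max: float = 600.0
    duration: float = 0.100
    dt: float = 0.001
    ipd_min: float = -np.pi / 2
    ipd_max: float = np.pi / 2

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("tone frequency f must be positive")
        if self.n_psi < 2:
            raise ValueError("need at least two input neurons per ear (n_psi >= 2)")
        if self.n_classes < 2:
            raise ValueError("need at least two IPD classes")
        if self.rate_max * self.dt > 1.0 + 1e-12:
            raise ValueError(
                f"rate_max*dt = {self.rate_max * self.dt:.3f} > 1: Bernoulli "
                "spike generation is invalid; decrease dt or rate_max"
            )
        n_bins = self.duration / self.dt
        if abs(n_bins - round(n_bins)) > 1e-9 or round(n_bins) < 1:
            raise ValueError("duration must be a positive integer multiple of dt")
        if not (self.ipd_min < self.ipd_max):
            raise ValueError("ipd_min must be below ipd_max")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_inputs(self) -> int:
        """Total input channels, both ears."""
        return 2 * self.n_psi


@dataclass
class SpikeBatch:
    """A batch of Poisson-encoded binaural stimuli.

    ``spikes`` is a binary (trials, time bins, 2*n_psi) tensor; channels
    0..n_psi-1 are the left ear, n_psi..2*n_psi-1 the right ear, each ear
    ordered by increasing phase delay psi.
    """

    spikes: np.ndarray
    dt: float
    ipd_true: np.ndarray
    class_true: np.ndarray

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        self.ipd_true = np.asarray(self.ipd_true, dtype=np.float64)
        self.class_true = np.asarray(self.class_true, dtype=np.int64)
        if self.spikes.ndim != 3:
            raise ValueError("spikes must be (trials, time, channels)")
        if len(self.ipd_true) != self.spikes.shape[0]:
            raise ValueError("ipd_true length must match trial count")

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    def to_hdf5(self, group) -> None:
        group.create_dataset("spikes", data=self.spikes.astype(np.uint8),
                             compression="gzip")
        group.create_dataset("ipd_true", data=self.ipd_true)
        group.create_dataset("class_true", data=self.class_true)
        group.attrs["dt"] = self.dt

    @classmethod
    def from_hdf5(cls, group) -> "SpikeBatch":
        return cls(
            spikes=group["spikes"][...],
            dt=float(group.attrs["dt"]),
            ipd_true=group["ipd_true"][...],
            class_true=group["class_true"][...],
        )


def phase_delays(n_psi: int) -> np.ndarray:
    """Per-neuron phase delays psi_j = j*pi/(2*(n_psi-1)), j = 0..n_psi-1.

    Both endpoints (0 and pi/2) are included.
    """
    if n_psi < 2:
        raise ValueError("n_psi must be at least 2")
    return np.arange(n_psi) * (np.pi / (2 * (n_psi - 1)))


def sample_ipds(n: int, rng: np.random.Generator,
                ipd_min: float = -np.pi / 2,
                ipd_max: float = np.pi / 2) -> np.ndarray:
    """Draw ``n`` IPDs uniformly from [ipd_min, ipd_max]."""
    if n < 1:
        raise ValueError("trial count n must be positive")
    return rng.uniform(ipd_min, ipd_max, size=n)


def input_rates(ipd: float, cfg: TaskConfig,
                psi: Optional[np.ndarray] = None) -> np.ndarray:
    """Instantaneous firing rates (time bins, 2*n_psi) for one stimulus.

    R_ij(t) = R_max * ((1 + sin(2 pi f t + i*alpha + psi_j)) / 2)^2, with
    ear index i = 0 (left, no alpha) or 1 (right, + alpha).  Rates are
    evaluated at bin start times t = 0, dt, 2 dt, ...
    """
    if abs(ipd) > np.pi / 2 + 1e-12:
        raise ValueError("|ipd| must not exceed pi/2")
    if psi is None:
        psi = phase_delays(cfg.n_psi)
    t = np.arange(cfg.n_bins) * cfg.dt
    # theta: (time, ears, n_psi)
    theta = (2 * np.pi * cfg.f * t)[:, None, None] \
        + (np.array([0.0, ipd]))[None, :, None] \
        + psi[None, None, :]
    rates = cfg.rate_max * ((1 + np.sin(theta)) / 2) ** 2
    return rates.reshape(cfg.n_bins, 2 * cfg.n_psi)


def batch_rates(ipds: np.ndarray, cfg: TaskConfig) -> np.ndarray:
    """Vectorised rates for many trials: (trials, time bins, 2*n_psi).

    Uses sin(base + i*alpha) = sin(base) cos(i*alpha) + cos(base) sin(i*alpha)
    with base = 2 pi f t + psi_j precomputed once, so per-trial work is
    elementwise only.  Single precision: the Bernoulli draw that follows
    dominates any rounding at this scale.
    """
    ipds = np.asarray(ipds, dtype=np.float64)
    psi = phase_delays(cfg.n_psi)
    t = np.arange(cfg.n_bins) * cfg.dt
    base = (2 * np.pi * cfg.f * t)[:, None] + psi[None, :]  # (T, n_psi)
    sin_b = np.sin(base).astype(np.float32)
    cos_b = np.cos(base).astype(np.float32)
    ca = np.cos(ipds).astype(np.float32)[:, None, None]
    sa = np.sin(ipds).astype(np.float32)[:, None, None]
    out = np.empty((len(ipds), cfg.n_bins, 2 * cfg.n_psi), dtype=np.float32)
    out[:, :, : cfg.n_psi] = sin_b[None]                      # left ear
    out[:, :, cfg.n_psi:] = sin_b[None] * ca + cos_b[None] * sa  # right ear
    np.add(out, 1.0, out=out)
    np.multiply(out, 0.5, out=out)
    np.square(out, out=out)
    np.multiply(out, np.float32(cfg.rate_max), out=out)
    return out


def generate_spikes(rates: np.ndarray, dt: float,
                    rng: np.random.Generator,
                    validate: bool = True) -> np.ndarray:
    """Bernoulli realisation of an inhomogeneous Poisson process.

    Each time bin of each channel spikes independently with p = rate * dt.
    ``validate=False`` skips the bound checks when the caller constructed
    the rates from a validated TaskConfig (R_max*dt <= 1 by invariant).
    """
    rates = np.asarray(rates)
    if validate:
        if np.any(rates < 0):
            raise ValueError("rates must be nonnegative")
        pmax = float(rates.max(initial=0.0)) * dt
        if pmax > 1.0 + 1e-9:
            offender = np.unravel_index(int(np.argmax(rates)), rates.shape)
            raise ValueError(
                f"rate*dt = {pmax:.3f} > 1 at index {offender}: Bernoulli "
                "spike generation invalid; decrease dt or the rate"
            )
    u = rng.random(rates.shape, dtype=np.float32)
    np.multiply(u, np.float32(1.0 / dt), out=u)   # u/dt < rate  <=>  u < rate*dt
    return np.less(u, rates).astype(np.float32)


def ipd_to_class(ipd, n_classes: int):
    """Map IPD(s) in [-pi/2, pi/2] to class indices.

    Class k covers [-pi/2 + k pi/N_c, -pi/2 + (k+1) pi/N_c); the upper
    boundary +pi/2 is assigned to the top class so the bins partition the
    closed interval.
    """
    ipd_arr = np.asarray(ipd, dtype=np.float64)
    if np.any(ipd_arr < -np.pi / 2 - 1e-12) or np.any(ipd_arr > np.pi / 2 + 1e-12):
        raise ValueError("ipd outside [-pi/2, pi/2]")
    scaled = (ipd_arr + np.pi / 2) / (np.pi / n_classes)
    # nudge values an ulp below a bin edge up onto it before flooring
    k = np.floor(scaled + 1e-9).astype(np.int64)
    k = np.clip(k, 0, n_classes - 1)
    return k if isinstance(ipd, np.ndarray) else int(k)


def class_to_midpoint(k, n_classes: int):
    """Midpoint angle (radians) of IPD class ``k``: -pi/2 + (k+1/2) pi/N_c."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr >= n_classes):
        raise ValueError(f"class index out of range [0, {n_classes})")
    mid = -np.pi / 2 + (k_arr + 0.5) * np.pi / n_classes
    return mid if isinstance(k, np.ndarray) else float(mid)


def make_batch(n: int, cfg: TaskConfig, rng: np.random.Generator,
               ipds: Optional[np.ndarray] = None) -> SpikeBatch:
    """Sample ``n`` stimuli (or encode given ``ipds``) into a SpikeBatch."""
    if ipds is None:
        ipds = sample_ipds(n, rng, cfg.ipd_min, cfg.ipd_max)
    rates = batch_rates(ipds, cfg)
    spikes = generate_spikes(rates, cfg.dt, rng, validate=False)
    return SpikeBatch(
        spikes=spikes,
        dt=cfg.dt,
        ipd_true=ipds,
        class_true=ipd_to_class(np.asarray(ipds), cfg.n_classes),
    )
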