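"""Trainable input delays: two differentiable mechanisms.

Differentiable delay layer (DDL)
    A spike train is delayed by translating it along the time axis; linear
    interpolation between adjacent bins makes the operation differentiable
    in the delay even though time is discrete (a 1-D, translation-only
    specialisation of the spatial-transformer idea).  Delays that are
    integer multiples of the time step reproduce exact index shifting.  The
    DDL network solves the IPD task with *delays only*: weights are fixed
    to one and biases to zero.  Each output class i compares a fixed-delay
    copy of the left-ear train with a learnably delayed copy of the
    right-ear train through dendritic leaky integrators u (tau_m du/dt =
    -u + S(t)) and a multiplicative synapse readout

        v_i = - sum_t (u_1i(t) - u_2i(t))^2

    which is maximal (zero) when the filtered trains coincide, i.e. when
    class i's delay compensates the stimulus IPD.

Dilated convolution with learnable spacings (DCLS)
    Each synapse is a 1-D temporal convolution whose kernel has a single
    non-zero element: the weight, positioned at the delay.  During training
    the kernel is a weight-scaled normalised Gaussian bump centred at a
    continuous position (differentiable in the position); the width sigma
    is annealed toward zero so that at inference the kernel collapses to a
    single non-zero tap at the rounded position.  This mechanism co-trains
    weights and delays through the spiking network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.signal import lfilter

from .network import V_THRESHOLD, log_softmax, readout_forward
from .seeding import rng_for
from .task import generate_spikes
from .training import Adam, EvalReport, TrainConfig, cross_entropy_loss, \
    loss_and_grads

__all__ = [
    "DelayParams", "DDLConfig", "DDLResult", "DCLSConfig", "DCLSSynapses",
    "DCLSResult", "ddl_shift", "multiplicative_readout", "train_ddl",
    "dcls_forward", "train_dcls", "binaural_spike_trains",
]


# ----------------------------------------------------------------------
# Shared stimulus helper: one (or a few identical-rate) Poisson channels
# per ear, no preassigned phase-delay population.


def binaural_spike_trains(ipds: np.ndarray, f: float, rate_max: float,
                          duration: float, dt: float,
                          rng: np.random.Generator,
                          n_per_ear: int = 1) -> Tuple[np.ndarray, np.ndarray]:
    """Poisson spike trains for the two ears without phase-delay fan-out.

    Every channel of ear i follows R(t) = rate_max*((1+sin(2 pi f t +
    i*alpha))/2)^2 (independent Poisson realisations).  Returns
    ``(left, right)`` of shape (trials, time bins, n_per_ear).
    """
    ipds = np.asarray(ipds, dtype=np.float64)
    n_bins = int(round(duration / dt))
    t = np.arange(n_bins) * dt
    phase = 2 * np.pi * f * t
    theta_l = phase[None, :] + np.zeros_like(ipds)[:, None]
    theta_r = phase[None, :] + ipds[:, None]
    out = []
    for theta in (theta_l, theta_r):
        rates = rate_max * ((1 + np.sin(theta)) / 2) ** 2
        rates = np.repeat(rates[:, :, None], n_per_ear, axis=2)
        out.append(generate_spikes(rates.astype(np.float32), dt, rng))
    return out[0], out[1]


# ----------------------------------------------------------------------
# Differentiable delay layer


@dataclass
class DelayParams:
    """Per-channel delay values for the DDL.

    ``delays`` is in seconds; continuous during training, snapped to
    multiples of ``min_delay`` (= dt) at evaluation.  ``learnable_mask``
    marks the channels whose delays train; ``pad`` is the zero-padding
    length in bins that bounds the largest representable delay.
    """

    delays: np.ndarray
    min_delay: float
    learnable_mask: np.ndarray
    pad: int

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=np.float64)
        self.learnable_mask = np.asarray(self.learnable_mask, dtype=bool)
        if self.learnable_mask.shape != self.delays.shape:
            raise ValueError("learnable_mask must match delays shape")
        max_bins = np.max(self.delays) / self.min_delay
        if max_bins > self.pad + 1e-9:
            raise ValueError("pad too small for the largest delay")

    def snapped(self) -> np.ndarray:
        """Delays rounded to integer multiples of min_delay."""
        return np.round(self.delays / self.min_delay) * self.min_delay


def ddl_shift(spikes: np.ndarray, delays: np.ndarray, dt: float) -> np.ndarray:
    """Translate each channel's spike train by its delay, interpolating.

    ``spikes``: (trials, time, channels); ``delays``: per-channel, seconds,
    nonnegative.  Integer-multiple-of-dt delays reproduce exact index
    shifting (the interpolation picks the coincident bin with weight one);
    fractional delays split spike mass linearly between the two adjacent
    bins.  Mass shifted past the end of the (caller-padded) window is
    dropped, which is why inputs should be zero-padded.
    """
    spikes = np.asarray(spikes)
    if isinstance(delays, DelayParams):
        delays = delays.delays
    delays = np.atleast_1d(np.asarray(delays, dtype=np.float64))
    n_ch = spikes.shape[2]
    if delays.shape != (n_ch,):
        raise ValueError("need one delay per channel")
    n_bins = spikes.shape[1]
    d_bins = delays / dt
    if np.any(d_bins < -1e-9):
        ch = int(np.argmin(d_bins))
        raise ValueError(f"negative delay on channel {ch}")
    if np.any(d_bins > n_bins):
        ch = int(np.argmax(d_bins))
        raise ValueError(f"delay on channel {ch} exceeds the padded window")
    k = np.floor(d_bins + 1e-9).astype(int)
    frac = d_bins - k
    frac[frac < 1e-9] = 0.0
    out = np.zeros_like(spikes, dtype=np.float64)
    for c in range(n_ch):
        if k[c] < n_bins:
            out[:, k[c]:, c] += (1.0 - frac[c]) * spikes[:, : n_bins - k[c], c]
        if frac[c] > 0 and k[c] + 1 < n_bins:
            out[:, k[c] + 1:, c] += frac[c] * spikes[:, : n_bins - k[c] - 1, c]
    return out


def _frac_gather(u: np.ndarray, d_bins: np.ndarray) -> np.ndarray:
    """Fractionally delayed copies of filtered traces.

    ``u``: (trials, time); ``d_bins``: (K,) nonnegative delays in bins.
    Returns (trials, K, time) where out[:, k, t] = u(t - d_k) under linear
    interpolation, zero before the signal starts.
    """
    n_bins = u.shape[1]
    k = np.floor(d_bins + 1e-12).astype(int)
    frac = (d_bins - k)[None, :, None]
    pad = int(np.max(k)) + 1
    up = np.concatenate([np.zeros((u.shape[0], pad), dtype=u.dtype), u], axis=1)
    t_idx = np.arange(n_bins)
    idx0 = t_idx[None, :] - k[:, None] + pad      # (K, T)
    g0 = up[:, idx0]                               # (trials, K, T)
    g1 = up[:, idx0 - 1]
    return (1.0 - frac) * g0 + frac * g1


def _leaky_filter(spikes: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """u_t = exp(-dt/tau) u_{t-1} + s_t along axis 1."""
    decay = float(np.exp(-dt / tau))
    return lfilter([1.0], [1.0, -decay], spikes, axis=1)


def multiplicative_readout(left: np.ndarray, right: np.ndarray,
                           delays: DelayParams, tau_m: float, dt: float,
                           return_traces: bool = False):
    """Per-class output potentials of the DDL network.

    ``left``/``right``: (trials, time) spike trains (zero-padded).
    ``delays.delays`` has shape (n_classes, 2): column 0 the fixed-ear
    delay, column 1 the learnable-ear delay for each class.  Each train is
    delayed, filtered into a dendritic potential u (leaky integration with
    tau_m), and combined as v_i = -sum_t (u_1i - u_2i)^2 <= 0, with
    equality iff the filtered delayed trains coincide.
    """
    if left.shape != right.shape:
        raise ValueError("left and right spike trains must have equal shape")
    d = delays.delays
    if d.ndim != 2 or d.shape[1] != 2:
        raise ValueError("DelayParams.delays must be (n_classes, 2)")
    # delay-then-filter equals filter-then-delay for a causal IIR filter on
    # zero-padded input, so filter once and gather fractional shifts.
    u_left = _leaky_filter(left.astype(np.float64), tau_m, dt)
    u_right = _leaky_filter(right.astype(np.float64), tau_m, dt)
    u1 = _frac_gather(u_left, d[:, 0] / dt)    # (trials, n_c, T)
    u2 = _frac_gather(u_right, d[:, 1] / dt)
    diff = u1 - u2
    v = -np.sum(diff**2, axis=2)
    if return_traces:
        return v, u1, u2
    return v


@dataclass
class DDLConfig:
    """The 36-class delay-only task and its training settings.

    Classes are the IPD angles -90, -85, ..., +85 degrees (5-degree steps);
    stimuli are single Poisson spike trains per ear.  A fine time step
    resolves sub-millisecond delay differences (at 50 Hz a 5-degree IPD
    step is ~0.28 ms of ITD).  The fixed ear's delay sits mid-range so the
    learnable ear can compensate IPDs of either sign.
    """

    f: float = 50.0
    rate_max: float = 600.0
    duration: float = 0.100
    dt: float = 1e-4
    n_classes: int = 36
    tau_m: float = 5e-3
    fixed_delay: float = 5e-3
    max_delay: float = 10e-3
    n_train: int = 1152
    batch_size: int = 128
    epochs: int = 20
    learning_rate: float = 0.03   # Adam, on delays expressed in ms
    seed: int = 0
    n_test: int = 1800

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))

    def class_angles(self) -> np.ndarray:
        """Class IPD angles in radians: -pi/2 + k*pi/n_classes."""
        return -np.pi / 2 + np.arange(self.n_classes) * np.pi / self.n_classes


@dataclass
class DDLResult:
    delays: DelayParams
    loss_history: np.ndarray
    accuracy: float
    mae_deg: float
    confusion: np.ndarray
    chance: float


def _ddl_eval(delays: DelayParams, cfg: DDLConfig,
              rng: np.random.Generator) -> Tuple[float, float, np.ndarray]:
    angles = cfg.class_angles()
    snapped = DelayParams(delays.snapped(), delays.min_delay,
                          delays.learnable_mask, delays.pad)
    confusion = np.zeros((cfg.n_classes, cfg.n_classes), dtype=np.int64)
    correct = 0
    abs_err = 0.0
    done = 0
    batch = 256
    while done < cfg.n_test:
        nb = min(batch, cfg.n_test - done)
        k_true = rng.integers(0, cfg.n_classes, size=nb)
        left, right = binaural_spike_trains(
            angles[k_true], cfg.f, cfg.rate_max, cfg.duration, cfg.dt, rng)
        v = multiplicative_readout(left[:, :, 0], right[:, :, 0], snapped,
                                   cfg.tau_m, cfg.dt)
        k_hat = np.argmax(v, axis=1)
        correct += int((k_hat == k_true).sum())
        abs_err += float(np.abs(np.degrees(angles[k_hat] - angles[k_true])).sum())
        np.add.at(confusion, (k_true, k_hat), 1)
        done += nb
    return correct / cfg.n_test, abs_err / cfg.n_test, confusion


def train_ddl(cfg: DDLConfig, progress: bool = False) -> DDLResult:
    """Gradient descent on the learnable-ear delays only.

    Weights are one and biases zero throughout; one delay per output class
    is trained on the non-fixed ear, by cross-entropy over softmax of the
    output potentials v_i.  Delays are parameterised in milliseconds for
    the optimizer and clamped to [0, max_delay].
    """
    n_c = cfg.n_classes
    n_bins = cfg.n_bins
    angles = cfg.class_angles()
    data_rng = rng_for(cfg.seed, "ddl-data")
    d_ms = np.full(n_c, cfg.fixed_delay * 1e3)  # learnable, init = fixed delay
    opt = Adam({"d": (n_c,)}, lr=cfg.learning_rate)
    n_batches = cfg.n_train // cfg.batch_size
    loss_history = np.empty(cfg.epochs)
    bins_per_ms = 1e-3 / cfg.dt

    for epoch in range(cfg.epochs):
        epoch_loss = 0.0
        for _ in range(n_batches):
            k_true = data_rng.integers(0, n_c, size=cfg.batch_size)
            left, right = binaural_spike_trains(
                angles[k_true], cfg.f, cfg.rate_max, cfg.duration, cfg.dt,
                data_rng)
            left, right = left[:, :, 0], right[:, :, 0]
            u_left = _leaky_filter(left.astype(np.float64), cfg.tau_m, cfg.dt)
            u_right = _leaky_filter(right.astype(np.float64), cfg.tau_m, cfg.dt)
            u1 = _frac_gather(u_left, np.full(n_c, cfg.fixed_delay / cfg.dt))
            d_bins = d_ms * bins_per_ms
            k_int = np.floor(d_bins + 1e-12).astype(int)
            frac = (d_bins - k_int)[None, :, None]
            pad = int(np.max(k_int)) + 2
            up = np.concatenate(
                [np.zeros((u_right.shape[0], pad)), u_right], axis=1)
            t_idx = np.arange(u_right.shape[1])
            idx0 = t_idx[None, :] - k_int[:, None] + pad
            g0 = up[:, idx0]
            g1 = up[:, idx0 - 1]
            u2 = (1.0 - frac) * g0 + frac * g1
            du2_dbins = g1 - g0   # d u2 / d (delay in bins)
            diff = u1 - u2
            v = -np.sum(diff**2, axis=2)
            # classification logits are the *time-mean* potentials, as in
            # the base model's readout; the raw sum saturates the softmax
            x = log_softmax(v / n_bins)
            loss = cross_entropy_loss(x, k_true)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"DDL training diverged at epoch {epoch}, "
                    f"learning_rate={cfg.learning_rate}")
            g_v = np.exp(x)
            g_v[np.arange(len(k_true)), k_true] -= 1.0
            g_v /= len(k_true) * n_bins   # includes the 1/T logit scaling
            # dv_i/d d_i = sum_t 2*(u1-u2) * du2/dd   (only class i's delay
            # enters v_i)
            dv_dd = np.sum(2.0 * diff * du2_dbins, axis=2) * bins_per_ms
            g_d = np.sum(g_v * dv_dd, axis=0)
            opt.step({"d": d_ms}, {"d": g_d})
            np.clip(d_ms, 0.0, cfg.max_delay * 1e3, out=d_ms)
            epoch_loss += loss
        loss_history[epoch] = epoch_loss / n_batches
        if progress:
            print(f"ddl epoch {epoch + 1:3d}/{cfg.epochs}  "
                  f"loss {loss_history[epoch]:.4f}")

    delays = DelayParams(
        delays=np.column_stack([np.full(n_c, cfg.fixed_delay), d_ms * 1e-3]),
        min_delay=cfg.dt,
        learnable_mask=np.column_stack([np.zeros(n_c, bool), np.ones(n_c, bool)]),
        pad=int(round(cfg.max_delay / cfg.dt)),
    )
    acc, mae, confusion = _ddl_eval(delays, cfg, rng_for(cfg.seed, "ddl-eval"))
    return DDLResult(delays=delays, loss_history=loss_history, accuracy=acc,
                     mae_deg=mae, confusion=confusion, chance=1.0 / n_c)


# ----------------------------------------------------------------------
# DCLS: delays as single-nonzero-element temporal convolutions


@dataclass
class DCLSSynapses:
    """Per-synapse weight + continuous delay position (bins).

    ``weight`` and ``position`` have shape (n_pre, n_post); ``sigma`` is
    the width of the interpolating Gaussian bump during training;
    ``kernel_len`` bounds the representable delay.  At inference the
    kernel has a single non-zero element at round(position).
    """

    weight: np.ndarray
    position: np.ndarray
    sigma: float
    kernel_len: int

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.position = np.asarray(self.position, dtype=np.float64)
        if self.weight.shape != self.position.shape:
            raise ValueError("weight and position must share a shape")
        if self.kernel_len < 1:
            raise ValueError("kernel_len must be >= 1")


def _clamped_positions(syn: DCLSSynapses) -> np.ndarray:
    pos = syn.position
    if np.any(pos < 0) or np.any(pos > syn.kernel_len - 1):
        warnings.warn("DCLS positions outside kernel range; clamping",
                      RuntimeWarning, stacklevel=3)
        pos = np.clip(pos, 0.0, syn.kernel_len - 1)
    return pos


def _dcls_kernel(syn: DCLSSynapses) -> np.ndarray:
    """Normalised Gaussian interpolation kernel, (n_pre, n_post, L).

    Columns sum to 1, so the kernel's total mass equals the weight after
    scaling (mass preservation for any position/sigma).
    """
    pos = _clamped_positions(syn)
    lags = np.arange(syn.kernel_len)
    z = (lags[None, None, :] - pos[:, :, None]) / max(syn.sigma, 1e-6)
    phi = np.exp(-0.5 * z**2)
    return phi / phi.sum(axis=2, keepdims=True)


def _shifted_views(spikes: np.ndarray, n_lags: int):
    """List of zero-padded views S[:, t-l, :] for l = 0..n_lags-1."""
    n_trials, n_bins, n_pre = spikes.shape
    padded = np.zeros((n_trials, n_bins + n_lags, n_pre), dtype=spikes.dtype)
    padded[:, n_lags:, :] = spikes
    return [padded[:, n_lags - l: n_lags - l + n_bins, :] for l in range(n_lags)]


def dcls_forward(spikes: np.ndarray, syn: DCLSSynapses,
                 mode: str = "train") -> np.ndarray:
    """Delayed weighted input currents, (trials, time, n_post).

    ``train`` mode convolves with the weight-scaled Gaussian bump kernel
    (differentiable in position); ``infer`` mode uses the collapsed kernel
    with a single non-zero element at round(position).
    """
    spikes = np.asarray(spikes, dtype=np.float32)
    n_trials, n_bins, n_pre = spikes.shape
    n_post = syn.weight.shape[1]
    out = np.zeros((n_trials, n_bins, n_post), dtype=np.float32)
    views = _shifted_views(spikes, syn.kernel_len)
    if mode == "train":
        kernel = _dcls_kernel(syn) * syn.weight[:, :, None]
        for l in range(syn.kernel_len):
            k_l = kernel[:, :, l]
            if not np.any(k_l):
                continue
            out += (views[l].reshape(-1, n_pre) @ k_l.astype(np.float32)
                    ).reshape(n_trials, n_bins, n_post)
    elif mode == "infer":
        pos = np.round(_clamped_positions(syn)).astype(int)
        for l in np.unique(pos):
            w_l = np.where(pos == l, syn.weight, 0.0)
            out += (views[l].reshape(-1, n_pre) @ w_l.astype(np.float32)
                    ).reshape(n_trials, n_bins, n_post)
    else:
        raise ValueError("mode must be 'train' or 'infer'")
    return out


@dataclass
class DCLSConfig:
    """12-class IPD task solved by co-training weights and delays.

    Input neurons carry no preassigned phase delays: each ear is
    ``n_per_ear`` independent Poisson channels with the ear's raw rate;
    per-synapse learnable delays take over the role the psi population
    played in the base model.  The kernel length covers somewhat more than
    one stimulus period's worth of useful delay at the default frequency.
    """

    f: float = 50.0
    rate_max: float = 600.0
    duration: float = 0.100
    dt: float = 1e-3
    n_classes: int = 12
    n_per_ear: int = 32
    n_hidden: int = 8
    kernel_len: int = 25
    sigma_start: float = 2.0
    sigma_end: float = 0.25
    tau_hidden: float = 2e-3
    tau_readout: float = 2e-3
    beta: float = 10.0
    r_minus: float = 100.0
    r_plus: float = 200.0
    n_train: int = 6144
    batch_size: int = 128
    epochs: int = 40
    learning_rate: float = 2e-3   # weights
    lr_position: float = 0.1      # delay positions, bins
    seed: int = 0
    n_test: int = 4096

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_inputs(self) -> int:
        return 2 * self.n_per_ear


@dataclass
class DCLSResult:
    synapses: DCLSSynapses
    w_ho: np.ndarray
    loss_history: np.ndarray
    metrics: EvalReport
    config: DCLSConfig

    def receptive_fields(self) -> np.ndarray:
        """(n_pre, n_hidden, 2) array of (learned delay bins, weight)."""
        delays = np.round(np.clip(self.synapses.position, 0,
                                  self.synapses.kernel_len - 1))
        return np.stack([delays, self.synapses.weight], axis=2)


def _dcls_stimuli(n: int, cfg: DCLSConfig, rng: np.random.Generator):
    ipds = rng.uniform(-np.pi / 2, np.pi / 2, size=n)
    k_true = np.floor((ipds + np.pi / 2) / (np.pi / cfg.n_classes)).astype(int)
    k_true = np.clip(k_true, 0, cfg.n_classes - 1)
    left, right = binaural_spike_trains(ipds, cfg.f, cfg.rate_max,
                                        cfg.duration, cfg.dt, rng,
                                        n_per_ear=cfg.n_per_ear)
    spikes = np.concatenate([left, right], axis=2)
    return spikes, ipds, k_true


def _dcls_hidden_forward(currents: np.ndarray, tau: float, dt: float,
                         beta: float):
    n_trials, n_bins, n_h = currents.shape
    a_dec = np.float32(np.exp(-dt / tau))
    v = np.zeros((n_trials, n_h), dtype=np.float32)
    s_rec = np.empty((n_trials, n_bins, n_h), dtype=np.float32)
    sd_rec = np.empty_like(s_rec)
    for t in range(n_bins):
        v = v * a_dec + currents[:, t]
        s = (v >= V_THRESHOLD).astype(np.float32)
        u = np.abs(v - V_THRESHOLD)
        sd_rec[:, t] = beta / (beta * u + 1.0) ** 2
        s_rec[:, t] = s
        v = v * (1.0 - s)
    return s_rec, sd_rec


def evaluate_dcls(syn: DCLSSynapses, w_ho: np.ndarray, cfg: DCLSConfig,
                  n_test: int, rng: np.random.Generator,
                  mode: str = "infer") -> EvalReport:
    """Test metrics with the collapsed single-tap kernels (or train mode)."""
    n_c = cfg.n_classes
    confusion = np.zeros((n_c, n_c), dtype=np.int64)
    correct, abs_err, done = 0, 0.0, 0
    spike_totals = np.zeros(cfg.n_hidden)
    mid = lambda k: -np.pi / 2 + (k + 0.5) * np.pi / n_c
    while done < n_test:
        nb = min(512, n_test - done)
        spikes, ipds, k_true = _dcls_stimuli(nb, cfg, rng)
        currents = dcls_forward(spikes, syn, mode=mode)
        s_rec, _ = _dcls_hidden_forward(currents, cfg.tau_hidden, cfg.dt,
                                        cfg.beta)
        _, v_bar = readout_forward(s_rec, w_ho, cfg.tau_readout, cfg.dt)
        k_hat = np.argmax(v_bar, axis=1)
        correct += int((k_hat == k_true).sum())
        abs_err += float(np.abs(np.degrees(mid(k_hat) - mid(k_true))).sum())
        np.add.at(confusion, (k_true, k_hat), 1)
        spike_totals += s_rec.sum(axis=(0, 1))
        done += nb
    return EvalReport(accuracy=correct / n_test,
                      mae_deg=abs_err / n_test,
                      confusion=confusion,
                      hidden_rates=spike_totals / (n_test * cfg.duration),
                      n_test=n_test)


def train_dcls(cfg: DCLSConfig, progress: bool = False) -> DCLSResult:
    """Co-train synaptic weights and delay positions with Adam.

    Sigma is annealed linearly from ``sigma_start`` to ``sigma_end`` over
    the epochs, so the interpolating bump sharpens into the single-tap
    inference kernel.  The hidden layer trains exactly as the base model
    (surrogate-gradient BPTT with the firing-rate regulariser); position
    gradients flow through the normalised-Gaussian kernel.
    """
    init_rng = rng_for(cfg.seed, "dcls-init")
    data_rng = rng_for(cfg.seed, "dcls-data")
    n_in, n_h, n_c = cfg.n_inputs, cfg.n_hidden, cfg.n_classes
    L = cfg.kernel_len
    lim_ih = np.sqrt(1.0 / n_in)
    lim_ho = np.sqrt(1.0 / n_h)
    weight = init_rng.uniform(-lim_ih, lim_ih, size=(n_in, n_h))
    position = init_rng.uniform(0, L - 1, size=(n_in, n_h))
    w_ho = init_rng.uniform(-lim_ho, lim_ho, size=(n_h, n_c))

    opt = Adam({"weight": weight.shape, "w_ho": w_ho.shape}, lr=cfg.learning_rate)
    opt_pos = Adam({"position": position.shape}, lr=cfg.lr_position)
    n_batches = cfg.n_train // cfg.batch_size
    loss_history = np.empty(cfg.epochs)
    duration = cfg.duration
    c_scale = float(np.log(n_c))
    a_dec = np.float32(np.exp(-cfg.dt / cfg.tau_hidden))
    b_dec = float(np.exp(-cfg.dt / cfg.tau_readout))
    lags = np.arange(L)

    for epoch in range(cfg.epochs):
        sigma = cfg.sigma_start + (cfg.sigma_end - cfg.sigma_start) * \
            (epoch / max(cfg.epochs - 1, 1))
        epoch_loss = 0.0
        for _ in range(n_batches):
            spikes, _, k_true = _dcls_stimuli(cfg.batch_size, cfg, data_rng)
            n_trials, n_bins = spikes.shape[:2]
            syn = DCLSSynapses(weight, position, sigma, L)
            # kernel and its position derivative
            pos = np.clip(position, 0.0, L - 1)
            z = (lags[None, None, :] - pos[:, :, None]) / sigma
            phi = np.exp(-0.5 * z**2)
            norm = phi / phi.sum(axis=2, keepdims=True)       # (n_in, n_h, L)
            zc = (lags[None, None, :] - pos[:, :, None]) / sigma**2
            dnorm = norm * (zc - np.sum(norm * zc, axis=2, keepdims=True))
            views = _shifted_views(spikes, L)
            currents = np.zeros((n_trials, n_bins, n_h), dtype=np.float32)
            kernel = (norm * weight[:, :, None]).astype(np.float32)
            for l in range(L):
                currents += (views[l].reshape(-1, n_in) @ kernel[:, :, l]
                             ).reshape(n_trials, n_bins, n_h)

            s_rec, sd_rec = _dcls_hidden_forward(currents, cfg.tau_hidden,
                                                 cfg.dt, cfg.beta)
            _, v_bar = readout_forward(s_rec, w_ho, cfg.tau_readout, cfg.dt)
            x = log_softmax(v_bar)
            ce = cross_entropy_loss(x, k_true)
            rates = s_rec.sum(axis=(0, 1)) / (n_trials * duration)
            over = np.maximum(rates - cfg.r_minus, 0.0) / (cfg.r_plus - cfg.r_minus)
            reg = float(c_scale * np.sum(over**2) / n_h)
            loss = ce + reg
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"DCLS training diverged at epoch {epoch}, "
                    f"learning_rate={cfg.learning_rate}")

            # backward: readout (geometric accumulation), then hidden BPTT
            g_vbar = np.exp(x)
            g_vbar[np.arange(n_trials), k_true] -= 1.0
            g_vbar /= n_trials
            geo = (1.0 - b_dec ** np.arange(n_bins, 0, -1)) / (1.0 - b_dec)
            G = ((g_vbar[:, None, :] / n_bins) * geo[None, :, None]
                 ).astype(np.float32)
            grad_w_ho = s_rec.reshape(-1, n_h).T @ G.reshape(-1, n_c)
            g_H = (G.reshape(-1, n_c) @ w_ho.T.astype(np.float32)
                   ).reshape(n_trials, n_bins, n_h)
            coef = (c_scale / n_h) * 2.0 * np.maximum(rates - cfg.r_minus, 0.0) \
                / (cfg.r_plus - cfg.r_minus) ** 2 / (n_trials * duration)
            g_H = g_H + coef[None, None, :].astype(np.float32)
            gv_all = np.empty_like(g_H)
            gv_next = np.zeros((n_trials, n_h), dtype=np.float32)
            for t in range(n_bins - 1, -1, -1):
                gv_next = g_H[:, t] * sd_rec[:, t] \
                    + a_dec * (1.0 - s_rec[:, t]) * gv_next
                gv_all[:, t] = gv_next
            gv_flat = gv_all.reshape(-1, n_h)
            grad_weight = np.zeros_like(weight)
            grad_pos = np.zeros_like(position)
            for l in range(L):
                m_l = (views[l].reshape(-1, n_in).T @ gv_flat).astype(np.float64)
                grad_weight += m_l * norm[:, :, l]
                grad_pos += m_l * weight * dnorm[:, :, l]

            opt.step({"weight": weight, "w_ho": w_ho},
                     {"weight": grad_weight, "w_ho": grad_w_ho.astype(np.float64)})
            opt_pos.step({"position": position}, {"position": grad_pos})
            np.clip(position, 0.0, L - 1, out=position)
            epoch_loss += loss
        loss_history[epoch] = epoch_loss / n_batches
        if progress:
            print(f"dcls epoch {epoch + 1:3d}/{cfg.epochs}  sigma {sigma:.2f}  "
                  f"loss {loss_history[epoch]:.4f}")

    syn = DCLSSynapses(weight, position, cfg.sigma_end, L)
    metrics = evaluate_dcls(syn, w_ho, cfg, cfg.n_test,
                            rng_for(cfg.seed, "dcls-eval"))
    return DCLSResult(synapses=syn, w_ho=w_ho, loss_history=loss_history,
                      metrics=metrics, config=cfg)
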