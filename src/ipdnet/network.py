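"""Forward dynamics of the three-layer IPD network.

Input Poisson spikes drive a hidden layer of leaky integrate-and-fire (LIF)
neurons through a dense weight matrix ``W_ih``; hidden spikes drive a layer
of leaky *non-spiking* readout neurons through ``W_ho``.  Each readout unit
is associated with one IPD class; the decision is the log-softmax of the
readout units' time-averaged membrane potentials.

Membrane dynamics follow tau dv/dt = -v between spikes, integrated with the
exact exponential update v <- v * exp(-dt/tau) per bin.  Input spikes
arriving in a bin are added after the decay; the threshold test (v >= 1)
and reset (v <- 0) happen in the same bin.

The spike nonlinearity is a Heaviside step in the forward pass; for
training, its pseudo-derivative is the fast-sigmoid surrogate

    d spike / d v  ~=  beta / (beta * |v - 1| + 1)^2

which is finite everywhere and peaks at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.signal import lfilter

from .task import SpikeBatch, class_to_midpoint

__all__ = [
    "NetworkParams", "ForwardTrace", "lif_forward", "readout_forward",
    "log_softmax", "classify", "surrogate_spike", "forward_full",
]

V_THRESHOLD = 1.0
V_RESET = 0.0


@dataclass
class NetworkParams:
    """Weights and neuron constants of the trainable model.

    ``w_ih`` has shape (2*n_psi, n_h); ``w_ho`` has shape (n_h, n_classes).
    ``tau_hidden`` and ``tau_readout`` are membrane time constants in
    seconds (separately configurable; the base model uses 2 ms for both).
    Optional sign masks implement Dale's principle: entry s of
    ``sign_mask_ih`` constrains every outgoing weight of presynaptic input
    unit s (one row of w_ih) to the given sign (+1 excitatory,
    -1 inhibitory, 0 unconstrained), and likewise ``sign_mask_ho`` for
    hidden units.
    """

    w_ih: np.ndarray
    w_ho: np.ndarray
    tau_hidden: float = 2e-3
    tau_readout: float = 2e-3
    v_th: float = V_THRESHOLD
    v_reset: float = V_RESET
    beta: float = 10.0
    sign_mask_ih: Optional[np.ndarray] = None
    sign_mask_ho: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.w_ih = np.asarray(self.w_ih, dtype=np.float64)
        self.w_ho = np.asarray(self.w_ho, dtype=np.float64)
        if self.w_ih.ndim != 2 or self.w_ho.ndim != 2:
            raise ValueError("weight matrices must be 2-D")
        if self.w_ih.shape[1] != self.w_ho.shape[0]:
            raise ValueError("w_ih columns must match w_ho rows (hidden size)")
        if self.tau_hidden <= 0 or self.tau_readout <= 0:
            raise ValueError("membrane time constants must be positive")
        for name, mask, w in (("sign_mask_ih", self.sign_mask_ih, self.w_ih),
                              ("sign_mask_ho", self.sign_mask_ho, self.w_ho)):
            if mask is not None:
                mask = np.asarray(mask)
                if mask.shape != (w.shape[0],):
                    raise ValueError(f"{name} must have one entry per presynaptic unit")
                bad = (mask[:, None] * w) < 0
                if np.any(bad):
                    raise ValueError(f"weights violate {name} sign constraint")

    @property
    def n_hidden(self) -> int:
        return self.w_ih.shape[1]

    @property
    def n_classes(self) -> int:
        return self.w_ho.shape[1]


@dataclass
class ForwardTrace:
    """Everything the forward pass computes for a batch of stimuli."""

    hidden_spikes: np.ndarray   # (trials, time, n_h) binary
    hidden_v: np.ndarray        # membrane before threshold test
    readout_v: np.ndarray       # (trials, time, n_classes)
    v_bar: np.ndarray           # (trials, n_classes) time-mean readout potential
    x: np.ndarray               # (trials, n_classes) log-softmax outputs


def _check_weights(w: np.ndarray, layer: str) -> None:
    if not np.all(np.isfinite(w)):
        raise FloatingPointError(f"non-finite weights in layer '{layer}'")


def lif_forward(spikes: np.ndarray, w: np.ndarray, tau: float, dt: float
                ) -> Tuple[np.ndarray, np.ndarray]:
    """LIF layer driven by a (trials, time, n_pre) spike tensor.

    Returns ``(out_spikes, v_trace)`` where ``v_trace`` holds the membrane
    potential *before* the threshold test of each bin (the value the
    surrogate derivative is evaluated at).
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    _check_weights(w, "hidden")
    spikes = np.asarray(spikes, dtype=np.float32)
    n_trials, n_bins, _ = spikes.shape
    n_post = w.shape[1]
    decay = np.float32(np.exp(-dt / tau))
    currents = spikes.reshape(-1, spikes.shape[2]) @ w.astype(np.float32)
    currents = currents.reshape(n_trials, n_bins, n_post)
    v = np.zeros((n_trials, n_post), dtype=np.float32)
    out = np.empty((n_trials, n_bins, n_post), dtype=np.float32)
    v_trace = np.empty_like(out)
    for t in range(n_bins):
        v *= decay
        v += currents[:, t]
        v_trace[:, t] = v
        s = (v >= V_THRESHOLD).astype(np.float32)
        out[:, t] = s
        v *= (1.0 - s)  # reset to 0 in the spiking bin
    return out, v_trace


def readout_forward(hidden_spikes: np.ndarray, w_ho: np.ndarray,
                    tau: float, dt: float) -> Tuple[np.ndarray, np.ndarray]:
    """Leaky non-spiking readout: same integration, no threshold.

    Returns ``(v_trace, v_bar)`` with ``v_bar`` the time-mean membrane
    potential over the whole stimulus (onset transient included).
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    _check_weights(w_ho, "readout")
    hidden_spikes = np.asarray(hidden_spikes, dtype=np.float32)
    n_trials, n_bins, _ = hidden_spikes.shape
    currents = hidden_spikes.reshape(-1, hidden_spikes.shape[2]) @ w_ho.astype(np.float32)
    currents = currents.reshape(n_trials, n_bins, w_ho.shape[1])
    decay = float(np.exp(-dt / tau))
    # v[t] = decay*v[t-1] + I[t]  ==  IIR filter with a = [1, -decay]
    v_trace = lfilter([1.0], [1.0, -decay], currents, axis=1).astype(np.float32)
    v_bar = v_trace.mean(axis=1)
    return v_trace, v_bar


def log_softmax(v_bar: np.ndarray) -> np.ndarray:
    """Row-wise log-softmax with max subtraction for stability."""
    v = np.asarray(v_bar, dtype=np.float64)
    shifted = v - v.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def classify(scores: np.ndarray, n_classes: int
             ) -> Tuple[np.ndarray, np.ndarray]:
    """Most-active-unit decision; ties break toward the lowest index.

    ``scores`` may be v_bar or its log-softmax — argmax is unaffected.
    Returns ``(k_hat, ipd_hat)`` with ipd_hat the class-interval midpoint.
    """
    scores = np.atleast_2d(scores)
    if scores.shape[-1] != n_classes:
        raise ValueError("scores last dimension must equal n_classes")
    k_hat = np.argmax(scores, axis=-1)
    return k_hat, class_to_midpoint(k_hat, n_classes)


def surrogate_spike(v, beta: float = 10.0):
    """Heaviside spike with fast-sigmoid pseudo-derivative.

    Returns ``(spike, d_spike_dv)`` with spike = step(v - 1) and
    d_spike_dv = beta / (beta*|v - 1| + 1)^2.
    """
    v = np.asarray(v, dtype=np.float64)
    spike = (v >= V_THRESHOLD).astype(np.float64)
    deriv = beta / (beta * np.abs(v - V_THRESHOLD) + 1.0) ** 2
    return spike, deriv


def forward_full(batch: SpikeBatch, params: NetworkParams) -> ForwardTrace:
    """Run a SpikeBatch through the whole network."""
    hidden_spikes, hidden_v = lif_forward(
        batch.spikes, params.w_ih, params.tau_hidden, batch.dt)
    readout_v, v_bar = readout_forward(
        hidden_spikes, params.w_ho, params.tau_readout, batch.dt)
    return ForwardTrace(
        hidden_spikes=hidden_spikes,
        hidden_v=hidden_v,
        readout_v=readout_v,
        v_bar=v_bar,
        x=log_softmax(v_bar),
    )
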