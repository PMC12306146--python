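"""Surrogate-gradient training of the IPD network.

The loss is cross-entropy on the log-softmax outputs plus an optional
firing-rate regulariser on the hidden layer: with per-neuron batch-mean
rate r_m (spikes/s),

    L_m = 0                                   if r_m <= r_minus
    L_m = ((r_m - r_minus)/(r_plus - r_minus))**2   otherwise
    L   = c * sum_m L_m / N_h

so a neuron at r_plus contributes 1 and anything below r_minus is free.
``c`` defaults to ln(N_c), the initial cross-entropy of a uniform
predictor, which makes rates near r_plus heavily penalised relative to the
classification loss.

Gradients are computed by backpropagation through time.  The spike step is
replaced in the backward pass by the fast-sigmoid surrogate derivative
(see :mod:`ipdnet.network`); the post-spike reset factor is treated as
constant in the backward pass (the standard surrogate-gradient choice,
which avoids the unstable -v * ds/dv term).  The backward recursions are
written out analytically, so the trainer needs nothing beyond numpy:

    readout:  dL/du_t = g_vbar / T,  accumulated as a geometric series
    hidden:   gv_t = gH_t * sd_t + a * (1 - s_t) * gv_{t+1}

with a = exp(-dt/tau), sd the surrogate derivative at the pre-reset
voltage, and gH the gradient arriving at the spike train (readout
backprojection + regulariser).

Dale's principle is enforced by sign-magnitude reparameterisation: each
presynaptic unit u is assigned a fixed sign sigma_u and the effective
weights are W = sigma * |theta|, so no optimizer step can flip a sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .network import NetworkParams, V_THRESHOLD, log_softmax, readout_forward, classify
from .seeding import rng_for
from .task import TaskConfig, SpikeBatch, batch_rates, generate_spikes, \
    sample_ipds, ipd_to_class, class_to_midpoint, make_batch

__all__ = [
    "TrainConfig", "TrainResult", "EvalReport", "cross_entropy_loss",
    "rate_regularizer", "loss_and_grads", "train", "evaluate",
    "apply_dale_constraint", "assign_dale_signs", "Adam",
]

DALE_MODES = ("none", "balanced", "excitatory_only", "inhibitory_only", "custom")


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    n_train: int = 16384          # stimuli per epoch
    batch_size: int = 128
    epochs: int = 100
    learning_rate: float = 1e-3
    r_minus: float = 100.0        # regulariser free zone, spikes/s
    r_plus: float = 200.0         # regulariser unit-penalty rate, spikes/s
    c: Optional[float] = None     # regulariser scale; None -> ln(n_classes)
    seed: int = 0
    n_hidden: int = 8
    tau_hidden: float = 2e-3
    tau_readout: float = 2e-3
    beta: float = 10.0
    dale_mode: str = "none"
    dale_frac_input: float = 0.5   # inhibitory fraction, input layer ('custom')
    dale_frac_hidden: float = 0.5  # inhibitory fraction, hidden layer ('custom')
    fixed_dataset: bool = False    # reuse one epoch's stimuli every epoch
    n_test: int = 4096

    def __post_init__(self) -> None:
        if not (self.r_plus > self.r_minus >= 0):
            raise ValueError("need r_plus > r_minus >= 0")
        if self.n_train % self.batch_size != 0:
            raise ValueError("batch_size must divide n_train")
        if self.dale_mode not in DALE_MODES:
            raise ValueError(f"dale_mode must be one of {DALE_MODES}")

    def reg_scale(self, n_classes: int) -> float:
        return float(np.log(n_classes)) if self.c is None else self.c


@dataclass
class EvalReport:
    """Test-set metrics of a trained network.

    ``mae_deg`` is the mean absolute IPD error between the estimated and
    true class midpoints (zero for a perfect classifier).  For reference,
    ``mae_deg_continuous`` measures against the continuous true IPD, which
    has an irreducible within-bin quantisation floor of (180/N_c)/4
    degrees even for a perfect classifier.
    """

    accuracy: float
    mae_deg: float
    confusion: np.ndarray       # (n_classes, n_classes), rows = true class
    hidden_rates: np.ndarray    # per-neuron mean rate, spikes/s
    n_test: int
    mae_deg_continuous: float = np.nan

    def to_dict(self) -> dict:
        return {
            "accuracy": float(self.accuracy),
            "mae_deg": float(self.mae_deg),
            "mae_deg_continuous": float(self.mae_deg_continuous),
            "confusion": self.confusion.tolist(),
            "hidden_rates": self.hidden_rates.tolist(),
            "n_test": int(self.n_test),
        }


@dataclass
class TrainResult:
    params: NetworkParams
    loss_history: np.ndarray
    metrics: EvalReport
    config: Optional[TrainConfig] = None
    task: Optional[TaskConfig] = None


def cross_entropy_loss(x: np.ndarray, k_true: np.ndarray) -> float:
    """Mean negative log-likelihood of the true classes.

    ``x`` must already be log-softmax outputs (rows normalised).
    """
    x = np.atleast_2d(x)
    k_true = np.asarray(k_true, dtype=np.int64)
    return float(-x[np.arange(len(k_true)), k_true].mean())


def rate_regularizer(hidden_spikes: np.ndarray, duration: float,
                     r_minus: float, r_plus: float, c: float) -> float:
    """Firing-rate penalty on batch-averaged per-neuron hidden rates."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    hidden_spikes = np.asarray(hidden_spikes)
    n_trials = hidden_spikes.shape[0]
    n_h = hidden_spikes.shape[2]
    rates = hidden_spikes.sum(axis=(0, 1)) / (n_trials * duration)
    over = np.maximum(rates - r_minus, 0.0) / (r_plus - r_minus)
    return float(c * np.sum(over**2) / n_h)


# ----------------------------------------------------------------------
# BPTT core


def _soft_spike(v: np.ndarray, beta: float) -> Tuple[np.ndarray, np.ndarray]:
    """Differentiable spike relaxation whose derivative is the fast sigmoid.

    Used only for gradient verification: s(v) integrates the surrogate
    derivative, so the analytic backward pass can be checked against finite
    differences without the step discontinuity.
    """
    u = v - V_THRESHOLD
    s = 0.5 + 0.5 * beta * u / (1.0 + beta * np.abs(u))
    ds = 0.5 * beta / (1.0 + beta * np.abs(u)) ** 2
    return s, ds


def loss_and_grads(spikes: np.ndarray, k_true: np.ndarray,
                   params: NetworkParams, cfg: TrainConfig, dt: float,
                   soft: bool = False) -> Tuple[dict, Dict[str, np.ndarray]]:
    """One forward/backward pass; returns (loss parts, weight gradients).

    ``soft=True`` replaces the hard threshold by the differentiable
    relaxation (and then backpropagates exactly, including through the
    reset), which is what the finite-difference gradient check exercises.
    """
    # float64 in soft (gradient-check) mode so finite differences are not
    # limited by single precision
    ftype = np.float64 if soft else np.float32
    w_ih = params.w_ih.astype(ftype)
    w_ho = params.w_ho.astype(ftype)
    beta = params.beta
    spikes = np.asarray(spikes, dtype=ftype)
    n_trials, n_bins, n_in = spikes.shape
    n_h, n_c = w_ho.shape
    duration = n_bins * dt
    a_dec = ftype(np.exp(-dt / params.tau_hidden))
    b_dec = float(np.exp(-dt / params.tau_readout))

    # ---- forward, hidden LIF
    currents = (spikes.reshape(-1, n_in) @ w_ih).reshape(n_trials, n_bins, n_h)
    v = np.zeros((n_trials, n_h), dtype=ftype)
    s_rec = np.empty((n_trials, n_bins, n_h), dtype=ftype)
    sd_rec = np.empty_like(s_rec)
    keep_rec = np.empty_like(s_rec)  # d v_post / d v_pre along the carry path
    for t in range(n_bins):
        v = v * a_dec + currents[:, t]
        if soft:
            s, sd = _soft_spike(v, beta)
            keep = (1.0 - s) - v * sd
        else:
            s = (v >= V_THRESHOLD).astype(ftype)
            u = np.abs(v - V_THRESHOLD)
            sd = (beta / (beta * u + 1.0) ** 2).astype(ftype)
            keep = 1.0 - s
        s_rec[:, t] = s
        sd_rec[:, t] = sd
        keep_rec[:, t] = keep   # backward factor d v_post / d v_pre
        v = v * (1.0 - s)       # forward reset is v*(1-s) in both modes

    # ---- forward, readout + losses (leaky integration as IIR filter)
    from scipy.signal import lfilter
    ro_currents = (s_rec.reshape(-1, n_h) @ w_ho).reshape(n_trials, n_bins, n_c)
    readout_v = lfilter([1.0], [1.0, -b_dec], ro_currents, axis=1).astype(ftype)
    v_bar = readout_v.mean(axis=1)
    x = log_softmax(v_bar)
    ce = cross_entropy_loss(x, k_true)
    c_scale = cfg.reg_scale(n_c)
    rates = s_rec.sum(axis=(0, 1)) / (n_trials * duration)
    over = np.maximum(rates - cfg.r_minus, 0.0) / (cfg.r_plus - cfg.r_minus)
    reg = float(c_scale * np.sum(over**2) / n_h)

    # ---- backward, readout
    probs = np.exp(x)
    g_vbar = probs.copy()
    g_vbar[np.arange(n_trials), np.asarray(k_true, dtype=np.int64)] -= 1.0
    g_vbar /= n_trials
    # dL/du_t is g_vbar/T for every t; the leaky recursion u_t = b*u_{t-1}+I_t
    # accumulates it into G_t = (g_vbar/T) * (1 - b^(T-t)) / (1 - b).
    geo = (1.0 - b_dec ** np.arange(n_bins, 0, -1)) / (1.0 - b_dec)
    G = (g_vbar[:, None, :] / n_bins) * geo[None, :, None]
    G = G.astype(ftype)
    grad_w_ho = s_rec.reshape(-1, n_h).T @ G.reshape(-1, n_c)
    g_H = (G.reshape(-1, n_c) @ w_ho.T).reshape(n_trials, n_bins, n_h)

    # regulariser gradient through the (surrogate) spike counts
    coef = (c_scale / n_h) * 2.0 * np.maximum(rates - cfg.r_minus, 0.0) \
        / (cfg.r_plus - cfg.r_minus) ** 2 / (n_trials * duration)
    g_H = g_H + coef[None, None, :].astype(ftype)

    # ---- backward, hidden recursion:
    # dL/dv_pre[t] = gH[t]*sd[t] + a*keep[t]*dL/dv_pre[t+1]
    gv_all = np.empty_like(g_H)
    gv_next = np.zeros((n_trials, n_h), dtype=ftype)
    for t in range(n_bins - 1, -1, -1):
        gv_next = g_H[:, t] * sd_rec[:, t] + a_dec * keep_rec[:, t] * gv_next
        gv_all[:, t] = gv_next
    grad_w_ih = spikes.reshape(-1, n_in).T @ gv_all.reshape(-1, n_h)

    losses = {"total": ce + reg, "ce": ce, "reg": reg,
              "rates": rates, "v_bar": v_bar, "x": x}
    grads = {"w_ih": grad_w_ih.astype(np.float64),
             "w_ho": grad_w_ho.astype(np.float64)}
    return losses, grads


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, shapes: Dict[str, tuple], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / \
                (np.sqrt(self.v[k] / b2t) + self.eps)


# ----------------------------------------------------------------------
# Dale's principle


def assign_dale_signs(n_units: int, frac_inhibitory: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Random assignment of +1/-1 signs with a given inhibitory fraction."""
    n_inh = int(round(frac_inhibitory * n_units))
    signs = np.ones(n_units, dtype=np.int8)
    inh = rng.choice(n_units, size=n_inh, replace=False)
    signs[inh] = -1
    return signs


def apply_dale_constraint(params: NetworkParams, mode: str,
                          rng: np.random.Generator,
                          frac_input: float = 0.5,
                          frac_hidden: float = 0.5) -> NetworkParams:
    """Assign per-presynaptic-unit signs and conform weights to them.

    Weights become sign * |w|; returned params carry the sign masks so the
    trainer's sign-magnitude parameterisation keeps the constraint exact
    after every optimizer step.
    """
    if mode == "none":
        return params
    if mode == "balanced":
        frac_input = frac_hidden = 0.5
    elif mode == "excitatory_only":
        frac_input = frac_hidden = 0.0
    elif mode == "inhibitory_only":
        frac_input = frac_hidden = 1.0
    elif mode != "custom":
        raise ValueError(f"unknown dale mode '{mode}'")
    sign_ih = assign_dale_signs(params.w_ih.shape[0], frac_input, rng)
    sign_ho = assign_dale_signs(params.w_ho.shape[0], frac_hidden, rng)
    return NetworkParams(
        w_ih=sign_ih[:, None] * np.abs(params.w_ih),
        w_ho=sign_ho[:, None] * np.abs(params.w_ho),
        tau_hidden=params.tau_hidden, tau_readout=params.tau_readout,
        beta=params.beta,
        sign_mask_ih=sign_ih, sign_mask_ho=sign_ho,
    )


def _effective(theta: np.ndarray, sign: Optional[np.ndarray]) -> np.ndarray:
    if sign is None:
        return theta
    return sign[:, None] * np.abs(theta)


def _grad_to_theta(grad_w: np.ndarray, theta: np.ndarray,
                   sign: Optional[np.ndarray]) -> np.ndarray:
    if sign is None:
        return grad_w
    return grad_w * sign[:, None] * np.sign(theta)


# ----------------------------------------------------------------------
# Training loop and evaluation


def init_params(task_cfg: TaskConfig, cfg: TrainConfig,
                rng: np.random.Generator) -> NetworkParams:
    """Uniform +-sqrt(1/fan_in) initialisation, seeded."""
    n_in = task_cfg.n_inputs
    lim_ih = np.sqrt(1.0 / n_in)
    lim_ho = np.sqrt(1.0 / cfg.n_hidden)
    return NetworkParams(
        w_ih=rng.uniform(-lim_ih, lim_ih, size=(n_in, cfg.n_hidden)),
        w_ho=rng.uniform(-lim_ho, lim_ho, size=(cfg.n_hidden, task_cfg.n_classes)),
        tau_hidden=cfg.tau_hidden, tau_readout=cfg.tau_readout, beta=cfg.beta,
    )


def train(task_cfg: TaskConfig, cfg: TrainConfig,
          net_init: Optional[NetworkParams] = None,
          progress: bool = False) -> TrainResult:
    """Train the network with Adam on cross-entropy + rate regulariser.

    Fresh stimuli are sampled every epoch (``fixed_dataset=True`` freezes
    one draw for ablations).  Deterministic given ``cfg.seed``.
    """
    init_rng = rng_for(cfg.seed, "init")
    data_rng = rng_for(cfg.seed, "train-data")
    dale_rng = rng_for(cfg.seed, "dale")

    params = net_init if net_init is not None else init_params(task_cfg, cfg, init_rng)
    if cfg.dale_mode != "none":
        params = apply_dale_constraint(params, cfg.dale_mode, dale_rng,
                                       cfg.dale_frac_input, cfg.dale_frac_hidden)
    theta = {"w_ih": params.w_ih.copy(), "w_ho": params.w_ho.copy()}
    signs = {"w_ih": params.sign_mask_ih, "w_ho": params.sign_mask_ho}

    opt = Adam({k: v.shape for k, v in theta.items()}, lr=cfg.learning_rate)
    n_batches = cfg.n_train // cfg.batch_size
    loss_history = np.empty(cfg.epochs)

    fixed_ipds = None
    if cfg.fixed_dataset:
        fixed_ipds = sample_ipds(cfg.n_train, data_rng,
                                 task_cfg.ipd_min, task_cfg.ipd_max)

    for epoch in range(cfg.epochs):
        if fixed_ipds is not None:
            epoch_ipds = fixed_ipds
        else:
            epoch_ipds = sample_ipds(cfg.n_train, data_rng,
                                     task_cfg.ipd_min, task_cfg.ipd_max)
        labels = ipd_to_class(epoch_ipds, task_cfg.n_classes)
        epoch_loss = 0.0
        for b in range(n_batches):
            sl = slice(b * cfg.batch_size, (b + 1) * cfg.batch_size)
            rates = batch_rates(epoch_ipds[sl], task_cfg)
            spikes = generate_spikes(rates, task_cfg.dt, data_rng,
                                     validate=False)
            eff = NetworkParams(
                w_ih=_effective(theta["w_ih"], signs["w_ih"]),
                w_ho=_effective(theta["w_ho"], signs["w_ho"]),
                tau_hidden=cfg.tau_hidden, tau_readout=cfg.tau_readout,
                beta=cfg.beta,
                sign_mask_ih=signs["w_ih"], sign_mask_ho=signs["w_ho"])
            losses, grads = loss_and_grads(spikes, labels[sl], eff, cfg,
                                           task_cfg.dt)
            if not np.isfinite(losses["total"]):
                raise RuntimeError(
                    f"training diverged (loss={losses['total']}) at epoch "
                    f"{epoch}, batch {b}, learning_rate={cfg.learning_rate}")
            g_theta = {k: _grad_to_theta(grads[k], theta[k], signs[k])
                       for k in theta}
            opt.step(theta, g_theta)
            epoch_loss += losses["total"]
        loss_history[epoch] = epoch_loss / n_batches
        if progress:
            print(f"epoch {epoch + 1:3d}/{cfg.epochs}  "
                  f"loss {loss_history[epoch]:.4f}")

    final = NetworkParams(
        w_ih=_effective(theta["w_ih"], signs["w_ih"]),
        w_ho=_effective(theta["w_ho"], signs["w_ho"]),
        tau_hidden=cfg.tau_hidden, tau_readout=cfg.tau_readout, beta=cfg.beta,
        sign_mask_ih=signs["w_ih"], sign_mask_ho=signs["w_ho"])
    metrics = evaluate(final, task_cfg, cfg.n_test, rng_for(cfg.seed, "eval"))
    return TrainResult(params=final, loss_history=loss_history,
                       metrics=metrics, config=cfg, task=task_cfg)


def evaluate(params: NetworkParams, task_cfg: TaskConfig, n_test: int,
             rng: np.random.Generator, batch: int = 1024) -> EvalReport:
    """Accuracy, MAE (degrees), confusion matrix and hidden rates on fresh stimuli."""
    if n_test < 1:
        raise ValueError("n_test must be positive")
    from .network import forward_full  # local import to avoid cycle at module load
    n_c = task_cfg.n_classes
    confusion = np.zeros((n_c, n_c), dtype=np.int64)
    correct = 0
    abs_err_class = 0.0
    abs_err_cont = 0.0
    spike_totals = None
    done = 0
    while done < n_test:
        nb = min(batch, n_test - done)
        sb = make_batch(nb, task_cfg, rng)
        trace = forward_full(sb, params)
        k_hat, ipd_hat = classify(trace.v_bar, n_c)
        correct += int((k_hat == sb.class_true).sum())
        mid_true = class_to_midpoint(sb.class_true, n_c)
        abs_err_class += float(np.abs(ipd_hat - mid_true).sum())
        abs_err_cont += float(np.abs(ipd_hat - sb.ipd_true).sum())
        np.add.at(confusion, (sb.class_true, k_hat), 1)
        counts = trace.hidden_spikes.sum(axis=(0, 1))
        spike_totals = counts if spike_totals is None else spike_totals + counts
        done += nb
    hidden_rates = spike_totals / (n_test * task_cfg.duration)
    return EvalReport(
        accuracy=correct / n_test,
        mae_deg=np.degrees(abs_err_class / n_test),
        confusion=confusion,
        hidden_rates=hidden_rates,
        n_test=n_test,
        mae_deg_continuous=np.degrees(abs_err_cont / n_test),
    )
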