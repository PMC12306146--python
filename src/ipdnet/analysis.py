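"""Post-training analysis of the IPD network.

Trained hidden units reliably develop *dip-shaped* IPD tuning: a high
baseline with a suppressed response at a least-preferred phase difference.
This module quantifies that structure and reduces the trained network to a
six-parameter description:

* per-neuron tuning curves (hidden firing rates, readout mean potentials);
* Gaussian-dip fits  a + b * exp(-(alpha - alpha_i)^2 / (2 sigma_a^2));
* a Ricker-wavelet ("Mexican hat") fit of the hidden-to-output weights
  W_ho ~ a (1 - (delta/sigma_d)^2) exp(-delta^2/(2 sigma_d^2)) + b with
  delta = o - N_c * h / N_h, capturing broad excitation with narrow
  inhibition (with a < 0: narrow inhibition on the diagonal);
* a rate-based closed form for hidden firing rates that ignores spike
  timing entirely: a LIF driven by constant suprathreshold drive r (in
  threshold units) fires at 1 / (t_refrac + tau * ln(r / (r - 1)));
* the reduced model: idealised Gaussian-dip hidden curves passed through
  the Ricker weight model — six free parameters replacing the full
  network's weights.

The quality of these approximations is the evidence that the trained
network uses a rate-based equalisation-cancellation-like strategy rather
than spike-timing coincidence detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit

from .network import NetworkParams, forward_full
from .task import TaskConfig, make_batch, batch_rates
from .training import EvalReport

__all__ = [
    "TuningCurve", "GaussianDipFit", "RickerFit", "ReducedModel",
    "tuning_curves", "fit_gaussian_dip", "fit_ricker", "rate_approximation",
    "hidden_drive", "rate_based_tuning", "reorder_hidden_by_worst_delay",
    "apply_hidden_permutation", "fit_reduced_model", "reduced_model_predict",
    "smooth_spikes",
]


@dataclass
class TuningCurve:
    """Mean response of one unit as a function of IPD, normalised to max 1."""

    ipd_grid: np.ndarray
    rate: np.ndarray
    neuron_id: int
    layer: str = "hidden"
    silent: bool = False


@dataclass
class GaussianDipFit:
    """a + b * exp(-(alpha - alpha_i)^2 / (2 sigma_alpha^2)); b < 0 is a dip."""

    a: float
    b: float
    alpha_i: float
    sigma_alpha: float
    r_squared: float = np.nan

    def __call__(self, alpha) -> np.ndarray:
        alpha = np.asarray(alpha, dtype=np.float64)
        return self.a + self.b * np.exp(
            -((alpha - self.alpha_i) ** 2) / (2 * self.sigma_alpha**2))


@dataclass
class RickerFit:
    """W(delta) = a (1-(delta/sigma)^2) exp(-delta^2/(2 sigma^2)) + b."""

    a: float
    b: float
    sigma_delta: float
    r_squared: float = np.nan

    def __call__(self, delta) -> np.ndarray:
        delta = np.asarray(delta, dtype=np.float64)
        z2 = (delta / self.sigma_delta) ** 2
        return self.a * (1 - z2) * np.exp(-z2 / 2) + self.b


@dataclass
class ReducedModel:
    """Six parameters: (a, b, sigma_alpha) of the idealised hidden tuning
    and (a, b, sigma_delta) of the Ricker weight model."""

    dip: GaussianDipFit
    ricker: RickerFit

    @property
    def n_params(self) -> int:
        return 6


def tuning_curves(params: NetworkParams, task_cfg: TaskConfig,
                  ipd_grid: Optional[np.ndarray] = None,
                  trials_per_point: int = 50,
                  rng: Optional[np.random.Generator] = None
                  ) -> Tuple[List[TuningCurve], List[TuningCurve]]:
    """Monte-Carlo tuning curves for hidden and output layers.

    Hidden curves are per-neuron mean firing rates, output curves the mean
    readout potentials v_bar, each normalised to a maximum of 1.  Neurons
    with no positive response anywhere are flagged silent and left
    unnormalised.
    """
    if trials_per_point < 10:
        raise ValueError("need at least 10 trials per grid point")
    if rng is None:
        rng = np.random.default_rng(0)
    if ipd_grid is None:
        ipd_grid = np.linspace(-np.pi / 2, np.pi / 2, 37)
    n_h, n_c = params.n_hidden, params.n_classes
    hid = np.zeros((len(ipd_grid), n_h))
    out = np.zeros((len(ipd_grid), n_c))
    for g, alpha in enumerate(ipd_grid):
        batch = make_batch(trials_per_point, task_cfg, rng,
                           ipds=np.full(trials_per_point, alpha))
        trace = forward_full(batch, params)
        hid[g] = trace.hidden_spikes.sum(axis=(0, 1)) / \
            (trials_per_point * task_cfg.duration)
        out[g] = trace.v_bar.mean(axis=0)

    def _normalise(col: np.ndarray) -> Tuple[np.ndarray, bool]:
        peak = col.max()
        if peak <= 0:
            return col, True
        return col / peak, False

    hidden_curves, output_curves = [], []
    for m in range(n_h):
        rate, silent = _normalise(hid[:, m])
        hidden_curves.append(TuningCurve(ipd_grid, rate, m, "hidden", silent))
    for k in range(n_c):
        rate, silent = _normalise(out[:, k])
        output_curves.append(TuningCurve(ipd_grid, rate, k, "output", silent))
    return hidden_curves, output_curves


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def fit_gaussian_dip(curve: TuningCurve) -> GaussianDipFit:
    """Trust-region least squares fit of the dip model to one tuning curve.

    The dip centre is initialised at the curve's argmin and the width at
    three grid spacings.  A flat curve comes back with |b| ~ 0 and
    r_squared near 0 — degenerate but not an error.
    """
    alpha = np.asarray(curve.ipd_grid, dtype=np.float64)
    y = np.asarray(curve.rate, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("tuning curve contains non-finite values")
    spacing = np.median(np.diff(alpha))
    p0 = [float(y.max()), float(y.min() - y.max()),
          float(alpha[np.argmin(y)]), float(3 * spacing)]

    def model(a_grid, a, b, alpha_i, sigma):
        return a + b * np.exp(-((a_grid - alpha_i) ** 2) / (2 * sigma**2))

    try:
        popt, _ = curve_fit(model, alpha, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"Gaussian-dip fit did not converge (p0={p0}, "
            f"residual at p0={np.sum((y - model(alpha, *p0))**2):.3g})"
        ) from err
    popt[3] = abs(popt[3])
    fit = GaussianDipFit(*popt)
    fit.r_squared = _r_squared(y, fit(alpha))
    return fit


def fit_ricker(w_ho: np.ndarray, n_h: Optional[int] = None,
               n_c: Optional[int] = None) -> RickerFit:
    """Fit the Ricker wavelet to all (hidden, output) weight pairs.

    ``w_ho`` should already have its rows ordered by the hidden units'
    least-preferred IPD (see :func:`reorder_hidden_by_worst_delay`), so
    that delta = o - N_c * h / N_h aligns the wavelet across rows.
    """
    w_ho = np.asarray(w_ho, dtype=np.float64)
    n_h = n_h if n_h is not None else w_ho.shape[0]
    n_c = n_c if n_c is not None else w_ho.shape[1]
    h_idx, o_idx = np.meshgrid(np.arange(n_h), np.arange(n_c), indexing="ij")
    delta = (o_idx - n_c * h_idx / n_h).ravel()
    y = w_ho.ravel()

    def model(d, a, b, sigma):
        z2 = (d / sigma) ** 2
        return a * (1 - z2) * np.exp(-z2 / 2) + b

    p0 = [float(y.min() - y.mean()), float(y.mean()), 1.5]
    try:
        popt, _ = curve_fit(model, delta, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"Ricker fit did not converge (p0={p0}, residual at "
            f"p0={np.sum((y - model(delta, *p0))**2):.3g})") from err
    popt[2] = abs(popt[2])
    fit = RickerFit(*popt)
    fit.r_squared = _r_squared(y, fit(delta))
    return fit


def rate_approximation(r_in: np.ndarray, tau: float,
                       t_refrac: float) -> np.ndarray:
    """Closed-form LIF firing rate for drive ``r_in`` in threshold units.

    r_h = 0 where r_in <= 1, else 1 / (t_refrac + tau * ln(r_in/(r_in-1))).
    Exact for constant drive in continuous time (with refractory period
    t_refrac, equal to one time step in the discrete simulation); a good
    approximation even for time-varying drive.
    """
    if t_refrac <= 0:
        raise ValueError("t_refrac must be positive")
    r_in = np.asarray(r_in, dtype=np.float64)
    out = np.zeros_like(r_in)
    above = r_in > 1.0
    ra = r_in[above]
    out[above] = 1.0 / (t_refrac + tau * np.log(ra / (ra - 1.0)))
    return out


def hidden_drive(rates: np.ndarray, w_ih: np.ndarray, tau: float,
                 dt: float) -> np.ndarray:
    """Hidden-unit drive trace in threshold units.

    Input rates (spikes/s) weighted by W_ih give a mean injected charge of
    sum_j W[j,h] R_j(t) dt per bin; with per-bin decay exp(-dt/tau) the
    membrane's steady state is that divided by (1 - exp(-dt/tau)).  Since
    the spike threshold is 1, the steady-state voltage *is* the drive in
    threshold units that the closed-form rate expects.
    """
    decay = np.exp(-dt / tau)
    return (rates @ w_ih) * dt / (1.0 - decay)


def rate_based_tuning(params: NetworkParams, task_cfg: TaskConfig,
                      ipd_grid: np.ndarray,
                      t_refrac: Optional[float] = None
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Spike-free prediction of hidden rates and readout activity.

    Returns ``(hidden, output)`` arrays of shape (grid, N_h) and
    (grid, N_c): the hidden rates are the closed form applied to the
    time-varying drive and averaged over time; the outputs are
    r_o = sum_h W_ho[h, o] * r_h, likewise time-averaged.
    """
    if t_refrac is None:
        t_refrac = task_cfg.dt
    ipd_grid = np.asarray(ipd_grid)
    rates = batch_rates(ipd_grid, task_cfg).astype(np.float64)  # (G, T, Ni)
    hidden = np.empty((len(ipd_grid), params.n_hidden))
    output = np.empty((len(ipd_grid), params.n_classes))
    for g in range(len(ipd_grid)):
        drive = hidden_drive(rates[g], params.w_ih, params.tau_hidden,
                             task_cfg.dt)
        r_h = rate_approximation(drive, params.tau_hidden, t_refrac)
        hidden[g] = r_h.mean(axis=0)
        output[g] = (r_h @ params.w_ho).mean(axis=0)
    return hidden, output


def reorder_hidden_by_worst_delay(fits: Sequence[GaussianDipFit]
                                  ) -> np.ndarray:
    """Permutation sorting hidden units by fitted least-preferred IPD.

    Ties break by neuron index (stable sort).  Apply with
    :func:`apply_hidden_permutation` to keep W_ih columns and W_ho rows
    consistent.
    """
    alphas = np.array([f.alpha_i for f in fits])
    return np.argsort(alphas, kind="stable")


def apply_hidden_permutation(params: NetworkParams,
                             perm: np.ndarray) -> NetworkParams:
    """Reorder hidden units of a network by ``perm``."""
    return NetworkParams(
        w_ih=params.w_ih[:, perm],
        w_ho=params.w_ho[perm, :],
        tau_hidden=params.tau_hidden, tau_readout=params.tau_readout,
        beta=params.beta,
        sign_mask_ih=params.sign_mask_ih,
        sign_mask_ho=None if params.sign_mask_ho is None
        else params.sign_mask_ho[perm],
    )


def fit_reduced_model(params: NetworkParams, task_cfg: TaskConfig,
                      hidden_curves: Sequence[TuningCurve],
                      dip_fits: Sequence[GaussianDipFit]) -> ReducedModel:
    """Distil a trained network into the six-parameter reduced model.

    Hidden units are reordered by their fitted least-preferred IPD; one
    (a, b, sigma_alpha) triple is then fitted *jointly* across all
    reordered curves with the dip centres fixed at the idealised tiling
    alpha_i = -pi/2 + i*pi/N_h, and the Ricker triple is fitted to the
    reordered hidden-to-output weights.
    """
    n_h = params.n_hidden
    perm = reorder_hidden_by_worst_delay(dip_fits)
    grid = np.asarray(hidden_curves[0].ipd_grid)
    curves = np.stack([np.asarray(hidden_curves[p].rate) for p in perm])
    alpha_i = -np.pi / 2 + np.arange(n_h) * np.pi / n_h
    centers = np.repeat(alpha_i, len(grid))
    grids = np.tile(grid, n_h)
    y = curves.ravel()

    def model(_x, a, b, sigma):
        return a + b * np.exp(-((grids - centers) ** 2) / (2 * sigma**2))

    popt, _ = curve_fit(model, np.arange(y.size), y,
                        p0=[float(y.max()), float(y.min() - y.max()),
                            float(np.pi / n_h)], maxfev=20000)
    dip = GaussianDipFit(popt[0], popt[1], 0.0, abs(popt[2]))
    dip.r_squared = _r_squared(y, model(None, *popt))
    ricker = fit_ricker(apply_hidden_permutation(params, perm).w_ho)
    return ReducedModel(dip=dip, ricker=ricker)


def reduced_model_predict(rm: ReducedModel, ipds: np.ndarray, n_h: int,
                          n_c: int) -> Tuple[np.ndarray, np.ndarray]:
    """Output activity and classifications of the six-parameter model.

    Idealised hidden curves dip at alpha_i = -pi/2 + i*pi/N_h; the
    hidden-to-output weights are the Ricker wavelet evaluated at
    delta = o - N_c*h/N_h.  No trained weight enters.  Returns
    ``(outputs, k_hat)`` with outputs of shape (len(ipds), N_c).
    """
    ipds = np.atleast_1d(np.asarray(ipds, dtype=np.float64))
    alpha_i = -np.pi / 2 + np.arange(n_h) * np.pi / n_h
    hidden = rm.dip.a + rm.dip.b * np.exp(
        -((ipds[:, None] - alpha_i[None, :]) ** 2)
        / (2 * rm.dip.sigma_alpha**2))
    h_idx, o_idx = np.meshgrid(np.arange(n_h), np.arange(n_c), indexing="ij")
    w = rm.ricker(o_idx - n_c * h_idx / n_h)
    outputs = hidden @ w
    return outputs, np.argmax(outputs, axis=1)


def smooth_spikes(spikes: np.ndarray, kernel_sigma: float,
                  axis: int = 1) -> np.ndarray:
    """Gaussian temporal smoothing of a spike tensor.

    ``kernel_sigma`` is in time bins.  The kernel is normalised, so total
    spike mass is preserved up to truncation at the edges.
    """
    if kernel_sigma < 0:
        raise ValueError("kernel_sigma must be nonnegative")
    spikes = np.asarray(spikes, dtype=np.float64)
    if kernel_sigma < 1e-12:
        return spikes.copy()
    return gaussian_filter1d(spikes, sigma=kernel_sigma, axis=axis,
                             mode="constant")
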