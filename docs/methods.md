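# Methods

`ipdnet` is a laboratory for studying how small spiking networks extract
the interaural phase difference (IPD) of a pure tone, how input delays can
be *learned* rather than preassigned, and how the trained solutions can be
understood. Everything is generated internally; there is no external data.

## Task and stimulus model

A tone of frequency `f` (default 50 Hz) reaches the two ears with IPD
`alpha` drawn uniformly from [-pi/2, pi/2] (frontal plane; for a pure tone
the IPD and the interaural time difference are interchangeable). Ear `i`
(0 = left, 1 = right; only the right ear carries `alpha`) feeds `N_psi`
input neurons (default 100/ear) with phase delays `psi_j = j*pi/(2(N_psi-1))`
tiling [0, pi/2] endpoints included. Neuron (i, j) fires as an
inhomogeneous Poisson process with intensity

    R_ij(t) = R_max * ((1 + sin(2 pi f t + i alpha + psi_j)) / 2)^2,

with `R_max` = 600 sp/s, realised as independent per-bin Bernoulli draws
with p = R dt. The simulation step is dt = 1 ms and the stimulus lasts
100 ms (both config-exposed; `R_max dt <= 1` is enforced as a config
invariant). Stimulus onset phase is 0 on every trial.

The IPD range is split into `N_c` = 12 equal classes
I_k = [-pi/2 + k pi/N_c, -pi/2 + (k+1) pi/N_c), with +pi/2 assigned to the
top class so the bins partition the closed interval. Decoded estimates are
class midpoints.

## Network and training

Input spikes drive `N_h` = 8 leaky integrate-and-fire neurons through
`W_ih` (200 x 8); hidden spikes drive 12 leaky *non-spiking* readout units
through `W_ho`. Membranes follow `tau dv/dt = -v` (tau = 2 ms in both
layers, separately configurable) integrated exactly per bin
(v <- v e^(-dt/tau)), inputs are added after the decay, and a hidden unit
that reaches the threshold of 1 spikes and resets to 0 within the same
bin. The decision is the argmax of the time-mean readout potentials
(equivalently of their log-softmax); ties break toward the lowest class.

The loss is cross-entropy plus a firing-rate regulariser on the hidden
layer: with batch-mean per-neuron rate r_m, each neuron contributes
`((r_m - r_minus)/(r_plus - r_minus))^2` once above `r_minus`, averaged
over neurons and scaled by `c = ln N_c` (the initial cross-entropy of a
uniform predictor). Defaults r_minus = 100, r_plus = 200 sp/s.

Training is Adam (lr 0.001) on batches of 128 for 100 epochs of 16,384
freshly sampled stimuli (a fixed-dataset mode exists for ablations).
Gradients flow through the spike step via the fast-sigmoid surrogate
`beta/(beta |v-1| + 1)^2` with beta = 10; the backward pass is written out
analytically (backprop through time in numpy): the readout's uniform
per-bin gradient accumulates as a geometric series, and the hidden
recursion is `g[t] = gH[t] sd[t] + e^(-dt/tau) keep[t] g[t+1]`, with the
reset factor treated as constant in the backward pass (the usual
surrogate-gradient choice). The implementation is verified against
central finite differences on a differentiable relaxation whose exact
derivative *is* the surrogate — there the backward pass, including the
reset term, matches to ~1e-7 relative error.

Weight init is uniform +-sqrt(1/fan_in) per layer, seeded. A single
experiment seed fans out to per-stage child seeds by stable hashing, so
data, init and evaluation streams are independently reproducible.

Evaluation draws 4,096 fresh stimuli and reports accuracy, confusion
matrix, per-neuron hidden rates, and the mean absolute IPD error in
degrees. `mae_deg` measures estimated-midpoint vs true-class-midpoint
(zero for a perfect classifier, ~ (1-accuracy) * 15 deg when confusions
are adjacent); `mae_deg_continuous` measures against the continuous IPD
and carries an irreducible within-bin floor of (180/N_c)/4 = 3.75 deg.
The headline error of the trained base model (~2.6 deg) is on the first
scale, which is the only one that can reach values below the floor.

## Dale's principle

`dale_mode` assigns every presynaptic unit a fixed sign (per-layer
inhibitory fractions configurable; `balanced` = half/half,
`excitatory_only`, `inhibitory_only`). Weights are parameterised as
sign * |theta| so the constraint survives every optimizer step exactly —
no projection needed. Inhibition-only input layers propagate no spikes
and classify at chance; excitation-only networks train but lose a
substantial fraction of balanced accuracy. Dale runs use the base
configuration (same tau, regulariser); whether the original experiments
did is not stated anywhere we could check, so this is the package's
choice.

## Learning delays

**Differentiable delay layer (DDL).** Translation along time plus linear
interpolation makes a spike train's delay differentiable: an integer
delay reproduces exact index shifting, a fractional delay splits mass
between adjacent bins. The DDL task uses 36 classes at the IPD angles
-90..+85 deg in 5-deg steps, one Poisson train per ear (no psi
population), weights fixed at one and biases zero. Each class i compares
a fixed-delay left-ear copy (5 ms) against a learnably delayed right-ear
copy through dendritic leaky integrators (tau_m = 5 ms) and the
multiplicative-synapse readout `v_i = -sum_t (u_1i - u_2i)^2`, maximal
when class i's delay compensates the stimulus ITD. Softmax cross-entropy
is applied to the *time-mean* potentials v_i/T — consistent with the base
model's mean-membrane readout, and necessary because the raw sums (order
-10^3) saturate the softmax. Delays are optimised in milliseconds with
Adam (lr 0.03), clamped to [0, 10 ms], and snapped to integer bins at
evaluation. The time step is 0.1 ms: at 50 Hz a 5-deg class step is only
~0.28 ms of ITD, so the delay grid must resolve sub-millisecond
differences. Training runs 20 epochs x 1,152 stimuli, after which the
delays have formed the diagonal ITD-compensation map and the loss is
flat. Accuracy stays modest by construction — adjacent classes differ by
a quarter of the dendritic time constant and single Poisson trains carry
~20 spikes — which is the regime the method is known for. Trained delays
sit within ~1 ms of the compensation map in the interior; a systematic
~1-bin outward repulsion of neighbouring classes (a property of the
discriminative objective, not of the optimiser) sets the recovery
granularity of the synthetic-recovery test.

**DCLS (single-nonzero-kernel temporal convolution).** Each
input->hidden synapse has a signed weight and a continuous delay position
inside a kernel of 25 bins (> one stimulus period of useful delay at
50 Hz / 1 ms). During training the kernel is the weight-scaled,
*normalised* Gaussian bump centred at the position (mass = weight for any
position/sigma); sigma anneals linearly from 2 to 0.25 bins over the
epochs, and at inference the kernel collapses to a single tap at the
rounded position. Inputs are 32 Poisson channels per ear with *no* phase
delays; hidden (8 LIF) and readout (12 classes) layers and the rate
regulariser are as in the base model. Weights and `W_ho` train with Adam
lr 2e-3, positions with lr 0.1 (bins); positions are clamped to the
kernel. These sizes and rates are the package's choices — none are
printed in the source material. Default protocol: 40 epochs x 6,144
stimuli.

## Analysis

*Tuning curves* are Monte-Carlo means on an IPD grid (hidden: firing
rates; output: mean potentials), normalised per neuron to max 1; silent
neurons are flagged and left unnormalised. Hidden units reliably develop
*dip* tuning — high baseline, suppressed response at a least-preferred
IPD — fitted by trust-region least squares to
`a + b exp(-(alpha-alpha_i)^2 / (2 sigma_alpha^2))` (centre initialised at
the argmin, width at three grid spacings). Hidden units are reordered by
fitted dip centre before weight-structure analysis.

*Rate-based closed form.* Ignoring spike timing entirely, a hidden unit
with drive r (in threshold units) fires at
`0 if r <= 1 else 1/(t_ref + tau ln(r/(r-1)))` — the exact rate of a
continuous-time LIF with constant suprathreshold drive and absolute
refractory period t_ref, taken equal to one simulation bin. The drive
trace is the weighted input rate expressed as the membrane's discrete
steady state, `(R W_ih) dt / (1 - e^(-dt/tau))`. Readout activity is
approximated by `r_o = sum_h W_ho r_h`, time-averaged. The quality of
this spike-free approximation is the quantitative form of the
observation that the trained network uses rates, not coincidences.

*Ricker weight model.* After reordering, `W_ho` is fitted by
`a (1 - (delta/sigma_d)^2) e^(-delta^2/(2 sigma_d^2)) + b` with
`delta = o - N_c h / N_h`: narrow inhibition on the class diagonal,
broad excitation around it (a < 0). Together with an idealised dip curve
(one (a, b, sigma) jointly fitted across the reordered hidden curves with
centres fixed at `alpha_i = -pi/2 + i pi/N_h`) this yields a
six-parameter reduced model that classifies through the Ricker weights
alone. Its agreement with the full network is computed per trial: the
reduced model is deterministic while the network's decisions near class
boundaries flip with the Poisson noise, so *exact* argmax agreement is
intrinsically capped (the network's own tuning curves combined with its
trained weights measure only ~74%); the quantitative statement the tests
pin down is that the reduced model stays within one class interval of
the full network on >= 95% of trials and reproduces the
flatter-at-the-extremes shape of the output tuning curves.

*Tensor component analysis.* Hidden spike tensors are smoothed in time
with a normalised Gaussian kernel (default sigma 3 bins) and decomposed
by rank-R nonnegative CP using hierarchical alternating least squares
(HALS): exact cyclic column minimisation projected onto the nonnegative
orthant, which makes the reconstruction error non-increasing over sweeps.
Five seeded restarts; convergence at relative error change < 1e-6 or 500
sweeps. Neuron and time factors are returned unit-norm with scale
absorbed into trial factors.

## Numerical and reproducibility choices

- Exponential-integrator membrane update: exact for the linear ODE, so
  free decay matches `v0 e^(-t/tau)` at bin edges for any dt.
- Forward passes run in float32 (the Bernoulli input noise dominates
  rounding); gradient verification runs in float64.
- Argmax ties break toward the lowest index; sorting ties break by neuron
  index (stable sorts).
- Flat tuning curves fit with |b| ~ 0 and near-zero R^2 and are flagged
  degenerate rather than raised as errors; non-convergent fits raise with
  the initialiser and residual attached.
- Training aborts with a diagnostic (epoch, learning rate) if the loss
  goes non-finite.
- HDF5 run files carry per-dataset SHA-256 checksums, verified on load.

## Acceptance protocol sizes

`scripts/acceptance.py` recomputes the headline numbers at reduced but
faithful scale: the base model trains for 40 epochs x 16,384 samples
(3 seeds) — the learning curve is flat from ~40 epochs — the Dale
comparison trains one balanced and one excitation-only network for
50 epochs x 16,384 samples, and the delay-learning runs use the package
defaults above. Evaluation is always on 4,096 fresh stimuli (DDL: 1,800).
Sign-constrained networks converge more slowly than unconstrained ones,
and the excitation-only deficit shrinks toward its asymptote as training
lengthens (we measure ~44% at 25 epochs, ~39% at 60), so the deficit
reported at this scale sits above the fully converged value.

## What the synthetic setting does and does not show

The generator *is* the study's stimulus model, so passing tests show the
algorithms behave as described on Poisson-coded pure tones with a fixed
level: no spectral structure, no level cues, no background noise, no
cochlear filtering, single-trial stationarity. Conclusions about real
auditory systems do not follow; the interesting transferable findings are
about the optimisation itself (dip-shaped solutions, the
equalisation-cancellation-like strategy, learnability of delays), and
those are exactly what the analysis module quantifies.

## Known limitations

- One spiking layer only: spike-timing strategies cannot emerge, which is
  why the rate-based reduction works so well; a multi-layer variant would
  need a different analysis.
- The DDL trains one delay per class on one ear; the general affine
  transform (scaling/rotation of the spatial-transformer family) is out
  of scope, as are multi-layer DDL stacks and event-driven delays.
- CPU-scale only; no GPU paths, no learning-rate schedules, no early
  stopping.
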