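"""Build a binaural stimulus and inspect its Poisson spike code.

A 50 Hz tone reaches the two ears with an interaural phase difference
(IPD).  Each ear drives 100 input neurons whose phase delays tile
[0, pi/2]; every neuron fires Poisson spikes at
R(t) = R_max*((1+sin theta)/2)^2.
"""

import numpy as np

from ipdnet import TaskConfig, make_batch, class_to_midpoint
from ipdnet.seeding import rng_for

task = TaskConfig()  # f=50 Hz, 100 neurons/ear, 600 sp/s peak, 100 ms, 1 ms bins
rng = rng_for(0, "example-stimulus")

batch = make_batch(5, task, rng)
print(f"spike tensor: {batch.spikes.shape}  (trials x time bins x channels)")
for i in range(batch.n_trials):
    ipd_deg = np.degrees(batch.ipd_true[i])
    mid_deg = np.degrees(class_to_midpoint(int(batch.class_true[i]),
                                           task.n_classes))
    n_spikes = int(batch.spikes[i].sum())
    print(f"trial {i}: IPD {ipd_deg:+6.1f} deg -> class "
          f"{batch.class_true[i]:2d} (midpoint {mid_deg:+6.1f} deg), "
          f"{n_spikes} input spikes")

# mean rate over the population should sit at R_max * mean((1+sin)/2)^2 = 3/8
mean_rate = batch.spikes.mean() / task.dt
print(f"\npopulation mean rate {mean_rate:.0f} sp/s "
      f"(theory 3/8 * R_max = {3 / 8 * task.rate_max:.0f} sp/s)")
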