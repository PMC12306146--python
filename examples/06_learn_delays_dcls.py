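"""Co-train weights and delays with single-nonzero-kernel convolutions.

Each input->hidden synapse has a weight and a continuous delay position
inside a temporal convolution kernel; during training the kernel is a
Gaussian bump (annealed toward a single tap).  Input neurons carry *no*
preassigned phase delays — the synaptic delays take over that role.
"""

import numpy as np

from ipdnet.delays import DCLSConfig, train_dcls

cfg = DCLSConfig(n_train=4096, epochs=25, seed=0, n_test=2048)
res = train_dcls(cfg, progress=True)

m = res.metrics
print(f"\ntest accuracy {m.accuracy:.3f}, MAE {m.mae_deg:.2f} deg "
      f"(single-tap inference kernels)")

rf = res.receptive_fields()   # (n_pre, n_hidden, [delay_bins, weight])
h = 0
order = np.argsort(rf[:, h, 0])
print(f"\nreceptive field of hidden neuron {h} "
      "(presynaptic channel, delay, weight):")
for i in order[:8]:
    print(f"  ch {i:3d}  delay {rf[i, h, 0] * cfg.dt * 1e3:4.0f} ms  "
          f"w {rf[i, h, 1]:+.3f}")
print("Excitation and inhibition separate in the (channel, delay) plane.")
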