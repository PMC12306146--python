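"""Learn input delays with the differentiable delay layer (DDL).

No weights are trained (all fixed at one): each of 36 IPD classes learns
one delay for the right-ear spike train, compared against a fixed-delay
left-ear copy through the multiplicative-synapse readout
v_i = -sum_t (u_1i - u_2i)^2.  A class's delay is correct when it exactly
compensates the stimulus ITD, making the filtered trains coincide.
"""

import numpy as np

from ipdnet.delays import DDLConfig, train_ddl

cfg = DDLConfig(seed=0)  # 36 classes, -90..+85 deg in 5 deg steps
res = train_ddl(cfg, progress=True)

print(f"\naccuracy {100 * res.accuracy:.1f}%  "
      f"(chance {100 * res.chance:.1f}%)")
print(f"mean absolute IPD error {res.mae_deg:.1f} deg")

angles = cfg.class_angles()
ideal = cfg.fixed_delay + angles / (2 * np.pi * cfg.f)
learned = res.delays.delays[:, 1]
print("\nclass    angle   learned delay   ITD-compensating delay")
for k in range(0, cfg.n_classes, 6):
    print(f"{k:4d}   {np.degrees(angles[k]):+6.1f}   {learned[k]*1e3:9.2f} ms"
          f"   {ideal[k]*1e3:9.2f} ms")
print("\nThe learned delays form the diagonal ITD-compensation map;")
print("5-degree classes sit only ~0.28 ms apart at 50 Hz, so Poisson")
print("noise keeps single-trial accuracy modest, as expected.")
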