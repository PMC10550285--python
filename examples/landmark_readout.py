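"""Intrinsic sequences as direction-invariant landmarks.

Trains two tempotron readouts on standing-still activity -- one at a
location crossed by the DG loop (y = +20 cm), one at a loop-free
location (y = -20 cm) -- then tests detection on runs through each
location from 8 directions.  The loop's hard-wired sequence is the same
whatever the approach direction, so only the with-loop readout
generalises.  (Reduced protocol for speed: 8 directions, 30 jitters.)
"""

from thetanet import get_preset
from thetanet.experiments import landmark_experiment

cfg = get_preset("tempotron_readout", seed=1).scaled(2)
res = landmark_experiment(cfg, seed=1, n_directions=8, n_jitter=30)

print(f"training-set detection: with-loop {res['train_detection_with_loop']:.2f}, "
      f"no-loop {res['train_detection_no_loop']:.2f}")
print(f"mean test accuracy over directions: "
      f"with-loop {res['mean_accuracy_with_loop']:.2f}, "
      f"no-loop {res['mean_accuracy_no_loop']:.2f}")
for d, a, b in zip(res["directions_deg"], res["accuracy_with_loop"],
                   res["accuracy_no_loop"]):
    print(f"  {d:5.0f} deg: with-loop {a:.2f}   no-loop {b:.2f}")
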