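"""Phase precession in the depression-only (extrinsic) network.

Simulates a 2-s rightward run at 20 cm/s through a half-density network
(1600 CA3 cells, same 80x80 cm arena), fits circular-linear phase
regressions for every active place cell and prints the population
summary.  Negative slopes mean spikes move to earlier theta phases as
the animal crosses a field -- phase precession.
"""

import numpy as np

from thetanet import analysis, build_network, get_preset, simulate
from thetanet.experiments import standard_run

cfg = get_preset("extrinsic_std", seed=1).scaled(2)
net = build_network(cfg)
traj = standard_run(0.0, cfg)  # (-20,0) -> (20,0) in 2 s
rec = simulate(cfg, traj, net)

prec = analysis.population_precession(rec, traj)
print(f"CA3 spikes: {rec.n_spikes('CA3')}, active cells (>5 spikes): {len(prec)}")
print(f"median slope : {prec['slope'].median():+.2f} rad per field traversal")
print(f"fraction precessing (slope < 0): {(prec['slope'] < 0).mean():.2f}")
print(f"circular-mean spike phase: "
      f"{np.rad2deg(analysis.circular_mean(prec['mean_phase'].to_numpy())):.0f} deg after theta peak")
# A negative median slope with a phase near the theta trough reproduces
# the classic phase-precession signature from recurrent depression alone.
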