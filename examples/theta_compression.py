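"""Theta compression and its dependence on the DG-loop direction.

Runs the full CA3-DG model (half density) on a rightward 2-s trajectory
with the loop aligned (0 deg) and opposing (180 deg), and under DG
lesion.  The compression slope a (rad/cm) is the circular-linear
regression of pair correlation-lag phases against field-centre distance:
positive a means cells with more distant fields fire at proportionally
later parts of the theta cycle -- behavioural distance compressed into
within-cycle time.
"""

import numpy as np

from thetanet import analysis, build_network, get_preset, simulate
from thetanet.experiments import standard_run

for label, preset, theta in [
    ("loop aligned (0 deg) ", "dg_loop", 0.0),
    ("loop opposing (180)  ", "dg_loop", np.pi),
    ("DG lesion            ", "dg_lesion", 0.0),
]:
    cfg = get_preset(preset, seed=1, theta_DG=theta).scaled(2)
    net = build_network(cfg)
    traj = standard_run(0.0, cfg)
    rec = simulate(cfg, traj, net)
    a, table = analysis.compression_slope(rec, traj)
    print(f"{label}: a = {a:+.3f} rad/cm over {len(table)} field pairs "
          f"(DG spikes: {rec.n_spikes('DG')})")
# An opposing loop pushes lag phases towards the opposite sign: the
# hard-wired sequence runs backwards relative to the movement.
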