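"""Config-driven scenario runner: simulate -> analyse -> tabulate.

Each scenario reproduces one of the study protocols end-to-end on
bidirectional 2-s straight runs (or the standing-still / multi-direction
protocols of the readout and gradient-map experiments) and returns a
JSON-serialisable summary.  A scenario is fully determined by its name,
parameter overrides and seed.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import analysis
from .config import NetworkConfig, get_preset
from .dynamics import SpikeRecord, build_network, simulate
from .geometry import Arena, make_straight_trajectory
from .tempotron import (
    Tempotron,
    box_afferents,
    evaluate_patterns,
    jitter_patterns,
    patterns_from_record,
)

RUN_SPEED = 20.0       # cm/s
RUN_DURATION = 2000.0  # ms
RUN_HALF = 20.0        # runs go from x = -20 cm to x = +20 cm


def standard_run(direction: float, config: NetworkConfig, duration: float = RUN_DURATION,
                 speed: float = RUN_SPEED, through=(0.0, 0.0)):
    """Straight run of given direction through a point (default the origin)."""
    through = np.asarray(through, float)
    half = speed * 1e-3 * duration / 2.0
    start = through - half * np.array([np.cos(direction), np.sin(direction)])
    return make_straight_trajectory(
        start, direction, speed, duration, config.dt,
        Arena(config.arena_width, config.arena_height),
    )


def lesion_transform(config: NetworkConfig) -> NetworkConfig:
    """Turn a control configuration into its DG-lesion counterpart.

    DG spiking is silenced and the facilitating sensory input is replaced
    by an elevated constant release level (no STF), compensating the lost
    excitatory loop drive.
    """
    lesion = get_preset("dg_lesion")
    return config.replace(
        dg_lesion=True,
        B_DG=0.0,
        A_pos=lesion.A_pos,
        A_dir=lesion.A_dir if config.A_dir > 0 else 0.0,
        S0F=lesion.S0F,
        S1F=lesion.S1F,
        phi_F=lesion.phi_F,
    )


def _sim_pair(config: NetworkConfig, duration=RUN_DURATION):
    """Simulate rightward and leftward runs on the same network wiring."""
    net = build_network(config)
    traj_f = standard_run(0.0, config, duration)
    traj_r = standard_run(np.pi, config, duration)
    rec_f = simulate(config, traj_f, net)
    rec_r = simulate(config, traj_r, net)
    return net, (traj_f, rec_f), (traj_r, rec_r)


def _sign_summary(config, ordering="axis"):
    """Peak lags of the averaged 4-cm-pair correlogram for both directions."""
    _, (traj_f, rec_f), (traj_r, rec_r) = _sim_pair(config)
    h_f = analysis.averaged_correlogram(
        rec_f, traj_f, ordering=ordering, reference_angle=0.0
    )
    h_r = analysis.averaged_correlogram(
        rec_r, traj_r, ordering=ordering, reference_angle=0.0
    )
    lag_f = analysis.peak_lag(h_f.counts)
    lag_r = analysis.peak_lag(h_r.counts)
    return {
        "peak_lag_fwd_ms": lag_f,
        "peak_lag_rev_ms": lag_r,
        "sign_invariant": bool(np.sign(lag_f) == np.sign(lag_r)),
        "n_spikes_fwd": rec_f.n_spikes("CA3"),
        "n_spikes_rev": rec_r.n_spikes("CA3"),
    }, (traj_f, rec_f), (traj_r, rec_r)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _scenario_intrinsic(config, seed, scale):
    summary, _, _ = _sign_summary(config)
    return summary


def _scenario_extrinsic(config, seed, scale):
    summary, (traj_f, rec_f), _ = _sign_summary(config)
    prec = analysis.population_precession(rec_f, traj_f)
    summary["median_slope_rad_per_field"] = (
        float(prec["slope"].median()) if len(prec) else float("nan")
    )
    summary["n_precessing_cells"] = int(len(prec))
    return summary


def _scenario_directional(config, seed, scale):
    summary, (traj_f, rec_f), _ = _sign_summary(config)
    prec = analysis.population_precession(rec_f, traj_f)
    heading = float(traj_f.headings[0])
    from .geometry import circular_difference

    diff = circular_difference(prec["preferred_dir"].to_numpy(), heading)
    best = prec[diff < np.deg2rad(30)]
    worst = prec[diff > np.deg2rad(150)]

    def _cm(sub, col):
        if len(sub) == 0:
            return float("nan")
        return analysis.circular_mean(sub[col].to_numpy())

    summary.update(
        {
            "mean_phase_best": _cm(best, "mean_phase"),
            "mean_phase_worst": _cm(worst, "mean_phase"),
            "onset_best": _cm(best, "onset"),
            "onset_worst": _cm(worst, "onset"),
            "n_best": int(len(best)),
            "n_worst": int(len(worst)),
        }
    )
    return summary


def _scenario_dg_loop(config, seed, scale):
    """Full loop model: Ex/In population statistics and compression slope."""
    _, (traj_f, rec_f), (traj_r, rec_r) = _sim_pair(config)
    table = analysis.ex_in_table(rec_f, rec_r, traj_f)
    a, pair_table = analysis.compression_slope(rec_f, traj_f)
    frac = analysis.extrinsic_fraction
    summary = {
        "n_pairs": int(len(table)),
        "fraction_extrinsic": float((table["pair_class"] == "extrinsic").mean())
        if len(table) else float("nan"),
        "frac_ex_both_best": frac(table, "bw_class", "both-best"),
        "frac_ex_both_worst": frac(table, "bw_class", "both-worst"),
        "frac_ex_similar": frac(table, "sim_class", "similar"),
        "frac_ex_dissimilar": frac(table, "sim_class", "dissimilar"),
        "compression_slope_rad_per_cm": a,
        "n_compression_pairs": int(len(pair_table)),
    }
    # orientation of centre-difference vectors per class (landmark recovery)
    for cls in ("extrinsic", "intrinsic"):
        sub = table[table["pair_class"] == cls] if len(table) else table
        summary[f"orientation_peak_{cls}_deg"] = (
            float(
                np.rad2deg(
                    analysis.circular_mean(2.0 * sub["orientation"].to_numpy()) / 2.0
                )
            )
            if len(sub)
            else float("nan")
        )
    return summary


def _scenario_compression(config, seed, scale):
    """Compression slope of a single rightward run (control or lesion)."""
    net = build_network(config)
    traj = standard_run(0.0, config)
    rec = simulate(config, traj, net)
    a, table = analysis.compression_slope(rec, traj)
    return {
        "compression_slope_rad_per_cm": a,
        "n_pairs": int(len(table)),
        "n_spikes": rec.n_spikes("CA3"),
        "n_dg_spikes": rec.n_spikes("DG"),
    }


def _scenario_tempotron(config, seed, scale, n_directions=24, n_jitter=100):
    return landmark_experiment(
        config, seed=seed, n_directions=n_directions, n_jitter=n_jitter
    )


def _scenario_gradients(config, seed, scale):
    """Spike-time gradient arrows for a standing stimulus and a run."""
    net = build_network(config)
    window = (500.0, 600.0)
    out = {}
    for label, (direction, speed) in {
        "training": (0.0, 0.0),
        "run_right": (0.0, RUN_SPEED),
    }.items():
        traj = standard_run(direction, config, duration=1000.0, speed=speed)
        rec = simulate(config, traj, net)
        arrows, valid = analysis.gradient_map(rec, window)
        if valid.any():
            mean_vec = arrows[valid].mean(axis=0)
            out[f"{label}_mean_angle_deg"] = float(
                np.rad2deg(np.arctan2(mean_vec[1], mean_vec[0]))
            )
            out[f"{label}_n_arrows"] = int(valid.sum())
        else:
            out[f"{label}_mean_angle_deg"] = float("nan")
            out[f"{label}_n_arrows"] = 0
    return out


SCENARIOS = {
    "intrinsic_asymmetry": ("intrinsic_asymmetry", _scenario_intrinsic),
    "extrinsic_std": ("extrinsic_std", _scenario_extrinsic),
    "directional_input": ("directional_input", _scenario_directional),
    "dg_loop_0": ("dg_loop", _scenario_dg_loop),
    "dg_loop_180": ("dg_loop", _scenario_dg_loop),
    "compression_control_0": ("dg_loop", _scenario_compression),
    "compression_control_180": ("dg_loop", _scenario_compression),
    "compression_lesion": ("dg_lesion", _scenario_compression),
    "dg_loop_oblique_45": ("dg_loop_2d", _scenario_dg_loop),
    "dg_loop_oblique_90": ("dg_loop_2d", _scenario_dg_loop),
    "dg_loop_oblique_225": ("dg_loop_2d", _scenario_dg_loop),
    "dg_loop_oblique_270": ("dg_loop_2d", _scenario_dg_loop),
    "no_recurrence": ("no_recurrence", _scenario_extrinsic),
    "no_recurrence_compression": ("no_recurrence_control", _scenario_compression),
    "no_recurrence_lesion": ("no_recurrence_lesion", _scenario_compression),
    "tempotron_landmark": ("tempotron_readout", _scenario_tempotron),
    "gradient_maps": ("dg_loop", _scenario_gradients),
}

_THETA_BY_SCENARIO = {
    "dg_loop_180": np.pi,
    "compression_control_180": np.pi,
    "dg_loop_oblique_45": np.deg2rad(45),
    "dg_loop_oblique_90": np.deg2rad(90),
    "dg_loop_oblique_225": np.deg2rad(225),
    "dg_loop_oblique_270": np.deg2rad(270),
}


def scenario_config(name: str, seed: int = 0, scale: int = 1, **overrides) -> NetworkConfig:
    """Resolve a scenario name to its (possibly scaled) configuration."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; valid: {sorted(SCENARIOS)}")
    preset, _ = SCENARIOS[name]
    cfg = get_preset(preset, seed=seed)
    if name in _THETA_BY_SCENARIO:
        cfg = cfg.replace(theta_DG=float(_THETA_BY_SCENARIO[name]))
    if overrides:
        cfg = cfg.replace(**overrides)
    if scale > 1:
        cfg = cfg.scaled(scale)
    return cfg


def run_scenario(
    name: str, seed: int = 0, scale: int = 1, out_dir=None, **overrides
) -> dict:
    """Execute one scenario and return (and optionally write) its summary."""
    cfg = scenario_config(name, seed=seed, scale=scale, **overrides)
    _, fn = SCENARIOS[name]
    t0 = time.time()
    summary = fn(cfg, seed, scale)
    summary["scenario"] = name
    summary["seed"] = seed
    summary["elapsed_s"] = round(time.time() - t0, 2)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / f"{name}.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# landmark readout protocol
# ---------------------------------------------------------------------------

def landmark_experiment(
    config: NetworkConfig | None = None,
    seed: int = 0,
    n_directions: int = 24,
    n_jitter: int = 100,
    train_epochs: int = 100,
    box_half: float = 10.0,
) -> dict:
    """Train and test the two landmark readouts.

    One tempotron is trained on standing-still activity at the with-loop
    location (on the DG path at y = +20 cm), one at the no-loop location
    (0, -20).  Both are then tested on 1-s, 20-cm runs through their
    location at ``n_directions`` equally spaced heading angles; accuracy
    is the fraction of jittered realisations in which any theta cycle
    elicits a readout spike.
    """
    cfg = config if config is not None else get_preset("tempotron_readout", seed=seed)
    net = build_network(cfg)
    locations = {"with_loop": (0.0, 20.0), "no_loop": (0.0, -20.0)}
    models = {}
    train_convergence = {}
    rng_seed = np.random.SeedSequence(seed)
    for k, (label, loc) in enumerate(locations.items()):
        traj = standard_run(0.0, cfg, duration=1000.0, speed=0.0, through=loc)
        rec = simulate(cfg, traj, net)
        ids = box_afferents(net.ca3, loc, box_half)
        cycles = patterns_from_record(rec, ids)
        rng = np.random.default_rng([seed, 7, k])
        train_sets = jitter_patterns(cycles, n_jitter, 2.0, rng)
        train_patterns = [p for real in train_sets for p in real if p.n_spikes]
        model = Tempotron(n_afferents=ids.size)
        history = model.train(train_patterns, epochs=train_epochs, seed=seed + k)
        models[label] = (model, ids, loc)
        train_convergence[label] = history[-1] if history else float("nan")

    directions = np.arange(n_directions) * (2.0 * np.pi / n_directions)
    accuracies = {label: [] for label in locations}
    for label, (model, ids, loc) in models.items():
        for j, phi in enumerate(directions):
            traj = standard_run(
                float(phi), cfg, duration=1000.0, speed=RUN_SPEED, through=loc
            )
            rec = simulate(cfg, traj, net)
            cycles = patterns_from_record(rec, ids)
            acc = evaluate_patterns(
                model, cycles, n_jitter=n_jitter, sd_ms=2.0,
                seed=(seed * 1009 + j) % (2**31)
            )
            accuracies[label].append(acc)
    return {
        "directions_deg": [float(np.rad2deg(d)) for d in directions],
        "accuracy_with_loop": accuracies["with_loop"],
        "accuracy_no_loop": accuracies["no_loop"],
        "mean_accuracy_with_loop": float(np.mean(accuracies["with_loop"])),
        "mean_accuracy_no_loop": float(np.mean(accuracies["no_loop"])),
        "train_detection_with_loop": train_convergence["with_loop"],
        "train_detection_no_loop": train_convergence["no_loop"],
    }
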