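"""Spiking network simulator.

Forward-Euler integration (default dt = 0.1 ms) of Izhikevich neurons
driven by three currents: recurrent conductance-based synapses with a 2-ms
transmission delay, box-shaped sensory place-field input with short-term
facilitation (CA3 only), and a subtractive theta drive common to all
neurons.  Short-term depression scales every synapse with a CA3
presynaptic cell.

The simulator is deterministic given (config, trajectory): all randomness
(preferred directions, inhibitory weights) is derived from ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EXCITATORY, INHIBITORY, IzhikevichParams, NetworkConfig, config_fingerprint
from .connectivity import (
    ca3_to_dg_weights,
    ca3_weights,
    dg_to_ca3_weights,
    inhibitory_weights,
)
from .geometry import Arena, PlaceCellGrid, Trajectory, assign_preferred_directions, build_grid

THETA_PERIOD = 100.0  # ms
THETA_AMPLITUDE = 7.0


def theta_drive(t) -> np.ndarray | float:
    """Oscillatory theta input I_theta(t) = 7 * [1 + cos(2 pi t / 100 ms)] / 2.

    Maximal at the theta peak (t = 0, 100, ... ms).  The drive is
    *subtracted* from each neuron's total current, so neurons are most
    excitable at the theta trough.
    """
    return THETA_AMPLITUDE * (1.0 + np.cos(2.0 * np.pi * t / THETA_PERIOD)) / 2.0


def mec_modulation(t, phase_shift_deg: float = 70.0) -> float:
    """Theta modulation of the sensory (entorhinal) input.

    Peaks ``phase_shift_deg`` (default +70 deg) after the theta peak, i.e.
    the sensory drive arrives phase-shifted towards the excitable theta
    trough.
    """
    shift = np.deg2rad(phase_shift_deg)
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * t / THETA_PERIOD - shift))


def directional_gain(heading, preferred_dirs, A_pos, A_dir):
    """Sensory amplitude A_pos + A_dir * exp(cos(psi(t) - psi_i) - 1)."""
    return A_pos + A_dir * np.exp(np.cos(heading - preferred_dirs) - 1.0)


def sensory_drive(
    pos,
    heading,
    grid: PlaceCellGrid,
    t,
    A_pos,
    A_dir,
    field_radius: float = 5.0,
    mec_phase_shift_deg: float = 70.0,
):
    """Raw per-cell sensory drive J_i^S(t) before facilitation.

    Non-zero only within ``field_radius`` (5 cm box envelope) of a field
    centre; amplitude combines positional and directional tuning and is
    modulated by the phase-shifted entorhinal theta input.
    """
    d2 = np.sum((grid.centers - np.asarray(pos)[None, :]) ** 2, axis=1)
    inside = d2 <= field_radius**2
    J = np.zeros(grid.n)
    if np.any(inside):
        amp = directional_gain(heading, grid.preferred_dirs[inside], A_pos, A_dir)
        J[inside] = amp * mec_modulation(t, mec_phase_shift_deg)
    return J


def stf_step(s_F, J_S, dt, S0F, S1F, phi_F, tau_F):
    """Euler update of the facilitation resource.

    ds_F/dt = (S0F - s_F)/tau_F + (S1F - s_F) * phi_F * J^S.
    The effective sensory current is J^S * s_F**2 (squared to capture the
    supralinear presynaptic calcium dependence).
    """
    return s_F + dt * ((S0F - s_F) / tau_F + (S1F - s_F) * phi_F * J_S)


def std_step(s_D, spiked, dt, U_D, tau_D, mode: str = "multiplicative"):
    """Depression resource update: recovery plus per-spike depletion.

    Between spikes ds_D/dt = (1 - s_D)/tau_D.  On a presynaptic spike the
    resource is depleted by the fraction U_D; the default multiplicative
    rule s_D <- s_D * (1 - U_D) keeps s_D in [0, 1] without clamping, the
    subtractive variant s_D <- max(s_D - U_D, 0) is available as
    ``mode='subtractive'``.
    """
    s = s_D + dt * (1.0 - s_D) / tau_D
    if np.any(spiked):
        if mode == "multiplicative":
            s = np.where(spiked, s * (1.0 - U_D), s)
        else:
            s = np.where(spiked, np.maximum(s - U_D, 0.0), s)
    return s


def izhikevich_step(v, u, I, params: IzhikevichParams, dt):
    """One Euler step of the Izhikevich model with spike detection/reset.

    v' = 0.04 v^2 + 5 v + 140 - u + I;  u' = a (b v - u).
    A spike is registered when v crosses 30 mV from below; then v <- c and
    u <- u + d.  Returns (v, u, spiked).
    """
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    u_new = u + dt * params.a * (params.b * v - u)
    spiked = (v < params.v_thresh) & (v_new >= params.v_thresh)
    if not np.all(np.isfinite(v_new)):
        raise FloatingPointError(
            "non-finite membrane potential; reduce dt or input amplitude"
        )
    v_new = np.where(spiked, params.c, v_new)
    u_new = np.where(spiked, u_new + params.d, u_new)
    return v_new, u_new, spiked


def conductance_izhikevich_step(v, u, gE, gI, I_ext, params, dt, V_E, V_I):
    """Izhikevich step with semi-implicit conductance driving forces.

    The synaptic terms g_E (V_E - v) and g_I (V_I - v) are linear in v and
    are treated implicitly, which keeps the update stable for arbitrarily
    large conductances (forward Euler would require dt < 2 / (g_E + g_I));
    the intrinsic quadratic nonlinearity stays explicit.  Reduces exactly
    to the explicit update as dt * (g_E + g_I) -> 0.
    """
    rhs = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I_ext
                    + gE * V_E + gI * V_I)
    v_new = rhs / (1.0 + dt * (gE + gI))
    u_new = u + dt * params.a * (params.b * v - u)
    spiked = (v < params.v_thresh) & (v_new >= params.v_thresh)
    if not np.all(np.isfinite(v_new)):
        raise FloatingPointError(
            "non-finite membrane potential; reduce dt or input amplitude"
        )
    v_new = np.where(spiked, params.c, v_new)
    u_new = np.where(spiked, u_new + params.d, u_new)
    return v_new, u_new, spiked


@dataclass
class NetworkArrays:
    """Grids and weight blocks of a concrete network realisation."""

    config: NetworkConfig
    ca3: PlaceCellGrid
    dg: PlaceCellGrid | None
    # transposed blocks, shape (n_pre, n_post), for fast row-gather delivery
    w_cc_t: np.ndarray | None
    w_cd_t: np.ndarray | None
    w_dc_t: np.ndarray | None
    w_inh_ca3_t: np.ndarray | None
    w_inh_dg_t: np.ndarray | None


def build_network(config: NetworkConfig) -> NetworkArrays:
    """Construct grids and all weight blocks from a configuration."""
    arena = Arena(config.arena_width, config.arena_height)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    ca3 = assign_preferred_directions(
        build_grid(arena, config.n_side_ca3, "CA3"), seeds[0]
    )
    use_dg = config.n_side_dg > 0 and config.B_DG > 0
    dg = None
    w_cd_t = w_dc_t = w_inh_dg_t = None
    if use_dg:
        dg = assign_preferred_directions(
            build_grid(arena, config.n_side_dg, "DG"), seeds[1]
        )
        w_cd_t = np.ascontiguousarray(
            ca3_to_dg_weights(
                ca3, dg, config.B_DG, config.K_DG, config.sigma,
                config.theta_DG, config.loop_anchor,
            ).W.T
        )
        w_dc_t = np.ascontiguousarray(
            dg_to_ca3_weights(
                dg, ca3, config.B_DG, config.K_DG, config.sigma, config.theta_DG
            ).W.T
        )
        if config.n_inh > 0 and config.W0_inh_dg > 0:
            w_inh_dg_t = np.ascontiguousarray(
                inhibitory_weights(
                    dg.n, config.n_inh, config.W0_inh_dg, seeds[3], "InhDG", "DG"
                ).W.T
            )
    w_cc_t = None
    if config.recurrence_on and (config.B_pos > 0 or config.B_dir > 0):
        w_cc_t = np.ascontiguousarray(
            ca3_weights(
                ca3, config.B_pos, config.B_dir, config.K_CA3,
                config.sigma, config.asymmetry_on,
            ).W.T
        )
    w_inh_ca3_t = None
    if config.n_inh > 0 and config.W0_inh_ca3 > 0:
        w_inh_ca3_t = np.ascontiguousarray(
            inhibitory_weights(
                ca3.n, config.n_inh, config.W0_inh_ca3, seeds[2], "InhCA3", "CA3"
            ).W.T
        )
    return NetworkArrays(
        config=config, ca3=ca3, dg=dg, w_cc_t=w_cc_t, w_cd_t=w_cd_t,
        w_dc_t=w_dc_t, w_inh_ca3_t=w_inh_ca3_t, w_inh_dg_t=w_inh_dg_t,
    )


@dataclass
class SpikeRecord:
    """Time-sorted spike events with population metadata.

    ``events`` has columns (layer, neuron_id, t_ms).  ``grids`` maps the
    excitatory layer names to their PlaceCellGrid, giving each neuron id a
    field centre and preferred direction.
    """

    events: pd.DataFrame
    grids: dict
    duration: float
    fingerprint: str = ""

    def spike_times(self, layer: str) -> dict[int, np.ndarray]:
        """Mapping neuron id -> sorted spike-time array for one layer."""
        sub = self.events[self.events["layer"] == layer]
        return {
            int(nid): np.sort(g["t_ms"].to_numpy())
            for nid, g in sub.groupby("neuron_id")
        }

    def spike_counts(self, layer: str, n: int) -> np.ndarray:
        sub = self.events[self.events["layer"] == layer]
        counts = np.zeros(n, dtype=int)
        ids, c = np.unique(sub["neuron_id"].to_numpy(), return_counts=True)
        counts[ids] = c
        return counts

    def n_spikes(self, layer: str | None = None) -> int:
        if layer is None:
            return len(self.events)
        return int((self.events["layer"] == layer).sum())

    def to_csv(self, path):
        self.events.to_csv(path, index=False)

    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["duration"] = self.duration
            f.attrs["fingerprint"] = self.fingerprint
            g = f.create_group("events")
            g.create_dataset(
                "layer", data=self.events["layer"].to_numpy().astype("S")
            )
            g.create_dataset("neuron_id", data=self.events["neuron_id"].to_numpy())
            g.create_dataset("t_ms", data=self.events["t_ms"].to_numpy())
            for name, grid in self.grids.items():
                gg = f.create_group(f"grids/{name}")
                gg.create_dataset("centers", data=grid.centers)
                gg.create_dataset("preferred_dirs", data=grid.preferred_dirs)
                gg.attrs["n_side"] = grid.n_side
                gg.attrs["arena_width"] = grid.arena.width
                gg.attrs["arena_height"] = grid.arena.height

    @classmethod
    def from_hdf5(cls, path) -> "SpikeRecord":
        import h5py

        with h5py.File(path, "r") as f:
            events = pd.DataFrame(
                {
                    "layer": [s.decode() for s in f["events/layer"][:]],
                    "neuron_id": f["events/neuron_id"][:],
                    "t_ms": f["events/t_ms"][:],
                }
            )
            grids = {}
            if "grids" in f:
                for name, gg in f["grids"].items():
                    arena = Arena(gg.attrs["arena_width"], gg.attrs["arena_height"])
                    grids[name] = PlaceCellGrid(
                        centers=gg["centers"][:],
                        n_side=int(gg.attrs["n_side"]),
                        layer=name,
                        arena=arena,
                        preferred_dirs=gg["preferred_dirs"][:],
                    )
            return cls(
                events=events,
                grids=grids,
                duration=float(f.attrs["duration"]),
                fingerprint=str(f.attrs.get("fingerprint", "")),
            )


def simulate(
    config: NetworkConfig,
    trajectory: Trajectory,
    network: NetworkArrays | None = None,
    max_total_spikes: int | None = None,
) -> SpikeRecord:
    """Run the full forward simulation and collect all spikes.

    Integrates CA3 and (unless absent or lesioned) DG place cells plus one
    interneuron pool per layer.  Theta drive reaches every neuron, sensory
    drive only CA3, and short-term depression every synapse with a CA3
    presynaptic cell.  Bitwise reproducible given (config, trajectory).
    """
    cfg = config
    if abs(trajectory.dt - cfg.dt) > 1e-12:
        raise ValueError("trajectory dt must match config dt")
    net = network if network is not None else build_network(cfg)
    if net.ca3.arena.width != cfg.arena_width:
        raise ValueError("network arena does not match config")

    n_steps = len(trajectory.times) - 1
    dt = cfg.dt
    delay_steps = max(1, int(round(cfg.tau_0 / dt)))

    ca3, dg = net.ca3, net.dg
    dg_active = dg is not None and not cfg.dg_lesion
    n_ca3 = ca3.n
    n_dg = dg.n if dg_active else 0
    n_inh = cfg.n_inh

    # state
    v_c = np.full(n_ca3, -70.0)
    u_c = EXCITATORY.b * v_c.copy()
    gE_c = np.zeros(n_ca3)
    gI_c = np.zeros(n_ca3)
    sD = np.ones(n_ca3)
    sF = np.full(n_ca3, cfg.S0F, dtype=float)
    if dg_active:
        v_d = np.full(n_dg, -70.0)
        u_d = EXCITATORY.b * v_d.copy()
        gE_d = np.zeros(n_dg)
        gI_d = np.zeros(n_dg)
    use_inh_ca3 = n_inh > 0 and cfg.W0_ca3_inh > 0
    use_inh_dg = dg_active and n_inh > 0 and cfg.W0_dg_inh > 0
    if use_inh_ca3:
        v_ic = np.full(n_inh, -65.0)
        u_ic = INHIBITORY.b * v_ic.copy()
        gE_ic = np.zeros(n_inh)
    if use_inh_dg:
        v_id = np.full(n_inh, -65.0)
        u_id = INHIBITORY.b * v_id.copy()
        gE_id = np.zeros(n_inh)

    decay_E = 1.0 - dt / cfg.tau_E
    decay_I = 1.0 - dt / cfg.tau_I
    # charge-normalised kernels: spikes inject charge W/N independent of tau
    norm_E = (cfg.tau_E if cfg.charge_normalized else 1.0) / cfg.efficacy_scale
    norm_I = (cfg.tau_I if cfg.charge_normalized else 1.0) / cfg.efficacy_scale_inh
    empty = np.empty(0, dtype=np.intp)
    empty_f = np.empty(0, dtype=float)
    buffers = {
        pop: [empty] * delay_steps for pop in ("CA3", "DG", "InhCA3", "InhDG")
    }
    # CA3 spikes travel with the depression resource available at emission
    # (before their own depletion), the resource actually consumed
    sd_buffer = [empty_f] * delay_steps

    # cache the directional sensory amplitude per distinct heading
    gain_cache: dict[float, np.ndarray] = {}

    def sensory_amplitude(heading: float) -> np.ndarray:
        key = round(float(heading), 9)
        if key not in gain_cache:
            gain_cache[key] = directional_gain(
                heading, ca3.preferred_dirs, cfg.A_pos, cfg.A_dir
            )
        return gain_cache[key]

    rec: dict[str, list] = {"CA3": [], "DG": [], "InhCA3": [], "InhDG": []}
    total_spikes = 0

    for k in range(n_steps):
        t = trajectory.times[k]
        slot = k % delay_steps

        # --- conductance decay ---------------------------------------
        gE_c *= decay_E
        gI_c *= decay_I
        if dg_active:
            gE_d *= decay_E
            gI_d *= decay_I
        if use_inh_ca3:
            gE_ic *= decay_E
        if use_inh_dg:
            gE_id *= decay_E

        # --- deliver spikes emitted delay_steps ago -------------------
        idx = buffers["CA3"][slot]
        if idx.size:
            sd = sd_buffer[slot]
            if net.w_cc_t is not None:
                gE_c += (sd @ net.w_cc_t[idx]) / (n_ca3 * norm_E)
            if dg_active and net.w_cd_t is not None:
                sd_dg = sd if cfg.std_to_dg else np.ones_like(sd)
                gE_d += (sd_dg @ net.w_cd_t[idx]) / (n_ca3 * norm_E)
            if use_inh_ca3:
                drive = sd.sum() if cfg.std_to_inhibitory else idx.size
                gE_ic += cfg.W0_ca3_inh * drive / (n_ca3 * norm_E)
        idx = buffers["DG"][slot]
        if idx.size:
            n_dg_norm = n_dg if cfg.norm_mode == "per-block" else n_ca3
            gE_c += net.w_dc_t[idx].sum(axis=0) / (n_dg_norm * norm_E)
            if use_inh_dg:
                gE_id += cfg.W0_dg_inh * idx.size / (n_dg_norm * norm_E)
        idx = buffers["InhCA3"][slot]
        if idx.size and net.w_inh_ca3_t is not None:
            gI_c += net.w_inh_ca3_t[idx].sum(axis=0) / (n_inh * norm_I)
        idx = buffers["InhDG"][slot]
        if idx.size and net.w_inh_dg_t is not None:
            gI_d += net.w_inh_dg_t[idx].sum(axis=0) / (n_inh * norm_I)

        # --- sensory input with STF (CA3 only) -----------------------
        pos = trajectory.positions[k]
        d2 = (ca3.centers[:, 0] - pos[0]) ** 2 + (ca3.centers[:, 1] - pos[1]) ** 2
        inside = d2 <= cfg.field_radius**2
        J_S = np.zeros(n_ca3)
        if inside.any():
            amp = sensory_amplitude(trajectory.headings[k])
            J_S[inside] = amp[inside] * mec_modulation(t, cfg.mec_phase_shift_deg)
        sF = stf_step(sF, J_S, dt, cfg.S0F, cfg.S1F, cfg.phi_F, cfg.tau_F)
        I_S = J_S * sF * sF

        # --- currents and integration --------------------------------
        i_theta = theta_drive(t)
        v_c, u_c, spk_c = conductance_izhikevich_step(
            v_c, u_c, gE_c, gI_c, I_S - i_theta, EXCITATORY, dt, cfg.V_E, cfg.V_I
        )
        spk_idx_c = np.flatnonzero(spk_c)
        sd_buffer[slot] = sD[spk_idx_c].copy()
        sD = std_step(sD, spk_c, dt, cfg.U_D, cfg.tau_D, cfg.std_mode)

        spk_idx_d = empty
        if dg_active:
            i_theta_dg = i_theta if cfg.theta_to_dg else 0.0
            v_d, u_d, spk_d = conductance_izhikevich_step(
                v_d, u_d, gE_d, gI_d, -i_theta_dg, EXCITATORY, dt, cfg.V_E, cfg.V_I
            )
            spk_idx_d = np.flatnonzero(spk_d)

        i_theta_inh = i_theta if cfg.theta_to_inhibitory else 0.0
        spk_idx_ic = spk_idx_id = empty
        if use_inh_ca3:
            v_ic, u_ic, spk_ic = conductance_izhikevich_step(
                v_ic, u_ic, gE_ic, 0.0, -i_theta_inh, INHIBITORY, dt,
                cfg.V_E, cfg.V_I,
            )
            spk_idx_ic = np.flatnonzero(spk_ic)
        if use_inh_dg:
            v_id, u_id, spk_id = conductance_izhikevich_step(
                v_id, u_id, gE_id, 0.0, -i_theta_inh, INHIBITORY, dt,
                cfg.V_E, cfg.V_I,
            )
            spk_idx_id = np.flatnonzero(spk_id)

        # --- record and queue ----------------------------------------
        t_spike = trajectory.times[k + 1]
        for name, idxs in (
            ("CA3", spk_idx_c), ("DG", spk_idx_d),
            ("InhCA3", spk_idx_ic), ("InhDG", spk_idx_id),
        ):
            buffers[name][slot] = idxs
            if idxs.size:
                rec[name].append((t_spike, idxs))
                total_spikes += idxs.size
        if max_total_spikes is not None and total_spikes > max_total_spikes:
            raise RuntimeError(
                f"spike count exceeded {max_total_spikes} at t={t:.0f} ms; "
                "network activity is running away"
            )

    frames = []
    for name, chunks in rec.items():
        if not chunks:
            continue
        ids = np.concatenate([c[1] for c in chunks])
        times = np.concatenate([np.full(c[1].size, c[0]) for c in chunks])
        frames.append(
            pd.DataFrame({"layer": name, "neuron_id": ids, "t_ms": times})
        )
    if frames:
        events = pd.concat(frames, ignore_index=True)
        events = events.sort_values(
            ["t_ms", "layer", "neuron_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        events = pd.DataFrame(
            {"layer": pd.Series(dtype=str),
             "neuron_id": pd.Series(dtype=int),
             "t_ms": pd.Series(dtype=float)}
        )
    grids = {"CA3": ca3}
    if dg is not None:
        grids["DG"] = dg
    return SpikeRecord(
        events=events,
        grids=grids,
        duration=float(trajectory.times[-1]),
        fingerprint=config_fingerprint(cfg),
    )
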