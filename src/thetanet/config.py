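"""Network configuration and named parameter presets.

Every scalar of the model lives in :class:`NetworkConfig`.  The named
presets correspond to the simulation variants of the study (purely
intrinsic asymmetric-weight network, purely extrinsic depression network,
directional sensory input, full CA3-DG loop model, DG lesion,
recurrence-free variants, and the readout-training network).

Some preset cells are contested: the source parameter table collapses
merged cells, so a few rows admit more than one column alignment.  The
values encoded here are the reading most consistent with the accompanying
model description (e.g. the purely extrinsic variant carries no short-term
facilitation, the lesion variants fix synaptic release at an elevated
constant level).  Any scalar can be overridden per run, so alternative
readings are reproducible from config alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml


@dataclass(frozen=True)
class IzhikevichParams:
    """Phenomenological spike-generation parameters (a, b, c, d).

    The excitatory preset (0.035, 0.2, -60, 8) yields burst firing, the
    inhibitory preset (0.02, 0.25, -65, 2) fast spiking.  Spike threshold
    is 30 mV for both.
    """

    a: float
    b: float
    c: float
    d: float
    v_thresh: float = 30.0


EXCITATORY = IzhikevichParams(a=0.035, b=0.2, c=-60.0, d=8.0)
INHIBITORY = IzhikevichParams(a=0.02, b=0.25, c=-65.0, d=2.0)


@dataclass
class NetworkConfig:
    """All scalar parameters of the CA3-DG network.

    Units: lengths cm, times ms, voltages mV.  Synaptic weights and input
    amplitudes are in the dimensionless current units of the spike
    generation model.
    """

    # arena / populations
    arena_width: float = 80.0
    arena_height: float = 80.0
    n_side_ca3: int = 80          # 6400 CA3 place cells
    n_side_dg: int = 40           # 1600 DG place cells (0 disables DG)
    n_inh: int = 250              # interneurons per layer

    # sensory input (CA3 only); field is a 5-cm-radius box
    A_pos: float = 6.5
    A_dir: float = 6.0
    field_radius: float = 5.0
    mec_phase_shift_deg: float = 70.0

    # short-term facilitation of the sensory input
    S0F: float = 0.0
    S1F: float = 2.0
    phi_F: float = 0.001
    tau_F: float = 500.0

    # CA3 recurrent weights
    B_pos: float = 1100.0
    B_dir: float = 1500.0
    K_CA3: float = 1.0
    sigma: float = 2.0
    asymmetry_on: bool = False    # rightward-only projections J_ij
    recurrence_on: bool = True    # CA3->CA3 block present at all

    # short-term depression on CA3-presynaptic synapses
    U_D: float = 0.7
    tau_D: float = 500.0
    std_mode: str = "multiplicative"   # or "subtractive"
    std_to_inhibitory: bool = False    # STD on CA3->interneuron synapses
    std_to_dg: bool = True             # STD on the CA3->DG loop leg

    # DG loop
    B_DG: float = 3000.0
    K_DG: float = 1.0
    theta_DG: float = 0.0              # loop direction, radians
    loop_anchor: tuple = (0.0, 0.0)    # centre of the 40-cm intrinsic path
    dg_lesion: bool = False            # silence DG spiking

    # inhibition
    W0_ca3_inh: float = 50.0
    W0_inh_ca3: float = 5.0
    W0_dg_inh: float = 350.0
    W0_inh_dg: float = 35.0
    theta_to_inhibitory: bool = False
    theta_to_dg: bool = False

    # synapses / integration
    #   "per-block": conductance jumps normalised by the presynaptic
    #   population size of each block; "global": all place-cell blocks
    #   (incl. DG sources) normalised by the CA3 count
    norm_mode: str = "per-block"
    #   charge-normalised synaptic kernels: each delivered spike increments
    #   the conductance by W/(N tau) so the injected charge is W/N
    #   independent of the synaptic time constant
    charge_normalized: bool = True
    #   synaptic efficacy multipliers applied to excitatory / inhibitory
    #   conductance jumps (robustness knobs; 1.0 = nominal)
    efficacy_scale: float = 2.0
    efficacy_scale_inh: float = 2.0
    tau_E: float = 12.0
    tau_I: float = 10.0
    V_E: float = 0.0
    V_I: float = -80.0
    tau_0: float = 2.0                 # transmission delay
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("tau_F", "tau_D", "tau_E", "tau_I", "tau_0", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.U_D <= 1.0:
            raise ValueError("U_D must lie in [0, 1]")
        if self.std_mode not in ("multiplicative", "subtractive"):
            raise ValueError("std_mode must be 'multiplicative' or 'subtractive'")

    @property
    def n_ca3(self) -> int:
        return self.n_side_ca3 ** 2

    @property
    def n_dg(self) -> int:
        return self.n_side_dg ** 2 if self.dg_on else 0

    @property
    def dg_on(self) -> bool:
        return self.n_side_dg > 0 and self.B_DG > 0 and not self.dg_lesion

    def replace(self, **overrides) -> "NetworkConfig":
        return dataclasses.replace(self, **overrides)

    def scaled(self, factor: int) -> "NetworkConfig":
        """Reduce place-cell density by an integer factor per axis.

        The arena, all length scales and the per-presynaptic-population
        conductance normalisation are kept, so the mean synaptic drive per
        neuron is approximately density-invariant.  Used for quick runs and
        the test suite.
        """
        def _even(n: int) -> int:
            m = max(2, n // factor)
            return m - m % 2

        return self.replace(
            n_side_ca3=_even(self.n_side_ca3),
            n_side_dg=_even(self.n_side_dg) if self.n_side_dg else 0,
        )


def _preset(**kw) -> NetworkConfig:
    return NetworkConfig(**kw)


_NO_DG = dict(n_side_dg=0, B_DG=0.0, W0_dg_inh=0.0, W0_inh_dg=0.0)

#: Named parameter presets.  Contested table cells (see module docstring)
#: are the STF row of `no_recurrence`, the Apos/Adir of the lesion columns
#: and the Bpos=0 of the readout preset.
PRESETS: dict[str, NetworkConfig] = {
    # fixed rightward asymmetric weights, no STD/STF, no DG, no inhibition
    "intrinsic_asymmetry": _preset(
        A_pos=7.5, A_dir=0.0, S0F=1.0, S1F=1.0, phi_F=0.0,
        B_pos=1100.0, B_dir=0.0, K_CA3=0.0, asymmetry_on=True, U_D=0.0,
        n_inh=0, W0_ca3_inh=0.0, W0_inh_ca3=0.0, **_NO_DG,
    ),
    # symmetric weights + strong STD: movement-driven sequences only
    "extrinsic_std": _preset(
        A_pos=9.0, A_dir=0.0, S0F=1.0, S1F=1.0, phi_F=0.0,
        B_pos=1100.0, B_dir=0.0, K_CA3=0.0, U_D=0.9, **_NO_DG,
    ),
    # directional sensory tuning and STF added, still no DG
    "directional_input": _preset(
        A_pos=6.5, A_dir=6.0, B_pos=1100.0, B_dir=2000.0, K_CA3=1.0,
        U_D=0.7, **_NO_DG,
    ),
    # full CA3-DG loop model (control condition of the lesion comparison)
    "dg_loop": _preset(
        A_pos=6.5, A_dir=6.0, B_pos=1100.0, B_dir=1500.0, K_CA3=1.0,
        U_D=0.7, B_DG=3000.0,
    ),
    # DG silenced; sensory release fixed at an elevated constant level
    "dg_lesion": _preset(
        A_pos=9.5, A_dir=9.0, S0F=1.25, S1F=1.25, phi_F=0.0,
        B_pos=1100.0, B_dir=1500.0, K_CA3=1.0, U_D=0.7,
        B_DG=0.0, dg_lesion=True,
    ),
    # stronger loop/inputs used for oblique loop orientations in 2-d
    "dg_loop_2d": _preset(
        A_pos=7.5, A_dir=8.0, B_pos=1100.0, B_dir=2000.0, K_CA3=1.0,
        U_D=0.7, B_DG=4000.0,
    ),
    # CA3 recurrence removed, compensated by stronger sensory input + loop
    "no_recurrence": _preset(
        A_pos=6.5, A_dir=6.0, S0F=0.25, S1F=1.5,
        B_pos=0.0, B_dir=0.0, recurrence_on=False, U_D=0.7, B_DG=4000.0,
    ),
    "no_recurrence_control": _preset(
        A_pos=6.5, A_dir=6.0, B_pos=0.0, B_dir=0.0, recurrence_on=False,
        U_D=0.7, B_DG=4000.0,
    ),
    "no_recurrence_lesion": _preset(
        A_pos=6.5, A_dir=6.0, S0F=1.25, S1F=1.25, phi_F=0.0,
        B_pos=0.0, B_dir=0.0, recurrence_on=False, U_D=0.7,
        B_DG=0.0, dg_lesion=True,
    ),
    # readout-training network: DG loop gated to a path at y = +20 cm
    "tempotron_readout": _preset(
        A_pos=6.5, A_dir=6.0, B_pos=0.0, B_dir=1500.0, K_CA3=1.0,
        U_D=0.7, B_DG=4000.0, loop_anchor=(0.0, 20.0),
    ),
}


def get_preset(name: str, **overrides) -> NetworkConfig:
    """Return a copy of a named preset with optional field overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return base.replace(**overrides) if overrides else base.replace()


_VALID_KEYS = {f.name for f in dataclasses.fields(NetworkConfig)}


def load_config(path) -> NetworkConfig:
    """Load a NetworkConfig from a YAML file.

    Schema: an optional ``preset`` key naming a base preset plus any
    NetworkConfig field as an override.  Unknown keys raise.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    preset = raw.pop("preset", None)
    unknown = set(raw) - _VALID_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "loop_anchor" in raw:
        raw["loop_anchor"] = tuple(raw["loop_anchor"])
    if preset is not None:
        return get_preset(preset, **raw)
    return NetworkConfig(**raw)


def config_fingerprint(config: NetworkConfig) -> str:
    """Short stable hash of a configuration, embedded in outputs."""
    import hashlib

    payload = repr(sorted(dataclasses.asdict(config).items())).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
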