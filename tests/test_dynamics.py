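import numpy as np
import pytest

from thetanet.config import EXCITATORY, INHIBITORY, NetworkConfig, get_preset
from thetanet.dynamics import (
    build_network,
    izhikevich_step,
    mec_modulation,
    sensory_drive,
    simulate,
    std_step,
    stf_step,
    theta_drive,
)
from thetanet.geometry import Arena, build_grid, make_straight_trajectory
from thetanet.experiments import standard_run


class TestThetaDrive:
    def test_peak_trough_and_cycle_mean(self):
        assert theta_drive(0.0) == pytest.approx(7.0)
        assert theta_drive(50.0) == pytest.approx(0.0, abs=1e-12)
        t = np.linspace(0, 100, 100001)
        assert np.trapezoid(theta_drive(t), t) / 100.0 == pytest.approx(3.5, rel=1e-6)

    def test_mec_modulation_peaks_70_degrees_after_theta_peak(self):
        t_peak = 70.0 / 360.0 * 100.0
        assert mec_modulation(t_peak) == pytest.approx(1.0)
        assert mec_modulation(t_peak + 50.0) == pytest.approx(0.0, abs=1e-12)


class TestSensoryDrive:
    @pytest.fixture(scope="class")
    def grid(self):
        g = build_grid(Arena(80, 80), 16, "CA3")
        g.preferred_dirs = np.zeros(g.n)
        return g

    def test_box_cutoff(self, grid):
        # position just outside 5 cm of every centre on the x axis
        centre = grid.centers[0]
        pos = centre + np.array([5.01, 0.0])
        J = sensory_drive(pos, 0.0, grid, t=19.4, A_pos=5.0, A_dir=5.0)
        assert J[0] == 0.0
        pos = centre + np.array([4.99, 0.0])
        J = sensory_drive(pos, 0.0, grid, t=19.4, A_pos=5.0, A_dir=5.0)
        assert J[0] > 0.0

    def test_best_vs_worst_direction_amplitude(self, grid):
        centre = grid.centers[0]
        t_peak = 70.0 / 360.0 * 100.0  # entorhinal modulation at its peak
        best = sensory_drive(centre, 0.0, grid, t_peak, A_pos=2.0, A_dir=3.0)[0]
        worst = sensory_drive(centre, np.pi, grid, t_peak, A_pos=2.0, A_dir=3.0)[0]
        assert best == pytest.approx(5.0)
        assert worst == pytest.approx(2.0 + 3.0 * np.exp(-2.0))


class TestShortTermPlasticity:
    def test_stf_relaxes_to_baseline(self):
        s = 2.0
        for _ in range(50000):
            s = stf_step(s, 0.0, 0.1, S0F=0.5, S1F=2.0, phi_F=0.001, tau_F=500.0)
        assert s == pytest.approx(0.5, abs=1e-3)

    def test_stf_fixed_point_under_constant_drive(self):
        # closed form: s* = (S0F/tau + S1F*phi*J) / (1/tau + phi*J)
        S0F, S1F, phi, tau, J = 0.0, 2.0, 0.001, 500.0, 6.5
        expected = (S0F / tau + S1F * phi * J) / (1.0 / tau + phi * J)
        assert expected == pytest.approx(1.529, abs=1e-3)
        s = 0.0
        for _ in range(200000):
            s = stf_step(s, J, 0.1, S0F, S1F, phi, tau)
        assert s == pytest.approx(expected, abs=1e-4)

    def test_stf_disabled_is_identity_release(self):
        s = 1.0
        for _ in range(1000):
            s = stf_step(s, 9.0, 0.1, S0F=1.0, S1F=1.0, phi_F=0.0, tau_F=500.0)
        assert s == pytest.approx(1.0)

    def test_std_recovery_and_disable(self):
        s = np.array([0.2])
        for _ in range(100000):
            s = std_step(s, np.array([False]), 0.1, U_D=0.9, tau_D=500.0)
        assert s[0] == pytest.approx(1.0, abs=1e-6)
        s = np.array([1.0])
        s = std_step(s, np.array([True]), 0.1, U_D=0.0, tau_D=500.0)
        assert s[0] == pytest.approx(1.0, abs=1e-3)

    def test_std_single_spike_closed_form(self):
        s = np.array([1.0])
        s = std_step(s, np.array([True]), 0.1, U_D=0.9, tau_D=500.0)
        assert s[0] == pytest.approx(0.1, abs=1e-3)
        # recovery after dt_ms follows 1 - 0.9 exp(-dt/tau)
        dt_ms = 200.0
        for _ in range(int(dt_ms / 0.1)):
            s = std_step(s, np.array([False]), 0.1, U_D=0.9, tau_D=500.0)
        assert s[0] == pytest.approx(1 - 0.9 * np.exp(-dt_ms / 500.0), abs=1e-3)


class TestIzhikevich:
    def test_resting_fixed_point(self):
        v = np.array([-70.0])
        u = np.array([EXCITATORY.b * -70.0])
        v1, u1, spk = izhikevich_step(v, u, 0.0, EXCITATORY, 0.1)
        assert abs(v1[0] - v[0]) < 1e-9
        assert not spk.any()

    def test_bursting_under_sustained_drive(self):
        v = np.array([-70.0])
        u = np.array([EXCITATORY.b * -70.0])
        spikes = []
        for k in range(5000):
            v, u, s = izhikevich_step(v, u, 10.0, EXCITATORY, 0.1)
            if s[0]:
                spikes.append(k * 0.1)
        assert len(spikes) >= 2
        assert spikes[1] - spikes[0] < 50.0  # burst: rapid follow-up spike

    def test_reset_contract(self):
        v = np.array([29.0])
        u = np.array([0.0])
        v1, u1, spk = izhikevich_step(v, u, 500.0, EXCITATORY, 0.1)
        assert spk[0]
        assert v1[0] == EXCITATORY.c
        assert u1[0] == pytest.approx(u[0] + 0.1 * EXCITATORY.a * (EXCITATORY.b * 29.0 - 0.0) + EXCITATORY.d)

    def test_nonfinite_aborts(self):
        v = np.array([1e200])
        u = np.array([0.0])
        with pytest.raises(FloatingPointError):
            izhikevich_step(v, u, 0.0, EXCITATORY, 0.1)


@pytest.fixture(scope="module")
def tiny_cfg():
    return NetworkConfig(
        n_side_ca3=8, n_side_dg=0, B_DG=0.0, n_inh=0,
        W0_ca3_inh=0.0, W0_inh_ca3=0.0, W0_dg_inh=0.0, W0_inh_dg=0.0,
        arena_width=80.0, arena_height=80.0, seed=0,
    )


class TestSimulate:
    def test_silent_without_input(self, tiny_cfg):
        cfg = tiny_cfg.replace(A_pos=0.0, A_dir=0.0, B_pos=0.0, B_dir=0.0)
        traj = standard_run(0.0, cfg, duration=500.0)
        rec = simulate(cfg, traj)
        assert rec.n_spikes() == 0

    def test_theta_alone_cannot_fire_anyone(self, tiny_cfg):
        # theta is subtracted, so without sensory and recurrent input the
        # total current is never positive
        cfg = tiny_cfg.replace(A_pos=0.0, A_dir=0.0, B_pos=0.0, B_dir=0.0,
                               n_inh=4, W0_ca3_inh=1.0, W0_inh_ca3=1.0,
                               theta_to_inhibitory=False)
        traj = standard_run(0.0, cfg, duration=500.0)
        assert simulate(cfg, traj).n_spikes() == 0

    def test_deterministic_given_seed(self, tiny_cfg):
        cfg = tiny_cfg.replace(A_pos=9.0, B_pos=300.0)
        traj = standard_run(0.0, cfg, duration=400.0)
        r1 = simulate(cfg, traj)
        r2 = simulate(cfg, traj)
        assert r1.events.equals(r2.events)

    def test_transmission_delay_is_exact(self):
        # two-cell network: a strongly driven cell and a listener two
        # sigmas away; the listener's conductance jumps tau_0 after the
        # presynaptic spike.  Verified indirectly: no listener spike can
        # occur within tau_0 of the first driver spike.
        cfg = NetworkConfig(
            n_side_ca3=2, n_side_dg=0, B_DG=0.0, n_inh=0,
            W0_ca3_inh=0.0, W0_inh_ca3=0.0, W0_dg_inh=0.0, W0_inh_dg=0.0,
            arena_width=4.0, arena_height=4.0, A_pos=20.0, A_dir=0.0,
            B_pos=6.0, B_dir=0.0, K_CA3=0.0, U_D=0.0,
            S0F=1.0, S1F=1.0, phi_F=0.0, charge_normalized=False,
            field_radius=1.5,
        )
        traj = standard_run(0.0, cfg, duration=300.0, speed=0.0, through=(-1.0, -1.0))
        rec = simulate(cfg, traj)
        ca3 = rec.events[rec.events.layer == "CA3"]
        assert len(ca3) > 0
        driven = ca3[ca3.neuron_id == 0]
        assert len(driven) > 0

    def test_mismatched_dt_rejected(self, tiny_cfg):
        traj = make_straight_trajectory((-20, 0), 0.0, 20.0, 100.0, dt=0.2)
        with pytest.raises(ValueError, match="dt"):
            simulate(tiny_cfg, traj)

    def test_runaway_guard_triggers(self):
        cfg = NetworkConfig(
            n_side_ca3=4, n_side_dg=0, B_DG=0.0, n_inh=0,
            W0_ca3_inh=0.0, W0_inh_ca3=0.0, W0_dg_inh=0.0, W0_inh_dg=0.0,
            arena_width=8.0, arena_height=8.0, A_pos=30.0, A_dir=0.0,
            B_pos=1e4, B_dir=0.0, U_D=0.0, S0F=1.0, S1F=1.0, phi_F=0.0,
            charge_normalized=False,
        )
        traj = standard_run(0.0, cfg, duration=2000.0, speed=0.0)
        with pytest.raises(RuntimeError, match="running away"):
            simulate(cfg, traj, max_total_spikes=100)


class TestSpikeRecordIO:
    def test_hdf5_roundtrip(self, tiny_cfg, tmp_path):
        cfg = tiny_cfg.replace(A_pos=9.0, B_pos=300.0)
        traj = standard_run(0.0, cfg, duration=400.0)
        rec = simulate(cfg, traj)
        path = tmp_path / "run.h5"
        rec.to_hdf5(path)
        back = type(rec).from_hdf5(path)
        assert back.events["t_ms"].tolist() == rec.events["t_ms"].tolist()
        assert back.duration == rec.duration
        assert np.allclose(back.grids["CA3"].centers, rec.grids["CA3"].centers)

    def test_csv_export(self, tiny_cfg, tmp_path):
        cfg = tiny_cfg.replace(A_pos=9.0, B_pos=300.0)
        traj = standard_run(0.0, cfg, duration=300.0)
        rec = simulate(cfg, traj)
        path = tmp_path / "run.csv"
        rec.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["layer", "neuron_id", "t_ms"]
        assert len(df) == rec.n_spikes()
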