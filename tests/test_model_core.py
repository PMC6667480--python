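"""Oscillator core: light processor, drives, integration, phase markers."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from circphase import model as M
from circphase.model import NonOscillatingError, PacemakerState
from circphase.params import ModelParameters


def minute_grid(days: float) -> np.ndarray:
    return np.arange(int(days * 1440) + 1) / 60.0


def pulse_cbtmin(params, pulse_start_h, pulse_lux, days=6):
    """CBTmin events after a single 3 h light pulse from an on-cycle start."""
    t = minute_grid(days)
    lux = np.zeros_like(t)
    lux[(t >= pulse_start_h) & (t < pulse_start_h + 3.0)] = pulse_lux
    drives = M.light_processor(t, lux, params)
    traj = M.integrate(drives, PacemakerState(0.0, -1.0, 0.0, 0.0),
                       params, mode="photic")
    return traj.cbtmin_abs_hours


class TestParameters:
    def test_invalid_values_rejected(self):
        for kw in ({"tau_c": -1}, {"mu": 0}, {"ls": 1.2}, {"p": 0},
                   {"rho": -0.1}, {"beta": 0}):
            with pytest.raises(ValueError):
                ModelParameters(**kw)

    def test_config_roundtrip(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("tau_c: 23.5\nas: 8.0\nmode: photic\n")
        from circphase.params import load_config
        params, extras = load_config(cfg)
        assert params.tau_c == 23.5 and params.as_ == 8.0
        assert extras == {"mode": "photic"}


class TestLightProcessor:
    def test_darkness_gives_zero_drive(self, params):
        t = minute_grid(1)
        ds = M.light_processor(t, np.zeros_like(t), params)
        assert np.all(ds.Bhat == 0.0)
        assert np.all(ds.n == 0.0)

    def test_reference_lux_fixed_point(self, params):
        # Closed form of the processor ODE at I = I0: n* = a0/(a0+b),
        # Bhat* = G a0 (1 - n*).
        t = minute_grid(2)
        ds = M.light_processor(t, np.full_like(t, 9500.0), params, n0=0.0)
        n_star = params.alpha0 / (params.alpha0 + params.beta)
        b_star = params.G * params.alpha0 * (1.0 - n_star)
        assert ds.n[-1] == pytest.approx(n_star, abs=1e-6)
        assert ds.Bhat[-1] == pytest.approx(b_star, abs=1e-6)
        assert b_star == pytest.approx(0.2201, abs=5e-5)

    def test_light_step_adapts(self, params):
        # A lux step drives Bhat to its maximum at onset, then the
        # photoreceptor pool depletes and Bhat decays monotonically.
        t = minute_grid(1)
        lux = np.where(t >= 6.0, 1000.0, 0.0)
        ds = M.light_processor(t, lux, params)
        onset = np.searchsorted(t, 6.0)
        assert ds.Bhat[onset] == ds.Bhat.max()
        tail = ds.Bhat[onset:]
        assert np.all(np.diff(tail) <= 1e-12)
        assert tail[-1] < tail[0]

    def test_rejects_bad_input(self, params):
        t = minute_grid(1)
        with pytest.raises(ValueError, match="non-negative"):
            M.light_processor(t, np.full_like(t, -1.0), params)
        with pytest.raises(ValueError, match="uniform"):
            M.light_processor(np.array([0.0, 1 / 60, 3 / 60]),
                              np.zeros(3), params)


class TestDrives:
    @pytest.mark.parametrize("bhat,x,xc,expected", [
        (1.0, 0.0, 0.0, 1.0),
        (0.0, 0.7, -0.7, 0.0),
        (1.0, 1.0, 1.0, 0.36),
    ])
    def test_photic_modulator(self, params, bhat, x, xc, expected):
        assert M.photic_drive(bhat, x, xc, params) == pytest.approx(expected)

    @pytest.mark.parametrize("nhat,x,expected", [
        (0.010667, 0.0, 0.010667),     # wake level rho/3, no modulation
        (0.5, 1.0, 0.0),               # saturation: 1 - tanh(10) ~ 0
        (0.5, -1.0, 1.0),              # anti-saturation: factor -> 2
    ])
    def test_nonphotic_modulator(self, params, nhat, x, expected):
        assert M.nonphotic_drive(nhat, x, params) == pytest.approx(
            expected, abs=1e-6)

    @pytest.mark.parametrize("x,xc,dx_expected", [
        (0.0, 0.0, 0.0),                                  # unstable origin
        (1.0, 0.0, (math.pi / 12) * 0.13 * (5 / 3 - 256 / 105)),
        (0.0, 1.0, math.pi / 12),
    ])
    def test_derivatives_dark(self, params, x, xc, dx_expected):
        dx, dxc = M.derivatives(PacemakerState(0, x, xc, 0.0), 0.0, 0.0,
                                params)
        assert dx == pytest.approx(dx_expected, abs=1e-12)
        k2 = (24.0 / (0.99729 * params.tau_c)) ** 2
        assert dxc == pytest.approx(-(math.pi / 12) * x * k2, abs=1e-12)


class TestIntegration:
    def test_origin_is_fixed_point(self, params):
        traj = M.free_run(params, days=1.0, x0=0.0, xc0=0.0)
        assert np.all(np.abs(traj.x) < 1e-12)
        with pytest.raises(NonOscillatingError):
            traj.cbtmin_events()

    @pytest.mark.parametrize("tau_c", [23.5, 24.2, 24.6])
    def test_free_running_period_equals_tau(self, params, tau_c):
        # The 24/(0.99729 tau_c) scaling makes the simulated period track
        # the intrinsic period across plausible human values.
        traj = M.free_run(params.replace(tau_c=tau_c), days=15)
        spacing = np.diff(traj.cbtmin_abs_hours)
        assert abs(spacing.mean() - tau_c) < 0.05

    @pytest.mark.parametrize("radius", [0.1, 1.5])
    def test_limit_cycle_amplitude(self, params, radius):
        traj = M.free_run(params, days=25, x0=-radius, xc0=0.0)
        tail = traj.x[-3 * 1440:]
        assert abs(np.abs(tail).max() - 1.00) < 0.05

    def test_step_refinement_stable(self, params):
        # Halving the step changes no sample by more than 1e-6: pulse on
        # day 1 makes the check cover the driven dynamics too.
        t1 = minute_grid(3)
        lux1 = np.where((t1 >= 30.0) & (t1 < 33.0), 1000.0, 0.0)
        d1 = M.light_processor(t1, lux1, params)
        init = PacemakerState(0.0, -1.0, 0.0, 0.0)
        tr1 = M.integrate(d1, init, params, mode="photic")

        t2 = np.arange(len(t1) * 2 - 1) / 120.0
        d2 = M.DriveSeries(t=t2, Bhat=np.repeat(d1.Bhat, 2)[: len(t2)],
                           Nhat=np.zeros_like(t2))
        tr2 = M.integrate(d2, init, params, mode="photic")
        assert np.max(np.abs(tr2.x[::2] - tr1.x)) < 1e-6

    def test_matches_adaptive_reference(self, params):
        # Unforced trajectory vs a high-accuracy adaptive integration.
        days = 14
        k2 = (24.0 / (0.99729 * params.tau_c)) ** 2
        w = math.pi / 12.0

        def rhs(_, y):
            x, xc = y
            dx = w * (xc + params.mu * (x / 3 + 4 / 3 * x**3
                                        - 256 / 105 * x**7))
            return [dx, -w * x * k2]

        t = minute_grid(days)
        ref = solve_ivp(rhs, (0, t[-1]), [-1.0, 0.0], t_eval=t,
                        method="DOP853", rtol=1e-11, atol=1e-12)
        traj = M.free_run(params, days=days)
        assert np.max(np.abs(traj.x - ref.y[0])) < 1e-4

    def test_photic_mode_is_pnp_with_zero_nhat(self, params):
        t = minute_grid(2)
        lux = np.where((t % 24) > 8, 500.0, 0.0)
        drives = M.light_processor(t, lux, params)
        init = PacemakerState(0.0, -0.8, 0.3, 0.0)
        a = M.integrate(drives, init, params, mode="photic")
        b = M.integrate(drives.with_nhat(np.zeros_like(t)), init, params,
                        mode="pnp")
        assert np.array_equal(a.x, b.x) and np.array_equal(a.xc, b.xc)

    def test_too_short_drive_series_rejected(self, params):
        with pytest.raises(ValueError, match="shorter"):
            M.integrate(
                M.DriveSeries(t=np.array([0.0]), Bhat=np.array([0.0]),
                              Nhat=np.array([0.0])),
                PacemakerState(0, -1, 0, 0), params)


class TestEntrainmentAndPRC:
    def test_entrains_to_24h_light_dark(self, params):
        # 16 h:8 h LD at 1000 lux: CBTmin locks to a fixed clock time.
        t = minute_grid(14)
        lux = np.where((t % 24.0) >= 8.0, 1000.0, 0.0)
        drives = M.light_processor(t, lux, params)
        init = M.initial_state_from_cbtmin(0.0, 4.0, params, lux0=0.0)
        traj = M.integrate(drives, init, params, mode="photic")
        events = traj.cbtmin_abs_hours
        drift_per_day = np.abs(np.diff(events[-5:]) - 24.0)
        assert np.all(drift_per_day < 1.0 / 60.0)

    def test_prc_direction(self, params):
        # Type-1 response: light ending before CBTmin delays the rhythm,
        # light beginning after CBTmin advances it.
        ctrl = pulse_cbtmin(params, 0.0, 0.0)
        cbt2 = ctrl[1] + (ctrl[1] - ctrl[0])  # expected 3rd-cycle nadir
        delay = pulse_cbtmin(params, cbt2 - 5.0, 1000.0)
        advance = pulse_cbtmin(params, cbt2 + 2.0, 1000.0)
        assert delay[4] > ctrl[4] + 0.1
        assert advance[4] < ctrl[4] - 0.1

    def test_dose_response_monotone(self, params):
        ctrl = pulse_cbtmin(params, 0.0, 0.0)
        cbt2 = ctrl[1] + (ctrl[1] - ctrl[0])
        shifts = [abs(ctrl[4] - pulse_cbtmin(params, cbt2 - 5.0, lux)[4])
                  for lux in (10.0, 100.0, 1000.0, 10000.0)]
        assert np.all(np.diff(shifts) >= 0)


class TestPhaseMarkers:
    def test_cbtmin_of_pure_cosine(self):
        t = np.arange(-60, 49 * 60) / 60.0
        x = -np.cos(2 * np.pi * t / 24.0)
        events = M.extract_cbtmin(t, x)
        assert events == pytest.approx([0.0, 24.0, 48.0], abs=1e-6)

    @pytest.mark.parametrize("offset,expected", [
        (0.0, (-1.0, 0.0)),
        (6.0, (0.0, 1.0)),
        (12.0, (1.0, 0.0)),
    ])
    def test_initial_state_harmonic_mapping(self, params, offset, expected):
        s = M.initial_state_from_cbtmin(offset, 0.0, params)
        assert (s.x, s.xc) == pytest.approx(expected, abs=1e-12)

    def test_initial_state_rotation_direction(self, params):
        # One hour after the nadir the free-running state must match the
        # mapping evaluated one hour later (same rotation sense as the flow).
        traj = M.free_run(params, days=0.05, x0=-1.0, xc0=0.0)
        i = np.searchsorted(traj.t, 1.0)
        mapped = M.initial_state_from_cbtmin(1.0, 0.0, params)
        assert traj.x[i] == pytest.approx(mapped.x, abs=0.05)
        assert traj.xc[i] == pytest.approx(mapped.xc, abs=0.05)

    def test_predict_acrophase_dated(self, params):
        import pandas as pd
        t = minute_grid(4)
        drives = M.DriveSeries(t=t, Bhat=np.zeros_like(t),
                               Nhat=np.zeros_like(t),
                               start=pd.Timestamp("2024-03-04"))
        init = M.initial_state_from_cbtmin(0.0, 3.9167, params)
        traj = M.integrate(drives, init, params, mode="photic")
        got = M.predict_acrophase(traj, "2024-03-04")
        # the dated event is the trajectory's own first CBTmin, and stays
        # within the on-cycle placement error of the harmonic mapping
        assert got == pytest.approx(traj.cbtmin_events()["clock_h"].iloc[0],
                                    abs=1e-9)
        assert got == pytest.approx(3.9167, abs=0.5)
        assert M.predict_acrophase(traj, "2024-03-04", offset_h=0.5) == \
            pytest.approx(got + 0.5, abs=1e-9)
        with pytest.raises(ValueError, match="no CBTmin"):
            M.predict_acrophase(traj, "2024-04-01")
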