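"""Limit-cycle oscillator model of the human circadian pacemaker.

The pacemaker state is a point ``(x, xc)`` in the phase plane of a forced
Van der Pol-type oscillator, where ``x`` tracks the daily variation of core
body temperature and ``xc`` is the Lienard complementary variable:

    dx/dt  = (pi/12) [ xc + mu (x/3 + 4x^3/3 - 256 x^7/105) + B(t) + N(t) ]
    dxc/dt = (pi/12) { Lq B(t) xc - x [ (24 / (0.99729 tau_c))^2 + Lk B(t) ] }

``B(t)`` is the state-modulated photic drive and ``N(t)`` the state-modulated
non-photic (rest/activity) drive:

    B(t) = Bhat(t) (1 - ls x) (1 - ls xc)
    N(t) = Nhat(t) (1 - tanh(as x))

``Bhat(t)`` comes from a dynamic light processor (Process L): a photoreceptor
pool with activated fraction ``n`` driven by illuminance ``I`` through
``alpha(I) = alpha0 (I/I0)^p``,

    dn/dt = 60 [ alpha(I) (1 - n) - beta n ]      (t in hours)
    Bhat  = G alpha(I) (1 - n)

so that a light step produces a strong initial drive that adapts as the pool
depletes.  ``Nhat(t)`` is a square wave over scored main rest intervals,
``rho (1/3 - sigma)`` with ``sigma = 1`` during rest.

Integration is fixed-step classical Runge-Kutta on the one-minute epoch grid
with drives held constant within each epoch, which makes trajectories exactly
reproducible and independent of any adaptive-solver heuristics.  The phase
marker is the core body temperature minimum (CBTmin): the local minima of
``x(t)``, refined by quadratic interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters
from .timeutils import wrap_clock_h

__all__ = [
    "PacemakerState",
    "DriveSeries",
    "Trajectory",
    "NonOscillatingError",
    "light_processor",
    "photic_drive",
    "nonphotic_drive",
    "derivatives",
    "integrate",
    "extract_cbtmin",
    "initial_state_from_cbtmin",
    "predict_acrophase",
    "free_run",
]


class NonOscillatingError(RuntimeError):
    """Raised when a trajectory shows no usable CBTmin events."""


@dataclass
class PacemakerState:
    """Oscillator state at a time ``t`` (hours since series start)."""

    t: float
    x: float
    xc: float
    n: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.n <= 1.0:
            raise ValueError(f"photoreceptor fraction n={self.n} outside [0, 1]")


@dataclass
class DriveSeries:
    """Pre-modulation drives on a uniform minute grid.

    ``t`` is in hours since series start; ``start`` (optional) anchors the
    grid to calendar time so that CBTmin events can be dated.
    """

    t: np.ndarray
    Bhat: np.ndarray
    Nhat: np.ndarray
    n: np.ndarray | None = None
    start: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.Bhat = np.asarray(self.Bhat, dtype=float)
        self.Nhat = np.asarray(self.Nhat, dtype=float)
        if not (len(self.t) == len(self.Bhat) == len(self.Nhat)):
            raise ValueError("drive arrays must share one grid")
        steps = np.diff(self.t)
        if len(steps) and not np.allclose(steps, steps[0], atol=1e-9):
            raise ValueError("drive grid must be uniform")
        if np.any(self.Bhat < 0):
            raise ValueError("Bhat must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def with_nhat(self, Nhat: np.ndarray) -> "DriveSeries":
        return replace(self, Nhat=np.asarray(Nhat, dtype=float))


@dataclass
class Trajectory:
    """Integrated pacemaker trajectory plus dated CBTmin events."""

    t: np.ndarray
    x: np.ndarray
    xc: np.ndarray
    n: np.ndarray
    Bhat: np.ndarray
    Nhat: np.ndarray
    start: pd.Timestamp | None = None

    _cbtmin_abs: np.ndarray | None = None

    @property
    def cbtmin_abs_hours(self) -> np.ndarray:
        """CBTmin event times in hours since series start."""
        if self._cbtmin_abs is None:
            self._cbtmin_abs = extract_cbtmin(self.t, self.x)
        return self._cbtmin_abs

    def cbtmin_events(self) -> pd.DataFrame:
        """CBTmin events as (abs_h, clock_h[, date]) rows."""
        abs_h = self.cbtmin_abs_hours
        out = pd.DataFrame({"abs_h": abs_h})
        if self.start is not None:
            ts = self.start + pd.to_timedelta(abs_h, unit="h")
            out["date"] = ts.normalize()
            out["clock_h"] = (
                ts - ts.normalize()
            ) / pd.Timedelta(hours=1)
        else:
            start_clock = 0.0
            out["clock_h"] = wrap_clock_h(abs_h + start_clock)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"x": self.x, "xc": self.xc, "n": self.n,
             "Bhat": self.Bhat, "Nhat": self.Nhat}
        )
        if self.start is not None:
            df.insert(0, "time_iso",
                      self.start + pd.to_timedelta(self.t, unit="h"))
        else:
            df.insert(0, "t_h", self.t)
        return df


def _alpha(lux: np.ndarray, params: ModelParameters) -> np.ndarray:
    return params.alpha0 * np.power(np.asarray(lux, dtype=float) / params.I0,
                                    params.p)


def light_processor(
    t_hours: np.ndarray,
    lux: np.ndarray,
    params: ModelParameters,
    n0: float | None = None,
    start: pd.Timestamp | None = None,
) -> DriveSeries:
    """Run the dynamic light processor over a minute-epoch lux series.

    Within each epoch the lux is constant, so the photoreceptor equation is
    linear with constant coefficients and is advanced by its exact
    exponential update; ``Bhat`` is evaluated at each epoch start.

    ``n0`` defaults to the fixed point for the first epoch's illuminance,
    removing the start-up transient.
    """
    t_hours = np.asarray(t_hours, dtype=float)
    lux = np.asarray(lux, dtype=float)
    if np.any(lux < 0) or np.any(~np.isfinite(lux)):
        raise ValueError("lux must be finite and non-negative")
    steps = np.diff(t_hours)
    if len(steps) == 0:
        raise ValueError("need at least two epochs")
    dt = steps[0]
    if not np.allclose(steps, dt, atol=1e-9):
        raise ValueError("epoch grid must be uniform")

    alpha = _alpha(lux, params)
    beta = params.beta
    # dn/dt = 60[alpha(1-n) - beta n]; fixed point alpha/(alpha+beta),
    # relaxation rate 60(alpha+beta) per hour.
    rate = 60.0 * (alpha + beta)
    n_inf = np.where(rate > 0, alpha / (alpha + beta), 0.0)
    decay = np.exp(-rate * dt)

    n = np.empty_like(lux)
    n[0] = n_inf[0] if n0 is None else float(n0)
    if not 0.0 <= n[0] <= 1.0:
        raise ValueError("initial n must lie in [0, 1]")
    ninf_l = n_inf.tolist()
    dec_l = decay.tolist()
    n_l = n.tolist()
    for i in range(len(lux) - 1):
        n_l[i + 1] = ninf_l[i] + (n_l[i] - ninf_l[i]) * dec_l[i]
    n = np.asarray(n_l)
    Bhat = params.G * alpha * (1.0 - n)
    return DriveSeries(t=t_hours, Bhat=Bhat, Nhat=np.zeros_like(Bhat),
                       n=n, start=start)


def photic_drive(Bhat: float, x: float, xc: float,
                 params: ModelParameters) -> float:
    """State-modulated photic drive B = Bhat (1 - ls x)(1 - ls xc)."""
    return Bhat * (1.0 - params.ls * x) * (1.0 - params.ls * xc)


def nonphotic_drive(Nhat: float, x: float, params: ModelParameters) -> float:
    """State-modulated non-photic drive N = Nhat (1 - tanh(as x))."""
    return Nhat * (1.0 - math.tanh(params.as_ * x))


def derivatives(state: PacemakerState, B: float, N: float,
                params: ModelParameters) -> tuple[float, float]:
    """Right-hand sides (dx/dt, dxc/dt) in h^-1 for given drives."""
    x, xc = state.x, state.xc
    w = params.omega_scale
    k2 = (24.0 / (params.period_correction * params.tau_c)) ** 2
    dx = w * (xc + params.mu * (x / 3.0 + (4.0 / 3.0) * x**3
                                - (256.0 / 105.0) * x**7) + B + N)
    dxc = w * (params.Lq * B * xc - x * (k2 + params.Lk * B))
    return dx, dxc


def integrate(drives: DriveSeries, initial: PacemakerState,
              params: ModelParameters, mode: str = "pnp") -> Trajectory:
    """Integrate the pacemaker over the drive grid (classical RK4).

    Drives are held constant within each epoch; the state-dependent
    modulators are re-evaluated at every RK4 substage.  ``mode='photic'``
    zeroes the non-photic drive, which is the exact photic-only special
    case of the full model.
    """
    if mode not in ("photic", "pnp"):
        raise ValueError(f"unknown mode {mode!r}")
    t = drives.t
    if len(t) < 2:
        raise ValueError("drive series shorter than one step: "
                         f"covers [{t[0] if len(t) else '-'}]")
    dt = drives.dt
    Bh = drives.Bhat.tolist()
    Nh = ([0.0] * len(t)) if mode == "photic" else drives.Nhat.tolist()

    w = params.omega_scale
    mu, Lq, Lk, ls, as_ = params.mu, params.Lq, params.Lk, params.ls, params.as_
    k2 = (24.0 / (params.period_correction * params.tau_c)) ** 2
    tanh = math.tanh

    def f(x, xc, bhat, nhat):
        B = bhat * (1.0 - ls * x) * (1.0 - ls * xc)
        N = nhat * (1.0 - tanh(as_ * x))
        dx = w * (xc + mu * (x / 3.0 + (4.0 / 3.0) * x**3
                             - (256.0 / 105.0) * x**7) + B + N)
        dxc = w * (Lq * B * xc - x * (k2 + Lk * B))
        return dx, dxc

    nsteps = len(t) - 1
    xs = [0.0] * len(t)
    xcs = [0.0] * len(t)
    x, xc = float(initial.x), float(initial.xc)
    xs[0], xcs[0] = x, xc
    half = dt / 2.0
    sixth = dt / 6.0
    for i in range(nsteps):
        bh, nh = Bh[i], Nh[i]
        k1x, k1c = f(x, xc, bh, nh)
        k2x, k2c = f(x + half * k1x, xc + half * k1c, bh, nh)
        k3x, k3c = f(x + half * k2x, xc + half * k2c, bh, nh)
        k4x, k4c = f(x + dt * k3x, xc + dt * k3c, bh, nh)
        x += sixth * (k1x + 2.0 * (k2x + k3x) + k4x)
        xc += sixth * (k1c + 2.0 * (k2c + k3c) + k4c)
        xs[i + 1], xcs[i + 1] = x, xc

    n_series = drives.n if drives.n is not None else np.full(len(t), initial.n)
    return Trajectory(
        t=t.copy(), x=np.asarray(xs), xc=np.asarray(xcs),
        n=np.asarray(n_series, dtype=float),
        Bhat=drives.Bhat.copy(),
        Nhat=np.zeros(len(t)) if mode == "photic" else drives.Nhat.copy(),
        start=drives.start,
    )


def extract_cbtmin(t: np.ndarray, x: np.ndarray,
                   min_separation_h: float = 16.0,
                   min_amplitude: float = 0.05) -> np.ndarray:
    """Locate CBTmin events: local minima of x, quadratically refined.

    Each discrete minimum is refined by fitting a parabola through the three
    surrounding samples.  Minima closer together than ``min_separation_h``
    (sub-cycle wiggles) are resolved in favour of the deeper one.  A
    trajectory with no minima, or with negligible oscillation amplitude,
    raises :class:`NonOscillatingError` rather than returning nothing.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(t) < 3:
        raise NonOscillatingError("trajectory too short for minima")
    if np.ptp(x) < min_amplitude:
        raise NonOscillatingError(
            f"oscillation amplitude {np.ptp(x):.3g} below {min_amplitude}")
    interior = (x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])
    idx = np.nonzero(interior)[0] + 1
    if idx.size == 0:
        raise NonOscillatingError("no local minimum found")

    dt = t[1] - t[0]
    times, depths = [], []
    for i in idx:
        a, b, c = x[i - 1], x[i], x[i + 1]
        denom = a - 2.0 * b + c
        shift = 0.5 * (a - c) / denom if denom > 0 else 0.0
        times.append(t[i] + shift * dt)
        depths.append(b)
    events: list[tuple[float, float]] = []
    for tm, dp in zip(times, depths):
        if events and tm - events[-1][0] < min_separation_h:
            if dp < events[-1][1]:
                events[-1] = (tm, dp)
        else:
            events.append((tm, dp))
    return np.array([e[0] for e in events])


def initial_state_from_cbtmin(
    start_clock_h: float,
    cbtmin_clock_h: float,
    params: ModelParameters,
    lux0: float = 0.0,
) -> PacemakerState:
    """Place the oscillator on the unit cycle from a CBTmin clock estimate.

    Assumes uniform angular velocity over the 24 h day and unit amplitude:
    the phase angle since the nadir is ``theta = 2 pi (t0 - t_cbtmin)/24``
    and the harmonic mapping ``x = -cos(theta), xc = sin(theta)`` puts x at
    its minimum at CBTmin and rotates in the direction of the free-running
    flow.  ``n`` starts at its fixed point for the first epoch's lux.
    """
    theta = 2.0 * math.pi * (start_clock_h - cbtmin_clock_h) / 24.0
    alpha = float(_alpha(max(lux0, 0.0), params))
    n0 = alpha / (alpha + params.beta) if alpha + params.beta > 0 else 0.0
    return PacemakerState(t=0.0, x=-math.cos(theta), xc=math.sin(theta), n=n0)


def predict_acrophase(traj: Trajectory, on_date,
                      offset_h: float = 0.0) -> float:
    """Predicted aMT6s acrophase (clock hours) on a calendar date.

    The model's CBTmin on that date is reported directly as the predicted
    acrophase (the two markers are equated in this analysis); ``offset_h``
    applies an optional fixed marker offset.
    """
    if traj.start is None:
        raise ValueError("trajectory has no calendar anchor")
    events = traj.cbtmin_events()
    target = pd.Timestamp(on_date).normalize()
    hits = events[events["date"] == target]
    if hits.empty:
        avail = ", ".join(str(d.date()) for d in events["date"])
        raise ValueError(
            f"no CBTmin event on {target.date()}; events on: {avail}")
    return float(wrap_clock_h(hits["clock_h"].iloc[0] + offset_h))


def zero_drives(days: float, start: pd.Timestamp | None = None,
                dt_min: float = 1.0) -> DriveSeries:
    """A dark, drive-free grid of the given length (minutes spacing)."""
    n = int(round(days * 24.0 * 60.0 / dt_min)) + 1
    t = np.arange(n) * (dt_min / 60.0)
    z = np.zeros(n)
    return DriveSeries(t=t, Bhat=z, Nhat=z.copy(), n=z.copy(), start=start)


def free_run(params: ModelParameters, days: float = 30.0,
             x0: float = -1.0, xc0: float = 0.0) -> Trajectory:
    """Integrate the unforced oscillator (B = N = 0) from an on-cycle start."""
    drives = zero_drives(days)
    init = PacemakerState(t=0.0, x=x0, xc=xc0, n=0.0)
    return integrate(drives, init, params, mode="photic")
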