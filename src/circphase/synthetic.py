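"""Synthetic shift-worker cohorts for end-to-end pipeline testing.

Emulates the field protocol this package analyses: minute-epoch wrist-worn
light and activity recordings over a diurnal schedule (habitual sleep about
23:16-07:23) followed by 3-5 consecutive night shifts (20:00-08:30, daytime
sleep about 09:20-15:57), plus block-collected urinary aMT6s profiles with a
known cosine acrophase.

Light is drawn per waking epoch from log-normal distributions.  On the
night schedule the waking illuminance distribution is calibrated so that
roughly 24% of waking epochs fall below 10 lux and 61% below 100 lux, the
dim-light profile characteristic of overnight hospital work (log-normal
with mu = 3.9526, sigma = 2.3362 on log-lux, the exact solution of those
two quantile constraints).  Diurnal waking light is brighter: indoor
log-normal around 150 lux with occasional outdoor excursions around
2000 lux.  Activity is a two-state Poisson process (near-zero counts during
rest, high bursty counts during wake), the simplest process that exercises
the rest-scoring thresholds.

Every generator is deterministic given its seed; ground truth (sleep
intervals, acrophases) is returned alongside the data so recovery can be
asserted exactly in the zero-noise mode.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .actigraphy import EpochSeries, RestInterval
from .cosinor import UrineSample

#: Night-schedule waking log-lux parameters: solve
#: P(lux < 10) = 0.24, P(lux < 100) = 0.61 for a log-normal.
NIGHT_LUX_MU = 3.9526
NIGHT_LUX_SIGMA = 2.3362


@dataclass(frozen=True)
class ScheduleSpec:
    """A diurnal-then-nights shift pattern (times in decimal clock hours)."""

    n_diurnal_days: int = 7
    n_night_shifts: int = 4
    start_date: str = "2024-03-04"
    diurnal_sleep: tuple[float, float] = (23.2667, 7.3833)   # 23:16-07:23
    night_sleep: tuple[float, float] = (9.3333, 15.95)       # 09:20-15:57
    day_shift: tuple[float, float] = (7.0, 15.5)
    evening_shift: tuple[float, float] = (15.0, 21.5)
    night_shift: tuple[float, float] = (20.0, 8.5)

    def __post_init__(self) -> None:
        if self.n_night_shifts not in (3, 4, 5):
            raise ValueError("n_night_shifts must be 3, 4 or 5")
        if self.n_diurnal_days < 1:
            raise ValueError("need at least one diurnal day")

    @property
    def n_days_total(self) -> int:
        # +1 trailing day: the final night shift ends, and its daytime sleep
        # and the following CBTmin fall, on the day after the last shift.
        return self.n_diurnal_days + self.n_night_shifts + 1

    @property
    def first_night_day(self) -> int:
        return self.n_diurnal_days


@dataclass(frozen=True)
class LightEnvironment:
    """Illuminance distributions per behavioural context (photopic lux)."""

    sleep_lux: float = 0.0
    indoor_median: float = 150.0
    indoor_sigma: float = 0.7        # sigma of log-lux
    outdoor_median: float = 2000.0
    outdoor_sigma: float = 0.6
    outdoor_prob_per_hour: float = 0.10
    outdoor_bout_min: int = 30
    night_mu: float = NIGHT_LUX_MU
    night_sigma: float = NIGHT_LUX_SIGMA
    lux_cap: float = 1.0e5


def _mask_window(hours_abs: np.ndarray, day: int, start_h: float,
                 end_h: float) -> np.ndarray:
    """Epoch mask for a clock window anchored to ``day`` (may wrap past
    midnight into the next day)."""
    t0 = day * 24.0 + start_h
    t1 = day * 24.0 + end_h if end_h > start_h else (day + 1) * 24.0 + end_h
    return (hours_abs >= t0) & (hours_abs < t1)


def generate_trace(
    spec: ScheduleSpec,
    env: LightEnvironment | None = None,
    seed: int = 0,
    sleep_jitter_min: float = 8.0,
    zero_noise: bool = False,
    offwrist_gaps: list[tuple] | None = None,
) -> tuple[EpochSeries, list[RestInterval], pd.DataFrame]:
    """Generate one subject's minute-epoch trace.

    Returns the EpochSeries, the ground-truth sleep intervals, and a work
    diary (shift_type, start_iso, end_iso).  ``zero_noise`` removes sleep
    timing jitter and makes rest epochs exactly dark and motionless so that
    scoring must recover the truth exactly.  ``offwrist_gaps`` marks the
    given (start, end) timestamp windows as not worn.
    """
    env = env or LightEnvironment()
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(spec.start_date)
    n_epochs = spec.n_days_total * 24 * 60
    index = pd.date_range(t0, periods=n_epochs, freq="1min")
    hours_abs = np.arange(n_epochs) / 60.0

    jitter = (lambda: 0.0) if zero_noise else (
        lambda: float(rng.normal(0.0, sleep_jitter_min)) / 60.0)

    sleep_episodes: list[tuple[float, float]] = []  # absolute hours
    for d in range(spec.n_diurnal_days):
        s = d * 24.0 + spec.diurnal_sleep[0] + jitter()
        e = (d + 1) * 24.0 + spec.diurnal_sleep[1] + jitter()
        sleep_episodes.append((s, e))
    for j in range(spec.n_night_shifts):
        day = spec.first_night_day + 1 + j
        s = day * 24.0 + spec.night_sleep[0] + jitter()
        e = day * 24.0 + spec.night_sleep[1] + jitter()
        sleep_episodes.append((s, e))

    asleep = np.zeros(n_epochs, dtype=bool)
    truth: list[RestInterval] = []
    for s, e in sleep_episodes:
        i, j = int(round(s * 60.0)), int(round(e * 60.0))
        i, j = max(i, 0), min(j, n_epochs)
        asleep[i:j] = True
        truth.append(RestInterval(index[i], index[i] + pd.Timedelta(
            minutes=j - i), "main"))

    # Shift roster: evening shifts across the diurnal block, then nights.
    diary_rows = []
    for d in range(spec.n_diurnal_days):
        diary_rows.append(("evening",
                           t0 + pd.Timedelta(hours=d * 24 + spec.evening_shift[0]),
                           t0 + pd.Timedelta(hours=d * 24 + spec.evening_shift[1])))
    on_shift = np.zeros(n_epochs, dtype=bool)
    for j in range(spec.n_night_shifts):
        day = spec.first_night_day + j
        m = _mask_window(hours_abs, day, *spec.night_shift)
        on_shift |= m
        diary_rows.append(("night",
                           t0 + pd.Timedelta(hours=day * 24 + spec.night_shift[0]),
                           t0 + pd.Timedelta(hours=(day + 1) * 24 + spec.night_shift[1])))
    diary = pd.DataFrame(diary_rows,
                         columns=["shift_type", "start_iso", "end_iso"])

    night_regime = hours_abs >= (spec.first_night_day * 24.0
                                 + spec.night_shift[0] - 4.0)
    awake = ~asleep

    lux = np.zeros(n_epochs)
    wake_diurnal = awake & ~night_regime
    wake_night = awake & night_regime
    lux[wake_diurnal] = rng.lognormal(np.log(env.indoor_median),
                                      env.indoor_sigma,
                                      int(wake_diurnal.sum()))
    # Outdoor excursions: Bernoulli bout starts per waking diurnal hour.
    idx_wd = np.nonzero(wake_diurnal)[0]
    p_start = env.outdoor_prob_per_hour / 60.0
    starts = idx_wd[rng.random(len(idx_wd)) < p_start]
    for i in starts:
        j = min(i + env.outdoor_bout_min, n_epochs)
        bout = wake_diurnal[i:j]
        lux[i:j][bout] = rng.lognormal(np.log(env.outdoor_median),
                                       env.outdoor_sigma, int(bout.sum()))
    lux[wake_night] = rng.lognormal(env.night_mu, env.night_sigma,
                                    int(wake_night.sum()))
    lux[asleep] = env.sleep_lux
    # one-decimal lux, matching device exports and keeping CSV round-trips exact
    lux = np.round(np.minimum(lux, env.lux_cap), 1)

    activity = np.zeros(n_epochs)
    lam = np.where(on_shift & awake, 180.0, 150.0)
    activity[awake] = rng.poisson(lam[awake])
    if not zero_noise:
        activity[asleep] = rng.poisson(1.0, int(asleep.sum()))

    worn = np.ones(n_epochs, dtype=bool)
    if offwrist_gaps:
        for gs, ge in offwrist_gaps:
            m = (index >= pd.Timestamp(gs)) & (index < pd.Timestamp(ge))
            worn[m] = False

    series = EpochSeries(pd.DataFrame(
        {"lux": lux, "activity": activity, "worn": worn}, index=index))
    return series, truth, diary


def block_plan(start: pd.Timestamp, total_h: float = 48.0,
               sleep_clock: tuple[float, float] = (23.0, 7.0)
               ) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Sequential urine blocks: 4-hourly, 8-hourly across the sleep window."""
    start = pd.Timestamp(start)
    end = start + pd.Timedelta(hours=total_h)
    lo, hi = sleep_clock
    blocks = []
    cur = start
    while cur < end:
        clock = cur.hour + cur.minute / 60.0
        in_sleep = (clock >= lo or clock < hi) if lo > hi else (
            lo <= clock < hi)
        dur = 8.0 if in_sleep else 4.0
        nxt = min(cur + pd.Timedelta(hours=dur), end)
        blocks.append((cur, nxt))
        cur = nxt
    return blocks


def generate_urine(
    true_acrophase_h: float,
    blocks: list[tuple[pd.Timestamp, pd.Timestamp]],
    mesor: float = 1000.0,
    amplitude: float = 700.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[UrineSample]:
    """Block-integrated cosine aMT6s excretion with a known acrophase.

    The per-block excreted amount is the exact integral of
    ``mesor + amplitude cos(2 pi (t - phi)/24)`` over the block, perturbed
    by multiplicative log-normal noise of the given log-SD, then split into
    a plausible urine volume and the matching assay concentration.
    """
    if amplitude > mesor:
        raise ValueError("amplitude must not exceed mesor "
                         "(excretion rates must stay non-negative)")
    rng = np.random.default_rng(seed)
    omega = 2.0 * np.pi / 24.0
    origin = pd.Timestamp(blocks[0][0]).normalize()
    samples = []
    for bs, be in blocks:
        t1 = (pd.Timestamp(bs) - origin) / pd.Timedelta(hours=1)
        t2 = (pd.Timestamp(be) - origin) / pd.Timedelta(hours=1)
        amount = mesor * (t2 - t1) + (amplitude / omega) * (
            np.sin(omega * (t2 - true_acrophase_h))
            - np.sin(omega * (t1 - true_acrophase_h)))
        if noise_sd > 0:
            amount *= float(np.exp(rng.normal(0.0, noise_sd)))
        volume = float(rng.uniform(100.0, 400.0)) * (t2 - t1) / 4.0
        samples.append(UrineSample(bs, be, volume, amount / volume))
    return samples


@dataclass
class CohortSpec:
    """Shape of a synthetic cohort, mirroring the field study's roster."""

    n_subjects: int = 25
    diurnal_days_mean: float = 7.2
    diurnal_days_sd: float = 2.9
    diurnal_days_range: tuple[int, int] = (2, 14)
    night_shift_choices: tuple[int, ...] = (3, 4, 5)
    acrophase_mean_h: float = 3.97
    acrophase_sd_h: float = 1.1
    shift_mean_h: float = -1.35     # diurnal minus night; negative = delay
    shift_sd_h: float = 1.0
    urine_noise_sd: float = 0.0
    mesor: float = 1000.0
    amplitude: float = 700.0
    zero_noise: bool = False


def generate_cohort(out_dir, cohort: CohortSpec | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Write a full multi-subject fixture set under ``out_dir``.

    Per subject: ``actigraphy.csv``, ``diary.csv``, ``urine_diurnal.csv``
    and ``urine_night.csv`` in the package's reader dialects, plus a
    cohort-level ``truth_table.csv`` holding every generated ground truth
    (schedule shape, true acrophases, reference dates, per-subject seeds).
    Deterministic and byte-identical per master seed.
    """
    cohort = cohort or CohortSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    for i in range(cohort.n_subjects):
        sid = f"S{i:02d}"
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        n_d = int(np.clip(round(rng.normal(cohort.diurnal_days_mean,
                                           cohort.diurnal_days_sd)),
                          *cohort.diurnal_days_range))
        n_n = int(rng.choice(cohort.night_shift_choices))
        spec = ScheduleSpec(n_diurnal_days=n_d, n_night_shifts=n_n)
        series, truth, diary = generate_trace(
            spec, seed=sub_seed, zero_noise=cohort.zero_noise)
        t0 = pd.Timestamp(spec.start_date)

        acro_d = float(rng.normal(cohort.acrophase_mean_h,
                                  cohort.acrophase_sd_h)) % 24.0
        shift = float(rng.normal(cohort.shift_mean_h, cohort.shift_sd_h))
        acro_n = (acro_d - shift) % 24.0

        # Diurnal collection: last 48 h of the diurnal block; night
        # collection: 48 h centred on the morning after the final shift.
        diurnal_start = t0 + pd.Timedelta(hours=(n_d - 2) * 24 + 8.0)
        final_day = spec.first_night_day + n_n - 1
        night_start = t0 + pd.Timedelta(hours=final_day * 24.0)
        ublocks_d = block_plan(diurnal_start, 48.0,
                               sleep_clock=(23.0, 7.5))
        ublocks_n = block_plan(night_start, 48.0,
                               sleep_clock=(9.0, 16.0))
        urine_d = generate_urine(acro_d, ublocks_d, cohort.mesor,
                                 cohort.amplitude, cohort.urine_noise_sd,
                                 seed=sub_seed + 1)
        urine_n = generate_urine(acro_n, ublocks_n, cohort.mesor,
                                 cohort.amplitude, cohort.urine_noise_sd,
                                 seed=sub_seed + 2)

        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        series.to_csv(sdir / "actigraphy.csv")
        d = diary.copy()
        d.insert(0, "subject_id", sid)
        d.to_csv(sdir / "diary.csv", index=False,
                 date_format="%Y-%m-%d %H:%M:%S")
        for name, samples in (("urine_diurnal.csv", urine_d),
                              ("urine_night.csv", urine_n)):
            pd.DataFrame({
                "subject_id": sid,
                "block_start_iso": [s.block_start for s in samples],
                "block_end_iso": [s.block_end for s in samples],
                "volume_ml": [round(s.volume_ml, 3) for s in samples],
                "amt6s_ng_ml": [round(s.concentration_ng_ml, 6)
                                for s in samples],
            }).to_csv(sdir / name, index=False,
                      date_format="%Y-%m-%d %H:%M:%S")

        rows.append({
            "subject_id": sid, "seed": sub_seed,
            "n_diurnal_days": n_d, "n_night_shifts": n_n,
            "true_acrophase_diurnal_h": round(acro_d, 4),
            "true_acrophase_night_h": round(acro_n, 4),
            "true_shift_h": round(shift, 4),
            "diurnal_ref_date": (diurnal_start
                                 + pd.Timedelta(hours=24)).date(),
            "night_ref_date": (night_start
                               + pd.Timedelta(hours=24)).date(),
        })
    table = pd.DataFrame(rows)
    table.to_csv(out / "truth_table.csv", index=False)
    return table
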