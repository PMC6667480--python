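"""Prediction-error statistics and the phase-error consequence analysis.

Prediction error is measured acrophase minus predicted acrophase, wrapped
to (-12, 12] h.  Group summaries mirror the usual field-validation table:
mean and SD of raw error, absolute mean error, error range, fraction of
subjects within +/-30, 60 and 120 min, Pearson correlation between measured
and predicted phase, and a paired t-test of predicted against measured
(equivalently, of the raw errors against zero).

``rt_consequence`` translates a phase-estimation error into its cost on a
phase-binned psychomotor reaction-time profile: for each circadian phase
bin it reports the mean absolute change in reaction time under a +/-Delta
phase error and a standardised effect size (change divided by the
within-bin dispersion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .timeutils import wrap_phase_h

log = logging.getLogger(__name__)

DEG_PER_HOUR = 15.0


@dataclass
class PhaseComparison:
    subject_id: str
    schedule: str                 # diurnal | night | shift
    measured_h: float
    predicted_h: float
    error_h: float = field(init=False)
    abs_error_h: float = field(init=False)

    def __post_init__(self) -> None:
        self.error_h = float(wrap_phase_h(self.measured_h - self.predicted_h))
        self.abs_error_h = abs(self.error_h)


@dataclass
class GroupSummary:
    n: int
    mean_error: float
    sd_error: float | None
    abs_mean_error: float
    min_abs_error: float
    max_abs_error: float
    pct_within_30min: float
    pct_within_60min: float
    pct_within_120min: float
    pearson_r: float | None = None
    r2: float | None = None
    r_pvalue: float | None = None
    paired_t: float | None = None
    t_pvalue: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def compare_phases(measured: dict, predicted: dict) -> list[PhaseComparison]:
    """Pair measured and predicted clock phases by (subject, schedule) key.

    Keys are ``(subject_id, schedule)`` tuples; unmatched keys on either
    side are reported in the log, never dropped silently.
    """
    mk, pk = set(measured), set(predicted)
    for key in sorted(mk - pk):
        log.warning("no prediction for %s", key)
    for key in sorted(pk - mk):
        log.warning("no measurement for %s", key)
    return [
        PhaseComparison(subject_id=str(sid), schedule=sched,
                        measured_h=float(measured[sid, sched]),
                        predicted_h=float(predicted[sid, sched]))
        for sid, sched in sorted(mk & pk)
    ]


def summarize(comparisons: list[PhaseComparison]) -> GroupSummary:
    """Group summary over a set of phase comparisons.

    The paired t-test of measured against predicted phase is computed as a
    one-sample t-test of the wrapped raw errors against zero (identical for
    errors far from the wrap, and the only consistent choice on the
    circle).  Correlation fields require n >= 3 and are omitted (None)
    with a warning below that.
    """
    n = len(comparisons)
    if n == 0:
        raise ValueError("no comparisons to summarize")
    err = np.array([c.error_h for c in comparisons])
    abs_err = np.abs(err)
    meas = np.array([c.measured_h for c in comparisons])
    pred = np.array([c.predicted_h for c in comparisons])

    summary = GroupSummary(
        n=n,
        mean_error=float(err.mean()),
        sd_error=float(err.std(ddof=1)) if n >= 2 else None,
        abs_mean_error=float(abs_err.mean()),
        min_abs_error=float(abs_err.min()),
        max_abs_error=float(abs_err.max()),
        pct_within_30min=float(100.0 * np.mean(abs_err <= 0.5)),
        pct_within_60min=float(100.0 * np.mean(abs_err <= 1.0)),
        pct_within_120min=float(100.0 * np.mean(abs_err <= 2.0)),
    )
    if n >= 3:
        if np.ptp(meas) > 0 and np.ptp(pred) > 0:
            r, rp = stats.pearsonr(meas, pred)
            summary.pearson_r = float(r)
            summary.r2 = float(r * r)
            summary.r_pvalue = float(rp)
        if err.std(ddof=1) > 0:
            tt = stats.ttest_1samp(err, 0.0)
            summary.paired_t = float(tt.statistic)
            summary.t_pvalue = float(tt.pvalue)
    else:
        log.warning("n=%d < 3: correlation and t-test omitted", n)
    return summary


def direction_accuracy(measured_shifts, predicted_shifts) -> dict:
    """Fraction of subjects with correctly predicted shift direction.

    Signs follow the diurnal-minus-night convention (negative = delay).  A
    zero shift is counted correct only against a zero shift.  The confusion
    counts report false advances (predicted advance, measured not) and
    false delays (predicted delay, measured not).
    """
    m = np.asarray(measured_shifts, dtype=float)
    p = np.asarray(predicted_shifts, dtype=float)
    if m.shape != p.shape:
        raise ValueError("shift lists must have equal length")
    sm_, sp_ = np.sign(m), np.sign(p)
    correct = sm_ == sp_
    return {
        "n": int(len(m)),
        "accuracy": float(np.mean(correct)) if len(m) else float("nan"),
        "n_correct": int(correct.sum()),
        "false_advance": int(np.sum((sp_ > 0) & (sm_ <= 0))),
        "false_delay": int(np.sum((sp_ < 0) & (sm_ >= 0))),
    }


def read_rt_profile(path) -> pd.DataFrame:
    """Read a phase-binned reaction-time profile CSV
    (phase_deg, median_rt_ms, sd_ms)."""
    df = pd.read_csv(path)
    required = {"phase_deg", "median_rt_ms", "sd_ms"}
    if not required <= set(df.columns):
        raise ValueError(f"RT profile needs columns {sorted(required)}")
    return df.sort_values("phase_deg").reset_index(drop=True)


def rt_consequence(profile: pd.DataFrame, error_h: float) -> pd.DataFrame:
    """Reaction-time cost of a phase-estimation error, per circadian bin.

    ``profile`` holds uniform bins over a full cycle (phase in degrees,
    0 = CBTmin), the median reaction time and a within-bin dispersion.  For
    a phase error of ``error_h`` hours (Delta = 15 deg/h), each bin gets

        |dRT|(phi) = mean( |RT(phi+Delta) - RT(phi)|,
                           |RT(phi-Delta) - RT(phi)| )

    with circular indexing, and an effect size |dRT| / sd(phi).  Shifts
    that are not a whole number of bins are handled by circular linear
    interpolation, with a warning.  The result carries 720 degrees of rows
    (double-plotted) for the conventional two-cycle display.
    """
    phase = profile["phase_deg"].to_numpy(dtype=float)
    rt = profile["median_rt_ms"].to_numpy(dtype=float)
    sd = profile["sd_ms"].to_numpy(dtype=float)
    widths = np.diff(phase)
    if len(widths) == 0 or not np.allclose(widths, widths[0]):
        raise ValueError("RT profile bins must be uniform")
    width = widths[0]
    if not np.isclose(phase[0] % width, 0) or not np.isclose(
            phase[-1] + width - phase[0], 360.0):
        raise ValueError("RT profile bins must tile 360 degrees")

    shift_deg = error_h * DEG_PER_HOUR
    steps = shift_deg / width
    if np.isclose(steps, round(steps)):
        k = int(round(steps))
        rt_plus, rt_minus = np.roll(rt, -k), np.roll(rt, k)
    else:
        log.warning("phase error %.2f h is not a whole number of %g-degree "
                    "bins; interpolating circularly", error_h, width)
        grid = np.concatenate([phase, [phase[0] + 360.0]])
        vals = np.concatenate([rt, [rt[0]]])
        rt_plus = np.interp((phase + shift_deg) % 360.0, grid, vals)
        rt_minus = np.interp((phase - shift_deg) % 360.0, grid, vals)

    abs_drt = 0.5 * (np.abs(rt_plus - rt) + np.abs(rt_minus - rt))
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.where(sd > 0, abs_drt / sd, 0.0)
    single = pd.DataFrame({
        "phase_deg": phase, "abs_delta_rt_ms": abs_drt, "effect_size": effect,
    })
    doubled = single.copy()
    doubled["phase_deg"] = doubled["phase_deg"] + 360.0
    return pd.concat([single, doubled], ignore_index=True)
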