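"""End-to-end analysis: actigraphy in, phase predictions and errors out.

Per subject: read the minute-epoch actigraphy and work diary, impute
off-wrist sleep and score rest intervals, compute the average diurnal
mid-sleep, initialise the oscillator (mid-sleep heuristic or the "oracle"
diurnal acrophase), run the light processor and the pacemaker in photic
and/or photic+non-photic (PNP) mode, date the CBTmin events, and compare
the predicted acrophases against the cosinor reference phases from the
urine collections on the matching dates.

Per cohort: run every subject with failure isolation, then aggregate the
comparisons into the standard prediction-error summary per schedule
(diurnal, night, phase shift) and per model mode.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import actigraphy as act
from . import cosinor as cos
from . import evaluation as ev
from . import model
from .params import ModelParameters
from .timeutils import clock_hours, wrap_phase_h

log = logging.getLogger(__name__)

DIURNAL_SLEEP_WINDOW = (23.2667, 7.3833)   # habitual nocturnal sleep
POST_NIGHT_SLEEP_WINDOW = (9.3333, 15.95)  # daytime sleep after a night shift


@dataclass
class RunConfig:
    """Options for a subject or cohort run."""

    mode: str = "both"               # photic | pnp | both
    init: str = "midsleep"           # midsleep | oracle
    params: ModelParameters = field(default_factory=ModelParameters)
    cbtmin_offset_h: float = 0.0
    alpha: float = cos.SIGNIFICANCE_ALPHA
    allow_nonsignificant: bool = False
    diurnal_ref_date: object = None  # override; default: from collection
    night_ref_date: object = None

    def modes(self) -> list[str]:
        if self.mode == "both":
            return ["photic", "pnp"]
        if self.mode in ("photic", "pnp"):
            return [self.mode]
        raise ValueError(f"unknown mode {self.mode!r}")


def expected_sleep_windows(diary: pd.DataFrame,
                           span: tuple[pd.Timestamp, pd.Timestamp]
                           ) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Expected sleep episodes over the recording span, from the diary.

    Mornings after a night shift get the daytime window; every other day
    gets the habitual nocturnal window anchored to its evening, except
    evenings on which a night shift starts.
    """
    start, end = pd.Timestamp(span[0]).normalize(), pd.Timestamp(span[1])
    night_starts = set()
    for _, row in diary.iterrows():
        if str(row["shift_type"]).strip().lower() == "night":
            night_starts.add(pd.Timestamp(row["start_iso"]).normalize())
    windows = []
    day = start
    while day <= end:
        if (day - pd.Timedelta(days=1)) in night_starts:
            windows.append((day + pd.Timedelta(hours=POST_NIGHT_SLEEP_WINDOW[0]),
                            day + pd.Timedelta(hours=POST_NIGHT_SLEEP_WINDOW[1])))
        if day not in night_starts:
            windows.append((day + pd.Timedelta(hours=DIURNAL_SLEEP_WINDOW[0]),
                            day + pd.Timedelta(days=1)
                            + pd.Timedelta(hours=DIURNAL_SLEEP_WINDOW[1])))
        day += pd.Timedelta(days=1)
    return [(s, e) for s, e in windows if s < end and e > start]


def _reference_fit(urine_csv, subject_id, alpha):
    samples = cos.read_urine_csv(urine_csv, subject_id)
    rates = cos.excretion_rates(samples)
    fit = cos.cosinor_fit(rates, alpha=alpha)
    mid = samples[0].block_start + (
        max(s.block_end for s in samples) - samples[0].block_start) / 2
    return fit, fit.acrophase_occurrence(mid)


def run_subject(subject_dir, config: RunConfig | None = None,
                subject_id: str | None = None) -> dict:
    """Analyse one subject directory (actigraphy.csv, diary.csv,
    urine_diurnal.csv, urine_night.csv).  Returns the subject report."""
    config = config or RunConfig()
    sdir = Path(subject_dir)
    sid = subject_id or sdir.name

    series = act.read_actigraphy(sdir / "actigraphy.csv")
    diary = pd.read_csv(sdir / "diary.csv")
    windows = expected_sleep_windows(
        diary, (series.start, series.index[-1]))
    series, pre = act.impute_offwrist_sleep(series, [], windows)
    intervals = act.score_rest_intervals(series, windows)
    # Imputed gaps are zeroed, so scoring re-finds them; keep the imputed
    # label only where scoring did not already cover the gap.
    for r in pre:
        if r.kind == "imputed_offwrist" and not any(
                q.start < r.end and r.start < q.end for q in intervals):
            intervals.append(r)
    intervals.sort(key=lambda r: r.start)

    night_rows = diary[diary["shift_type"].str.lower() == "night"]
    if night_rows.empty:
        raise ValueError(f"{sid}: diary contains no night shifts")
    first_night_start = pd.Timestamp(night_rows["start_iso"].min())
    diurnal_mains = [r for r in intervals
                     if r.is_main and r.midpoint < first_night_start]
    midsleep_h = act.mid_sleep(diurnal_mains)

    fit_d, occ_d = _reference_fit(sdir / "urine_diurnal.csv", sid,
                                  config.alpha)
    fit_n, occ_n = _reference_fit(sdir / "urine_night.csv", sid,
                                  config.alpha)
    measured_shift = cos.measured_phase_shift(
        fit_d, fit_n, allow_nonsignificant=config.allow_nonsignificant)

    ref_date_d = (pd.Timestamp(config.diurnal_ref_date)
                  if config.diurnal_ref_date is not None
                  else occ_d.normalize())
    ref_date_n = (pd.Timestamp(config.night_ref_date)
                  if config.night_ref_date is not None
                  else occ_n.normalize())

    if config.init == "midsleep":
        cbtmin_est = midsleep_h
    elif config.init == "oracle":
        cbtmin_est = fit_d.acrophase
    else:
        raise ValueError(f"unknown init {config.init!r}")
    initial = model.initial_state_from_cbtmin(
        series.start_clock_h, cbtmin_est, config.params,
        lux0=float(series.lux[0]))

    drives = model.light_processor(series.hours, series.lux, config.params,
                                   n0=initial.n, start=series.start)
    nhat = act.build_nonphotic_input(series, intervals, config.params)
    drives = drives.with_nhat(nhat)

    report = {
        "subject_id": sid,
        "init": config.init,
        "mid_sleep_h": midsleep_h,
        "cbtmin_init_h": cbtmin_est,
        "n_days_data": len(series) / 1440.0,
        "n_main_rest": sum(r.is_main for r in intervals),
        "measured": {
            "diurnal_acrophase_h": fit_d.acrophase,
            "night_acrophase_h": fit_n.acrophase,
            "phase_shift_h": measured_shift,
            "diurnal_p": fit_d.p_value,
            "night_p": fit_n.p_value,
        },
        "ref_dates": {"diurnal": str(ref_date_d.date()),
                      "night": str(ref_date_n.date())},
        "predictions": {},
    }
    for mode in config.modes():
        traj = model.integrate(drives, initial, config.params, mode=mode)
        pred_d = model.predict_acrophase(traj, ref_date_d,
                                         config.cbtmin_offset_h)
        pred_n = model.predict_acrophase(traj, ref_date_n,
                                         config.cbtmin_offset_h)
        pred_shift = float(wrap_phase_h(pred_d - pred_n))
        report["predictions"][mode] = {
            "diurnal_acrophase_h": pred_d,
            "night_acrophase_h": pred_n,
            "phase_shift_h": pred_shift,
            "error_diurnal_h": float(wrap_phase_h(fit_d.acrophase - pred_d)),
            "error_night_h": float(wrap_phase_h(fit_n.acrophase - pred_n)),
            "error_shift_h": float(wrap_phase_h(measured_shift - pred_shift)),
        }
    return report


def run_cohort(cohort_dir, config: RunConfig | None = None) -> dict:
    """Analyse every subject directory under ``cohort_dir``.

    Subjects that fail are itemised in the report, never fatal unless all
    fail.  The summary block mirrors the standard validation table: one
    GroupSummary per (mode, comparison) cell plus direction-of-shift
    accuracy per mode.
    """
    config = config or RunConfig()
    root = Path(cohort_dir)
    subject_dirs = sorted(d for d in root.iterdir()
                          if d.is_dir() and (d / "actigraphy.csv").exists())
    if not subject_dirs:
        raise ValueError(f"no subject directories under {root}")

    reports, failures = [], {}
    for sdir in subject_dirs:
        try:
            reports.append(run_subject(sdir, config))
        except Exception as exc:  # noqa: BLE001 - failure isolation per subject
            log.error("subject %s failed: %s", sdir.name, exc)
            failures[sdir.name] = str(exc)
    if not reports:
        raise RuntimeError(f"all subjects failed: {failures}")

    out = {"n_subjects": len(reports), "failures": failures, "summary": {}}
    for mode in config.modes():
        measured, predicted = {}, {}
        m_shift, p_shift = [], []
        for rep in reports:
            sid = rep["subject_id"]
            pred = rep["predictions"][mode]
            for sched, mkey, pkey in (
                ("diurnal", "diurnal_acrophase_h", "diurnal_acrophase_h"),
                ("night", "night_acrophase_h", "night_acrophase_h"),
            ):
                measured[sid, sched] = rep["measured"][mkey]
                predicted[sid, sched] = pred[pkey]
            measured[sid, "shift"] = rep["measured"]["phase_shift_h"]
            predicted[sid, "shift"] = pred["phase_shift_h"]
            m_shift.append(rep["measured"]["phase_shift_h"])
            p_shift.append(pred["phase_shift_h"])
        comparisons = ev.compare_phases(measured, predicted)
        mode_summary = {}
        for sched in ("diurnal", "night", "shift"):
            subset = [c for c in comparisons if c.schedule == sched]
            mode_summary[sched] = ev.summarize(subset).to_dict()
        mode_summary["direction"] = ev.direction_accuracy(m_shift, p_shift)
        out["summary"][mode] = mode_summary
    out["subjects"] = reports
    return out


def cohort_summary_frame(report: dict) -> pd.DataFrame:
    """Flatten a cohort report's summary block into a tidy table."""
    rows = []
    for mode, sched_map in report["summary"].items():
        for sched, summary in sched_map.items():
            if sched == "direction":
                continue
            row = {"mode": mode, "schedule": sched}
            row.update(summary)
            rows.append(row)
    return pd.DataFrame(rows)
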