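"""Reference circadian phase from urinary aMT6s excretion.

Urine is collected in sequential blocks (4-hourly while awake, 8-hourly
across sleep); each block yields an excretion rate
``concentration * volume / duration`` (ng/h) assigned to the block
midpoint.  A single-component cosinor with fixed 24 h period,

    rate(t) = M + A cos(2 pi (t - phi) / 24),

is fitted by ordinary least squares in its linear parametrisation
(mesor, cosine and sine coefficients); the acrophase ``phi`` is the clock
time of the fitted peak and the zero-amplitude F-test gives the fit's
significance.  Fits with p above the significance level (default 0.10) are
flagged rather than silently accepted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .timeutils import wrap_clock_h, wrap_phase_h

log = logging.getLogger(__name__)

PERIOD_H = 24.0
SIGNIFICANCE_ALPHA = 0.10


@dataclass
class UrineSample:
    """One collection block: total volume and assayed aMT6s concentration."""

    block_start: pd.Timestamp
    block_end: pd.Timestamp
    volume_ml: float
    concentration_ng_ml: float

    def __post_init__(self) -> None:
        self.block_start = pd.Timestamp(self.block_start)
        self.block_end = pd.Timestamp(self.block_end)
        if self.block_end <= self.block_start:
            raise ValueError("urine block must have end > start")
        if self.volume_ml < 0 or self.concentration_ng_ml < 0:
            raise ValueError("volume and concentration must be non-negative")

    @property
    def duration_h(self) -> float:
        return (self.block_end - self.block_start) / pd.Timedelta(hours=1)

    @property
    def midpoint(self) -> pd.Timestamp:
        return self.block_start + (self.block_end - self.block_start) / 2


@dataclass
class CosinorFit:
    mesor: float          # ng/h
    amplitude: float      # ng/h
    acrophase: float      # clock hours in [0, 24)
    p_value: float        # zero-amplitude F-test
    r2: float
    n: int
    significant: bool

    def acrophase_occurrence(self, near: pd.Timestamp) -> pd.Timestamp:
        """The acrophase occurrence (a concrete timestamp) closest to ``near``."""
        near = pd.Timestamp(near)
        day = near.normalize()
        best = min(
            (day + pd.Timedelta(days=k) + pd.Timedelta(hours=self.acrophase)
             for k in (-1, 0, 1)),
            key=lambda ts: abs(ts - near),
        )
        return best


def read_urine_csv(path, subject_id: str | None = None) -> list[UrineSample]:
    """Read blocks from a CSV with columns
    subject_id, block_start_iso, block_end_iso, volume_ml, amt6s_ng_ml."""
    df = pd.read_csv(path)
    if subject_id is not None and "subject_id" in df.columns:
        df = df[df["subject_id"].astype(str) == str(subject_id)]
    return [
        UrineSample(row["block_start_iso"], row["block_end_iso"],
                    float(row["volume_ml"]), float(row["amt6s_ng_ml"]))
        for _, row in df.iterrows()
    ]


def excretion_rates(samples: list[UrineSample]) -> pd.DataFrame:
    """Per-block aMT6s excretion rates (ng/h) at block midpoints.

    Requires at least 5 blocks spanning at least 24 h.  Overlapping blocks
    or gaps over 2 h are tolerated with a warning; insufficient coverage is
    an error.
    """
    if len(samples) < 5:
        raise ValueError(f"need >= 5 urine blocks, got {len(samples)}")
    samples = sorted(samples, key=lambda s: s.block_start)
    span_h = (samples[-1].block_end - samples[0].block_start) / pd.Timedelta(
        hours=1)
    if span_h < 24.0:
        raise ValueError(f"urine collection spans {span_h:.1f} h < 24 h")
    for prev, cur in zip(samples, samples[1:]):
        gap_h = (cur.block_start - prev.block_end) / pd.Timedelta(hours=1)
        if gap_h > 2.0:
            log.warning("gap of %.1f h between urine blocks at %s",
                        gap_h, prev.block_end)
        elif gap_h < 0:
            log.warning("overlapping urine blocks at %s", cur.block_start)
    return pd.DataFrame({
        "midpoint": [s.midpoint for s in samples],
        "rate_ng_h": [
            s.concentration_ng_ml * s.volume_ml / s.duration_h
            for s in samples
        ],
        "block_start": [s.block_start for s in samples],
        "block_end": [s.block_end for s in samples],
    })


def cosinor_fit(rates: pd.DataFrame, period_h: float = PERIOD_H,
                alpha: float = SIGNIFICANCE_ALPHA) -> CosinorFit:
    """Fixed-period cosinor fit of a rate series.

    Times enter the design as clock-continuous hours so the acrophase
    comes out directly as a clock time.  When the series carries block
    boundaries (the output of :func:`excretion_rates`), the cosine and
    sine regressors are their exact averages over each block, so that
    block integration attenuates the fitted amplitude without biasing the
    acrophase even for blocks of unequal length; point samples use plain
    midpoint regressors.  The zero-amplitude test is the F-test of the
    joint nullity of the cosine and sine coefficients.
    """
    mids = pd.DatetimeIndex(rates["midpoint"])
    origin = mids[0].normalize()
    t = ((mids - origin) / pd.Timedelta(hours=1)).to_numpy(dtype=float)
    y = rates["rate_ng_h"].to_numpy(dtype=float)
    omega = 2.0 * np.pi / period_h
    if {"block_start", "block_end"} <= set(rates.columns):
        t1 = ((pd.DatetimeIndex(rates["block_start"]) - origin)
              / pd.Timedelta(hours=1)).to_numpy(dtype=float)
        t2 = ((pd.DatetimeIndex(rates["block_end"]) - origin)
              / pd.Timedelta(hours=1)).to_numpy(dtype=float)
        wd = omega * (t2 - t1)
        c = (np.sin(omega * t2) - np.sin(omega * t1)) / wd
        s = -(np.cos(omega * t2) - np.cos(omega * t1)) / wd
        X = np.column_stack([c, s])
    else:
        X = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
    if np.linalg.matrix_rank(np.column_stack([np.ones_like(t), X])) < 3:
        raise ValueError("cosinor design is rank deficient "
                         "(all samples at the same circadian phase)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits divide by ~0 variance
        res = sm.OLS(y, sm.add_constant(X)).fit()
    mesor, a, b = res.params
    amplitude = float(np.hypot(a, b))
    acro = float(wrap_clock_h(np.arctan2(b, a) / omega))
    if res.ssr <= 1e-10 * max(res.centered_tss, 1.0):
        # (near-)perfect fit: degenerate F statistic
        p_value = 0.0 if amplitude > 1e-8 * max(abs(mesor), 1.0) else 1.0
    else:
        p_value = float(res.f_pvalue)
    if np.isnan(p_value):
        p_value = 1.0
    r2 = 0.0 if res.centered_tss <= 0 else float(res.rsquared)
    fit = CosinorFit(
        mesor=float(mesor), amplitude=amplitude, acrophase=acro,
        p_value=p_value, r2=r2, n=len(y), significant=p_value <= alpha,
    )
    if not fit.significant:
        log.warning("cosinor fit not significant (p=%.3f > %.2f)",
                    p_value, alpha)
    return fit


def measured_phase_shift(diurnal: CosinorFit, night: CosinorFit,
                         allow_nonsignificant: bool = False) -> float:
    """Phase shift = diurnal acrophase - night acrophase, wrapped to
    (-12, 12] h; negative values are phase delays."""
    if not allow_nonsignificant and not (diurnal.significant
                                         and night.significant):
        raise ValueError("phase shift requested from non-significant "
                         "cosinor fit(s); pass allow_nonsignificant=True "
                         "to override")
    return float(wrap_phase_h(diurnal.acrophase - night.acrophase))
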