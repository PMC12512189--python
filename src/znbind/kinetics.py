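"""ThT aggregation-kinetics processing: blank correction, normalisation,
half-time (t50) extraction and the dose-response fold-change table.

t50 is defined as the time at which a normalised fluorescence trace
first reaches half of its maximum, located by linear interpolation
between the bracketing samples. This is deliberately model-free — it
matches the verbal definition of the half-time and needs no assumption
about the aggregation mechanism. A logistic fit is available as an
optional cross-check.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclasses.dataclass(frozen=True)
class ThTTrace:
    """One plate-reader well: fluorescence vs time.

    ``condition`` is the ligand:protein molar-equivalents ratio of the
    well (the shared dose axis); blank wells carry dye and ligand but no
    protein.
    """

    time: np.ndarray
    fluorescence: np.ndarray
    condition: float
    replicate: int = 1
    is_blank: bool = False

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("time and fluorescence must be equal-length 1-D")
        if t.size < 20:
            raise ValueError("need >= 20 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)


def blank_correct(traces: list[ThTTrace],
                  blanks: list[ThTTrace]) -> list[ThTTrace]:
    """Subtract the time-pointwise mean blank from each sample trace.

    Blanks are matched by condition; a condition with no blank of its
    own falls back to the plate-wide mean blank.
    """
    if not blanks:
        raise ValueError("no blank wells supplied")
    by_cond: dict = {}
    for b in blanks:
        by_cond.setdefault(b.condition, []).append(b.fluorescence)
    plate_mean = np.mean([b.fluorescence for b in blanks], axis=0)
    out = []
    for tr in traces:
        stack = by_cond.get(tr.condition)
        mean_blank = np.mean(stack, axis=0) if stack else plate_mean
        out.append(dataclasses.replace(
            tr, fluorescence=tr.fluorescence - mean_blank))
    return out


def normalize_trace(trace: ThTTrace) -> ThTTrace:
    """Divide by the trace maximum so the output peaks at 1."""
    m = trace.fluorescence.max()
    if m <= 0:
        raise ValueError("trace maximum is not positive; cannot normalise")
    return dataclasses.replace(trace, fluorescence=trace.fluorescence / m)


def extract_t50(trace: ThTTrace, smooth: bool = False) -> float:
    """First upward half-maximum crossing time, in hours.

    Expects a normalised (or at least blank-corrected) trace. With
    ``smooth`` a centred moving median of window 3 is applied before
    crossing detection; the crossing is interpolated linearly between
    the bracketing samples of the raw values used.
    """
    y = trace.fluorescence
    if smooth:
        y = np.copy(y)
        y[1:-1] = np.median(
            np.column_stack([trace.fluorescence[:-2],
                             trace.fluorescence[1:-1],
                             trace.fluorescence[2:]]), axis=1)
    diffs = np.diff(y)
    if (diffs == 0).all():
        raise ValueError("flat trace; no assembly detected")
    if (diffs <= 0).all():
        raise ValueError("trace is monotone decreasing; no assembly phase")
    half = 0.5 * y.max()
    above = y >= half
    if above[0]:
        # already at/above half-maximum from the first sample
        return float(trace.time[0])
    crossings = np.nonzero(~above[:-1] & above[1:])[0]
    if crossings.size == 0:
        raise ValueError("trace never reaches half-maximum (no assembly)")
    i = crossings[0]
    t0, t1 = trace.time[i], trace.time[i + 1]
    y0, y1 = y[i], y[i + 1]
    return float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))


def fit_logistic_t50(trace: ThTTrace) -> float:
    """Logistic-sigmoid fit alternative to the crossing estimator."""

    def logistic(t, a, t50, k):
        return a / (1.0 + np.exp(-k * (t - t50)))

    t, y = trace.time, trace.fluorescence
    p0 = [y.max(), t[np.argmin(np.abs(y - 0.5 * y.max()))],
          4.0 / max(t[-1] - t[0], 1e-9) * 10]
    popt, _ = curve_fit(logistic, t, y, p0=p0, maxfev=20000)
    return float(popt[1])


def t50_table(traces: list[ThTTrace], smooth: bool = False) -> pd.DataFrame:
    """Per-replicate t50 for every non-blank trace."""
    rows = [(tr.condition, tr.replicate, extract_t50(tr, smooth=smooth))
            for tr in traces if not tr.is_blank]
    return pd.DataFrame(rows, columns=["equivalents", "replicate", "t50_h"])


def fold_change_curve(t50s: pd.DataFrame) -> pd.DataFrame:
    """Fold reduction of t50 relative to the zero-equivalents condition.

    ``t50s`` has columns equivalents, replicate, t50_h (one row per
    replicate). Replicates are summarised as mean +/- sd per condition
    and the fold change is mean_t50(0) / mean_t50(x).
    """
    if not (t50s["equivalents"] == 0).any():
        raise ValueError("reference condition (0 equivalents) missing")
    summary = (t50s.groupby("equivalents")["t50_h"]
               .agg(mean_t50_h="mean", sd_t50_h="std", n="count")
               .reset_index().sort_values("equivalents", ignore_index=True))
    ref = summary.loc[summary["equivalents"] == 0, "mean_t50_h"].iloc[0]
    summary["fold_change"] = ref / summary["mean_t50_h"]
    return summary
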