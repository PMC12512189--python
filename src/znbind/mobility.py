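"""Traveling-wave ion-mobility calibration and compaction metrics.

T-wave arrival times have no closed-form relation to collision cross
section (CCS); the standard protocol corrects arrival times for
mass-dependent post-IM flight time, reduces literature CCS values of
denatured calibrant ions by charge and reduced mass, and fits the
power law CCS' = A * t'^B. Sample arrival times are then mapped back
through the fitted law.

The compaction statistic is model-free: the fraction of integrated
arrival-time intensity in the compact window (4.0-7.0 ms) relative to
compact + extended (up to 10 ms), for the charge state that populates
both conformational families (8+ by default).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

#: Average mass of N2 drift gas, Da.
N2_MASS = 28.006

#: Default instrument EDC (enhanced duty cycle) delay coefficient.
DEFAULT_EDC = 1.35

COMPACT_WINDOW = (4.0, 7.0)
EXTENDED_WINDOW = (7.0, 10.0)


@dataclasses.dataclass(frozen=True)
class ArrivalTimeDistribution:
    """Intensity vs arrival time for one ion population.

    ``n_bound`` may be None when all ligand-bound states of the charge
    are pooled (the default analysis pools them).
    """

    time: np.ndarray
    intensity: np.ndarray
    charge: int
    n_bound: int | None = None
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if t.shape != i.shape or t.ndim != 1:
            raise ValueError("time and intensity must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(i < 0) or not np.all(np.isfinite(i)):
            raise ValueError("intensities must be finite and >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", i)

    def requires_windows(self, lo: float = 4.0, hi: float = 10.0):
        if self.time[0] > lo or self.time[-1] < hi:
            raise ValueError(
                f"time grid [{self.time[0]}, {self.time[-1]}] ms does not "
                f"cover the analysis windows [{lo}, {hi}] ms")


@dataclasses.dataclass(frozen=True)
class CCSCalibration:
    """A fitted power-law T-wave calibration CCS' = A * t'^B."""

    calibrants: pd.DataFrame
    edc_coefficient: float
    fit_a: float
    fit_b: float
    r_squared: float


def corrected_drift_time(arrival_ms: float, mz: float,
                         edc_coefficient: float = DEFAULT_EDC) -> float:
    """Arrival time corrected for mass-dependent post-mobility flight.

    t' = t - EDC * sqrt(m/z) / 1000 (ms).
    """
    if np.any(np.asarray(arrival_ms) <= 0):
        raise ValueError("arrival time must be positive")
    t = np.asarray(arrival_ms, dtype=float) - \
        edc_coefficient * np.sqrt(mz) / 1000.0
    if np.any(t <= 0):
        raise ValueError(
            "corrected drift time <= 0; calibrant inconsistent with the "
            "EDC coefficient")
    return t if np.ndim(arrival_ms) else float(t)


def reduced_ccs(ccs: float, charge: int, ion_mass: float,
                gas_mass: float = N2_MASS) -> float:
    """CCS' = CCS * sqrt(mu) / z with reduced mass mu of ion and gas."""
    for name, val in (("ccs", ccs), ("charge", charge),
                      ("ion_mass", ion_mass), ("gas_mass", gas_mass)):
        if np.any(np.asarray(val) <= 0):
            raise ValueError(f"{name} must be positive")
    mu = ion_mass * gas_mass / (ion_mass + gas_mass)
    return ccs * np.sqrt(mu) / charge


def fit_powerlaw_calibration(calibrants: pd.DataFrame,
                             edc_coefficient: float = DEFAULT_EDC,
                             gas_mass: float = N2_MASS) -> CCSCalibration:
    """OLS fit of ln(CCS') on ln(t') over a calibrant table.

    ``calibrants`` needs columns species, mass_da, charge, ccs_a2,
    arrival_ms (the literature-CCS row format of the Bush-style
    calibrant databases). Warns if r^2 < 0.98.
    """
    if len(calibrants) < 3:
        raise ValueError("need >= 3 calibrant rows")
    mz = (calibrants["mass_da"] + calibrants["charge"] * 1.00728) \
        / calibrants["charge"]
    tprime = corrected_drift_time(calibrants["arrival_ms"].to_numpy(),
                                  mz.to_numpy(), edc_coefficient)
    if np.unique(np.round(tprime, 12)).size < 2:
        raise ValueError("degenerate calibrants: identical drift times")
    ccs_red = reduced_ccs(calibrants["ccs_a2"].to_numpy(),
                          calibrants["charge"].to_numpy(),
                          calibrants["mass_da"].to_numpy(), gas_mass)
    res = stats.linregress(np.log(tprime), np.log(ccs_red))
    r2 = res.rvalue ** 2
    if r2 < 0.98:
        warnings.warn(f"calibration r^2 = {r2:.4f} < 0.98; check calibrants")
    return CCSCalibration(calibrants=calibrants.copy(),
                          edc_coefficient=edc_coefficient,
                          fit_a=float(np.exp(res.intercept)),
                          fit_b=float(res.slope), r_squared=float(r2))


def drift_to_ccs(arrival_ms: float, mz: float, charge: int, ion_mass: float,
                 cal: CCSCalibration, gas_mass: float = N2_MASS) -> float:
    """Map an arrival time to CCS (A^2) through a fitted calibration."""
    tprime = corrected_drift_time(arrival_ms, mz, cal.edc_coefficient)
    mu = ion_mass * gas_mass / (ion_mass + gas_mass)
    return cal.fit_a * tprime ** cal.fit_b * charge / np.sqrt(mu)


def _window_integral(atd: ArrivalTimeDistribution, lo: float,
                     hi: float) -> float:
    # interpolate the exact window edges so the integral is insensitive
    # to where grid samples fall relative to the boundaries
    t, i = atd.time, atd.intensity
    inner = (t > lo) & (t < hi)
    x = np.concatenate([[lo], t[inner], [hi]])
    y = np.concatenate([[np.interp(lo, t, i)], i[inner],
                        [np.interp(hi, t, i)]])
    return float(np.trapezoid(y, x))


def compaction_fraction(atd: ArrivalTimeDistribution,
                        compact_window: tuple = COMPACT_WINDOW,
                        extended_window: tuple = EXTENDED_WINDOW) -> float:
    """Percent of (compact + extended) ATD area in the compact window.

    Windows partition [4.0, 10.0] ms at 7.0 ms; intensity outside both
    windows is ignored.
    """
    atd.requires_windows(compact_window[0], extended_window[1])
    a_c = _window_integral(atd, *compact_window)
    a_e = _window_integral(atd, *extended_window)
    if a_c + a_e <= 0:
        raise ValueError("no intensity inside the analysis windows")
    return 100.0 * a_c / (a_c + a_e)


def compaction_curve(atds: list[ArrivalTimeDistribution],
                     equivalents: np.ndarray,
                     charge: int = 8) -> pd.DataFrame:
    """Percent-compact vs molar equivalents for one charge state."""
    sel = [a for a in atds if a.charge == charge]
    if len(sel) != len(equivalents):
        raise ValueError(
            f"{len(sel)} ATDs at charge {charge} vs "
            f"{len(equivalents)} titration points")
    return pd.DataFrame({
        "equivalents": np.asarray(equivalents, dtype=float),
        "percent_compact": [compaction_fraction(a) for a in sel],
    })


def ensemble_average_ccs(atds: list[ArrivalTimeDistribution],
                         cal: CCSCalibration, mz_by_charge: dict,
                         ion_mass: float,
                         gas_mass: float = N2_MASS) -> float:
    """Intensity-weighted mean CCS pooled over charge states.

    Each ATD grid point is transformed through the calibration at its
    charge's m/z; the mean is weighted by intensity across all ATDs.
    """
    if not atds:
        raise ValueError("no arrival-time distributions supplied")
    num = 0.0
    den = 0.0
    for atd in atds:
        ccs = drift_to_ccs(atd.time, mz_by_charge[atd.charge], atd.charge,
                           ion_mass, cal, gas_mass)
        num += float(np.sum(ccs * atd.intensity))
        den += float(np.sum(atd.intensity))
    if den <= 0:
        raise ValueError("all intensities are zero")
    return num / den
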