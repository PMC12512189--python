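"""Cross-technique synthesis: align dose-response channels, find the
saturation dose, and quantify concordance.

Binding occupancy (native MS), compaction (ion mobility) and the
aggregation half-time (ThT) are measured on different titration grids
but share the molar-equivalents dose axis. Aligned and normalised so
every channel increases with dose (the t50 channel enters as its fold
reduction), the three responses can be compared directly: their
saturation doses and rank correlations quantify how tightly binding,
monomer compaction and accelerated assembly track one another.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr, spearmanr

CHANNELS = ("occupancy_pct", "compaction_pct", "t50_drop")


@dataclasses.dataclass
class DoseResponseSet:
    """Aligned raw and normalised channels on a shared equivalents grid.

    ``data`` columns: equivalents, occupancy_pct, compaction_pct, t50_h,
    t50_drop (the reduction t50(0) - t50(x), hours), t50_fold
    (t50(0)/t50(x)), plus ``<channel>_norm`` in [0, 1] for each entry
    of :data:`CHANNELS` (NA outside a channel's measured range).
    """

    data: pd.DataFrame

    @property
    def equivalents(self) -> np.ndarray:
        return self.data["equivalents"].to_numpy()

    def normalized(self, channel: str) -> np.ndarray:
        return self.data[f"{channel}_norm"].to_numpy()


def _interp_channel(grid, x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    out = np.interp(grid, x, y)
    out[(grid < x.min()) | (grid > x.max())] = np.nan  # no extrapolation
    return out


def _normalize(vals: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(vals)
    lo, hi = vals[ok].min(), vals[ok].max()
    if hi <= lo:
        return np.where(ok, 0.0, np.nan)
    return (vals - lo) / (hi - lo)


def align_responses(occupancy: pd.DataFrame, compaction: pd.DataFrame,
                    t50s: pd.DataFrame) -> DoseResponseSet:
    """Join the three stage outputs on a shared equivalents grid.

    Inputs are the stage tables: occupancy (equivalents, percent_bound),
    compaction (equivalents, percent_compact) and the t50 summary
    (equivalents, mean_t50_h). The union of the dose grids restricted
    to the overlapping range is used; channels are linearly interpolated
    onto it and never extrapolated. Normalised channels are rescaled to
    [0, 1] over their observed range; the t50 channel is inverted to
    the half-time reduction t50(0) - t50(x) so all channels increase
    with dose (an affine inversion that preserves the dose-response
    shape, unlike the fold ratio, which is also tabulated).
    """
    chans = {
        "occupancy_pct": (occupancy["equivalents"], occupancy["percent_bound"]),
        "compaction_pct": (compaction["equivalents"],
                           compaction["percent_compact"]),
        "t50_h": (t50s["equivalents"], t50s["mean_t50_h"]),
    }
    for name, (x, _) in chans.items():
        if len(x) < 4:
            raise ValueError(f"channel {name} has fewer than 4 points")
    lo = max(float(np.min(x)) for x, _ in chans.values())
    hi = min(float(np.max(x)) for x, _ in chans.values())
    if hi <= lo:
        raise ValueError("dose ranges of the channels do not overlap")
    grid = np.unique(np.concatenate(
        [np.asarray(x, dtype=float) for x, _ in chans.values()]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    data = pd.DataFrame({"equivalents": grid})
    for name, (x, y) in chans.items():
        data[name] = _interp_channel(grid, x, y)
    if not (t50s["equivalents"] == 0).any():
        raise ValueError("t50 channel is missing the zero-dose reference")
    ref_t50 = float(
        t50s.loc[t50s["equivalents"] == 0, "mean_t50_h"].iloc[0])
    data["t50_drop"] = ref_t50 - data["t50_h"]
    data["t50_fold"] = ref_t50 / data["t50_h"]
    for name in CHANNELS:
        data[f"{name}_norm"] = _normalize(data[name].to_numpy())
    return DoseResponseSet(data=data)


def saturation_point(equivalents, response, plateau_fraction: float = 0.95,
                     hill_bounds: tuple = (0.3, 4.0)) -> float:
    """Dose at which a saturating channel reaches a fraction of plateau.

    Fits R(x) = Rmax * x^h / (K^h + x^h) by least squares (h bounded;
    on a truly hyperbolic channel the fit returns h = 1 and the result
    reduces to K * pf/(1-pf)) and returns

        x* = K * (pf / (1 - pf))^(1/h).

    The exponent accommodates dose-response channels steeper than a
    rectangular hyperbola, e.g. multi-site occupancy under ligand
    depletion. The channel's minimum is subtracted before fitting, so a
    channel with a nonzero zero-dose baseline is measured as response
    above baseline (and the result is shift-invariant).
    """
    x = np.asarray(equivalents, dtype=float)
    y = np.asarray(response, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValueError("need >= 5 points for a saturation fit")
    if not (0 < plateau_fraction < 1):
        raise ValueError("plateau_fraction must be in (0, 1)")
    span = y.max() - y.min()
    if span <= 0:
        raise ValueError("flat channel; saturation undefined")
    # monotone within tolerance (10% of span) on the dose-sorted series
    order = np.argsort(x)
    if np.any(np.diff(y[order]) < -0.10 * span):
        raise ValueError("channel is not monotone; saturation fit refused")
    y = y - y.min()  # response above the zero-dose baseline

    def hill(xx, rmax, k, h):
        return rmax * xx ** h / (k ** h + xx ** h)

    xpos = x[x > 0]
    k0 = float(np.median(xpos)) if xpos.size else 1.0
    try:
        popt, _ = curve_fit(
            hill, x, y, p0=[y.max(), k0, 1.0],
            bounds=([0, 1e-9, hill_bounds[0]],
                    [np.inf, np.inf, hill_bounds[1]]),
            maxfev=20000)
    except RuntimeError as err:
        raise ValueError(f"saturation fit did not converge: {err}") from err
    _, k, h = popt
    return float(k * (plateau_fraction / (1 - plateau_fraction)) ** (1 / h))


def concordance(drset: DoseResponseSet, min_points: int = 4) -> pd.DataFrame:
    """Pairwise Pearson and Spearman correlation of normalised channels."""
    rows = []
    for a, b in itertools.combinations(CHANNELS, 2):
        va = drset.normalized(a)
        vb = drset.normalized(b)
        ok = ~(np.isnan(va) | np.isnan(vb))
        n = int(ok.sum())
        if n < min_points:
            raise ValueError(
                f"channels {a}/{b} share only {n} points (< {min_points})")
        rows.append((a, b, float(pearsonr(va[ok], vb[ok])[0]),
                     float(spearmanr(va[ok], vb[ok])[0]), n))
    return pd.DataFrame(
        rows, columns=["channel_a", "channel_b", "pearson", "spearman", "n"])
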