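"""Stepwise macroscopic ligand-binding model and Kd estimation.

The model describes sequential, noncooperative binding of a metal ion M
to a protein P through ``n`` macroscopic steps

    P·M_{i-1} + M  <=>  P·M_i ,   Kd_i = [P·M_{i-1}][M] / [P·M_i],

so the equilibrium fraction of the i-ligand species at free-metal
concentration L is

    f_i  ∝  Π_{j<=i} (L / Kd_j),        f_0 ∝ 1,   Σ f_i = 1.

Each Kd is a free parameter ("all Kds free"); macroscopic stepwise
constants are the most that stoichiometry-resolved native-MS peak
intensities can identify — microscopic site constants are not
distinguishable from these data.

Fitting follows the statsmodels convention: build a
:class:`StepwiseKdModel` from a peak-area table and a titration design,
call :meth:`~StepwiseKdModel.fit`, and read estimates, standard errors
and diagnostics off the returned :class:`StepwiseKdResults`.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares


@dataclasses.dataclass(frozen=True)
class TitrationDesign:
    """A ligand titration at fixed protein concentration.

    Parameters
    ----------
    protein_conc : float
        Total protein concentration, M.
    ligand_concs : tuple of float
        Total ligand concentrations, M; strictly increasing, starting at 0.
    n_replicates : int
        Replicates per titration point.
    """

    protein_conc: float
    ligand_concs: tuple
    n_replicates: int = 1

    def __post_init__(self):
        lc = tuple(float(x) for x in self.ligand_concs)
        object.__setattr__(self, "ligand_concs", lc)
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be positive")
        if len(lc) < 2 or lc[0] != 0.0:
            raise ValueError("ligand_concs must start at 0 and have >= 2 points")
        if any(b <= a for a, b in zip(lc, lc[1:])):
            raise ValueError("ligand_concs must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def equivalents(self) -> np.ndarray:
        """Ligand:protein molar ratio at each titration point."""
        return np.asarray(self.ligand_concs) / self.protein_conc

    @property
    def n_points(self) -> int:
        return len(self.ligand_concs)


@dataclasses.dataclass(frozen=True)
class StepwiseBindingModel:
    """Sequential binding model with one macroscopic Kd per step."""

    kds: tuple

    def __post_init__(self):
        kds = tuple(float(k) for k in self.kds)
        object.__setattr__(self, "kds", kds)
        if len(kds) == 0:
            raise ValueError("at least one Kd is required")
        if not all(np.isfinite(k) and k > 0 for k in kds):
            raise ValueError("all Kds must be positive and finite")

    @property
    def n_sites(self) -> int:
        return len(self.kds)


def stepwise_species_fractions(model: StepwiseBindingModel,
                               free_ligand: float) -> np.ndarray:
    """Equilibrium fractions f_0..f_n at a given free-ligand concentration.

    f_i ∝ Π_{j<=i} (L/Kd_j), normalised to sum to 1. Evaluated in log
    space so very large L/Kd ratios cannot overflow.
    """
    if free_ligand < 0:
        raise ValueError("free_ligand must be >= 0")
    if free_ligand == 0.0:
        out = np.zeros(model.n_sites + 1)
        out[0] = 1.0
        return out
    log_terms = np.concatenate(
        [[0.0], np.cumsum(np.log(free_ligand) - np.log(model.kds))])
    log_terms -= log_terms.max()
    terms = np.exp(log_terms)
    return terms / terms.sum()


def mean_occupancy(model: StepwiseBindingModel, free_ligand: float) -> float:
    """Average number of ligands bound per protein at free concentration L."""
    f = stepwise_species_fractions(model, free_ligand)
    return float(np.arange(f.size) @ f)


def solve_free_ligand(total_ligand: float, total_protein: float,
                      model: StepwiseBindingModel) -> float:
    """Free-ligand concentration satisfying the mass balance.

    Solves L + P_tot * <n>(L) = L_tot for L on [0, L_tot]. Bound ligand
    P_tot*<n>(L) is non-decreasing in L, so the residual is strictly
    increasing and the bracketed root is unique; Brent's method is used
    for guaranteed convergence.
    """
    if total_ligand < 0 or total_protein < 0:
        raise ValueError("totals must be >= 0")
    if total_ligand == 0.0:
        return 0.0
    if total_protein == 0.0:
        return float(total_ligand)

    def residual(L):
        return L + total_protein * mean_occupancy(model, L) - total_ligand

    if residual(total_ligand) <= 0:  # only if binding is numerically nil
        return float(total_ligand)
    return float(brentq(residual, 0.0, total_ligand,
                        xtol=1e-30, rtol=1e-14, maxiter=200))


def predict_bound_fractions(design: TitrationDesign,
                            model: StepwiseBindingModel) -> np.ndarray:
    """Species-fraction matrix, one row per titration point.

    Row t holds f_0..f_n at the free-ligand concentration solved from
    the mass balance for titration point t; rows sum to 1.
    """
    out = np.empty((design.n_points, model.n_sites + 1))
    for t, l_tot in enumerate(design.ligand_concs):
        free = solve_free_ligand(l_tot, design.protein_conc, model)
        out[t] = stepwise_species_fractions(model, free)
    return out


def percent_occupancy(areas: pd.DataFrame, titration_point=None) -> float:
    """Percent of protein signal carrying at least one ligand.

    100 * Σ_{n>=1} area_n / Σ_{n>=0} area_n over the rows of a
    peak-area table (columns ``n_bound`` and ``area``) for a single
    charge state and titration point.

    Parameters
    ----------
    areas : pandas.DataFrame
        Peak-area rows; if ``titration_point`` is given the table is
        filtered on its ``titration_point`` column first.
    """
    t = areas
    if titration_point is not None:
        t = t[t["titration_point"] == titration_point]
    if (t["n_bound"] == 0).sum() == 0:
        raise ValueError("no apo (n_bound=0) row present")
    total = t["area"].sum()
    if total <= 0:
        raise ValueError("all peak areas are zero; occupancy undefined")
    bound = t.loc[t["n_bound"] >= 1, "area"].sum()
    return float(100.0 * bound / total)


def occupancy_curve(areas: pd.DataFrame, design: TitrationDesign,
                    charge=None) -> pd.DataFrame:
    """Percent occupancy vs molar equivalents for one charge state.

    Replicates are averaged after computing occupancy per replicate.
    Returns a DataFrame with columns ``equivalents`` and ``percent_bound``.
    """
    t = areas
    if charge is not None:
        t = t[t["charge"] == charge]
    if t.empty:
        raise ValueError("no rows for requested charge")
    rows = []
    eqs = design.equivalents
    for i, point in enumerate(sorted(t["titration_point"].unique())):
        sub = t[t["titration_point"] == point]
        vals = [percent_occupancy(g) for _, g in sub.groupby("replicate")]
        rows.append((eqs[i], float(np.mean(vals))))
    return pd.DataFrame(rows, columns=["equivalents", "percent_bound"])


def _normalised_fraction_matrix(areas: pd.DataFrame,
                                design: TitrationDesign,
                                n_sites: int) -> np.ndarray:
    """Observed per-point fractional areas (points x n_sites+1)."""
    points = sorted(areas["titration_point"].unique())
    if len(points) != design.n_points:
        raise ValueError(
            f"area table has {len(points)} titration points, design has "
            f"{design.n_points}")
    obs = np.zeros((len(points), n_sites + 1))
    for i, point in enumerate(points):
        sub = areas[areas["titration_point"] == point]
        grouped = sub.groupby("n_bound")["area"].mean()
        for n, a in grouped.items():
            if n <= n_sites:
                obs[i, int(n)] = a
        row_sum = obs[i].sum()
        if row_sum <= 0:
            raise ValueError(f"titration point {point!r} has zero total area")
        obs[i] /= row_sum
    return obs


class StepwiseKdModel:
    """Multistate all-Kds-free titration model for one charge state.

    Observed data are row-normalised fractional peak areas per titration
    point; the loss is the sum of squared differences between observed
    and model species fractions, which removes per-point total-intensity
    nuisance (equal ionisation efficiency across bound states is
    assumed). Kds are parameterised on the log scale.

    Parameters
    ----------
    areas : pandas.DataFrame
        Peak-area table (columns titration_point, charge, n_bound,
        replicate, area) restricted to, or filterable to, one charge.
    design : TitrationDesign
    n_sites : int
        Number of sequential binding steps (default 5).
    charge : int, optional
        Filter ``areas`` to this charge state.
    """

    def __init__(self, areas: pd.DataFrame, design: TitrationDesign,
                 n_sites: int = 5, charge=None):
        if charge is not None:
            areas = areas[areas["charge"] == charge]
        if areas.empty:
            raise ValueError("empty peak-area table")
        n_states = areas["n_bound"].nunique()
        if n_states < n_sites + 1:
            raise ValueError(
                f"need >= {n_sites + 1} bound states, table has {n_states}")
        if design.n_points < n_sites + 2:
            raise ValueError(
                f"need >= {n_sites + 2} titration points, design has "
                f"{design.n_points}")
        self.design = design
        self.n_sites = n_sites
        self.charge = charge
        self.endog = _normalised_fraction_matrix(areas, design, n_sites)

    def _residuals(self, log_kds: np.ndarray) -> np.ndarray:
        model = StepwiseBindingModel(tuple(np.exp(log_kds)))
        return (predict_bound_fractions(self.design, model)
                - self.endog).ravel()

    def fit(self, n_starts: int = 8,
            start_range: tuple = (1e-6, 1e-3)) -> "StepwiseKdResults":
        """Multistart nonlinear least squares over log-Kds.

        ``n_starts`` uniform-in-log starting points spanning
        ``start_range`` (default 1-1000 uM); the best local optimum is
        returned. Standard errors come from the local quadratic
        approximation at the optimum (Gauss-Newton covariance).
        """
        best = None
        for start in np.geomspace(*start_range, n_starts):
            x0 = np.full(self.n_sites, np.log(start))
            try:
                res = least_squares(self._residuals, x0, method="lm",
                                    xtol=1e-14, ftol=1e-14, max_nfev=4000)
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise RuntimeError(
                "Kd fit failed to converge from any start; check that the "
                "area table covers the titration and bound states")

        dof = max(best.fun.size - self.n_sites, 1)
        s2 = 2.0 * best.cost / dof
        jtj = best.jac.T @ best.jac
        try:
            cov_log = s2 * np.linalg.inv(jtj)
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        except np.linalg.LinAlgError:
            se_log = np.full(self.n_sites, np.nan)
        kds = np.exp(best.x)
        return StepwiseKdResults(
            model=self,
            binding_model=StepwiseBindingModel(tuple(kds)),
            kds_stderr=kds * se_log,  # delta method from log scale
            residual_norm=float(np.sqrt(2.0 * best.cost)),
            n_obs=int(best.fun.size),
        )


@dataclasses.dataclass
class StepwiseKdResults:
    """Fitted stepwise-Kd estimates with uncertainties and diagnostics."""

    model: StepwiseKdModel
    binding_model: StepwiseBindingModel
    kds_stderr: np.ndarray
    residual_norm: float
    n_obs: int

    @property
    def kds(self) -> np.ndarray:
        return np.asarray(self.binding_model.kds)

    @property
    def kds_um(self) -> np.ndarray:
        return self.kds * 1e6

    def fitted_fractions(self) -> np.ndarray:
        return predict_bound_fractions(self.model.design, self.binding_model)

    def summary(self) -> pd.DataFrame:
        """Per-site table of Kd estimates (uM) and standard errors."""
        return pd.DataFrame({
            "site": np.arange(1, self.kds.size + 1),
            "kd_um": self.kds_um,
            "stderr_um": self.kds_stderr * 1e6,
            "n_points": self.model.design.n_points,
        })

    def __str__(self):
        lines = ["Stepwise Kd fit (all Kds free)",
                 f"  charge: {self.model.charge}",
                 f"  n_obs: {self.n_obs}  residual norm: "
                 f"{self.residual_norm:.3e}"]
        for _, row in self.summary().iterrows():
            lines.append(f"  Kd{int(row['site'])} = {row['kd_um']:8.2f} uM"
                         f"  (+/- {row['stderr_um']:.2f})")
        return "\n".join(lines)


def fit_kds(areas: pd.DataFrame, design: TitrationDesign,
            n_sites: int = 5, charge=None, **fit_kwargs) -> StepwiseKdResults:
    """Convenience wrapper: build a :class:`StepwiseKdModel` and fit it."""
    return StepwiseKdModel(areas, design, n_sites=n_sites,
                           charge=charge).fit(**fit_kwargs)


def select_n_sites(areas: pd.DataFrame, design: TitrationDesign,
                   candidates: Sequence[int] = (1, 2, 3, 4, 5),
                   charge=None) -> pd.DataFrame:
    """AIC comparison across site counts (off the default path).

    Gaussian AIC on the fraction residuals: n*log(RSS/n) + 2k.
    """
    rows = []
    for n in candidates:
        try:
            res = fit_kds(areas, design, n_sites=n, charge=charge)
        except (ValueError, RuntimeError):
            continue
        rss = res.residual_norm ** 2
        aic = res.n_obs * np.log(max(rss, 1e-300) / res.n_obs) + 2 * n
        rows.append((n, rss, aic))
    return pd.DataFrame(rows, columns=["n_sites", "rss", "aic"])
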