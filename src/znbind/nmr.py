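"""Chemical-shift perturbation (CSP) analysis of HSQC titrations.

CSP combines the amide proton and nitrogen shift changes of a residue
into a single distance in ppm,

    CSP = sqrt((d_dH)^2 + w_N * (d_dN)^2),

with the nitrogen weight w_N = 0.14 compensating the larger 15N shift
dispersion. Peaks are matched across titration points by residue
assignment, and residues whose CSP exceeds a threshold (the mean CSP
over all residues by default) are called significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_NITROGEN_WEIGHT = 0.14

#: Required columns of a residue shift table (one row per assigned peak).
SHIFT_COLUMNS = ["residue_index", "residue_label", "delta_h_ppm",
                 "delta_n_ppm", "titration_point"]


def csp(delta_h: float, delta_n: float,
        nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT) -> float:
    """Combined 1H/15N chemical-shift perturbation in ppm."""
    dh = np.asarray(delta_h, dtype=float)
    dn = np.asarray(delta_n, dtype=float)
    if not (np.all(np.isfinite(dh)) and np.all(np.isfinite(dn))):
        raise ValueError("shift differences must be finite")
    out = np.sqrt(dh ** 2 + nitrogen_weight * dn ** 2)
    return out if out.ndim else float(out)


def _validate_table(table: pd.DataFrame, name: str):
    missing = [c for c in ("residue_index", "delta_h_ppm", "delta_n_ppm")
               if c not in table.columns]
    if missing:
        raise ValueError(f"{name} table missing columns {missing}")
    if table["residue_index"].duplicated().any():
        raise ValueError(f"{name} table has duplicate residue indices")


def csp_table(reference: pd.DataFrame, titrated: pd.DataFrame,
              nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT
              ) -> pd.DataFrame:
    """Per-residue CSP between a reference and a titrated peak list.

    Residues present in only one of the two tables are reported with
    CSP = NA (an unassigned or exchange-broadened peak is missing
    information, not a zero perturbation). Returns columns
    residue_index, residue_label, csp_ppm.
    """
    _validate_table(reference, "reference")
    _validate_table(titrated, "titrated")
    merged = reference.merge(
        titrated, on="residue_index", how="outer",
        suffixes=("_ref", "_tit"), sort=True)
    if merged[["delta_h_ppm_ref", "delta_h_ppm_tit"]].notna().all(axis=1).sum() == 0:
        raise ValueError("reference and titrated tables share no residues")
    both = merged["delta_h_ppm_ref"].notna() & merged["delta_h_ppm_tit"].notna()
    vals = np.full(len(merged), np.nan)
    vals[both.to_numpy()] = csp(
        (merged.loc[both, "delta_h_ppm_tit"]
         - merged.loc[both, "delta_h_ppm_ref"]).to_numpy(),
        (merged.loc[both, "delta_n_ppm_tit"]
         - merged.loc[both, "delta_n_ppm_ref"]).to_numpy(),
        nitrogen_weight)
    label_col = None
    for cand in ("residue_label_ref", "residue_label_tit", "residue_label"):
        if cand in merged.columns:
            label_col = merged[cand]
            if cand == "residue_label_ref":
                label_col = label_col.fillna(merged.get("residue_label_tit"))
            break
    return pd.DataFrame({
        "residue_index": merged["residue_index"].astype(int),
        "residue_label": label_col if label_col is not None else "",
        "csp_ppm": vals,
    })


def significance_threshold(profile: pd.DataFrame,
                           method: str = "mean") -> float:
    """CSP significance cut-off over a per-residue CSP profile.

    ``mean`` (default) is the arithmetic mean of all non-NA CSPs — the
    conventional dashed line of CSP bar plots; ``mean_plus_sd`` adds one
    standard deviation for a stricter call.
    """
    vals = profile["csp_ppm"].dropna()
    if len(vals) < 2:
        raise ValueError("need >= 2 residues with CSP values")
    if method == "mean":
        return float(vals.mean())
    if method == "mean_plus_sd":
        return float(vals.mean() + vals.std(ddof=1))
    raise ValueError(f"unknown method {method!r}")


def significant_residues(profile: pd.DataFrame,
                         method: str = "mean") -> tuple[float, list[int]]:
    """Threshold and the residues strictly above it."""
    thr = significance_threshold(profile, method)
    sig = profile.loc[profile["csp_ppm"] > thr, "residue_index"]
    return thr, sorted(int(r) for r in sig)


def titration_trajectory(tables: dict, residue: int,
                         nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
                         noise_tol: float = 0.0) -> pd.DataFrame:
    """CSP of one residue across titration points, ordered by dose.

    ``tables`` maps molar equivalents to a residue shift table; the
    lowest dose is taken as the reference. The returned frame carries a
    ``monotone`` attribute in ``.attrs``: True when the series is
    non-decreasing within ``noise_tol`` ppm, the signature of
    fast-exchange binding.
    """
    eqs = sorted(tables)
    if len(eqs) < 3:
        raise ValueError("need the residue in >= 3 titration points")
    ref = tables[eqs[0]]
    rows = []
    for eq in eqs:
        tab = tables[eq]
        hit = tab[tab["residue_index"] == residue]
        if hit.empty:
            raise ValueError(f"residue {residue} absent at {eq} equivalents")
        ref_hit = ref[ref["residue_index"] == residue]
        if ref_hit.empty:
            raise ValueError(f"residue {residue} absent in reference table")
        val = csp(float(hit["delta_h_ppm"].iloc[0])
                  - float(ref_hit["delta_h_ppm"].iloc[0]),
                  float(hit["delta_n_ppm"].iloc[0])
                  - float(ref_hit["delta_n_ppm"].iloc[0]),
                  nitrogen_weight)
        rows.append((eq, val))
    out = pd.DataFrame(rows, columns=["equivalents", "csp_ppm"])
    diffs = np.diff(out["csp_ppm"].to_numpy())
    out.attrs["monotone"] = bool(np.all(diffs >= -noise_tol))
    return out
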