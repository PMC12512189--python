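# znbind

Quantitative analysis of metal-ion binding to an intrinsically
disordered protein and its consequences for monomer compaction and
amyloid-formation kinetics — built around the Zn²⁺ / α-synuclein
system, driven end-to-end by a synthetic titration generator so every
stage has a known-answer test without instrument data.

## Who this is for

Native mass spectrometrists and amyloid biophysicists who titrate a
ligand (here zinc acetate, 0–800 μM) against a protein (here 20 μM
N-acetylated α-synuclein, 140 residues, ~14.5 kDa) and want to link,
on one molar-equivalents dose axis:

- **binding occupancy** from native-MS adduct peak areas,
- **stepwise apparent K_d values** from a multistate titration fit,
- **conformational compaction** from traveling-wave ion-mobility
  arrival-time distributions (and calibrated CCS),
- **aggregation kinetics** (ThT half-times, t₅₀),
- **residue-level binding sites** from HSQC chemical-shift
  perturbations.

## The models

**Stepwise binding.** Sequential macroscopic equilibria
P·M_{i−1} + M ⇌ P·M_i with dissociation constants K_{d,i}, all free
("all K_d's free"). At free-metal concentration L the species
fractions are f_i ∝ Π_{j≤i} (L / K_{d,j}), Σf_i = 1, and L is obtained
from the mass balance L + P_tot·⟨n⟩(L) = L_tot by bracketed root
finding. `StepwiseKdModel.fit()` estimates log-K_d by multistart
nonlinear least squares on row-normalised peak-area fractions and
returns a `StepwiseKdResults` with estimates, standard errors and a
`summary()` table.

**Occupancy and compaction.** Percent occupancy is
100·Σ_{n≥1} A_n / Σ_{n≥0} A_n over the adduct series of one charge
state. Percent compaction is the integrated arrival-time intensity in
the compact window (4.0–7.0 ms) over compact + extended (up to 10 ms)
for the conformationally mixed 8⁺ charge state. T-wave CCS calibration
uses the standard corrected-drift-time power law ln CCS′ = ln A +
B·ln t′.

**Kinetics and NMR.** t₅₀ is the first half-maximum crossing of a
blank-corrected, max-normalised ThT trace. CSP = √(Δδ_H² + 0.14·Δδ_N²)
per residue, with the mean CSP over all residues as the significance
line.

**Synthesis.** The three dose–response channels are aligned on the
shared equivalents grid, each channel's saturation dose is the point
where a fitted Hill-type saturation curve reaches 95% of its plateau,
and pairwise Pearson/Spearman coefficients quantify concordance.

## Worked example

Simulate the default 13-point titration (0–800 μM Zn²⁺ vs 20 μM
protein), extract the 8⁺ adduct peak areas, and fit five stepwise
K_d values:

```python
import pandas as pd
from znbind import (scenario_paper_mimic, simulate_titration_spectra,
                    assign_adduct_series, extract_peak_areas, fit_kds)

truth = scenario_paper_mimic()
specs = simulate_titration_spectra(truth, charges=[8])
assignments = assign_adduct_series(truth.protein_avg_mass, 8, 5,
                                   truth.adduct_mass_shift)
areas = pd.concat([extract_peak_areas(s, assignments) for s in specs],
                  ignore_index=True)
print(fit_kds(areas, truth.design, n_sites=5, charge=8))
```

```
Stepwise Kd fit (all Kds free)
  charge: 8
  n_obs: 78  residual norm: 1.029e-02
  Kd1 =    53.74 uM  (+/- 0.17)
  Kd2 =    62.45 uM  (+/- 0.34)
  Kd3 =    48.34 uM  (+/- 0.30)
  Kd4 =    67.59 uM  (+/- 0.32)
  Kd5 =    59.81 uM  (+/- 0.15)
```

The generating first-site K_d of the 8⁺ charge state is 54 μM; with 1%
peak-amplitude noise the fit recovers it to 53.7 ± 0.2 μM, and the
similar values of sites 1–5 are the signature of stepwise,
noncooperative binding.

The full pipeline (all four modalities, alignment, saturation,
concordance) runs from the command line:

```bash
znbind run --seed 20 --out runs/demo
```

which reports, among other things, five fitted K_d values per analysed
charge state, a t₅₀ fold change of ≈5 at 15 molar equivalents, and
saturation of the occupancy, compaction and t₅₀ channels at ≈15, ≈15
and ≈14 equivalents respectively (`runs/demo/summary.json`).

## Layout

```
src/znbind/
  scenario.py   ground-truth scenarios + four modality simulators
  spectra.py    adduct-series assignment, peak-area extraction
  binding.py    stepwise model, free-ligand solver, StepwiseKdModel/Results
  mobility.py   CCS calibration, compaction statistic
  kinetics.py   ThT blank correction, normalisation, t50, fold change
  nmr.py        CSP metric, significance threshold, trajectories
  correlate.py  channel alignment, saturation dose, concordance
  io.py         CSV schemas, mzML MS1 reader, pipeline config
  pipeline.py   end-to-end runner
  cli.py        `znbind` subcommands
```

See `docs/methods.md` for the modelling assumptions, parameter
defaults and known limitations.
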