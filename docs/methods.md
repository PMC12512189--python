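# Methods

This note documents the models implemented in `znbind`, the defaults
and units of the parameters that matter, what the synthetic generator
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Stepwise macroscopic binding model

Binding of a divalent metal M to a protein P is described by `n`
sequential macroscopic steps

    P·M_{i-1} + M  ⇌  P·M_i,     K_{d,i} = [P·M_{i-1}][M] / [P·M_i],

so at free-metal concentration L the fraction of the i-bound species
is f_i ∝ Π_{j≤i}(L/K_{d,j}) with Σ f_i = 1. Macroscopic stepwise
constants — not microscopic site constants — are used deliberately:
stoichiometry-resolved native-MS intensities determine only how much
protein carries 0, 1, …, n ligands, and microscopic constants are not
identifiable from that information. Five sites are fitted by default,
matching the number of resolved adduct peaks above a reasonable
signal-to-noise threshold for this system; an AIC-based comparison
across site counts is available (`select_n_sites`) but off by default.

The free-ligand concentration at each titration point solves the mass
balance L + P_tot·⟨n⟩(L) = L_tot. Bound ligand is non-decreasing in L,
so the residual is strictly increasing and the root on [0, L_tot] is
unique; it is found by Brent's method with relative tolerance 1e-14
(conservation holds to better than 1e-9 relative in tests). Species
fractions are evaluated in log space so saturating ratios cannot
overflow.

### Kd fitting

The fit minimises the sum of squared differences between model species
fractions and observed row-normalised fractional peak areas. Fitting
fractions rather than raw areas removes the per-point total-intensity
nuisance (spray variability); the flip side is the assumption that all
bound states ionise with equal efficiency, which the pipeline records
as an explicit flag in its summary output. K_d values are
parameterised on the log scale (they are positive and span decades),
optimised by Levenberg–Marquardt from 8 starting points log-spaced
over 1–1000 μM, and the best local optimum is kept. Standard errors
come from the Gauss–Newton covariance at the optimum, delta-transformed
back from log scale. Preconditions: at least n+1 resolved bound states
and n+2 titration points.

On the default 13-point design (0–800 μM ligand, 20 μM protein) with
1% multiplicative peak noise, the first-site K_d is recovered to ~1%;
across random 1–5-site models with K_d ∈ [10, 500] μM the median
first-site error is well under 15%, i.e. the design identifies the
model.

## Occupancy, adduct assignment and peak areas

Adduct peaks of charge z are spaced (m_metal − 2·m_H)/z apart: a
divalent ion displaces two protons at constant observed charge. The
default mass shift is 63.364 Da (average Zn mass 65.38 − 2 × 1.00794);
the observed spacing is instrument- and ion-dependent, so the value is
configurable. m/z centers use the average (not monoisotopic) mass of
the packaged 140-residue N-acetylated α-synuclein sequence
(14 502.05 Da) and a proton mass of 1.00728 Da — adduct envelopes, not
isotopes, are the analysis currency at this resolution.

Peak areas are extracted in ±2 Th windows around each center.
`integrate` (trapezoid, with interpolated window edges so the result
is stable under grid refinement) is the default; `local_max` mirrors
the intensity-based extraction of common titration-fitting tools.
When windows of consecutive adducts would overlap (spacing < 4 Th,
i.e. charge ≥ 16 at this mass), both half-widths shrink to half the
spacing with a warning. Percent occupancy is 100·Σ_{n≥1}A_n / Σ_n A_n;
charge states 5–8⁺ are classed as compact conformers and 9–17⁺ as
extended when summarising charge-state distributions.

## Ion mobility

T-wave arrival times are first corrected for mass-dependent post-IM
flight time, t′ = t − EDC·√(m/z)/1000, with EDC defaulting to 1.35 (an
instrument constant; it cancels in relative compaction metrics and is
exercised by round-trip tests). Literature calibrant CCS values are
reduced by CCS′ = CCS·√μ/z (μ: reduced mass with N₂, 28.006 Da) and
ln CCS′ is regressed on ln t′; the fit warns below r² = 0.98.
Calibrant tables are user-supplied CSV rows
(species, mass_da, charge, ccs_a2, arrival_ms); tests use synthetic
calibrants generated exactly from a known power law, and the
round-trip identity holds to 1e-8.

The compaction statistic integrates the 8⁺ arrival-time distribution
over a compact window [4.0, 7.0] ms versus an extended window
(7.0, 10.0] ms. The two windows partition the analysis range at
exactly 7.0 ms — a display-rounding gap between 7.0 and 7.1 ms in the
verbal definition is closed so that compact + extended = 100% whenever
the signal lies inside [4, 10] ms. All ligand-bound states of the
charge are pooled. Window-edge intensities are interpolated, making
the fraction insensitive to grid placement (< 0.1% difference between
500- and 5000-point grids).

## ThT kinetics

Traces are blank-corrected by subtracting the time-pointwise mean
blank of the matching condition (plate-wide mean as fallback), then
normalised to their own maximum. t₅₀ is the first upward crossing of
half-maximum, linearly interpolated between bracketing samples — a
model-free estimator that matches the half-time's definition without
committing to a kinetic mechanism. A logistic-fit estimator is
provided for cross-checks, and an optional moving-median smoothing
(window 3) guards against single-sample spikes; smoothing is off by
default and recorded in run metadata. t₅₀ is extracted per replicate
and then averaged (never from an averaged trace), and the fold change
is mean t₅₀(0) / mean t₅₀(x). Error cases are distinguished: a flat
trace ("no assembly detected") versus a monotone-decreasing trace.

## Chemical-shift perturbation

CSP = √(Δδ_H² + w_N·Δδ_N²) with w_N = 0.14 (equivalent to the common
0.374-scaling convention; configurable). Peaks are matched across
titration points by residue assignment — automated peak tracking is
out of scope — and a residue missing from either list yields NA, not
zero, since a broadened-out peak is missing information. The
significance threshold defaults to the mean CSP over all residues
(the conventional dashed line of CSP bar plots); mean + 1 sd is
available as a stricter rule. The displayed per-residue CSP profile
uses the highest-concentration titration point, recorded in output
metadata. Intensity-attenuation analysis is reduced to an optional
intensity-ratio column; no lineshape fitting is attempted.

## Cross-technique synthesis

The occupancy, compaction and t₅₀ channels are interpolated linearly
(monotonicity-preserving, no overshoot on sparse grids) onto the union
of their dose grids restricted to the overlapping range; extrapolation
is forbidden (NA). Each channel is rescaled to [0, 1] over its
observed range. The t₅₀ channel enters the normalised set as the
half-time *reduction* t₅₀(0) − t₅₀(x): an affine inversion preserves
the dose–response shape, whereas the fold *ratio* t₅₀(0)/t₅₀(x)
(which is also tabulated, and is the natural headline number) warps
the dose axis and pushes its apparent saturation far beyond that of
the other channels.

The saturation dose fits R(x) = R_max·x^h/(K^h + x^h) to the response
above its zero-dose baseline and reports
x* = K·(p/(1−p))^{1/h} at plateau fraction p = 0.95. The Hill
exponent (bounded to [0.3, 4]) is essential here, not cosmetic: a
five-site occupancy curve under ligand depletion is steeper than a
rectangular hyperbola, and a pure hyperbolic fit overshoots the
plateau and misplaces x* by a factor of 2–3. On a truly hyperbolic
channel the fit returns h = 1 and x* reduces to the classical
K·p/(1−p). Channels that are non-monotone beyond 10% of their span
are refused. Concordance is reported as pairwise Pearson and Spearman
coefficients over shared non-NA points (≥ 4 required per pair).

## Synthetic scenario

The default scenario (`scenario_paper_mimic`) encodes the study
conditions as ground truth:

| parameter | default | unit | rationale |
|---|---|---|---|
| protein_conc | 20 | μM | titration protein concentration |
| ligand_concs | 0, 2, 10, 20, 40, 60, 100, 150, 200, 300, 400, 500, 800 | μM | the 13-point design (0–40× equivalents) |
| first-site K_d | 58 (7⁺), 54 (8⁺), 55 (10⁺), 27 (12⁺), 50 otherwise | μM | reported apparent per-charge affinities; ~50 μM scale |
| site multipliers | 1, 1.15, 0.9, 1.25, 1.1 | — | similar stepwise affinities (noncooperative) |
| peak FWHM | 0.5 | Th | adducts resolved, isotopes not |
| spectrum_noise_sd | 1 | % | per-peak amplitude noise |
| atd centers / σ | 5.5, 8.5 / 0.35, 0.45 | ms | compact and extended conformer families |
| compaction link | 0.20 + 0.60·(bound fraction) | — | compact weight rises with occupancy |
| t50_baseline / plateau | 30 / 4.8 | h | calibrated to a 5-fold reduction at 15 equivalents |
| t50 half-saturation | 0.75 | equivalents | places the t₅₀ channel's saturation with the others |
| tht_noise_sd / blank | 2% / 5% | of amplitude | plate noise; constant blank exercises correction |
| csp_halfsat | 50 | μM | fast-exchange isotherm on the apparent-affinity scale |
| csp_profile peaks | H50 patch (48–52), C-terminal 113–138, max at D121 | ppm | the two binding hot spots; mean max-CSP ≈ 0.006 ppm |

One master seed derives per-modality child seeds by fixed offsets, so
a single modality can be regenerated bit-identically. The charge-state
envelope centre drifts from 11⁺ toward 8⁺ as binding occupancy grows,
shifting signal into the compact class.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: isotope structure, m/z
calibration drift, detector saturation and ion statistics;
nucleation–growth asymmetry of ThT curves (only the half-maximum
crossing is consumed downstream, so a logistic with the true t₅₀
suffices); unequal ionisation efficiencies across bound states;
nonspecific electrospray adduction; peak overlap between charge
states; intermediate-exchange lineshape effects in NMR. Recovery of a
K_d to 1% here shows the estimator and design are sound, not that a
real spectrum's systematic effects are that small. ThT plateau
amplitudes are normalised to 1 by fiat — absolute fluorescence units
carry no information used downstream.

## Degenerate inputs and tie-breaks

Zero total ligand short-circuits the solver (all-apo). An all-zero
peak-area point is an error, not a zero occupancy. Flat response
channels refuse saturation fitting. ATD grids must cover [4, 10] ms.
Unsorted spectrum m/z values are sorted on load with a warning;
duplicate m/z samples are dropped. Windows extending beyond the
spectrum raise an error naming the offending assignment.

## Problem sizes

Default analyses operate on 13-point titrations with up to 6 adduct
states per charge, profile grids of ~0.02 Th spacing, 481-point ATD
grids and 301-point ThT traces — sizes at which the full pipeline,
including the multistart fits for four charge states, completes in a
few seconds on one CPU.

## Known limitations

Apparent K_d values from native-MS intensities are semiquantitative;
no in-solution reference exists in this workflow, so accuracy is
defined against synthetic truth only. Cooperative (Hill-type) binding
models are deliberately absent from the binding stage (the stepwise
fits justify noncooperativity for this system); mechanistic
nucleation–elongation kinetics, Bayesian charge
deconvolution, multi-Gaussian ATD deconvolution and NMR-derived K_d
fitting are out of scope.
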