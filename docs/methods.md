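# Methods

## Scope and model

`bretfit` analyses live-cell NanoBRET ligand-binding data: a receptor is
fused at its extracellular N terminus to a NanoLuc luciferase (BRET donor)
and binding of a fluorophore-labeled ligand (acceptor) is read out as the
acceptor/donor emission ratio in a 96-well plate. Because energy transfer
requires < 10 nm proximity, the ratio reports receptor-bound ligand
specifically. All models assume a single class of non-interacting sites,
mass-action kinetics, and negligible ligand depletion (well volumes and
ligand excess make the free concentration effectively constant).

The four assay modes and their models:

* **Saturation.** Total wells follow
  `y = baseline + Bmax·L/(L + Kd) + ns·L`; matched NSB wells (excess
  unlabeled ligand co-added to occupy the specific site) follow
  `y = baseline + ns·L`. The two well sets are fitted jointly per
  experiment with shared `baseline` and `ns`, rather than subtracting NSB
  wells pointwise; this uses every well and cannot produce negative
  "specific" values.
* **Association kinetics.** After vehicle baseline correction the specific
  signal at ligand concentration `L` rises as
  `B_eq(L)·(1 − exp(−k_obs·t))` with `k_obs = kon·L + koff` and
  `B_eq(L) = Bmax·L/(L + koff/kon)`. A single concentration only
  identifies `k_obs`; fitting ≥ 2 (by default 5) concentrations
  simultaneously with shared `kon`, `koff` and a single shared amplitude
  `Bmax` separates the two rate constants. The shared amplitude is an
  identifiability choice: per-concentration amplitudes would trade off
  against the occupancy factor in `B_eq`.
* **Competition.** At each fixed probe concentration the signal follows a
  four-parameter inhibition curve with the slope factor fixed at 1
  (mass action); each fitted IC50 is converted to the competitor affinity
  by Cheng–Prusoff, `Ki = IC50/(1 + L/Kd)`, using the probe Kd from a
  saturation experiment. Across probe concentrations the IC50 is affine in
  `L` (`IC50 = Ki + (Ki/Kd)·L`), so an ordinary least-squares line gives an
  independent estimate of `Ki` (intercept) and of the probe `Kd`
  (intercept/slope).
* **Concentration–response.** A logistic (Hill) curve with slope 1 by
  default; reported as pEC50 = −log10(EC50/M) plus `emax` and `basal`.

Derived kinetic quantities: kinetic `Kd = koff/kon`, association half-time
`t½ = ln2/(kon·[A] + koff)`, residence time `1/koff`.

## Units and conventions

Molar and minutes internally; nM at the CSV/CLI/report boundary
(parameter names ending `_nM`). `kon` is in M⁻¹·min⁻¹, `koff` in min⁻¹.
pKi and pEC50 are −log10 of molar values.

## Estimation

Per-experiment nonlinear least squares (Levenberg–Marquardt via lmfit),
unweighted — no variance model is assumed for well noise. Affinities,
midpoints and rate constants are fitted as log10 quantities with bounds
(`kon ∈ [10³, 10¹²] M⁻¹min⁻¹`, `koff ∈ [10⁻⁵, 10²] min⁻¹`, affinities
1 fM–100 µM) for positivity and conditioning; reported values and
delta-method standard errors are back-transformed. Starting values come
from the data (NSB slope by linear fit; `k_obs` per concentration from
single-curve fits, then `kon`/`koff` from the line `k_obs` vs `L`; curve
midpoints from the first crossing of the half-signal). If the first start
fails, three deterministic starts spread over the bound box are tried;
there is no randomness anywhere in fitting. Degenerate inputs (flat
traces, all-NSB tables, a single kinetic concentration) are flagged or
rejected rather than returning unidentified numbers.

Summaries follow the independent-experiment convention: each experiment is
fitted separately and parameters are reported as mean ± SEM (SD/√n) over
experiments. The kinetic Kd is computed as koff/kon *within* each
experiment before averaging; a mean of per-experiment ratios generally
differs from the ratio of mean rates, which is why tabulated kinetic Kd
values need not equal the quotient of tabulated mean rate constants.
Pooled pKi is −log10 of the linear-scale mean Ki across probe
concentrations (configurable in principle; this convention is the
default). Probe dependence of pKi can be tested with a one-way
fixed-effects ANOVA over probe concentrations.

`power_delta_pki` computes the exact power of a two-sample two-sided
t test for a pKi shift from the noncentral t distribution; the anticipated
SD is an explicit input, since power claims are meaningless without it.

## The synthetic-data generator

The generator reproduces the statistical structure of the plate designs,
with defaults set to the reference study conditions: 5 independent
experiments, duplicate wells, saturation over 8 concentrations
(0.1–30 nM) with paired 100 nM-unlabeled NSB wells, association at 1, 2.5,
5, 10 and 20 nM sampled every 30 s for 20 min with vehicle wells,
competition at probe concentrations 0.5–5 nM, and a half-log competitor
series (0.01–100 nM plus a competitor-free well) and CR series
(0.01–1000 nM plus zero dose) chosen to bracket the ground-truth
midpoints, since the papers' plate maps do not print the dilution series.
Default ground truths are the NRP1 parameter set (Kd 4.41 nM,
kon 7.11×10⁷ M⁻¹min⁻¹, koff 0.26 min⁻¹, competitor pKi 9.54, pEC50 8.16).

Noise is additive iid Gaussian on the ratio scale with default SD equal to
5% of the specific window (`0.001` ratio units for `Bmax = 0.02`); real
plate noise magnitudes are not recoverable from published summaries, so
this is a free simulation parameter. Raw ratio magnitudes
(baseline 0.05, Bmax 0.02) are arbitrary; every affinity and rate estimate
is invariant to them. Time zero is the moment of ligand addition (the
5-min substrate equilibration is not simulated). Per-experiment RNG
streams are spawned from one seed, so adding experiments never changes
earlier ones, and a fixed seed gives byte-identical CSV output.

Not emulated: donor signal decay and substrate consumption over long
kinetic reads, plate-position effects, emission-filter bleed-through, and
ligand depletion. Passing recovery tests on these simulations therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to those instrument artifacts.

## Numerical and design notes

* Noiseless recovery of every generator ground truth is exact to optimizer
  tolerance (≲10⁻⁶ relative); the suite asserts 10⁻⁴–10⁻⁶ per mode.
* The regression-based probe Kd (intercept/slope) is a ratio of estimates
  and becomes heavy-tailed when noise rivals the smallest probe's specific
  window; the consistency tests exercise it in the regime where it is
  well-behaved, and the per-curve Cheng–Prusoff route is the robust
  default for Ki.
* Division-at-zero cases (`koff = 0`, `kd ≤ 0`) raise errors: they denote
  invalid physics, not edge cases to be propagated as infinities.
* Zero concentrations are allowed where they mean something (competitor-
  free wells, zero-dose response wells) and rejected elsewhere.
* Test problem sizes (2–5 simulated experiments, 41-point time courses,
  10⁵-rep Monte-Carlo power oracle) were chosen so the full suite runs in
  a few seconds while keeping Monte-Carlo error well below the asserted
  tolerances.

## Limitations

One-site models only: no two-site or cooperative binding, no depletion
correction, no kinetic-competition (Motulsky–Mahan) analysis, and no
vendor plate-file parsers — input is the documented long-format CSV.
Cross-experiment aggregation is mean ± SEM, not hierarchical/Bayesian
pooling.
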