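# Methods

This note documents the statistical model behind `rbemap`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## Experimental design the package assumes

A 96-well plate (rows A–H, columns 1–12) sits in a stepped attenuator so
that each column lies at a different depth along a particle beam. A column
is therefore a *condition*: one (dose ladder, LET_d, y_d) combination.
Rows are replicate wells; with 8 rows per column and 2 plates irradiated
per exposure level, every dose/beam-quality combination carries 16
replicate wells. Sham-irradiated control plates carry the same layout at
dose 0. Wells are seeded at 100 cells (configurable); colonies are scored
upstream (the ≥50-cell criterion and imaging are outside this package —
the input is a per-well integer count, or a missing mark for unscoreable
wells, which is deliberately distinct from a zero count since zero is a
Poisson datum).

## Survival bookkeeping

Plating efficiency is pooled over all control wells,
PE = Σcounts / (n_wells · N_seeded), which is invariant to how the control
wells are split across plates. Per-well surviving fraction is
count/(N·PE); replicate wells at one condition/dose are summarised by the
mean and the standard error of the mean (sample SD, n−1 denominator, over
all 16 wells — not over per-plate means; the two plates per exposure are
treated as exchangeable replicates).

The limit of detection is the SF corresponding to one colony per well,
LOD = 1/(N·PE) — 0.02 at PE 0.5 and 0.03 at PE 1/3 for 100 cells/well.
Exclusion is applied at the condition/dose level: a dose group whose mean
SF is strictly below the LOD is dropped from fitting and the highest
retained dose becomes the fit's *coverage bound*. Individual wells are
never dropped.

## Poisson linear-quadratic fitting

Counts are modelled as independent Poisson with mean
N·PE·exp(−αD−βD²); α, β ≥ 0. The PE offset is fixed from controls rather
than jointly estimated (normalise-then-fit; PE uncertainty is not
propagated — joint estimation would be an extension, not the procedure the
assay uses). The likelihood is maximised with L-BFGS-B under box
constraints, with the analytic gradient; because the log link is canonical
the observed information equals Σμ·x xᵀ with x = (−D, −D²), and the
covariance is its inverse over the *free* parameters. Initialisation is
deterministic: α₀ from a through-origin log-linear fit of mean survival on
dose, β₀ = 0.01 Gy⁻²; no random restarts.

A parameter that lands at the zero boundary (tolerance 1e−8) is flagged
and its Wald variance reported unavailable — Wald theory is invalid on a
boundary, and pure-α fits do occur at the highest beam qualities. Whether
to constrain during fitting or truncate afterwards is a genuine choice; we
constrain during fitting so the reported optimum is the constrained MLE.
If the optimizer reports abnormal termination (its line search can stall
at the tight tolerance), the solution is accepted only when the projected
gradient is negligible relative to the data scale.

Degenerate inputs: all-zero counts, zero/negative PE, no positive dose, or
a flat fitted curve (α = β = 0) raise errors rather than returning
unusable objects. Fractional "counts" are accepted so exact expected
counts can be fitted in validation work.

### Nested-model comparison

Whether two datasets share one LQ curve is tested by an
analysis-of-deviance F approximation: F = [(D_pooled − D_separate)/df₁] /
[D_separate/df₂], referred to F(df₁, df₂). The classical extra
sum-of-squares F test is a least-squares construction; rendering it on the
Poisson deviance keeps one coherent likelihood framework for every fit and
reduces to the same test in the Gaussian limit. This is a deliberate
departure, not an oversight.

## RBE and uncertainty

RBE(s) = D_ref(s)/D_ion(s), each dose the positive root of
αD + βD² = −ln s (computed in the numerically stable form
2L/(α+√(α²+4βL))). Standard errors use the first-order delta method with
the analytic gradients dD/dα = −D/(α+2βD), dD/dβ = −D²/(α+2βD); the
reference and ion fits come from independent irradiations, so no
cross-covariance term. If either fit has a boundary-pinned parameter, the
SE is reported unavailable while the point estimate is retained.

The photon reference curve is a required user input. The synthetic default
(α = 0.2 Gy⁻¹, β = 0.02 Gy⁻², zero covariance) is an invented but typical
photon-like curve used in tests and examples only; it is not a measured
reference.

An RBE estimate is *excluded* when its isosurvival dose exceeds the ion
fit's coverage bound — extrapolating a survival level beyond the doses
with above-LOD data would manufacture precision the data do not contain.
Packaged published tables mark such entries the same way.

Profiles order per-column estimates by column index (depth); y_d need not
be monotone near the distal edge. The peak is the maximum over
non-excluded points, ties broken toward lower y_d; it is undefined with
fewer than two usable points. Overkill is declared when the maximum sits
at a non-final usable point and at least one later point is strictly lower
— a flat profile is not overkill, and with fewer than three usable points
the answer is undefined (None), not False.

## Microdosimetry

Lineal energy y = ε/l̄ with l̄ = 2d/3 exactly (Cauchy chord length of a
convex sphere); default site diameter 2 µm. y_f = ⟨y⟩, y_d = ⟨y²⟩/⟨y⟩, and
the saturation-corrected

    y* = y₀² ⟨1 − exp(−y²/y₀²)⟩ / ⟨y⟩,  default y₀ = 150 keV/µm,

the form used with the modified microdosimetric kinetic model. Since
1 − e⁻ᵗ ≤ t, y* ≤ y_d always, with equality as y₀ → ∞; y* is monotone
non-decreasing in y₀. Dose-averaged LET over a discrete field is
Σφ L²/Σφ L (dose weight ∝ φL); the track average Σφ L/Σφ is also exposed.

Numerics: grid spectra are integrated trapezoidally on the supplied grid —
no automatic re-gridding; densities are renormalised on construction.
Event lists always use exact sample sums for moments, never a histogram,
to avoid binning bias (a spectrum histogrammed from events carries the raw
sample along for exactly this reason). Spectra may be supplied as
frequency density f(y) or converted from dose density d(y) = y f(y)/⟨y⟩.

## Synthetic-data generator

The generator emulates the *statistical* structure of the experiment, not
its physics:

- **y_d ladders.** The helium and carbon presets reproduce the published
  per-column y_d values entry-for-entry; the proton ladder is an invented
  monotone rise to ~20 keV/µm.
- **Dose ladders.** No per-column doses are published, so the presets use
  invented plausible ladders: nominal entrance levels (0.25, 0.5, 1, 2, 4)
  Gy scaled by a parametric Bragg-like column factor (entrance 1.0, peak
  3.0 at column 6 for the heavy-ion presets, distal floor 0.8 so every
  column retains fittable data). This is a shape, not a transport
  calculation.
- **Truth model.** α(y_d) = α_ref·(1 + A·exp(−(ln(y/y_peak))²/(2σ²))) with
  A = 4, y_peak = 87.9 keV/µm, σ = 0.3, and β(y_d) = β_ref constant,
  against the synthetic photon reference above. The log-normal bump gives
  the rise-peak-decline (overkill) shape with a peak RBE near 5 — the
  scale reported for carbon beams. A and σ were fixed once as a plausible
  effect size; custom α(y_d)/β(y_d) callables can replace them.
- **Counts.** Poisson around N·PE·SF(D); PE defaults to 0.5 (H460-like;
  use 1/3 for an H1437-like line). An optional gamma-mixed Poisson
  (variance = w·mean) exists purely to stress-test the fitter and is off
  by default, matching the Poisson regression used for analysis. Counts
  are capped at the seeding density to respect the data model's hard
  invariant; at realistic PEs the cap is essentially never active.
- **Randomness.** One `numpy.random.Generator` passed explicitly; same
  seed, byte-identical experiment.

What it does **not** emulate — and therefore what passing tests do *not*
establish about real data: secondary-particle contamination and mixed
fields, plate-position or edge effects, colony-merging/undercounting at
high density, inter-experiment PE drift, non-Poisson biological
variability (beyond the optional stress mode), and any transport physics.
Recovery results on synthetic data validate the *estimator chain*, not the
biology.

## Problem sizes in routine checks

The test suite exercises the chain at the design scale it analyses: 16
replicate wells per dose/quality combination, 100 cells/well, 5 exposure
levels, 12 columns (~1150 wells per experiment). Repeated-run checks use
100 seeded experiments for peak-column recovery, 200 simulations for Wald
coverage of α, 100 comparisons each for the null and alternative of the
deviance F test, 10⁴ draws for the parametric-bootstrap check of the
delta-method SE, and 1000 randomised spectra for the microdosimetric
inequalities; each choice gives comfortable Monte-Carlo resolution for the
asserted bounds at interactive runtimes.

## Known limitations

- PE uncertainty is not propagated into α, β or RBE.
- Delta-method SEs are first-order; they degrade for strongly curved
  likelihoods (few doses, low counts) and are unavailable at boundaries —
  a profile-likelihood or bootstrap interval would be the next step.
- The deviance-F comparison is an approximation; its small-sample
  calibration is checked empirically (null rejection ≤ ~5–10%) rather
  than derived.
- Overkill detection is a structural test on point estimates; it does not
  weigh estimate uncertainties.
- The LOD rule excludes whole dose groups by their mean SF; wells are
  never individually censored, so a group straddling the limit is kept or
  dropped as a unit.
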