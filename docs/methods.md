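# Methods

This note records the models implemented in `quenchbind`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Binding model and mass conservation

All equilibrium calculations assume `n` equivalent, independent sites with
per-site association constant `Ka` (Langmuir occupancy). For total protein
`P`, total ligand `L_tot`, the free-ligand concentration solves

    L_tot = L + n · (Ka·L / (1 + Ka·L)) · P.

`solve_binding` brackets the root on `[0, L_tot]` (Brent's method,
relative tolerance at machine precision) and then applies up to five
exact-derivative Newton steps. The polish matters: the bracketed root can
leave a mass-conservation residual amplified by `(1 + n·Ka·P)`, and the
residual contract here is `< 1e-13 · max(L_tot, 1e-12)`. For `n = 1` the
solution has a closed quadratic form, which the test suite uses as an
independent oracle (agreement to 1e-10 relative over a grid of
concentrations and Ka from 1e3 to 1e6 M⁻¹); the solver itself stays
iterative because it must handle any `n`.

Binding density is `ν = n·Ka·L/(1+Ka·L)`; the fraction of protein with
every site empty is `(1+Ka·L)^(−n)`, which is what the dark-complex
simulator scales the protein band by.

## Synthetic data: what is and is not emulated

`GroundTruth` + `simulate_titration` produce a two-band emission model on a
305–570 nm grid (1 nm spacing):

* protein band — Gaussian at 340 nm, FWHM 50 nm, peak `f0_peak` (1000 a.u.
  default) scaled per titration point by the quenching factor;
* ligand band — Gaussian at 480 nm, FWHM 76 nm, amplitude proportional to
  total ligand (`ligand_band_gain`, default 5e6 a.u./M, i.e. a ligand band
  comparable to the protein band near the top of a titration). The bands
  are far enough apart that the ligand tail at 340 nm is ~7e-5 of the
  ligand peak; exactness tests that require a truly single-band spectrum
  set the gain to zero.

Static quenching uses the dark-complex model: protein with an occupied
site contributes nothing, so `F/F0` at the band center equals the free
protein fraction exactly and the double-log fit is exact for `n = 1` on
noiseless data. Dynamic quenching scales amplitude and every decay
lifetime by `1/(1 + K_D·L_free)`, so `F0/F = τ0/τ` pointwise by
construction.

Per-point absorbances follow Beer–Lambert from the ligand's extinction
coefficients (16,500 M⁻¹cm⁻¹ at the excitation band; 1,000 M⁻¹cm⁻¹ default
at the emission band) and the simulator attenuates the observed spectra by
the same half-path inner-filter factor that the preprocessing stage
inverts, so correction is exact in the noiseless limit. Noise is pointwise
multiplicative Gaussian (`noise_rel`, typically 0.01) on the wavelength
grid; decay histograms get Poisson counts around the multi-exponential
expectation. All randomness flows from the `seed` field through
`numpy.random.default_rng`.

Not emulated: instrument response convolution of decays, wavelength-dependent
inner-filter effects beyond the two scalar absorbances, scatter/baseline
structure, band-shape changes on binding (the fluorophore microenvironment
is assumed polarity-stable), and anisotropy. Passing tests therefore show
the estimators recover their own generating model; they do not certify
robustness to band shifts or correlated instrument drift in real data.

## Intensity extraction

The default extraction reads the inner-filter-corrected peak intensity at
the band center (340 nm). Integral mode (trapezoid over band_center ±
window/2, default 50 nm window) gives identical `F0/F` ratios for a fixed
band shape — a tested property — and averages pointwise spectral noise
down by roughly √(window points) ≈ 7×. The quench-curve (IDF) and
mechanism-classification campaigns use integral mode for exactly that
reason: the IDF level inversion differentiates two fitted curves and is
the noise-sensitive step of the whole pipeline.

## Stern–Volmer and mechanism rules

The Stern–Volmer slope is fitted with the intercept constrained to 1
(`F0` comes from the same series, so the zero-quencher ratio is 1 by
construction; a free intercept only absorbs noise). Classification
defaults, all config-exposed via `ClassificationThresholds`:

* `kq_limit = 1e10 M⁻¹s⁻¹` — the diffusion ceiling for collisional
  quenching;
* `tau_flat_tol = 0.05` — mean `|τ0/τ − 1|` below this counts as a flat
  lifetime series, and `max(F0/F) − 1` must exceed the same threshold for
  quenching to be considered real;
* `equiv_tol = 0.05` — maximum pointwise relative gap between `F0/F` and
  `τ0/τ` for the dynamic (equivalence) rule.

Static requires `k_q > kq_limit` *and* flat lifetimes with real intensity
quenching; dynamic requires `k_q ≤ kq_limit` *and* ratio equivalence;
anything else is inconclusive. Note that an observable dynamic campaign
with `k_q` below the ceiling needs a long-lived fluorophore: with
`K_D = 5e2 M⁻¹`, `k_q = 5e9 M⁻¹s⁻¹` corresponds to `τ0 = 100 ns`
(pyrene-like), and the synthetic dynamic campaigns are parameterised that
way. A 4.8 ns tryptophan with any measurable collisional constant would
exceed the ceiling arithmetic.

## TCSPC decay fitting

Weighted nonlinear least squares of `Σ Aᵢ·exp(−t/τᵢ) + background` (1–3
components) on 1024 channels. Defaults: 50 ns window (scaled to ~10·τ0 for
long-lived fluorophores in the campaign helpers) and 1e5 total counts, a
desk-scale TCSPC regime. Initialisation is deterministic: τ guesses
log-spaced across the window at three fixed scales (1.0, 0.3, 3.0) with
equal amplitudes — no random restarts, so fits are reproducible without
seed plumbing.

Weighting is the one place the obvious choice is wrong: pure
observed-count (Neyman) weights `1/max(c,1)` over-weight tail channels
that happen to fluctuate low and bias the short component of a 1.5/5.0 ns
biexponential downward by ~19% at 1e5 counts. The fitter therefore runs an
observed-count first pass and two refits re-weighted by the fitted model
counts (iterated Pearson weighting), which brings the bias to ~2% on the
minor component and below 0.1% on the major one. The remaining per-seed
scatter of the minor component is ~4–5% s.d. at 1e5 counts — estimates of
a 30%-amplitude 1.5 ns component at this photon budget are honest to about
one part in twenty, and the tests assert medians over replicates
accordingly. `τ0/τ` ratio series are insensitive to the residual bias
because it cancels between numerator and denominator.

The background term starts strictly inside its bound: a parameter starting
exactly at a bound stalls the bounded trust-region step.

## Double-log binding fit

`y = log₁₀((F0−F)/F)` on `x = log₁₀(L_tot − ((F0−F)/F0)·P)`, ordinary
least squares, decadic logs (the base cancels in `n` but not in `Ka`, so
it is fixed). For the 1:1 dark-complex model the bracketed free-ligand
estimate is algebraically the true free-ligand concentration, so the
regression is exactly linear on noiseless data. Points with non-positive
free-ligand estimates are dropped (with a warning), never clamped —
clamping biases the slope. `Ka = 10^(a/b)` gets its standard error from
the delta method on `(a, b)` jointly, since the two are strongly
correlated in this parametrisation.

## van't Hoff decomposition

OLS of `ln Ka` on `1/T`; `ΔH = −R·slope`, `ΔS = R·intercept`,
`R = 8.314 J mol⁻¹K⁻¹`. ΔH is treated as temperature-independent over the
fitted range (three points cannot support a ΔCp term). Reported ΔG comes
from the fitted pair via `ΔG = ΔH − T·ΔS` — one enthalpy for all rows —
with pointwise `−RT·ln Ka` kept as a diagnostic column. Standard errors
are regression covariances and are labelled as such; with exactly two
temperatures the line interpolates and the SEs are reported as NaN rather
than zero.

## IDF and Scatchard

Quench percentages are reported as magnitudes, `ΔF = 100·(F0−F)/F0`, so
curves increase with ligand. Each curve ΔF vs `log₁₀ L_tot` is smoothed
with an asymmetric logistic (Richards) form, bottom fixed at 0:

    ΔF(x) = top / (1 + 10^(slope·(center − x)))^asym.

A symmetric 4-parameter logistic was tried first and rejected: with
micromolar protein the ligand-depletion skew leaves a systematic ~0.4%
misfit that propagates through the level inversion into a ~6% bias on K_b
even on noiseless data. The asymmetry exponent removes the skew (noiseless
K_b error ~0.5%) while keeping a closed-form inverse, which the level
inversion uses directly (no numeric root finding).

Default levels: 10 equally spaced ΔF values across the overlap of the
curves' fitted ranges, excluding the outer 5% of the overlap at each end —
the logistic inverse blows up at its asymptotes. Both the level lines and
the Scatchard regression are unweighted OLS. With exactly two protein
concentrations each level line is an exact interpolation, so per-level
standard errors are undefined (reported NaN) and uncertainty is quoted at
the Scatchard stage only.

## Problem sizes and defaults used by tests and the acceptance script

Equilibrium titrations: 12 points, 4 μM steps, 4 μM protein. IDF
titrations: 60 points, 1 μM steps, at 4 and 8 μM protein. Decays: 1024
channels, 1e5 counts. Replicate studies: 20 seeds at 1% relative noise.
These mirror a realistic bench campaign and keep the full suite and the
acceptance script each under a minute of compute.

## Known limitations

* The dark-complex assumption makes `(F0−F)/F0` the bound fraction; real
  complexes with partial fluorescence would bias both the double-log and
  IDF routes, and no partial-quantum-yield model is provided.
* No IRF deconvolution: fitted lifetimes below ~2 channel widths are not
  meaningful.
* The Scatchard stage refuses positively sloped regressions rather than
  modelling anti-cooperativity; cooperative or lattice binding models are
  out of scope.
* Ellipticity handling is the unit conversion to mean residue ellipticity
  only; secondary-structure deconvolution needs external reference-set
  software and is deliberately not reimplemented.
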