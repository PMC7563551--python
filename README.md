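# quenchbind

Fluorescence-quenching binding analysis for protein–ligand titrations:
from raw emission spectra and TCSPC decay histograms to quenching-mechanism
classification, binding constants, van't Hoff thermodynamics and the
model-free interaction density function (IDF) / Scatchard analysis.

The package grew out of the characterisation of the interleukin-1β /
piperine complex, where the single tryptophan (Trp120) of IL-1β is quenched
by a ligand that forms a non-fluorescent ground-state complex, but the
machinery is generic to any single-fluorophore titration experiment.

## What it computes

**Inner-filter correction.** Observed intensities are corrected for
attenuation of the excitation and emission beams,
`F_corr = F_obs · 10^((A_ex·d_ex + A_em·d_em)/2)`, with absorbances per
1 cm and the cuvette path lengths `d_ex`, `d_em` (default 10 × 2 mm cell:
exponent `(5·A_ex + A_em)/10`).

**Stern–Volmer analysis.** `F0/F = 1 + K_SV·[Q]`, intercept fixed at 1.
The bimolecular constant `k_q = K_SV/τ0` against the diffusion-limited
ceiling (~10¹⁰ M⁻¹s⁻¹), together with the comparison of `F0/F` and `τ0/τ`,
classifies quenching as *static* (ground-state complex, lifetime flat) or
*dynamic* (collisional, `F0/F = τ0/τ` pointwise).

**TCSPC lifetimes.** Multi-exponential fits
`I(t) = Σ αᵢ·exp(−t/τᵢ) + bg` with iterated Poisson weighting; the headline
quantity is the intensity-weighted average `⟨τ⟩ = Σαᵢτᵢ²/Σαᵢτᵢ`.

**Binding constant and site number.** The double-logarithm regression
`log₁₀((F0−F)/F) = n·log₁₀(Ka) + n·log₁₀([L]_free)`, with
`[L]_free = [L]_tot − ((F0−F)/F0)·[P]_tot`.

**Thermodynamics.** `ln Ka` vs `1/T` gives ΔH (slope) and ΔS (intercept);
`ΔG = ΔH − T·ΔS` per temperature, with a qualitative entropic/enthalpic
driving-force call.

**IDF / Scatchard.** Quench curves ΔF(log₁₀[L]) at ≥ 2 protein
concentrations are smoothed with an asymmetric logistic; equal-ΔF levels
are inverted to mass-conservation lines
`[L]_tot = [L]_free + Σνᵢ·[P]_tot`, and the (Σνᵢ, [L]_free) pairs feed the
Scatchard regression `Σνᵢ/[L]_free = n·K_b − K_b·Σνᵢ`.

A seeded synthetic-data generator (`quenchbind.synthetic`) produces
titration spectra, per-point absorbances and Poisson decay histograms with
known ground truth, so every stage is testable end to end.

## Worked example

```python
from quenchbind import (GroundTruth, classify_campaign, binding_recovery_campaign,
                        vant_hoff_fit, interpret_forces, idf_campaign)

kas_true = {288.0: 1.44e4, 298.0: 2.41e4, 308.0: 4.42e4}
fits = []
for i, (T, ka) in enumerate(kas_true.items()):
    gt = GroundTruth(ka=ka, tau0=4.8, mechanism="static", noise_rel=0.01,
                     seed=1 + i, decay_alphas=(0.3, 0.7), decay_taus=(1.565, 5.216))
    sv = classify_campaign(gt)
    fit = binding_recovery_campaign(gt, mode="integral")
    fits.append((T, fit.ka))
    print(f"T={T:.0f} K  K_SV={sv.k_sv:.3g} M^-1  k_q={sv.k_q:.3g} M^-1 s^-1  "
          f"mechanism={sv.mechanism}  Ka={fit.ka:.3g} M^-1  n={fit.n_sites:.3f}")

res = vant_hoff_fit(fits)
print(res.summary())
print(interpret_forces(res))

sc, _ = idf_campaign(GroundTruth(ka=1.43e5, mechanism="static", noise_rel=0.01, seed=4))
print(sc.summary())
```

prints

```
T=288 K  K_SV=1.38e+04 M^-1  k_q=2.85e+12 M^-1 s^-1  mechanism=static  Ka=1.44e+04 M^-1  n=1.002
T=298 K  K_SV=2.28e+04 M^-1  k_q=4.74e+12 M^-1 s^-1  mechanism=static  Ka=2.41e+04 M^-1  n=0.993
T=308 K  K_SV=4.11e+04 M^-1  k_q=8.56e+12 M^-1 s^-1  mechanism=static  Ka=4.42e+04 M^-1  n=0.997

van't Hoff thermodynamic analysis
-------------------------------------------------------
dH     41.43 +/- 2.77 kJ/mol
dS    223.25 +/- 9.30 J/(mol K)
R^2   0.9956

T (K)    dG (kJ/mol)         T*dS (kJ/mol)
 288.0    -22.87 +/- 0.12      64.30
 298.0    -25.10 +/- 0.08      66.53
 308.0    -27.33 +/- 0.12      68.76
{'spontaneous': True, 'driving_force': 'entropic'}

IDF / Scatchard analysis
-----------------------------------------------
Kb        1.422e+05 +/- 7.5e+02 M^-1
n_sites      0.9798 +/- 0.0029
R^2         0.99978
```

Each simulated campaign quenches the 340 nm tryptophan band with the given
true Ka, classifies the mechanism as static (k_q two orders of magnitude
above the collisional ceiling, flat lifetimes), and recovers the binding
constant; the three (T, Ka) pairs decompose into an endothermic,
entropy-driven, spontaneous association; the two-protein-concentration IDF
route recovers K_b ≈ 1.43 × 10⁵ M⁻¹ and one binding site independently of
any binding model.

The `quenchbind` command exposes the same stages as subcommands
(`simulate`, `extract`, `quench`, `lifetime`, `binding`, `thermo`, `idf`,
`all`) operating on the CSV formats described in `quenchbind.io`.

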