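# smallfield

Output factors and detector-specific output correction factors for **small
megavoltage photon fields**, determined the way a dual-reference-detector
film + plastic-scintillator campaign does it: FWHM field sizing from 2D
dose maps, closed-form volume-averaging corrections, Čerenkov correction
of the two-channel scintillator signal, joint analytic curve fitting, and
summary-statistics comparisons.

## The problem

In fields smaller than ~2 cm, lateral charged-particle equilibrium is lost
and the collimators partially occlude the source, so a detector's raw
signal ratio between a clinical field and the 10 cm × 10 cm reference field
is *not* the field output factor Ω. The formalism adopted by the IAEA/AAPM
small-field code of practice (TRS-483) writes

$$\Omega = \frac{M_{\mathrm{clin}}}{M_{\mathrm{ref}}}\, k(S_{\mathrm{clin}})$$

with a detector- and field-size-specific output correction factor *k*, and
characterises field size by the equivalent square
$S_{\mathrm{clin}}=\sqrt{A\,B}$ of the measured FWHM widths *A*, *B*.

This package implements the full determination chain for two reference
detectors treated as perturbation-free except for volume averaging —
radiochromic film (EBT3) and the Exradin W1 plastic scintillator:

1. **Field sizing** (`smallfield.geometry`) — field centre as the fixed
   point of half-maximum-midpoint iteration, FWHM by linear interpolation,
   central ROI dose, $S_{\mathrm{clin}}=\sqrt{AB}$.
2. **Volume averaging** (`smallfield.volume`) — the central 3 mm × 3 mm of
   the film dose map is fitted to
   $f(x,y)=a\,e^{-\frac12[(x/b)^2+(y/c)^2]}$ and each detector's footprint
   (equal-area square of side $d=r\sqrt\pi$) gets the closed-form factor

   $$k_{\mathrm{vol}} = \frac{d^2}{2\pi b c\,
   \operatorname{erf}\!\big(\tfrac{d}{2\sqrt2\,b}\big)
   \operatorname{erf}\!\big(\tfrac{d}{2\sqrt2\,c}\big)} \;\ge 1,$$

   cross-checked against direct 2D quadrature.
3. **Scintillator correction** (`smallfield.scintillator`) — Čerenkov
   light ratio from two-point fibre-length calibration,
   $M = M^{\mathrm{Ch1}} - \mathrm{CLR}\cdot M^{\mathrm{Ch2}}$, and
   cross-normalization of the scintillator series to the film series by
   the mean signal ratio $\bar\epsilon$ over the nine clinical fields.
4. **Output-factor curve** (`smallfield.output_factors`) — both detectors'
   corrected points fitted jointly (SD-weighted least squares ⇔ Gaussian
   maximum likelihood) by the Sauer–Wilbert saturation model
   $\Omega(S)=P_\infty S^n/(l^n+S^n)+S_\infty(1-e^{-bS})$, normalized to
   $\Omega(10\,\mathrm{cm})=1$, with seeded parametric-bootstrap
   uncertainties.
5. **Correction factors** (`smallfield.correction`) — discrete
   $k=\Omega/\mathrm{ratio}$ per solid-state detector with quadrature SD,
   fitted by the TRS-483 analytic form
   $k(S)=\frac{1+d\,e^{-(10-a)/b}}{1+d\,e^{-(S-a)/b}}+c\,(S-10)$
   (points below 0.8 cm excluded from the fit but reported).
6. **Statistics** (`smallfield.stats`) — one/two-tailed two-sample t-tests
   from summary statistics (Welch or pooled).
7. **Synthetic campaigns** (`smallfield.synthetic`) — fully seeded
   simulator of dose maps (separable rect ⊗ Gaussian-penumbra model),
   film/scintillator/diode reading tables, and planted ground truth, so
   every stage is testable without external data.

The shipped reference data (`smallfield.beams`) characterise the eight
beams of an Elekta Versa HD and a Varian TrueBeam (6/10 MV, with and
without flattening filter): fitted output-factor parameters, measured
equivalent-square tables, and detector active-area geometries.

## Worked example

Simulate one beam's campaign (film + scintillator + a microdiamond
detector) and run the full analysis:

```python
import smallfield as sf

cfg = sf.SimulationConfig(linac="Elekta Versa HD", beam="6 MV WFF", seed=42)
campaign = sf.simulate_campaign(cfg, detectors=("EBT3", "W1", "PTW 60019 mD"))
result = sf.analyze_campaign(campaign.dose_maps, campaign.readings,
                             clr=cfg.clr, seed=7, n_bootstrap=200)
print(result.omega_table.round(3).to_string(index=False))
```

```
 nominal_field_cm  s_clin_cm  omega    sd
              0.5      0.599  0.450 0.003
              0.8      0.817  0.598 0.004
              1.0      1.000  0.670 0.005
              1.5      1.498  0.761 0.005
              2.0      1.995  0.800 0.006
              3.0      2.990  0.846 0.006
              4.0      3.989  0.878 0.006
              5.0      4.989  0.905 0.006
             10.0      9.991  1.000 0.000
```

The nominal 0.5 cm field measures as a 0.60 cm equivalent square — the
dosimetric field is wider than the collimator setting — and its output
factor is only 0.45: the field delivers less than half the reference dose
per monitor unit. Volume-averaging factors at that field show the
footprint ordering (film ROI < scintillator < microdiamond):

```
    detector  d_mm  k_vol
    EBT3 ROI 0.443  1.002
      W1 PSD 0.886  1.010
PTW 60019 mD 1.950  1.047
```

and the microdiamond's recovered correction factors rise to ~1.06 at the
smallest field (its large active area under-reads the peaked dose) while
pinning to 1 at the reference field:

```
    detector  nominal_field  s_clin     k    sd
PTW 60019 mD            0.5   0.599 1.056 0.009
PTW 60019 mD            0.8   0.817 1.022 0.008
...
PTW 60019 mD           10.0   9.991 1.000 0.003
```

A CLI mirrors the stages (`smallfield simulate | sizecal | kvol | clr |
fit-of | kfactors | compare | run-all`); see `smallfield --help`.

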