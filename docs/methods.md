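# Methods

This note records the models, conventions and numerical choices behind
`smallfield`, and what the synthetic-data validation does and does not
demonstrate.

## Units and coordinates

All internal lengths are millimetres; field sizes cross API boundaries in
centimetres (the field's customary mixed convention: cm field sizes, mm
detector dimensions). Grid coordinates refer to pixel centres; a dose
map's origin is user metadata and defaults to placing (0, 0) at the grid's
geometric centre. Indices are 0-based.

## Field sizing

The field centre is defined as the centre of the dose profiles in both
axes, computed as a fixed point: extract the row/column profile through
the current centre estimate (bilinear interpolation for off-grid lines),
locate the half-maximum crossings by linear interpolation between
bracketing samples, move the centre to the midpoint of the crossings per
axis; iterate to < 0.01 mm change (cap 20 iterations). The half level is
half the *profile maximum* — the standard FWHM convention — not half a
ROI-mean dose. Profiles that never fall below half maximum raise a
degenerate-field error. No smoothing is applied before FWHM extraction;
profiles from calibrated film at ≥ 150 dpi are smooth enough that
smoothing would only bias the penumbra. The equivalent square small field
size is S_clin = sqrt(A·B) of the in-line and cross-line FWHM.

The central ROI dose is the mean over pixels whose centres fall in a
0.5 mm-diameter circle; when the pitch is too coarse for at least 4 pixels
the ROI is first resampled bilinearly at 0.05 mm pitch.

## Volume averaging

The central 3 mm × 3 mm of the film dose map is fitted by unweighted least
squares to a bivariate Gaussian a·exp(−½[(x/b)² + (y/c)²]) (three starting
points; scales reported as absolute values; initial scale = region
half-width / 1.177 with a 0.3 mm floor). A detector's circular active area
of radius r is replaced by the equal-area square of side d = r·√π (square
chips keep their side), and

k_vol = d² / (2π·b·c · erf(d/(2√2·b)) · erf(d/(2√2·c))).

This closed form is exactly the ratio of the central dose times d² to the
Gaussian integrated over the axis-aligned, beam-centred d×d square —
`kvol_numeric` evaluates that integral by adaptive quadrature as a
cross-check, and the two agree to 1e-6 relative over randomized
geometries. The peak amplitude cancels. k_vol ≥ 1 by construction;
values within 1e-9 below 1 (round-off) are clipped to 1.

Two conventions follow the field's practice: corrections are applied only
when k_vol − 1 > 1e-3 (configurable threshold; skipped corrections are
logged), and a central region with no measurable curvature (large flat-top
fields) is treated as k_vol = 1 for every detector rather than as a fit
failure of the pipeline — the standalone fit function still raises so that
callers probing a single map get a diagnosis.

## Scintillator chain

The Čerenkov light ratio is CLR = ΔM^Ch1/ΔM^Ch2 between maximal (~30 cm)
and minimal (~10 cm) fibre length in the reference field; repeated pairs
are averaged. A channel-2 span below 1e-12 of the larger channel-2
reading is rejected as ill-conditioned. The corrected signal is
M^Ch1 − CLR·M^Ch2; non-positive results are flagged and returned, not
rejected, since they can legitimately occur in noisy data. Linear channel
response is assumed throughout.

Scintillator and film measure on different absolute scales. The pipeline
reduces every detector to per-field signal ratios M_clin/M_ref first, so
the absolute scale cancels before cross-normalization; the mean
scintillator/film ratio over the common fields (ε̄) then only absorbs the
residual volume-averaging mismatch and is ≈ 1. This is a scale-free
reformulation of the usual raw-signal cross-normalization with identical
fitted results, and it makes ε̄ a useful consistency diagnostic.

## Uncertainty convention

The quoted uncertainty of a mean reading is the **sample SD of the
repeated readings** (1 SD of a single measurement), not the standard error
of the mean — the conservative convention of dosimetry uncertainty tables,
whose printed percent-level 1-SD values match per-reading scatter.
Downstream, relative SDs combine in quadrature under independence
(different detectors/sessions). Bootstrap curve uncertainties inherit this
convention and are therefore conservative by roughly √n_repeats.

## Output-factor fitting

The Sauer–Wilbert model Ω(S) = P∞·Sⁿ/(lⁿ+Sⁿ) + S∞·(1 − e^(−bS)) is fitted
to the pooled film + scintillator corrected ratios by SD-weighted least
squares, which maximises the Gaussian likelihood with known per-point SDs
— the standard reading of "maximum likelihood" for metrology data with
quoted uncertainties. Points with sd = 0 receive the median weight. The
saturating term is evaluated as 1/(1 + exp(n·(ln l − ln S))) so large n
cannot overflow. Bounds: P∞, n, l, b > 0 and S∞ ∈ (−1, 10], which admits
the near-degenerate flattening-filter-free solutions where S∞ and b trade
off (one shipped beam has S∞ = 1.424, b = 0.016). Five randomized starts
(seeded) guard against local minima. Normalization to Ω(10 cm) = 1 is
applied *after* the fit, since the input ratios are themselves ≈ 1 at the
reference field.

The fit's precondition requires ≥ 6 distinct field sizes spanning below
1 cm and reaching the reference field; "reaching" carries 5% slack
(≥ 9.5 cm) because the FWHM-measured size of a nominal 10 cm field can
land at 9.99 cm.

Discrete Ω uncertainties come from a seeded parametric bootstrap (default
500 resamples): model values perturbed by each point's SD, refitted from
the solution, SD taken over the ensemble. Rows at exactly S = 10 report
sd = 0 by the normalization constraint.

## Correction factors

k = Ω(S_clin)/ratio per detector and field, with SD from quadrature
combination of the Ω bootstrap SD and the ratio SD (independent sources).
The TRS-483 analytic form is fitted by SD-weighted least squares with b
parameterised as exp(log b) to keep it positive; d is fitted by default
but can be frozen (`fix_d`) since published practice is ambiguous about
whether it is a fitted coefficient. Points below 0.8 cm (configurable) are
excluded from the residuals — the analytic form does not follow measured
correction factors down to 0.5 cm — but kept in the output, flagged
`used = False`.

## t-tests

Two-sample t-tests are computed from (mean, SD, n) summaries; default
n = 3 per group (three film pieces / three readings per field) and Welch
variances with Welch–Satterthwaite degrees of freedom; the pooled variant
is provided for sensitivity analysis. One-tailed p-values test the
directional alternative mean2 > mean1. Published per-field p-values of
this kind are generally not reproducible from printed means and SDs alone
(the underlying df and pairing are unpublished), so the module reports its
own values rather than matching any specific table; the implementation is
verified against an independent summary-statistics t-test implementation.

## Synthetic campaigns

The dose model is separable: D(x, y) = D0·g(x)·g(y) with
g(u) = ½[erf((w/2−u)/(σ√2)) + erf((w/2+u)/(σ√2))], a rectangular
collimator opening w convolved with a Gaussian penumbra of width σ. For
w ≫ σ the centre is flat; for w of a few σ the axis dose is depressed and
the FWHM exceeds w — a surrogate for partial source occlusion that
reproduces the measured behaviour of equivalent squares exceeding nominal
sizes at 0.5 cm. Per-beam σ defaults (1.58–2.05 mm) were set once by
root-finding so each beam's simulated 0.5 cm field reproduces its measured
equivalent square; they are not re-tuned.

Readings are built from a planted truth curve (the shipped per-beam
parameters by default), the *exact* volume-averaging factor of the dose
model for each detector footprint (1D quadrature of g, no Gaussian
approximation — deliberately independent of the analysis path), and an
optional planted perturbation curve per solid-state detector:
ratio(S) = Ω_true(S)·k_vol,true(S)⁻¹·p(S)⁻¹, so the pipeline should
return Ω_true and k_true = k_vol,true·p. Scintillator channel pairs are
constructed so that subtracting the planted CLR × channel 2 recovers the
intended signal exactly; channel 2 grows with field size as a crude
fibre-irradiation surrogate. Default noise (relative 1 SD per reading):
film 0.8%, scintillator 0.5%, diodes 0.5% — consistent with the
percent-level uncertainties of published campaign tables. Three repeats
per clinical field; the reference field is emitted twice (pre/post
session) and pooled, mirroring bracketing reference measurements. All
randomness flows from one seed through spawned generators; regeneration
is bit-identical.

The default grid pitch is 25.4/150 mm (150 dpi scanning). Tests and
validation runs use 0.25–0.3 mm pitch — sizing and k_vol accuracy at
these problem sizes is pitch-limited well below the assertion tolerances,
and the full nine-field campaign then analyses in seconds.

What the simulator does *not* emulate: film graininess and scanner
artefacts, lateral/inter-scan response, occlusion physics beyond the
erf-core surrogate, energy dependence of detector response, and setup/
positioning errors. Passing recovery tests therefore demonstrates the
correctness and statistical calibration of the *analysis chain*, not the
accuracy of any physical detector model on real data.

## Known limitations

* Published per-detector correction-factor tables cannot be reproduced
  bit-exactly without the unpublished raw signal ratios; validation is via
  planted-truth recovery plus the identity constraints Ω(10) = 1 and
  k(10) = 1.
* The bivariate Gaussian is a local model of the central 3 mm × 3 mm only;
  its k_vol differs from the exact dose-model average by < 1e-3 at the
  field sizes where corrections matter, which is inside the quoted
  uncertainties but not zero.
* The equal-area square substitution (πr² = d²) is a convention, exact for
  square chips and a close approximation for circular footprints on
  near-Gaussian tops.
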