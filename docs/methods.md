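# Methods

This note documents the models, conventions and numerical choices behind
`aortapipe`, and what the synthetic-data experiments do and do not show.

## Synthetic cine model

Each participant's ascending-aortic lumen is rendered as a filled ellipse
whose area follows a raised-cosine systolic pulse occupying the first 40%
of the cardiac cycle (peak at 20%), moving from the diastolic area `a_d` to
the systolic area `a_s` and back; the remaining 60% of the loop rests at
`a_d`. This gives a single smooth systolic peak with well-separated
extremes, which is the property the max/min phenotype definition relies
on. Defaults (units in parentheses):

| parameter | default | why |
|---|---|---|
| image size / spacing | 192×192 px at 0.55 mm/px | lumen radius ≈ 25–30 px, large enough that the border-polygon area convention biases areas by ≲3% (see below) |
| n_frames | 100 | one cine loop per cycle |
| `a_d`, `a_s` ranges (cm²) | U(6.2, 8.2), U(7.0, 9.2), clipped to `a_s ≥ a_d` | population means ≈ 7.2 / 8.1 cm² |
| blood pressure (mmHg) | SBP ~ N(133.6, 17.8), DBP ~ N(78.9, 8.5), corr 0.666 | the correlation reproduces a pulse-pressure SD ≈ 13.7; SBP is floored at DBP + 5 |
| anthropometry | height N(170, 9) cm, weight N(76, 13) kg | BSA ≈ 1.9 ± 0.2 m² |
| age, sex | N(64.1, 7.5) clipped to [40, 85]; 48.4% male | late-middle-aged imaging cohort |
| area age/sex trends | +0.04 cm²/yr; +1.1 cm² male | makes the stratified reference table age- and sex-structured; both extremes shift jointly so the trend lowers distensibility with age |
| brightness | lumen 200, background 60 + smooth texture (amp 15), noise σ 2.5 | bright lumen on darker textured background lets a threshold segmenter work; σ_n on clean frames sits near 2.8, below the 4.1 QC cut |
| lumen edge | smoothstep ramp, 2.5 px | keeps the second spatial derivative at the wall small so the Immerkær estimator responds to noise, not anatomy |
| artefacts | 10% of participants prone; within them each systolic-phase frame affected with rate 0.3; uniform ±60 brightness inside the lumen | flow-void artefacts cluster within participants and in systole; affected frames give σ_n ≈ 15 ≫ 4.1 |

Ground truth records the analytic area schedule, the rendered masks, the
artefact frame indices, and the distensibility computed exactly from
`(a_s − a_d)/(a_d · PP)`. Per-participant RNG streams are derived by
hashing (global seed, participant id), so cohorts are reproducible and a
study can be regenerated in isolation bit-identically.

What the generator does **not** emulate: MR physics (no k-space, no
partial-volume or bias fields), breathing or through-plane motion,
non-elliptical lumen shapes, and any neighbouring anatomy. Passing tests
on this imagery therefore validates the *post-segmentation* measurement
and QC chain and the statistical layers — not segmentation of real CMR.

## Measurement conventions

Contours are traced through pixel centres by Moore border following
(8-connectivity, Jacob stopping criterion). Area is the shoelace area of
that polygon and perimeter its arc length (diagonal steps √2) — the
convention of classical contour-moment implementations, under which a
filled 10×10 block measures area 81 px² and perimeter 36 px. By Pick's
theorem the polygon area is smaller than the pixel count by about half the
boundary length, a deficit of order 1/r relative; at the default
resolution this is ≈3% on areas and mostly cancels in the distensibility
ratio (<2% after the max/min difference). The raw pixel count is exposed
alongside for diagnostics. Roundness is computed in pixel space, before
metric conversion; with anisotropic spacing a warning is attached and
length conversions use the mean spacing while areas always use the exact
spacing product.

The "smallest bounding ellipse" is read as the minimum-volume enclosing
ellipse, computed by Khachiyan's barycentric ascent with away steps
(duality-gap tolerance 10⁻⁷, iteration cap 500 after reduction to the
convex hull). Rasterized near-circular contours have many tied support
points, where the gap decays slowly; the cap bounds the minimality error
at roughly 0.1% of an axis, and a final inflation by the worst residual
guarantees containment exactly. A least-squares ellipse fit is available
as an alternative reading.

The Immerkær noise estimate uses the 3×3 kernel [[1,−2,1],[−2,4,−2],
[1,−2,1]] on the centred 80×80 crop, with the convolution evaluated only
where the kernel fits. The 4.1 exclusion threshold presumes an 8-bit-like
brightness scale (the generator's); it is configurable because real
acquisition scales vary.

## QC cascade

Rule order: frame-level first (empty mask → roundness < 0.85 → area < 3
cm² → area > 20 cm²; the first failure labels the frame), then
participant-level (more than 25% of frames failed, or mean |Δarea| over
consecutive *retained* frames > 0.3 cm² → all traits), then the noise rule
(any frame σ_n > 4.1 → systolic traits only), then covariate missingness
(BSA → area traits; blood pressure → distensibility). The 25% rule counts
frame-QC failures only, and the frame-difference statistic skips gaps left
by excluded frames; both points are deliberate choices where the
procedure is underdetermined. Tightening any threshold can only shrink
the included set (tested as a monotonicity property).

## Phenotypes and statistics

AAo_max/AAo_min are the extreme frame areas over retained frames — the
only operator consistent with "relative enlargement" in the
distensibility ratio. BSA uses Du Bois (0.007184·w^0.425·h^0.725) by
default with Mosteller selectable. The inverse normal transform is
Φ⁻¹((rank − 0.5)/n) with average ranks on ties and NaN passthrough; the
Blom offset (3/8) is available. Reference tables stratify by sex and the
age bins <55, 55–65, 65–75, >75 (left-closed). Report rounding follows
the clinical convention of one decimal for areas (cm²) and distensibility
(10⁻³ mmHg⁻¹).

ICC is fixed to ICC(2,1) — two-way random effects, single measure,
absolute agreement — the standard form for method comparison, with the
McGraw–Wong F-based confidence interval; a consistency form is available
behind a flag. Dice of two empty masks is defined as 1 with a flag so
callers can exclude such items.

## Genetics layer

The association scan is OLS on unrelated synthetic individuals
(Frisch–Waugh residualization, exact full-model degrees of freedom),
standing in for a mixed-model engine: relatedness and population structure
are absent from the generator by construction, so the mixed model's extra
machinery would be inert here. Variant filters: MAF ≥ 0.5%, INFO ≥ 0.3
when present. Clumping is greedy by ascending p (ties by position), with
R² ≥ 0.005 within ±5 Mb removed per lead; LD is the squared Pearson
correlation of dosages. Loci are leads ±1 Mb, merged across traits by
interval overlap keeping the lowest-p lead. Lambda is the median
association χ²₁ over 0.4549.

The summary-statistic simulator draws true instrument effects from
N(0, sd²) *conditioned on detectability* (|β| > 5.45·SE, the genome-wide
z), because MR instruments are genome-wide-significant leads by
construction; without this conditioning, near-null instruments whose
orientation is noise-scrambled attenuate the Egger intercept. Directional
pleiotropy is injected relative to the exposure-increasing allele — the
frame in which the Egger intercept is defined. Standard errors follow
1/√(2·maf(1−maf)·n).

## MR engine

Harmonization aligns outcome effects to the exposure's effect allele,
recognising direct, swapped and strand-complement reporting; palindromic
variants are dropped above MAF 0.42 (or when frequency is missing) and
aligned by frequency concordance below it. Instrument R² on the exposure
is 2·maf(1−maf)·β² (unit-variance phenotype); for binary outcomes the
log-odds effect is mapped to the liability scale, v/(v + π²/3) — an
approximation, flagged as such, used only to make the Steiger comparison
scale-consistent. Steiger removes a variant iff its outcome R² exceeds its
exposure R² *and* the two-sided z-test on the Fisher-transformed
correlations is significant at 0.05.

IVW uses zero-intercept weighted regression (weights 1/se_Y²) with
multiplicative random effects — SE inflated by √(max(1, Q/(k−1))) — and
normal-theory p-values; with one variant it reduces exactly to the Wald
ratio. MR-Egger orients instruments to β_X ≥ 0 (the estimator is not
orientation-invariant), uses the same weights, t-based inference on k−2
df, the same multiplicative SE floor, and reports Q′ and I²_GX (precision-
weighted dispersion of β_X; > 0.95 indicates low regression-dilution
risk). The Rücker rule selects Egger over IVW only when Q − Q′ exceeds the
χ²₁ 5% critical value *and* the intercept differs from zero at p < 0.05.
Weighted median interpolates the inverse-variance-weighted ratio CDF at
0.5; weighted mode maximizes a normal-kernel density with bandwidth
0.9·min(SD, MAD/0.6745)·k^(−1/5) times a user factor; both use parametric
bootstrap SEs (1000 replicates, recorded seed). CIs are normal-theory on
the log scale; odds ratios are exponentiated.

## Problem sizes and determinism

The shipped experiments use desk-scale sizes chosen to exercise every code
path with stable statistics: 200-frame fixtures for Dice, 100-participant
cohorts for agreement ICC, 40–60 participants for calibration-slope
checks, 200 replicates for IVW recovery and coverage, 100 for the Egger
intercept. All randomness flows from explicit seeds (global seed →
per-participant streams by CRC32 hashing; separate offsets per pipeline
stage), so every table in a run directory is reproducible, and run
directories are content-addressed by a configuration hash.

## Known limitations

* The baseline segmenter is a threshold-plus-components heuristic for
  synthetic imagery; it is not a substitute for a trained model on real
  CMR, and the Dice/ICC floors verified here say nothing about real-image
  segmentation accuracy.
* Binary-outcome R² and the latent-scale mapping are single-variant
  approximations; exposures are assumed inverse-rank normalized.
* The association layer assumes unrelated individuals and ignores
  imputation uncertainty beyond the INFO filter.
* Border-polygon areas carry the 1/r deficit discussed above; at
  substantially coarser resolutions than the default it becomes the
  dominant error in absolute (not relative) area phenotypes.
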