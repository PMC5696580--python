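# Methods

This note documents the models behind `osakit`, the defaults that matter,
and what the synthetic generators do and do not emulate.

## Cohort model

A cohort is a joint distribution over clinical variables (AHI, height,
age, cervical perimeter, BMI) and optional phenotypic feature blocks
(three craniofacial measurements; thirty vowel formant/bandwidth
variables, female reference only).

**Marginals.** Every variable is bounded by its published range. AHI is
modelled as a lognormal truncated to [0, range-max]: its published sd
exceeds its mean, which a (truncated) normal cannot produce, while a
lognormal is the standard choice for a non-negative, right-skewed event
rate. All other variables are truncated normals. In both families the
underlying parameters are *calibrated* — solved numerically (closed-form
truncated-lognormal moments; `scipy.stats.truncnorm` moments under a root
finder) so that the truncated distribution's mean and sd equal the
published descriptive values. The published tables describe observed,
in-range data, so matching the truncated moments (rather than plugging the
values in as untruncated parameters) is what makes sample means reproduce
the tables; the raw-parameter shortcut would bias, e.g., female weight by
about +1.4 kg and the TRS angle by −0.4°.

**Dependence.** A Gaussian copula targets a Spearman rank-correlation
matrix assembled from the published significant correlations (zero
elsewhere). Target ρ_S converts to the copula's Pearson parameter through
the exact relation r = 2·sin(πρ_S/6); because the marginal transforms are
monotone, the sample Spearman converges to ρ_S regardless of marginal
shape. Partially specified matrices can be indefinite; they are repaired
by clipping eigenvalues at 1e−6 and renormalizing to unit diagonal. A
matrix whose smallest eigenvalue is below −0.5 is rejected as an invalid
specification instead. On the shipped reference specs the clinical and
craniofacial blocks are already positive definite; the full
female block (38 variables) has a smallest eigenvalue of −0.045 and the
repair perturbs its cells by less than 0.01 (cross-checked against the
Higham nearest-correlation algorithm in the test suite).

**BMI and weight.** The package enforces the identity BMI =
weight/height(m)² exactly. To do that while still controlling the
published BMI correlations (which the craniofacial features depend on
strongly), BMI is a copula variable and *weight is derived* per subject as
BMI·height². Weight's own marginal and correlations are therefore
emergent; empirically the female derived-weight marginal lands at mean
78.0, sd ≈ 19 against the published 78.0 (18.0). The two published
correlation cells that reference weight directly (cervicomental ratio vs
weight) cannot be set and are left to be induced.

**Severity groups.** Group-conditional generation replaces marginal
mean/sd with per-group overrides and restricts the AHI support to the
group's window (control < 10, OSA ≥ 10, mild 10–30, severe > 30 events/h;
boundary values go to the higher-severity side of each cut). Every
generated subject's AHI is therefore consistent with its label by
construction. The published OSA-group female height of 150.9 cm (against
a control 162.3 and an overall mean 161.1) is treated as a typo; height
keeps its overall marginal in both groups.

## Vowel synthesis

Source–filter model: an impulse train at f0 (default 200 Hz female /
120 Hz male), white aspiration noise added *at the source* (default SNR
30 dB, a quiet-room headset level), a lumped −6 dB/oct glottal/radiation
tilt (one-pole filter, a = 0.95), and a cascade of second-order all-pole
resonators with pole radius exp(−π·BW/fs) and angle 2π·Fc/fs. Injecting
the noise at the source keeps the overall spectrum all-pole — as in real
phonation, where turbulence passes through the same tract — and is what
makes the waveforms usable as formant-tracking ground truth; adding flat
noise after the filter would drown the tilted spectrum's upper band.

Table-driven presets set F1–F3 and BW1–BW3 to the published female means
and append canonical female upper resonances F4 = max(3900, F3+500) Hz
(BW 350) and F5 = F4+800 Hz (BW 450). Real vocal tracts always carry
upper resonances; without them the spectrum above F3 is bare roll-off and
the F3 pole of back vowels degenerates.

## Formant analysis

Frames of 25 ms every 5 ms at 16 kHz (polyphase resampling on ingest);
per frame: pre-emphasis, window, autocorrelation LPC
(`scipy.linalg.solve_toeplitz`), polynomial roots, candidates kept inside
90–5500 Hz with pole bandwidth ≤ 600 Hz, lowest three assigned to F1–F3.
Frames more than 30 dB below the loudest frame, or yielding fewer than
three candidates, are marked unvoiced.

The steadiest 800-ms window of the voiced span is found by exhaustive
search, minimizing Σ_i sd(F_i)/mean(F_i) (normalization keeps F3 from
dominating); ties break to the earliest window. Estimates are means over
the window's voiced frames. Recordings whose voiced span is shorter than
800 ms fall back to the full voiced span and are flagged
`short-utterance`.

Two estimator presets emulate a dual-software cross-checking protocol
with one code path: A = per-vowel LPC order {a:12, e:14, i:12, o:12,
u:14}, Hamming window, pre-emphasis 0.95; B = fixed order 12, Gaussian
window, pre-emphasis 0.97. The per-vowel orders were calibrated once
against synthetic vowels with known resonances — the practice of choosing
the pole count from the vowel's formant structure — and a uniform order
16 at 16 kHz was measurably worse (harmonic capture biases F1 of /a/ by
≈3%). Per formant, estimates agreeing within 70 Hz (F1, F2) or 150 Hz
(F3) are averaged; beyond the threshold the formant is re-measured from
the −3 dB interval of the LPC spectral envelope of the selected segment
(the automated analogue of manual spectrogram review). The averaging of
in-threshold values is this package's documented choice.

**Accuracy, and what passing tests show.** On synthetic ground truth the
pipeline recovers F2 within 2% and F3 within 3% across the published
female formant ranges. F1 accuracy is governed by the ratio of the first
formant's bandwidth to the harmonic spacing: broad-BW1 /a/ tracks to 2%,
intermediate /o/ to 3%, and the narrow-BW1 vowels /e/, /i/, /u/ (BW1
22–69 Hz, less than one harmonic interval at any adult f0) carry an
irreducible nearest-harmonic bias, bounded at 5% in the tests and visible
as the ≈+7% F1 offset on /i/ at f0 = 200 Hz. Bandwidth estimates are
order-of-magnitude only (tested at 65% relative for true BW ≥ 100 Hz,
factor two below): pole bandwidths convolve with the ≈50-Hz main lobe of
the 25-ms analysis window and sample the harmonic comb. These are
properties of short-window LPC on voiced speech, not of the synthesizer;
real recordings add room noise, jitter/shimmer, and f0 drift that the
generator does not emulate, so passing tests bound estimator error under
clean stationary conditions only.

## Craniofacial geometry

All measurements operate in y-down pixel coordinates on uncalibrated
images. The cervicomental rectangle is axis-aligned, spanned by chain
landmarks 23 (bottom-left) and 11 (upper-right); the measured polygon is
the closed path 11→12→20→21→22→23→V (V the rectangle's bottom-right
vertex), its area by the shoelace formula. The ratio area(polygon)/
area(rectangle) is 0.5 for a straight-line contour and *decreases* as the
contour sags toward V — the fuller-neck direction — matching the intent
that the value falls as submental fat deposition rises. Chain points
outside the rectangle are clipped to it with a warning (the degenerate
case is not specified anywhere; clipping keeps the ratio defined).
No head-pose normalization is applied, mirroring an uncontrolled
photographic protocol; an optional pre-rotation by the tragion–ramus axis
is available but off by default.

The landmark generator starts from fixed hand-drawn mean shapes (24-point
profile, 52-point frontal schematic; the anatomical placement of the neck
chain follows this package's documented reading of the pictorial
definitions) and applies targeted deformations: stomion rotation about
the ramus for the TRS angle (closed form), a perpendicular sinusoidal
chain bulge solved by bisection for the cervicomental ratio, and
symmetric midface displacement for the face-width ratio. With zero jitter
the measurements round-trip to 1e−6 relative; Gaussian landmark jitter
emulates automatic-landmarking noise, and ground truth always refers to
the unjittered construction.

## Statistics

Spearman: midranks for ties, r as the Pearson correlation of ranks,
two-tailed p from the t approximation with n−2 df, exact permutation
enumeration for n ≤ 9. Strength labels follow the Fowler bins
(|r| < .2 very weak, < .4 weak, < .7 modest, < .9 strong, else very
strong); significance tiers at .05 and .01 two-tailed; rendered
correlation tables omit nonsignificant cells and mark tiers with
footnote asterisks.

Mann-Whitney U: midranks, U = R₁ − n₁(n₁+1)/2; exact enumeration of all
C(n₁+n₂, n₁) assignments when n₁+n₂ ≤ 12, otherwise the normal
approximation with tie and continuity correction. The approximation's
worst-case gap from exact over all attainable U is .0375 at n₁ = n₂ = 3,
shrinking with size — the exhaustive bound is asserted in the tests, and
the exact path makes it invisible to users at those sizes. No
multiple-testing correction is applied anywhere, matching the reporting
convention this package renders; treat the tables accordingly.

Matched subsets: covariate range filters followed by a verification
battery — Mann-Whitney on every clinical covariate (requiring p > α) and
on AHI (requiring p ≤ α) between the filtered control/OSA groups. The
shipped presets are age 41–55 with BMI ≥ 25 (female) and age ≤ 46 with
BMI 25–30 (male).

## Pipeline and reproducibility

All randomness flows from a single seed through `numpy` `SeedSequence`
spawning, so a fixed configuration reproduces byte-identical output
bundles. The acceptance script regenerates every reference quantity at
the sizes stated in its functions (cohorts of n = 5000, severity groups
of n = 2000 per group, 2000 landmark constructions, single 1.5-s
vowels) — sizes chosen so rank-correlation sampling error (≈1/√n) is well
inside the comparison tolerances.

## Known limitations

- The copula is Gaussian: it reproduces pairwise rank correlations but
  has no tail dependence and cannot encode the published correlations
  involving derived weight directly.
- Male vowel feature marginals are not published, so the male reference
  spec has no speech block.
- Narrow-bandwidth F1 and all bandwidth estimates are biased, as
  quantified above.
- The landmark generator produces schematic faces for geometry testing,
  not photorealistic or anatomically population-calibrated shapes;
  landmark jitter is isotropic Gaussian, while real automatic-landmarking
  errors are structured.
- Severity thresholds (10/30 events/h) are fixed by `SeverityPolicy`
  defaults and surfaced in configuration rather than hard-coded, but no
  alternative clinical conventions (e.g. 5/15/30) are bundled.
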