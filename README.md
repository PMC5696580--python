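# osakit

Speech and craniofacial phenotyping for obstructive sleep apnea (OSA)
cohorts.

OSA severity is measured by the apnea-hypopnea index (AHI, breathing-event
episodes per hour of sleep), obtained from an expensive overnight
polysomnography. Because OSA is linked to upper-airway anatomy, two cheap
proxies have been studied as screening signals: resonances of the vocal
tract measured on sustained vowel phonations (formant frequencies F1–F3
and their bandwidths BW1–BW3), and uncalibrated craniofacial measurements
taken from ordinary frontal/profile photographs. `osakit` packages that
analysis chain for researchers who want to study — or simulate — the
associations between AHI, clinical covariates (age, weight, height, BMI,
cervical perimeter) and these acoustic/facial features, with explicit
attention to sex differences.

The toolkit has four layers:

- **`osakit.cohort` / `osakit.vowels` / `osakit.landmarks`** — synthetic
  data generation. Cohorts are drawn from a Gaussian copula: each variable
  X_i has a bounded marginal F_i (truncated normal, or shifted lognormal
  for the right-skewed AHI) calibrated so its truncated mean/sd equal the
  published descriptive values, and the joint dependence targets a Spearman
  matrix ρ_S via the exact copula relation r = 2·sin(πρ_S/6), with
  eigenvalue-clipping repair when the assembled matrix is indefinite.
  Sustained vowels are source–filter synthesized (impulse train at f0 plus
  source-injected aspiration noise, cascade of second-order resonators with
  pole radius e^(−πB/fs)). Landmark sets (52-point frontal grid, 24-point
  profile with neck chain) are deformed from a mean shape to attain exact
  ground-truth measurements.
- **`osakit.acoustics`** — frame-wise autocorrelation LPC formant tracking
  (5-ms step, 25-ms window, 16 kHz), selection of the steadiest 800-ms
  segment of the phonation, averaging, and a dual-estimator protocol: two
  differently configured trackers are reconciled per formant, with
  disagreements beyond 70 Hz (F1, F2) / 150 Hz (F3) re-measured from the
  −3 dB interval of the LPC spectral envelope.
- **`osakit.craniofacial`** — the three photograph measurements:
  cervicomental contour ratio (area under the anterior-neck contour within
  its bounding rectangle; decreases with submental fat deposition),
  face-width ratio (midface width / interocular width), and
  tragion–ramus–stomion angle (mandibular retraction). All three are
  invariant to translation, rotation, and uniform scale.
- **`osakit.stats`** — Spearman correlation with Fowler strength labels and
  .05/.01 significance tiers, Mann-Whitney U contrasts (exact enumeration
  for small samples), AHI severity grouping (control < 10, mild 10–30,
  severe > 30 events/h), matched-subset construction with a verification
  battery, and paper-style table rendering.

`osakit.pipeline` ties the stages into one deterministic, seeded run, and
the `osakit` CLI exposes each stage (`simulate`, `extract-formants`,
`measure-face`, `analyze`, `run`).

## Worked example

```python
from osakit import cohort, stats, vowels, acoustics

# a 129-subject synthetic female cohort with craniofacial features
spec = cohort.build_reference_spec("female", features="craniofacial",
                                   n=129, seed=1)
df = cohort.cohort_to_frame(cohort.generate_cohort(spec))
res = stats.spearman(df.age, df.ahi, var_x="age", var_y="ahi")
print(f"age-AHI: r={res.r:.2f} (p={res.p:.4f}, {res.fowler}, tier {res.tier})")

# formant analysis of a synthetic sustained /i/
x, fs = vowels.synthesize_vowel(vowels.table_spec("i", seed=1))
est, report = acoustics.analyze_vowel(x, fs, vowel="i")
print(f"/i/: F1={est.F1:.1f} F2={est.F2:.1f} F3={est.F3:.1f} Hz "
      f"(source={est.source})")

# severity contrast on a clinical variable
labels = stats.assign_severity(df.ahi.to_numpy())
ctrl, osa = df[labels == "control"], df[labels == "osa"]
c = stats.mann_whitney(ctrl.cervical_perimeter, osa.cervical_perimeter,
                       group_names=("control", "osa"))
print(f"cervical perimeter control {c.means[0]:.1f} ({c.sds[0]:.1f}) vs "
      f"OSA {c.means[1]:.1f} ({c.sds[1]:.1f}) cm, U={c.U:.0f}, p={c.p:.3f}")
```

prints

```
age-AHI: r=0.42 (p=0.0000, modest, tier .01)
/i/: F1=394.8 F2=2600.6 F3=3168.8 Hz (source=averaged)
cervical perimeter control 35.9 (2.7) vs OSA 37.5 (2.8) cm, U=1352, p=0.002
```

At n=129 the sampled age–AHI rank correlation (here .42) scatters around
its generator target of .52; the /i/ formant estimates sit close to the
synthesis targets (F2 target 2620 Hz), with the familiar upward bias on
the narrow-bandwidth F1; and the severity contrast recovers the higher
cervical perimeter of the OSA group.

The same stages are available from the shell:

```sh
osakit simulate cohort --sex female --n 129 --seed 1 --out cohort.csv
osakit simulate vowel --vowel i --seed 1 --out i.wav
osakit simulate landmarks --view profile --trs-angle 113.2 --out lm.csv
osakit run --seed 1 --out bundle/
```

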