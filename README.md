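# eegmicrostates

Resting-state EEG **microstate analysis** as a tested, reusable Python
pipeline, with an application to comparing stroke patients against healthy
controls and relating microstate dynamics to clinical motor scales
(Fugl-Meyer Assessment, IADL).

A microstate is a quasi-stable scalp potential topography that persists for
roughly 60–120 ms before switching to another; resting EEG is dominated by
four canonical classes (A–D). The package implements the full analysis
chain and a synthetic-cohort generator with known ground truth, so every
stage has a recovery test:

1. **Segmentation** — global field power
   `GFP(t) = sqrt( Σᵢ (Vᵢ(t) − V̄(t))² / N )` and extraction of the
   topographic maps at GFP local maxima ("original maps").
2. **Clustering** — polarity-invariant *modified k-means*: similarity is
   the squared spatial correlation, the cluster centroid is the dominant
   eigenvector of the member maps; best of `n_restarts` by global explained
   variance (GEV). Model-order diagnostics (CV, dispersion W,
   Krzanowski–Lai) are reported for k = 3–8; resting-state analyses
   conventionally fix k = 4 and the prototypes are labeled A–D by optimal
   matching to canonical templates.
3. **Back-fitting** — winner-take-all assignment of every sample to the
   prototype with the highest |spatial correlation|, then temporal
   smoothing that absorbs segments shorter than 30 ms.
4. **Features** — per class: mean duration (Dur, ms), occurrence
   (Occ, 1/s), coverage (Cov), mean GFP, plus the zero-diagonal k×k
   transition-probability (TP) matrix. `Cov = Occ × Dur / 1000` holds
   exactly by construction.
5. **Statistics** — Welch's unequal-variance t-test per feature between
   groups, Pearson and age-controlled partial correlations of features
   against clinical scales within the patient group, two-factor
   ANOVA / ANCOVA, simple linear regression with R². All tests two-tailed,
   α = 0.05.

## Worked example

Simulate a 24-subject cohort (12 "patients", 12 "healthy"; 64 channels,
250 Hz, 60 s each) with the default planted effects — a 25 ms reduction of
the class-C mean duration in the patient group, a positive coupling of the
C→D transition probability with an FMA-like motor score, and a negative
coupling of Dur_A with a lower-limb score — and run the full pipeline:

```python
from eegmicrostates import PipelineConfig, run_pipeline

cfg = PipelineConfig.from_dict({
    "seed": 0,
    "simulate": {"n_per_group": 12, "duration": 60.0},
})
result = run_pipeline(cfg, out_dir="run0")
print(open("run0/report.txt").read())
```

The report the code prints for this config begins:

```
Microstate pipeline summary
===========================
subjects: 24 (12 patient / 12 healthy)

Group differences (Welch's t, two-tailed, alpha = 0.05):
  Dur_C: t = -3.782, df = 20.5, p = 0.0011
  Cov_C: t = -3.255, df = 16.1, p = 0.0049
  Cov_B: t = 2.265, df = 21.5, p = 0.0340

Scale correlations within the patient group (|p| < 0.05):
  C-D ~ fma_total: r = 0.9110 (p = 0.0000); age-partial r = 0.9100 (p = 0.0001)
  ...
```

The planted structure is recovered: the class-C duration is the strongest
group difference (patients shorter — the negative t means the
patient-group mean is below the healthy mean), coverage of C follows it
(Cov = Occ × Dur), and the C→D transition probability correlates
positively with the FMA-like score, essentially unchanged when age is
partialled out. With only 12 patients the sample correlation scatters
widely around its planted population value, and a few of the 28 uncorrected
tests reach p < 0.05 by chance — the same caveats that apply to a real
cohort of this size.

The same run is available from the shell:

```bash
eegms run-all --config cfg.yaml --out run0/
```

and every stage (`simulate`, `preprocess`, `segment`, `cluster`,
`backfit`, `features`, `stats`) is exposed as a subcommand operating on
the delimited-text artifacts, so any stage can be re-run from its
predecessor's output. All randomness flows from the explicit config seed;
reruns are byte-identical.

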