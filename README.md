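# spinetopo

Predicting the shape of the internal spinal column from skin-surface
landmarks.

Surface topography (3D non-contact surface scanning, 3DSS) is an appealing
radiation-free alternative to radiographs for assessing spinal posture and
curvature — but only if markers placed on the skin over the spinous
processes actually track the underlying bones. `spinetopo` implements the
analysis pipeline used to validate that premise on lateral-lying cohorts
imaged with both MRI and a surface scanner:

* **SCP vs FMP** — the *spinal column profile* (MRI spinous processes)
  against the *fiducial marker profile* (MRI skin markers): how far, and how
  differently curved, is the skin from the bone?
* **FMP vs 3MP** — the MRI skin markers against the *surface-scan marker
  profile* after rigid alignment into the MRI frame: how reproducible is the
  posture across the two modalities?

The geometric core: per subject and plane (sagittal / coronal), labeled
landmarks are projected into an anatomical frame (origin at the L1 marker,
antero-posterior axis along the substrate normal, cephalo-caudal axis toward
L1 from the mid-point of the PSIS markers), a 7th-order polynomial v(z) is
fitted to each source, sampled at 20 mm stations along the cephalo-caudal
axis, and compared by the root-mean-square distance (RMSD) at matched
stations. Curvature at each station comes from the plane-parametric-curve
formula

    k = |x'·y'' − y'·x''| / (x'² + y'²)^{3/2}

with finite-difference derivatives over the stations. Curvature (phase 1)
and coordinate (phase 2) distributions are compared with two-sample
Kolmogorov–Smirnov tests at α = 0.05; subject-level RMSDs are related to
BMI, age and gender (coded F = 1, M = 2) through a Pearson correlation
matrix; observer reliability of repeated landmark selections is quantified
per axis with ICC(2,1), where ICC > 0.81 is "almost perfect agreement".

Because such studies rest on private clinical images, the package ships a
first-class synthetic cohort generator (`spinetopo.synthetic`) that emulates
the measurement structure — a T1–L5 spinous-process chain with kyphosis /
lordosis and a mild coronal S-deviation, BMI-dependent posterior adipose
offsets with a left-lateral bias, a smooth postural-misalignment field
between modalities, and duplicate observer-selection sessions — so the whole
pipeline is testable end to end without any data download.

## Worked example

```python
from spinetopo import GeneratorConfig, generate_cohort, analyze_cohort

cfg = GeneratorConfig(n_subjects=50, seed=1)
demographics, landmark_sets = generate_cohort(cfg)
res = analyze_cohort(demographics, landmark_sets)

t = res.subject_table
sag = t["rmsd_overall_SCP_vs_FMP_sagittal"]
print(f"sagittal skin-to-bone RMSD {sag.mean():.2f} +/- {sag.std():.2f} mm")
print(f"subjects with left-lateral marker bias: {100*res.subject_left_fraction:.0f}%")
for e in res.correlations:
    if {e.var_a, e.var_b} == {"sagittal RMSD", "BMI"}:
        print(f"BMI vs sagittal RMSD: r = {e.r:.3f} ({e.strength})")
```

prints

```
sagittal skin-to-bone RMSD 22.05 +/- 2.94 mm
subjects with left-lateral marker bias: 100%
BMI vs sagittal RMSD: r = 0.895 (strong)
```

i.e. the skin markers sit ~22 mm posterior to the spinous processes, almost
always biased toward the subject's left, and the offset grows strongly with
BMI — the subcutaneous adipose layer, not marker error, dominates the
skin-to-bone distance.

A command-line interface wraps the same pipeline:

```sh
spinetopo simulate --out sim/ --n-subjects 50 --seed 1
spinetopo analyze --landmarks sim/landmarks.csv \
                  --demographics sim/demographics.csv --out results/
```

writing per-subject comparisons, the correlation matrix, KS summaries and a
run manifest as CSV/JSON.

## Documentation

`docs/methods.md` describes the model, the generator's assumptions and
calibration, numerical choices and known limitations.
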