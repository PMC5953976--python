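# petmtv

Metabolic tumour volume (MTV) on baseline FDG-PET is a strong prognostic
biomarker in diffuse large B cell lymphoma, but the number you get depends
on how tumour is delineated. `petmtv` is a tested, reusable pipeline for
nuclear-medicine researchers that implements three common SUV-thresholding
definitions of MTV, the statistics used to compare them, and the survival
analysis used to judge their prognostic value — exercised end-to-end on
synthetic phantoms and simulated cohorts with known ground truth.

**Segmentation methods** (thresholds inclusive, 26-connectivity default):

* *fixed25* — connected component of SUV ≥ 2.5 grown from an operator seed;
* *pct41* — within an operator-drawn constraining box, the component of
  SUV ≥ 0.41 × SUV<sub>max</sub> containing the maximum;
* *percist* — all components of SUV ≥ T, with T = 1.5 × mean + 2 × SD over
  a 3 cm³ liver VOI (or a 1 × 1 × 2 cm aortic VOI when the liver is
  involved), followed by operator editing of physiological uptake.

Per-lesion volumes are summed to the total MTV (cm³); TLG = Σ volume × mean
SUV per lesion.

**Agreement**: Kolmogorov–Smirnov (Lilliefors) normality pre-check,
cube-root transform, two-way mixed consistency ICC(3,1), Kendall's tau-b,
and non-parametric Bland–Altman (median bias; limits of agreement as the
2.5th/97.5th percentiles of paired differences).

**Prognosis**: ROC over all observed MTV cut-offs with the optimal cut-off
minimising (1−sens)² + (1−spec)², DeLong AUC confidence intervals,
Kaplan–Meier with 5-year read-offs, the log-rank test, and univariate Cox
hazard ratios (Breslow ties) for high- vs low-MTV groups.

## Worked example

Segment a two-compartment phantom lesion (hot core SUV 10 inside a warm rim
SUV 3, analytic volume 113.1 cm³) with all three methods:

```python
import petmtv as pm

lesion = pm.LesionSpec(center=(96, 96, 96), semi_axes=(30, 30, 30),
                       core_suv=10.0, rim_suv=3.0)
spec = pm.PhantomSpec(shape=(48, 48, 48), background_suv=0.3,
                      background_noise_sd=0.05, lesions=(lesion,),
                      liver_center=(40, 40, 60), liver_mean=1.0,
                      liver_sd=0.1, rng_seed=7)
img, truth, ann = pm.generate_phantom(spec)

ref = pm.liver_stats(img, ann["liver_center_mm"])
thr = pm.percist_threshold(ref, pm.PercistConfig())
print(f"liver mean={ref.mean_suv:.3f} SD={ref.sd_suv:.3f} "
      f"-> PERCIST threshold={thr:.3f}")
for rec in pm.segment_patient(img, ann, patient_id="phantom-01"):
    print(f"{rec.method:8s} MTV={rec.total_mtv:8.2f} cm3  "
          f"TLG={rec.tlg:9.1f}  lesions={len(rec.lesion_volumes)}")
```

prints

```
liver mean=1.020 SD=0.102 -> PERCIST threshold=1.734
fixed25  MTV=  114.62 cm3  TLG=    518.1  lesions=1
pct41    MTV=   24.90 cm3  TLG=    249.0  lesions=1
percist  MTV=  114.62 cm3  TLG=    518.1  lesions=1
```

The fixed-2.5 rule keeps the whole lesion (rim SUV 3 ≥ 2.5) and recovers
the analytic 113.1 cm³ to within ~1.5%. The 41% rule thresholds at
0.41 × 10 = 4.1, drops the rim and keeps only the hot core — the mechanism
by which this method yields systematically smaller volumes on heterogeneous
disease. This phantom's liver is low-uptake (mean ≈ 1.0), so the PERCIST
threshold (1.73) falls below 2.5 and the PERCIST volume is at least the
fixed-2.5 volume.

The same stages run from the shell:

```sh
petmtv all --out out --seed 3          # simulate → segment → compare → survival
petmtv survival --cohort-csv out/sim/cohort.csv --out out
```

`out/agreement.csv` holds the pairwise ICC / tau / Bland–Altman table and
`out/survival.json` the per-method AUC, optimal cut-off, 5-year PFS/OS by
MTV group, log-rank and Cox results on the simulated 147-patient cohort.

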