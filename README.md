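# mmpol — Müller-matrix polarimetry simulation and tissue classification

`mmpol` is a tested, end-to-end pipeline for studying whether raw
spectro-polarimetric measurements separate tissue classes that plain
intensity imaging cannot. It targets the setting of ex-vivo pancreatic
biopsy screening: a dual-rotating-retarder Müller-matrix polarimeter
images fresh specimens at five visible wavelengths, a pathologist's
annotations label pixels normal or abnormal, and a small MLP classifies
each pixel from the raw (normalized) Müller-matrix values — no
hand-crafted polarimetric parameters.

Because clinical polarimetry datasets of this kind are not public, the
package ships a first-class synthetic-data generator: multi-patient
cohorts of labeled tissue phantoms with class-dependent retardance,
depolarization and diattenuation, intra-patient correlation, unlabeled
annotation borders, saturated pixels, and optional label misregistration.
Everything downstream of the generator — instrument forward model,
Müller-matrix reconstruction, features, classifier, evaluation — is the
same code that would run on real acquisitions.

## The model

Light with Stokes vector **S** = (I, Q, U, V)ᵀ interacts with a sample
through its 4×4 real Müller matrix **M**: **S**′ = **M S**. The simulated
polarimeter probes **M** with a polarization state generator (fixed
polarizer + quarter-wave plate at angle kΔ) and analyzer (quarter-wave
plate at qkΔ + fixed polarizer, rotation ratio q = 5), recording

  I_k = g · a_kᵀ **M** s_k = (a_k ⊗ s_k) · vec(**M**),   k = 0 … N−1,

so the N = 36 counts per pixel and wavelength are linear in vec(**M**)
and all 16 elements are recovered by least squares against the N×16
design matrix. Per pixel this yields 16 × 5 = 80 raw values; scaling each
matrix by 1/M₀₀ and dropping the first element leaves the **75-dim
polarimetric feature vector** (pol). The **5-dim intensity vector**
(no-pol) is M₀₀ per wavelength — what a polarization-blind multispectral
camera would see. The classifier is a single-hidden-layer MLP (64 ReLU
units, logistic output, cross-entropy, Adam at 10⁻⁵, ten epochs).

Evaluation is patient-wise k = 4 cross-validation (all samples of a
patient share a fold), reporting per-fold pixel ROC/AUC, the confusion
summary at a fixed 0.43 threshold, and specimen-level AUC where a
sample's prediction is the p-th percentile (p = 50 … 99) of its pixel
scores and a specimen is abnormal if any annotated pixel is.

## Worked example

```python
from mmpol.workbench import default_config, run_pipeline, compare_modes

config = default_config(seed=1)          # 4 patients, 6 mixed 32x32 samples,
reports = run_pipeline(config, "demo")   # intensity-matched classes
for mode, r in reports.items():
    print(f"{mode}: mean pixel AUC {r.mean_auc:.3f} +/- {r.sd_auc:.3f} over {r.k} folds")
table = compare_modes(reports["pol"], reports["nopol"])
print(table.to_string(index=False))
```

prints

```
pol: mean pixel AUC 0.992 +/- 0.005 over 4 folds
nopol: mean pixel AUC 0.492 +/- 0.015 over 4 folds
 fold  auc_pol  auc_nopol  auc_difference
    0 0.983433   0.491835        0.491598
    1 0.991428   0.514165        0.477263
    2 0.995735   0.471945        0.523790
    3 0.996325   0.488110        0.508215
```

The demo cohort is *intensity-matched*: both classes share the same
reflectance distribution, so the 5-dim intensity features carry no class
signal by construction (AUC ≈ 0.5) while the 75-dim polarimetric features
separate the classes almost perfectly (AUC ≈ 0.99). That head-to-head
contrast — polarization information is what makes pixel-wise tissue
differentiation work — is the package's central reproducible property.
The run directory also receives the simulated raw stacks (TIFF),
reconstructed Müller images, feature tables (CSV), trained models (JSON),
per-sample probability maps (16-bit PNG) and a manifest with the
cohort's pixel accounting (here 6144 acquired pixels, 67 saturated,
3845 labeled+valid pixels used).

The same stages are available on the command line:

```bash
mmpol run-all --seed 1 --out demo
mmpol compare --pol demo/report_pol.json --nopol demo/report_nopol.json
```

## Layout

| module | role |
| --- | --- |
| `mmpol.mueller` | Stokes–Müller calculus and physical-realizability checks |
| `mmpol.instrument` | dual-rotating-retarder forward model, noise, saturation |
| `mmpol.reconstruct` | least-squares Müller-matrix recovery, identifiability |
| `mmpol.phantom` | synthetic multi-patient labeled cohorts, misregistration |
| `mmpol.features` | 75-dim pol / 5-dim no-pol feature tables |
| `mmpol.classifier` | single-hidden-layer MLP (sklearn-compatible estimator) |
| `mmpol.evaluate` | patient-wise CV, ROC/AUC, specimen percentile scoring |
| `mmpol.workbench` / `mmpol.cli` | config-driven orchestration and CLI |

See `docs/methods.md` for the modeling assumptions, parameter defaults
and known limitations.
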