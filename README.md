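# pntquant

Dual-convention left-ventricular (LV) quantification on synthetic short-axis
cine MRI, built around a question that matters in hypertrophic disease such
as Fabry cardiomyopathy: **should papillary muscles and trabeculations (P&T)
count as myocardium or as blood pool?**

The two standard contouring conventions disagree:

* **M<sub>inc</sub>P&T** — the endocardial border follows the blood–tissue
  interface; P&T with signal within 1 SD of the free-wall myocardial signal
  belong to the myocardium (structures thinner than 1.5 mm are not
  segmented). Cavity volumes are smaller, LV mass (LVM) larger.
* **M<sub>ex</sub>P&T** — the endocardial border is a smooth contour along
  the compacted myocardium; P&T fall inside the blood pool. Cavity volumes
  are larger, LVM smaller.

For both conventions the package computes LVEDV, LVESV, LVSV = LVEDV −
LVESV, LVEF = 100·LVSV/LVEDV, LVM (at end-diastole, slice-summation
volume × 1.05 g/ml), BSA-indexed LVM (Mosteller), and the P&T mass fraction
100·(LVM<sub>inc</sub> − LVM<sub>ex</sub>)/LVM<sub>inc</sub>. A through-plane
phase-contrast aortic velocity series provides the internal reference stroke
volume (net flow integral over an automatically detected vessel ROI), and a
statistics layer reproduces the study design: paired t-tests between methods,
Welch t-tests between groups, mean ± SEM cohort tables, Bland-Altman
agreement with 95% limits and the coefficient of repeatability, and a
simulated observer-repeatability analysis.

Because no clinical images ship with the package, a **digital cine phantom**
supplies the data: a truncated half-ellipsoid cavity in a myocardial shell,
papillary cylinders, sinusoidal trabecular ridges that compact into the wall
during systole, bSSFP-like contrast, partial-volume voxelization, Gaussian
noise, and a matched aortic velocity series whose forward integral equals
the true stroke volume. Cohort presets (`control`, `fabry`) are calibrated so
that simulated cohorts match the published group means (e.g. Fabry: blood
EDV 127 ml, LVM 178 g, EF 0.73, P&T fraction 20%). Exact analytic ground
truth accompanies every subject.

## Worked example

```python
from pntquant import (preset, build_phantom, segment_subject,
                      ventricular_measures, pnt_fraction,
                      body_surface_area, aortic_stroke_volume)

spec = preset("fabry").mean_spec                  # mean Fabry anatomy
cine, velocity, truth = build_phantom(spec, seed=3)
seg = segment_subject(cine)
bsa = body_surface_area(178.0, 80.0)
minc = ventricular_measures(seg, cine, "minc", bsa=bsa)
mex = ventricular_measures(seg, cine, "mex", bsa=bsa)
flow = aortic_stroke_volume(velocity)
print(minc.rounded())
print(mex.rounded())
print(f"P&T fraction: {pnt_fraction(minc.lvm, mex.lvm):.1f} %")
print(f"aortic SV: {flow.aortic_sv:.1f} ml (true {truth.true_sv:.1f} ml)")
```

prints

```
{'method': 'minc', 'lvedv': 126, 'lvesv': 34, 'lvsv': 92, 'lvef': 73, 'lvm': 177, 'pnt_fraction': 20, 'lvm_indexed': 89}
{'method': 'mex', 'lvedv': 160, 'lvesv': 55, 'lvsv': 105, 'lvef': 66, 'lvm': 141, 'pnt_fraction': 0, 'lvm_indexed': 71}
P&T fraction: 20.2 %
aortic SV: 92.7 ml (true 92.7 ml)
```

Reading the numbers: including P&T (`minc`) the stroke volume (92 ml) agrees
with the aortic flow reference (92.7 ml) to a fraction of a millilitre;
excluding them (`mex`) overestimates it by ~12 ml, because ~11 ml of
trabecular tissue that is inside the smooth contour at end-diastole has
compacted into the wall by end-systole. P&T account for 20% of this
hypertrophic ventricle's mass, so the convention also shifts LVM by 36 g.

## Command line

```bash
pntquant simulate --group fabry --n 20 --seed 42 --out sim/      # NIfTI + manifest
pntquant quantify --data sim/ --subject fabry000                 # both methods, JSON
pntquant flow     --data sim/ --subject fabry000                 # aortic SV
pntquant run --n-control 20 --n-fabry 20 --seed 42 --out run/    # full study bundle
```

`run` writes per-subject measures (CSV), a mean ± SEM method-comparison
table with p-values (CSV/JSON), flow-concordance and Bland-Altman JSON, and
optionally reclassification counts against a user-supplied indexed-LVM
cutoff. Identical seed and config reproduce byte-identical outputs.

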