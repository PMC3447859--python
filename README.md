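# ihcquant

Quantification toolkit for DAB-immunohistochemistry sections and the
companion assay statistics of an antitumor-peptide study, exercised entirely
on synthetic data with known ground truth.

It is aimed at researchers who quantify brightfield micrographs of tumor
sections developed with the brown peroxidase chromogen DAB
(3,3′-diaminobenzidine) over a blue hematoxylin counterstain — e.g. Ki67
for proliferation or CD34 for vessel density — and who accompany that with
standard antitumor assay arithmetic: dose-response GI50, LDH-release
cytotoxicity, soft-agar colony counts and caliper tumor-growth curves.

## What it computes

**Stained-section segmentation** (`ihcquant.segment`). For a field *I* with
channels (R, G, B) in [0, 1]:

1. flat-field correction: `I ← I / max(F, ε) · mean(F)` per channel, with
   *F* a light-field acquisition of the empty optical path;
2. non-specific-signal suppression: pixels whose hue lies outside the
   DAB-brown (10–50°) and hematoxylin-blue (200–260°) sectors are
   desaturated;
3. adaptive red/blue contrast `C = αR − (1−α)B`: each α on a grid is scored
   by the normalized between-class variance at its isodata threshold
   (zeroed when the would-be positive class is not DAB-red); a
   four-parameter logistic of metric vs α picks α*;
4. band-pass background removal: difference of Gaussians with
   σ = structure-size/2 between the small (2 px) and large (80 px) scales;
5. isodata (Ridler–Calvard intermeans) threshold *T* on the 8-bit rescaled
   contrast; pixels strictly above *T* are positive;
6. artifact rejection: 8-connected objects are kept iff
   `mean R ≥ τ · mean B` (τ = 1.15) and area ≥ 20 px.

The result carries the mask, α*, *T*, positive area (px and µm²), area
fraction and object counts; groups of fields are summarized as mean ± SD/SEM
with an unpaired two-tailed Student t-test (`* p<0.05, ** p<0.01,
*** p<0.001`).

**Assay statistics** (`ihcquant.stats`). Four-parameter logistic
`y = bottom + (top − bottom) / (1 + (EC50/x)^h)` fitted by least squares
with closed-form GI50 inversion at half the untreated-control mean; LDH
percent cytotoxicity `100 · released/total`; caliper tumor volume
`V = 4/3·π·R₁²·R₂` (R₁ ≤ R₂); percent inhibition
`100 · (1 − treated/control)`; percent of control.

**Synthetic data** (`ihcquant.synth`). Ground-truthed DAB/hematoxylin
fields (elliptical DAB blobs over nuclei, smooth illumination, Gaussian
noise) and tabular generators for dose-response, LDH plates, caliper series
and Poisson colony counts. Named presets pin the effect sizes the pipeline
is expected to recover; see `docs/methods.md`.

## Worked example

```python
import numpy as np
from ihcquant import synth, segment, stats

# a two-group staining study: 6 control + 6 treated fields, 512x512
control, treated = synth.generate_ihc_study("ki67-fig3c", 6, seed=42)
c = [segment.segment_field(f).positive_area_um2 for f, _ in control]
t = [segment.segment_field(f).positive_area_um2 for f, _ in treated]
summary = stats.summarize_groups(c, t)
print(f"decrease {summary.percent_change:.1f}% "
      f"(p={summary.p_value:.2g} {summary.stars})")
# -> decrease 35.9% (p=4.3e-21 ***)

# GI50 from a noise-free synthetic proliferation curve (true GI50 1.24 uM)
curve = stats.FourPLFit(bottom=0, top=1000, ec50=1.24, hill=-1.5)
tab = synth.generate_dose_response(curve, [0, 0.1, 0.3, 1, 3, 10, 15], cv=0)
fit = stats.fit_4pl(tab.dose_uM, tab["count"])
print(round(stats.gi50(fit, tab.loc[tab.dose_uM == 0, "count"].mean()), 3))
# -> 1.24
```

The 35.9% measured decrease is the pipeline's end-to-end recovery of the
36% ground-truth difference in DAB-positive area encoded in the
`ki67-fig3c` preset; the GI50 line shows the fit-and-invert machinery
returning the curve's generating value.

An end-to-end demo run (simulate → quantify → fit → report) is available
from the shell:

```bash
ihcquant run --seed 5 --out demo_run
ihcquant simulate ihc --preset cd34-fig3d --seed 1 --out fields
ihcquant quantify --images fields --out quant
```

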