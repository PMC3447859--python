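# Methods

## Scope and data model

The package reproduces, on synthetic ground-truthed inputs, the
quantitative layer of a DAB-immunohistochemistry antitumor study: a
stained-section segmentation pipeline and the surrounding assay statistics.
No raw micrographs or tables exist for the original experiments, so all
absolute levels here are design values; only the control-vs-treated
*ratios* encoded in the presets are treated as quantities the analyses must
recover. Passing tests therefore demonstrate that the machinery measures
what it is pointed at — not that it would reach the same accuracy on real
tissue (see Limitations).

## Synthetic IHC fields

A field is composed as a near-white background (0.92, 0.90, 0.90), circular
hematoxylin nuclei (0.35, 0.35, 0.65), and elliptical DAB blobs
(0.42, 0.28, 0.14) painted on top, so the ground-truth positive mask is
exactly the union of blob ellipses and nuclei never count as positive.
Stain colors are literature-typical hues rendered as RGB; they are
configurable because acquisition color balance varies between microscopes.
The image is multiplied by a smooth illumination surface (sum of three
low-frequency cosines, normalized so max/min equals the configured
peak-to-trough ratio, default 1.2) and perturbed by zero-mean Gaussian
intensity noise (default SD 0.02), then clipped to [0, 1]. Gaussian rather
than Poisson shot noise is used deliberately: at 8-bit brightfield exposure
levels the distinction is immaterial for thresholding, and a single SD knob
is easier to reason about.

Blobs are added one at a time (axes ~ Normal(12, 3) px, uniform
orientation, centers kept one blob-radius inside the border so the analytic
ellipse area π·a·b matches the rasterized mask) until the positive area
reaches the requested fraction; the final blob is shrunk by bisection so
the realized fraction lands within a 0.5% working tolerance (the contract
is 10% relative). An unreachable fraction — too few / too small blobs —
raises an error naming the constraint. The illumination surface depends
only on (width, height, gradient, seed), so the matching light-field image
can be regenerated independently via `generate_flatfield`, mimicking a
flat-field acquisition of the optical path.

Every generator is a pure function of (parameters, seed); per-field seeds
in a study are spawned from the master seed with `numpy` `SeedSequence`.

## Presets

| preset | encodes | design values |
|---|---|---|
| `ki67-fig3c` | proliferation-marker area decrease 36% | fractions 0.25 → 0.16 |
| `cd34-fig3d` | vessel-marker area decrease 24% | fractions 0.10 → 0.076 |
| `ldh-fig4a` | LDH release plateaus from 3 h | released/total 0.02 / 0.15 / 0.80 |
| `colony-fig1b` | colony suppression | Poisson means 30, 7.5 (0.1 µM), 1.5 (1 µM), 0 (≥ 2.5 µM) |
| `tumor-fig3a` | endpoint volume inhibition 55% | ratio 0.45, lognormal CV 0.6 |

Invented absolute levels: the LDH total signal (2.0 a.u.), the early
(pre-3 h) released fractions 0.06 and 0.30, the 1 µM colony mean (1.5),
the xenograft enrollment volume (25 mm³), control endpoint (500 mm³),
duration (47 d, 14 caliper sessions) and spheroid aspect ratio R₂/R₁ = 1.3.
Each mouse grows exponentially from the enrollment volume to an endpoint
`group_mean · L` with `L` lognormal of mean 1 and CV 0.6, so the treated /
control endpoint-mean ratio is exact in expectation and the large
between-animal dispersion of xenografts is reproduced.

## Segmentation pipeline

Stages and their tunables (`SegmentationConfig`):

- **Flat-field correction** — `out = in / max(F, 10⁻³) · mean(F)` per
  channel, clipped to [0, 1]; preserves each channel's spatial mean when no
  clipping occurs. The floor guards against dead flat-field pixels.
- **Non-specific suppression** — HSV transform; hue sectors kept: DAB
  10–50°, hematoxylin 200–260° (defaults chosen to bracket the two stain
  hues the later red/blue sorting assumes); off-sector saturation scaled by
  0 by default. Gray pixels are a fixed point; the operation is idempotent.
- **Adaptive contrast** — grid α ∈ {0, 0.05, …, 1}. Candidate score:
  normalized between-class variance (Otsu's η) at the candidate's isodata
  threshold, computed on the min-max 8-bit rescale of `C = αR − (1−α)B`.
  Polarity gate: the score is zeroed unless the above-threshold class
  itself reaches the artifact filter's red/blue cutoff — the positive class
  must be DAB-like. Without this gate the metric is polarity-blind and at
  high α the threshold can split the gray background by illumination,
  selecting the background as "positive". A 4PL curve is fitted to metric
  vs α and α* is the grid point maximizing the fitted curve (ties toward
  larger α, favoring the red axis). Metric curves are typically step-like,
  which drives the fitted Hill slope to a boundary; such fits, and any fit
  whose argmax would give up more than 5% of the best raw-grid
  separability, fall back to the exhaustive grid argmax — the grid is the
  oracle the fitted shortcut must agree with.
- **Band-pass** — difference of Gaussians, σ = structure-size/2 with
  defaults 2 px and 80 px; output recentred to exactly zero mean. The DoG
  transfer `exp(−2π²σ_s²f²) − exp(−2π²σ_l²f²)` retains ≥ 70% of amplitude
  at mid-band periods and ~7% at eight times the large scale.
- **Isodata threshold** — iterative intermeans on the 256-bin histogram,
  starting from the truncated overall mean and updating
  `T ← int((mean_≤T + mean_>T)/2)`; truncation (not round-half-even) is the
  convention, so equal spikes at 0 and 255 give T = 127. Single-level
  histograms raise a degenerate-field error. Pixels strictly above T are
  positive.
- **Artifact rejection** — 8-connected objects kept iff
  `mean R ≥ τ · mean B` on the flat-field-corrected image (τ = 1.15,
  boundary inclusive — the comparison is linear, avoiding the asymmetry a
  division epsilon would introduce) and area ≥ 20 px. τ and the minimum
  area are justified purely by synthetic-data performance. Boundary objects
  are kept; degenerate fields are excluded from summaries, never imputed.

The pipeline contains no randomness; identical inputs give identical masks.
Because every stage after flat-field correction is invariant to a global
intensity scale (hue/saturation, the linear contrast, min-max rescaling),
segmenting a shaded scene with its known light field reproduces the
unshaded mask.

## Dose-response fitting and GI50

Model: `y = bottom + (top − bottom) / (1 + (EC50/x)^h)`, the concentration
form in which a negative Hill slope is an inhibition curve and the dose-0
limit is `top`. Fitting is Levenberg–Marquardt least squares with EC50 in
log-space; initialization: top = mean response at dose 0, bottom = mean at
the maximal dose, EC50 = geometric mid-dose, h = −1; tolerances 10⁻¹².
Requirements: ≥ 4 distinct doses including 0. Flat responses raise
(EC50 unidentifiable); |h| > 25 flags the fit as non-converged rather than
returning a silently arbitrary step fit. GI50 is the closed-form solution
of `y(x) = control_mean/2`; if the target response is outside the fitted
asymptotes, or beyond 10× the tested dose range, the computation fails
with "GI50 not reached" — the honest analogue of assay reports quoting no
GI50 up to the maximal dose. When bottom = 0 and top equals the control
mean, GI50 = EC50 exactly.

## Group statistics

SD uses ddof = 1; SEM = SD/√n; both are always computed (report layers may
quote either). The two-group test is Student's pooled-variance unpaired
two-tailed t-test — chosen over Welch because the modeled study names only
"unpaired two-tailed t-test", with Welch available behind a flag — with
stars `*** p<0.001, ** p<0.01, * p<0.05`. Zero variance with equal means
returns p = 1. Caliper radii are canonicalized by sorting (R₁ ≤ R₂) with a
logged warning rather than rejected, since calipers do not guarantee axis
order.

## Problem sizes

Default verification sizes: staining studies use 6 fields per group at
512×512 (the conventional six random fields per section); unit and
property tests use 128–256 px fields; the colony and tumor checks use 1000
wells/dose and 200 mice/group, where Monte-Carlo error on the reported
percentages is well under the tolerances quoted for them.

## Limitations

- Synthetic fields are flat-textured constant-color shapes; real tissue has
  stain-intensity gradients, chromogen co-localization, touching
  counterstained structures and out-of-focus blur, none of which are
  modeled. Performance figures here bound the algorithmic, not the
  biological, error.
- The quantification is area-based; no per-cell positivity scoring or
  nucleus counting is attempted.
- Stain separation uses fixed hue sectors and a red/blue ratio, not
  data-driven stain-vector estimation; strongly shifted color balance
  requires reconfiguring the sectors.
- The LDH step profile is piecewise-constant in time; kinetics between 0.5
  and 3 h are not modeled beyond the two plateau levels.
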