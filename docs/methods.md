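# Methods

## Scope and design

`endoprofile` re-implements, at analysis level, an MRI + biochemistry
pipeline for profiling endothelial function in atherosclerotic
(ApoE/LDLR⁻/⁻) mice. It starts from reconstructed magnitude images and
finished plasma concentration tables; pulse-sequence programming,
retrospective self-gating reconstruction, LC-MS/MS signal processing and
plaque assessment are out of scope. Because no imaging data were deposited
with the study it emulates, the package's synthetic generators are
first-class components with exact ground truth, and all quantitative claims
the test suite makes are claims about recovery of that ground truth.

## Vessel phantom

The phantom is a branched tube in scanner (mm) coordinates: a main vessel
sampled along the slice axis with per-point radius, one branch appearing at
a configurable slice, a wall of fixed thickness, and a perivascular rim
defined as a fixed-thickness shell (default 2 in-plane voxels) outside the
wall. Choices worth knowing:

- **Ach response encoding.** `dilation_factor` multiplies the end-diastolic
  lumen *volume* between the pre- and post-Ach states; radii scale by its
  square root. 0.9282 therefore encodes a −7.18 % response.
- **Pulsation.** Radius is modulated sinusoidally over the cardiac cycle,
  `r(f) = r₀·(1 + a·(1 − cos 2π(f − f_d)/n)/2)`, with its minimum (exactly
  r₀) at the designated diastolic frame `f_d` (default frame 4 of 7).
  Default amplitude a = 0.08.
- **Tilt/dither.** The centerline drifts in-plane by (0.071, 0.043) mm per
  slice. Real vessels are not grid-aligned, and the incommensurate drift
  also varies the sub-voxel phase per slice so that pixel-count
  quantisation errors of the 5-slice volume average out; without it the
  recovered percent change carries a deterministic quantisation bias of up
  to ~1 pp.
- **Default lumen radius 1.25 mm.** At the functional protocol's 0.117 mm
  in-plane pitch this gives ≈ 360 lumen pixels per cross-section, keeping
  the discretisation error of pixel-counted areas below ~0.3 % — small
  against the smallest encoded response (±2.39 %). Smaller, more
  BCA-realistic radii degrade volumetric precision roughly linearly in
  1/r and are available as a parameter.
- **Rendering.** Cine frames are rendered with a linear partial-volume ramp
  one in-plane pixel wide across each compartment boundary, so edge pixels
  mix intensities as reconstructed magnitude images do and half-maximum
  thresholding finds the boundary with sub-pixel accuracy. The VFA series
  is rendered from hard labels: each voxel's noiseless intensity is exactly
  the SPGR signal of its compartment, which is what makes the noiseless
  Npx50 worked examples exact.
- **Cine contrast.** In the gated bright-blood angiogram, compartments carry
  apparent intensities (blood 100, wall 25, rim 30, background 20, a.u.)
  rather than SPGR-predicted ones: inflow enhancement, not T1 recovery,
  dominates blood signal in vivo, and the wall appears dark. SNR is defined
  as blood intensity over the Rician σ.
- **Noise.** Magnitude noise is Rician (`sqrt((S+n₁)² + n₂²)`,
  n ~ N(0, σ²)); background-only voxels are Rayleigh, which the suite
  verifies by a KS test. A plain Gaussian model exists for debugging.
- **Tissue T1 defaults** (9.4 T, configurable; the emulated study reports
  none): blood 1900 ms pre / 400 ms post contrast, wall 1200 ms unchanged,
  perivascular 1200 ms with leaky voxels shortened to 500 ms, background
  900 ms. The contrast agent only ever shortens T1 (enforced).
- **Leak model.** Exactly `round(leak_fraction × n_rim)` rim voxels, chosen
  reproducibly from the seed, take the shortened post-contrast T1. There is
  no pharmacokinetics; contrast uptake is encoded directly as T1 values.

## T1 mapping

`spgr_signal` implements the ideally spoiled steady state
`S = M0 sin α (1−E)/(1−E cos α)`, `E = exp(−TR/T1)`; it matches an
iterative Bloch rotation–relaxation oracle to 1e−12. Fitting uses the
classic linearisation (S/sin α regressed on S/tan α; slope = E) followed by
default nonlinear least-squares refinement of the exact model started from
the linear estimate. Policies:

- Slopes outside (0, 1) (non-physical E), all-zero signals, and estimates
  outside (0, 10 s] are *undefined* with a coded reason — never clamped and
  never zero-filled — and undefined pixels are excluded from every
  downstream statistic (a zero would masquerade as a 100 % T1 change).
- Flip angles are taken as nominal; B1 inhomogeneity is not modelled
  (documented limitation; the acquisition sets angles by pulse length).
- Noiseless round trips are exact to 1e−6 relative over the acquisition's
  eight angles (2°–50°, TR 10 ms); at SNR 50 the T1 bias at 1000 ms is
  < 2 % over 200 noise draws.

## Npx50 permeability statistic

`relative_t1_change = (T1_pre − T1_post)/T1_pre` (per pixel, both maps
defined), and `npx50` counts ROI pixels with change **strictly** greater
than the threshold (default 0.50). Decisions: the counted direction is a T1
*decrease* (the agent shortens T1; an absolute-change mode exists because
"changed" is ambiguous); the denominator is the pre-contrast T1; the ROI is
the morphological dilation of the lumen minus the lumen, computed slice-wise
(slices are thick relative to pixels); excluded-pixel counts are reported.
Group summaries of Npx50 use the median (a count with skewed group
distributions, analysed non-parametrically). Npx50 for multi-slice stacks
is summed over the stack.

## Vasomotor analysis

Per scan: (1) the diastolic frame is the frame of minimal total segmented
lumen area (ties → lowest index; single-frame cines return 0); (2) the
analysis range is the five contiguous slices ending immediately before the
first slice whose thresholded lumen mask splits into two connected
components (the branch), overridable; (3) each slice is thresholded at the
fraction (default 0.5) of the way from the background level (slice median)
to the lumen peak (99.9th percentile), per slice; the component containing
or nearest the seed point is kept and hole-filled; area = pixel count ×
pixel area; (4) volume = Σ area × slice thickness (rectangular rule). The
slice range is determined on the pre-Ach scan and reused for the post scan
(the acquisition is co-registered); Otsu thresholding is available as an
alternative. The suite checks end-to-end recovery of dilation factors
encoding −10 % … +9.3 % to ±0.5 pp noiseless and ±1 pp at SNR 30 (5 seeds
in-suite; the acceptance script uses 20).

## Plasma cohort generator and statistics

Per-animal concentrations are drawn from a zero-truncated normal with the
group's location and SD = SEM·√n, so simulated group means recover the
specified location with the specified SEM; a log-scale
(median-parameterised) variant serves right-skewed, count-like endpoints.
The shipped reference tables use the published absolute means/SEMs where
printed (Ang II 119.8 ± 11.3 → 85.5 ± 5.4 / 50.2 ± 4.1; Ang III
206.2 ± 15.5 → 130.4 ± 10.0 / 96.2 ± 8.7 fmol/ml) and published percent
changes applied to plausible baselines elsewhere. Unprinted dispersions
default to SEM = 10 % of location for angiotensin peptides and 5 % for
amino acids (typical for such LC-MS panels). Amino-acid baselines (L-Arg
75, L-Cit 60, L-Orn 50, ADMA 0.80, SDMA 0.30, Met 45, Hcy 5.5 µmol/L) are
literature-plausible placeholders; every percent-change endpoint is
invariant to them. The 2-month amino-acid locations are calibrated so the
group-location L-Arg/ADMA ratio reproduces the reported 2-month shifts
(×2.07 MNA, ×2.40 perindopril) together with the reported ADMA decreases
(−15 % / −20 %); the reported 1-month and 2-month percent changes cannot
all hold simultaneously, and the 2-month ratio shift is the headline
number, so it wins the calibration.

Group comparisons: Kruskal–Wallis (tie-corrected) with Dunn's z-tests and
Holm adjustment as post hoc (the emulated analysis names no post-hoc test;
Dunn–Holm is the standard companion), or one-way ANOVA with Tukey's HSD;
per-group Kolmogorov–Smirnov normality checks are recorded either way.
Spearman correlations are rank-Pearson with average ranks; the suite pins
both Kruskal–Wallis and Spearman to brute-force oracles.

A coupled cohort generator draws a latent per-animal endothelial-health
score that jointly drives the vasomotor response (up), Npx50 (down) and the
two protective ratios (up), with group-level shifts placing untreated
animals at −7.18 % median response and Npx50 ≈ 15; this reproduces the
published correlation sign pattern ({volume change, Npx50} ×
{L-Arg/ADMA, Ang-(1–7)/Ang II}, plus volume change × Npx50).

## What the synthetic data do and do not show

The phantom emulates geometry, partial volume, pulsation, contrast-driven
T1 change and Rician noise. It does **not** emulate motion and gating
artefacts, B1/B0 inhomogeneity, flow-related signal variation within the
lumen, intensity inhomogeneity across the FOV, or anatomically irregular
lumen shapes; plasma panels assume independent analytes within animal
(except the deliberately coupled cohort). Passing tests therefore
demonstrate correctness of the estimators and their noise robustness under
the stated model — not performance on artefact-laden in vivo data.

## Numerical and interface choices

0-based slice/frame indexing; arrays ordered (slice, row, col[, frame]);
physical units (mm, mm², mm³, ms) carried in all outputs; NIfTI is the
canonical volume format with voxel size in the header (round-trip to 1e−6
mm) and JSON sidecars for protocol/angle metadata; plasma panels are
long-format CSV. Every stochastic stage consumes an explicit integer seed
(configs without a seed refuse to run) and all outputs are bit-reproducible
given config + seed. Decimal-comma correlation values in the emulated
study's table are read as decimal points. The problem sizes used by the
test suite (reduced 96×96×12 phantoms for unit tests, full 256×256×30
phantoms with 5–20 noise seeds for end-to-end checks, 200-seed panels) were
chosen as the smallest sizes at which each claim is sharp.
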