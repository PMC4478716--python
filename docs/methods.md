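# Methods

`densestrain` measures regional left-ventricular (LV) deformation from
DENSE (Displacement Encoding with Stimulated Echoes) cardiac MRI and asks
whether reduced deformation identifies myocardial segments with a large
scar burden. This note documents the models, the numerical choices, what
the synthetic phantoms do and do not emulate, and the known limitations.

## Signal model: displacement in the phase

After a DENSE encoding block, the in-plane tissue displacement `u`
accumulated since encoding is stored in the per-voxel signal phase,

```
phi_d = 2*pi * ke * (e_d . u_px) + phi_bg,
```

where `e_d` is the unit encoding direction, `u_px` the displacement in
pixels, `ke` the encoding strength in cycles/pixel (default 0.30: one full
phase cycle per ~3.33 px of displacement) and `phi_bg` a background phase
shared by all directions (coil phase, off-resonance). We use balanced
multipoint encoding: three directions at 0°, 120° and 240° whose unit
vectors sum to zero. Pairwise phase differences then cancel `phi_bg`
exactly and carry effective encoding vectors `e_i − e_j`.

The observed phase is wrapped into `(-pi, pi]` (the boundary convention
keeps +pi). Complex Gaussian noise with per-channel standard deviation
`magnitude / SNR` is added to the complex signal, giving a phase noise of
~`1/SNR` radians at high SNR.

### Reconstruction

1. **Differencing.** Two independent wrapped difference maps are formed
   from the pairs (0,1) and (1,2); background phase cancels here, so only
   two maps need unwrapping.
2. **Unwrapping.** Quality-guided region growing: quality is the inverse
   of the 3×3-window variance of the wrapped phase gradients; growth
   starts at the highest-quality pixel (which keeps its wrapped value) and
   absorbs neighbours in order of decreasing quality, each receiving its
   neighbour's value plus the wrapped difference (so jumps along the
   growth path stay within ±pi; a true jump of exactly pi resolves to
   +pi). Disconnected mask components are unwrapped independently from
   their own seeds and flagged.
3. **Cycle anchoring.** The data determine each unwrapped map only up to a
   global multiple of 2*pi. `reconstruct_displacement` shifts each map so
   its mask-mean phase lies in `(-pi, pi]`. This assumes the in-plane
   displacement is approximately zero-mean over the myocardium, which
   holds for contraction and twist about the cavity centre (radial and
   tangential fields have zero mean projection on any fixed direction).
   Fields with a large bulk translation would need a different anchor.
4. **Decoding.** Per pixel, `2*pi*ke*(E_eff u_px) = phi_diff` is solved in
   the least-squares sense (exactly determined for two difference maps)
   and converted to millimetres by the reconstructed pixel spacing
   (1.36 mm by default).

Displacement is expressed at the *reference* (encoded, end-diastolic)
positions, so all strain derived from it is Lagrangian by construction.

## Strain

The deformation gradient is estimated per pixel by a weighted linear
least-squares fit of `u(X) ≈ u0 + A (X − X0)` over the masked
neighbourhood within `radius_px` pixels; `F = I + A` and the
Green–Lagrange tensor is `E = (FᵀF − I)/2`. Because `E` is quadratic in
`F`, rigid rotations contribute exactly zero strain — the property that
distinguishes this convention from infinitesimal strain, and the reason
the twist component of the phantom is invisible to the strain maps.

Numerical choices:

* **Neighbourhood radius 2.0 px, weights `w = 1/(0.5 + d²)`.** Near the
  mask edge the neighbourhood is one-sided and the affine model picks up a
  bias proportional to the field curvature; this is largest for radial
  strain in the subendocardial layer, where the radial displacement
  profile is most curved. With radius 2.0 and inverse-square weights the
  worst-case per-segment bias on the noiseless analytic phantom is
  0.8 strain-% (1.3% at SNR 20); wider neighbourhoods (2.5–3 px) or softer
  weights push the noiseless bias beyond 1.4%, which we considered
  unacceptable against the closed-form oracle. The radius is exposed in
  the configuration.
* Pixels with fewer than 5 usable neighbours, or with rank-deficient
  (collinear) support, are flagged missing rather than raised.
* Directional strain is `100 · dᵀE d` along reference-configuration unit
  directions (radial/circumferential on short-axis slices from the cavity
  centroid; longitudinal/across-wall radial on long-axis slices). An
  engineering-strain option `100·(λ−1)`, `λ = sqrt(1 + 2 dᵀE d)`, is
  available behind a flag since both conventions circulate in the
  literature.

### Segmental reporting

The LV is divided into the AHA 16-segment model (6 basal + 6 mid 60°
sectors, 4 apical 90° sectors, apical cap excluded), with segment 1
(anterior) centred at +90° image angle by default (configurable; the
angular origin is a convention). Layers: *subendocardial* is transmural
depth < 0.5 (depth from the dual distance transform
`d_endo/(d_endo+d_epi)`, which handles non-circular contours), a tie at
exactly 0.5 counts as epicardial, and *transmural* is the whole wall.
Short-axis slices yield radial and circumferential strain in three layers
(6 combinations); long-axis slices yield transmural longitudinal and
radial strain (2 more), for the 8 combinations × 16 segments = 128
measurements per subject. Each cell is the arithmetic mean over its
pixels (means match how such tables are conventionally reported; the
statistic is configurable), with a minimum of 10 pixels per cell —
smaller cells are reported missing, and missing cells propagate into the
success-rate accounting of the run manifest. Long-axis wall sides map to
anatomical walls per view (2-chamber: anterior/inferior; 4-chamber:
anterolateral/inferoseptal; 3-chamber: inferolateral/anteroseptal); the
two long-axis contributions that land on the same apical segment are
pooled by pixel-weighted mean. Global strain per direction is the plain
mean of the 16 segmental transmural values, with missing segments
excluded and counted.

Only the aortic-valve-closure frame is analysed (the generator labels its
single frame accordingly); with unlabelled multi-frame input the frame
with maximal mean |E_cc| would be selected, with a warning.

## Scar statistics

Per-segment scar burden is a scar-area fraction in [0, 1] (in clinical use
this comes from late-gadolinium-enhancement segmentation; here the phantom
provides it as ground truth). A segment is *scarred* when the fraction
exceeds 1%, binned into 1–25 / 26–50 / 51–75 / >75%, and the *detection
endpoint* is a fraction above 50%.

* **ROC.** Segments are the analysis unit: endpoint-positive segments of
  scar-group subjects versus all control-group segments; within-subject
  clustering is deliberately ignored (a simplification — see
  limitations). AUC is the Mann–Whitney statistic (ties counted ½).
  Scores are oriented so larger = more scar-like: shortening strains
  (circumferential, longitudinal) as-is, thickening strains (radial)
  negated. The cut-off is the smallest observed threshold whose
  specificity is at least the requested level (default 0.80) —
  "at least the level, closest from above" — which maximizes sensitivity
  under the constraint and is exactly reproducible on finite samples,
  unlike interpolation. Cut-offs are reported back on the natural strain
  scale together with the comparison rule.
* **Differential strain** is the control-group segmental mean minus the
  measured value (a patient at the reference scores 0; hypokinesia gives
  negative differential circumferential strain, so scar classifies at
  differential ≤ cut-off). The wording of this definition admits either
  sign; both conventions are implemented and the default is the literal
  reading. Under a reference that is constant across segments the
  differential ROC is identical to the raw ROC (monotone transform); a
  segment-dependent reference can change it, which is the motivation for
  the construction.
* **ICC.** Reproducibility (inter-observer or scan–rescan) uses
  ICC(2,1): two-way random effects, absolute agreement, single measures,
  with the Shrout–Fleiss F-based 95% CI. Rows with missing cells are
  dropped and counted; a table with zero total variance is an error.
* **Group comparison.** One-way ANOVA plus pairwise t-tests with
  Bonferroni multiplication (capped at 1) across the control / mixed /
  scar groups.

## The synthetic phantom

No imaging data ship with the package; every stage is validated against
analytic LV phantoms with closed-form ground truth.

**Short-axis slices** are circular annuli (endo/epi radii 25/35 mm basal,
23/33 mid, 20/30 apical; one slice per AHA ring) deformed by the
area-preserving contraction `r(R) = sqrt(R² − (R_endo² − r_endo²))`
composed with a rigid twist. The map is exactly incompressible
(det F = 1), its Green–Lagrange strains are `E_cc = ((r/R)² − 1)/2` and
`E_rr = ((R/r)² − 1)/2` with `λ_c λ_r = 1`, and subendocardial shortening
exceeds epicardial shortening automatically (r/R is smaller at the endo).
**Long-axis slices** are rectangular wall frames (cavity half-width 20 mm,
wall 10 mm, length 80 mm) under the incompressible stretch `x' = x/λ_L`,
`y' = λ_L y`, giving uniform `E_ll = (λ_L² − 1)/2` and
`E_rr = (λ_L⁻² − 1)/2`.

**Scar sectors** multiply the displacement by `contraction_scale` inside
an angular window, blended to normal tissue by a cosine ramp
(`transition_deg`, default 10°) and optionally restricted in transmural
depth. Where the scale is locally constant the deformation gradient is
`F = I + s (F_full − I)` — still closed form; inside the blending zone no
closed form exists and the strain oracle refuses (or returns NaN). Ground
truth scar fractions are pixel counts of the sector core inside each
segment on the short-axis slices. On long-axis slices scar weights are
evaluated at each wall's anatomical azimuth so long-axis strain is
consistent with short-axis scar labels.

**Wall-motion heterogeneity.** A phantom in which every control beats
identically would make radial strain an implausibly clean biomarker: in
control cohorts radial strain is empirically far more variable (segmental
SDs of roughly 8–13 strain-%) than circumferential strain (2–4%), and 2D
slices are not truly incompressible in vivo because through-plane motion
decouples wall thickening from in-plane shortening. The generator
therefore adds per-subject wall-motion modes: radial perturbations
`a · depth · cos(mθ + ψ)` (endocardium fixed, epicardium displaced) whose
deformation gradient remains closed form. They perturb radial thickening
strain strongly and circumferential shortening only at second order,
reproducing the direction-dependent variability (measured on the default
cohort: control segmental SD ≈ 6.6 strain-% radial vs ≈ 1.3
circumferential).

**Cohort defaults** (chosen once; all configurable): 20 control + 20 scar
subjects at SNR 20; contraction ratio ~N(0.80, 0.015), twist ~N(4°, 1°),
longitudinal stretch ~N(0.87, 0.02), sub-pixel centre jitter, wall-motion
amplitudes ~N(0, 0.4 mm) at angular orders 0/1/2; scar subjects carry one
transmural sector of width U(80°, 110°) at contraction_scale 0.4 — wide
enough that at least one 60° segment is covered over >60% of its area and
crosses the detection endpoint. A *mixed* group (pathological but
scar-free) is available as a globally hypokinetic variant (whole
deformation scaled by U(0.75, 0.95)). These conditions produce control
strain magnitudes of the order seen in healthy-segment tables
(circumferential ≈ −13%, longitudinal ≈ −12%, radial ≈ +15%) and the
expected discrimination ordering (circumferential transmural AUC ≈ 1.0 >
radial AUC ≈ 0.8–0.95 across seeds) without reproducing — or claiming —
any clinical cohort's values.

**What the phantom does not emulate:** pulse-sequence physics (spiral
k-space, stimulated-echo T1 decay, fat signal), through-plane motion and
3D geometry (the heterogeneity modes only mimic its first-order effect on
2D incompressibility), trabeculation, contour-drawing error, breath-hold
failure, and realistic scar-image (LGE) synthesis. Passing tests
demonstrate that the measurement chain is correct under its stated model,
not that clinical accuracy would match.

## Determinism and problem sizes

A run is reproducible from its configuration plus a single seed, which
deterministically spawns per-subject and per-stage sub-seeds; subject
parameters and acquisition noise derive from separate streams, so
scan–rescan experiments re-use subjects with fresh noise
(`noise_seed`). Grids are 96×96 at 1.36 mm (the reconstructed DENSE
resolution); a full default cohort (40 subjects × 6 slices: encode,
unwrap, decode, strain, statistics) runs in well under a minute on one
CPU, and the bundled verification script completes in under a minute —
sizes chosen so the whole chain is exercised end-to-end at interactive
speed.

## Known limitations

* Single-frame analysis at the aortic-valve-closure label; no cine
  tracking or strain rate.
* 2D per-slice strain only; no torsion or 3D tensors.
* ROC ignores within-subject clustering of segments, and no AUC
  confidence interval is computed.
* The global-cycle anchor assumes near-zero-mean displacement; bulk
  motion (e.g. poor breath-hold) would defeat it.
* Real-data ingestion (DICOM) is an extension point, not implemented:
  inputs are the package's HDF5 subject containers plus contour CSVs.
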