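# densestrain

Segmental left-ventricular strain from DENSE cardiac MRI, with analytic
phantoms and scar-detection statistics.

DENSE (Displacement Encoding with Stimulated Echoes) stores the in-plane
tissue displacement **u** accumulated since encoding in the per-voxel signal
phase, `phi_d = 2*pi*ke*(e_d . u) + phi_bg`, using three balanced encoding
directions at strength `ke = 0.30` cycles/pixel. This package implements the
full analysis chain a strain study needs:

* **Inverse path** — pairwise phase differences (cancelling the background
  phase exactly), quality-guided phase unwrapping, and least-squares decoding
  to millimetre displacement on the reference grid.
* **Strain** — per-pixel deformation gradient `F = I + du/dX` by weighted
  local least squares, Green–Lagrange tensor `E = (F'F − I)/2` (rotation
  invariant, Lagrangian by construction), projected onto radial /
  circumferential (short-axis) and longitudinal / radial (long-axis)
  directions; reported per AHA 16-segment model in transmural,
  subendocardial (inner 50% of wall) and epicardial layers — 8
  layer/direction combinations, 128 measurements per subject.
* **Scar statistics** — per-segment scar-area fractions (>1% = scar, >50% =
  detection endpoint), segment-level ROC with cut-offs at a fixed
  specificity, differential strain against a control-group reference,
  ICC(2,1) reproducibility with 95% CI, and ANOVA/Bonferroni group
  comparisons.
* **Synthetic phantoms** — analytic short-axis annuli (area-preserving
  contraction + twist) and long-axis walls (incompressible longitudinal
  shortening) with closed-form displacement and strain, scar sectors with
  reduced contraction, wall-motion heterogeneity, phase wrapping and complex
  Gaussian noise. Every stage is testable against exact ground truth with no
  data download.

Who it is for: developers of displacement-encoded MRI analysis who need a
validated, reproducible reference pipeline, and methodologists studying how
strain-based scar detection behaves under controlled deformation, scar
severity and noise.

## Worked example

Simulate a small cohort (4 controls, 4 scar subjects, SNR 20), run the whole
chain, and print the ROC summary:

```sh
cat > config.json <<'EOF'
{"cohort": {"n_control": 4, "n_mixed": 0, "n_scar": 4, "snr": 20.0, "seed": 1},
 "icc_rescan_subjects": 0}
EOF
densestrain run --config config.json --out bundle
densestrain report --bundle bundle
```

which prints (abridged):

```
"strain": {"measurements_attempted": 1024, "measurements_succeeded": 1024, "success_rate": 1.0}
AUC by layer/direction (raw strain):
       transmural       radial_sa  AUC=0.816  sens=0.55 @spec>=0.81  rule: strain <= 7.259
   subendocardial       radial_sa  AUC=0.875  sens=0.70 @spec>=0.81  rule: strain <= 10.21
       epicardial       radial_sa  AUC=0.751  sens=0.35 @spec>=0.81  rule: strain <= 4.914
       transmural circumferential  AUC=1.000  sens=1.00 @spec>=0.81  rule: strain >= -10.9
   subendocardial circumferential  AUC=1.000  sens=1.00 @spec>=0.81  rule: strain >= -12.5
       epicardial circumferential  AUC=0.989  sens=1.00 @spec>=0.81  rule: strain >= -9.146
       transmural       radial_la  AUC=0.980  sens=1.00 @spec>=0.81  rule: strain <= 11.43
       transmural    longitudinal  AUC=1.000  sens=1.00 @spec>=0.81  rule: strain >= -10.77
```

Reading this: all 8×128 segmental measurements succeeded; circumferential
strain separates endpoint-positive segments (scar area >50%) from control
segments essentially perfectly — a segment is classified as scar when its
circumferential transmural strain is less negative than −10.9% — while
radial strain, whose between-subject variability is much larger, discriminates
far less well (AUC 0.75–0.88). The bundle directory holds the per-segment
strain table (`strain.csv`, 128 rows per subject), scar fractions with
transmurality bins (`scar.csv`), the control reference (`reference.csv`),
ROC rows for raw and differential strain (`roc.csv`), global strain per
subject (`global_strain.csv`), bull's-eye values (`bullseye.csv`), subject
HDF5 containers under `subjects/`, and a `manifest.json` that reproduces the
run.

The same stages are available as a library:

```python
from densestrain import CohortSpec, RunConfig, analyze_subject, generate_cohort

subjects = generate_cohort(CohortSpec(n_control=2, n_scar=2, seed=1))
table = analyze_subject(subjects[0], RunConfig())   # 128-row DataFrame
```

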