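# Methods

## The aging model and its calibration

Cortical gray-matter (GM) values of T1, PD, T2, T2′ and the cortical-shell
thickness are generated per subject as

    value = baseline + b·(age − age₀) + η,    η ~ N(0, σ_res²)

For each parameter the slope and residual SD are calibrated from a target
population correlation `r` with age and a target between-subject SD:

    b = r · SD_param / SD_age,      σ_res = SD_param · √(1 − r²)

so that in the infinite-cohort limit the marginal SD and the Pearson
correlation with age reproduce the targets exactly (checked in the tests by
a 10 000-subject scalar simulation, tolerance ±0.02 on r and ±2% on the
SD). The default targets are a published adult cohort's global cortical
statistics (ages 19–71, SD_age 14.97 y):

| parameter | baseline | between-subject SD | r with age | within-cortex SD |
|---|---|---|---|---|
| T1 [ms] | 1528.75 | 40.58 | −0.421 | 146.73 |
| PD [p.u.] | 79.48 | 1.85 | +0.287 | 5.45 |
| T2 [ms] | 86.99 | 4.17 | +0.445 | 27.69 |
| T2′ [ms] | 201.50 | 22.47 | −0.724 | 90.83 |
| thickness [mm] | 2.45 | 0.08 | −0.444 | — |

The reference age `age₀` is 45 y, the mean of the uniform [19, 71] age
distribution, so cohort means coincide with the baselines. Ages are drawn
uniformly on [19, 71] (population SD 15.01, matching the target 14.97);
sexes are assigned deterministically to the configured counts (default
19 male / 21 female) and shuffled by the seed.

**T2\* is never calibrated directly.** Its ground truth is the voxelwise
composite `1/T2* = 1/T2 + 1/T2′`, so the T2′ trend — the iron-sensitive
headline parameter — is injected exactly and physicality (T2\* < T2) holds
by construction. The consequence is a known structural limitation: the
three transverse-relaxation statistics above are mutually inconsistent with
a deterministic composite. Propagating the calibrated T2 and T2′ trends
through the composite yields cov(T2\*, age) ≈ −0.57·SD_age, which with the
small T2\* between-subject SD (≈2.4 ms, matching the published 2.48 ms)
implies r(T2\*, age) ≈ −0.25 at the scalar level and ≈ −0.39 through the
voxelwise pipeline (the harmonic composition over the textured cortex
amplifies it) — not the near-null value a real cohort shows, where
measurement error and regional heterogeneity decouple T2\* from the derived
T2′. The alternative (inject T2\* and derive T2′) would misplace the far
more important T2′ correlation (≈ −0.30 instead of −0.724), so this
trade-off is deliberate; the acceptance script reports the recovered
r(T2\*) honestly.

## Phantom geometry

Each subject is a set of nested ellipsoids on an isotropic grid (default
64³ at 2 mm): an outer CSF shell (3 mm), a pial surface (semi-axes
48 × 44 × 40 mm), a GM shell whose thickness is the subject's aging-model
draw, a WM core, and one ventricle (CSF). Labels are mutually exclusive and
tile the head; TIV is the volume of all brain + CSF voxels. Subjects differ
geometrically by a global scale factor (SD 2.5%, plus a 2.5% male–female
offset so TIV is a meaningful covariate), a sub-voxel centre jitter
(±0.5 voxel) and a small axial rotation (±8°). The jitter and rotation are
not cosmetic: they decorrelate voxel-grid quantisation across subjects,
which is what lets a ~0.12 mm age-related thickness change survive
measurement on a 2 mm grid (measured residual quantisation SD ≈ 0.035 mm).

Within-cortex spatial variation is a smooth Gaussian random field (1.5-voxel
smoothing), scaled to the within-cortex SD above, floor-clipped to physical
ranges and re-centred so the subject's cortical mean is exact. T2 and T2′
textures are drawn independently; real cortical T2/T2′ covary regionally,
which this does not model. WM and CSF parameters are fixed 3 T
literature-style constants (WM: T1 850, PD 69, T2 75, T2′ 150; CSF: T1
4000, PD 100, T2 500, T2′ 2000; ms / p.u.).

## Forward signal models

All stacks share multiplicative smooth transmit (κ) and receive (R) bias
fields — random degree-2 polynomials with ±10% peak amplitude — and additive
Gaussian magnitude noise (Rician optional) whose SD is the mean cortical-GM
signal of the T1-weighted VFA volume divided by the SNR (default 50).

* VFA (two spoiled GE volumes): `S = R·PD·sin(κα)·(1 − E1)/(1 − cos(κα)·E1)
  · e^(−TE/T2*)`, `E1 = e^(−TR/T1)`, TR 16.4 ms, TE 6.7 ms, α 4°/24°.
* FSE (T2): `S = R·PD·(1 − e^(−TR/T1))·e^(−TE/T2)`, ideal refocusing,
  TE 17/86/103/120 ms, TR 8 s.
* GE (T2\*): spoiled steady state × `e^(−TE/T2*)`, TE 10–52 ms step 6,
  α 30°, TR 2.4 s.
* B1 pair: a reference spoiled-GE volume and a saturation-prepared copy
  with longitudinal magnetisation scaled by `cos(κβ)` (nominal β 60°). The
  exact prepulse timing of a production sequence is not modelled; the
  ratio/arccos relation is the operative content.
* TE pair: two GE volumes at TE 6.7 and 13.4 ms for the T2\* correction of
  the PD pathway.

The forward models are the exact inverses of the fitters, which gives the
round-trip property: noiseless synthesis followed by fitting recovers every
ground-truth map to < 10⁻⁶ relative error (tested voxelwise).

## Fitters: numerical choices

* **B1**: `κ = arccos(clip(S_prep/S_ref, −1, 1))/β`; voxels below the
  signal floor, with κ ≤ 0 (unsaturated ratio ≥ 1) or κ > 2 are masked. If
  the prepared volume is brighter than the reference in most voxels the
  pair is reported as swapped rather than silently fitted.
* **T1/intercept**: exact two-point solution of the `S/sin(κα)` vs
  `S/tan(κα)` line (no regression machinery — with two angles the line is
  determined); slope outside (0, 1) or effective angles ≥ 90° mask the
  voxel.
* **T2/T2\***: log-domain weighted least squares with weights S² (the
  first-order variance of log S under additive noise is σ²/S², so squared-
  signal weights are variance-stabilising). Per voxel, echoes below the
  floor (3× the noise SD, estimated from background corner patches or
  passed explicitly in simulation) are dropped; fewer than two usable
  echoes, or a non-negative decay slope, mask the voxel. A per-voxel
  nonlinear least-squares fitter exists as a flagged alternative and serves
  as the test oracle (agreement < 1% at SNR 40). Stimulated/secondary-echo
  contamination of spin-echo trains is not modelled; a `drop_first_fse_echo`
  option stands in for an explicit correction.
* **PD**: `M0 = intercept/(1 − e^(−TR/T1))`, times `e^(TE_vfa/T2*_pair)`
  with `T2*_pair = −ΔTE / ln(S₂/S₁)` from the TE pair, divided by the
  receive field, then scaled so the ventricle-CSF median is 100 p.u. In
  simulation mode the known synthetic receive field is consumed; a
  log-domain polynomial estimator over the brain mask is provided for
  field-free inputs (coarse — it assumes near-flat tissue composition).
* **T2′**: `1/T2′ = 1/T2* − 1/T2`; voxels where noise pushes T2\* ≥ T2 are
  masked invalid, **not** clipped — clipping at a finite ceiling would
  bias region means downward, masking keeps them unbiased.

## Ribbon surrogate

The anatomy stage replaces a surface-reconstruction tool chain with voxel
surrogates. Synthetic MP-RAGE contrast uses the closed-form ideal-inversion,
full-relaxation approximation `S ∝ PD·sin α·(1 − 2e^(−TI/T1) + e^(−TR/T1))`
(TI 900 ms, TR 1.9 s, α 9°), rescaled to [0, 1000]; the full Bloch
recursion of a real readout is intentionally out of scope, the PD factor
carries the mixed T1/PD weighting. Segmentation is a 3-class Gaussian
mixture on within-brain intensities ordered CSF < GM < WM (GM Dice ≥ 0.95
at SNR 50 on the default phantom); an oracle mode returns the ground-truth
labels so statistics tests do not inherit segmentation error — the
acceptance runs use the oracle ribbon deliberately, to isolate acquisition
and fitting error.

Thickness is measured per ribbon voxel as (Euclidean distance to the
nearest WM voxel) + (distance to the nearest CSF voxel) − one voxel; the
subtraction removes the two half-voxel centre-to-boundary overshoots and
makes the estimator exact on flat slabs, and within half a voxel on
analytic shells at 0.5–2 mm voxels. It is a voxel analogue of, not a
substitute for, mesh-based thickness: systematically comparable, not
identical.

Lobes are fixed angular sectors of the sagittal-plane polar angle around
the head centre in the subject-native frame: frontal = anterior 100°
wedge, occipital = posterior 60° wedge, parietal = remaining dorsal,
temporal = remaining ventral sector, each split by hemisphere. This is a
deterministic, hemisphere-symmetric stand-in for an atlas parcellation.

## Statistics

Sample SDs (n − 1) are used everywhere. Partial correlations are computed
by residualising both variables on [1, covariates] and correlating the
residuals, with p from the t transform at n − 2 − k df; the implementation
is cross-checked against the inverse-correlation-matrix identity to 1e−10
and against an independent library. Smoothing is Gaussian (σ = FWHM/2.3548,
default FWHM 10 mm) with mask-renormalised weights, so constants are
preserved on the ribbon and nothing bleeds in from outside; on a thin
ribbon with a 10 mm kernel this choice preserves level, not integral mass.

Voxelwise inference: per-voxel Pearson r with age on the template ribbon
(the reference-age phantom without subject variation; subject maps are
sampled there with nearest-valid fill), suprathreshold voxels at
uncorrected p < 0.05 grouped into 6-connected clusters **separately by
sign** (one-sided families, matching separate hot/cold maps), and a
max-cluster-size permutation null from random relabelings of age:
`p_cluster = (1 + #{perm max ≥ observed})/(1 + n_perm)` (the +1 avoids
zero p-values; with exhaustive enumeration the unconditional fraction is
used). Whether a production Monte-Carlo cluster correction is one- or
two-sided per map is ambiguous; sign-split one-sided was chosen and is
flagged here. The family-wise error calibration is verified empirically
(200 null repeats, rate within the binomial band of 5%), and the cluster
p-values are verified exactly against brute-force enumeration on a
3×3/n = 6 toy. Parameters are analysed independently — no cross-parameter
multiple-comparison correction.

The per-subject "SD across cortex" summary is interpreted as the mean over
subjects of the within-subject spatial SD (the generator's within-cortex
texture SD), which is how the two columns of the calibration table are
read.

## Problem sizes and what the tests show

The desk-scale configuration is a 64³ grid at 2 mm with n = 40 subjects;
the acceptance experiment averages 20 independent cohorts (800 simulated
subjects, a few minutes on one CPU), chosen as the smallest scale at which
the quantisation-dithered thickness measurement and the correlation
recovery are stable. A 1 mm grid is supported through the geometry
configuration.

Passing the closed-loop tests shows that the *pipeline* is unbiased and
correctly propagates calibrated effects through synthesis, fitting and
reduction under Gaussian noise, smooth bias fields and grid quantisation.
It does not show robustness to what the generator omits: gyral folding,
partial-volume mixing beyond quantisation, motion/B0/flow artifacts,
imperfect spoiling, stimulated echoes, spatially correlated T2/T2′
physiology, or segmentation error in real anatomies (the acceptance loop
uses the oracle ribbon). Longitudinal designs are out of scope.

## Degenerate inputs and edge behaviour

|r| ≥ 1 calibration requests, GM shells thinner than one voxel, sex counts
not summing to n, cohorts of fewer than 3 subjects, degenerate age ranges,
swapped B1 pairs, empty CSF masks (PD calibration), empty lobe sectors and
collapsed intensity mixtures all raise typed errors; per-voxel failures
(signal floor, non-physical T2\* ≥ T2, slopes outside range) mask voxels
rather than aborting. Every stage is deterministic under a fixed seed
(per-subject streams are spawned from the cohort seed, so cohorts are
reproducible bit-exactly).
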