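# Methods

## Scope and data model

The package measures two decomposition signals on 3-D CT volumes of logs:
excavated (insect) volume and fungal-decay volume. Volumes are arrays in
Hounsfield Units (HU; water = 0, air = −1000, linear in attenuation
relative to water), indexed `(z, y, x)` with axis 0 the longitudinal stem
axis; spacing is carried explicitly (in-plane pixel spacing and slice
thickness, mm). Connectivity is 26-neighborhood in 3-D and 8-neighborhood
in 2-D throughout.

Supported formats: DICOM series directories (rescale slope/intercept
applied on read), NIfTI, and multi-page TIFF with a JSON spacing sidecar.
Label volumes use stable integer codes (background 0, bark 1, wood 2,
tunnel-in-bark 3, tunnel-in-wood 4, crack 5, drilling 6, larva 7, decay 8)
written with a JSON code map.

## Preprocessing

**Scanner-bed removal.** The bed is a dense horizontal band constant across
slices. On the slice-averaged image, the topmost row in which ≥30 % of the
pixels exceed an opacity level (default 200 HU — far above any wood value)
marks the table line; that row and everything below is replaced by air.
Absence of a bed is a logged no-op, and the operation is idempotent.

**Normalization.** `value = clip((HU + offset)/factor, 0, 1)` with
`offset = +1000 HU` and `factor = 2500 HU`. The offset is chosen so air
maps exactly to 0; only then does the upper bound 1.0 correspond to
1500 HU = 250 % of water attenuation, which fixes both parameters'
interpretation. Values outside [0, 1] are clipped; the inverse transform is
exact inside the unclipped range. Whether the offset should be global or
per scanner is data-dependent; it is a parameter.

## Beetle-tunnel pipeline

1. **Solid detection.** Hysteresis thresholding on the normalized volume:
   voxels ≥ `high` (default 0.20) seed regions grown through voxels ≥
   `low` (default 0.12), followed by removal of components below 64 voxels.
   The defaults sit between air (0.0) and moist wood (≈0.24 upward) and are
   calibrated on phantoms; they are configuration, not constants.
   Morphological closing of the solid is available but off by default: a
   closing would seal the 1–2-voxel shrinkage cracks that cavity detection
   must still see.
2. **Bark separation.** Per slice, depth is measured from the outer
   surface as the Euclidean distance inside the slice's convex hull
   (the hull, not the solid, so interior cavities contribute no spurious
   boundary; a log cross-section is convex, so the hull also bridges crack
   slits and drill openings). Depths are binned to voxels; the bark is the
   longest run of outer bins whose median normalized intensity stays below
   `bark_value_max` (default 0.22, midway between bark and earlywood).
   Wood is the remaining solid. Empty shallow bins — an artifact of the
   polygonal hull overshooting the rasterized disc — are skipped rather
   than treated as the end of the bark.
3. **Cavity detection.** The mirrored hysteresis rule (seeds ≤ `low`,
   grown through ≤ `high`) inside the convex hull eroded in-plane by
   2 voxels (removing hull-overshoot slivers), minus the solid.
4. **Cavity classification.** Components are first split by local
   thickness: voxels ≥ 1.5 voxels deep inside the cavity mask seed "cores"
   that absorb their shell (≤ 3 voxels); the thin residual forms separate
   components. This separates 1-voxel crack sheets from ≥ 2-voxel tunnel
   tubes even where they intersect. Per component, PCA of the voxel
   coordinates (mm) gives elongation (√(λ₁/λ₂)), planarity (√(λ₂/λ₃)) and
   the sheet normal; the radius estimate is the maximum interior distance;
   straightness is end-to-end over arc length of a polyline through
   centroids binned along the main axis. Rules (all configurable):
   *crack* = planarity ≥ 3 ∧ |normal·tangential| ≥ 0.6 ∧ touches surface ∧
   radius ≤ 1 mm; *drilling* = straightness ≥ 0.92 ∧ radius in the auger
   band (2–6 mm); otherwise *tunnel*, assigned to bark or wood by the
   nearest-tissue compartment (majority per component; per-voxel for
   mixed components). Components under 8 voxels default to tunnel.
5. **Larvae.** Bright voxels in a configurable band (default normalized
   0.40–0.47 around +60 HU) form components kept only when 26-connected to
   a tunnel and within a size range — this gate is what keeps moist wood
   from being counted as larvae. Larvae count toward tunnel volume by
   default (they occupy excavated space); a flag disables this.
6. **Quantification.** Relative volumes use the compartment including the
   excavated space: `tunnel/(bark+wood+tunnel)` for the whole log and the
   corresponding per-compartment forms. Refilled (frass-packed) galleries
   are not detected — they are indistinguishable from wood at this contrast
   and contribute negligibly to cavity volume; this is a documented
   limitation, as are detached bark (overestimation) and bark loss
   (underestimation), which the phantom can reproduce but the pipeline does
   not correct.
7. **Bark unrolling.** For each slice and angle, the radial ray through the
   bark shell is sampled (class-priority projection for labels,
   max-intensity for HU) onto a (slice, angle) image.

## Decay classifier

The per-pixel classifier is a three-level convolutional encoder–decoder
with skip connections (48→24→12 px for the default 48 px patch; channels
8/16/32), 3×3 convolutions with ReLU, 2×2 max pooling, nearest-neighbor
upsampling, and a 1×1 sigmoid head; loss is binary cross-entropy, the
optimizer Adam (lr 3·10⁻³), all hyperparameters in `TrainConfig`. It is
implemented directly in numpy with hand-derived backpropagation, verified
against finite differences in the unit tests, and is fully deterministic
under its seed. Training samples patches from annotated slices (half
anchored on decay pixels when balancing is on) with flip/rotation
augmentation.

Inference extracts patches at anchors on a 12 px stride, final anchors
clamped to the border (no padding — no fabricated context at edges, where
prediction reliability is lowest), and recombines them as a per-pixel
weighted average with a radial raised-cosine window,
`w = (cos(πd/D)+1)/2` floored at 10⁻³ (the raw cosine vanishes at the
corners; any strictly positive center-peaked window is valid because the
weights renormalize per pixel). Cross-validation folds are assigned over
slices, not patches, to avoid leakage between overlapping patches of one
slice; the default is 5 folds.

The binarization threshold maximizes F1 over a 0.01-step candidate grid,
ties broken toward the lower (more sensitive) threshold. Optional
longitudinal smoothing (1-D Gaussian along the stem axis, σ in slices)
evens out slice-to-slice jitter of the 2-D predictions; decay spreads
preferentially along the grain, so smoothing in z is biologically
consistent. Decay volume is the fraction of wood voxels above threshold,
with crack voxels excluded (cracks are missing wood, not decayed wood).

## Synthetic phantoms

`generate_phantom` carves a cylindrical spruce log into a voxel grid:
bark annulus, annual rings (outer 30 % of each 2.5 mm period as dense
latewood), wood-borer galleries as 3-D correlated random walks reflected at
the wood boundary, bark-beetle galleries as walks confined to the mid-bark
shell, radial shrinkage cracks 1–2 voxels wide reaching in from the
surface, straight in-plane drill holes (8 mm auger), larvae as ball-chain
ellipsoids attached to gallery ends, and decay regions as z-elongated
ellipsoids whose ring texture is flattened and shifted by a signed contrast
(default −150 HU), optionally with a ~4 mm cuboidal cleft grid mimicking
brown rot. Labels are recorded before Gaussian HU noise (default σ = 20 HU)
is added, so they are exact. The default HU palette (air −1000, bark −500,
earlywood −400, latewood −100, larva +60) is a plausible invention; only
the ordering air < decayed < earlywood < latewood < larva is asserted.
Default geometry mirrors the field logs (radius 90 mm, 500 mm length at
0.29/0.67 mm voxels); benchmarks and tests use explicitly scaled-down specs
(radius 24–30 mm, 16–60 slices at 0.5/1.0 mm voxels), chosen so every
structure class remains resolvable (tunnel radii ≥ 2 voxels) while a full
pipeline run takes seconds.

What the phantoms do *not* emulate: partial-volume blur at cavity walls,
beam hardening and scatter, anatomically realistic gallery architectures of
specific species, moisture gradients, detached or lost bark (constructible
but not default). Passing phantom tests therefore demonstrates the
correctness and internal consistency of the measurement chain, not
field-data accuracy; thresholds tuned here are starting points for real
scans, not validated field settings.

`simulate_experiment` reproduces the mesocosm design (61 mesocosms × 2
logs; 26/20/15 control / bark-beetle / wood-borer) with per-log effect
draws (lognormal around guild means: bark beetles bark-only 2.3 % of bark,
wood-borers 1.8 % of wood plus 2 % of bark, CV 0.5 — magnitudes chosen so
rendered logs reproduce the observed guild contrast pattern of a >4× total
excavation for wood-borers and a bark-concentrated beetle signal). The mass
model assigns voxel mass ∝ (HU + 1000) — invented but monotone in density —
so dry-mass loss is the mass of excavated voxels plus a decay term
(default 20 % density loss over the decayed fraction), giving a positive
tunnel–mass-loss correlation by construction. Disc records carry within-log
heterogeneity (CV 4 % on the dry:fresh ratio) and 0.1 g scale resolution,
so the disc estimator shows realistic errors including negative apparent
mass loss. Fresh spruce density 850 kg/m³ and dry:fresh ratio 0.45 are
standard values for green Norway spruce.

## Metrics

Precision, sensitivity, specificity, accuracy and F1 come from exact
confusion counts over an optional evaluation region. Zero-denominator
metrics are reported as explicitly undefined (`None`), never silently 0 or
1 — a silent default would corrupt F1-based threshold selection. Spearman
correlation uses average ranks for ties; the two-sided p-value is exact
(full permutation enumeration) for n ≤ 10 and the t-approximation above.
The beta regression with post-hoc tests used for treatment comparisons on
field data is out of scope; the package exports tidy per-log CSV summaries
for external statistical software.

## Numerical and design notes

* Hysteresis defaults (0.12/0.20) must only separate air from wet wood;
  the exact field values are scanner- and moisture-dependent.
* Tie-breaks: threshold selection takes the lowest maximizing candidate;
  cavity-shell voxels equidistant to two cores follow scan order (this can
  move a few voxels between same-class components under rotation).
* Degenerate inputs: all-air volumes raise "no log found"; slices without
  solid yield empty masks with a log notice; empty annotation sets and
  label sets without positives raise instead of returning defaults.
* The DICOM writer stores uint16 with a fixed −1024 intercept; HU outside
  that range are rejected rather than wrapped.
* Determinism: phantoms, the simulated experiment and training are
  bit-reproducible given their seeds; the only known tolerance is float
  accumulation order in convolutions, which numpy keeps stable on one CPU.
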