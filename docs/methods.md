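# Methods

This note documents the models, conventions, parameters and known
limitations of `choroseg`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinates and units

Volumes are indexed `[z, x, y]` — depth (z = 0 anterior), fast axis,
slow axis. Depth coordinates are 0-based; depth intervals half-open
`[start, stop)`. One depth voxel spans `axial_sampling_um` of optical
path; anatomical distance divides by the group refractive index
(default 1.4, the conversion constant is a config input because depth
sampling calibration is instrument-specific). Transverse scale is
0.289 mm/° (emmetropic schematic eye) unless overridden.

## Boundary detection

Each interface is a per-B-scan minimum-cost column path through signed
axial-gradient evidence: a dark-to-bright transition for the
hyperintense RBC band, bright-to-dark for the CSI. Depth jumps between
adjacent A-scans cost `boundary_lambda` (default 2) evidence units per
voxel; `lambda = inf` degenerates to a flat surface at the median best
depth. The volume is smoothed transversely (Gaussian,
`boundary_smooth_sigma = 4` A-scans) before edge detection so locally
dark vessel lumens — which produce edges of nearly the same magnitude
as the CSI — cannot divert the path, while the smooth large-scale
boundary surfaces survive. The CSI search is restricted to at least
`csi_min_gap_voxels` (10) below the detected RBC. The forward/backward
dynamic program is exact; the detected depth indexes the first voxel of
the new medium, so the choroid interval is `[rbc, csi)`. On
speckle-free phantoms the detection RMS error is below one voxel;
confidence (normalized path evidence) flags contrast-free inputs
instead of raising.

The choroid region is `[ceil(rbc), floor(csi))` per A-scan; crossing
surfaces mark the A-scan undefined (counted in the log); `rbc == csi`
gives a defined zero-length interval.

## Vessel segmentation

Vessels are the hyporeflective phase of the 1060-nm choroid. The
pipeline:

1. **Median denoising**, radius 1 (3×3×3), the standard speckle
   surrogate filter.
2. **Attenuation flattening**: the per-depth gain below the RBC complex
   is the 80th percentile of choroidal intensities at each
   depth-below-RBC offset (the stroma is the bright phase, so a high
   percentile tracks attenuation even where vessel lumens are locally
   in the majority), lightly smoothed and divided out.
3. **Candidate selection**: by default the threshold is derived from
   the flattened choroidal intensity histogram by Otsu's method, which
   adapts to the actual vessel fraction. A fixed per-1°-tile percentile
   (`candidate_mask`) is available and contract-tested; a fixed
   percentile p necessarily mislabels about (p − vessel fraction)% of
   stromal voxels, which is why the automatic threshold is the default.
4. **Cone voting**: every candidate boundary voxel (≥ 1 non-candidate
   6-neighbor) with gradient magnitude at or above the 60th percentile
   casts total weight 1 uniformly into a 3D cone (half-angle 30°,
   length 12 voxels) along its inward gradient direction; votes land
   only on candidates. Directions are quantised to the 26 neighbor
   directions, which keeps the quantisation error (≤ 22°) inside the
   cone aperture.
5. **Cores** are voxels at or above the 50th percentile of positive
   votes; **geodesic dilation** (6-connected, default 24 iterations —
   the largest tube radius in voxels — rather than to stability, which
   bounds leakage through chance candidate bridges) recovers full
   caliber.
6. **Components** are labeled with 26-connectivity (permissive for
   undulating tubes); surface voxels use the 6-neighbor rule so that
   surface counts match the volume/surface ratio analysis; components
   below 2 voxels are removed (the single-voxel noise rule).

On the speckle-free standard phantom the voxelwise Dice overlap with
ground truth is ≈ 0.98; with speckle (gamma shape 8) ≈ 0.96.

## Sublayer split

Per 1°×1° tile (14 A-scans per degree at the instrument pitch), vessel
voxels are binned by depth-from-sclera (`floor(csi) − 1 − z`; bin 0 is
the deepest choroid voxel) and the per-bin ratio of vessel volume
voxels to vessel surface voxels is formed. Bins whose vessel voxels are
all interior (volume > 0, surface = 0 within the tile) are maximally
vessel-filled and enter as ratio = volume count; bins with no vessel
voxels are undefined. Profiles are smoothed by a 5-bin NaN-aware moving
average.

Border rule: Haller's layer runs from the scleral boundary through the
profile maximum until the first small ratio. Concretely, the valley
separating the large-vessel from the medium-vessel mode is the running
minimum after the maximum once the profile rebounds by ≥ 0.2
(`valley_prominence`) *and* the minimum fell below 0.6× the peak (this
scale guard rejects sampling wiggles riding on large modes); the border
is then placed at the first bin after the peak that descends to within
`min(0.15 × (peak − valley), 1.0)` of the valley level — the onset of
the valley floor, where large-vessel mass ends. The scan then continues
anteriorly to the first bin with no vessels at all (`noise_floor = 1.0`;
single-voxel noise is already removed by the component filter, and the
per-bin ratio of genuine 1–3-voxel-wide vessels sits at 1.0–1.1, so a
higher floor would amputate Sattler's layer), which closes Sattler's
layer. Profiles that decay without an interior valley yield a
zero-thickness Sattler layer, so near-zero layers are representable.
Borders are clamped to the tile's choroidal depth and converted to µm
with the axial voxel pitch; tile maps are block-expanded to A-scan
resolution for field averaging (block expansion preserves tile-area
weighting exactly).

## ETDRS summarization

Central disc 1.5 mm (the central submacular field of this pipeline),
inner annulus 1.5–3 mm, outer annulus 3–6 mm, quadrants split by the
±45° diagonals, nasal/temporal flipped by laterality; the total macular
field is the whole 6 mm disc. The central diameter follows the CSM
definition used throughout (1.5 mm rather than the 1 mm of the classic
grid); the 3 mm inner ring is the standard layout. Subfields with more
than 50% undefined cells are reported missing. When a map covers less
than 6 mm — the synthetic patches below do — the total field falls back
to the whole mapped area, documented in the output.

## Repeatability statistics

For paired sessions: mean difference with t-based 95% CI; limits of
agreement `mean ± 2·SD` of the differences (the small-group rule,
sample SD); Bland–Altman difference-vs-mean correlation as the
proportional-bias check; two-way single-measure absolute-agreement ICC
(`(MSR − MSE) / (MSR + (k−1)MSE + k/n (MSC − MSE))`) with the
McGraw–Wong F-based interval, cross-checked against `pingouin` in the
tests; coefficient of repeatability `1.96·SD(differences)`, expressed
relatively against the grand mean of the measurements entering the
differences (the natural denominator when the difference mean is ~0);
one-way repeated-measures ANOVA on the session factor. Negligible sums
of squares are snapped to zero so degenerate inputs (identical
sessions) give exactly ICC 1, F 0, CR 0.

## The synthetic phantom: what it emulates and what it does not

The standard study configuration (`default_phantom_config()`) is a
5.5° × 5.5° macular patch sampled by 128 × 128 A-scans × 256 depth
voxels: transverse pitch ≈ 12.4 µm, axial optical sampling 7 µm
(anatomical 5 µm at n = 1.4). The transverse pitch is finer than the
20 µm of a 512-A-scan/36° raster; at 20 µm a 12–30 µm-radius vessel is
1–3 voxels wide and its volume/surface ratio is pinned at ~1,
indistinguishable from noise — the sublayer analysis presumes the
medium-vessel layer is resolvable, and the finer pitch provides that
while the CSM disc still fits the patch.

Anatomy per eye: smooth boundary surfaces from a random low-order 2D
cosine series (amplitude 6 voxels) around mean depths 100/200
(choroid ≈ 500 µm); 12 Haller tubes (radius 40–100 µm) whose anterior
surfaces track a per-tube fraction 0.42–0.445 of the local choroidal
thickness — the large-vessel band of a real choroid has a coherent
anterior envelope, and the per-tile ground-truth border is defined as
that envelope (the maximum over tubes of each tube's anterior-most
voxel depth in the tile); 45 Sattler tubes (radius 12–30 µm) filling
the 0.42–0.75 band so the two layers are contiguous, as in real
anatomy. Tubes run roughly parallel to the raster axes with mild
undulation — the regime in which vessel cross-sections are not round.
Intensities: background 15, stroma 100, vessel 40, exponential depth
attenuation (tau = 250 voxels) below the RBC, multiplicative unit-mean
gamma speckle (shape 8, i.e. ~35% intensity noise before filtering).
The noise parameters are plausible knobs, not claims about any
instrument.

Not emulated: interferometric image formation, motion artifacts, RPE
lesions/drusen, the choriocapillaris, vessel branching, and caliber
gradients within a layer. Passing tests therefore demonstrate that the
algorithm chain recovers the geometry it assumes from realistic
contrast and noise — not clinical accuracy on diseased eyes.

## Study sizes and observed performance

All numbers below are recomputed by `tests/test_acceptance.py` and
`scripts/acceptance.py`.

* Border recovery (speckled standard phantom, 1 seed fixed in the
  tests): ≥ 90% of defined tiles within 3 depth bins (15 µm) of the
  ground-truth envelope; across other seeds the fraction varies roughly
  between 83% and 97% with only ~35 defined tiles per phantom. CSM
  means of both sublayers within 15% of truth (typically 2–10%).
* Segmentation: voxelwise Dice ≥ 0.9 without speckle; no single-voxel
  components.
* Repeated-imaging experiment: 10 eyes (per-eye choroidal thickness
  varied ±25%) × 3 sessions differing only by fresh speckle; the full
  pipeline runs per rendering. Haller CSM ICC ≥ 0.99 and relative CR
  ≈ 3% — session noise is the only variance source, so agreement is
  near-perfect by construction; positioning jitter (`session_jitter_
  voxels`, default 2, disabled in the experiment's noise-only form)
  adds the axial-placement variability seen between real sessions.
* The synthetic cohort's scale resembles healthy eyes: Haller CSM
  ≈ 230 µm, Sattler CSM ≈ 130–150 µm.

## Numerical choices and degenerate inputs

* Half-open integer depth intervals everywhere; voxel centers, not
  subvoxel interface positions.
* Valley ties resolve to the most posterior bin; tile partitions are
  non-overlapping with remainder A-scans split between the edge tiles.
* Constant (contrast-free) volumes yield zero-confidence surfaces, not
  exceptions; empty candidate masks yield zero accumulators and empty
  masks; all-undefined ratio profiles mark the tile missing.
* Determinism: every random quantity derives from an explicit seed or
  `numpy` Generator; identical (config, seed) reproduce byte-identical
  CSV artifacts, hashed in the run manifest.

## Known limitations

* The valley rule fails in tiles where the medium-vessel mode does not
  rebound above the inter-layer dip (no detectable valley): such tiles
  degrade to zero Sattler thickness; they are the dominant residual
  error source (~1 tile per phantom).
* The border detector marks where large-vessel *ratio signal* ends,
  which can sit 1–2 bins anterior of the geometric envelope because of
  profile smoothing.
* Per-bin ratios of vessels thinner than ~2 transverse voxels carry
  little caliber information; at coarse transverse pitch the Sattler
  signal disappears entirely (see the phantom pitch discussion above).
* The boundary detector is a simplified stand-in sufficient for
  phantom-grade contrast; clinical data with RPE pathology would need
  the full statistical-model segmentation it replaces.
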