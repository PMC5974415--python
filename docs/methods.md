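# Methods

`tractgex` reimplements, as a tested pipeline on synthetic phantoms, an
imaging-transcriptomics analysis for the mouse brain: skeleton-based
white-matter statistics on fractional anisotropy (FA) maps, affine transfer
of atlas gene-expression "energy" volumes into a common space, and a
rank-sum decoding step that asks which genes of the 16p11.2-syntenic
deletion panel are overexpressed where the anatomy changed.  This note
documents the models, the defaults and why they were chosen, and what the
synthetic studies do and do not establish.

## Data model

All images are `Volume` objects: a 3D scalar array, a voxel-to-world affine
(RAS, mm, 0-based voxel indices) and an optional missing-data sentinel.
The sentinel (−1 by the atlas energy-volume convention) marks voxels with
no expression annotation; every sampling and statistics operation excludes
it, and resampling propagates it without ever blending it into real values
(masked, renormalized trilinear interpolation; a voxel whose nearest source
voxel is missing stays missing).  NIfTI-1 qform is authoritative on read;
data are written float32, so round-trips are bit-exact.

Spatial mappings are 12-parameter affines (3 translations mm, 3 rotations
deg, 3 scales, 3 shears), built as `T·C·Rz Ry Rx·Shear·Scale·C⁻¹` about an
optional centre, so identity parameters give the identity matrix.  Chains
carry explicit space labels and are always composed into a single matrix
before resampling — each map is interpolated exactly once, and the
histogram QC (Jensen–Shannon divergence of intensity histograms over
non-missing voxels, natural log, range [0, ln 2]) guards against
distortion introduced by the alignment.

The header-respacing helper reproduces the small-animal trick of
relabelling sub-millimetre voxels as 1 mm isotropic for tooling calibrated
to human head sizes: only the affine changes, the data bytes do not.
Internally all geometry uses the recorded spacing, so the trick is honored
but irrelevant to the numerics.

## Synthetic phantoms

The generator replaces the two data sources that cannot be shipped: ex vivo
diffusion MRI of a deletion cohort, and atlas in situ hybridization energy
volumes.

* **Anatomy.**  An ellipsoidal brain shell (semi-axes 0.42 of the grid
  extent) containing three tract-like structures defined analytically in
  world mm: a thin "callosal" sheet, a medial "peristriatal" tube running
  anterior–posterior, and a posterior "cerebellar" blob.  Structure masks
  are smoothed by a 1-voxel Gaussian to give soft edges; the template adds
  a smooth seeded texture (σ = 2.5 voxels, amplitude 0.15) inside the
  brain because purely geometric phantoms are nearly mirror-symmetric and
  would make rotation recovery ill-posed, which real anatomy is not.
* **Grids.**  Two scales are generated so the resolution-mismatch path is
  exercised: a "diffusion" grid at 0.125 mm (matching the acquisition the
  study conditions describe) and an "expression" grid at 0.2 mm (the atlas
  energy resolution); the 200→25 µm upsampling path (factor 8 per axis) is
  implemented and tested separately.
* **FA cohort.**  Per animal: base FA (0.10 inside brain, 0.60 on the
  sheet and tube, 0.55 on the blob) plus the animal's group offsets, plus
  voxelwise Gaussian noise (sd 0.03), clipped to [0, 1], then warped by a
  small random affine whose true parameters are returned.  Default group
  sizes are 6/4/6/5 (male WT, male del/+, female WT, female del/+ — the
  21-animal cohort of the study conditions).  Default effects mirror the
  qualitative result pattern: +0.15 FA on the tube in male del/+ only,
  −0.10 on the sheet in del/+ of both sexes, +0.05 on the blob in female
  del/+ only.  Misalignment jitter defaults to 0.15 mm / 1.5° / 1% scale.
* **Energy maps.**  One volume per available panel gene (26 of 27; one
  gene has no atlas map and is carried as unavailable): i.i.d. log-normal
  energy (σ = 0.3) around baseline 1.0 inside the brain, −1 outside.
  Genes in `enriched_sets` are multiplied by their factor inside the named
  structure; the default plants {Mvp, Sez6l2, Taok2} ×3 in the tube,
  {Kctd13, AldoA} ×3 in the sheet and {Kif22} ×3 in the blob, so the
  male-increase contrast has a known exclusive gene set.

Everything is bit-deterministic under (spec, seed); seeds fan out through
`numpy` `SeedSequence` spawn keys.

What the phantoms do **not** model: anatomically faithful mouse geometry,
diffusion signal formation (FA maps are simulated directly), nonlinear
tissue deformation (all warps are affine), spatial autocorrelation of
expression noise, and between-gene correlation.  Passing tests therefore
establish the correctness and calibration of the machinery, not effect
sizes on real data.

## Registration

12-parameter affine registration driven by normalized cross-correlation
(same modality) or normalized mutual information with 32 bins
(cross-modality, e.g. histology-to-MRI steps).  The optimizer is fully
deterministic: intensity centre-of-mass initialization for translation, a
coarse rotation grid (default within ±90°, multi-start over the 5 best
cells, each with its own centre-of-mass translation), Powell refinement
over all 12 scaled parameters through a 3-level image pyramid.  Candidate
rotations are scored and refined at the *mid* pyramid level: the coarsest
level's smoothing erases the texture that disambiguates near-symmetric
anatomy and can collapse rival rotation basins onto the wrong one.  The
metric is evaluated by interpolating the moving image at the fixed image's
informative voxels only (brain plus margin, capped at 20 000 points),
which is cheaper and keeps empty background from diluting the similarity.

Measured on planted transforms (translations up to 5 mm, rotations up to
±20° per axis, scales 0.9–1.1, 48³ phantom), median recovery error is
≈0.02 voxels translation and ≈0.2° rotation; occasional trials (~1 in 10)
settle in a symmetric rival basin several degrees off, which is why the
recovery criterion is stated on medians.  Jittered volumes for these
trials are generated on a padded grid — anatomy clipped off the field of
view has no consistent true alignment.

"Most typical" target selection registers every volume to every candidate
target and scores each target by the mean warp magnitude over movers,
where warp magnitude is the mean world displacement (mm) of in-brain
voxels; ties break to the lowest index.

## Skeleton statistics

The mean of the aligned FA maps is thinned to a skeleton: a voxel is kept
iff mean FA ≥ 0.2 (the threshold the study conditions settled on) and it
is a local maximum along the tract-perpendicular directions — the two
leading eigenvectors (by |eigenvalue|) of the Hessian of the σ = 1 voxel
smoothed mean FA.  Using both directions thins tubes to centrelines
instead of diametral planes; along a sheet's in-plane direction the
profile is flat and the condition is vacuous.  The comparison uses a 5–15%
relative slack (default 0.15) because a ridge whose crest falls between
voxel centres would otherwise lose all of its voxels; the default keeps
skeletons 1–2 voxels thick, comparable to the field's standard
implementation, and was fixed after verifying on the idealized Gaussian
tube that even the loosest setting stays on the centreline (max deviation
0.71 voxels).

Each animal's FA is projected onto the skeleton as the maximum along the
± perpendicular direction within a 4-voxel search radius, absorbing
residual misalignment of tract centres.

Group inference is an unpaired pooled-variance t statistic per skeleton
voxel (Welch available by option), enhanced by TFCE with the skeleton
convention E = 1, H = 2 (volumetric maps use E = 0.5), dh = max/100, on
the 26-connected skeleton voxel graph.  Family-wise error is controlled by
the max-TFCE permutation null: label permutations (default 500) drawn
without replacement from the distinct assignments, enumerated exactly
whenever they fit the budget (e.g. 4 vs 6 males → all 210 assignments), and

    p(voxel) = (1 + #{null max ≥ observed TFCE}) / (1 + #permutations).

Both one-sided directions are computed (del/+ increase and decrease, per
sex — four contrasts).  Significant voxels (corrected p < 0.05; the
threshold is read as FWE-corrected, with a voxelwise switch) are grouped
into 26-connected clusters, sorted by size with deterministic ids.  The
TFCE sweep is a union-find over voxels activated in decreasing height
order, JIT-compiled, because the calibration studies need ~10⁵
evaluations.

Calibration measured by the package's own studies: across 200 null
cohorts the significant-voxel fraction at α = 0.05 is ~3·10⁻⁴ (family-wise
control is conservative at the voxel level, as expected), and a planted
d = 3 tube effect is detected in ≈95% of tube skeleton voxels.

## Expression decoding

Significant clusters are transported to the expression grid by mapping
each cluster voxel centre through the composed chain and rounding to the
nearest expression voxel (nearest-neighbour transport; a nonempty cluster
always contributes at least one voxel).  Per gene and contrast, the pooled
expression over the contrast's cluster voxels is compared to the
expression over the entire skeleton with a two-sided Wilcoxon rank-sum
test.  The reference sample deliberately *includes* the cluster voxels
(the reference is the whole skeleton); exclusion is a config option.  The
pooled-voxel sample follows the described usage; a per-cluster-mean
variant is available by option.

The rank-sum p-value is exact whenever feasible: the classical no-tie
exact distribution when min(n, m) ≤ 8, or a full permutation enumeration
with midrank tie handling when the pooled size is ≤ 12; otherwise the
normal approximation with tie-corrected variance and continuity
correction.  A gene is called overexpressed when p < 0.05 (raw — no
multiple-testing correction, matching the described analysis;
Benjamini–Hochberg is available but off by default) *and* the cluster
median exceeds the skeleton median.  Genes significantly lower are
reported with direction "under", never as overexpressed; the unavailable
panel gene appears with status `no_map`, never as a negative result.

The exclusivity report lists, per contrast, the genes called in that
contrast and none of the other three.  On the packaged tables of the
published analysis this yields per-contrast counts 7/8/3/5 and the
exclusive male-increase trio.

A known consequence of the raw-threshold design: with 26 genes tested per
contrast, a marginal false positive (p just under 0.05) joins a contrast
list in roughly one synthetic run in ten, in which case the recovered
exclusive set gains one spurious gene.  This is intrinsic to uncorrected
multiplicity at these sample sizes, is measured (not hidden) by the
end-to-end study, and disappears with the `bh` correction option.

## Study sizes and runtime choices

The validation studies use: 64³ diffusion grids (0.125 mm) for cohort
analyses; 200 null cohorts and 3 power replicates at 500 permutations;
20 registration trials at 48³/0.25 mm; 200 random small-sample rank-sum
cases against the enumeration oracle.  These sizes put every Monte-Carlo
standard error well below the decision margins while keeping a full
validation run in the ten-minute range on one core.

## Known limitations

* Only affine transforms; the nonlinear residuals of real inter-subject
  registration are outside the model.
* The skeleton search direction per voxel is a single eigenvector; FSL's
  additional tube heuristics are approximated by the two-direction rule.
* Expression noise is spatially independent, which makes the rank-sum
  voxel-independence assumption exactly true in simulation; on real energy
  maps the effective sample size would be smaller.
* The "most typical" target selection is O(n²) registrations and is
  intended for small cohorts.
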