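# Methods

## The problem

When several clinical target volumes (CTVs) are treated through a single
isocentre — here the prostate (PO), prostate + seminal vesicles (PSV) and
the pelvic lymph-node volume (LN) — a couch correction that centres one
target displaces the others. Classical CTV→PTV margin recipes assume a
single rigid, roughly spherical target and an effectively infinite number
of fractions, so they cannot allocate margins between targets that move
differentially. The composite-volume method sidesteps those assumptions by
working directly with observed per-fraction anatomy.

## The method

For one patient, one structure and one image-matching protocol:

1. Per-fraction contours are mapped into the planning frame by the rigid
   translation of that protocol's registration (bone match or
   prostate-based soft-tissue match) and rasterized onto the planning
   voxel grid.
2. The **composite structure** is the voxelwise union of the registered
   per-fraction masks — the envelope of target positions actually observed
   over treatment.
3. A uniform margin is swept around the planning CTV (default 0–12 mm in
   1 mm steps). At each increment the overlap of the expanded CTV (the
   candidate PTV) with the composite is expressed as a percentage **of the
   composite volume** — the denominator is always the composite, because
   the question is how much of the observed envelope the PTV covers.
4. The individual margin m95 is the smallest expansion reaching 95%
   overlap, obtained by linear interpolation between the bracketing
   increments. If 95% is already met at the first increment the first
   margin is returned (no extrapolation below the sweep); if it is unmet at
   the last increment the sweep auto-extends in 1 mm steps to a 50 mm cap,
   beyond which the patient is reported non-convergent.
5. The population margin for a structure/protocol is

       margin = x̄ + 1.28 s

   over the cohort's m95 values (sample mean and n−1 SD) — the margin
   achieving the 95%-overlap criterion in 90% of a normally distributed
   population — reported to 0.1 mm, rounded half away from zero (with
   half-up rounding, mean 3.93 and SD 1.50 give 5.85 → 5.9 mm).

The classical recipe `2.5 Σ + 0.7 σ` (systematic and random displacement
SDs) is retained as a comparator for geometries that satisfy its
assumptions; for multi-target treatments it has no per-structure answer,
which is the method's motivation.

Cohort statistics: a two-sided Wilcoxon signed-rank test compares the
paired per-patient overlap distributions of the two protocols at each
margin increment (exact null for ≤ 25 informative tie-free pairs, normal
approximation with continuity correction otherwise; zero differences
dropped, ties mid-ranked; all-zero differences give p = 1, flagged
degenerate). A Shapiro–Wilk screen of the m95 sample gates whether the
normal-theory aggregation is reported with a non-normality warning. No
multiple-testing correction is applied across increments; read family-wise
claims accordingly.

## Geometry semantics

* Everything lives on a physical voxel grid in mm (anisotropic spacing
  allowed; the clinical scenario is 1 mm in-plane, 2.5 mm slices). Axis
  order is (x, y, z), 0-based.
* Rasterization: a voxel is occupied iff its centre lies inside an odd
  number of the slice's polygons (even-odd rule); contour planes snap to
  the nearest grid slice within half a slice spacing, beyond which the
  contour is rejected as unmappable. Partial-volume effects are ignored —
  a second-order error at 1 mm resolution.
* Shifts are applied to continuous contour coordinates **before**
  rasterization, which is volume-preserving for non-integer translations.
  Fraction structures supplied as voxel masks (NIfTI path) are translated
  at nearest-voxel resolution instead; prefer contour sources when margins
  below the voxel size matter.
* Isotropic expansion uses the exact Euclidean distance transform on voxel
  centres with physical sampling: a voxel joins the expansion iff its
  centre is within the margin (closed ball) of an occupied input centre.
  One distance map of the planning CTV serves every increment of a sweep,
  so a 13-step sweep costs one EDT plus 13 threshold counts.
* Ties/plateaus: the first threshold crossing is used; deterministic and
  conservative when voxelization flattens the overlap curve.

Centre-of-voxel semantics carry a sub-voxel surface bias: an expanded
structure's measured volume falls short of the continuum limit by roughly
half a voxel's width of boundary layer. For a 15 mm sphere grown by 5 mm
on a 1 mm grid the measured volume is ~1.7% below (4/3)π·20³ when the
sphere is sampled symmetrically about a voxel corner (and ~2.3% below when
its centre coincides with a voxel centre, which aligns the boundary with
the lattice). A treatment-planning system using surface-mesh expansion
will differ from this EDT expansion at the sub-voxel level.

## The synthetic cohort

No public structure sets exist for this scenario, so the package generates
its own study conditions:

* **Anatomy** (2 mm isotropic grid by default; 1 mm available): a
  spherical prostate (~26 cm³), two posterosuperior vesicle lobes added to
  form the PSV (~35 cm³), and a horseshoe (annular-sector) nodal volume
  (~360 cm³) — the volume scale of a high-risk prostate cohort. Shapes are
  emitted as per-slice polygons, the same currency as clinical structure
  sets. The PSV reuses the prostate polygons, so PO ⊆ PSV exactly.
* **Motion**: per patient a systematic prostate displacement
  (per-axis SD `sigma_sys`, default 2.0 mm) plus per fraction a random
  displacement (`sigma_rand`, 1.5 mm), both Gaussian and axis-independent —
  the error structure both margin formulas assume. PO and PSV move
  coherently. The nodal volume instead follows the bony frame apart from an
  independent per-fraction displacement (`node_decoupling`, 2.0 mm),
  modelling the observed prostate-vs-node differential motion (clinically
  up to ~6 mm). A per-fraction isotropic scale jitter about each structure
  centroid (`volume_jitter`, SD 0.03) stands in for contouring and filling
  variation.
* **Protocols**: both registrations are emitted from the same draws. Bone
  match: zero shift (the bony frame is the planning frame), so targets keep
  their full displacement. Soft-tissue match: the shift re-centres the
  prostate up to a residual match error (`soft_tissue_residual`, 1.0 mm),
  collapsing PO/PSV residuals while the LN inherits the full differential
  motion. This reproduces the clinical pattern: prostate matching shrinks
  PO/PSV margins and inflates the LN margin.
* Defaults were chosen once for plausibility; the resulting composite-to-
  planning volume ratios (~1.25–1.45) sit in the clinically reported
  1.2–1.6 range.

Every draw descends from one integer seed through `SeedSequence.spawn`, so
identical inputs give byte-identical reports.

**What the generator does not emulate:** inter-patient anatomical
variability (every synthetic patient shares the phantom, so planning-volume
SD across patients is 0), rotations/pitch/roll, deformation beyond
isotropic scaling, bladder/rectum filling mechanics, intrafraction drift,
and CBCT image formation (only structures are generated). Passing tests
therefore validate the geometry and statistics of the method, not the
clinical realism of any particular margin value.

## Problem sizes used in tests and the acceptance script

Studies run at 2 mm grid spacing: 20 patients × 5 fractions for the
default and zero-motion cohorts, 50 patients for the rigid-sphere recipe
comparison (where 2.5Σ + 0.7σ = 6.4 mm at Σ = σ = 2 mm; the
composite-volume margin lands within ±1.5 mm — slightly below, as a
5-fraction composite under-samples the random error that the
infinite-fraction recipe integrates over). Randomized geometry oracles use
grids up to 30³ where exhaustive per-voxel brute force is exact and cheap.

## Known limitations

* Translational registrations only — by design, matching the clinical
  workflow modelled; rotations are future work.
* The composite built from N fractions is a biased-down estimate of the
  true motion envelope for small N; margins derived from 5 fractions are
  slightly tighter than the infinite-fraction recipe's.
* Nearest-slice contour snapping quantises the z-component of sub-voxel
  shifts on coarse (2.5 mm) slices.
* Unadjusted per-increment p-values, as noted above.
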