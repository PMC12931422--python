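# Methods

This note documents the models, conventions and numerical choices
behind `marrowdose`, what the synthetic fixtures do and do not emulate,
and the known limits of the approach.

## Coordinate and raster conventions

Everything geometric lives in the DICOM patient coordinate system
(LPS), in millimetres. Raster volumes are indexed `(i, j, k)` along
`(x, y, z)`, 0-based, and a voxel's coordinate is its **center**:
`world = origin + index * spacing`. Only axis-aligned volumes (identity
direction cosines) are supported; a CT series with oblique orientation
or a non-uniform z grid (missing slices) is rejected at read time
rather than silently resampled. RT-dose values are scaled to Gy at read
time (`stored * DoseGridScaling`).

## Phantom model and selection

A phantom is two co-registered integer rasters — bone-site label and
tissue subtype (cortical / spongiosa / medullary cavity) — plus body
metadata (age, sex, height, weight). The on-disk container is two NRRD
volumes and a JSON sidecar, written and read through SimpleITK; site
names must match the packaged 34-site nomenclature (case-insensitive).

Selection is strict lexicographic with priority age > sex > height >
weight: no weighted distance, no interpolation between phantoms.
Rationale: the priority order is a stated property of the workflow and
a weighted metric would introduce free parameters with no reference
values. Two deliberate refinements where the procedure is otherwise
underdetermined: if no candidate of the patient's sex survives the age
filter, selection proceeds with the opposite sex and returns a flag
(selection never fails on sex alone); residual ties go to the smallest
phantom id, making selection a pure function of its inputs. A missing
patient height or weight skips that comparison level.

## Skeletal registration

The patient skeleton is every CT voxel with HU ≥ 200 (configurable).
200 HU is a conventional floor for bone attenuation — low enough to
keep trabecular bone, high enough to exclude soft tissue; the value is
surfaced in the config and in logs because contrast agents and metal
implants can cross it.

Registration is point-to-point ICP: nearest-neighbour correspondence
through a k-d tree alternating with the closed-form least-squares rigid
update (Kabsch SVD; the Umeyama scale estimate when isotropic scaling
is enabled, which it is not by default — phantoms are rigid and body
size is handled by selection, not warping). The phantom skeleton is the
moving set, so bone-site labels land in patient coordinates. Point sets
larger than `subsample` (default 20 000) are reduced by seeded uniform
random subsampling.

Two numerical choices deserve explanation:

* **Multi-start initialization.** Voxel-derived skeletons are solid
  lattice clouds, and a solid lattice is nearly self-similar under
  small shifts: interior voxels always have a neighbour within half a
  voxel regardless of alignment, so they contribute almost no
  rotational gradient and single-start ICP locks into lattice-shifted
  local minima (measured: 1–3 mm residual even for 2° rotations on the
  test phantom). `icp_register` therefore runs the canonical loop from
  the centroid start *and* from the four proper principal-axis
  alignments of the two clouds (in similarity mode, the RMS-radius
  ratio seeds the scale) and keeps the start with the lowest final mean
  correspondence distance; ties go to the earlier start so identical
  clouds return the identity. This restores exact recovery of rigid
  displacements up to 45° / 100 mm on noise-free point sets. It can be
  disabled (`ICPConfig.multi_start = False`) to get classical
  single-start behaviour.
* **Monotone history.** The recorded objective is the mean
  nearest-neighbour distance per iteration. The Kabsch step minimizes
  the *squared* loss, which guarantees a non-increasing RMS but not a
  non-increasing mean; an update that would worsen the mean is
  discarded and iteration stops, so the reported history is
  non-increasing by construction. Convergence is declared when the mean
  improves by less than `convergence_tol` (default 0.01 mm) within
  `max_iterations` (default 100) — both defaults are conservative for
  millimetre-scale clinical rasters and are overridable.

Registration accuracy against a planted ground truth is voxel-limited
once the skeleton has passed through a CT raster: positions snap to the
nearest CT voxel, so ~half-voxel RMS residuals are expected and
observed (≈3 mm at 4 mm voxels).

## Registration QA

The volume overlap fraction discretizes the registered phantom points
to their nearest patient-CT voxel (duplicates collapse; the score is
set-based) and divides the intersection by the *patient* voxel count —
the score is deliberately asymmetric and is never applied as an
automatic acceptance threshold: thin bones (ribs, clavicles) overlap
poorly even when well aligned, and bones deep inside or far outside the
field contribute little dose error either way. Acceptance is an input:
two independent review flags ANDed, supplied interactively (flag file)
or by a scripted policy for automated runs. VOF-vs-characteristics
associations use Spearman rank correlation (average-rank ties,
two-sided large-sample p), chosen for robustness to skew and for
handling binary-coded sex; a constant characteristic yields a missing
(not zero) coefficient.

## Marrow-fraction weighting and dose metrics

The packaged reference table gives the fraction of total active marrow
at each of 34 bone sites for reference ages {0, 1, 5, 10, 15, 30} and
both sexes (ages 0–10 sex-shared); every column sums to 1 within
rounding of the printed values (±0.002, verified by test). Lookups snap
to the nearest reference age with ties toward the older column; no
interpolation between columns, since the fractions are published
reference values rather than a continuous model.

Within a site the fraction is divided equally over the spongiosa and
medullary-cavity voxels; cortical voxels carry no marrow. Sites whose
fraction is zero for the patient's age/sex are dropped from the sample
(numerically identical to carrying zero-weight voxels). A site with a
positive fraction but no non-cortical voxels is an error, not a silent
renormalization. Total weight therefore equals the summed fraction of
the sites present — 1.0 only for a full 34-site phantom, which is the
correct behaviour for truncated anatomies.

Doses are sampled by trilinear interpolation at the registered voxel
centers (node-exact, the treatment-planning convention) with exactly
zero dose outside the dose-grid hull — matching the assumption that the
planning system knows nothing beyond its grid, and introducing the same
systematic downward bias that assumption carries in practice.

The dose distribution is kept as an exact weighted empirical
distribution — no histogram binning, hence no bin-width parameter; any
binned DVH can be derived from it. Conventions:

* V(d) = 100 · P(dose ≥ d); right-continuous staircase between atoms.
* D# is the (100−#)-th weighted percentile with the lower-boundary
  convention, `inf{d : F(d) ≥ 1 − #/100}`. This reproduces the
  characteristic D50 = 0 of mostly-unirradiated marrow and makes
  D50 ≤ D10 ≤ D1 hold identically.
* The staircase polyline returned by `DVH.curve()` carries the
  right-hand value on each step, so trapezoidal integration of V/100
  over the curve reproduces the weighted mean exactly (tested to 1e-9).
* `mean_per_rx` is the mean marrow dose divided by the session's total
  prescribed dose; it is reported missing when the prescription is zero
  or absent.

Cumulative dosimetry for multi-session patients sums doses voxelwise on
a single shared phantom selected once from the patient's
characteristics, taking weights once; linearity then makes the
cumulative mean equal the sum of session means. Requiring one phantom
per patient is what makes cross-session accumulation well defined;
sessions with genuinely different anatomy coverage remain an open
problem here as in practice.

## Synthetic fixtures

The generator emulates the *structure* of the inputs, not anatomy: each
bone site is a compact digital blob (outer shell cortical, core
medullary where requested, spongiosa between), stacked cranio-caudally
with lateral stagger so the cloud has distinct principal axes. CTs
embed the skeleton at bone-range HU (default 1000 HU on a 0 HU
background, optional Gaussian texture noise on bone voxels) under a
known rigid transform, written as standard-conformant DICOM CT series;
dose grids are uniform boxes and/or Gaussian beams written as RTDOSE;
plans carry per-beam prescriptions and isocenters as RTPLAN. All UIDs
derive deterministically from the seed, so a fixture tree is
reproducible byte for byte. Cohorts plant record mismatches
(±0.5 Gy), alignment failures (via planted review flags, emulating the
human evaluation) and multi-session patients to exercise every
exclusion path with exactly known counts.

What passing tests on these fixtures shows: geometric, arithmetic and
bookkeeping correctness of every stage under controlled truth. What
they do not show: performance on real anatomy — posture variation,
couch and implant artifacts in the HU threshold, partial-body CTs,
non-rigid patient-phantom shape differences, and realistic dose
gradients. Those effects are exactly why the human-review gate exists
in the workflow.

Default problem sizes (a 2 150-voxel six-site phantom on a 44×44×80
grid of 4 mm voxels, cohorts of ~10 patients, dose-metric oracles at
10⁵ voxels) were chosen as the smallest scales at which every geometric
effect of interest — multi-voxel blobs per site, sub-voxel registration
residuals, z-separated treatment fields — is still present.

## Known limitations

* Rigid registration only: posture differences and anatomical
  truncation are failure modes, handled by rejection, not correction.
* No out-of-field dose model: dose beyond the planning grid is zero by
  assumption, biasing distant-marrow dose downward.
* Treatment-region categorization is a configurable keyword/isocenter
  stub, not a validated clinical taxonomy.
* Reference marrow fractions are population values; individual marrow
  distribution (age-related conversion, prior therapy) is not modelled.
* No fractionation or biologically-effective-dose corrections; doses
  are summed physically across sessions.
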