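# Methods

`cdvim` re-creates, end to end on synthetic data, a connectivity-based
procedure for localising the ventralis intermedius nucleus (Vim) of the
thalamus — the stereotactic target for tremor surgery, invisible on
conventional MRI.  The Vim is the thalamic relay of the dentato-thalamo-
cortical pathway (DTCp), which runs from the cerebellar dentate nucleus
through the superior cerebellar peduncle (SCP), decussates, and terminates
in primary motor cortex (M1).  Reconstructing the DTCp with probabilistic
tractography and intersecting it with the thalamus yields a
connectivity-defined Vim (cd-Vim) whose centroid can be compared, subject by
subject, with the atlas coordinate used in surgical planning.

The package has five scientific layers: a fibre phantom generator with known
ground truth, a probabilistic streamline tracker, the cd-Vim extraction
rule, the AC-PC atlas formula, and the variability / confound / test-retest
statistics suite.  A pipeline driver and CLI glue them together.

## The fibre phantom

Real inputs to this kind of analysis are per-voxel multi-fibre orientation
posteriors plus anatomical masks.  The phantom emits those directly — no
diffusion signal is simulated, and no registration beyond an optional
Jacobian bump is modelled.

**Grid.** 64x64x64 voxels at 1.25 mm isotropic (the resolution of the
diffusion data the procedure targets), world origin at the mid-commissural
point (MCP); +x right (ML), +y anterior (AP), +z superior (SI).  Masks and
fields are built on voxel *centres*, and the tracker decides mask membership
by the nearest voxel centre (floor(v + 0.5) of the continuous voxel
coordinate).  This one consistent convention is used everywhere; reported
results use voxel-to-world mapping.

**Geometry.** Each hemisphere's DTCp is a tube around a piecewise-linear
skeleton smoothed with a monotone PCHIP interpolant: a straight arm from an
M1 patch (±20, −12, 32) down *through* the canonical Vim coordinate to a
bend point 15 mm below it, then a second straight arm across the midline to
the contralateral cerebellar blob (∓15, −30, −28).  Guard knots confine the
smoothed corner to ±5.5 mm of the bend, so the tube crosses the thalamus
box as a single straight chord and crosses the midline exactly once (the
medio-lateral coordinate is strictly monotone along the knots).  The left
DTCp therefore traverses the *right* SCP and ends in the *right* cerebellum,
as the decussating anatomy requires.  Tube radius is 3.2 mm, pinched to half
the configured SCP width (default 3 mm, within the healthy 2–4 mm range) at
the waist where the lower arm reaches 4 mm across the midline, flaring to
4.8 mm in the cerebellum.

**Canonical coordinates.** The default canonical Vim centroids are the
published cohort-average cd-Vim world coordinates (left (−13.71, −18.78,
2.67), right (13.09, −17.61, 3.94) in ML / AP-from-AC / SI), re-expressed in
the MCP frame assuming a 26 mm AC-PC distance (AC = (0, 13, 0),
PC = (0, −13, 0)).  Default per-axis jitter SDs are the published
left-hemisphere SDs (AP 1.14, ML 1.22, SI 1.33 mm).

**Ground truth.** The true cd-Vim centroid is the volume centroid of the
continuous tube clipped by the thalamus box, evaluated by quadrature on a
0.4 mm lattice tied to the box.  Because the tube bends below the box, a box
centred on the Vim waypoint would have a slightly biased intersection
centroid; the box centre is therefore iterated (at most 8 Newton-style
updates, tolerance 0.05 mm) until the intersection centroid lands on the
configured canonical coordinate.  Lattice, box and tube all move rigidly
with a subject's jitter, so the jittered truth is exactly canonical +
jitter — which is what makes the fast analytic cohort samplers
(`sample_cohort_truths`, `sample_retest_truths`) exact rather than
approximate.

**Fibre field.** Voxels inside a tube carry that tube's local tangent as a
fibre population (volume fraction 0.6, configurable dispersion, default
8°).  Voxels inside both tubes — the decussation region, where the two
hemispheres' pathways cross — carry two populations at fraction 0.45 each.
Orientation noise is a Gaussian perturbation of the polar angle about the
mean direction with uniform azimuth: the simplest sampler with one
interpretable parameter.

**Masks.** Thalamus: a 16x20x16 mm box at the (iterated) centre.  M1: a
3.5 mm ball at the cortical end.  Cerebellum: a 6 mm ball at the cerebellar
end.  Exclusions per tract: the contralateral supratentorial compartment
and the ipsilateral infratentorial compartment, with margins chosen so the
tract's own tube never touches them.  SCP masks: the tube voxels within
±3 mm arc length of the waist, named by the side of the peduncle itself
(the left DTCp's waist is the right SCP).  Termination: a CSF shell
wrapping each waist (the peduncle is surrounded by CSF in vivo), kept
≥1.5 mm clear of both tubes.

**Jitter, retest noise, confounds.** Each circuit (tube + its masks) is
rigidly translated by a per-subject Gaussian offset (per-axis SD and
optional per-hemisphere mean).  Test-retest pairs share one subject-level
offset and add independent within-scan noise (default SD 0.5 mm, required
to be below the between-subject SD — the regime the reliability analysis
assumes).  Five confounds are drawn per subject: two movement surrogates
(log-normal, median ≈ exp(−1)·e^0.3 ≈ 0.5 mm and 0.37 mm — typical
volume-to-volume head motion), M1 and cerebellar mask volumes (normal,
9 500 ± 1 000 and 140 000 ± 15 000 mm³) and total intracranial volume
(normal, 1.42 ± 0.14 L, matching the reported cohort).  Confounds are
independent of jitter unless `confound_coupling=(name, coeff)` explicitly
adds `coeff · z(confound)` mm to the AP offset.  The Jacobian field is 1
everywhere with an optional multiplicative bump inside the SCP masks,
isolating the volumetric integration step.  What the phantom does *not*
emulate: partial-volume and susceptibility artefacts, curving cortical
sheets, distance-dependent connectivity decay, registration error — so
passing tests demonstrate the correctness of the pipeline's logic and
statistics, not its robustness to real-data artefacts.

## Probabilistic tracking

Per seed voxel, `samples_per_voxel` streams (desk-scale default 250; the
full-scale protocol's 5000 by configuration) are propagated bidirectionally
in 0.5 mm steps, up to 2000 steps per half.  Fibre populations are looked up
at the nearest voxel (no interpolation — a documented simplification).
Among populations whose volume fraction clears the floor (0.01), the first
step samples proportionally to the fractions; subsequent steps follow the
population best aligned with the previous direction (maximum |dot|),
sign-aligned.  A step is kept only when the cosine with the previous
direction is ≥ 0.2 (≈78.5° permitted bend).  Entering an exclusion mask
rejects the sample; entering the CSF termination mask ends that half-track
(the entry voxel still counts); a sample is accepted only if the full track
visits every waypoint.  The output value at a voxel is the fraction of
launched samples that were accepted and visited it, counted once per sample
— a probabilistic index of connectivity (PICo).  Mainstream multi-fibre trackers report
streamline counts instead; the difference is a global scale that the
combined-map normalisation cancels.

The two-seed reconstruction (seed M1 with waypoints contralateral
cerebellum + thalamus; seed cerebellum with waypoints contralateral M1 +
thalamus) is summed and divided by its maximum, so the combined map has
maximum exactly 1; the division constant is retained as the tract's peak
connectivity for the SCP-volume correlation.  Two implementation notes:
streams are propagated in vectorised batches (chunks of ≤32 768) with
results identical to one-at-a-time propagation (tested); and when the field
is fully deterministic — zero dispersion everywhere and at most one
population above the floor at every seed voxel — one sample per seed voxel
is propagated and counts are scaled, which is bit-identical to brute force
(also tested) and keeps noise-free cohort studies fast.

## cd-Vim extraction

The combined map is zeroed outside the thalamic mask; an all-zero
intersection raises a "no connectivity" signal that the pipeline records as
a subject exclusion.  The adaptive threshold keeps voxels ≥ 20% of the
maximum *within the intersection* — relative to the subject's own peak, so
the rule is invariant to any positive rescaling (a 1e-12 relative guard
keeps exact-boundary voxels on the same side under rescaling).  The centroid
is the unweighted mean voxel-centre position of the largest 26-connected
component, mapped through the affine; exact size ties are broken by higher
mean connectivity, and a connectivity-weighted centroid is available behind
a flag.  The reported volume is the thresholded ROI in mm³ (count × voxel
volume); the pre-threshold intersection support volume is emitted alongside
since either reading of "intersection ROI volume" is defensible.

## Atlas targeting

The surgical standard: AP = (AC-PC length)/3 − 2 mm anterior to the PC,
ML = midline ± 12.5 mm (the conventional 12–14 mm band), SI = 0 on the
axial AC-PC plane.  For tilted landmark pairs the target is built in an
AC-PC local frame — y along PC→AC, x the world-ML axis orthogonalised
against it, z completing the right-handed frame — and this convention (a
package choice; no standard exists for tilted planes) reduces to the world
frame for axis-aligned landmarks.  AC-PC lengths ≤ 6 mm would place the
target behind the PC and produce a warning status rather than an error.

## Statistics suite

Axes are reported in the stereotactic sign convention (posterior to AC,
left of midline, inferior to the AC-PC plane negative).  Displacements are
absolute per-axis distances plus the Euclidean distance (ED); cohorts are
summarised by RMS ED, maximum ED and per-axis maximum absolute
displacement.  Hemispheric position: paired t per axis, with |ML| compared
so both sides measure distance from the midline.  Hemispheric variability:
the Pitman-Morgan paired-variance test, t = (F−1)√(n−2) / (2√(F(1−r²))) on
n−2 df with F the variance ratio and r the pair correlation — algebraically
the Pearson-correlation t between pair sums and differences, which is also
how the permutation validation oracle is built (shuffling the sum-difference
pairing; exact under the equal-variance bivariate-normal null).  Note the
exactly-equal-variance corner (F = 1) is defined as t = 0.  Atlas
comparison: one-sample t of the signed per-axis offsets.  Confound screen:
each of 4 displacement metrics regressed on each of 5 confounds per
hemisphere (20 cells), F-test per cell, flagged at the published corrected
level 0.007 (the nominal 0.05/20 = 0.0025 flag is emitted alongside, since
the published level is not 0.05/20); a constant confound invalidates only
its own cells.  Principal directions: eigendecomposition of the 3×3
centroid covariance, eigenvalues descending, eigenvector signs fixed by
first nonzero component.  SCP volumetrics: Jacobian determinants integrated
over the SCP mask × voxel volume; peak tract connectivity is correlated
(Pearson) against the *contralateral* SCP volume — the peduncle the
decussating tract actually traverses.  Test-retest: left-tailed Wilcoxon
signed-rank of within-subject (scan1−scan2) displacements against
between-subject (scan1−cohort mean) displacements per metric, reflecting
the a-priori expectation that repeat scans differ less; zero differences
are dropped (Wilcoxon's original prescription), the exact null is used for
≤25 nonzero pairs and the continuity-corrected normal approximation above.
Hemispheric volume asymmetry: two-sided Wilcoxon with medians reported —
the source analysis reports medians without naming its test, so the
signed-rank choice is an assumption of this package.  Degenerate inputs
(zero-variance differences, all-zero Wilcoxon differences) produce explicit
exact-difference or not-applicable reports rather than spurious p-values.
All tests use α = 0.05 unless a corrected level applies.

## Problem sizes and numerical choices

The evaluation experiments run at these sizes, chosen as the package's
standard study conditions: localisation recovery on a zero-noise cohort of
5 subjects (10 centroids) at 250 samples/voxel; type-I calibration with
10 000 replicates of n = 100 pairs per test; variance recovery on a tracked
cohort of 100 subjects with per-axis SDs (1.1, 1.2, 1.3) mm; the SCP sweep
over waist widths of 1, 2, 3 voxels with 20 repetitions each; test-retest
detection with 44 pairs (the reliability cohort's size) over 100
replicates; and the reduced-sampling check comparing 250 against 5000
samples/voxel voxelwise with a 4-SE pooled binomial bound.  Seeds are
threaded through `numpy.random.SeedSequence` everywhere; identical seeds
give bit-identical cohorts, maps and reports (tested).

## Known limitations

Tube phantoms cannot probe false-positive pathways other than the built-in
decussation crossing; nearest-voxel orientation lookup underestimates
partial-volume dispersion; the atlas local-frame convention for tilted
AC-PC planes is one of several defensible choices; the volume-asymmetry
test and the pre/post-threshold volume convention are assumptions where the
source procedure is ambiguous; and the confound generator draws mask
volumes rather than measuring them from the phantom masks, so the screen's
null behaviour — not a true anatomical coupling — is what is exercised by
default.
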