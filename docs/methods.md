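# Methods

## Geometry

All geometry lives in one world frame: RAS axes, millimetres, 0-based
voxel indices, a voxel's world position its center.  A trajectory is a
straight segment entry→target.

* **Mask distance** is measured to nonzero-voxel *centers* (0 when the
  segment intersects a nonzero voxel box).  Sub-voxel structure boundaries
  are deliberately not modelled: the center convention is unambiguous and
  directly checkable against a Euclidean distance transform.
* **Transgression** is decided by exact segment / axis-aligned-box
  intersection via Amanatides–Woo 3-D DDA traversal in voxel coordinates,
  so there is no step-size artefact.  Segments touching a box face are a
  measure-zero boundary case resolved by the traversal's floor convention.
* **Streamline distance** treats every polyline edge as a straight segment
  (TRK semantics; no spline interpolation) and minimises the robust
  clamped segment–segment distance over all edges.
* **Midline distance** is the minimum unsigned distance from the whole
  segment to the midsagittal plane (0 when the endpoints straddle it).
  The plane passes through the mid-commissural point with the left–right
  axis as normal, obtained by orthogonalising +x against the AC–PC line.
  Measuring over the whole trajectory (rather than at the entry point
  only) is a design choice: the alternative conventions differ only for
  trajectories that converge towards the midline at depth.

Zone classification uses strict thresholds: zone 1 iff distance <
threshold (vessel 3 mm, CST 3 mm, midline 20 mm, all configurable).  A
distance exactly equal to a threshold is zone 2; the high-risk zones are
defined by strict inequalities on both sides and equality is a
measure-zero case.

The TSI sums four indicators (sulcus, eloquent cortex, vessel zone 1,
midline zone 1).  Ventricle transgression and the CST zone are computed
and reported but never scored.  A direct consequence used as an internal
consistency check: a group's mean TSI equals the sum of its four
component counts divided by the group size, exactly.

Vessels may be given as centerline polylines, a mask, or both; with both
the smaller distance is used, since the appropriate representation depends
on the upstream segmentation.

## Statistics

* Continuous outcomes: Welch two-sample t-test; experience-adjusted
  analysis by OLS of the outcome on arm + years of neurosurgical
  experience (the arm coefficient's p-value is the adjusted p).  Binary
  safety flags use logistic regression.  Logistic regression cannot apply
  to continuous outcomes, hence the linear/logistic split by outcome type.
* 2×2 component incidences: Pearson chi-square without continuity
  correction; zero-margin tables fall back to Fisher's exact test and are
  flagged.
* Normalized planning time: per-trainee min–max over that trainee's ten
  exercises, (t − min)/(max − min) ∈ [0, 1]; a degenerate constant range
  maps to 0.5.  Min–max was chosen because it is scale-free per trainee
  and yields cohort means on the unit interval comparable across arms.
* Learning curve: OLS of log planning time on exercise order within an
  arm; slope, standard error, p and 95% CI are reported.
* Clustering: the four profile features (trajectory changes, lobe
  changes, tractography availability, normalized time) are z-scored; a
  symmetrized kNN graph (default knn = 15) over the *unique* feature rows
  is partitioned by Leiden modularity (resolution 1.0, fixed seed);
  identical profiles share a label, making the partition invariant to row
  order and feature column order.  A 2-D UMAP embedding (same seed) is
  attached for display only.  The number of clusters is data-dependent
  and is not a calibrated quantity.
* Raw p-values are reported without multiplicity correction, matching
  standard reporting for this kind of exploratory cohort.

## Synthetic scenes

The hemisphere is a half-ellipsoid (semi-axes 62 × 84 × 66 mm, right
hemisphere x > 0, midsagittal plane at x = 0).  Each scene contains:

* a spherical tumour (radius 8–11 mm) confined to a deep central-core box,
  with the biopsy target at its centroid;
* a CST of 25 streamlines from the precentral (M1) band down through an
  internal-capsule waypoint posterior to the tumour into a brainstem box,
  cubic-spline smoothed and resampled at ~2 mm.  Points falling inside the
  tumour's clearance sphere (radius + 2.5 mm) are moved laterally (+x)
  onto the sphere: the bundle is deviated *around*, never through, the
  lesion, and strictly laterally — the displacement pattern of these
  tumours.  Dense resampling before the push keeps polyline chords from
  cutting back through the clearance sphere;
* cortical vessels as random smooth walks on the ellipsoid surface
  (72 polylines, ~4 mm steps), density set so that roughly half of all
  planned trajectories pass a vessel within 3 mm;
* sulci as 14 thin (≈2 mm half-width) sheets through the brain center
  restricted to the outer cortical shell; an M1 band on the precentral
  shell; a paraventricular ellipsoid ventricle;
* a sampled cortical surface (~2 800 points) for entry-point candidates.

Every generator is a pure function of its seed.

## Behavioural cohort simulator

The simulator emulates the study design: 19 trainees (5 junior ST1–2,
7 intermediate ST3–5, 7 advanced ST6–8; experience drawn per tier so the
cohort mean is ≈4.1 years) each plan all 10 tumours in one session,
patients alternating between arms in a fixed order.

One planning session works by candidate rejection:

1. the number of trajectory changes is Poisson with the arm's calibrated
   mean (T-nBx 2.89, A-nBx 3.66 — the published cohort means);
2. candidate entries are sampled on the cortical surface with a
   superior-approach and convexity bias, shaped by the planner's *visible*
   CST: the tractography arm down-weights entries whose path would
   approach the true (deviated) bundle, the anatomy arm down-weights
   entries approaching a canonical medially-shifted "textbook" course
   plus a per-trainee random offset — its avoidance is systematically
   misdirected, which is what produces its higher true-CST and M1 hit
   rates;
3. each rejected candidate switches lobe (4-way angular partition of the
   hemisphere around fixed landmark planes) with probability
   lobe-mean / change-mean, so lobe-change counts match the published
   means (T 0.23, A 0.66) in expectation while never exceeding the
   trajectory-change count;
4. the accepted entry minimises a penalty over the candidates: length,
   sulcus/M1 transgression, vessel zone 1 and visible-CST proximity, plus
   per-candidate judgment noise (larger in the anatomy arm);
5. planning time is arm mean × change-count factor × learning factor ×
   lognormal noise, every factor mean-one so the arm means are exactly the
   published 197.5 s (T) and 252.8 s (A).  The anatomy arm carries a
   linear decrement of 0.06 on log-time per exercise position (its
   learning curve; the tractography arm has none).  Log-time dispersion is
   0.55 (T) and 0.35 (A): with the tractography overlay, planning time
   collapses for easy windows and stretches for conflicted ones, while
   anatomy-only planning is uniformly laborious.  This split is what
   reproduces the published per-trainee min–max normalized time means
   (≈0.33 vs ≈0.48); a single dispersion cannot, because lognormal right
   skew pulls both normalized means down together.

Change counts are Poisson rather than a shifted variant so the calibrated
mean is matched exactly with no extra shape parameter; times are lognormal,
consistent with the published range (tens of seconds to ~20 minutes).

Replicate cohorts for calibration checks share one fixed set of 10 scenes
(the study reused the same 10 patients for every trainee) and vary only
the behavioural seed; 20 replicates of 190 plans keep the whole
calibration suite under a minute on one CPU.

## What the simulator does and does not show

The generator reproduces the *group-level statistical structure* of the
study cohort — change counts, times, normalized times, learning-curve
pattern, the vessel/sulcus incidence scale, the CST zone-1 asymmetry
between arms, and the M1-transgression direction.  Passing tests therefore
demonstrate that the measurement pipeline and statistics recover known
structure from data of this shape; they say nothing about real tissue:
there is no MR intensity or diffusion signal, no brain shift, sulci and
vessels are geometric cartoons, and trainee cognition is an emulation
device (candidate rejection), not a model of decision making.

Known limitation: with a single shared anatomy, the tractography arm's
safe windows (anterior or posterior of the tract) lie farther from the
laterally-placed tumour than the average anatomy-arm entry, so the
tractography arm's mean trajectory length comes out slightly *longer*,
whereas the study — with different patients in each arm — reported it
shorter.  The anatomy-arm mean length (≈57 mm here) is within the
published dispersion of its 62.37 mm value; the between-arm length
ordering is not reproduced and is not claimed.

## Numerical choices

* Distances are exact (closed-form segment/edge and DDA traversal);
  oracle suites check the streamline distance against dense resampling to
  0.01 mm and the mask distance against a sampled distance transform to
  half a voxel diagonal.
* Voxel size 2 mm everywhere; scene grids ≈39 × 90 × 73.
* Penalty evaluation during simulation uses precomputed distance fields
  and mask lookups (fast, approximate); final scoring always uses the
  exact primitives.
* Degenerate inputs fail loudly: zero-length segments, empty masks or
  bundles, missing scored structures, invalid cohort rows (reported with
  CSV line numbers), constant-experience adjustment (flagged fallback to
  the unadjusted p).
* All randomness flows through numpy Generators seeded from explicit
  integers; per-session seeds derive from (cohort seed, trainee, exercise)
  so any single plan can be regenerated in isolation.
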