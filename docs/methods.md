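# Methods

## Coordinate conventions

All positions are world-space millimetres taken from each image's affine
(voxel indices are 0-based; a voxel's coordinate is its centre).  World
axes follow RAS: +x patient Right, +y Anterior, +z Superior.  Landmark
names containing "left"/"right" follow radiological display convention
(image left = patient right); the auxiliary-landmark axis table encodes
this explicitly, so the names never have to be re-interpreted at run
time.

## The displacement model

The model state is, for every ordered pair (u, k) of the 17 canonical
landmarks, a trivariate Gaussian for the position of u relative to k:
mean μ<sub>u,k</sub> = E[l<sub>u</sub> − l<sub>k</sub>] and covariance
Σ<sub>u,k</sub>.  Fitting is the sample mean and sample covariance
(n − 1 denominator) over the subjects where both landmarks are present,
plus a ridge λI.  Choices:

- **λ = 1 mm² (configurable).**  A personalized model is fit from 10
  cases; a 3×3 sample covariance from 10 points can be near-singular,
  and every fused prediction inverts these matrices.  1 mm² is far below
  anatomical variance (tens–hundreds of mm²) yet bounds the condition
  number.
- **Minimum 4 valid samples per pair.**  A 3D covariance needs at least
  4 points to be generically full rank; below that the pair is flagged
  unusable and excluded from inference (never silently zeroed).
- **Antisymmetry** μ<sub>u,k</sub> = −μ<sub>k,u</sub> holds by
  construction and is asserted in tests; covariances are symmetric under
  pair reversal because covariance is sign-invariant.

Prediction of an unknown landmark multiplies the conditional Gaussians of
all present, usable contributors.  The product of Gaussians is Gaussian,
so the mode is closed-form (precision-weighted average of the
contributors' predicted positions); all density work is log-domain.  The
voxel-grid heatmap path exists for export and as an independent check:
the grid argmax must agree with the closed form to within one voxel
(tie-break: lowest flattened index).  Predicted landmarks are never
chained back in as contributors — every target is predicted independently
from the originally observed set, which keeps the estimator convex and
each prediction attributable to observed evidence.  Contributors may be
any present landmark, auxiliary or Couinaud; the evaluation protocol
restricts the known set to the nine auxiliaries.

## Personalization

The inter-patient distance is the double sum over ordered pairs of common
present landmarks of the componentwise (L1) absolute difference of
displacements, normalised by K′² where K′ is the common count.  Reading
|·| as the componentwise absolute value is the literal reading of the
formula; an L2 variant is available (`norm="l2"`).  Normalising by the
*common* count keeps distances comparable between pairs with and without
missing landmarks.  Using ordered pairs double-counts each unordered
pair; an unordered variant would halve every distance uniformly and
change no ranking.  Ties in the ranking break lexicographically by
subject id, and a query drawn from the cohort is excluded from its own
ranking (leave-one-out semantics).  The personalized model is an
ordinary fit on the n = 10 nearest cases — nothing else changes.

## Couinaud partition

Five planes are built from landmark triples: umbilical (UF, LPV, IVCs),
mid-hepatic (GBF, MHV, IVCs), right-hepatic (RHV, IVCi, IVCs), and two
transverse portal planes through each portal branch point, IVCi, and a
copy of the branch point shifted 50 mm along the inter-portal
(LPV↔RPV) axis.  The shift direction is derived from landmarks rather
than a fixed world axis so the whole table is rigid-motion equivariant
(volume fractions are invariant under any rigid transform applied to
image and landmarks together); a fixed world-vector shift remains
available for custom tables.

Segment conjunctions form a binary decision tree over the planes —
left-lateral (2/3) vs medial at the umbilical plane, 4a/4b vs right lobe
at the mid-hepatic plane, 5/8 vs 6/7 at the right-hepatic plane, and
superior/inferior splits at the portal planes — written out as explicit
sign conjunctions that are mutually exclusive and jointly exhaustive, so
the partition property holds for any non-degenerate landmark geometry.
Voxels exactly on a plane (|d| < 1e-9 mm) count as positive.  The
default table is an explicit package choice expressed in an overridable
YAML schema: the plane triples in surgical guides can be encoded
exactly, including the side assignment of 5/8 vs 6/7 relative to the
right-hepatic plane, which depends on the orientation-reference
convention chosen.  The caudate (segment 1) is not landmark-defined and
is deliberately absent.  Volume percentages are voxel counts × voxel
volume over labelled liver volume; NIfTI output encodes 4a/4b as 41/42.

## Auxiliary landmark heuristics

Three deterministic rules extract the nine auxiliary landmarks from organ
masks: `extreme_point` (centroid of the farthest `robust_fraction` slab
along a signed world axis; default fraction 0.05 to resist single-voxel
segmentation noise), `corner_point` (voxel maximising the sum of two
bounding-box-normalised signed coordinates; normalisation stops
elongated organs biasing the corner toward their long axis), and
`centroid`.  All tie-breaks are lowest flattened voxel index, so
extraction is bit-reproducible.  Absent structures yield not-present
landmarks, mirroring the model's missing-landmark handling.  The binding
of landmarks to structures, rules and axes is a package default table
and is overridable; it should not be read as a clinical standard.

## The synthetic world

The generator emulates a population of 17-landmark anatomies.  The
template geometry is hand-crafted plausible adult-abdomen geometry —
package constants, not measured anatomy.  A subject is
`scale · R · (template_z + ε) + b`: subtype z from the template mixture,
per-landmark isotropic Gaussian jitter ε (default 5 mm), lognormal scale
(σ = 0.05), small rotation (2° per axis), translation (20 mm), and
independent per-landmark missingness (default 0.012, the order of one
missing landmark per ~5 subjects seen in abdominal cohorts).  Per-subject
RNG substreams derive from the master seed, so subject i is identical
regardless of cohort size.

The default second subtype shifts GBF, RPV, RHV, GB_TOP and RKID_TOP by
15 mm laterally: a right-sided variant of vascular branching plus
visceral position with a preserved liver envelope.  This composition is
deliberate: the variant must be visible to the auxiliary landmarks (else
similarity search cannot find same-subtype neighbours) yet leave most
contributors biased under a population-average model (else
personalization has nothing to fix).  Shifting the entire right side
including the liver corner makes three of nine auxiliaries unbiased
predictors of the shifted targets, and the fusion all but removes the
average-model bias on its own — an interesting regime, but one in which
the personalization contrast drowns in Monte-Carlo noise.

Procedural organ masks are placed so the heuristics recover the
generating landmarks to within about a voxel by construction: top-point
organs are ellipsoids whose continuous heuristic argmax sits at the
landmark; corner-point organs are convex polytopes with a true vertex at
the landmark, blunted by a cone-plus-spike cap oriented along the
negated corner-objective gradient (down-gradient caps cannot steal the
argmax for any cone width, and the spike guarantees a mask voxel within
about one voxel of the vertex at every grid phase).  The liver is a
bicone over its three corner landmarks; its voxel centroid is driven
onto the LIVER_CENTER landmark by a damped voxel-transfer iteration
confined to the middle of the corner bounding box (so the adjustment can
never become a corner extreme).  Organs are painted in a fixed order
with earlier structures excluded, so masks are pairwise disjoint; the
liver is painted last and acquires anatomically sensible holes where the
portal vein and vena cava pass through it.

What a green closure test establishes: the extraction heuristics and the
generator agree to within twice the voxel spacing under jitter, pose and
scale variation.  What it does not establish: performance on real
segmenter output, whose surfaces are noisy, non-convex and sometimes
wrong in ways this generator does not emulate (no intensity artefacts,
no segmentation failures, no pathology).

## Evaluation protocol

LOOCV removes one subject's slice of the 4D displacement matrix —
provably identical to refitting on the remaining P − 1 subjects, and
asserted as such.  Couinaud landmarks are predicted from the held-out
case's auxiliary landmarks only; personalized mode selects the n most
similar remaining cases using those same auxiliaries.  Volume errors are
absolute differences in percent of whole-liver volume per segment; the
robustness summary is the fraction of cases with at least one segment
above 10%.  Method comparisons use a paired two-sided Wilcoxon
signed-rank test on per-case errors (an explicit package choice), with
skipped landmarks excluded pairwise.  Plot-oriented log errors use
ln(error + 1 mm) to admit zeros.

On homogeneous (single-template) cohorts, personalization confers no
benefit and costs a little: the n = 10 fit adds estimation noise
(≈ +0.5 mm at P = 80 with 5 mm jitter).  The suite tests exactly that —
no significant improvement, cost bounded — rather than exact neutrality,
which small-sample theory rules out.

## Known limitations

- The prediction error floor is the target landmark's own independent
  jitter: contributors constrain a landmark only through displacements,
  so mean LOOCV errors in the synthetic world sit near √3·σ_jitter even
  for a perfect model.
- The plane-based partition approximates boundaries that are vascular,
  not planar, in real livers; the default rule table is a geometry
  scaffold, not a clinical standard.
- Synthetic population variability is not calibrated to any clinical
  cohort; absolute error magnitudes in millimetres should not be read as
  clinical performance.
- The similarity metric assumes the query's known landmarks suffice to
  identify its anatomical subtype; variants invisible to the auxiliary
  landmarks cannot be personalized for.
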