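# Methods

This note records the models, conventions and numerical choices behind
calcmorph, and what the synthetic-data layer does and does not emulate.

## Landmark model and measurement definitions

A calcaneus is reduced to six surface landmarks A–F (see README for their
anatomical definitions) plus two constructed points: G = (C + D)/2 and H,
the orthogonal projection of A onto the *calcaneal axis* — the infinite
line through G and E. H is deliberately not clamped to the segment GE: the
perpendicular foot may fall outside the segment for extreme shapes, and
the height of the posterior facet is defined as a point-to-line distance.

The seven landmark parameters are Euclidean distances (LCA = |GE|,
HPF = |AH|, LPF = |AB|, LAP = |BC|, HAP = |CD|) and two angles: Gissane's
angle at vertex B between rays BA and BC, and Böhler's angle expressed as
180° − ∠CAF. Angles are computed as `atan2(‖u×v‖, u·v)`, which is stable
near 0° and 180° where the arccosine of a normalized dot product loses
precision. All landmark parameters are exactly invariant under rigid
motion and behave as expected under uniform scaling (lengths ×s, angles
unchanged); the test suite asserts both to 1e-9.

## Inverse construction (realizing a parameter vector)

The measurement definitions are forward maps; simulation needs the
inverse. The construction places B at the origin, C at (LAP, 0, 0), A in
the z = 0 plane on the +y side with |AB| = LPF and ∠ABC = GA, and D at
C + HAP·d with the fixed oblique unit direction d = (3, −12, 4)/13 —
"downward and slightly anterior-lateral", chosen once so that the
calcaneocuboid joint line is neither vertical (which would be anatomically
wrong) nor coplanar with the other landmarks (which would make the
construction degenerate). E is solved in the z = 0 plane from the two
constraints |GE| = LCA and dist(A, line GE) = HPF; this is a
circle–line intersection with up to four solutions, of which the most
posterior (smallest x, then smallest y) is taken, matching the anatomical
position of the tuberosity. F lies in the z = 0 plane at |AF| = LCA/2 with
∠CAF = 180° − BA; the AF length is a free convention since only the angle
is measured. Feasibility requires HPF < |A−G| (checked explicitly, with
the violated constraint named) and a real circle–line intersection. The
construction is deterministic and closed-form, so the round trip
realize → measure reproduces the seven landmark parameters to floating
point (< 1e-9 relative), which the tests and the acceptance checks rely
on.

Facet areas are *not* realized geometrically in cohort simulation:
prescribing the area of a curved facet patch while simultaneously
prescribing seven landmark constraints is over-constrained and buys
nothing for the statistical layer, so APF/AMF are carried as sampled
values. Geometric area fidelity is exercised separately on phantoms with
closed-form cap areas.

## Synthetic cohorts and measurement error

Per-gender parameter distributions are truncated normals with the bundled
normative mean/SD/min/max per parameter (male n = 83, female n = 96 by
default, with matching body-height distributions for the ANCOVA).
Sampling is by inverse CDF on the truncated interval — exact, and
reproducible from a single seed. Parameters are sampled independently
within subject: no covariance structure is published for them, and this
is a stated limitation — real calcanei certainly correlate length with
height and facet size. Truncation shifts means slightly off the nominal
values (e.g. the male axis length by about −0.26 mm); recovery tests
compare against the truncation-adjusted expectation.

Repeated measurements follow an additive two-component error model:

    y(subject, examiner, session) = truth + b(subject, examiner) + e(session)

with b ~ N(0, σ_between²) drawn once per subject–examiner pair and
e ~ N(0, σ_within²) independent per session. Within-observer SDs are the
bundled per-parameter precision magnitudes; between-observer SDs are
calibrated from the examiner-pair repeat SDs as √(pair² − within²), the
moment solution under this model. The defaults put areal precision in cm²,
the same units as the areal measurements themselves (published precision
figures are ambiguous between mm² and cm² across sources; using the
measurement's own units keeps CV well-defined).

The default reliability design mirrors the study: 36 subjects drawn at
random across both sexes, one main examiner measuring twice, two others
once. A male-only subset would understate between-subject variance and
depress the ICC, which is why the subset is sampled, not truncated.

## Phantoms

Phantoms are unions of spheres voxelized on a regular grid: voxel centre
inside the union → bone HU (default 700), outside → background (0), plus
optional Gaussian noise. Two constructions are provided. The single-sphere
phantom carries an apex spherical cap of height h as a stand-in articular
facet with closed-form area 2πRh and a 64-point boundary circle. The
calcaneus-like phantom realizes a parameter vector exactly and builds a
connected blobby solid from a core sphere at the landmark centroid plus
chains of overlapping 5 mm "arm" spheres ending tangent to each landmark;
every sphere's radius is capped at its distance to the nearest landmark so
no arm engulfs another arm's landmark. All six landmarks therefore lie
exactly on the continuous surface, and within one voxel diagonal of the
extracted mesh.

What the phantoms do **not** emulate: anatomical calcaneal shape,
partial-volume tapering at the bone boundary, beam hardening, or any
scanner physics beyond additive noise. Passing phantom tests demonstrates
that segmentation, meshing and area measurement are unbiased on known
geometry at CT-like resolution — not that landmarks can be found
automatically on real bones (landmark placement is an input everywhere in
this package).

## Segmentation and meshing

Bone is thresholded at HU ≥ 150 (the conventional cut-off for this
protocol; configurable). Connected components use 26-connectivity and are
labelled in decreasing size. Touching bones are separated by marker-based
watershed on the negated Euclidean distance transform, one seed per bone —
a reproducible stand-in for interactive labelling tools: the result is
independent of seed order, and seeds in disjoint components keep their
components. Components containing no seed are left unlabelled with a
warning rather than guessed.

Meshes are extracted by marching cubes from the binary mask of the target
label after Gaussian anti-aliasing (σ = 1 voxel), at the 0.5 level of the
smoothed mask. The threshold decision is already encoded in the mask, so
the surface remains an estimate of the 150-HU boundary; the smoothing step
is what makes it accurate. Measured on the sphere phantom, marching cubes
applied directly to the two-valued HU field carries a staircase area
excess of +9–13% at any isosurface level, while the anti-aliased 0.5-level
surface is within 1.5% at 1.0 mm spacing and 0.2% at 0.5 mm, converging as
spacing shrinks. σ = 1 voxel is the smallest smoothing that removes the
staircase bias without eroding features; larger σ starts shrinking the
surface. Degenerate faces are dropped and winding fixed outward after
extraction.

## Facet areas

A facet boundary is an ordered loop of points near the surface plus one
interior seed. Boundary points snap to their nearest mesh vertices
(tolerance 2× mean edge length; farther points are an error naming the
offender), consecutive snapped vertices are joined by unweighted shortest
edge paths (BFS with sorted neighbour order, ties to the lowest vertex
index — deterministic), and triangles are flood-filled across face
adjacency from the triangle nearest the seed without crossing boundary
edges. A leak — the fill wrapping around an unclosed cycle so that both
faces flanking some boundary edge are filled — is an error, not a number.
On an open planar mesh the enclosed region may legitimately be the whole
mesh (rim edges have no second side), which the leak criterion handles
correctly. Areas are summed in mm² and reported in cm². The snapped
polyline wiggles around the drawn curve by ~half an edge length with
near-zero mean, giving cap-area errors of ~2% at 0.5 mm spacing against
the 2πRh closed form. For conjoined middle/anterior facets the algorithm
measures whatever the supplied middle-facet boundary encloses; splitting
off the calcaneal-beak portion is the annotator's responsibility.

## Reliability statistics

ICC(2,1) is computed from the two-way ANOVA mean squares of the complete
subjects × raters table (Shrout–Fleiss), with the F-based confidence
interval using Satterthwaite degrees of freedom for the rater term
(McGraw–Wong). The implementation is cross-checked in the tests against an
independent library computation and a variance-component identity. A table
with zero total variance is flagged degenerate rather than returned as a
number; perfect agreement returns a collapsed CI at 1. Inter-observer
reliability is reported both pairwise per examiner pair and as the joint
all-examiner ICC(2,1), since both views are standard.

RMS-SD uses the sample SD (ddof = 1) across each subject's repeats;
subjects with fewer than two repeats are an error naming the subject. CV
is reported for lengths and areas only — angle scales have an arbitrary
origin for this purpose, so their CV row is NA.

Bonett's approximation n = ⌈8·z²·(1−ρ0)²·(1+(k−1)ρ0)²/(k(k−1)w²) + 1⌉
defaults to k = 3 raters; with ρ0 = 0.8, w = 0.2, α = 0.05 it gives the
36-subject design used throughout, and it is verified against a
brute-force search over the width expression.

The gender comparison fits `value ~ sex + height` per parameter (equal
slopes, no interaction — conventional ANCOVA) and reports the type-II F
and p for sex plus adjusted means at the pooled mean height. A constant
covariate is dropped with a warning. Significance is α = 0.05 two-sided
with no multiple-testing correction, matching the study design this
mirrors; with nine parameters, one expects ~0.45 false positives per
cohort under the global null. Demographic comparisons use the pooled-
variance independent-samples t-test, with zero-variance cases flagged.

## Problem sizes and determinism

Cohort-recovery checks run at 10× the study's group sizes (1790 subjects),
where truncated-normal means are determined to ±0.15 units; the Böhler
re-measurement check realizes 10 000 landmark configurations; reliability
recovery uses 200 replicates of the 36 × 2 design. Phantom tests use a
10 mm sphere at 0.5 mm spacing (and 1.0/0.5/0.25 mm for the convergence
trend) and the calcaneus phantom at 1.0 mm. These sizes make every
stochastic check tight relative to its tolerance while keeping the whole
suite fast. All random draws flow from explicit seeds through
`numpy.random.Generator`; identical seeds give byte-identical output
files.

## Known limitations

* Landmarks and facet boundaries are inputs; nothing is detected
  automatically.
* Parameter independence within subject, and normality with hard
  truncation, are modelling conveniences, not validated anatomy.
* The watershed split is a stand-in for interactive segmentation, not a
  claim of equivalence to any particular tool.
* Volumes with non-axis-aligned direction matrices are read with a warning
  and treated as axis-aligned; no resampling is performed.
* Facet-area accuracy is bounded by mesh resolution (~2–3% at 0.5 mm
  voxels for cm²-scale patches); boundary snapping assumes the drawn curve
  is within two edge lengths of the surface.
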