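# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `densecranio`, in the spirit of a methods appendix.

## Problem setting

Craniofacial bone surfaces extracted from CBCT/CT scans are analysed by
*dense correspondence*: a template mesh (the "mask") with Q fixed vertices
is non-rigidly fitted to each individual, after which vertex `i` of every
fitted mask refers to the same anatomical location — a quasi-landmark. All
geometry is in millimetres; meshes are triangle meshes with 0-based
indices. The package's axis convention is +x lateral-left, +y anterior,
+z superior.

## Preprocessing: shrink-wrap and remeshing

Raw bone segmentations are uneven, multi-sheeted and perforated. A
half-cylindrical grid (axis superior-inferior, arc spanning the anterior
half-space, radius = max lateral half-extent + `margin`, default 10 mm,
default grid 200×200) is iteratively pulled onto the skull. Each iteration
projects every wrap vertex to its closest surface point, rejects
projections that clamp onto an open boundary (hole rims, field-of-view
cuts), diffuses the displacement field over the grid so unsupported
vertices inherit motion from their neighbors, and applies a tangential
relaxation pass so vertices do not accumulate on convex features. The fixed
point of this iteration lies *on* the target surface — there is no
Laplacian shrinkage bias — and holes are bridged by smooth interpolation,
which is precisely what later produces "gap" quasi-landmarks.

Resolution control is a classic incremental isotropic remesher: edges
longer than 4/3 of the target edge length are split at midpoints, edges
shorter than 4/5 are collapsed (with a link condition to preserve manifold
topology and frozen boundaries to preserve open rims), vertices are relaxed
tangentially, and everything is reprojected onto the input surface. The
target edge length is derived from the surface area and the requested face
budget (default 30,000 faces) and steered over rounds until the face count
is within ~8% of the budget. On smooth closed fixtures this preserves area
to within a few percent and yields an edge-length coefficient of variation
around 0.2.

## Registration

**Step 1 — similarity initialization.** Corresponding named landmarks
(typically 11 per surface) give a closed-form least-squares similarity
transform (rotation, translation, uniform scale) via the SVD-based
(Umeyama) solution. Collinear or under-determined configurations are
rejected.

**Step 2 — similarity ICP.** Correspondences are exact-ish surface
projections (closest point on the k=4 nearest candidate faces).
Projections landing on an open boundary edge of the target are discarded;
of the rest, the worst 20% by residual are trimmed, which tolerates partial
targets. The transform update is a linearized point-to-plane similarity
step (7 unknowns: rotation vector, translation, log-scale), which converges
rotationally much faster than point-to-point on smooth surfaces; whenever
the plane step fails to decrease the objective the update falls back to the
guaranteed-descent point-to-point (Umeyama) fit on the same matches. The
sparse initialization landmarks additionally enter as soft point anchors
carrying half the total weight by default: closest-point terms are blind to
tangential sliding on smooth regions, and without the anchors a small
fraction of initializations converged to tangentially rotated poses several
millimetres off. Iteration stops on relative objective improvement below
1e-9 (default max 60 iterations).

**Step 3 — non-rigid adaptation.** An annealed smoothed-displacement ICP.
Per iteration:

1. every mask vertex gets a target position as the inverse-distance
   weighted blend of its closest points on the `correspondence_k = 3`
   nearest faces of the target, optionally symmetrized by a pull term in
   which each target vertex attracts its nearest mask vertex;
2. confidence weights: zero for boundary-clamped projections, softly
   reduced for residuals beyond `median + κ·max(MAD·1.4826, median/2)` with
   `κ = 3` (the median floor prevents regions with large *genuine*
   deformation from being starved of correspondences);
3. the confidence-weighted displacement field is diffused over the mask
   graph by `s` passes of `0.5·I + 0.5·(neighbor mean)`, with `s` annealed
   geometrically from `stiffness_start = 40` to `stiffness_end = 4` over
   `num_iterations = 80` iterations; displacement and confidence are
   diffused jointly (normalized diffusion), so zero-confidence regions are
   carried entirely by reliable neighbors — this is what interpolates the
   mask smoothly across holes and truncations.

Scale is frozen during step 3. The output preserves the mask topology and
vertex count exactly; the identity target is an exact fixed point. On
synthetic individuals (5 mm RMS smooth deformation at 40 mm wavelength) the
mean dense correspondence error is ≈ 0.02–0.2 mm; isolated vertices in the
deep foramen-magnum concavity can err by several millimetres when the
random deformation there exceeds ~10 mm, a known failure mode of
closest-point correspondences in narrow concavities.

## Template construction

Masked shapes are averaged by generalized Procrustes analysis: center,
optionally scale to unit centroid size, iteratively rotate each shape to
the consensus (orthogonal Procrustes) and update the consensus until the
mean moves by less than 1e-12 (tighter than strictly necessary, so that
the consensus is order-independent to ~1e-11). The consensus is rescaled to
the mean original centroid size so templates keep mm units — whether the
averaging of the real study used scaled or size-restored coordinates is not
determinable, and size-restored is this package's choice. Mirror pairs are
identified once per template by mutual nearest neighbors under x-negation;
`reflection_average` re-indexes the reflection by that pairing, aligns it
back by orthogonal Procrustes, and averages, producing an exactly symmetric
template. `plane_symmetrize` (snap |x| < 0.5 mm to the midplane, keep the
x ≥ 0 half, mirror) builds a symmetric preliminary mask from a single
skull.

## Landmark transfer

A sparse landmark is encoded against a masked shape as its 3 nearest
quasi-landmarks plus the affine (barycentric) coordinates of its orthogonal
projection onto their plane; near-collinear triples (condition number >
1e8) fall back to normalized inverse-distance weights, and nearest-3 ties
break toward lower indices. Transfer to a new skull averages the *decoded
positions* of all training anchors on the target's masked shape and
projects the mean to the closest point on the target's actual surface.
Averaging decoded positions (rather than pooling weights) is well defined
even when the nearest triple differs between training skulls, and uses only
correspondence information. Leave-one-out evaluation transfers from all
remaining skulls to each held-out one, per observer and for the
observer-mean landmarks, and reports per-landmark Euclidean errors.

## True vs gap quasi-landmarks

For each masked skull, the distance from every quasi-landmark to the
original (pre-wrap) surface is measured along ± its vertex normal, taking
the nearer hit (the wrap can sit inside or outside local bone); no hit
within `max_range = 50` mm is censored at that value and counts as
exceeding any threshold. A quasi-landmark is a *gap* iff its distance
exceeds 10 mm in more than half of the skulls; flags are then symmetrized
conservatively (a mirror pair survives only if both members survive).
Distances are absolute, not signed. Topology fidelity is the mean ± sd of
these distances over the true set.

## Statistics

- **RMS repeatability** is dispersion about the per-landmark mean over
  repeats; this makes manual-round RMS directly comparable to the
  registration-repeat RMS. The mean-pairwise alternative (differing by the
  exact factor `sqrt(2R/(R−1))`) is available via `mode="pairwise"`.
- **ICC**: single-measure two-way consistency `(MSR−MSE)/(MSR+(k−1)MSE)`
  and agreement `(MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n)`; 95% CIs by the
  standard F bounds (Satterthwaite for agreement). Verified against an
  independent mean-squares oracle and `pingouin`.
- **ANOVA on centroid size** uses sequential (type-I) sums of squares via
  `statsmodels`, with `a/b` nesting expanding to `a + a:b`; output columns
  follow the conventional Df / Sum Sq / Mean Sq / F value / Pr(>F) layout.
- **Shape variance decomposition**: sequential projection increments of the
  GPA-aligned coordinates give per-factor `R² = SS/SS_total`; p-values come
  from seeded permutation of reduced-model residuals (default 999 rounds;
  99 inside the bundled study for speed).
- **PLSR covariate removal** fits one PLS component per covariate
  (`scikit-learn`) and returns residual shapes with the mean added back;
  constant covariates are dropped with a warning.

## Synthetic data: what it emulates, and what it does not

The generator builds an ellipsoidal cranium (semi-axes 65 × 85 × 75 mm)
with Gaussian radial features (nasal ridge, zygomatic arches, orbital
depressions, brow, alveolar ridge, chin, occiput, temporal fossae) — enough
geometric salience that surface registration is well posed, as it is on
real skulls. Individuals are produced by smooth random displacement fields
(30 Gaussian radial-basis bumps at the stated wavelength, scaled to an
exact RMS amplitude; default 3 mm at 40 mm wavelength), plus a smaller
asymmetric field (0.5 mm). CBCT artifacts are emulated by removing the
posterior fraction of faces and punching circular holes. Twenty named
craniofacial landmarks ride on specific template vertices, so their true
positions after deformation are known exactly.

Observers place landmarks as truth + a smooth per-observer bias field +
isotropic per-round noise, re-projected onto the surface (observers can
only click on rendered geometry). Defaults are three observers with round
noise 0.3/0.6/0.9 mm and bias amplitude 0.5/1.0/1.5 mm at 60 mm
wavelength: the bias field is smooth and persistent, so inter-observer
disagreement exceeds within-observer scatter, the pattern real landmarking
studies show; amplitudes rise with noise because unskilled observers both
scatter more and interpret definitions more idiosyncratically.

What passing tests on this data do **not** show: anatomical realism (no
teeth, sutures, or thin bone), CBCT physics (beam hardening, metal
artifacts), observer fatigue or learning, and the specific landmark
definitions of any atlas. Conclusions transfer to real data only insofar
as the difficulty drivers (smooth shape variation, partial coverage,
observer noise structure) are representative.

## Study sizes and numerical choices

The bundled validation study uses 10 skulls at template resolution Q = 642
(icosphere subdivision 3), 3 observers × 3 rounds, 3 registration repeats
with initialization landmarks jittered by 2 mm, and leave-one-out transfer
of the 20 landmarks — a deliberately compact analogue of a clinical
validation design that a laptop reproduces in seconds per seed. All
randomness derives from a single integer seed; identical seeds give
byte-identical outputs. Degenerate inputs are handled by explicit errors
(empty meshes, collinear landmark sets, zero-variance ICC ratings,
rank-deficient ANOVA designs, non-involutive mirror pairings).

## Known limitations

- Closest-point correspondences can mis-assign in deep narrow concavities;
  extreme local deformations (>2× the feature depth) may leave a few
  quasi-landmarks several millimetres off even when the mean error is
  ~0.05 mm.
- The remesher targets face count and uniformity, not curvature adaptivity.
- The equivariance of the full registration chain under rigid motion holds
  to float64 accumulation (~1e-4 mm over 80 iterations at ~100 mm
  coordinates), not to machine epsilon.
- ICC confidence intervals assume the usual normal two-way model;
  permutation alternatives are not implemented.
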