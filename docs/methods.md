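# Methods

This note records the model, the numerical choices, and the design decisions
taken where the method family leaves the design open, together with what the
synthetic phantom does and does not establish.

## Energy model

Segmentation is a binary labelling of a 6-connected voxel graph minimizing

E(ω) = Σ_u D_u(ω_u) + λ Σ_{(u,v)} B_uv K_uv [ω_u ≠ ω_v],

solved globally by s-t max-flow (python-igraph's push-relabel core). The
pairwise term is submodular (all weights ≥ 0), so the min cut is the global
optimum; `tests` verify this against exhaustive enumeration on 1,000 random
grids of ≤ 12 voxels, and verify flow = cut-capacity duality. Hard seed and
exclusion constraints are large-but-finite terminal weights, ten times the
largest soft capacity sum; the constant is irrelevant beyond "never cut" and
finite weights keep solvers exact.

Default parameters: λ = 0.15 (smoothness weight), σ = 10 HU (Gaussian
boundary scale), μ₁ = 12 / μ₂ = 8 (object/background expansion scales).

## Data term

`Pr(x_u | ω)` is computed by level-wise front expansion from the seed
regions. The front at level l is the set of unvisited 6-neighbours of the
previous front; each voxel is scored exactly once, synchronously, as the
best candidate over its visited neighbours:

cand(l ← p) = min( L(p), exp(−I_w(l) · μ · (Int_l − Int̄_p)² / (dis(l,p) + Dis_p)) ),

with the running state updated on acceptance: Int̄_l = (Int_l + Int̄_p)/2,
Dis_l = dis(l,p) + Dis_p (mm, from voxel spacing). Seeds start at L = 1,
Int̄ = own intensity, Dis = δ_dis = 1 mm (any positive constant avoids a
zero denominator at the first step; 1 mm keeps magnitudes at the voxel
scale).

Three choices here were genuinely open:

* **Weakest-step accumulation.** The per-step value alone is not a usable
  likelihood: the running average re-adapts within a few steps of crossing a
  boundary, so a background voxel far from the seeds would score liver-like
  again. Taking a path to be as strong as its weakest step (the
  fuzzy-connectedness convention the path-connectivity data term descends
  from) makes the likelihood non-increasing along every path, which is the
  behaviour the term needs: once an organ boundary is crossed, the object
  likelihood stays down. On a clean two-class phantom, arg-max
  classification of the two fields then recovers 100 % of voxels.
* **Visit-once order.** Re-relaxing voxels to a global best-path fixed point
  lets likelihood percolate through noise along contorted lucky paths — at
  10 HU noise this measurably floods the volume with μ-asymmetric leakage
  and destroys the field's contrast. The synchronous visit-once front (with
  a deterministic neighbour-order tie-break) is order-independent,
  reproducible, and matches an independent scalar reference implementation
  on small grids.
* **Intensity weight applies to the object expansion only.** `I_w` encodes a
  liver HU prior: 1 on the dubitable margins of the interval, exp(q·Ĩ_w)
  with q = −4 on the confident central band (Ĩ_w is the normalized parabola
  (I−ς)(ξ−I)/(ξ−ς)², so θ = 6/49 puts the band edges at 1/7 and 6/7 of the
  interval). q < 0 is the only direction in which the band *relieves* the
  penalty, letting the object expansion jump false edges inside the liver.
  The interval defaults to mean ± 3 std of the object-seed HU (sharp bounds
  cannot be fixed a priori); the background expansion has no such prior.

Likelihoods are floored at ε = 10⁻⁶, so data costs are finite
(−log ε ≈ 13.8).

## Enhanced image and certainty fields

Per slice, each pixel carries two local appearance profiles over a 5×5
window: a 32-bin intensity histogram (range = seed interval ± 50 HU) and a
64-bin histogram of ζ-offset LBP codes (M = 6 samples, radius 1, ζ = 1.6 HU,
circular bilinear sampling; 64 bins are forced by the code alphabet).
Profiles are built with an integral histogram, linear in pixels × bins, and
verified against a naive per-window histogram. The global appearance model
is the mean seed profile with a scalar variance σ² = mean squared
1-Wasserstein deviation of seed profiles from their mean, floored at 10⁻³
(homogeneous seeds would otherwise blow up the division). The certainty
field per feature is W1(local, global)/σ²; the enhanced image is the
per-slice sum of the two fields rescaled to [0, 1].

The 5×5 window is the smallest odd window exceeding the LBP support (3×3);
it matters because the certainty transition across an organ boundary is as
wide as the window, and the pheromone ridge — hence the cheap-cut ring —
can sit up to half a window inside the organ. Larger windows measurably
bias the cut inward.

## Variant ACO

Ants walk the 8-connected pixel lattice of the enhanced slice, choosing
among non-tabu neighbours (tabu list of the last 8 pixels) with probability
∝ τ^α η^β, where η is the per-pixel maximum of the four opposing-pair
absolute differences in the 3×3 neighbourhood, globally normalized. With
β = 2 > α = 1, image evidence dominates the trail. Per slice:
n_ants = ⌈√pixels⌉ ants of 40 steps, 4 local iterations per global update,
10 global updates, fresh uniform-random starts each local iteration.

Selective updating: τ (initialized at max(τ⁰, τ_min)) is strictly frozen
during local iterations — the test suite snapshots the field after every
local iteration to prove it. At each global update the round's *elite*
tours (mean η ≥ half the round's best; zero-score tours never qualify) are
reinforced, τ ← (1−ρ)τ + ρ, and all other pixels evaporate, τ ← (1−φ)τ,
with clamping to [0.001, 0.999] after every update. Reinforcing the elite
set of a round, rather than a single best tour, is what lets the pheromone
cover an entire organ contour: a lone 40-pixel tour cannot move the median
τ of a contour hundreds of pixels long, while per-round elites from random
restarts tile the strong ridges. On a featureless slice no tour qualifies
and the field decays to τ_min.

Per-edge pheromone for the 3D graph: in-slice edges take max(τ_u, τ_v)
(an edge touching a confident boundary pixel is a boundary edge);
inter-slice edges average the two slices' values. B = 1 − τ then modulates
the Gaussian term; with the swarm stage disabled B ≡ 1 and I_w ≡ 1, which
is exactly the classic seeded graph cut used as the comparison baseline.

## ROI reduction

A bounding box (user-supplied, or automatically the seed extent dilated by
30 mm) crops the computing space, with offset bookkeeping so masks re-embed
exactly. A crossline at the spine centre — detected as the centroid of
voxels above 200 HU in the posterior half of the mid slice, or given
manually — optionally eliminates an axial quadrant (right-bottom by
default; the side is configurable because patient orientation conventions
vary). Excluded voxels are kept as hard-background nodes rather than
removed, so all grids stay congruent. Reductions that would remove an
object seed raise an error: seeds are ground truth.

## Evaluation

VOE and RVD are voxel-count errors; surface distances use 6-connectivity
border voxels and voxel-centre distances from a mm-scaled Euclidean
distance transform, pooled symmetrically over both surfaces (ASD mean, RMSD
root-mean-square, MSD max). The per-metric score is the unique linear map
through the two published anchor points — zero error scores 100, the
reference inter-rater errors (6.4 %, 4.7 %, 1.0 mm, 1.8 mm, 19.0 mm) score
75 — clamped at 0, with RVD scored by absolute value (a signed RVD would
otherwise score above 100). This scheme reproduces every one of the twenty
published per-volume benchmark totals to ±0.01 and the MICCAI mean (80.8)
to one decimal; the published IRCAD mean is not consistent with its own
score column (it recomputes to ≈ 81.1) and is not a reproduction target.

## Phantom

The generator emulates the two regimes the method exists for: an adjacent
organ pressed against the liver over a broad face at a configurable HU
offset (Δ ≈ 0 reproduces the near-iso-intense "special slice" problem), and
bright vessels inside the liver (false internal edges). Geometry is an
ellipsoidal liver with a lobe (≈ 20 % of the grid, a realistic fraction of
a tightly cropped liver ROI), an adjacent organ, a posterior bone cylinder,
soft-tissue background and an air rim; HU palette liver 110, vessels 180,
organ 110 + Δ, background 40, bone 700, air −1000; boundaries are blurred
with a 1 mm Gaussian and 10 HU i.i.d. noise is added. Everything is
deterministic in the RNG seed.

Seeds are placed the way an operator initializes this workflow: object
seeds as the eroded organ core; background seeds as the adjacent-organ
interior plus everything beyond an 8-voxel margin around liver and organ.
The closed background shell matters: leaving the far field unseeded creates
data-term ties across zero-cost air interfaces, where whole components
attach to either label arbitrarily — a degeneracy the real workflow's
bounding box, quadrant cut and background contours preclude.

Problem sizes in the test suite: full-pipeline recovery on a 64³ phantom
(Δ = 60 HU) and a five-seed swarm-vs-plain comparison on 48³ near-iso
phantoms (Δ = 5 HU), solver-optimality on 1,000 grids of ≤ 12 voxels, and
pheromone properties on 64×64 slices.

**What passing these tests shows — and does not.** The phantom establishes
that the implementation is faithful (bounded selective pheromone dynamics,
globally optimal cuts, metric identities) and that the swarm modulation
specifically helps where boundaries are nearly invisible: on the Δ = 5 HU
phantom the plain graph cut occasionally collapses catastrophically
(VOE ≈ 80 %) while the modulated cut does not, and its median VOE is lower.
It does not establish clinical accuracy: real livers have far more shape
variability, textured parenchyma, pathology, and anisotropic spacing, and
the published per-volume benchmark results require the original MICCAI/IRCAD
volumes. Those results enter this package only through their error rows as
inputs to the (exactly reproduced) scoring arithmetic.

## Numerical and degenerate-input choices

* Likelihood floor ε = 10⁻⁶; all data costs finite.
* Seed HU interval falls back to std = 1 HU for constant seeds; σ² of the
  appearance model floored at 10⁻³.
* Constant slices: LBP codes 0 everywhere, certainty 0, η ≡ 0, τ decays to
  τ_min, B ≈ 1 — the pipeline degenerates gracefully to the plain cut.
* Ties in the front expansion resolve by fixed neighbour order; ACO is
  bitwise reproducible given its seed; per-slice ACO seeds are derived from
  the run seed and slice index.
* DICOM series with inconsistent slice gaps: median gap used, with a
  warning; intensities rescaled to HU via slope/intercept at read time.

## Known limitations

* The data term's absolute likelihood values collapse toward the floor at
  realistic noise (10 HU) with the default μ scales; segmentation is then
  carried by the seed constraints and the (modulated) boundary term. The
  likelihood fields are informative at low noise and near the seeds.
* Enhancement and ACO are strictly per-slice (the certainty model is
  pooled across slices); no 3D spherical LBP sampling.
* Single global solve; no narrow-band refinement, no atlas or shape prior,
  no automatic liver localization — initialization is the user's (or the
  phantom's) seeds.
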