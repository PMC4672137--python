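# swarmcut

Seeded 3D liver segmentation from contrast-enhanced abdominal CT by a
graph-cut energy whose data and boundary terms are shaped by anatomical
domain knowledge and swarm intelligence.

Liver segmentation is a prerequisite for volumetry, vasculature analysis and
resection planning, and it is hard for exactly two reasons this package
attacks head-on: neighbouring organs (heart, stomach, right kidney) share
the liver's HU range across blurred boundaries, and the liver itself is
intensity-diverse (parenchyma vs. contrast-filled vessels). The package is
aimed at researchers in medical image analysis who want a fully scriptable,
reproducible implementation of this family of interactive segmentation
methods, including the standard five-metric evaluation stack used by the
public liver-segmentation benchmarks.

## The model

A CT volume is a 6-connected voxel graph with terminal nodes for the object
(liver) and background classes. A labelling `ω` is scored by

```
E(ω) = Σ_u D_u(ω_u)  +  λ Σ_{(u,v)∈N6} B_uv · K_uv · [ω_u ≠ ω_v]
```

* `D_u(ω) = −log Pr(x_u | ω)` — the data term. `Pr(x_u | ω)` is a
  seed-anchored path-connectivity likelihood: a level-wise front expansion
  from the user seeds in which a step from a visited voxel penalizes the
  squared deviation of the new voxel's HU from the running path-average
  intensity, relieved by the accumulated path length in mm, and a path is as
  strong as its weakest step. Inside the confident central band of the liver
  HU interval (bounded by the parabola level θ = 6/49, i.e. fractional
  positions 1/7 and 6/7 of the interval) the penalty is damped by the
  intensity weight `I_w`, so false edges inside liver tissue do not block
  the expansion.
* `K_uv = exp(−(I_u − I_v)² / 2σ²)` — the Gaussian boundary term.
* `B_uv = 1 − τ_uv` — the swarm factor. `τ` is a per-pixel boundary-confidence
  (pheromone) field in [0.001, 0.999] built by a variant ant colony
  optimization on an appearance-certainty *enhanced image*: per slice, every
  pixel's local intensity and LBP histograms are compared (1-Wasserstein
  distance between CDFs, normalized by the seed appearance variance) with a
  global appearance model pooled from the object seeds. Ants walk toward
  strong certainty edges (`τ^α η^β` transition rule, β > α); pheromone is
  frozen during local iterations and, at each global update, reinforced on
  the elite tours and evaporated elsewhere. High `τ` on a genuine boundary
  makes the cut cheap exactly where the intensity contrast is too weak to
  guide it — the near-iso-intense "special slices" where a plain graph cut
  underestimates the organ.

The globally optimal labelling is found by s-t max-flow/min-cut. Default
parameters: λ = 0.15, μ₁ = 12, μ₂ = 8 (object/background expansion scales),
σ = 10 HU, α = 1, β = 2, τ⁰ = 10⁻⁶, φ = 0.2, ρ = 0.3.

Evaluation implements VOE, RVD, ASD, RMSD and MSD plus the challenge-style
linear score per metric — `max(0, 100 − 25·error/reference)` with reference
errors (6.4 %, 4.7 %, 1.0 mm, 1.8 mm, 19.0 mm) — averaged into a total score.

## Worked example

No patient data is needed: the built-in phantom generator produces an
abdominal volume (liver with lobe and vessels, adjacent organ sharing a
boundary face, bone, blur and noise) with ground truth and operator-style
seeds.

```python
import swarmcut as sc

spec = sc.PhantomSpec(shape=(48, 48, 48), organ_delta=60.0, rng_seed=1)
volume, truth, seeds = sc.generate_phantom(spec)

model = sc.LiverSegmentation(volume, seeds, sc.PipelineConfig(seed=1))
result = model.fit()
print(result.summary(truth))
```

```
Swarm-modulated graph-cut segmentation
==============================================
grid (ROI)        : (48, 48, 48)  of  (48, 48, 48)
spacing [mm]      : (1.0, 1.0, 1.0)
object voxels     : 14333
max-flow value    : 648959.8321
labelling energy  : 648959.8321
swarm stage       : on
config digest     : bf3864f5a55bedbe  seed: 1
----------------------------------------------
VOE  [%]  :    11.37   score  55.60
RVD  [%]  :    -5.44   score  71.05
ASD  [mm] :     0.62   score  84.52
RMSD [mm] :     0.84   score  88.34
MSD  [mm] :     3.16   score  95.84
total score       : 79.07
```

The block reports the fitted mask size, the max-flow value (which equals the
labelling energy — the duality check), and the five errors against the
ground truth with their per-metric scores: here the mask overlaps the truth
to within 11.4 % volumetric error, sits 0.62 mm from the true surface on
average and never strays more than 3.2 mm from it.

The same pipeline is scriptable from the shell:

```sh
swarmcut phantom --out ph --seed 1
swarmcut segment --volume ph/volume.nii.gz --seeds ph/seeds.nii.gz \
                 --reference ph/truth.nii.gz --out pred.nii.gz
swarmcut evaluate --pred pred.nii.gz --ref ph/truth.nii.gz
swarmcut score-table          # recompute benchmark totals from error rows
```

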