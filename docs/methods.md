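# Methods

## Scope and model

`retcf` implements classifier-guided diffusion counterfactuals at desk
scale. The generative core is a standard DDPM: a forward process
`q(x_t|x_0) = N(sqrt(abar_t) x_0, (1-abar_t) I)` with a linear beta
schedule, and a learned reverse process whose mean is parameterized
through an epsilon-predictor. The default schedule uses `T=250` steps with
beta bounds scaled by `1000/T` so that the terminal signal level `abar_T`
matches the `T=1000` reference schedule (`abar_T < 1e-4` in both); a
shorter chain keeps a guided reverse pass affordable on one CPU without
changing the noise geometry at the start point.

Counterfactual generation noises the original to step `ceil(T/2)` and
runs the reverse chain with a shifted transition mean. The shift combines
the classifier-guidance gradient `d log p(k|x0_hat) / d x_t` and the
negative gradient of the l2 distance between `x0_hat` (the denoised
estimate, clamped to the value range) and the original. Both gradients are
taken through the full `predict_x0` map including the denoiser Jacobian —
the classifiers are trained on clean images, so they are evaluated on
`x0_hat` rather than on the noisy state.

### Adaptive shift scaling

Each gradient term is normalized to unit l2 norm before weighting, so the
guidance scale `s` (default 1) and the regularization strength `lambda_d`
(default 0.5) act consistently across images and steps. The weighted sum
is scaled per step by `c * sqrt(beta_tilde_t)` with `c = 3`: the shift is
kept commensurate with the *standard deviation* of the reverse-step noise.
Scaling by the variance instead makes the shift O(beta) while the noise is
O(sqrt(beta * d)); at d = 3072 pixels the drift is then ~2 orders of
magnitude below the per-step noise, and empirically neither guidance nor
the distance pull has any effect on the trajectory (the diseased-to-healthy
direction never flips). `c = 3` was fixed during method bring-up, before
the evaluation suite was frozen. The combined weight is capped at 2 so
that an extreme `lambda_d` (the regularization-dominates regime) pulls
toward the original without overshooting within a step.

### Cone projection

In `cone` mode the robust classifier's gradient `g_r` is replaced by its
Euclidean projection onto the convex cone of vectors within angle `alpha`
(default 30°) of the plain classifier's gradient `g_p`: vectors already in
the cone are unchanged, vectors in the polar cone map to zero, and all
others map to the boundary ray within span{g_p, g_r}, preserving the
component of `g_r` along that ray. A zero `g_p` leaves the constraint set
undefined; the implementation falls back to `g_r` and logs a warning. The
projection is verified against a numerically solved second-order-cone
least-squares problem.

### Classifiers

Both classifiers are a small 3-block CNN (3x3 convolutions, SiLU, 2x2 max
pooling, global mean+max head). Max pooling matters here: the disease
evidence is a handful of dot lesions, and average pooling washes their
activations out to the point where training never leaves the majority
class. Training is SGD (momentum 0.9, lr 0.01, cosine decay, batch 16),
with checkpoint selection on validation balanced accuracy. The robust
model minimizes TRADES, `CE(x,y) + beta * KL(p(.|x) || p(.|x_adv))`, with
the inner maximizer an 8-step l2 PGD (module default radius 0.25; the desk
experiment trains at 0.35 — at 32x32 an l2 ball of ~0.5 can erase an
entire microaneurysm, so radii much beyond that make the classes
genuinely inseparable and training rightly collapses to a constant, while
at 0.25 the plain model itself retains about half its accuracy under
attack and the robust-vs-plain contrast is weak). `beta = 6` with a
linear warm-up over the first third of training; without the warm-up the
KL term pins the predictions at uniform from the start. The robust
checkpoint is selected on the mean of clean and adversarial validation
balanced accuracy (scored every second epoch with a 10-step attack):
TRADES optimization on a net this small is seed-sensitive, and clean-only
selection can return an epoch with no robustness. PGD uses l2-normalized
ascent steps of size `2.5*eps/steps` with exact ball projection for p in
{2, inf} and radial rescaling for p in {1.5, 4} (no closed-form
projection exists there).

### Sparse baseline

The SVC baseline maximizes the target log-probability (sum over the
plain+robust ensemble by default) inside an l4 ball with vanilla
Frank-Wolfe: the linear subproblem has the closed form
`s_i ∝ sign(g_i)|g_i|^(1/(p-1))`, steps follow `2/(t+2)`, and the [0,1]
box is enforced by clipping, which only moves coordinates toward the
original and therefore preserves ball feasibility. The adaptive step-size
machinery of Auto-Frank-Wolfe is not reproduced.

## Phantom generator

The generator emulates the *class structure* of graded fundus and OCT
datasets, not their appearance. Fundus phantoms: circular field of view
with a radial color gradient and per-subject tint, an optic disc, and a
vessel tree drawn as a seeded branching random walk anchored at the disc —
anatomy depends only on `(seed, subject_id)`, giving every subject a
stable identity across grades and instances. Lesions are stamped with
flat-core radial profiles and rejection-sampled positions that keep them
clear of the disc, the vessels and each other; counts are drawn from
per-grade clipped Poisson laws whose means are monotone in severity
(healthy: none; mild: 1-2 microaneurysms; moderate adds hemorrhages and
exudates; severe/proliferative more of each). Realized counts can fall
slightly below the law at 32x32 when placement saturates; the recorded
ground truth is always what was actually rendered. OCT phantoms are
grayscale five-band images with smooth per-subject boundary curves;
drusen lift the RPE boundary as discrete bumps, DME adds dark
intraretinal cavities, CNV adds a bright subretinal membrane under a
disrupted RPE.

What the phantoms do **not** model: camera/illumination variation, real
lesion morphology and texture, co-occurring pathologies, resolution above
~64 px. Passing the end-to-end suite therefore demonstrates that the
guidance machinery moves the oracle-measurable semantics in the right
direction on images whose generative factors are fully known — not that
the method produces clinically convincing images.

## Lesion oracle

The oracle recovers lesion counts from pixels alone. Fundus: black/white
top-hat transforms (disk radius 4 at 32 px, scaled with resolution) inside
the field of view, connected components filtered by area, elongation (to
reject vessel fragments), and a core-intensity check (a dark component
must contain a truly dark pixel, a bright one a truly bright pixel) that
rejects top-hat halos cast by neighbouring structures of opposite
polarity; dark components split into microaneurysms vs hemorrhages by
area. The optic disc is located as the large bright region surviving a
grey opening and excluded. OCT: the RPE trace (first row above an
intensity level per column, interpolated across disrupted columns) gives a
median-filtered baseline; drusen are counted as peaks of the trace
elevation, cavities as compact dark blobs above the RPE, CNV as a compact
bright component well below the RPE baseline. All thresholds live in
`OracleConfig` and were calibrated once against the generator: exact
ground-truth recovery on >= 99% of images at 32 and 64 px (measured on
500/450 images per modality during calibration).

## Desk-scale experiment

`retcf.experiment.run_desk_experiment` is the package's analogue of a
full-scale evaluation: 64 images per class at 32x32 (5 grades, 2 images
per subject, subject-wise 75/15/10 splits), diffusion trained 2,500
iterations (Adam, batch 16, base width 8), plain (50 epochs) and TRADES
(80 epochs, radius 0.35) classifiers on the binary "referable" task (healthy+mild vs
moderate-or-worse), then a lambda_d sweep over {0.7, 0.5, 0.3, 0.2} with
16 correctly-classified originals per direction in cone mode. Reported:
non-flip fractions per lambda_d and direction, per-image monotonicity of
the counterfactual-to-original distance in lambda_d, median oracle
lesion-count deltas (at lambda_d = 0.5), PGD accuracy of both models at
the training radius (20-step attack, two restarts), an identity check
(counterfactuals are closer to their own original than to another
subject's image of the same class), and the SVC flip fraction at an l4
radius of 3.0 (chosen once for the 32x32 geometry). These problem sizes
are the package's default study conditions; they were chosen so the whole
pipeline runs in roughly 12 minutes on a single CPU core.

## Numerical choices and degenerate inputs

* Internal diffusion range is [-1, 1]; [0, 1] at module boundaries; all
  tensors float32 (the nn layers upcast transparently if fed float64,
  which the finite-difference tests use).
* `abar_0 = 1` by convention; `predict_x0` requires `t >= 1`.
* Reverse variance is the fixed posterior `beta_tilde_t`; a denoiser may
  return a second output interpreted as the log-variance interpolation
  coefficient between `beta_tilde_t` and `beta_t`, which `reverse_step`
  honors, but the shipped trainer optimizes the epsilon-MSE objective only
  (no hybrid VLB), a deliberate desk-scale simplification.
* Gradient normalization guards divide-by-zero with a 1e-12 floor; a zero
  gradient contributes a zero term.
* Cone ties at exactly alpha keep the robust gradient; zero plain
  gradient falls back to the robust gradient with a warning.
* Every stochastic entry point takes an integer seed and is bit
  reproducible; dataset, lesion and anatomy streams are separate
  `SeedSequence` children so changing one draw cannot shift another.

## Known limitations

* The adaptive shift formula (unit-normalization, sd scaling, `c = 3`) is
  a documented stand-in for the exact parameterization of the original
  guided-counterfactual formulation, which is not printed in the main
  text we follow.
* Learned reverse variances are supported in sampling but not trained.
* The GLM is fixed-effects only (trial-level independence; no rater
  random effects), matching the analysis it mirrors.
* Reported confidences come from the plain classifier.
* The phantom task is binary-separable by design; multiclass grading at
  32x32 is noisier and only the binary referable task is exercised
  end-to-end.
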