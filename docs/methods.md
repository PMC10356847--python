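# Methods

This document describes the models implemented in `deepcenterline`, the
assumptions behind them, the main parameters, and the numerical choices.
It is a description of what the code does, not a benchmark report; measured
numbers live in the README's worked example and in the output of
`scripts/acceptance.py`.

## 1. Problem setting

The package addresses centerline detection and identity-preserving tracking
of many swimming nematodes (*C. elegans*-like) in dense 2-D microscopy
video, where worms frequently overlap. Classical segmentation-based
trackers fail on overlaps because a binary mask of two crossing worms is
not separable. The approach here sidesteps segmentation entirely: a
convolutional network regresses whole centerlines directly from a short
stack of frames, redundancy among candidate detections is removed in a
learned latent space rather than by mask overlap, and linking uses a
*directed* distance on centerline triplets so that temporal order breaks
ties that a symmetric distance cannot.

## 2. Swimming simulator (`simulator`)

### 2.1 Undulation model

A worm's posture is described by the tangent angle along the body
coordinate `s ∈ [0, 1]`:

```
ψ(s, t) = ψ_u(s, t) + ψ_s(s, t)
ψ_u = A cos(2πt/T + ρ₁) cos(k_u s + ρ₂)           (whole-body bend)
ψ_s = Ã(t) cos(2πt/T + k_s s + ρ₃)                (travelling wave)
Ã(t) = ½ (1 + |sin 2πt|) A                        (amplitude modulation)
```

The travelling-wave term propels the worm; the whole-body term produces
C- and S-shaped postures; the modulation makes stroke vigor vary over
time. The body centerline follows by integrating the unit tangent
`(cos(γ + ψ), sin(γ + ψ))` along `s` at fixed length `L`, with `γ` the
rigid-body orientation.

Parameters are sampled uniformly per worm (`ParamRanges`): amplitude
`A ∈ [0.3, 1.2]` rad, period `T ∈ [0.4, 1.2]` s, bend wavenumber
`k_u ∈ [0, 2π]`, wave wavenumber `k_s ∈ [1.5π, 3.5π]`, length
`L ∈ [30, 46]` px, drag anisotropy `α = α_n/α_t ∈ [1.2, 2.5]`, phases
uniform on `[0, 2π)`. These ranges deliberately oversample posture
variability relative to any single recording so the detector is trained on
a broad repertoire.

### 2.2 Resistive force theory (RFT)

The shape dynamics prescribe only the body-frame deformation; the
rigid-body translation `V` and rotation `Ω` per time step come from
low-Reynolds-number force and torque balance. Each arc-length element
moving with velocity `u` experiences a drag density

```
f = α_t (u·t̂) t̂ + α_n (u·n̂) n̂
```

with tangent `t̂`, normal `n̂`, and anisotropic coefficients
`α_n > α_t` (anisotropy is what converts undulation into thrust). Setting
net force and net torque about the center of mass to zero gives a 3×3
linear system for `(V_x, V_y, Ω)`, assembled from arc-length quadrature
over the discretized body and solved exactly per step. Integration is
explicit Euler in `(γ, x_cm)` with default `dt = 0.05` s; the shape itself
is evaluated analytically at each time, so no stiffness arises and Euler
error affects only the (slow) rigid-body drift.

**Numerical choices.** Tangents are computed with central differences
(`np.gradient`) and quadrature uses uniform weights `1/k` over `k` body
points. Force/torque closure of the solved state holds to machine
precision by construction (the same discrete operators are used to
assemble and to verify the balance), which is exercised in the tests.

**Assumptions and limits.** 2-D motion only; no worm–worm hydrodynamic or
contact interaction (worms pass through each other — acceptable for
generating overlapping *images*, not for studying collective physics);
drag coefficients constant along the body; no boundary effects from the
arena walls (worms may swim out of frame).

## 3. Synthetic video renderer (`synthvideo`)

Rendering stamps each worm as a union of disks along its centerline with a
tapered radius profile

```
r(s) = R̃ √(1 − ((a·s + b)² − 1)²),   a = 2, b = −1
```

which is 0 at both ends and maximal mid-body; `R̃` is sampled in
`[0.8, 1.3]` px. Overlapping worms are composited with a pixelwise
maximum (worms are brighter than background, and two overlapping worms are
not twice as bright). Imaging artefacts are applied in order: a smooth
random illumination field (Gaussian-filtered noise, amplitude 0.12, scale
48 px), Gaussian blur (σ = 0.6 px), additive sensor noise (σ = 0.03),
and clamping to [0, 1].

Training batches (`make_training_batch`) simulate 0–4 worms (configurable)
in an `H×W` frame at 20 fps, render an 11-frame stack, and label the
central frame with a *centerline triplet* `(x⁻, x, x⁺)` — the centerline
one frame before, at, and after the central frame. A worm is *fully
visible* when all triplet points lie inside the frame (half-open pixel
bounds); only fully visible worms contribute to the regression loss.
Worm centroids are placed with a small inward margin (−0.25 mean body
lengths) so that roughly two thirds of training worms are fully visible
while the rest exercise border truncation.

Real clips are conditioned to resemble the synthetic statistics
(`preprocess_real`): polarity inversion when the background is bright,
per-frame CLAHE, then an affine intensity map matching the clip's mean and
standard deviation to the synthetic targets (0.06, 0.15).

**Realism limits.** The renderer does not model out-of-focus depth
changes, specular highlights, self-occlusion brightness changes in coils,
or debris. The artefact model (smooth field + blur + white noise) is
deliberately simple; `preprocess_real` carries part of the burden of
closing the domain gap by normalizing real footage toward the synthetic
statistics rather than the other way around.

## 4. Shape space and distances (`geometry`)

Centerlines are resampled to `k` equidistant points (default `k = 49`) by
arc-length interpolation. A PCA basis is fit to a simulated shape ensemble
after centering each shape at its centroid; each centerline is encoded as
`κ = 8` components `λ` plus a 2-D centroid. Because point-order reversal
of a resampled centerline is a linear map (a flip of the point order),
it conjugates to an orthogonal matrix `F` on the components: flipping a
shape is `λ → Fλ`, which the network exploits (below).

Two distances drive everything downstream:

- **Flip-invariant centerline distance** `d(x, y)²` — the minimum over the
  two point orderings of the summed squared point distances. Head/tail
  orientation is not observable from a single frame, so all losses and
  metrics must not punish a reversed but otherwise perfect prediction.
- **Weighted triplet distance** `d_s²` over `(x⁻, x, x⁺)` with weights
  `ω = 2ω⁻ = 2ω⁺` (present frame counts double), normalized so the weights
  sum to one over the three curves. The flip is applied jointly to all
  three curves (a worm's head is the same in all three frames).

The evaluation metric is the **average dynamic time warping distance
(ADTW)** between a label polyline (N points) and a predicted polyline
(M points): the mean over label points of the distance to their assigned
prediction *segment*, minimized over monotone assignments and over both
traversal directions. It is computed exactly in O(NM) with a
prefix-minimum dynamic program over clamped point-to-segment distances.
ADTW is insensitive to parameterization differences between label and
prediction and to head/tail orientation.

## 5. Detector network (`network`, `nn`)

### 5.1 Architecture

The detector is a ResNet-style CNN implemented in pure NumPy with manual
backpropagation (`nn` provides Conv2d via im2col, BatchNorm, ReLU,
average pooling, Dense, residual blocks, Adam, and HDF5 persistence). The
stem (7×7 stride-2 conv + average pool) and four residual stages
downsample the 11-frame input stack by a total of 16×; the initial
max-pool of a standard ResNet is replaced by average pooling to keep
features translation-sensitive. A 1×1-conv head emits, for every cell of
the 16×-downsampled grid, `C` candidates of `3(κ+2)+1` numbers each:
whitened shape components for the three triplet curves, per-curve centroid
offsets in cell-local units, and one confidence logit.

**Anchoring.** Offsets are relative to the candidate's grid-cell corner
and expressed in units of the cell size. This makes predictions
translation-equivariant and the model input-size agnostic: any frame with
`H, W` divisible by 16 is processed by the same weights, and large frames
are handled by a sliding window with overlap in `interface.detect`.

**λ whitening.** The head predicts *z-scored* PCA components: the decoded
shape is `(λ̂ ⊙ σ_λ)·A + mean`, where `σ_λ` is the per-component ensemble
standard deviation of the basis. Without whitening the first component
(tens of px of spread) dominates the gradient and the minor components —
which carry the fine shape — barely train. The flip operator is
conjugated accordingly (`F_scaled = diag(1/σ_λ) F diag(σ_λ)`) so flips
remain exact in the whitened coordinates.

### 5.2 Flip-invariant encoder

For suppression, an encoder maps a candidate's (whitened components,
offsets) to a `D = 8`-dimensional latent. The candidate and its
point-order-reversed counterpart are passed through the same first dense
layer and the two activations are *summed* before the rest of the MLP.
Since `a + b = b + a` exactly in floating point, the latent of a
prediction and its flip are bitwise identical — invariance holds by
construction, not approximately.

### 5.3 Losses

Three losses are optimized concurrently on each batch:

- **Detection loss `l_x`** — for each fully visible labeled worm, the
  minimum over all candidates of the weighted triplet distance `d_s²`
  between candidate and label. The min-assignment makes the loss
  permutation-invariant; gradients flow only into each label's best
  candidate.
- **Score loss `l_s`** — L2 between the sigmoid of the confidence logit
  and a soft target `ŝ = exp(−d_s²/σ_s²)` computed against the nearest
  label, with `d_s²` treated as a constant (stop-gradient): the score head
  learns to *report* quality without the quality definition leaking
  gradients into the regressor. `σ_s` defaults to `2√k` px, anchored on
  the worm half-width: a 2-px RMS error per point (about one worm width)
  maps to a target of `e⁻¹`, keeping targets O(1) over the quality range
  the score must discriminate. Smaller values collapse the targets toward
  zero (the score head then predicts ≈0 everywhere); much larger values
  saturate all near-duplicates at the same target.
- **Latent loss `l_p`** — a score-weighted binary cross entropy on
  pairwise latent distances: candidate pairs targeting the same label are
  pulled together (`P = exp(−‖Δp‖²) → 1`), pairs targeting different
  labels pushed apart. Pair weights are products of score targets, and
  the loss updates *only* the encoder parameters (stop-gradient into the
  detector), so suppression training cannot degrade localization.

Training uses Adam on synthetic batches generated on the fly, with a
constant learning rate for most of the budget and a cosine-annealed
final phase (the low-lr tail contributes the largest accuracy gain);
augmentation applies axis flips, 90° rotations and time reversal (which
swaps the `x⁻`/`x⁺` curves) consistently to clips and labels. Because simulating and rendering a batch costs several times
more than a forward/backward pass at small frame sizes, `train()` can
take several optimizer steps per generated batch
(`steps_per_batch`), drawing a fresh augmentation for each step — the
streaming equivalent of multiple epochs over a dataset.

## 6. Latent-space suppression (`suppression`)

Duplicate candidates are removed by greedy non-maximum suppression in the
learned latent space: candidates are visited in descending score order,
and a candidate is suppressed by an already-kept one when their
same-object probability `P = exp(−‖p_i − p_j‖²)` exceeds `τ_o = 0.5` —
equivalently when `‖Δp‖² ≤ ln 2` — gated to pairs whose centroids are
within `σ_l` px (default 1.5 mean body lengths). Because flips share a
latent bitwise, a detection and its reversed duplicate always merge.
A spatial hash over centroids keeps the procedure near-linear in the
number of candidates.

Unlike mask- or box-IoU NMS, latent NMS can keep two *overlapping* worms
(different objects, similar positions, distinct latents) while merging two
*redundant* candidates of the same worm — exactly the failure mode that
makes dense scenes hard.

## 7. Tracking (`tracking`)

Each detection carries the full triplet `(x⁻, x, x⁺)`, enabling a
**directed** linking cost between a detection at `t` and one at `t+1`:

```
c(i → j) = d(x_i, x⁻_j) + d(x⁺_i, x_j)
```

with the flip-invariant distance `d`. Agreement of *i*'s present with
*j*'s past and *i*'s future with *j*'s present is evidence of identity in
a way a symmetric centroid distance is not; two worms swapping positions
produce asymmetric costs that keep identities straight.

Frame-to-frame assignment is solved exactly as a rectangular linear sum
assignment with dummy rows/columns pricing track birth and death at
`cost_max` (default 2.0 body lengths' worth of distance), after spatial
gating at 38 px on centerline midpoints. Unmatched tracks stay linkable
for up to `max_gap = 2` further frames before they close, so an isolated
missed detection does not split an identity. Post-processing merges
single-frame identity branches caused by duplicate detections, removes
stub tracks shorter than 5 frames, and reverses centerlines where needed
so each track keeps a consistent head/tail order over time.

## 8. Evaluation metrics (`metrics`)

- **Detection:** labels are matched to predictions by ADTW with a gate
  `σ_ε` (default 3 px); TP rate is the fraction of labels matched within
  the gate, FN its complement.
- **Tracking integrity** `ι`: for one ground-truth worm observed in `N`
  frames, let `c_t` be the sizes of the contiguous runs assigned to the
  same track identity; then `ι = Σ c_t² / N²`. `ι = 1` iff one track
  covers the worm's whole lifetime; an identity switch at half-duration
  gives `ι = ½`; fragmentation into `m` equal pieces gives `1/m`. Frames
  where no track covers the worm contribute singleton runs, so misses are
  penalized as well as switches. A track "covers" a worm in a frame when
  the flip-invariant RMS distance between the track's centerline and the
  worm's is below a body-scale threshold. Dataset-level integrity is the
  mean over worms, reported with its standard error.

## 9. Known limitations

- The NumPy network trains on CPU at desk scale (64×64 frames, reduced
  channels) in minutes, but the full-size configuration is slow without a
  GPU framework; the architecture is deliberately framework-agnostic so a
  port changes only the `nn` backend.
- The simulator's lack of worm–worm contact means the generator slightly
  overstates how often deep overlaps occur and understates postural
  reactions to contact.
- Score calibration lags localization during training: score targets
  `exp(−d_s²/σ_s²)` are near zero until candidates localize to a few px
  RMS, so early in training the suppression stage ranks candidates on
  weak signals. Even once localization converges, ranking *near-duplicate*
  candidates of the same worm by predicted score is intrinsically hard:
  the residual localization error of a well-trained candidate is largely
  the network's own estimation noise, which the score head cannot observe.
  The suppression survivor for a worm is therefore a typical-quality
  duplicate rather than the best one, and post-suppression accuracy tracks
  the median candidate error, not the minimum. Longer training narrows the
  duplicate spread and with it this gap.
- Track post-processing (branch merging, stub removal) is heuristic;
  pathological duplicate patterns can still split identities, which the
  integrity metric duly reports.
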