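# Methods

## The problem

In routine obstetric ultrasound, biometry (head circumference, abdominal
circumference) is measured on a diagnostic plane the operator selects.
Frame-classification *task models* can judge whether an individual video
frame would support a sufficiently accurate measurement.  Once such a model
exists, operator skill can be redefined operationally: a skilled operator
is one who keeps the probe on frames the task model rates highly.  This
package implements that framework end to end:

1. sparse manual biometry annotations are extended to every video frame by
   regressing the relative biometry error from image similarity to the
   diagnostic plane (label-efficient surrogate labels);
2. a frame classifier `f_task` is trained on the resulting binary labels
   (positive ⇔ relative error ≤ δ_min);
3. two windowed task-performance scores summarise classifier output over
   τ consecutive frames — `f_skill_pos`, the window mean of predicted
   positive probabilities, and `f_skill_acc`, the fraction of window
   frames classified correctly at a cut-off c;
4. a multi-modal regressor `f_assess` learns to predict those scores from
   the raw frame window plus the synchronized 3-axis angular-velocity
   probe trace, so skill can be estimated in real time without running the
   task pipeline.

## Relative error and labels

For a frame with biometry `b` and diagnostic-plane biometry `b_dp`, the
relative error is `δ = |b − b_dp| / b_dp`, stored as a fraction in [0, 1];
δ_min ∈ {0.01, 0.02, 0.03, 0.04} corresponds to a 1–4 % precision
requirement.  (A ratio-only formula without the subtraction would be ≈ 1
at the diagnostic plane itself and is inconsistent with thresholds of a
few per cent, so the absolute relative deviation is used throughout and
surfaced here deliberately.)

The error model is ordinary least squares from the five similarity metrics
(feature-space cosine, MSE, cross-correlation, mutual information, SSIM)
to δ.  One non-obvious numerical fact: on zero-mean unit-variance images,
`mse = 2 − 2·cross_corr` *identically*, so the five-metric design matrix
is always rank-deficient on preprocessed data.  `fit_error_model` detects
this and names the collinear columns; the pipeline therefore fits with a
tiny ridge penalty (1e−6), which leaves full-rank designs numerically
untouched.  Manual frames always keep their exact-δ label; surrogate
frames are thresholded on the estimate δ̂ (positive iff δ̂ ≤ δ_min), which
makes the positive sets nested across rising δ_min by construction.

## Models

Neural components are *fixed-feature convolutional networks*: a
seed-deterministic convolutional encoder whose filters are drawn once from
the seed and never trained, followed by a trainable head optimised with a
hand-written Adam + minibatch loop.  Random convolutional features are a
standard desk-scale stand-down from end-to-end training; they make every
run bit-reproducible from its seed and keep a full ablation grid tractable
on one CPU, at the cost of some accuracy headroom.

* **Task model** — frames are resized (default 224×288; the desk profile
  uses 56×72) and z-scored; a 16-filter 5×5 convolutional bank with ReLU
  and 4×4 adaptive average pooling feeds a logistic head trained with
  cross-entropy (lr 1e−4 full scale / 1e−2 desk, batch 64, 50 epochs full
  / ≤30 desk).  The checkpoint with the highest class-balanced accuracy
  (mean of sensitivity and specificity) on the validation clips is kept.
  A five-frame temporal context concatenates the centred ±2 neighbours'
  features, replicate-padded at clip edges.  Classification uses the
  strict rule ĝ > c (ties negative), c = 0.5 unless calibrated.
* **Cut-off calibration** — the smallest observed negative score whose
  empirical specificity reaches the target (0.8 or 0.9); by construction
  the achieved specificity lies within 1/(number of negatives) above the
  target, and sensitivity is non-increasing in the target.
* **Skill predictor** — video branch: the *same* fixed 2-D convolutional
  encoder as the task model (identical filter bank from the same seed),
  applied per frame.  Sharing the encoder is deliberate: the scores the
  predictor must regress are functionals of the task model's output, and
  the classifier's decision margin is a linear function of the shared
  features, so the window mean of the predictor's features already spans
  the window mean of the classifier scores.  Motion branch: a 1-D
  residual convolutional encoder
  (channel-mixing input convolution + two conv-ReLU-conv residual blocks)
  over the z-scored 3-channel angular-velocity segment.  Per-frame branch
  features are standardized and augmented with their elementwise squares —
  a fixed quadratic nonlinearity without which the window average could
  never represent quantities like "fraction of the window near the
  decision boundary", which is exactly what `f_skill_acc` measures.  The
  augmented features are adaptively average-pooled over the τ-frame
  window (windows overlap with stride 1, so pooling is a cumulative-sum
  sliding mean and cost is linear in frames, not windows), concatenated,
  and fused by a trained linear layer into a 32-long vector followed by a
  linear output layer.  Training is MSE with weight decay 1e−4; the
  lowest-validation-RMSE checkpoint is kept (early stop after 25 stale
  desk epochs).  Three such heads are trained from different
  initialisation seeds and their predictions averaged — on
  nearly-constant targets prediction variance is the dominant error term,
  and the ensemble average reduces exactly that term.

### Shrinkage calibration

Held-out score series are often nearly constant (a competent operator's
window accuracy sits near 1), so an unregularised regressor can lose to
the trivial predict-the-training-mean baseline purely through prediction
variance.  After head training, two decoupled shrinkage weights are
selected on the validation clips: α blends each clip's predicted *level*
(its mean raw prediction) with the global training-mean score, and γ
independently scales the within-clip fluctuation around that level.
Decoupling matters: for near-constant targets the best policy is often
"baseline level plus a small correlated fluctuation", i.e. α ≈ 0 with
γ > 0, which a coupled single-weight blend cannot express.  γ is kept
strictly positive (grid 0.1–1.5) so a predicted series never collapses to
a per-clip constant, whose correlation with the target would be
undefined.  Because a handful of validation clips cannot reliably rank
near-tied settings, selection follows the one-standard-error rule
familiar from cross-validated model selection: among all (α, γ) whose
mean per-clip validation RMSE lies within one standard error of the
minimum, the most conservative (smallest α, then smallest γ) is kept.
Both axes are per-clip affine maps, so they rescale but never flip the
within-clip correlation between predicted and true series.

## Synthetic scan generator

The generator emulates the structure of a biometry scanning session with
closed-form ground truth:

* **Pose.** A latent 1-D probe pose offset follows a mean-reverting
  (Ornstein–Uhlenbeck) walk toward the diagnostic plane: reversion rate
  `1 + 4·skill` s⁻¹ and volatility `0.45 − 0.35·skill` for the latent
  per-operator skill in [0, 1].  Skilled operators revert faster and
  wander less, so the fraction of frames under any error threshold grows
  monotonically with skill.  The diagnostic-plane frame is the path's
  closest approach to zero (restricted to the final three quarters of the
  clip), anchored exactly at pose 0.
* **Biometry.** The anatomy is an elliptical bright ring whose
  circumference is the biometry; `δ = min(1, 0.5·|pose|)` exactly, and
  the per-frame biometry is `b_dp · (1 + sign(pose)·δ)`.
* **Appearance.** Off-plane frames dim (`1/(1+2|pose|)`), scale their
  axes (`1 + 0.5·pose`) and defocus (Gaussian blur, σ = 3·|pose| px) over
  a fixed per-subject background texture; speckle is multiplicative gamma
  noise with relative SD 0.1 (0.02 in the low-noise separable variant).
* **Motion.** The three angular-velocity channels are finite-difference
  derivatives of `pose`, `pose²/2` and `sin(pose)` at the frame rate plus
  white sensor noise whose SD, `0.3·(1.1 − skill)`, falls with skill.
* **Defaults.** 30 Hz, 6–12 s clips (tests and the acceptance script use
  6–10 s and 56×72-pixel frames to keep runtimes in minutes; these sizes
  are stated in each test), one subject per clip, operators' skills evenly
  spaced over [0.1, 0.9].
* **Ablation variants.** `video_informative=False` renders every frame at
  pose 0 (appearance carries no signal); `motion_informative=False`
  replaces the trace with skill-independent white noise.

What the generator does *not* emulate: B-mode physics, real anatomy,
probe-image geometric calibration, raw 400 Hz IMU characteristics, or the
actual statistics of human probe motion per skill level (the skill→motion
map is an assumption).  Passing tests therefore demonstrate that the
pipeline's machinery is correct and recoverable under its stated
assumptions — not that the specific clinical numbers of any real cohort
are reproduced.

## Evaluation protocol

Clips are partitioned at the operator level into development and holdout
test sets (no operator or subject on both sides); the development set is
split 85:15 by clip into train and validation.  Reported metrics: RMSE and
Pearson correlation between predicted and task-model-generated score
series, aggregated per test clip (mean ± SD across clips); the trivial
predict-the-training-mean baseline RMSE accompanies every predictor
result.  Pearson correlation of a constant series is undefined and is
reported as NaN, never coerced to 0.

## Numerical choices and degenerate inputs

* Mutual information: 32×32 equal-width joint histogram over each image's
  observed range, natural-log entropies.
* SSIM: 7×7 Gaussian-weighted window (σ 1.5), K1 = 0.01, K2 = 0.03,
  dynamic range from the pair's joint observed range.
* Constant images: cross-correlation and SSIM return 1 when both inputs
  are constant and equal, else 0, with a logged warning; z-scoring leaves
  a constant image's variance untouched.
* Metric orientation is not harmonised (MSE is a dissimilarity); the
  linear error model absorbs signs.
* The feature embedder is a fixed-seed Gaussian random projection of the
  4×-average-pooled image — deterministic and training-free — behind a
  plug-in interface that accepts any user-supplied extractor.

## Known limitations

* Fixed random encoders trade accuracy for reproducibility and speed;
  depth and filter counts are configurable but no pretrained weights ship.
* The `f_skill_acc` series on competent operators is close to constant and
  its fluctuations are partly classifier-idiosyncratic; its predictability
  margin over the mean baseline is small, which matches the weak and
  sometimes negative correlations this criterion shows in clinical
  reports.  The shrinkage calibration exists precisely for this regime.
* The PNG writer quantises frames to 8 bits; readers of both storage
  formats produce identical tensors only to within 1/255.
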