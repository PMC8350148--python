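# Methods

## The model

`pairconn` implements an end-to-end network that maps a parcellated
fMRI scan — one matrix per subject with N regional BOLD time courses of
length T — to a small vector of clinical logits. Six stages are applied
per subject:

1. **Region embedding.** A shared 1-D CNN `E` turns each regional
   series s_i into an embedding e_i ∈ R^d. The extractor has six conv
   layers (kernel 3, padding 1, ReLU), with 2× max-pooling after every
   layer except the third and fifth (four halvings in total, so T ≥ 16
   is required), followed by a linear map to d. Full-scale widths are
   64/128/256/256/512/512 with d = 32.
2. **Pairwise connectivity.** A shared MLP `F` (two hidden ReLU layers,
   terminal sigmoid) scores every ordered pair:
   k_ij = F([e_i, e_j]) ∈ (0, 1), giving the connectivity matrix K.
   The diagonal is computed (the classifier consumes a dense flatten)
   but never enters the attention sums or the edge statistics.
3. **Attention.** Each region aggregates its outgoing scores:
   w_i = β + (1 − β) Σ_{j≠i} k_ij, with β ∈ [0, 1] (default 0.9).
   The sum is implemented exactly as written — unnormalized — so
   w_i ∈ [β, β + (1 − β)(N − 1)]; this bound is asserted on every
   forward pass. A mean-normalized variant was considered and
   rejected to stay with the printed form.
4. **Reweighting.** e_i′ = w_i · e_i.
5. **Updated connectivity.** K′ from the same F applied to the
   reweighted embeddings.
6. **Classification.** Logits = C(flatten(K′)) with C a three-layer
   MLP; the first layer projects the N² vector to 100 features (these
   are the features used for the 2-D embedding analysis), the first
   two layers carry ReLU + dropout (rate 0.5).

Head sizes: l = 3 (diagnosis at three time-points), l = 20 (DSM-5
symptoms), l = 1 (persistence), plus a regression variant (l = 3, MSE
on z-scored severity scores).

`F` is not symmetrized during the forward pass (F([e_i,e_j]) ≠
F([e_j,e_i]) in general); the edge statistics average (k′_ij + k′_ji)/2
before testing. Permuting region order permutes K, K′ and w
consistently; classifier logits change only through flatten order.

Ablations: `identity_E` (embeddings are the raw series), `pearson_F`
(connectivity is the sample Pearson correlation — differentiable, so E
still trains through it; entries then live in [−1, 1] and the
attention-weight bound does not apply), `no_reweighting` (classify on
K; K′ is not computed), and an independent-per-time-point driver that
fits one l = 1 model per diagnosis time-point.

## Training objective

The classifier is applied twice per batch with shared parameters: once
to K (loss L1) and once to K′ (loss L2), and L = λ·L1 + (1 − λ)·L2
(default λ = 0.6) is minimized. Inference always uses the K′ path.
Losses are binary cross-entropy with logits, computed per head
coordinate, with three refinements:

- **Class weighting.** The positive-label term of each coordinate is
  weighted by (#observed negatives)/(#observed positives) computed on
  the training split, so both classes carry equal total mass; a
  72%-positive head weights positives by 28/72. A single-class head
  gets weight 1 with a warning.
- **Masking.** Missing follow-up labels are excluded coordinate-wise by
  0/1 masks and the loss is averaged over observed entries only. A
  masked entry's stored value never influences loss, gradient, or
  metrics (asserted bit-exactly in tests). Masking was chosen over
  imputation because it uses all first-time-point data without
  inventing follow-up outcomes.
- **Regression variant.** For severity scores the same dual-path
  objective uses MSE; targets are z-scored on the training split and
  the scaler is stored with the model.

Optimization is Adam (β1 = 0.5, β2 = 0.999), initial learning rate
1e-4, divided by 10 every 30 epochs, batch size 20, 100 epochs — these
are the package defaults. Evaluation uses five random subject-level
80/20 train/test splits; metrics are reported as the mean ± SD of
per-split values (not subject-pooled). Accuracy uses the 0.5
probability threshold; AUC and average precision are rank statistics
and are reported as undefined (NaN) when a head sees one class.

## Initialization

Weight matrices followed by ReLU use He-normal fan-in scaling; output
layers use Glorot-uniform; biases start at zero. With plain
fan-in-uniform initialization the across-subject spread of K entries
collapses to ~1e-5 through the deep shared extractor and sigmoid
similarity net, leaving the network input-insensitive and untrainable
at desk scale, so variance-preserving initialization is load-bearing
here, not cosmetic.

## Similarity warm-start (optional, used by the desk presets)

Supervised training from scratch proved unreliable on small synthetic
cohorts: on some data realizations the classifier memorizes the
training subjects before the similarity net discovers the coupling
structure, and held-out performance never leaves chance. The desk
presets therefore precede supervised training with a short
self-supervised stage that fits K to each subject's sample Pearson
correlation matrix (mapped from [−1, 1] to [0, 1]), for 60 epochs at
learning rate 1e-3. No label information enters this stage; it merely
grounds F in the pairwise-correlation semantics the architecture is
built around. After the warm-start, 40 supervised epochs reach
held-out AUC ≈ 1.0 on every strong-coupling cohort realization we
generated, where supervised-only training was bimodal (sometimes ~0.85,
sometimes stuck at 0.5). The stage is off by default and enabled
explicitly via `TrainConfig.pretrain_epochs`.

## Synthetic cohorts

The generator (`pairconn.simulate`) emulates the statistical structure
the model and the edge statistics assume, not fMRI physics:

- **Signals.** Each region is a stationary AR(1) process (default
  autoregression 0.3, noise SD 1). For subjects whose latent
  chronic-case indicator is set, each planted region pair additionally
  receives a shared latent AR(1) signal scaled by `effect_strength`
  into both regions. With gain g the planted-pair correlation is
  g²/(g² + 1) (≈ 0.94 at the desk preset's g = 4). Each series is
  z-scored before use, so after standardization the group signal lives
  **only** in pairwise coupling — marginal distributions are identical
  between groups (an amplitude confound can be switched on).
- **Diagnosis.** T1 status is Bernoulli at the configured prevalence
  (study-like default 72%). A single per-subject latent uniform drives
  remission timing, making positives nested across time-points
  (T3 ⊆ T2 ⊆ T1) with marginals matching the configured 29%/23%;
  subjects positive at all three time-points are the chronic cases that
  carry the planted coupling and define the persistence label.
- **Symptoms.** Diagnosed subjects draw 20 symptom bits at rate 0.55
  and are then topped up so all four DSM-5 cluster criteria hold
  (≥1 of 5 B, ≥1 of 2 C, ≥2 of 7 D, ≥2 of 6 E); non-diagnosed subjects
  carry sub-threshold noise at rate 0.08.
- **Severity.** CAPS-like scores are 20 + 30·dx + 10·chronic + N(0, 5),
  clipped at zero — monotone in diagnosis by construction.
- **Dropout.** Follow-up missingness is monotone (lost at T2 ⇒ lost at
  T3), at rates typical of prospective clinical cohorts (25/160 and 5/135); masks are explicit and
  nothing is imputed.

What the generator does **not** emulate: hemodynamics, task structure,
spatial autocorrelation between atlas neighbours, scanner drift,
motion artefacts, site effects, or realistic symptom co-occurrence
structure. Passing tests therefore show that the implementation
recovers planted pairwise structure under its own assumptions — they
say nothing about clinical performance on real fMRI.

## Desk-scale study conditions

The reference experiments (tests and `scripts/acceptance.py`) use
n = 200 subjects, N = 20 regions, T = 120 samples, 10 planted pairs
covering all regions, gain 4, and — for the persistent-label cohort —
equal 50% prevalence at all three time-points so that every diagnosed
subject is chronic and all three heads share the planted signal. The
network is narrowed to conv widths 8/16/16/32/32/32, d = 16, F hidden
widths 32/8, classifier 100/16, trained in float32 with batch size 10,
60 warm-start epochs and 40 supervised epochs (learning rate 3e-4 —
Adam steps are learning-rate-sized, and at the default 1e-4 the
output heads cannot traverse enough parameter space in 640 steps to
calibrate, which leaves rank-correct but threshold-miscalibrated
logits; one 10× decay at epoch 30). These sizes are the package's choices for
single-CPU reproducibility; the full-scale widths remain the
defaults of `ModelConfig`.

## Edge statistics

Per unordered pair, k′ entries are symmetrized and compared between
diagnosed and non-diagnosed subjects with a two-sample t-test
(pooled-variance by default, Welch optional), then Benjamini–Hochberg
corrected across all N(N−1)/2 pairs at α = 0.05. Degenerate-variance
edges get p = 1 with a warning. Tests can pool all subjects (the
default, mirroring a whole-cohort association analysis) or any subject
subset. The package's own calibration runs the tests on **held-out**
subjects: fitting, however briefly, on the same subjects used for the
t-tests makes K′ genuinely label-dependent in-sample and inflates the
null discovery rate (we measured mean false-discovery proportion 0.15
in-sample vs 0.05 held-out over 20 null cohorts), so held-out testing
is the honest protocol at desk scale.

## Symptom clusters, dominance, persistence

The 20 symptoms map positionally to DSM-5 clusters B (0–4), C (5–6),
D (7–13), E (14–19) with minimum counts 1/1/2/2. A subject's dominant
cluster maximizes the within-cohort mid-rank percentile of the
met-fraction scores; the maximum must exceed the runner-up strictly
(configurable margin), otherwise no dominant cluster is assigned and
the subject is skipped in visualizations. Hidden features for the 2-D
embedding are the 100-dim first-classifier-layer activations of a
trained l = 20 model, embedded by seeded t-SNE. The persistence task
takes subjects positive at T1 with an observed T3 diagnosis; the label
is still-positive-at-T3; a per-cluster variant filters by cluster
criterion instead.

## Numerical and design notes

- All network numerics run on a small reverse-mode autodiff engine
  over numpy (`pairconn.autodiff`); every op's gradient is checked
  against central finite differences in the test suite. float64 is the
  default; the desk presets run float32 (dtype is preserved end to
  end). Training is bit-reproducible given configs and seed on CPU.
- The flatten of K′ includes the diagonal (dense fixed-size input);
  attention sums and edge tests exclude it.
- Hidden widths of F (64/16) and the classifier's second layer (32),
  and the dropout rate (0.5), are package choices where the reference protocol fixes no
  value; all are configurable.
- Time-series files store timepoints as rows (human-inspectable);
  memory orientation is regions × timepoints. Values round-trip
  bit-exactly (17 significant digits, `float_precision="round_trip"`
  on read).
- Masked values are carried by explicit mask arrays, never sentinels.
- NIfTI/BIDS ingestion is out of scope; any function producing a
  `SubjectTimeSeries` can feed the pipeline.

## Known limitations

- The synthetic generator's distributional choices beyond the
  reference prevalences are stand-ins; none were fit to real data.
- The warm-start stage is this package's own addition to the training
  protocol; it is documented here precisely because the desk presets
  depend on it.
- The GCN aggregation variant and voxel-level preprocessing are not
  implemented (out of scope).
- Metrics average per-split values; with unequal test sizes this is
  not subject-weighted.
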