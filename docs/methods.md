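# Methods

This note documents the models, the synthetic data the package is tested
on, and the design choices that were genuinely open.

## Data model and preprocessing

A recording is a T×9 matrix of accelerations at a fixed rate (default
64 Hz) with per-row annotations 0/1/2 (excluded / normal gait / FoG).
Annotation semantics follow the public Daphnet convention; the mapping is a
config key (`data.label_map`) for datasets that deviate.

Preprocessing is deliberately minimal: per-channel min–max normalization
into [0, 1], fitted on training data only and applied with clipping to
held-out data (extrapolation would leak the test range into the feature
scale; clipping is the conservative choice). Channels constant in training
are mapped to 0 and flagged. No resampling, filtering or gravity removal is
performed. The fitted normalization travels with the trained model and its
checkpoint, so raw sequences are always scored on the training scale.

Recurrent batching needs fixed-length inputs, so recordings are cut into
sequences of `data.sequence_length` = 128 samples (≈2 s at 64 Hz),
non-overlapping by default (`data.stride` = 128). No per-window features
are extracted — the network sees raw normalized samples. Windows never
span an annotation change: each example lies inside one constant-annotation
run, rows annotated 0 are excluded outright, and runs shorter than one
window are skipped. This keeps labels unambiguous at the cost of discarding
a fraction of short-episode data.

## Channel selection

The three filter statistics are computed on per-timestep channel values
pooled by class. Nothing in the pipeline requires this granularity — the
scorers accept any two samples — but per-timestep pooling matches the
no-feature-engineering stance and gives the statistics large samples.

- AUC uses the exact Mann–Whitney estimator via midranks (ties count ½).
  Informativeness is max(AUC, 1 − AUC): a channel anti-correlated with the
  class is as useful as a correlated one.
- The rank-sum z uses E[W] = n₁(n₁+n₂+1)/2 and
  Var[W] = n₁n₂/12·((n+1) − Σ(t³−t)/(n(n−1))) over midranks (t = tie-group
  sizes). All-tied input has zero variance; z is defined as 0 with a
  warning.
- SNR = (μ₁ − μ₂)/(σ₁ + σ₂) uses population standard deviations, which
  makes the score exactly invariant under sample duplication. A zero
  denominator with distinct means yields signed infinity, which sorts to
  the top rank with a warning; with equal means the score is 0.

Rank fusion is a Borda count (C − rank points per metric), chosen over
plurality voting because it is deterministic and uses the full orderings.
Vote ties break on the mean min–max-normalized informativeness, then on
channel index.

The wrapper stage summarizes each sequence by per-channel mean and standard
deviation (2·|channels| features), and scores channel subsets with k-NN
(k = 5, Euclidean distance, majority vote with an inverse-distance
tie-break) under stratified 10-fold cross-validation with a fixed fold seed
(default 42). Only prefixes of the vote order are evaluated — C subsets
instead of 2^C — mirroring incremental-subset selection; the smallest
prefix achieving the maximal CV accuracy wins, so redundant channels are
not kept on ties. k = 5 is odd (no binary ties among neighbours in the
common case) and small enough for the minority-pattern clusters the
synthetic data produces.

## The CBA-BiLSTM

Composition order: conv front-end → BiLSTM → bottleneck attention →
softmax. The three conv groups default to (16, 32, 64) filters, kernel 3,
max-pool 2, so L = 128 becomes L′ = 16 steps of 64-dimensional features.
The BiLSTM (64 units per direction) emits L′×128; this output is viewed as
a feature map with C = 2H = 128 channels on an N×M = 16×1 grid so both
attention branches are well defined on sequence data. Because the map
already concatenates the forward and backward streams along the channel
axis, one reduce/expand pair over C covers both directions jointly; no
separate stream merge is needed.

Channel branch: global average pool → FC (C → C/r, ReLU) → FC (C/r → C) →
batch norm. Spatial branch: 1×1 conv (C → C/r, ReLU) → two dilated 3×3
convs (dilation d, ReLU) → 1×1 conv (→ 1) → batch norm. There is no
sigmoid inside the branches; the single sigmoid sits at the fusion,
M = σ(M_c ⊕ M_s) (broadcast add; multiplicative fusion available via
`model.fusion = "product"`). The attended map is applied residually,
F′ = F + F ⊗ M, so gradients reach F even where M saturates at 0.
Defaults r = 16 and d = 4 are the usual bottleneck-attention settings; r
is padded up (C/r rounded to ≥1) when it does not divide C.

Batch normalization uses batch statistics during training and running
statistics (momentum 0.1, ε = 1e-5) at inference, making inference
deterministic and batch-independent. Weights are Glorot-uniform from a
config seed; LSTM forget-gate biases start at 1. The default network has
82,860 trainable parameters — the compactness is the point of the
bottleneck design.

Everything runs on a small in-repo reverse-mode autodiff over float64
NumPy arrays (`gaitfreeze.autodiff`). Convolutions are implemented as
sums of shifted matrix products (3 taps in 1-D, 9 in 2-D), max-pooling as
pairwise elementwise maxima, and BPTT falls out of the tape. Gradients of
every operation are checked against central finite differences; one known
subtlety is that gradient accumulation must never happen in place, because
pass-through operations hand the same array to several consumers.

## Training and evaluation

Adam (β = 0.9/0.999, ε = 1e-8) at initial lr 0.001, constant through epoch
100, then multiplied by 0.1 once per 10-epoch block ("decreases by 0.1" is
read multiplicatively — the subtractive reading goes negative by epoch 120;
`lr_decay_mode = "subtractive"` implements it anyway, floored at 0).
Batch size 128, shuffling from the config seed, default 200 epochs with a
hard cap of 300. The default loss is MSE on one-hot targets applied to the
softmax output — unusual for classification but kept as the primary
regimen, with cross-entropy one config key away. Per-epoch loss and RMSE
curves are recorded; non-finite loss aborts with a diagnostic.

Metrics come from the confusion matrix (rows = truth): per-class precision,
sensitivity, specificity, accuracy and F-score; macroAVG is the unweighted
class mean and microAVG pools one-vs-rest counts — with the standard
convention, under which micro precision = micro sensitivity = accuracy for
single-label problems (an identity the tests assert). Zero-denominator
metrics are defined as 0 and flagged rather than NaN so reports always
serialize. Cohen's κ = (p_o − p_e)/(1 − p_e) from the marginals; ROC/AUC
by threshold sweep with trapezoid integration, which agrees with the
Mann–Whitney AUC to 1e-10 (two independent routes, cross-checked, and both
checked against scikit-learn). Cross-validation is stratified k-fold with
a fresh model per fold; repeated runs use a seed list.

## Synthetic data: what it emulates and what it does not

The generator plants the structure the method is designed to exploit.
Episodes alternate with normal gait; segment lengths are exponential with
mean 5 s for episodes (a realistic FoG scale) and the normal-gait mean set
so the expected FoG time fraction equals `episode_rate` (default 0.3).
Signals are mixtures of three random sinusoids: locomotor band 0.5–3 Hz
during normal gait, freeze band 3–8 Hz during expressed episodes on
informative channels — the classical freeze-index convention — scaled by
`amplitude_ratio` (2.0) and shifted by `fog_offset` (2.0, a postural-tilt
gravity shift; without a location change, per-timestep statistics could not
distinguish the classes at all). Gaussian noise (sd 0.1) is added
everywhere. Default informative channels are 5 and 8 (vertical upper-leg,
vertical trunk), the axes that dominate real recordings.

Crucially, FoG expresses heterogeneously across sensor sites: each episode
draws a per-informative-channel expression mask (Bernoulli 0.8,
conditioned on at least one channel expressing, since an annotated episode
is by construction visible somewhere). This is what makes channel subsets
genuinely complementary — one vertical channel misses the episodes
expressed only on the other — and it is why the selection stage keeps both
planted channels rather than stopping at a perfect singleton. With full
expression (`channel_expression = 1.0`) the clean regime is recovered:
planted channels reach per-timestep AUC ≈ 0.98 and a single channel
suffices, which is exactly how the single-informative-channel tests are
configured. Defaults (4 recordings × 240 s) were chosen so each
expression pattern has enough windows (≈10) for k-NN neighbourhoods;
recovery of {5, 8} was verified on 60 independent seeds.

What the simulator does **not** model: biomechanical gait shape, tremor
and bradykinesia, sensor drift and orientation changes, inter-subject
variability, annotation noise, or class imbalance at the real 1:10 scale.
Passing tests therefore demonstrate that the pipeline recovers planted
structure under its own assumptions, not clinical performance; the
published Daphnet-scale numbers require the real dataset, which this
repository intentionally does not bundle.

## Numerical choices and degenerate inputs

- float64 throughout; no stochastic kernels, so single-threaded runs are
  bit-reproducible from the seeds.
- Midranks everywhere ranks appear (AUC, rank-sum, per-metric ranks).
- Degenerate cases return defined values with warnings instead of raising:
  constant channels (normalize → 0; AUC 0.5; SNR 0), all-tied rank-sum
  (z = 0), zero-denominator metrics (0 + flag), chance agreement 1
  (κ = 0).
- Problem sizes in tests and the acceptance script (240 s recordings,
  tens of training epochs, 20-seed recovery runs) are the package's
  standard desk-scale conditions; they keep every experiment reproducible
  on a single CPU in seconds to tens of seconds.

## Known limitations

- The k-NN wrapper sees only mean/sd summaries; channels informative purely
  in spectral shape at equal variance would be invisible to it (the filter
  metrics share this limitation by construction).
- MSE-on-softmax trains more slowly than cross-entropy at small batch
  counts; the tiny-model tests compensate with smaller batches or a higher
  learning rate.
- Prefix-only subset search cannot select a channel set that is not a
  prefix of the vote order.
- The autodiff core implements exactly the operations the model needs; it
  is not a general-purpose framework.
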