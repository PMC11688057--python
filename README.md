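# gaitfreeze

Detection of **freezing of gait (FoG)** — the transient episodes in which a
Parkinson's patient's forward stepping stalls despite the intent to walk —
from body-worn tri-axial accelerometers, using an ensemble channel-selection
stage in front of a **convolution bottleneck-attention BiLSTM (CBA-BiLSTM)**
classifier.

The package is aimed at researchers working with Daphnet-style recordings:
plain-text files with a millisecond timestamp, nine acceleration channels
(ankle, upper leg and trunk, each with horizontal-forward, vertical and
horizontal-lateral axes) and an annotation per row (0 = outside the
experiment, 1 = normal gait, 2 = FoG). A built-in simulator generates
two-class recordings with planted informative channels, so the entire stack
runs and is tested without any external download.

## Method

**Channel selection.** Each channel *c* is scored on its per-timestep values
pooled by class with three filter statistics:

- empirical ROC AUC (Mann–Whitney): AUC = P(X₁ > X₂) + ½·P(X₁ = X₂),
  used orientation-free as max(AUC, 1 − AUC);
- the standardized rank-sum statistic z = (W − E[W]) / √Var[W], with
  E[W] = n₁(n₁+n₂+1)/2 and the tie-corrected variance; ranked by |z|;
- a signal-to-noise contrast SNR = (μ₁ − μ₂)/(σ₁ + σ₂), ranked by |SNR|.

The three rankings are fused by a Borda vote (each metric awards C − rank
points). Prefixes of the vote order of sizes 1…C are then compared by
stratified 10-fold cross-validated k-NN accuracy (k = 5, per-sequence
mean/sd features); the smallest prefix achieving the maximum accuracy is
selected.

**Classifier.** Sequences of L = 128 samples (≈2 s at 64 Hz) pass through
three conv + max-pool groups, a BiLSTM (64 units per direction) with the
standard gate equations

    iₜ = σ(ωᵢ·[xₜ, hₜ₋₁] + rᵢ)   fₜ = σ(ω_f·[xₜ, hₜ₋₁] + r_f)
    oₜ = σ(ω_o·[xₜ, hₜ₋₁] + r_o)  cₜ = fₜ⊙cₜ₋₁ + iₜ⊙tanh(ω_c·[xₜ, hₜ₋₁] + r_c)
    hₜ = oₜ⊙tanh(cₜ),             Outₜ = [hₜ→ ; hₜ←]

and a bottleneck attention block: treating the BiLSTM output as a feature
map F with C = 2H channels on an N×M = L′×1 grid, a channel branch
(global average pooling → FC reduce/expand with ratio r = 16 → batch norm)
produces M_c ∈ ℝ^C, a spatial branch (1×1 reduce → two dilated 3×3
convolutions, d = 4 → 1×1 collapse → batch norm) produces M_s ∈ ℝ^(N×M),
and the fused map M = σ(M_c ⊕ M_s) is applied residually,
F′ = F + F ⊗ M, before a softmax head. The default network has **82,860
trainable parameters**.

Training follows Adam at lr 0.001 (constant through epoch 100, ×0.1 per
10-epoch block after), batch size 128, MSE loss on one-hot targets.
Evaluation reports per-class precision, sensitivity, specificity, accuracy
and F-score with macro/micro averages, Cohen's κ, ROC AUC and RMSE.

The network and its training run on an in-repo reverse-mode autodiff core
over NumPy (`gaitfreeze.autodiff`), with gradients verified against finite
differences in the test suite.

## Worked example

```sh
gaitfreeze run-all --out-dir runs/full --seed 7 --epochs 30
```

simulates four 240-second recordings (planted informative channels 5 and 8
— vertical upper-leg and vertical trunk), selects channels, trains and
evaluates. Output:

```
wrote 4 recordings to runs/full/data
selected channels: [8, 5]
checkpoint written to runs/full/model.h5 (training accuracy 100.00%)
accuracy 100.00%  kappa 100.00%  auc 1.0000
```

`runs/full/selection.json` holds the vote tally and the accuracy trace over
incremental channel subsets; for this run the top votes were
`{8: 24, 5: 21, 9: 18, …}` and the k-NN CV accuracy rose from 0.953 with
channel {8} alone to 1.000 with {8, 5}, so the pair was selected — the two
vertical-axis channels carry the planted freeze signature. The evaluation
report mirrors the tabulated metric suite (per-class, macroAVG, microAVG,
κ, AUC, RMSE).

The same pipeline is available as a library:

```python
from gaitfreeze.train_eval import end_to_end_synthetic
selection, report = end_to_end_synthetic(seed=7, epochs=40)
print([c.index for c in selection.selected], report.accuracy)  # [8, 5] 100.0
```

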