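# metadecode

Neural decoding — predicting a behavioral variable such as the trial type
from brain-derived features — usually depends on manually annotated labels,
and manual annotation is noisy. `metadecode` implements a meta-learning
answer to this problem for binary trial-type decoding: an MLP decoder whose
training samples are **reweighted online** so that a one-step-updated model
minimizes the loss on a small, trusted validation set. Samples whose
gradients align with the clean validation gradient are up-weighted;
mislabeled samples are driven to weight exactly zero.

The package is aimed at computational neuroscientists who have a large,
coarsely labeled trial set and a small, carefully labeled one, and want the
large set to help rather than hurt. It ships with:

- a **leaky integrate-and-fire population simulator** (two groups of 40
  neurons in a feed-forward arrangement; the label is a nonlinear sine-band
  function of the mean group-B firing rate) for generating benchmark
  datasets with a ~3:1 class imbalance;
- **label-noise injection** by random shuffling of a portion of labels, with
  mislabel masks and realized-noise bookkeeping, plus pooling of datasets of
  mixed annotation quality;
- the **reweighted trainer** and two plain baselines (train on merged
  train+validation data; train on the validation data alone);
- **evaluation tools**: F1, balanced accuracy, and weight-separation
  statistics (zero-weight fraction, exact/asymptotic Wilcoxon rank-sum);
- **experiment runners** for the noise sweep, validation-size sweep,
  mixed-annotator pooling, and a session-structured trial-trajectory study
  with a synthetic calcium-imaging-style fixture generator.

## The method

Given noisy training data {(x_i, y_i)} and clean validation data
{(x_j^v, y_j^v)}, each step perturbs the batch loss by per-sample factors
ε_i and takes a virtual SGD step

    θ̂(ε) = θ_t − α ∇_θ Σ_i ε_i f_i(θ_t),

then scores every sample by the meta-gradient of the validation loss

    μ_i = −η ∂/∂ε_i [ (1/m) Σ_j f_j^v(θ̂(ε)) ] |_{ε=0}
        = η α ⟨∇_θ L_val(θ_t), ∇_θ f_i(θ_t)⟩,

rectifies and normalizes ω̃_i = max(μ_i, 0), ω_i = ω̃_i / (Σ ω̃ + δ(Σ ω̃)),
and applies an Adam step on the weighted loss Σ_i ω_i f_i(θ_t). The second
equality is exact because θ̂ is linear in ε; the test suite verifies it
against a nested finite-difference oracle.

## Worked example

```python
from metadecode import (SimulatorParams, calibrate_simulator, generate_dataset,
                        shuffle_labels, NoiseSpec, ReweightedDecoder,
                        f1_score, balanced_accuracy, weight_separation)

params = calibrate_simulator(SimulatorParams(), 136/600, n_pilot=3000, seed=7)
train = shuffle_labels(generate_dataset(params, 600, seed=1),
                       NoiseSpec(portion=1.0, seed=2))   # ~35% label noise
val   = generate_dataset(params, 20, seed=3)             # small, clean
test  = generate_dataset(params, 600, seed=4)            # clean

fit = ReweightedDecoder(train, val).fit(seed=5)
pred = fit.predict(test.features)
print(f"F1 {f1_score(test.labels, pred):.3f}  "
      f"balanced accuracy {balanced_accuracy(test.labels, pred):.3f}")
ws = weight_separation(fit.aggregate_weights, train.mislabel_mask)
print(f"mislabeled samples at weight 0: {ws.zero_weight_fraction_mislabeled:.1%}  "
      f"rank-sum p = {ws.p_value:.2g}")
```

Output from this exact script:

```
F1 0.939  balanced accuracy 0.948
mislabeled samples at weight 0: 86.2%  rank-sum p = 4.1e-44
```

Despite ~35% of the training labels being wrong, the decoder stays near 0.9
on both metrics, and 86% of the mislabeled samples receive meta-learned
weight exactly zero — the reweighting has effectively filtered them out
(the rank-sum test confirms the separation between correctly-labeled and
mislabeled weights).

A command-line interface mirrors the library:

```bash
metadecode simulate --n 600 --seed 1 --out data.csv
metadecode corrupt --in data.csv --portion 0.8 --seed 2 --out noisy.csv
metadecode train --method reweight --train noisy.csv --val val.csv --out run/
metadecode experiment noise-sweep --out results/
```

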