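# Methods

This note documents the models, defaults, and design choices behind
`metadecode`: what is simulated, how the reweighted decoder is trained, how
the evaluation statistics are computed, and what the synthetic benchmarks
can and cannot say about real recordings.

## The decoding problem and the reweighting procedure

The decoder maps a feature vector (80 per-neuron firing rates for the
simulated study; a 91-point trial trajectory for the trial-trajectory
study) to a binary trial type. It is an MLP with hidden layers of 128 and
64 ReLU units and a 2-unit linear output feeding a softmax cross-entropy
loss, optimized with Adam. Three training regimes are provided:

- **reweighted** (`ReweightedDecoder`): noisy training data plus a small
  trusted validation set;
- **baseline 1** (`PlainDecoder` on the merged train+validation data);
- **baseline 2** (`PlainDecoder` on the validation data alone).

At each reweighted step, a training mini-batch the same size as the
validation set is drawn (so each "validation mini-batch" is the whole
validation set). The meta-gradient of the mean validation loss through a
one-step virtual SGD update of step size α is, exactly,

    μ_i = η α ⟨∇_θ L_val(θ_t), ∇_θ f_i(θ_t)⟩,

because the virtual update is linear in the per-sample perturbations. The
implementation computes per-sample training gradients in a single batched
backward pass and takes inner products with the validation gradient; the
test suite checks this against a nested finite-difference oracle that never
touches the backprop code. Weights are rectified at zero and normalized to
sum to one; a batch whose every μ is non-positive receives the all-zero
weight vector (the δ guard), avoiding division by zero. Rectification plus
normalization makes the weights invariant to any positive scaling of μ, so
both η and α cancel; they are retained as documented parameters only.

### Optimization defaults and numerical choices

| parameter | default | notes |
|---|---|---|
| learning rate (outer Adam) | 1e-3 | β₁=0.9, β₂=0.999, ε=1e-8 |
| inner step α | 1e-3 | cancelled by normalization |
| batch size | = validation size | per the method's construction |
| max epochs / steps | 200 / 6000 | whichever is reached first |
| early stopping | patience 20 epochs, min_delta 0 | on epoch-mean weighted loss |
| snapshot | validation-loss optimal | `restore_best=True` |
| init | U(−1/√fan_in, +1/√fan_in) | seeded |
| standardization | on | z-score with training-set statistics |

Features are z-scored inside `fit()` using training-set statistics (applied
to the validation set at fit time and to any features passed to `predict`);
firing rates span 0–140 Hz and an unstandardized MLP at these defaults
collapses to the majority class. Convergence is monitored on the epoch-mean
weighted loss, which at batch size 20 is noisy; the parameters reported are
therefore the snapshot from the epoch with the lowest epoch-mean validation
loss. Alternatives evaluated during development (step-wise learning-rate
decay, stopping on the validation loss, fixed long schedules, tail
parameter averaging, restart selection by validation loss) did not improve
on this configuration.

Per-sample weight reporting: `aggregate_weights` holds, for each training
sample, its normalized weight during the epoch whose parameters are
reported (so the weight distribution describes the reported model);
per-final-epoch and last-step conventions are available via
`weight_aggregation`. The "weight = 0" statistic counts exact zeros — a
weight is exactly 0 iff its raw meta-gradient was ≤ 0. Prediction ties
(equal class scores) go to class 0. Non-finite losses or meta-gradients
abort training with the step index rather than being clipped.

## The integrate-and-fire simulator

Two groups of 40 leaky integrate-and-fire neurons form a feed-forward
network: group A is driven by a stimulus current whose amplitude is drawn
once per trial from a uniform distribution (mean 2.0, sd 0.8 across trials,
in threshold units); each group-B neuron receives instantaneous voltage
kicks from 2–3 randomly chosen group-A neurons. Membrane dynamics are
dV/dt = (−V + I)/τ with τ = 20 ms, threshold 1, reset 0, forward-Euler at
dt = 1 ms over 500 ms trials. Independent Gaussian current noise (sd 1.0
per step, per neuron — the same order as the stimulus drive, i.e. a
fluctuation-driven regime) is added to every neuron. The per-edge synaptic
weight scales inversely with the fan-in so that the expected drive per
group-B neuron is identical across random wirings; without this, the
class balance drifts between independently wired datasets by more than
binomial error.

The feature vector is the per-neuron spike count divided by the trial
duration (rates in Hz, group A first). The label is
y = 1 iff sin(π·r_B) > 0.85, where r_B is the mean group-B rate divided by
`activity_normalizer`. The positive class is therefore a *band* of
intermediate population activity — a nonlinear rule a linear readout cannot
express. Because the paper-style class ratio (~3:1) depends on magnitudes
the model leaves free, `calibrate_simulator` runs a pilot (2000 trials
pooled over three wirings), evaluates the positive fraction as a function
of the normalizer directly on the pilot rates, and picks the smallest
normalizer hitting the target fraction (keeping r_B within ≈[0, 1.5] with
the sine band mid-distribution); the result is verified on an independent
pilot and must land within ±0.05 of the target, else calibration fails
loudly. Labels are deterministic functions of the stored group-B rates, so
they can be recomputed exactly from the features.

## Label-noise model

Corruption selects round(p·n) samples without replacement (round-half-even)
and applies a uniform random permutation to their labels. This preserves
total class counts, so the ~3:1 imbalance survives every noise portion. The
expected realized noise level — the fraction of labels actually changed —
is p·2n₀n₁/n² for binary labels (≈0.35 at p = 1 for a 464/136 split); both
the closed form and Monte-Carlo shuffling are checked in the tests. A
"noise level" counts any label differing after the shuffle. Mixed-quality
pooling concatenates datasets, and the pooled noise level is the
sample-size-weighted mean of the components'.

## Study layout (simulated)

Each study replicate: five 600-sample training sets corrupted at portions
1.0/0.8/0.6/0.4/0.2; a 600-sample validation pool corrupted at portion 0.10
(realized ≈3.5% noise) from which the 20-sample guidance set is drawn
uniformly; a clean 600-sample test set. The validation-size study trains on
the highest-noise set with five resampled validation sets per size; the
mixed study pools the noisy training sets cumulatively (worst two, worst
three, …, all five = 3000 samples). All sub-seeds derive from one
`SeedSequence`, so every runner is reproducible from the plan seed, and
stochastic summaries are medians over five replicates. These problem sizes
match the study design the simulator emulates and run end-to-end in a few
minutes on one CPU.

## Evaluation statistics

F1 (positive class = label 1, the minority class; configurable) and
balanced accuracy are computed by direct confusion-matrix arithmetic with
documented zero-division conventions (0, never NaN); the tests cross-check
them against scikit-learn to 1e-12. The Wilcoxon rank-sum comparison of
correctly-labeled vs mislabeled weights uses exact enumeration of the
mid-rank U distribution when both groups have ≤ 10 members (two-sided p =
2·min(lower tail, upper tail), capped at 1) and scipy's tie-corrected
normal approximation otherwise.

## Trial-trajectory study and its fixture

The trial-trajectory runner accepts any trials × 91 matrix with binary
labels and session ids (delimited text or `.npz`). Sessions are ranked by a
between-class/within-class separation ratio; the top session becomes the
clean validation set, the next two the clean test set, the rest the
training pool, which is then copied and corrupted at each portion. Features
are zero-mean normalized per timepoint with training-split statistics.

Because the original recordings are not redistributed, a synthetic fixture
generator stands in for them: two smooth class templates sharing an early
stimulus bump and diverging in a late response-epoch window, plus
autocorrelated Gaussian noise (white noise smoothed over ~4 timepoints) and
a multiplicative per-session gain, with labels balanced within session and
48–67 trials per session. The fixture reproduces the shape, smoothness,
session structure and learnability (a plain MLP exceeds 0.9 F1 on clean
fixture data) of ensemble calcium-imaging trajectories — not indicator
dynamics, real epoch timing, or realistic inter-neuron correlation
structure. Results on the fixture therefore validate the pipeline and the
relative ordering of methods, not absolute decodability of any real
dataset.

## Known limitations

- The simulator's physical magnitudes are design choices, not fits to data;
  only the class ratio is calibrated. With the uniform stimulus, ~8% of
  trials fall within 0.03 of a sine-band edge, which bounds how far test
  accuracy can rise given a 20-sample validation set.
- The 20-sample guidance set inherits ~3.5% label noise from its pool;
  draws that catch two or more mislabeled samples degrade the meta-gradient
  badly (training on such a set directly degrades the same way). Replicate
  medians absorb occasional draws of this kind, but single fits at batch
  size 20 have high seed-to-seed variance.
- Binary decoding only; no convolutional/recurrent architectures; no
  automatic hyperparameter search.
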