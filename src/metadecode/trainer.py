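"""Meta-learned sample reweighting for MLP decoders, plus plain baselines.

The decoder is an MLP (input -> 128 -> 64 -> 2, ReLU hidden layers, softmax
cross entropy, Adam). Under label noise, each training mini-batch is
reweighted online: perturb the batch loss by per-sample factors eps_i,
take one virtual SGD step of size alpha,

    theta_hat(eps) = theta_t - alpha * grad_theta sum_i eps_i * f_i(theta_t),

and score each sample by how much increasing its weight would *lower* the
loss of a clean validation batch after that step:

    mu_i = -eta * d/d eps_i [ (1/m) sum_j f_j^val(theta_hat(eps)) ] at eps=0.

Because theta_hat is linear in eps, mu_i equals exactly
``eta * alpha * <grad L_val(theta_t), grad f_i(theta_t)>`` — samples whose
gradient aligns with the validation gradient get positive mu. Weights are
rectified at zero and normalized to sum to one (an all-negative batch gets
the all-zero weight vector rather than a division by zero), and the outer
Adam step descends the weighted batch loss. Mislabeled samples tend to get
mu <= 0 and hence weight exactly 0.

``ReweightedDecoder(train, val).fit()`` is the main entry point; functional
wrappers (``train_reweighted``, ``train_plain``, ``meta_gradient_step``,
``rectify_and_normalize``, ``forward_predict``, ``epsilon_weighted_loss``)
expose the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _mlp
from .datasets import LabeledDataset

__all__ = [
    "TrainerConfig",
    "WeightRecord",
    "FitResult",
    "ReweightedDecoder",
    "PlainDecoder",
    "TrainingError",
    "forward_predict",
    "epsilon_weighted_loss",
    "meta_gradient_step",
    "rectify_and_normalize",
    "train_reweighted",
    "train_plain",
]


class TrainingError(RuntimeError):
    """Raised when training produces non-finite losses or gradients."""


@dataclass(frozen=True)
class TrainerConfig:
    """Architecture and optimization settings.

    ``inner_step_size`` is the virtual SGD step alpha of the one-step
    meta-update; ``meta_rate`` is the eta of the raw meta-gradient — it is
    cancelled by the weight normalization and kept only so the raw mu values
    are on a documented scale. The reweighted trainer uses a train batch
    size equal to the validation sample size (so the "validation mini-batch"
    is the whole validation set). Training runs for at most ``max_epochs``
    epochs or ``max_steps`` outer steps, whichever comes first, with early
    stopping once the epoch-mean weighted loss has not improved by
    ``min_delta`` for ``patience`` consecutive epochs.
    """

    hidden_sizes: tuple[int, ...] = (128, 64)
    inner_step_size: float = 1e-3
    learning_rate: float = 1e-3
    meta_rate: float = 1.0
    max_epochs: int = 200
    max_steps: int = 6000
    batch_size: int | None = None
    patience: int = 20
    min_delta: float = 0.0
    seed: int = 0
    weight_aggregation: str = "best_epoch_mean"  # or "final_epoch_mean", "last_step"
    standardize: bool = True
    restore_best: bool = True
    lr_decay: float = 1.0  # multiplier applied to the Adam rate every lr_decay_every epochs
    lr_decay_every: int = 40

    def __post_init__(self) -> None:
        if self.inner_step_size < 0 or self.learning_rate <= 0:
            raise ValueError("step sizes must be positive")
        if self.meta_rate <= 0:
            raise ValueError("meta_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.weight_aggregation not in (
            "best_epoch_mean", "final_epoch_mean", "last_step"
        ):
            raise ValueError("unknown weight_aggregation mode")


@dataclass
class WeightRecord:
    """Per-sample meta-weights at one outer step.

    ``mu`` is the raw meta-gradient, ``rectified`` its positive part, and
    ``normalized`` the weights actually applied (sum 1, or all zero when
    every mu is non-positive).
    """

    step: int
    sample_ids: np.ndarray
    mu: np.ndarray
    rectified: np.ndarray
    normalized: np.ndarray


@dataclass
class FitResult:
    """A fitted decoder: parameters, diagnostics and (optionally) weights.

    For reweighted fits, ``aggregate_weights`` holds the per-training-sample
    summary of the meta-learned weights (by default the weights of the epoch
    whose parameters are reported, i.e. the validation-optimal snapshot),
    aligned with the training dataset's rows.
    """

    params: _mlp.Params
    config: TrainerConfig
    method: str
    n_train: int
    n_epochs_run: int = 0
    n_steps_run: int = 0
    weight_trace: list[WeightRecord] = field(default_factory=list)
    aggregate_weights: np.ndarray | None = None
    weighted_loss_curve: np.ndarray | None = None
    train_loss_curve: np.ndarray | None = None
    val_loss_curve: np.ndarray | None = None
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape[1] != self.params[0][0].shape[0]:
            raise ValueError(
                f"feature width {features.shape[1]} does not match model input "
                f"{self.params[0][0].shape[0]}"
            )
        if self.feature_mean is not None:
            features = (features - self.feature_mean) / self.feature_sd
        logits, _ = _mlp.forward(self.params, features)
        return logits

    def predict(self, features: np.ndarray) -> np.ndarray:
        scores = self.predict_scores(features)
        # ties broken toward class 0
        return (scores[:, 1] > scores[:, 0]).astype(int)

    def summary(self) -> str:
        lines = [
            "Decoder fit summary",
            "=" * 40,
            f"method            : {self.method}",
            f"architecture      : {self.params[0][0].shape[0]}-"
            + "-".join(str(s) for s in self.config.hidden_sizes)
            + "-2",
            f"n training samples: {self.n_train}",
            f"epochs / steps run: {self.n_epochs_run} / {self.n_steps_run}",
        ]
        if self.weighted_loss_curve is not None and len(self.weighted_loss_curve):
            lines.append(
                f"final weighted loss : {self.weighted_loss_curve[-1]:.4f}"
            )
        if self.train_loss_curve is not None and len(self.train_loss_curve):
            lines.append(f"final training loss : {self.train_loss_curve[-1]:.4f}")
        if self.val_loss_curve is not None and len(self.val_loss_curve):
            lines.append(f"final validation loss: {self.val_loss_curve[-1]:.4f}")
        if self.aggregate_weights is not None:
            w = self.aggregate_weights
            lines.append(
                f"aggregate weights  : mean {np.nanmean(w):.4g}, "
                f"zero fraction {(w == 0).mean():.3f}"
            )
        return "\n".join(lines)

    def plot_weight_distribution(self, mislabel_mask: np.ndarray, ax=None):
        """Boxplots of aggregate weights, correctly-labeled vs mislabeled."""
        if self.aggregate_weights is None:
            raise ValueError("no weights: not a reweighted fit")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        mask = np.asarray(mislabel_mask, dtype=bool)
        ax.boxplot(
            [self.aggregate_weights[~mask], self.aggregate_weights[mask]],
            tick_labels=["correct", "mislabeled"],
        )
        ax.set_ylabel("aggregate sample weight")
        return ax


# ---------------------------------------------------------------------------
# functional surface


def forward_predict(
    model: FitResult | _mlp.Params, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class scores (n, 2) and hard predictions; ties go to class 0."""
    params = model.params if isinstance(model, FitResult) else model
    features = np.asarray(features, dtype=float)
    if features.shape[1] != params[0][0].shape[0]:
        raise ValueError("feature width does not match model input size")
    scores, _ = _mlp.forward(params, features)
    return scores, (scores[:, 1] > scores[:, 0]).astype(int)


def epsilon_weighted_loss(
    model: FitResult | _mlp.Params,
    features: np.ndarray,
    labels: np.ndarray,
    eps: np.ndarray,
) -> float:
    """Perturbed batch loss ``sum_i eps_i * CE_i``; zero at eps = 0."""
    params = model.params if isinstance(model, FitResult) else model
    eps = np.asarray(eps, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if eps.shape != labels.shape:
        raise ValueError("eps must have one entry per batch sample")
    logits, _ = _mlp.forward(params, np.asarray(features, dtype=float))
    value = float(eps @ _mlp.per_sample_ce(logits, labels))
    if not np.isfinite(value):
        raise TrainingError("non-finite perturbed loss")
    return value


def rectify_and_normalize(mu: np.ndarray) -> np.ndarray:
    """max(mu, 0), normalized to sum 1; all-zero when every mu <= 0."""
    rectified = np.maximum(np.asarray(mu, dtype=float), 0.0)
    total = rectified.sum()
    return rectified / total if total > 0 else rectified


def meta_gradient_step(
    model: FitResult | _mlp.Params,
    train_batch: tuple[np.ndarray, np.ndarray],
    val_batch: tuple[np.ndarray, np.ndarray],
    config: TrainerConfig,
    step: int = 0,
    sample_ids: np.ndarray | None = None,
) -> WeightRecord:
    """Raw and normalized meta-weights for one training batch.

    Uses the exact inner-product form of the one-step meta-gradient (the
    virtual update is linear in eps, so no numerical differentiation through
    it is needed): ``mu_i = eta * alpha * <grad L_val, grad f_i>``.
    """
    params = model.params if isinstance(model, FitResult) else model
    xf, yf = np.asarray(train_batch[0], float), np.asarray(train_batch[1], int)
    xv, yv = np.asarray(val_batch[0], float), np.asarray(val_batch[1], int)
    if len(xf) == 0 or len(xv) == 0:
        raise ValueError("batches must be non-empty")
    sample_grads, _ = _mlp.per_sample_grads(params, xf, yf)
    val_grad, _ = _mlp.mean_grad(params, xv, yv)
    mu = config.meta_rate * config.inner_step_size * _mlp.grad_inner_products(
        sample_grads, val_grad
    )
    if not np.isfinite(mu).all():
        raise TrainingError(f"non-finite meta-gradient at step {step}")
    if sample_ids is None:
        sample_ids = np.arange(len(yf))
    return WeightRecord(
        step=step,
        sample_ids=np.asarray(sample_ids),
        mu=mu,
        rectified=np.maximum(mu, 0.0),
        normalized=rectify_and_normalize(mu),
    )


# ---------------------------------------------------------------------------
# model objects


class ReweightedDecoder:
    """MLP decoder trained with meta-learned per-sample weights.

    Parameters
    ----------
    train : LabeledDataset
        Noisy training data.
    val : LabeledDataset
        Small, (near-)clean validation data that guides the reweighting.
        The training batch size equals ``val.n_samples``.
    config : TrainerConfig, optional
    """

    def __init__(
        self,
        train: LabeledDataset,
        val: LabeledDataset,
        config: TrainerConfig | None = None,
    ):
        if train.n_features != val.n_features:
            raise ValueError("train/val feature dimensions differ")
        self.train_data = train
        self.val_data = val
        self.config = config or TrainerConfig()
        if (
            self.config.batch_size is not None
            and self.config.batch_size != val.n_samples
        ):
            raise ValueError(
                "batch_size must equal the validation sample size "
                f"({val.n_samples}); leave it unset to use that default"
            )

    @classmethod
    def from_arrays(
        cls,
        train_features: np.ndarray,
        train_labels: np.ndarray,
        val_features: np.ndarray,
        val_labels: np.ndarray,
        config: TrainerConfig | None = None,
    ) -> "ReweightedDecoder":
        return cls(
            LabeledDataset(train_features, train_labels),
            LabeledDataset(val_features, val_labels),
            config,
        )

    def fit(self, seed: int | None = None) -> FitResult:
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        xf, yf = self.train_data.features, self.train_data.labels
        xv, yv = self.val_data.features, self.val_data.labels
        feat_mean = feat_sd = None
        if cfg.standardize:
            # z-score with training-set statistics (applied to val at fit
            # time and to any features given to predict later)
            feat_mean = xf.mean(axis=0)
            feat_sd = xf.std(axis=0) + 1e-12
            xf = (xf - feat_mean) / feat_sd
            xv = (xv - feat_mean) / feat_sd
        n, m = len(yf), len(yv)
        batch = min(m, n)
        rng = np.random.default_rng(cfg.seed)
        sizes = (xf.shape[1], *cfg.hidden_sizes, 2)
        params = _mlp.init_params(sizes, rng)
        adam = _mlp.Adam(params, lr=cfg.learning_rate)

        trace: list[WeightRecord] = []
        weighted_losses: list[float] = []
        val_losses: list[float] = []
        last_seen = np.full(n, np.nan)
        final_epoch_w = np.full(n, np.nan)
        best_epoch_w = np.full(n, np.nan)
        steps_per_epoch = max(1, n // batch)
        best, stale = np.inf, 0
        best_val = np.inf
        best_params = params
        step = 0
        epochs_run = 0

        for _epoch in range(cfg.max_epochs):
            if step >= cfg.max_steps:
                break
            perm = rng.permutation(n)
            epoch_w = np.full(n, np.nan)
            epoch_loss = []
            epoch_val = []
            for b in range(steps_per_epoch):
                if step >= cfg.max_steps:
                    break
                ids = perm[b * batch : (b + 1) * batch]
                sample_grads, losses = _mlp.per_sample_grads(
                    params, xf[ids], yf[ids]
                )
                val_grad, val_loss = _mlp.mean_grad(params, xv, yv)
                mu = (
                    cfg.meta_rate
                    * cfg.inner_step_size
                    * _mlp.grad_inner_products(sample_grads, val_grad)
                )
                if not (np.isfinite(mu).all() and np.isfinite(losses).all()):
                    raise TrainingError(f"non-finite values at step {step}")
                omega = rectify_and_normalize(mu)
                trace.append(
                    WeightRecord(
                        step=step,
                        sample_ids=ids.copy(),
                        mu=mu,
                        rectified=np.maximum(mu, 0.0),
                        normalized=omega,
                    )
                )
                epoch_w[ids] = omega
                last_seen[ids] = omega
                w_loss = float(omega @ losses)
                weighted_losses.append(w_loss)
                epoch_loss.append(w_loss)
                val_losses.append(val_loss)
                epoch_val.append(val_loss)
                grads = _mlp.weighted_combination(sample_grads, omega)
                params = adam.step(params, grads)
                step += 1
            epochs_run += 1
            final_epoch_w = epoch_w
            if epoch_val and float(np.mean(epoch_val)) < best_val:
                best_val = float(np.mean(epoch_val))
                best_params = [(W.copy(), b.copy()) for W, b in params]
                best_epoch_w = epoch_w
            mean_loss = float(np.mean(epoch_loss)) if epoch_loss else np.nan
            if cfg.lr_decay != 1.0 and epochs_run % cfg.lr_decay_every == 0:
                adam.lr *= cfg.lr_decay
            if mean_loss < best - cfg.min_delta:
                best, stale = mean_loss, 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break

        if cfg.weight_aggregation == "last_step":
            aggregate = last_seen
        elif cfg.weight_aggregation == "best_epoch_mean" and cfg.restore_best:
            # describe the same model that is reported: the weights of the
            # epoch at which the restored (validation-optimal) snapshot was
            # taken, falling back to the last observed weight elsewhere
            aggregate = np.where(np.isnan(best_epoch_w), last_seen, best_epoch_w)
        else:
            # mean over the final epoch; fall back to the last observed
            # weight for samples the final (possibly truncated) epoch missed
            aggregate = np.where(np.isnan(final_epoch_w), last_seen, final_epoch_w)
        if step == 0:
            aggregate = None
        # the weight trace/aggregates describe the full training run; the
        # reported parameters are the validation-loss-optimal snapshot
        if cfg.restore_best:
            params = best_params

        return FitResult(
            params=params,
            config=cfg,
            method="reweight",
            n_train=n,
            n_epochs_run=epochs_run,
            n_steps_run=step,
            weight_trace=trace,
            aggregate_weights=aggregate,
            weighted_loss_curve=np.array(weighted_losses),
            val_loss_curve=np.array(val_losses),
            feature_mean=feat_mean,
            feature_sd=feat_sd,
        )


class PlainDecoder:
    """Same MLP architecture, standard (unweighted) cross-entropy training.

    Used for the two baselines: training on the merged train+validation data,
    and training on the validation data alone.
    """

    def __init__(self, data: LabeledDataset, config: TrainerConfig | None = None):
        if data.n_samples == 0:
            raise ValueError("data must be non-empty")
        self.data = data
        self.config = config or TrainerConfig()

    def fit(self, seed: int | None = None) -> FitResult:
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        x, y = self.data.features, self.data.labels
        feat_mean = feat_sd = None
        if cfg.standardize:
            feat_mean = x.mean(axis=0)
            feat_sd = x.std(axis=0) + 1e-12
            x = (x - feat_mean) / feat_sd
        n = len(y)
        batch = min(cfg.batch_size or 32, n)
        rng = np.random.default_rng(cfg.seed)
        params = _mlp.init_params((x.shape[1], *cfg.hidden_sizes, 2), rng)
        adam = _mlp.Adam(params, lr=cfg.learning_rate)

        losses_curve: list[float] = []
        best, stale = np.inf, 0
        step = 0
        epochs_run = 0
        steps_per_epoch = max(1, n // batch)
        for _epoch in range(cfg.max_epochs):
            if step >= cfg.max_steps:
                break
            perm = rng.permutation(n)
            epoch_loss = []
            for b in range(steps_per_epoch):
                if step >= cfg.max_steps:
                    break
                ids = perm[b * batch : (b + 1) * batch]
                grads, loss = _mlp.mean_grad(params, x[ids], y[ids])
                if not np.isfinite(loss):
                    raise TrainingError(f"non-finite loss at step {step}")
                params = adam.step(params, grads)
                epoch_loss.append(loss)
                losses_curve.append(loss)
                step += 1
            epochs_run += 1
            mean_loss = float(np.mean(epoch_loss)) if epoch_loss else np.nan
            if cfg.lr_decay != 1.0 and epochs_run % cfg.lr_decay_every == 0:
                adam.lr *= cfg.lr_decay
            if mean_loss < best - cfg.min_delta:
                best, stale = mean_loss, 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break

        return FitResult(
            params=params,
            config=cfg,
            method="plain",
            n_train=n,
            n_epochs_run=epochs_run,
            n_steps_run=step,
            train_loss_curve=np.array(losses_curve),
            feature_mean=feat_mean,
            feature_sd=feat_sd,
        )


def train_reweighted(
    train: LabeledDataset, val: LabeledDataset, config: TrainerConfig | None = None
) -> FitResult:
    """Fit the reweighted decoder (functional form of ReweightedDecoder.fit)."""
    return ReweightedDecoder(train, val, config).fit()


def train_plain(
    data: LabeledDataset, config: TrainerConfig | None = None
) -> FitResult:
    """Fit the plain baseline decoder (functional form of PlainDecoder.fit)."""
    return PlainDecoder(data, config).fit()
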