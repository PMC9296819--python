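"""End-to-end experiment runners: noise sweep, validation-size sweep, mixed
annotator pooling, and a trial-trajectory (calcium-imaging-style) study.

The simulated study uses the integrate-and-fire population: five 600-sample
training sets corrupted at shuffle portions 100/80/60/40/20%, a 600-sample
validation pool corrupted at portion 10% (near-clean) from which a small
guidance set is subsampled, and a clean 600-sample test set. The
trial-trajectory study operates on trials-by-timepoints matrices (91
timepoints, zero-mean normalized with training-split statistics) organized
by imaging session; a synthetic fixture generator stands in for real
recordings, which are not redistributed here.

Every runner is deterministic given the plan seed, returns a complete
pandas grid (failed cells carry an ``error`` entry instead of metrics), and
derives all sub-seeds from a single ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .datasets import LabeledDataset
from .metrics import balanced_accuracy, f1_score, weight_separation
from .noise import NoiseSpec, mix_datasets, realized_noise_level, shuffle_labels
from .simulator import SimulatorParams, calibrate_simulator, generate_dataset
from .trainer import PlainDecoder, ReweightedDecoder, TrainerConfig, TrainingError

__all__ = [
    "ExperimentPlan",
    "StudyData",
    "TrialMatrix",
    "make_simulated_study",
    "run_noise_sweep",
    "run_validation_size_sweep",
    "run_mixed_experiment",
    "generate_alm_like_fixture",
    "zero_mean_normalize",
    "load_trial_matrix",
    "save_trial_matrix",
    "run_alm_like_experiment",
]


@dataclass
class ExperimentPlan:
    """Grid definition and shared configuration for all runners."""

    portions: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4, 0.2)
    val_sizes: tuple[int, ...] = (20, 40, 60, 80, 100)
    n_resamples: int = 5
    methods: tuple[str, ...] = ("reweight", "baseline1", "baseline2")
    seed: int = 0
    n_train: int = 600
    n_val_pool: int = 600
    n_test: int = 600
    val_size: int = 20
    val_pool_portion: float = 0.10
    target_positive_fraction: float = 136 / 600
    calibrate: bool = True
    simulator: SimulatorParams = field(default_factory=SimulatorParams)
    trainer: TrainerConfig = field(default_factory=TrainerConfig)

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.portions):
            raise ValueError("portions must lie in [0, 1]")
        if any(s < 1 for s in self.val_sizes) or self.val_size < 1:
            raise ValueError("validation sizes must be >= 1")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


@dataclass
class StudyData:
    """Simulated-study datasets shared by the runners."""

    params: SimulatorParams
    train_sets: dict[float, LabeledDataset]  # portion -> noisy training set
    val_pool: LabeledDataset  # 600 samples, portion-0.10 noise
    val: LabeledDataset  # small guidance subset of the pool
    test: LabeledDataset  # clean


def _seed_of(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def make_simulated_study(plan: ExperimentPlan) -> StudyData:
    """Calibrate the simulator and generate the train/val/test datasets."""
    ss = np.random.SeedSequence(plan.seed)
    s_cal, s_train, s_noise, s_pool, s_poolnoise, s_sub, s_test = ss.spawn(7)
    params = plan.simulator
    if plan.calibrate:
        params = calibrate_simulator(
            params, plan.target_positive_fraction, n_pilot=2000, seed=_seed_of(s_cal)
        )
    train_clean = {
        p: generate_dataset(params, plan.n_train, _seed_of(child))
        for p, child in zip(plan.portions, s_train.spawn(len(plan.portions)))
    }
    train_sets = {
        p: shuffle_labels(train_clean[p], NoiseSpec(portion=p, seed=_seed_of(child)))
        for p, child in zip(plan.portions, s_noise.spawn(len(plan.portions)))
    }
    pool_clean = generate_dataset(params, plan.n_val_pool, _seed_of(s_pool))
    val_pool = shuffle_labels(
        pool_clean, NoiseSpec(portion=plan.val_pool_portion, seed=_seed_of(s_poolnoise))
    )
    rng = np.random.default_rng(s_sub)
    val = val_pool.subset(rng.choice(val_pool.n_samples, plan.val_size, replace=False))
    test = generate_dataset(params, plan.n_test, _seed_of(s_test))
    return StudyData(params=params, train_sets=train_sets, val_pool=val_pool, val=val, test=test)


def _fit_method(
    method: str,
    train: LabeledDataset,
    val: LabeledDataset,
    cfg: TrainerConfig,
    seed: int,
):
    """Dispatch one (method, dataset) fit; returns a FitResult."""
    if method == "reweight":
        return ReweightedDecoder(train, val, replace(cfg, batch_size=None)).fit(seed)
    if method == "baseline1":
        # drop noise bookkeeping before pooling: the merged baseline only
        # needs features and (possibly noisy) labels
        merged = mix_datasets(
            [
                LabeledDataset(train.features, train.labels),
                LabeledDataset(val.features, val.labels),
            ]
        )
        return PlainDecoder(merged, replace(cfg, batch_size=val.n_samples)).fit(seed)
    if method == "baseline2":
        return PlainDecoder(val, replace(cfg, batch_size=val.n_samples)).fit(seed)
    raise ValueError(f"unknown method {method!r}")


def _metric_row(fit, test: LabeledDataset) -> dict:
    y_pred = fit.predict(test.features)
    return {
        "f1": f1_score(test.labels, y_pred),
        "balanced_accuracy": balanced_accuracy(test.labels, y_pred),
    }


def _weight_columns(fit, train: LabeledDataset) -> dict:
    if fit.aggregate_weights is None or train.mislabel_mask is None:
        return {}
    if not train.mislabel_mask.any() or train.mislabel_mask.all():
        return {}
    ws = weight_separation(fit.aggregate_weights, train.mislabel_mask)
    return {
        "mean_weight_correct": ws.mean_weight_correct,
        "mean_weight_mislabeled": ws.mean_weight_mislabeled,
        "median_weight_correct": ws.median_weight_correct,
        "median_weight_mislabeled": ws.median_weight_mislabeled,
        "zero_weight_fraction_mislabeled": ws.zero_weight_fraction_mislabeled,
        "ranksum_statistic": ws.statistic,
        "ranksum_p": ws.p_value,
    }


def run_noise_sweep(
    plan: ExperimentPlan, study: StudyData | None = None
) -> pd.DataFrame:
    """Train every method at every noise portion; one row per grid cell.

    Reweight rows additionally carry weight-separation columns (group
    means/medians, zero-weight fraction of the mislabeled samples, and the
    rank-sum test).
    """
    study = study or make_simulated_study(plan)
    ss = np.random.SeedSequence((plan.seed, 1))
    rows = []
    for portion, child in zip(plan.portions, ss.spawn(len(plan.portions))):
        train = study.train_sets[portion]
        for method, mchild in zip(plan.methods, child.spawn(len(plan.methods))):
            row = {
                "method": method,
                "portion": portion,
                "realized_noise": realized_noise_level(train),
            }
            try:
                fit = _fit_method(method, train, study.val, plan.trainer, _seed_of(mchild))
                row.update(_metric_row(fit, study.test))
                if method == "reweight":
                    row.update(_weight_columns(fit, train))
            except TrainingError as exc:  # keep the grid complete
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def run_validation_size_sweep(
    plan: ExperimentPlan, study: StudyData | None = None
) -> pd.DataFrame:
    """Reweighted training at the highest noise level vs validation size.

    For each size, ``n_resamples`` validation sets are drawn without
    replacement from the near-clean pool; the table reports mean and SD of
    the test metrics over the resampled fits.
    """
    study = study or make_simulated_study(plan)
    train = study.train_sets[max(plan.portions)]
    ss = np.random.SeedSequence((plan.seed, 2))
    rows = []
    for size, child in zip(plan.val_sizes, ss.spawn(len(plan.val_sizes))):
        f1s, bals = [], []
        for rchild in child.spawn(plan.n_resamples):
            rng = np.random.default_rng(rchild)
            val = study.val_pool.subset(
                rng.choice(study.val_pool.n_samples, size, replace=False)
            )
            fit = ReweightedDecoder(train, val, plan.trainer).fit(_seed_of(rchild))
            m = _metric_row(fit, study.test)
            f1s.append(m["f1"])
            bals.append(m["balanced_accuracy"])
        rows.append(
            {
                "val_size": size,
                "mean_f1": float(np.mean(f1s)),
                "sd_f1": float(np.std(f1s, ddof=1)),
                "mean_balanced_accuracy": float(np.mean(bals)),
                "sd_balanced_accuracy": float(np.std(bals, ddof=1)),
                "n_resamples": plan.n_resamples,
            }
        )
    return pd.DataFrame(rows)


def default_mixtures(portions: tuple[float, ...]) -> list[tuple[float, ...]]:
    """Cumulative pools: worst two annotators, worst three, ... all five."""
    ordered = sorted(portions, reverse=True)
    return [tuple(ordered[: k + 2]) for k in range(len(ordered) - 1)]


def run_mixed_experiment(
    plan: ExperimentPlan,
    study: StudyData | None = None,
    mixtures: list[tuple[float, ...]] | None = None,
) -> pd.DataFrame:
    """Reweighted training on pooled training sets of mixed annotation quality."""
    study = study or make_simulated_study(plan)
    if mixtures is None:
        mixtures = default_mixtures(plan.portions)
    if any(len(m) < 1 for m in mixtures):
        raise ValueError("each mixture needs at least one component")
    ss = np.random.SeedSequence((plan.seed, 3))
    rows = []
    for mixture, child in zip(mixtures, ss.spawn(len(mixtures))):
        pooled = mix_datasets([study.train_sets[p] for p in mixture])
        row = {
            "mixture": "+".join(f"{p:g}" for p in mixture),
            "n_train": pooled.n_samples,
            "realized_noise": realized_noise_level(pooled),
        }
        try:
            fit = ReweightedDecoder(pooled, study.val, plan.trainer).fit(_seed_of(child))
            row.update(_metric_row(fit, study.test))
            row.update(_weight_columns(fit, pooled))
        except TrainingError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trial-trajectory (calcium-imaging-style) study


@dataclass
class TrialMatrix:
    """Trials-by-timepoints matrix with trial-type labels and session ids."""

    data: np.ndarray
    labels: np.ndarray
    session_ids: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.session_ids = np.asarray(self.session_ids, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be trials x timepoints")
        n = self.data.shape[0]
        if self.labels.shape != (n,) or self.session_ids.shape != (n,):
            raise ValueError("labels/session_ids must have one entry per trial")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def session(self, sid: int) -> "TrialMatrix":
        m = self.session_ids == sid
        return TrialMatrix(self.data[m], self.labels[m], self.session_ids[m])

    def to_dataset(self) -> LabeledDataset:
        return LabeledDataset(self.data, self.labels)


def generate_alm_like_fixture(
    n_sessions: int = 18,
    trials_range: tuple[int, int] = (48, 67),
    timepoints: int = 91,
    seed: int = 0,
    noise_amplitude: float = 0.5,
    session_gain_sd: float = 0.1,
    class_contrast: float = 1.0,
) -> TrialMatrix:
    """Synthesize session-structured trial trajectories (synthetic stand-in).

    Two class-conditional smooth templates share an early stimulus bump and
    diverge mainly in a late response-epoch window; trials add temporally
    autocorrelated Gaussian noise (white noise smoothed over ~4 timepoints)
    and a multiplicative per-session gain. Labels are balanced within each
    session. This emulates only the trials x timepoints shape, smoothness
    and session structure of ensemble calcium-imaging trajectories — not
    their indicator dynamics or real epoch timing.
    """
    if n_sessions < 1 or trials_range[0] < 1 or trials_range[0] > trials_range[1]:
        raise ValueError("invalid session/trial counts")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, timepoints)
    common = np.exp(-(((t - 0.3) / 0.15) ** 2))
    response = np.exp(-(((t - 0.82) / 0.1) ** 2))
    templates = {
        0: common + class_contrast * response,
        1: common - class_contrast * response,
    }
    data, labels, sessions = [], [], []
    for sid in range(n_sessions):
        n_trials = int(rng.integers(trials_range[0], trials_range[1] + 1))
        gain = 1.0 + session_gain_sd * rng.standard_normal()
        lab = np.zeros(n_trials, dtype=int)
        lab[n_trials // 2 :] = 1
        rng.shuffle(lab)
        for y in lab:
            noise = rng.standard_normal(timepoints)
            if noise_amplitude > 0:
                noise = gaussian_filter1d(noise, sigma=4.0, mode="nearest")
                noise = noise / max(noise.std(), 1e-12) * noise_amplitude
            else:
                noise = 0.0
            data.append(gain * templates[int(y)] + noise)
        labels.append(lab)
        sessions.append(np.full(n_trials, sid))
    return TrialMatrix(
        data=np.array(data),
        labels=np.concatenate(labels),
        session_ids=np.concatenate(sessions),
    )


def zero_mean_normalize(
    matrix: TrialMatrix, means: np.ndarray | None = None
) -> tuple[TrialMatrix, np.ndarray]:
    """Subtract per-timepoint means; returns (normalized, means used).

    Pass the means computed on the training split to normalize validation
    and test splits with training statistics.
    """
    if means is None:
        means = matrix.data.mean(axis=0)
    means = np.asarray(means, dtype=float)
    if means.shape != (matrix.n_timepoints,):
        raise ValueError("means must have one entry per timepoint")
    return (
        TrialMatrix(matrix.data - means, matrix.labels, matrix.session_ids),
        means,
    )


def save_trial_matrix(matrix: TrialMatrix, path: str | Path) -> None:
    """Write trials as delimited text (t0..tK, label, session) or ``.npz``."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            data=matrix.data,
            labels=matrix.labels,
            session_ids=matrix.session_ids,
        )
        return
    df = pd.DataFrame(
        matrix.data, columns=[f"t{j}" for j in range(matrix.n_timepoints)]
    )
    df["label"] = matrix.labels
    df["session"] = matrix.session_ids
    df.to_csv(path, index=False)


def load_trial_matrix(path: str | Path) -> TrialMatrix:
    """Read a trial matrix written by :func:`save_trial_matrix`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return TrialMatrix(z["data"], z["labels"], z["session_ids"])
    df = pd.read_csv(path)
    t_cols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    t_cols.sort(key=lambda c: int(c[1:]))
    if not t_cols or "label" not in df.columns:
        raise ValueError("expected timepoint columns t0..tK and a 'label' column")
    if df[t_cols].isna().any().any():
        raise ValueError("ragged rows / missing values in trial matrix")
    return TrialMatrix(
        df[t_cols].to_numpy(dtype=float),
        df["label"].to_numpy(dtype=int),
        df["session"].to_numpy(dtype=int)
        if "session" in df.columns
        else np.zeros(len(df), dtype=int),
    )


def _session_snr(matrix: TrialMatrix) -> dict[int, float]:
    """Between-class template separation over within-class spread, per session."""
    out = {}
    for sid in np.unique(matrix.session_ids):
        sess = matrix.session(sid)
        m0 = sess.data[sess.labels == 0]
        m1 = sess.data[sess.labels == 1]
        if len(m0) == 0 or len(m1) == 0:
            out[int(sid)] = 0.0
            continue
        sep = np.linalg.norm(m0.mean(axis=0) - m1.mean(axis=0))
        spread = 0.5 * (m0.std(axis=0).mean() + m1.std(axis=0).mean())
        out[int(sid)] = float(sep / max(spread, 1e-12))
    return out


def run_alm_like_experiment(
    plan: ExperimentPlan, data: TrialMatrix
) -> pd.DataFrame:
    """Session-split trial-trajectory study across noise portions.

    The highest-SNR session becomes the clean validation set, the next two
    the clean test set, the rest the training pool. The training pool is
    copied once per portion in ``plan.portions`` and label-shuffled; all
    methods in ``plan.methods`` are trained per copy. Features are zero-mean
    normalized with training-split statistics.
    """
    snr = _session_snr(data)
    ranked = sorted(snr, key=snr.get, reverse=True)
    if len(ranked) < 4:
        raise ValueError("need at least four sessions to split")
    val_sid, test_sids = ranked[0], ranked[1:3]
    train_sids = [s for s in ranked if s != val_sid and s not in test_sids]

    train_mask = np.isin(data.session_ids, train_sids)
    train_raw = TrialMatrix(
        data.data[train_mask], data.labels[train_mask], data.session_ids[train_mask]
    )
    train_norm, means = zero_mean_normalize(train_raw)
    val_norm, _ = zero_mean_normalize(data.session(val_sid), means)
    test_mask = np.isin(data.session_ids, test_sids)
    test_norm, _ = zero_mean_normalize(
        TrialMatrix(data.data[test_mask], data.labels[test_mask],
                    data.session_ids[test_mask]),
        means,
    )
    train_ds, val_ds, test_ds = (
        train_norm.to_dataset(),
        val_norm.to_dataset(),
        test_norm.to_dataset(),
    )

    ss = np.random.SeedSequence((plan.seed, 4))
    rows = []
    for portion, child in zip(plan.portions, ss.spawn(len(plan.portions))):
        nchild, *mchildren = child.spawn(1 + len(plan.methods))
        noisy = shuffle_labels(train_ds, NoiseSpec(portion=portion, seed=_seed_of(nchild)))
        for method, mchild in zip(plan.methods, mchildren):
            row = {
                "method": method,
                "portion": portion,
                "realized_noise": realized_noise_level(noisy),
                "n_train": noisy.n_samples,
            }
            try:
                fit = _fit_method(method, noisy, val_ds, plan.trainer, _seed_of(mchild))
                row.update(_metric_row(fit, test_ds))
                if method == "reweight":
                    row.update(_weight_columns(fit, noisy))
            except TrainingError as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
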