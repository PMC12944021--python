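"""Training harness: cross-entropy + Adam optimisation, random hyperparameter
search over the published ranges, leave-one-participant-out cross-validation,
and cohort pooling.

Training operates on fixed-length windows (default 200 frames at 50 Hz, i.e.
4 s) cut from each participant's recording; the shorter remainder window of
each recording is kept, since every model accepts variable-length input.
Evaluation always runs on whole recordings so predictions are dense over
every frame a participant contributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import LabelSequence, SignalWindow, select_channels, window_recording
from .models import (
    ConvLayerSpec,
    DenseLabeller,
    FramePredictions,
    ModelConfig,
    softmax,
)
from .synthetic import SyntheticRecording


class TrainingDiverged(RuntimeError):
    """Loss became non-finite during optimisation."""


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings; learning rate defaults to the model config's."""

    learning_rate: float | None = None
    batch_size: int = 16
    max_epochs: int = 12
    patience: int = 3
    seed: int = 0
    window_len: int = 200
    # Adam moment decays and epsilon: conventional defaults
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")


@dataclass
class FoldResult:
    """One LOPO fold: the held-out participant, its dense predictions, truth."""

    held_out_participant: str
    model: DenseLabeller
    predictions: FramePredictions
    truth: LabelSequence
    train_participants: tuple[str, ...]


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def frame_cross_entropy(
    predictions: FramePredictions | np.ndarray, truth: LabelSequence | np.ndarray
) -> float:
    """Mean over frames of -log probability assigned to the true class.

    Probabilities are clipped at 1e-12 so the loss stays finite for
    degenerate (one-hot wrong) predictions.
    """
    probs = (
        predictions.probabilities
        if isinstance(predictions, FramePredictions)
        else np.asarray(predictions, float)
    )
    y = truth.labels if isinstance(truth, LabelSequence) else np.asarray(truth)
    if probs.shape[0] != y.shape[0]:
        raise ValueError(f"{probs.shape[0]} prediction rows but {y.shape[0]} labels")
    p_true = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.log(p_true).mean())


# ---------------------------------------------------------------------------
# window preparation
# ---------------------------------------------------------------------------

def windows_from_recordings(
    recordings: Sequence[SyntheticRecording],
    window_len: int,
    site: str = "both",
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut training windows: (T, n) signal and (T,) label arrays per window."""
    out = []
    for rec in recordings:
        signal = select_channels(rec.signal, site) if site != "both" else rec.signal
        for sig, lab in window_recording(signal, rec.labels, window_len):
            out.append((sig.values.T.copy(), lab.labels.copy()))
    return out


def split_by_participant(
    recordings: Sequence[SyntheticRecording],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Grouped random split: every participant's data lands in exactly one of
    train/validation/test."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(recordings))
    n = len(recordings)
    n_train = max(1, int(round(fractions[0] * n)))
    n_val = max(1, int(round(fractions[1] * n)))
    n_train = min(n_train, n - 2) if n >= 3 else n_train
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    return (
        [recordings[i] for i in idx_train],
        [recordings[i] for i in idx_val],
        [recordings[i] for i in idx_test],
    )


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive moment estimation on the model's named parameter arrays."""

    def __init__(self, tcfg: TrainingConfig, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = tcfg.beta1, tcfg.beta2, tcfg.eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, named_params) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for name, arr, grad in named_params:
            if name not in self.m:
                self.m[name] = np.zeros_like(arr)
                self.v[name] = np.zeros_like(arr)
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * grad
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * grad**2
            arr -= self.lr * (self.m[name] / b1t) / (np.sqrt(self.v[name] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _batches(windows, batch_size, rng):
    """Shuffle windows, bucket by length, yield (B, T, n) / (B, T) batches."""
    order = rng.permutation(len(windows))
    buckets: dict[int, list[int]] = {}
    for i in order:
        buckets.setdefault(windows[i][0].shape[0], []).append(i)
    starts = []
    for T in sorted(buckets):
        idxs = buckets[T]
        for s in range(0, len(idxs), batch_size):
            starts.append(idxs[s : s + batch_size])
    rng.shuffle(starts)
    for group in starts:
        x = np.stack([windows[i][0] for i in group])
        y = np.stack([windows[i][1] for i in group])
        yield x, y


def _validation_weighted_f1(model: DenseLabeller, val_windows) -> tuple[float, float]:
    from .ensemble import compute_metrics  # local import to avoid a cycle

    preds, truths, losses = [], [], []
    for x, y in val_windows:
        fp = model.predict(x.T)
        preds.append(fp.argmax_labels)
        truths.append(y)
        losses.append(frame_cross_entropy(fp, y))
    report = compute_metrics(np.concatenate(preds), np.concatenate(truths))
    return report.weighted["f1"], float(np.mean(losses))


def train_model(
    config: ModelConfig,
    train_windows: list[tuple[np.ndarray, np.ndarray]],
    val_windows: list[tuple[np.ndarray, np.ndarray]],
    tcfg: TrainingConfig,
) -> tuple[DenseLabeller, pd.DataFrame]:
    """Minimise frame cross-entropy with Adam, early-stopping on validation
    weighted F1; returns the best-validation model and the epoch history.

    Deterministic given ``tcfg.seed`` (single-threaded NumPy arithmetic; exact
    bit-reproducibility can vary with the BLAS backend).
    """
    if not train_windows or not val_windows:
        raise ValueError("train and validation window sets must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 0xA11]))
    model = DenseLabeller(config, seed=int(rng.integers(2**31)))
    lr = tcfg.learning_rate if tcfg.learning_rate is not None else config.learning_rate
    optimiser = Adam(tcfg, lr)

    best_f1 = -np.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0
    history = []
    for epoch in range(tcfg.max_epochs):
        epoch_losses = []
        for x, y in _batches(train_windows, tcfg.batch_size, rng):
            model.net.zero_grads()
            logits = model.net.forward(x, training=True, rng=rng)
            probs = softmax(logits)
            B, T, C = probs.shape
            p_true = np.clip(
                np.take_along_axis(probs, y[..., None], axis=2), 1e-12, None
            )
            loss = float(-np.log(p_true).mean())
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, family={config.family}, lr={lr}"
                )
            dlogits = (probs - np.eye(C)[y]) / (B * T)
            model.net.backward(dlogits)
            optimiser.step(model.net.named_parameters())
            epoch_losses.append(loss)
        val_f1, val_loss = _validation_weighted_f1(model, val_windows)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_weighted_f1": val_f1,
            }
        )
        if val_f1 > best_f1:
            best_f1, stale = val_f1, 0
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        else:
            stale += 1
            if stale >= tcfg.patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# random hyperparameter search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """Discretised grids of the published hyperparameter ranges.

    Random search draws ``n_draws`` configurations uniformly from the grids
    (per architecture family); duplicates are re-drawn up to a bound.
    """

    n_draws: int = 50
    cnn_layers: tuple[int, ...] = (1, 2, 3, 4, 5)
    kernel_counts: tuple[int, ...] = (32, 64, 128, 256, 512, 1024)
    kernel_sizes: tuple[int, ...] = tuple(range(1, 12))
    strides: tuple[int, ...] = tuple(range(1, 12))
    gru_layers: tuple[int, ...] = (1, 2, 3)
    gru_units: tuple[int, ...] = (32, 64, 128, 256)
    dropout_rates: tuple[float, ...] = (0.3, 0.6)
    learning_rates: tuple[float, ...] = (0.001, 0.003, 0.01, 0.03, 0.1)
    bidirectional: bool = True


def sample_config(
    space: SearchSpace,
    family: str,
    rng: np.random.Generator,
    input_channels: int = 6,
    class_count: int = 9,
) -> ModelConfig:
    """Draw one configuration uniformly from the family's grids."""
    dropout = float(rng.choice(space.dropout_rates))
    lr = float(rng.choice(space.learning_rates))
    conv_specs: tuple[ConvLayerSpec, ...] = ()
    gru_units: tuple[int, ...] = ()
    if family in ("cnn", "convrec", "reconv"):
        n_conv = int(rng.choice(space.cnn_layers)) if family == "cnn" else int(
            rng.choice(space.cnn_layers[:2])
        )
        conv_specs = tuple(
            ConvLayerSpec(
                kernel_count=int(rng.choice(space.kernel_counts)),
                kernel_size=int(rng.choice(space.kernel_sizes)),
                stride=int(rng.choice(space.strides)),
                dropout_rate=dropout,
            )
            for _ in range(n_conv)
        )
    if family in ("gru", "convrec", "reconv"):
        n_gru = int(rng.choice(space.gru_layers))
        gru_units = tuple(int(rng.choice(space.gru_units)) for _ in range(n_gru))
    return ModelConfig(
        family=family,
        input_channels=input_channels,
        class_count=class_count,
        conv_specs=conv_specs,
        gru_units=gru_units,
        bidirectional=space.bidirectional,
        dropout_rate=dropout,
        learning_rate=lr,
    )


def sample_search_configs(
    space: SearchSpace,
    family: str,
    seed: int,
    input_channels: int = 6,
    class_count: int = 9,
) -> list[ModelConfig]:
    """The full, de-duplicated list of ``n_draws`` sampled configurations."""
    if space.n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EA]))
    configs: list[ModelConfig] = []
    seen = set()
    attempts = 0
    while len(configs) < space.n_draws and attempts < 20 * space.n_draws:
        cfg = sample_config(space, family, rng, input_channels, class_count)
        key = repr(cfg)
        attempts += 1
        if key in seen:
            continue
        seen.add(key)
        configs.append(cfg)
    if len(configs) < space.n_draws:  # grid smaller than n_draws: allow repeats
        while len(configs) < space.n_draws:
            configs.append(sample_config(space, family, rng, input_channels, class_count))
    return configs


def random_search(
    space: SearchSpace,
    train_windows,
    val_windows,
    tcfg: TrainingConfig,
    family: str = "gru",
    input_channels: int = 6,
    class_count: int = 9,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Train every sampled configuration on the fixed split; rank by
    validation weighted F1 and return the best configuration + leaderboard."""
    configs = sample_search_configs(
        space, family, tcfg.seed, input_channels, class_count
    )
    rows = []
    failures = 0
    for i, cfg in enumerate(configs):
        try:
            _, history = train_model(cfg, train_windows, val_windows, tcfg)
            best = float(history["val_weighted_f1"].max())
        except (TrainingDiverged, ValueError) as exc:
            best = np.nan
            failures += 1
        rows.append({"draw": i, "config": cfg, "val_weighted_f1": best})
    if failures == len(configs):
        raise RuntimeError("every search configuration failed to train")
    board = pd.DataFrame(rows).sort_values(
        "val_weighted_f1", ascending=False, na_position="last"
    ).reset_index(drop=True)
    return board.loc[0, "config"], board


# ---------------------------------------------------------------------------
# leave-one-participant-out cross-validation
# ---------------------------------------------------------------------------

class FoldFailure(RuntimeError):
    def __init__(self, failures: list[tuple[str, Exception]], folds: list[FoldResult]):
        self.failures = failures
        self.folds = folds
        super().__init__(
            "LOPO folds failed for participants: "
            + ", ".join(f"{p} ({e})" for p, e in failures)
        )


def lopo_cv(
    cohort: Sequence[SyntheticRecording],
    config: ModelConfig,
    tcfg: TrainingConfig,
    site: str = "both",
) -> list[FoldResult]:
    """One fold per participant: train on everyone else, predict the held-out
    participant's whole recording densely.

    Within each fold the training participants are further split (grouped,
    seeded) into train and validation for early stopping.  Fold failures are
    collected and surfaced together at the end, never silently dropped.
    """
    ids = [rec.participant_id for rec in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("participant ids must be unique")
    if len(cohort) < 2:
        raise ValueError("LOPO-CV needs at least 2 participants")
    folds: list[FoldResult] = []
    failures: list[tuple[str, Exception]] = []
    for i, held_out in enumerate(cohort):
        rest = [rec for rec in cohort if rec.participant_id != held_out.participant_id]
        fold_seed = int(
            np.random.SeedSequence([tcfg.seed, 0xF0, i]).generate_state(1)[0] & 0x7FFFFFFF
        )
        rng = np.random.default_rng(fold_seed)
        n_val = max(1, int(round(0.15 * len(rest))))
        val_idx = set(rng.choice(len(rest), size=n_val, replace=False).tolist())
        train_recs = [r for j, r in enumerate(rest) if j not in val_idx]
        val_recs = [r for j, r in enumerate(rest) if j in val_idx]
        assert held_out.participant_id not in {r.participant_id for r in train_recs}
        try:
            model, _ = train_model(
                config,
                windows_from_recordings(train_recs, tcfg.window_len, site),
                windows_from_recordings(val_recs, tcfg.window_len, site),
                replace(tcfg, seed=fold_seed),
            )
            signal = (
                select_channels(held_out.signal, site) if site != "both" else held_out.signal
            )
            predictions = model.predict(signal)
        except Exception as exc:  # noqa: BLE001 — surfaced via FoldFailure
            failures.append((held_out.participant_id, exc))
            continue
        folds.append(
            FoldResult(
                held_out_participant=held_out.participant_id,
                model=model,
                predictions=predictions,
                truth=held_out.labels,
                train_participants=tuple(r.participant_id for r in train_recs),
            )
        )
    if failures:
        raise FoldFailure(failures, folds)
    return folds


def concatenate_fold_results(
    folds: Sequence[FoldResult],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate all folds' held-out predictions, truths and probabilities
    into single arrays for cohort-level metrics."""
    pred = np.concatenate([f.predictions.argmax_labels for f in folds])
    truth = np.concatenate([f.truth.labels for f in folds])
    probs = np.concatenate([f.predictions.probabilities for f in folds], axis=0)
    return pred, truth, probs


def pool_cohorts(
    young: Sequence[SyntheticRecording], old: Sequence[SyntheticRecording]
) -> list[SyntheticRecording]:
    """Pool two cohorts into one training population, keeping cohort tags.

    Participant ids must be disjoint (cohort-name prefixes guarantee this for
    generated cohorts); a collision is an error rather than a silent merge.
    """
    combined = list(young) + list(old)
    ids = [rec.participant_id for rec in combined]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"participant id collision between cohorts: {dupes}")
    return combined
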