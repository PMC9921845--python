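"""Day-level peak classifier: dataset assembly, search, training, prediction.

The learning task: given the 14-day feature window ending the day before an
anchor date, predict the probability that the anchor date is a flight-peak
day.  Positives are the labeled peak DOYs (at most one per site-season-
generation), everything else in the anchor range is negative, so the classes
are heavily skewed and the training partition is rebalanced.  Site-seasons
never straddle partitions.

Hyperparameters are drawn from a configurable search space (layer count,
per-layer widths and activations, learning rate, optimizer) by seeded random
search; each trial trains with early stopping on validation loss and the
winner is the trial with the best *validation peak-matching F1* — day-level
cross-entropy is only the training signal, while the scientific currency is
the peak event, so model selection uses the event metric.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import FlightPeak, peaks_to_frame
from .evaluation import compute_metrics, match_events
from .nn import FeedForwardNet, LayerSpec, TrainingResult

__all__ = [
    "WindowSet",
    "LabeledDataset",
    "DatasetSplit",
    "SearchSpace",
    "ModelConfig",
    "TrainedModel",
    "build_dataset",
    "balance_dataset",
    "split_by_group",
    "search_and_train",
    "predict_peak_doys",
    "peaks_from_probabilities",
    "peak_f1",
    "rank_relevance",
    "PUBLISHED_BEST_CONFIG",
]


@dataclass(frozen=True)
class WindowSet:
    """All anchor windows of one site-season."""

    site_id: str
    season: int
    X: np.ndarray
    anchor_doys: np.ndarray
    feature_names: list[str]


@dataclass
class LabeledDataset:
    X: np.ndarray
    y: np.ndarray
    site_ids: np.ndarray
    seasons: np.ndarray
    anchor_doys: np.ndarray
    feature_names: list[str]

    def __len__(self) -> int:
        return len(self.y)

    def group_labels(self) -> np.ndarray:
        return np.char.add(np.char.add(self.site_ids.astype(str), "|"), self.seasons.astype(str))

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.X[mask],
            self.y[mask],
            self.site_ids[mask],
            self.seasons[mask],
            self.anchor_doys[mask],
            self.feature_names,
        )


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[tuple[str, int], ...]
    validation: tuple[tuple[str, int], ...]
    test: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = parts[i] & parts[j]
                if overlap:
                    raise ValueError(f"site-season groups leak across partitions: {sorted(overlap)[:3]}")

    def mask(self, ds: LabeledDataset, which: Literal["train", "validation", "test"]) -> np.ndarray:
        wanted = {f"{s}|{y}" for s, y in getattr(self, which)}
        return np.isin(ds.group_labels(), list(wanted))


def build_dataset(window_sets: Sequence[WindowSet], peaks: Sequence[FlightPeak] | pd.DataFrame) -> LabeledDataset:
    """Concatenate site-season windows and label anchor dates.

    Label 1 iff the anchor DOY equals a labeled peak DOY of that site-season
    (any generation).  Duplicate (site, season, anchor) windows are an input
    error; peaks whose DOY has no covering window are dropped with a log
    entry (their site-season keeps its negatives).
    """
    if not window_sets:
        raise ValueError("no window sets given")
    names = window_sets[0].feature_names
    for ws in window_sets:
        if ws.feature_names != names:
            raise ValueError(f"feature-order signature mismatch for {ws.site_id}/{ws.season}")

    peak_frame = peaks if isinstance(peaks, pd.DataFrame) else peaks_to_frame(peaks)
    peak_doys: dict[tuple[str, int], set[int]] = {}
    for r in peak_frame.itertuples(index=False):
        peak_doys.setdefault((str(r.site_id), int(r.season)), set()).add(int(r.doy))

    Xs, ys, sids, seas, anchors = [], [], [], [], []
    n_dropped = 0
    for ws in window_sets:
        if len(np.unique(ws.anchor_doys)) != len(ws.anchor_doys):
            raise ValueError(f"duplicate anchor windows for {ws.site_id}/{ws.season}")
        labels = np.isin(ws.anchor_doys, list(peak_doys.get((ws.site_id, ws.season), ())))
        covered = set(ws.anchor_doys.tolist())
        n_dropped += len(peak_doys.get((ws.site_id, ws.season), set()) - covered)
        Xs.append(ws.X)
        ys.append(labels.astype(float))
        sids.append(np.full(len(ws.anchor_doys), ws.site_id, dtype=object))
        seas.append(np.full(len(ws.anchor_doys), ws.season, dtype=int))
        anchors.append(np.asarray(ws.anchor_doys, int))
    if n_dropped:
        import logging

        logging.getLogger(__name__).info("build_dataset: %d peak(s) had no covering window", n_dropped)
    return LabeledDataset(
        np.vstack(Xs),
        np.concatenate(ys),
        np.concatenate(sids),
        np.concatenate(seas),
        np.concatenate(anchors),
        list(names),
    )


def balance_dataset(
    ds: LabeledDataset,
    ratio: float = 3.0,
    method: Literal["oversample", "undersample"] = "oversample",
    seed: int = 0,
) -> LabeledDataset:
    """Rebalance to at most ``ratio`` negatives per positive.

    Default randomly oversamples positives (with replacement) and discards
    nothing; ``undersample`` instead thins the negatives, a desk-scale
    option for small experiments.  Deterministic under seed; already
    balanced input is returned unchanged.
    """
    pos = np.nonzero(ds.y > 0.5)[0]
    neg = np.nonzero(ds.y <= 0.5)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    if len(neg) <= ratio * len(pos):
        return ds
    if method == "oversample":
        target = int(np.ceil(len(neg) / ratio))
        extra = rng.choice(pos, target - len(pos), replace=True)
        idx = np.concatenate([np.arange(len(ds)), extra])
    elif method == "undersample":
        target = int(np.floor(ratio * len(pos)))
        keep = rng.choice(neg, target, replace=False)
        idx = np.sort(np.concatenate([pos, keep]))
    else:
        raise ValueError(f"unknown balance method {method!r}")
    return ds.subset(idx)


def split_by_group(
    ds: LabeledDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Partition (site, season) groups into train/validation/test.

    Groups are canonically sorted before shuffling, so the split is
    invariant to input row order.  Each partition receives at least one
    group; fractions are honoured within +/-1 group.
    """
    groups = sorted({(str(s), int(y)) for s, y in zip(ds.site_ids, ds.seasons)})
    n = len(groups)
    if n < 3:
        raise ValueError(f"need at least 3 site-season groups to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [groups[i] for i in order]
    n_val = max(1, round(fractions[1] * n))
    n_test = max(1, round(fractions[2] * n))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("fractions leave no training groups")
    return DatasetSplit(
        tuple(shuffled[:n_train]),
        tuple(shuffled[n_train : n_train + n_val]),
        tuple(shuffled[n_train + n_val :]),
    )


# --------------------------------------------------------------------------
# search space and model containers


@dataclass(frozen=True)
class SearchSpace:
    """Random-search space for the classifier (defaults: published setup)."""

    n_layers: tuple[int, int] = (3, 10)
    intermediate_units: tuple[int, ...] = (0,) + tuple(range(32, 513, 16))
    last_two_units: tuple[int, ...] = tuple(range(16, 465, 16))
    activations: tuple[str, ...] = ("selu", "linear", "tanh", "softmax")
    learning_rates: tuple[float, ...] = (1e-3, 1e-2, 1e-1)
    optimizers: tuple[str, ...] = ("sgd", "adam", "rmsprop")
    patience: int = 17
    min_delta: float = 0.17
    max_epochs: int = 1000

    def sample(self, rng: np.random.Generator) -> "ModelConfig":
        n_layers = int(rng.integers(self.n_layers[0], self.n_layers[1] + 1))
        layers: list[LayerSpec] = []
        for pos in range(n_layers):
            pool = self.last_two_units if pos >= n_layers - 2 else self.intermediate_units
            units = int(rng.choice(pool))
            if units == 0:
                continue  # width 0 = layer absent
            activation = str(rng.choice(self.activations))
            layers.append(LayerSpec(units, activation))
        if not layers:  # all intermediate widths drawn as 0
            layers = [LayerSpec(int(rng.choice(self.last_two_units)), str(rng.choice(self.activations)))]
        return ModelConfig(
            layers=tuple(layers),
            learning_rate=float(rng.choice(self.learning_rates)),
            optimizer=str(rng.choice(self.optimizers)),
        )


@dataclass(frozen=True)
class ModelConfig:
    layers: tuple[LayerSpec, ...]
    learning_rate: float = 1e-3
    optimizer: str = "adam"

    def describe(self) -> str:
        arch = " / ".join(f"{l.units} {l.activation}" for l in self.layers)
        return f"[{arch}] + sigmoid, lr={self.learning_rate:g}, {self.optimizer}"


#: The published best architecture, as a directly buildable configuration.
PUBLISHED_BEST_CONFIG = ModelConfig(
    layers=(
        LayerSpec(96, "linear"),
        LayerSpec(336, "selu"),
        LayerSpec(64, "linear"),
        LayerSpec(144, "selu"),
    ),
    learning_rate=1e-3,
    optimizer="adam",
)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it elsewhere."""

    config: ModelConfig
    net: FeedForwardNet
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    train_seed: int

    def predict_proba(self, X: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
        if feature_names is not None and list(feature_names) != self.feature_names:
            raise ValueError("feature-order signature mismatch between model and windows")
        Z = (np.asarray(X, float) - self.scaler_mean) / self.scaler_std
        return self.net.predict_proba(Z)

    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "layers": [[l.units, l.activation] for l in self.config.layers],
            "learning_rate": self.config.learning_rate,
            "optimizer": self.config.optimizer,
            "feature_names": self.feature_names,
            "train_seed": self.train_seed,
            "n_inputs": self.net.n_inputs,
        }
        (model_dir / "model.json").write_text(json.dumps(meta, indent=2))
        np.savez(
            model_dir / "weights.npz",
            scaler_mean=self.scaler_mean,
            scaler_std=self.scaler_std,
            **self.net.get_weights(),
        )

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "model.json").read_text())
        config = ModelConfig(
            layers=tuple(LayerSpec(u, a) for u, a in meta["layers"]),
            learning_rate=meta["learning_rate"],
            optimizer=meta["optimizer"],
        )
        net = FeedForwardNet(meta["n_inputs"], list(config.layers), seed=meta["train_seed"])
        data = np.load(model_dir / "weights.npz")
        net.set_weights({k: data[k] for k in data.files if k.startswith(("W", "b"))})
        return cls(
            config,
            net,
            list(meta["feature_names"]),
            data["scaler_mean"],
            data["scaler_std"],
            int(meta["train_seed"]),
        )


# --------------------------------------------------------------------------
# peak extraction from day-level probabilities


def peaks_from_probabilities(
    probs: np.ndarray,
    doys: np.ndarray,
    span_days: int = 28,
    max_generations: int = 3,
) -> list[int]:
    """Up to three peak DOYs from a per-day probability series.

    Greedy selection: repeatedly take the highest-probability day (earliest
    on ties) whose DOY is at least ``span_days`` from every day already
    chosen — i.e. the generations occupy non-overlapping 28-day spans.
    Returned DOYs are sorted ascending.
    """
    probs = np.asarray(probs, float)
    doys = np.asarray(doys, int)
    if probs.shape != doys.shape:
        raise ValueError("probs and doys must align")
    available = np.ones(len(probs), bool)
    chosen: list[int] = []
    while available.any() and len(chosen) < max_generations:
        masked = np.where(available, probs, -np.inf)
        best = int(np.argmax(masked))  # first index on ties -> earliest day
        chosen.append(int(doys[best]))
        available &= np.abs(doys - doys[best]) >= span_days
    return sorted(chosen)


def predict_peak_doys(
    model: TrainedModel,
    X: np.ndarray,
    anchor_doys: np.ndarray,
    site_id: str,
    season: int,
    span_days: int = 28,
    max_generations: int = 3,
) -> list[FlightPeak]:
    """Predicted flight peaks for one site-season's ordered windows."""
    probs = model.predict_proba(X)
    doys = peaks_from_probabilities(probs, anchor_doys, span_days, max_generations)
    return [FlightPeak(site_id, season, g + 1, d) for g, d in enumerate(doys)]


def _true_peaks_frame(ds: LabeledDataset, groups: set[str]) -> pd.DataFrame:
    labels = ds.group_labels()
    mask = np.isin(labels, list(groups)) & (ds.y > 0.5)
    rows = []
    for site, season in {(s, y) for s, y in zip(ds.site_ids[mask], ds.seasons[mask])}:
        sub = mask & (ds.site_ids == site) & (ds.seasons == season)
        for g, d in enumerate(sorted(ds.anchor_doys[sub].tolist())):
            if g >= 3:
                break
            rows.append((site, int(season), g + 1, int(d)))
    return pd.DataFrame(rows, columns=["site_id", "season", "generation", "doy"])


def peak_f1(
    model: TrainedModel,
    ds: LabeledDataset,
    group_keys: Sequence[tuple[str, int]],
    tolerance_days: int = 3,
    span_days: int = 28,
    probs_override: np.ndarray | None = None,
) -> float:
    """Peak-matching F1 of the model over the given site-season groups.

    Ground truth is the positive labels of ``ds``; predictions come from the
    probability series of each group.  ``probs_override`` substitutes
    precomputed probabilities (used by the permutation-importance ranker).
    """
    labels = ds.group_labels()
    probs = probs_override if probs_override is not None else model.predict_proba(ds.X)
    pred_rows, obs_frames = [], []
    wanted = {f"{s}|{y}" for s, y in group_keys}
    for site, season in group_keys:
        sub = labels == f"{site}|{season}"
        if not sub.any():
            continue
        order = np.argsort(ds.anchor_doys[sub])
        doys = peaks_from_probabilities(probs[sub][order], ds.anchor_doys[sub][order], span_days)
        pred_rows.extend((site, int(season), g + 1, d) for g, d in enumerate(doys))
    predicted = pd.DataFrame(pred_rows, columns=["site_id", "season", "generation", "doy"])
    observed = _true_peaks_frame(ds, wanted)
    if observed.empty:
        raise ValueError("no positive labels in the requested groups (degenerate evaluation set)")
    counts = match_events(observed, predicted, tolerance_days, unmatched="two-sided")
    return compute_metrics(counts, tolerance_days).f1


# --------------------------------------------------------------------------
# random search


@dataclass
class SearchResult:
    best: TrainedModel
    best_trial: int
    trials: pd.DataFrame
    training: TrainingResult | None = field(default=None, repr=False)


def search_and_train(
    ds: LabeledDataset,
    split: DatasetSplit,
    space: SearchSpace = SearchSpace(),
    n_trials: int = 50,
    seed: int = 0,
    tolerance_days: int = 3,
    span_days: int = 28,
    batch_size: int = 256,
    balance: tuple[str, float] = ("oversample", 3.0),
    fixed_config: ModelConfig | None = None,
) -> SearchResult:
    """Random hyperparameter search with early-stopped training per trial.

    The training partition is rebalanced once (method, ratio = ``balance``);
    every trial trains on the same rebalanced matrix, stops early on
    validation day-level loss, and is scored by validation peak-matching F1
    at ``tolerance_days``.  Non-finite losses mark the trial failed and the
    search continues; if every trial fails the search errors out.  With
    ``fixed_config`` the sampler is bypassed (n_trials then applies to
    repeated trainings of that configuration).  Fully reproducible per seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)

    train_mask = split.mask(ds, "train")
    val_mask = split.mask(ds, "validation")
    train = ds.subset(train_mask)
    val = ds.subset(val_mask)
    method, ratio = balance
    train = balance_dataset(train, ratio=ratio, method=method, seed=int(rng.integers(2**31)))

    mean = train.X.mean(axis=0)
    std = train.X.std(axis=0)
    std[std == 0] = 1.0
    Xtr = (train.X - mean) / std
    Xval = (val.X - mean) / std

    rows = []
    best_model: TrainedModel | None = None
    best_f1 = -np.inf
    best_trial = -1
    best_training: TrainingResult | None = None
    for trial in range(n_trials):
        config = fixed_config or space.sample(rng)
        trial_seed = int(rng.integers(2**31))
        net = FeedForwardNet(ds.X.shape[1], list(config.layers), seed=trial_seed)
        model = TrainedModel(config, net, ds.feature_names, mean, std, trial_seed)
        try:
            result = net.fit(
                Xtr,
                train.y,
                Xval,
                val.y,
                learning_rate=config.learning_rate,
                optimizer=config.optimizer,
                max_epochs=space.max_epochs,
                batch_size=batch_size,
                patience=space.patience,
                min_delta=space.min_delta,
                seed=trial_seed,
            )
            f1 = peak_f1(model, ds.subset(val_mask), list(split.validation), tolerance_days, span_days)
            status, val_loss, epochs = "ok", result.best_val_loss, result.epochs_run
        except (FloatingPointError, ValueError) as exc:
            status, val_loss, epochs, f1, result = f"failed: {exc}", np.nan, 0, np.nan, None
        rows.append((trial, config.describe(), status, epochs, val_loss, f1))
        if status == "ok" and f1 > best_f1:
            best_f1, best_model, best_trial, best_training = f1, model, trial, result

    trials = pd.DataFrame(
        rows, columns=["trial", "config", "status", "epochs", "val_loss", "val_peak_f1"]
    )
    if best_model is None:
        raise RuntimeError("all search trials failed")
    return SearchResult(best_model, best_trial, trials, best_training)


# --------------------------------------------------------------------------
# permutation importance


_LAG_RE = re.compile(r"^(?P<base>.+)_d(?P<lag>\d+)$")


def feature_groups(names: Sequence[str]) -> dict[str, list[int]]:
    """Column indices grouped by base variable (the 14 lags of one variable
    form one unit; statics are their own group)."""
    groups: dict[str, list[int]] = {}
    for i, name in enumerate(names):
        m = _LAG_RE.match(name)
        groups.setdefault(m.group("base") if m else name, []).append(i)
    return groups


def rank_relevance(
    model: TrainedModel,
    ds_val: LabeledDataset,
    group_keys: Sequence[tuple[str, int]],
    seed: int = 0,
    k: int = 10,
    tolerance_days: int = 3,
    span_days: int = 28,
) -> pd.DataFrame:
    """Permutation importance of each feature group on validation data.

    Importance = mean drop in validation peak-matching F1 over ``k``
    joint row-shuffles of the group's columns.  Descending order;
    deterministic under seed.  A constant feature scores ~0.
    """
    rng = np.random.default_rng(seed)
    baseline = peak_f1(model, ds_val, group_keys, tolerance_days, span_days)
    rows = []
    for base, cols in feature_groups(ds_val.feature_names).items():
        drops = []
        for _ in range(k):
            perm = rng.permutation(len(ds_val))
            X = ds_val.X.copy()
            X[:, cols] = X[perm][:, cols]
            probs = model.predict_proba(X)
            shuffled = peak_f1(
                model, ds_val, group_keys, tolerance_days, span_days, probs_override=probs
            )
            drops.append(baseline - shuffled)
        rows.append((base, float(np.mean(drops))))
    out = pd.DataFrame(rows, columns=["feature_group", "importance"])
    return out.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
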