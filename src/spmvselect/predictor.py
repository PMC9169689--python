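"""Learned per-format performance predictor and selector.

A fully-connected feedforward network maps the seven matrix features
(standardized with training-set mean and std) through ReLU hidden layers
to three linear outputs: the predicted SpMV throughput in GFLOPs for the
CSR, ELLPACK-R and dense layouts.  The selector reads out the argmax.
Framing the problem as regression rather than 3-way classification keeps
the targets on a physically meaningful scale and lets one trained model
answer "how much faster" as well as "which".

Training minimizes mean squared error with Adam (scikit-learn's
``MLPRegressor`` does the fitting); prediction runs an explicit numpy
forward pass over the extracted weights, so trained models serialize to a
single JSON document and reload to bit-identical predictions.

Model selection follows the benchmark protocol of the surrounding
tooling: selection accuracy (fraction of records whose argmax matches the
measured best format) under repeated 5-fold cross-validation, a seeded
random search over depth/width/learning-rate for hyperparameters, and a
learning curve over training-set fractions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import RepeatedKFold
from sklearn.neural_network import MLPRegressor

from .benchmark import FORMAT_PRIORITY, Dataset, best_format_of
from .features import FeatureVector

__all__ = [
    "PredictorModel",
    "SearchSpace",
    "train",
    "predict",
    "select_format",
    "cross_validate",
    "CVResult",
    "hyperparameter_search",
    "SearchResult",
    "learning_curve",
    "save_model",
    "load_model",
]

N_FEATURES = 7


@dataclass
class PredictorModel:
    """Normalization statistics plus the trained network weights."""

    feature_mean: np.ndarray  # (7,)
    feature_std: np.ndarray   # (7,)
    hidden_layer_sizes: Tuple[int, ...]
    coefs: List[np.ndarray]       # per layer, (fan_in, fan_out)
    intercepts: List[np.ndarray]  # per layer, (fan_out,)
    output_formats: Tuple[str, ...] = FORMAT_PRIORITY
    log_targets: bool = False
    training_meta: dict = field(default_factory=dict)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Batch forward pass on raw (unnormalized) feature rows."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
        h = (X - self.feature_mean) / self.feature_std
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)  # ReLU hidden layers
        out = h @ self.coefs[-1] + self.intercepts[-1]  # linear output
        if self.log_targets:
            out = np.expm1(out)
        return out


@dataclass(frozen=True)
class SearchSpace:
    """Bounds of the hyperparameter search."""

    depth_range: Tuple[int, int] = (2, 5)
    width_range: Tuple[int, int] = (64, 256)
    learning_rate_range: Tuple[float, float] = (1e-7, 1e-2)
    n_trials: int = 150

    def __post_init__(self) -> None:
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] < 1:
            raise ValueError("invalid depth range")
        if self.width_range[0] > self.width_range[1] or self.width_range[0] < 1:
            raise ValueError("invalid width range")
        lo, hi = self.learning_rate_range
        if not 0 < lo <= hi:
            raise ValueError("invalid learning-rate range")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def _validate_training_data(X: np.ndarray, Y: np.ndarray) -> None:
    if X.shape[0] < 2:
        raise ValueError("training requires at least 2 records")
    if not np.isfinite(X).all() or not np.isfinite(Y).all():
        raise ValueError("non-finite feature or target values")


def train(
    dataset: Dataset,
    architecture: Sequence[int] = (128, 128, 128),
    learning_rate: float = 3e-3,
    epochs: int = 300,
    seed: int = 0,
    batch_size: int = 32,
    early_stopping: bool = False,
    log_targets: bool = False,
) -> PredictorModel:
    """Fit the per-format throughput regressor on a labelled dataset.

    Normalization statistics are estimated from the given records only, so
    calling this inside a CV loop on the training fold cannot leak test
    rows.  Deterministic for a fixed ``(dataset, hyperparameters, seed)``.
    """
    X = dataset.feature_matrix()
    Y = dataset.target_matrix()
    _validate_training_data(X, Y)
    if log_targets:
        Y = np.log1p(Y)

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0.0] = 1.0  # constant features pass through unscaled
    Xn = (X - mean) / std

    net = MLPRegressor(
        hidden_layer_sizes=tuple(int(w) for w in architecture),
        activation="relu",
        solver="adam",
        alpha=0.0,
        batch_size=min(batch_size, X.shape[0]),
        learning_rate_init=learning_rate,
        max_iter=epochs,
        shuffle=True,
        random_state=seed,
        tol=0.0,                      # run the full epoch budget
        n_iter_no_change=max(epochs, 10),
        early_stopping=early_stopping,
        validation_fraction=0.1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(Xn, Y)

    return PredictorModel(
        feature_mean=mean,
        feature_std=std,
        hidden_layer_sizes=tuple(int(w) for w in architecture),
        coefs=[np.array(W) for W in net.coefs_],
        intercepts=[np.array(b) for b in net.intercepts_],
        log_targets=log_targets,
        training_meta={
            "learning_rate": learning_rate,
            "epochs": epochs,
            "seed": seed,
            "batch_size": batch_size,
            "early_stopping": early_stopping,
            "n_train": int(X.shape[0]),
            "loss_curve": [float(v) for v in net.loss_curve_],
            "final_loss": float(net.loss_),
        },
    )


def predict(model: PredictorModel, f: FeatureVector) -> Dict[str, float]:
    """Predicted throughput (GFLOPs) per format for one feature vector."""
    out = model.forward(f.as_array()[None, :])[0]
    return dict(zip(model.output_formats, (float(v) for v in out)))


def select_format(model: PredictorModel, f: FeatureVector) -> str:
    """Format with the highest predicted throughput (ties: csr > ellpack_r > dense)."""
    return best_format_of(predict(model, f))


def _selection_accuracy(model: PredictorModel, dataset: Dataset,
                        idx: np.ndarray) -> float:
    X = dataset.feature_matrix()[idx]
    out = model.forward(X)
    labels = dataset.labels()[idx]
    hits = 0
    for row, label in zip(out, labels):
        chosen = best_format_of(dict(zip(model.output_formats, row)))
        hits += chosen == label
    return hits / len(idx)


@dataclass(frozen=True)
class CVResult:
    mean: float
    std: float
    per_fold: Tuple[float, ...]
    folds: int
    repeats: int


def cross_validate(
    dataset: Dataset,
    architecture: Sequence[int] = (128, 128, 128),
    learning_rate: float = 3e-3,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    epochs: int = 300,
    log_targets: bool = False,
) -> CVResult:
    """Repeated k-fold selection accuracy of the learned selector.

    Each repetition partitions the records into ``folds`` non-overlapping
    folds; each fold in turn is held out, a model is trained on the rest
    (normalization included — no leakage), and accuracy is the fraction of
    held-out records whose predicted-best format equals the measured best.
    """
    n = len(dataset)
    if n < folds:
        raise ValueError(f"dataset of {n} records cannot be split into {folds} folds")
    ss = np.random.SeedSequence(seed)
    split_seed, train_seed0 = (int(s.generate_state(1)[0] % (2**31))
                               for s in ss.spawn(2))
    splitter = RepeatedKFold(n_splits=folds, n_repeats=repeats,
                             random_state=split_seed)
    accs: List[float] = []
    for k, (tr, te) in enumerate(splitter.split(np.arange(n))):
        sub = Dataset(records=[dataset.records[i] for i in tr],
                      provenance=dataset.provenance)
        model = train(sub, architecture=architecture,
                      learning_rate=learning_rate, epochs=epochs,
                      seed=train_seed0 + k, log_targets=log_targets)
        accs.append(_selection_accuracy(model, dataset, te))
    return CVResult(
        mean=float(np.mean(accs)), std=float(np.std(accs)),
        per_fold=tuple(accs), folds=folds, repeats=repeats,
    )


@dataclass(frozen=True)
class SearchResult:
    architecture: Tuple[int, ...]
    learning_rate: float
    accuracy: float
    trials: Tuple[dict, ...]


def hyperparameter_search(
    dataset: Dataset,
    space: SearchSpace = SearchSpace(),
    seed: int = 0,
    folds: int = 5,
    epochs: int = 300,
) -> SearchResult:
    """Seeded random search over depth, per-layer width and learning rate.

    The objective is mean single-repeat k-fold CV selection accuracy; the
    fold assignment is fixed across trials so objective values are
    comparable.  Per-layer widths are sampled independently (architectures
    need not be rectangular); the learning rate is log-uniform.
    """
    rng = np.random.default_rng(seed)
    trials: List[dict] = []
    best: Optional[dict] = None
    for t in range(space.n_trials):
        depth = int(rng.integers(space.depth_range[0], space.depth_range[1] + 1))
        widths = tuple(int(w) for w in rng.integers(
            space.width_range[0], space.width_range[1] + 1, size=depth))
        lo, hi = space.learning_rate_range
        lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        result = cross_validate(
            dataset, architecture=widths, learning_rate=lr,
            folds=folds, repeats=1, seed=seed, epochs=epochs,
        )
        record = {
            "trial": t, "architecture": widths, "learning_rate": lr,
            "accuracy": result.mean,
        }
        trials.append(record)
        if best is None or record["accuracy"] > best["accuracy"]:
            best = record
    return SearchResult(
        architecture=best["architecture"],
        learning_rate=best["learning_rate"],
        accuracy=best["accuracy"],
        trials=tuple(trials),
    )


def learning_curve(
    dataset: Dataset,
    fractions: Sequence[float],
    architecture: Sequence[int] = (128, 128, 128),
    learning_rate: float = 3e-3,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    epochs: int = 300,
) -> List[dict]:
    """Repeated-CV selection accuracy as a function of dataset fraction.

    Fraction 1.0 uses the full dataset and reproduces
    :func:`cross_validate` with the same parameters and seed exactly.
    """
    rows: List[dict] = []
    n = len(dataset)
    rng = np.random.default_rng(seed)
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        size = int(round(frac * n))
        if size < folds:
            raise ValueError(
                f"fraction {frac} yields {size} records, fewer than {folds} folds")
        if size == n:
            sub = dataset
        else:
            idx = np.sort(rng.choice(n, size=size, replace=False))
            sub = Dataset(records=[dataset.records[i] for i in idx],
                          provenance=dataset.provenance)
        res = cross_validate(sub, architecture=architecture,
                             learning_rate=learning_rate, folds=folds,
                             repeats=repeats, seed=seed, epochs=epochs)
        rows.append({"fraction": frac, "n": size,
                     "accuracy_mean": res.mean, "accuracy_std": res.std})
    return rows


# ---------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------

def save_model(model: PredictorModel, path: Union[str, Path]) -> None:
    """Write the model (normalization, architecture, weights, meta) as JSON."""
    doc = {
        "feature_mean": model.feature_mean.tolist(),
        "feature_std": model.feature_std.tolist(),
        "hidden_layer_sizes": list(model.hidden_layer_sizes),
        "coefs": [W.tolist() for W in model.coefs],
        "intercepts": [b.tolist() for b in model.intercepts],
        "output_formats": list(model.output_formats),
        "log_targets": model.log_targets,
        "training_meta": model.training_meta,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: Union[str, Path]) -> PredictorModel:
    doc = json.loads(Path(path).read_text())
    return PredictorModel(
        feature_mean=np.array(doc["feature_mean"]),
        feature_std=np.array(doc["feature_std"]),
        hidden_layer_sizes=tuple(doc["hidden_layer_sizes"]),
        coefs=[np.array(W) for W in doc["coefs"]],
        intercepts=[np.array(b) for b in doc["intercepts"]],
        output_formats=tuple(doc["output_formats"]),
        log_targets=bool(doc["log_targets"]),
        training_meta=doc["training_meta"],
    )
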