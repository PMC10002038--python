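"""Per-class occurrence-probability surfaces from driver layers.

A single-hidden-layer neural network (logistic hidden units, one output
per land-cover class) is fitted to a uniform random sample of cells and
then evaluated over the whole grid, producing one probability surface per
class.  The surfaces are renormalized per cell so the class probabilities
sum to exactly 1 everywhere — the invariant every later allocation step
relies on.

Defaults follow common practice for this model family: 12 hidden neurons
and a 2% uniform sampling rate, both exposed in :class:`ANNConfig`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPClassifier

from greenscape.grid import DriverStack, LandCoverGrid, require_aligned

__all__ = [
    "ANNConfig",
    "SuitabilityCube",
    "TrainingSample",
    "sample_training",
    "train_suitability_model",
    "predict_suitability",
    "suitability_rmse",
]

_EPS = 1e-9


@dataclass
class ANNConfig:
    """Network and sampling settings.

    hidden_units : neurons in the single hidden layer.
    sampling_rate : fraction of valid cells drawn (without replacement)
        as training samples.
    max_epochs / learning_rate : stochastic-gradient training budget.
    """

    hidden_units: int = 12
    sampling_rate: float = 0.02
    max_epochs: int = 200
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not 0.0 < self.sampling_rate <= 1.0:
            raise ValueError("sampling_rate must lie in (0, 1]")


@dataclass
class TrainingSample:
    """Sampled (driver vector, class index) pairs plus full-grid priors."""

    X: np.ndarray  # (n_samples, n_drivers)
    y: np.ndarray  # (n_samples,) scheme indices
    priors: np.ndarray  # (n_classes,) class frequencies over all valid cells
    n_classes: int


@dataclass
class SuitabilityCube:
    """Per-cell, per-class occurrence probabilities on the valid cells.

    ``prob`` has shape (n_valid, n_classes) in scheme order; every row sums
    to 1 within 1e-6.  ``valid`` maps rows back onto the grid.
    """

    prob: np.ndarray
    valid: np.ndarray  # boolean grid mask, True where prob rows apply

    def __post_init__(self) -> None:
        sums = self.prob.sum(axis=1)
        if len(sums) and np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("per-cell probabilities must sum to 1")

    def as_grid(self) -> np.ndarray:
        """(rows, cols, k) dense view with NaN outside the valid mask."""
        k = self.prob.shape[1]
        out = np.full(self.valid.shape + (k,), np.nan)
        out[self.valid] = self.prob
        return out


def sample_training(
    grid: LandCoverGrid, drivers: DriverStack, cfg: ANNConfig
) -> TrainingSample:
    """Uniform random sample of valid cells, without replacement.

    Returns driver vectors paired with scheme class indices, plus the
    class frequencies over all valid cells (used as the fallback prior for
    classes the sample happens to miss).
    """
    if not drivers.normalized:
        raise ValueError("drivers must be normalized before sampling")
    require_aligned(grid.shape, drivers.shape)
    idx = grid.class_indices()
    valid = idx >= 0
    n_valid = int(valid.sum())
    n_sample = math.ceil(cfg.sampling_rate * n_valid)
    if n_sample > n_valid:
        raise ValueError("sample larger than the number of valid cells")
    rng = np.random.default_rng(cfg.seed)
    flat_valid = np.flatnonzero(valid.ravel())
    chosen = rng.choice(flat_valid, size=n_sample, replace=False)
    chosen.sort()
    X = drivers.as_matrix()[chosen]
    y = idx.ravel()[chosen]
    k = grid.scheme.n_classes
    priors = np.bincount(idx[valid], minlength=k) / n_valid
    return TrainingSample(X=X, y=y, priors=priors, n_classes=k)


@dataclass
class SuitabilityModel:
    """Fitted network plus bookkeeping for classes absent from training."""

    mlp: MLPClassifier
    classes_seen: np.ndarray  # scheme indices present in training
    priors: np.ndarray
    n_classes: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) probabilities in scheme order, rows summing to 1.

        Classes never seen in training receive their full-grid prior
        frequency; the row is then renormalized.
        """
        raw = self.mlp.predict_proba(X)
        out = np.zeros((X.shape[0], self.n_classes))
        out[:, self.classes_seen] = raw
        missing = np.setdiff1d(np.arange(self.n_classes), self.classes_seen)
        if len(missing):
            out[:, missing] = self.priors[missing]
        out = np.clip(out, _EPS, None)
        out /= out.sum(axis=1, keepdims=True)
        return out


def train_suitability_model(
    samples: TrainingSample, cfg: ANNConfig
) -> SuitabilityModel:
    """Fit the single-hidden-layer network to the sampled cells.

    Training is deterministic given ``cfg.seed``.  A class absent from the
    sample triggers a warning; its surface falls back to the full-grid
    prior frequency.
    """
    seen, counts = np.unique(samples.y, return_counts=True)
    if (counts < 10).any():
        thin = seen[counts < 10]
        warnings.warn(
            f"classes {thin.tolist()} have fewer than 10 training samples",
            stacklevel=2,
        )
    missing = np.setdiff1d(
        np.flatnonzero(samples.priors > 0), seen
    )
    if len(missing):
        warnings.warn(
            f"classes {missing.tolist()} absent from training sample; "
            "falling back to prior-only probabilities",
            stacklevel=2,
        )
    mlp = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        activation="logistic",
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        max_iter=cfg.max_epochs,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        # the epoch budget is a config choice, not a convergence failure
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        mlp.fit(samples.X, samples.y)
    return SuitabilityModel(
        mlp=mlp,
        classes_seen=np.asarray(mlp.classes_, dtype=np.int64),
        priors=samples.priors,
        n_classes=samples.n_classes,
    )


def predict_suitability(
    model: SuitabilityModel, drivers: DriverStack, grid: LandCoverGrid
) -> SuitabilityCube:
    """Evaluate the model over every valid cell of the grid."""
    if not drivers.normalized:
        raise ValueError("drivers must be normalized before prediction")
    require_aligned(grid.shape, drivers.shape)
    valid = grid.valid_mask
    X = drivers.as_matrix(valid)
    prob = model.predict_proba(X)
    return SuitabilityCube(prob=prob, valid=valid)


def suitability_rmse(cube: SuitabilityCube, grid: LandCoverGrid) -> float:
    """Pooled RMSE between predicted probabilities and the one-hot truth.

    The mean square is taken over all (valid cell, class) pairs; a cube
    that reproduces the map exactly scores 0, and the uniform cube over k
    classes scores sqrt((k-1)/k) / sqrt(k).
    """
    require_aligned(cube.valid.shape, grid.shape)
    idx = grid.class_indices()[cube.valid]
    k = cube.prob.shape[1]
    onehot = np.zeros_like(cube.prob)
    onehot[np.arange(len(idx)), idx] = 1.0
    return float(np.sqrt(np.mean((cube.prob - onehot) ** 2)))
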