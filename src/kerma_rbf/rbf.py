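"""Radial basis function network with K-means center placement.

Three layers: a linear input layer (here: min-max normalization of the
four features r, theta, phi, kVp), a hidden layer of Gaussian units
phi_j(x) = exp(-||x - c_j||^2 / 2 sigma^2) whose centers c_j come from
K-means on the training inputs, and a linear output layer solved in
closed form by rank-tolerant least squares.  Kerma targets are fitted on
a log scale so the approximation error is multiplicative, matching the
relative-error criterion the surrogate is judged by.

K-means and the network itself are implemented here from scratch; they
are the method, not plumbing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .grid import FEATURE_COLUMNS, KermaDataset


# ---------------------------------------------------------------------------
# Input normalization
# ---------------------------------------------------------------------------

def normalize_inputs(X: np.ndarray):
    """Min-max map of each feature to [0, 1] over the given samples.

    Returns the normalized matrix and ``(shift, scale)`` for reuse at
    prediction time.  A constant feature gets scale 1 (maps to all zeros).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    shift = X.min(axis=0)
    scale = X.max(axis=0) - shift
    scale = np.where(scale == 0, 1.0, scale)
    return (X - shift) / scale, (shift, scale)


def apply_normalization(X: np.ndarray, params) -> np.ndarray:
    shift, scale = params
    return (np.atleast_2d(np.asarray(X, dtype=float)) - shift) / scale


# ---------------------------------------------------------------------------
# K-means (Lloyd's algorithm, k-means++ seeding, restarts)
# ---------------------------------------------------------------------------

def _kmeanspp_seed(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[j] = X[rng.integers(n)]
            continue
        centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, iters: int) -> tuple[np.ndarray, float]:
    for _ in range(iters):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        new = centers.copy()
        for j in range(len(centers)):
            members = labels == j
            if members.any():
                new[j] = X[members].mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its center
                new[j] = X[d2.min(axis=1).argmax()]
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return centers, float(d2.min(axis=1).sum())


def kmeans_centers(
    X: np.ndarray,
    k: int,
    iters: int = 100,
    seed: int = 0,
    restarts: int = 5,
) -> np.ndarray:
    """Cluster centers by Lloyd's algorithm with k-means++ seeding.

    Runs ``restarts`` independent seedings and keeps the lowest
    within-cluster sum of squares; deterministic under ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} available samples")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    best, best_wcss = None, np.inf
    for _ in range(max(restarts, 1)):
        centers, wcss = _lloyd(X, _kmeanspp_seed(X, k, rng), iters)
        if wcss < best_wcss:
            best, best_wcss = centers, wcss
    return best


# ---------------------------------------------------------------------------
# RBF layers
# ---------------------------------------------------------------------------

def euclidean_distance(x: np.ndarray, c: np.ndarray) -> float:
    """r = sqrt(sum_i (x_i - c_i)^2)."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    if x.shape != c.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {c.shape}")
    return float(np.sqrt(((x - c) ** 2).sum()))


def gaussian_basis(r, sigma: float):
    """Gaussian activation exp(-r^2 / 2 sigma^2); in (0, 1], decreasing in r."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return np.exp(-np.square(r) / (2.0 * sigma**2))


def hidden_activations(x: np.ndarray, centers: np.ndarray, sigma) -> np.ndarray:
    """Hidden-layer outputs phi_j = exp(-||x - c_j||^2 / 2 sigma_j^2).

    ``x`` may be one normalized input (returns a length-k vector) or an
    n x d batch (returns n x k).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != centers.shape[1]:
        raise ValueError("input/center dimension mismatch")
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    act = np.exp(-d2 / (2.0 * np.square(sigma)))
    return act[0] if single else act


def fit_output_weights(activations: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares output layer on [Phi | 1] (last weight is the bias)."""
    Phi = np.atleast_2d(np.asarray(activations, dtype=float))
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(Phi)):
        raise ValueError("non-finite activations")
    A = np.hstack([Phi, np.ones((len(Phi), 1))])
    w, *_ = np.linalg.lstsq(A, y, rcond=None)
    return w


def mean_nn_distance(centers: np.ndarray) -> float:
    """Mean distance from each center to its nearest other center."""
    if len(centers) < 2:
        return 1.0
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    return float(np.sqrt(d2.min(axis=1)).mean())


# ---------------------------------------------------------------------------
# Model container, training, prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Hyperparameters of the surrogate fit.

    ``k`` is the hidden-layer size (50 in the reference protocol).  The
    shared width is sigma_factor times the mean nearest-neighbor distance
    among the centers.  ``log_targets`` fits log(kerma) so that residuals
    are relative errors; kerma spans orders of magnitude across the grid.
    """

    k: int = 50
    kmeans_iters: int = 100
    kmeans_restarts: int = 5
    sigma_rule: str = "mean_nn"
    sigma_factor: float = 2.0
    log_targets: bool = True
    seed: int = 0


@dataclass
class RBFModel:
    """A fitted network: centers, width(s), output weights, normalization."""

    centers: np.ndarray          # k x d, in normalized input space
    sigma: float | np.ndarray    # shared scalar (or per-center vector)
    weights: np.ndarray          # length k + 1, last entry the bias
    shift: np.ndarray            # per-feature min of the training inputs
    scale: np.ndarray            # per-feature range of the training inputs
    log_targets: bool = True
    config: TrainingConfig | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("sigma must be positive")
        if len(self.weights) != len(self.centers) + 1:
            raise ValueError("need one output weight per center plus a bias")

    @property
    def k(self) -> int:
        return len(self.centers)

    def to_json(self, path) -> None:
        payload = {
            "centers": self.centers.tolist(),
            "sigma": np.asarray(self.sigma).tolist(),
            "weights": self.weights.tolist(),
            "shift": np.asarray(self.shift).tolist(),
            "scale": np.asarray(self.scale).tolist(),
            "log_targets": self.log_targets,
            "config": vars(self.config) if self.config else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RBFModel":
        with open(path) as fh:
            payload = json.load(fh)
        sigma = payload["sigma"]
        sigma = float(sigma) if np.isscalar(sigma) else np.asarray(sigma)
        cfg = TrainingConfig(**payload["config"]) if payload["config"] else None
        return cls(
            centers=np.asarray(payload["centers"]),
            sigma=sigma,
            weights=np.asarray(payload["weights"]),
            shift=np.asarray(payload["shift"]),
            scale=np.asarray(payload["scale"]),
            log_targets=payload["log_targets"],
            config=cfg,
        )


def train(dataset: KermaDataset, cfg: TrainingConfig | None = None) -> RBFModel:
    """Fit the surrogate: normalize -> (log targets) -> K-means -> width
    rule -> least-squares output layer.  Deterministic under cfg.seed."""
    cfg = cfg or TrainingConfig()
    X, y = dataset.X, dataset.y
    if cfg.k > len(X):
        raise ValueError(f"k={cfg.k} exceeds n_train={len(X)}")
    if cfg.log_targets and np.any(y <= 0):
        raise ValueError("log-target fit requires strictly positive kerma")
    Xn, (shift, scale) = normalize_inputs(X)
    t = np.log(y) if cfg.log_targets else y
    centers = kmeans_centers(
        Xn, cfg.k, iters=cfg.kmeans_iters, seed=cfg.seed,
        restarts=cfg.kmeans_restarts,
    )
    if cfg.sigma_rule != "mean_nn":
        raise ValueError(f"unknown sigma rule {cfg.sigma_rule!r}")
    sigma = cfg.sigma_factor * mean_nn_distance(centers)
    Phi = hidden_activations(Xn, centers, sigma)
    weights = fit_output_weights(Phi, t)
    return RBFModel(
        centers=centers, sigma=sigma, weights=weights,
        shift=shift, scale=scale, log_targets=cfg.log_targets, config=cfg,
    )


def predict(model: RBFModel, X: np.ndarray) -> np.ndarray | float:
    """Kerma prediction for raw feature vectors (r_mm, theta_deg, phi_deg, kVp)."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    single = X.ndim == 1
    Xn = apply_normalization(X, (model.shift, model.scale))
    act = hidden_activations(Xn, model.centers, model.sigma)
    out = act @ model.weights[:-1] + model.weights[-1]
    if model.log_targets:
        out = np.exp(out)
    return float(out[0]) if single else out


__all__ = [
    "RBFModel",
    "TrainingConfig",
    "apply_normalization",
    "euclidean_distance",
    "fit_output_weights",
    "gaussian_basis",
    "hidden_activations",
    "kmeans_centers",
    "mean_nn_distance",
    "normalize_inputs",
    "predict",
    "train",
]
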