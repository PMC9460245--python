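"""Feature ranking and selection via minibatch stochastic gradient descent.

A multinomial logistic (softmax) classifier with an L2 penalty is trained by
shuffled minibatch SGD, theta <- theta - eta * grad J(theta; batch), with
validation-loss early stopping.  Features are then scored by the Euclidean
norm of their weight row across classes: on min-max normalized inputs a
feature the linear model does not use gets a near-zero row, so weight
magnitude is a direct relevance ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["SGDModel", "sgd_fit", "rank_features", "select_top_k"]


@dataclass
class SGDModel:
    """A softmax classifier fitted by minibatch SGD.

    theta : ndarray (features x classes)
        Weight matrix; ``bias`` holds the per-class intercepts.
    loss_trace : list of (train_objective, validation_loss)
        Per-epoch penalized training objective and validation cross-entropy.
    """

    theta: np.ndarray | None = None
    bias: np.ndarray | None = None
    classes: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    learning_rate: float = 0.01
    batch_size: int = 1000
    l2: float = 1e-4
    seed: int = 0
    loss_trace: list[tuple[float, float]] = field(default_factory=list)

    @property
    def fitted(self) -> bool:
        return self.theta is not None and len(self.loss_trace) > 0


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def _nll(x: np.ndarray, y_onehot: np.ndarray, theta: np.ndarray, bias: np.ndarray) -> float:
    logp = _log_softmax(x @ theta + bias)
    return float(-(y_onehot * logp).sum() / x.shape[0])


def sgd_fit(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    learning_rate: float = 0.01,
    batch_size: int = 1000,
    max_epochs: int = 2000,
    l2: float = 1e-4,
    validation_fraction: float = 0.1,
    patience: int = 10,
    seed: int = 0,
) -> SGDModel:
    """Fit the softmax model by shuffled minibatch gradient descent.

    Expects min-max normalized features (values materially outside [0, 1]
    trigger a logged warning, not an error).  A stratified fraction of rows
    is held out; training stops after ``patience`` consecutive epochs without
    a validation-loss improvement, or at ``max_epochs``, and the parameters
    from the best-validation epoch are kept.  All randomness (validation
    split, epoch shuffles) is driven by ``seed``.
    """
    x = features.values
    y = np.asarray(labels if labels is not None else features.labels).astype(str)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    thin = [c for c, k in counts.items() if k < 2]
    if thin:
        raise ValueError(f"need >= 2 rows per class; too few for {thin}")
    if x.min() < -0.01 or x.max() > 1.01:
        logger.warning(
            "features outside [0, 1] (range %.3g..%.3g); expected min-max normalized input",
            x.min(), x.max(),
        )

    rng = np.random.default_rng(seed)
    n, p = x.shape
    k = len(classes)
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[c] for c in y])
    onehot = np.eye(k)[y_idx]

    # stratified validation split so every class stays present in training
    val_idx: list[int] = []
    for c in classes:
        rows = np.flatnonzero(y == c)
        rows = rng.permutation(rows)
        n_val = int(math.floor(validation_fraction * rows.size))
        n_val = min(n_val, rows.size - 2)  # keep >= 2 training rows per class
        val_idx.extend(rows[:max(0, n_val)].tolist())
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    train_rows = np.flatnonzero(~val_mask)
    val_rows = np.flatnonzero(val_mask)

    bs = min(batch_size, train_rows.size)
    theta = np.zeros((p, k))
    bias = np.zeros(k)
    best = (np.inf, theta.copy(), bias.copy())
    stale = 0
    trace: list[tuple[float, float]] = []
    for _ in range(max_epochs):
        order = rng.permutation(train_rows)
        for start in range(0, order.size, bs):
            batch = order[start : start + bs]
            xb, yb = x[batch], onehot[batch]
            prob = np.exp(_log_softmax(xb @ theta + bias))
            grad_theta = xb.T @ (prob - yb) / batch.size + l2 * theta
            grad_bias = (prob - yb).mean(axis=0)
            theta -= learning_rate * grad_theta
            bias -= learning_rate * grad_bias
        train_obj = _nll(x[train_rows], onehot[train_rows], theta, bias) + 0.5 * l2 * float(
            np.sum(theta * theta)
        )
        if val_rows.size:
            val_loss = _nll(x[val_rows], onehot[val_rows], theta, bias)
        else:
            val_loss = train_obj
        trace.append((train_obj, val_loss))
        if val_loss < best[0] - 1e-12:
            best = (val_loss, theta.copy(), bias.copy())
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    _, theta, bias = best
    return SGDModel(
        theta=theta,
        bias=bias,
        classes=classes,
        feature_names=list(features.feature_names),
        learning_rate=learning_rate,
        batch_size=bs,
        l2=l2,
        seed=seed,
        loss_trace=trace,
    )


def rank_features(model: SGDModel) -> list[tuple[str, float]]:
    """Features in descending order of weight-row Euclidean norm.

    The per-class bias is excluded; ties are broken by feature name so the
    ordering is fully deterministic.
    """
    if not model.fitted:
        raise ValueError("model has not been fitted")
    scores = np.linalg.norm(model.theta, axis=1)
    pairs = list(zip(model.feature_names, scores.tolist()))
    return sorted(pairs, key=lambda t: (-t[1], t[0]))


def select_top_k(
    matrix: FeatureMatrix, ranking: list[tuple[str, float]], k: int | float
) -> FeatureMatrix:
    """Keep the top-k ranked columns of a feature matrix.

    ``k`` may be an integer count or a float fraction in (0, 1]; fractions
    map to ``ceil(k * n_features)``.  Row order, values and metadata are
    untouched; columns keep the matrix's original order.
    """
    p = matrix.n_features
    if isinstance(k, float) and not k.is_integer():
        if not 0.0 < k < 1.0:
            raise ValueError("fractional k must lie in (0, 1)")
        count = math.ceil(k * p)
    else:
        count = int(k)
    if not 1 <= count <= p:
        raise ValueError(f"k={k} resolves to {count}, outside [1, {p}]")
    chosen = [name for name, _ in ranking[:count]]
    return matrix.select_columns(chosen)
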