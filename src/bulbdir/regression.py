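"""Circular-target regressors for the per-view 2D growth angle.

The 2D growth angle is periodic, so every regressor predicts the pair
(cos theta, sin theta) and the angle is recovered with a quadrant-aware
arctangent after projecting the prediction to the unit circle. Three
interchangeable regressors are provided:

* ``svr`` — two independent epsilon-SVRs with a Gaussian kernel
  (one per target component), kernel width 500;
* ``elm`` — a kernel extreme learning machine, i.e. the closed-form
  kernel ridge solution (K + I/C)^-1 Y with the same Gaussian kernel,
  optionally on a seeded random subset of anchor points;
* ``ann`` — a fully connected 105-60-30-15-2 network with tanh hidden
  activations, trained full-batch to minimize the mean-squared error of
  the unit-circle-projected output, stopping at a gradient tolerance of
  1e-6 or 1000 iterations.

The Gaussian kernel is parameterized exp(-||x-x'||^2 / (2 w^2)) by
default; ``width_param="plain"`` switches to exp(-||x-x'||^2 / w).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.svm import SVR

from .geometry import wrap_angle

__all__ = [
    "RegressionError",
    "UndecodableAngleError",
    "TrainingDivergenceError",
    "encode_angle",
    "decode_angle",
    "TrainingSet",
    "AngleRegressor",
    "SVRAngleRegressor",
    "KernelELMRegressor",
    "MLPAngleRegressor",
    "train_regressor",
]

KERNEL_WIDTH_DEFAULT = 500.0


class RegressionError(ValueError):
    """Base class for regression failures."""


class UndecodableAngleError(RegressionError):
    """The predicted (cos, sin) vector is too close to zero to decode."""


class TrainingDivergenceError(RegressionError):
    """Training produced a non-finite loss."""


def encode_angle(theta: float) -> np.ndarray:
    """Encode an angle as its (cos, sin) pair."""
    return np.array([math.cos(theta), math.sin(theta)])


def decode_angle(v: np.ndarray) -> float:
    """Recover an angle in (-pi, pi] from a (cos, sin)-like 2-vector.

    The vector is projected to the unit circle; the angle is
    atan2(sin-component, cos-component). Raises
    :class:`UndecodableAngleError` for near-zero vectors.
    """
    v = np.asarray(v, dtype=float)
    if np.linalg.norm(v) <= 1e-9:
        raise UndecodableAngleError("cannot decode an angle from a near-zero vector")
    return wrap_angle(math.atan2(v[1], v[0]))


@dataclass(frozen=True)
class TrainingSet:
    """Feature matrix with (cos, sin) targets and per-bulb group labels."""

    features: np.ndarray
    targets: np.ndarray
    bulb_ids: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        Y = np.asarray(self.targets, dtype=float)
        ids = np.asarray(self.bulb_ids)
        if X.ndim != 2 or Y.shape != (X.shape[0], 2) or ids.shape != (X.shape[0],):
            raise RegressionError("inconsistent training-set shapes")
        if not np.allclose(np.linalg.norm(Y, axis=1), 1.0, atol=1e-12):
            raise RegressionError("target rows must be unit (cos, sin) pairs")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "targets", Y)
        object.__setattr__(self, "bulb_ids", ids)

    @classmethod
    def from_angles(
        cls, features: np.ndarray, thetas: np.ndarray, bulb_ids: np.ndarray
    ) -> "TrainingSet":
        thetas = np.asarray(thetas, dtype=float)
        Y = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
        return cls(features=features, targets=Y, bulb_ids=bulb_ids)


def _gaussian_kernel(
    A: np.ndarray, B: np.ndarray, width: float, width_param: str = "half_sq"
) -> np.ndarray:
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    d2 = np.maximum(d2, 0.0)
    if width_param == "half_sq":
        return np.exp(-d2 / (2.0 * width**2))
    if width_param == "plain":
        return np.exp(-d2 / width)
    raise RegressionError(f"unknown kernel width parameterization {width_param!r}")


class AngleRegressor:
    """Common surface: a fitted model mapping a 105-vector to an angle."""

    kind: str = "base"

    def predict_encoded(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_angles(self, X: np.ndarray) -> np.ndarray:
        """Decoded angles, each wrapped to (-pi, pi]."""
        enc = self.predict_encoded(np.atleast_2d(np.asarray(X, dtype=float)))
        return np.array([decode_angle(row) for row in enc])

    def predict_angle(self, x: np.ndarray) -> float:
        return float(self.predict_angles(np.atleast_2d(x))[0])


@dataclass
class SVRAngleRegressor(AngleRegressor):
    """Two independent Gaussian-kernel epsilon-SVRs (cos and sin)."""

    width: float = KERNEL_WIDTH_DEFAULT
    C: float = 10.0
    epsilon: float = 0.01
    width_param: str = "half_sq"
    kind: str = field(default="svr", init=False)
    _models: tuple[SVR, SVR] | None = field(default=None, init=False, repr=False)

    def fit(self, ts: TrainingSet) -> "SVRAngleRegressor":
        if self.width_param == "half_sq":
            gamma = 1.0 / (2.0 * self.width**2)
        else:
            gamma = 1.0 / self.width
        models = []
        for comp in range(2):
            svr = SVR(kernel="rbf", gamma=gamma, C=self.C, epsilon=self.epsilon)
            svr.fit(ts.features, ts.targets[:, comp])
            models.append(svr)
        self._models = (models[0], models[1])
        return self

    def predict_encoded(self, X: np.ndarray) -> np.ndarray:
        if self._models is None:
            raise RegressionError("model is not fitted")
        return np.stack([m.predict(X) for m in self._models], axis=1)


@dataclass
class KernelELMRegressor(AngleRegressor):
    """Kernel extreme learning machine: closed-form kernel ridge.

    Output weights solve (K + I/C) alpha = Y on the anchor set; the
    anchor set is the full training set by default, or a seeded random
    subset of ``n_anchors`` points (the model's optional randomness).
    """

    width: float = KERNEL_WIDTH_DEFAULT
    C: float = 100.0
    seed: int | None = None
    n_anchors: int | None = None
    width_param: str = "half_sq"
    kind: str = field(default="elm", init=False)
    _anchors: np.ndarray | None = field(default=None, init=False, repr=False)
    _alpha: np.ndarray | None = field(default=None, init=False, repr=False)

    def fit(self, ts: TrainingSet) -> "KernelELMRegressor":
        X, Y = ts.features, ts.targets
        if self.n_anchors is not None and self.n_anchors < X.shape[0]:
            rng = np.random.default_rng(self.seed)
            idx = rng.choice(X.shape[0], size=self.n_anchors, replace=False)
            X, Y = X[idx], Y[idx]
        K = _gaussian_kernel(X, X, self.width, self.width_param)
        K = K + np.eye(K.shape[0]) / self.C
        try:
            alpha = np.linalg.solve(K, Y)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by ridge
            raise RegressionError(
                "singular kernel system; increase regularization (lower C)"
            ) from exc
        self._anchors = X
        self._alpha = alpha
        return self

    def predict_encoded(self, X: np.ndarray) -> np.ndarray:
        if self._anchors is None or self._alpha is None:
            raise RegressionError("model is not fitted")
        k = _gaussian_kernel(
            np.atleast_2d(X), self._anchors, self.width, self.width_param
        )
        return k @ self._alpha


def _init_params(
    rng: np.random.Generator, sizes: tuple[int, ...]
) -> list[tuple[np.ndarray, np.ndarray]]:
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = math.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        params.append((W, b))
    return params


def _flatten(params: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    return np.concatenate([p.ravel() for W, b in params for p in (W, b)])


def _unflatten(
    flat: np.ndarray, sizes: tuple[int, ...]
) -> list[tuple[np.ndarray, np.ndarray]]:
    params = []
    ofs = 0
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = flat[ofs : ofs + fan_in * fan_out].reshape(fan_in, fan_out)
        ofs += fan_in * fan_out
        b = flat[ofs : ofs + fan_out]
        ofs += fan_out
        params.append((W, b))
    return params


@dataclass
class MLPAngleRegressor(AngleRegressor):
    """105-60-30-15-2 tanh network trained full-batch on circular targets.

    The loss is the mean squared error between the output projected to
    the unit circle and the (cos, sin) target (``unit_circle_loss=False``
    uses the plain MSE). Optimization is full-batch quasi-Newton with a
    gradient tolerance of 1e-6 and a cap of ``max_epochs`` iterations;
    initialization is seeded, so training is reproducible.
    """

    hidden: tuple[int, ...] = (60, 30, 15)
    seed: int = 0
    max_epochs: int = 1000
    grad_tol: float = 1e-6
    unit_circle_loss: bool = True
    kind: str = field(default="ann", init=False)
    _sizes: tuple[int, ...] | None = field(default=None, init=False, repr=False)
    _flat: np.ndarray | None = field(default=None, init=False, repr=False)

    def _forward(
        self, params: list[tuple[np.ndarray, np.ndarray]], X: np.ndarray
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        activations = [X]
        h = X
        for i, (W, b) in enumerate(params):
            z = h @ W + b
            h = np.tanh(z) if i < len(params) - 1 else z
            activations.append(h)
        return h, activations

    def _loss_grad(
        self, flat: np.ndarray, X: np.ndarray, Y: np.ndarray
    ) -> tuple[float, np.ndarray]:
        sizes = self._sizes
        assert sizes is not None
        params = _unflatten(flat, sizes)
        out, acts = self._forward(params, X)
        n = X.shape[0]
        if self.unit_circle_loss:
            norms = np.maximum(np.linalg.norm(out, axis=1, keepdims=True), 1e-9)
            q = out / norms
            resid = q - Y
            loss = float(np.sum(resid**2) / n)
            # d/d out of q = (I - q q^T) / ||out||
            dq = 2.0 * resid / n
            d_out = (dq - q * np.sum(dq * q, axis=1, keepdims=True)) / norms
        else:
            resid = out - Y
            loss = float(np.sum(resid**2) / n)
            d_out = 2.0 * resid / n
        if not math.isfinite(loss):
            raise TrainingDivergenceError("non-finite training loss")
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(params)  # type: ignore
        delta = d_out
        for i in range(len(params) - 1, -1, -1):
            W, _ = params[i]
            a_prev = acts[i]
            grads[i] = (a_prev.T @ delta, delta.sum(axis=0))
            if i > 0:
                delta = (delta @ W.T) * (1.0 - acts[i] ** 2)
        return loss, _flatten(grads)

    def fit(self, ts: TrainingSet) -> "MLPAngleRegressor":
        X, Y = ts.features, ts.targets
        if X.shape[0] < 10:
            raise RegressionError("need at least 10 samples to train the network")
        self._sizes = (X.shape[1], *self.hidden, 2)
        rng = np.random.default_rng(self.seed)
        x0 = _flatten(_init_params(rng, self._sizes))
        res = minimize(
            self._loss_grad,
            x0,
            args=(X, Y),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_epochs, "gtol": self.grad_tol,
                     "maxcor": 20, "ftol": 0.0},
        )
        self._flat = res.x
        return self

    def predict_encoded(self, X: np.ndarray) -> np.ndarray:
        if self._flat is None or self._sizes is None:
            raise RegressionError("model is not fitted")
        params = _unflatten(self._flat, self._sizes)
        out, _ = self._forward(params, np.atleast_2d(np.asarray(X, dtype=float)))
        return out


def train_regressor(kind: str, ts: TrainingSet, seed: int = 0, **kwargs) -> AngleRegressor:
    """Fit a regressor of the requested kind ('svr', 'elm' or 'ann')."""
    if kind == "svr":
        model: AngleRegressor = SVRAngleRegressor(**kwargs)
    elif kind == "elm":
        model = KernelELMRegressor(seed=seed, **kwargs)
    elif kind == "ann":
        model = MLPAngleRegressor(seed=seed, **kwargs)
    else:
        raise RegressionError(f"unknown regressor kind {kind!r}")
    return model.fit(ts)  # type: ignore[attr-defined]
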