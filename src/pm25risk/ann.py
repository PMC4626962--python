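"""Two-layer back-propagation network for PM2.5 regression.

The model is a single-hidden-layer feed-forward network with logistic
hidden units and a linear output layer:

    H_j = f(sum_i w_in[i,j] * x_i - theta_hidden[j]),   f(t) = 1/(1+exp(-t))
    O_k = sum_j H_j * w_out[j,k] - theta_out[k]

Thresholds are *subtracted*, following the convention of the classic
formulation this package implements.  Training minimizes the sum of squared
errors between network output and (normalized) targets; three optimizers
are available through :func:`fit` -- per-sample gradient descent with the
classic update rules (``gd``), resilient backpropagation (``trainrp``) and
Levenberg-Marquardt (``trainlm``), the latter two in :mod:`.optimizers`.

The classic per-sample update rules are implemented verbatim in
:func:`gd_step`, including their idiosyncratic threshold updates: the
hidden and output threshold corrections carry the *opposite* sign of a
strict gradient-descent derivation, and the output threshold update has no
learning-rate factor.  ``strict_bias_update=False`` applies the learning rate to
the output-threshold update as well; the batch optimizers instead use the
exact analytic gradient (:func:`sse_and_gradient`), which is
finite-difference checked in the test suite.

Forecasting follows the fit-then-forecast (P-T-P'-T') protocol: the
network is trained on historical covariate/concentration pairs (P, T) and
then applied, with the *training* normalization frozen, to projected
future covariates P' to produce future concentrations T'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "Normalizer",
    "FitResult",
    "logistic",
    "forward",
    "forward_batch",
    "output_error",
    "gd_step",
    "pack",
    "unpack",
    "sse_and_gradient",
    "residuals_and_jacobian",
    "init_params",
    "fit",
    "predict",
    "predict_ptpt",
]


def logistic(t: np.ndarray) -> np.ndarray:
    """Numerically safe standard logistic 1/(1+exp(-t))."""
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class NetworkParams:
    """Weights and thresholds of the two-layer network.

    ``w_in[i, j]`` connects input i to hidden unit j; ``w_out[j, k]``
    connects hidden unit j to output k.  ``theta_hidden`` and ``theta_out``
    are the subtracted thresholds of the hidden and output layers.
    """

    w_in: np.ndarray
    w_out: np.ndarray
    theta_hidden: np.ndarray
    theta_out: np.ndarray

    def __post_init__(self):
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.theta_hidden = np.asarray(self.theta_hidden, dtype=float)
        self.theta_out = np.asarray(self.theta_out, dtype=float)
        n, l = self.w_in.shape
        l2, m = self.w_out.shape
        if l2 != l or self.theta_hidden.shape != (l,) or self.theta_out.shape != (m,):
            raise ValueError(
                f"inconsistent shapes: w_in {self.w_in.shape}, w_out "
                f"{self.w_out.shape}, theta_hidden {self.theta_hidden.shape}, "
                f"theta_out {self.theta_out.shape}"
            )
        for a in (self.w_in, self.w_out, self.theta_hidden, self.theta_out):
            if not np.all(np.isfinite(a)):
                raise ValueError("network parameters must be finite")

    @property
    def n_in(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[1]

    @property
    def n_out(self) -> int:
        return self.w_out.shape[1]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.w_in.copy(), self.w_out.copy(),
            self.theta_hidden.copy(), self.theta_out.copy(),
        )


def forward(params: NetworkParams, x: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Single-sample forward pass; returns (hidden vector H, output vector O)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_in,):
        raise ValueError(f"input must have shape ({params.n_in},), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input vector must be finite")
    H = logistic(x @ params.w_in - params.theta_hidden)
    O = H @ params.w_out - params.theta_out
    return H, O


def forward_batch(params: NetworkParams, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batch forward pass for X of shape (N, n_in)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.n_in:
        raise ValueError(f"expected {params.n_in} features, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    H = logistic(X @ params.w_in - params.theta_hidden)
    O = H @ params.w_out - params.theta_out
    return H, O


def output_error(O: Sequence[float], Y: Sequence[float]) -> np.ndarray:
    """Prediction error e = Y - O (positive when the network under-predicts)."""
    O = np.asarray(O, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if O.shape != Y.shape:
        raise ValueError(f"shape mismatch: O {O.shape} vs Y {Y.shape}")
    return Y - O


def gd_step(
    params: NetworkParams,
    x: Sequence[float],
    y: Sequence[float],
    eta: float,
    strict_bias_update: bool = True,
) -> NetworkParams:
    """One classic per-sample update, applied simultaneously from old values.

    Update rules (e = y - O):

        w_in[i,j]  += eta * H_j (1-H_j) * x_i * sum_k w_out[j,k] e_k
        w_out[j,k] += eta * H_j * e_k
        theta_hidden[j] += eta * H_j (1-H_j) * sum_k w_out[j,k] e_k
        theta_out[k]    += e_k          (or eta * e_k if strict_bias_update=False)
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    H, O = forward(params, x)
    e = output_error(O, y)
    s = params.w_out @ e                  # sum_k w_out[j,k] e_k, per hidden j
    d = H * (1.0 - H) * s
    new = params.copy()
    new.w_in += eta * np.outer(x, d)
    new.w_out += eta * np.outer(H, e)
    new.theta_hidden += eta * d
    new.theta_out += e if strict_bias_update else eta * e
    return new


# ---------------------------------------------------------------------------
# flattened-parameter machinery shared by the batch optimizers


def pack(params: NetworkParams) -> np.ndarray:
    return np.concatenate([
        params.w_in.ravel(), params.w_out.ravel(),
        params.theta_hidden, params.theta_out,
    ])


def unpack(theta: np.ndarray, n: int, l: int, m: int) -> NetworkParams:
    theta = np.asarray(theta, dtype=float)
    i0 = n * l
    i1 = i0 + l * m
    return NetworkParams(
        theta[:i0].reshape(n, l),
        theta[i0:i1].reshape(l, m),
        theta[i1:i1 + l],
        theta[i1 + l:],
    )


def sse_and_gradient(
    params: NetworkParams, X: np.ndarray, Y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Sum of squared errors and the gradient of SSE/2 in packed order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    H, O = forward_batch(params, X)
    e = Y - O                              # (N, m)
    sse = float(np.sum(e * e))
    # d(SSE/2)/dO = -e
    g_w_out = -H.T @ e                     # (l, m)
    g_theta_out = e.sum(axis=0)            # dO/dtheta_out = -1
    dH = -(e @ params.w_out.T) * H * (1.0 - H)   # (N, l) = d(SSE/2)/d(net_j)
    g_w_in = X.T @ dH                      # (n, l)
    g_theta_hidden = -dH.sum(axis=0)       # dnet/dtheta_hidden = -1
    grad = np.concatenate([
        g_w_in.ravel(), g_w_out.ravel(), g_theta_hidden, g_theta_out,
    ])
    return sse, grad


def residuals_and_jacobian(
    params: NetworkParams, X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residual vector r = (Y - O).ravel() and its Jacobian dr/dtheta.

    The Jacobian satisfies J.T @ r == gradient of SSE/2, the form consumed
    by the Levenberg-Marquardt optimizer.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    N = X.shape[0]
    n, l, m = params.n_in, params.n_hidden, params.n_out
    H, O = forward_batch(params, X)
    r = (Y - O).ravel()
    Hp = H * (1.0 - H)                     # (N, l)
    # dO[p,k]/dw_in[i,j] = w_out[j,k] * Hp[p,j] * X[p,i];  dr = -dO
    J_w_in = -np.einsum("pi,pj,jk->pkij", X, Hp, params.w_out).reshape(N * m, n * l)
    eye_m = np.eye(m)
    J_w_out = -np.einsum("pj,kq->pkjq", H, eye_m).reshape(N * m, l * m)
    J_th_h = np.einsum("pj,jk->pkj", Hp, params.w_out).reshape(N * m, l)
    J_th_o = np.tile(eye_m, (N, 1))
    return r, np.hstack([J_w_in, J_w_out, J_th_h, J_th_o])


# ---------------------------------------------------------------------------
# normalization


@dataclass
class Normalizer:
    """Per-feature min-max scaling fitted on the training set.

    ``mode="minmax_01"`` maps to [0, 1]; ``mode="minmax_sym"`` to [-1, 1].
    A target range of [0.1, 0.9] (``lo``/``hi``) keeps the inverse map
    stable at the edges of the training range.  Degenerate features
    (max == min) are dropped with a warning and recorded in ``dropped``.
    """

    lo: float = 0.0
    hi: float = 1.0
    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None
    keep: np.ndarray | None = None
    dropped: list[int] = field(default_factory=list)

    @classmethod
    def from_mode(cls, mode: str, lo=None, hi=None) -> "Normalizer":
        if mode == "minmax_01":
            return cls(lo=0.0, hi=1.0)
        if mode == "minmax_sym":
            return cls(lo=-1.0, hi=1.0)
        raise ValueError(f"unknown normalization mode {mode!r}")

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.mins = X.min(axis=0)
        self.maxs = X.max(axis=0)
        span = self.maxs - self.mins
        self.keep = span > 0
        self.dropped = list(np.nonzero(~self.keep)[0])
        if self.dropped:
            warnings.warn(
                f"dropping degenerate feature(s) {self.dropped} (max == min)",
                stacklevel=2,
            )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.mins):
            raise ValueError(
                f"expected {len(self.mins)} features, got {X.shape[1]}"
            )
        span = np.where(self.keep, self.maxs - self.mins, 1.0)
        Z = self.lo + (X - self.mins) / span * (self.hi - self.lo)
        return Z[:, self.keep]

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        mins = self.mins[self.keep]
        span = (self.maxs - self.mins)[self.keep]
        return mins + (Z - self.lo) / (self.hi - self.lo) * span


# ---------------------------------------------------------------------------
# training front end


@dataclass
class TrainConfig:
    eta: float = 0.1
    max_epochs: int = 200
    tol: float = 0.0
    seed: int = 0
    normalization: str = "minmax_01"
    n_hidden: int | None = None        # default 2*n_in + 1
    strict_bias_update: bool = True
    clip_nonneg: bool = True           # clip inverse-normalized predictions at 0
    clip_inputs: bool = True           # clamp prediction inputs to the training range
    optimizer_options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


@dataclass
class FitResult:
    params: NetworkParams
    x_norm: Normalizer
    y_norm: Normalizer
    trace: list[float]                 # SSE on normalized targets, per epoch
    config: TrainConfig
    optimizer: str
    converged: bool


def init_params(n: int, l: int, m: int, seed: int) -> NetworkParams:
    """Seeded uniform(-0.5, 0.5) weights; thresholds start at zero."""
    rng = np.random.default_rng(seed)
    return NetworkParams(
        rng.uniform(-0.5, 0.5, size=(n, l)),
        rng.uniform(-0.5, 0.5, size=(l, m)),
        np.zeros(l),
        np.zeros(m),
    )


def fit(
    X: np.ndarray,
    Y: np.ndarray,
    cfg: TrainConfig | None = None,
    optimizer: str = "trainlm",
) -> FitResult:
    """Normalize, initialize and train the network.

    Inputs are min-max normalized per ``cfg.normalization``; targets are
    mapped to [0.1, 0.9].  ``optimizer`` is one of ``gd`` (per-sample
    classic rules), ``trainrp`` or ``trainlm`` (batch, in
    :mod:`.optimizers`).  Training stops once the epoch SSE on normalized
    targets drops to ``cfg.tol`` or after ``cfg.max_epochs`` epochs.
    """
    from . import optimizers  # late import; optimizers imports this module

    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(X) != len(Y) or len(X) == 0:
        raise ValueError("X and Y must be non-empty and of equal length")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("training data must not contain missing values")

    x_norm = Normalizer.from_mode(cfg.normalization).fit(X)
    y_norm = Normalizer(lo=0.1, hi=0.9).fit(Y)
    Xn = x_norm.transform(X)
    Yn = y_norm.transform(Y)

    n, m = Xn.shape[1], Yn.shape[1]
    l = cfg.n_hidden if cfg.n_hidden is not None else 2 * n + 1
    params = init_params(n, l, m, cfg.seed)

    if optimizer == "gd":
        params, trace, converged = _train_gd(params, Xn, Yn, cfg)
    elif optimizer in ("trainrp", "trainlm"):
        params, trace, converged = optimizers.train_batch(
            params, Xn, Yn, cfg, algo=optimizer
        )
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    return FitResult(params, x_norm, y_norm, trace, cfg, optimizer, converged)


def _train_gd(params, Xn, Yn, cfg):
    """Per-sample classic updates, presentation order reshuffled each epoch."""
    rng = np.random.default_rng(cfg.seed)
    trace: list[float] = []
    converged = False
    for _ in range(cfg.max_epochs):
        order = rng.permutation(len(Xn))
        for p in order:
            params = gd_step(params, Xn[p], Yn[p], cfg.eta, cfg.strict_bias_update)
        sse, _ = sse_and_gradient(params, Xn, Yn)
        trace.append(sse)
        if sse <= cfg.tol:
            converged = True
            break
    return params, trace, converged


def predict(fitres: FitResult, X: np.ndarray) -> np.ndarray:
    """Predict on the original scale (training normalization frozen).

    By default inputs are clamped, feature by feature, to the training
    range: the network is a nonparametric fit and is not trusted to
    extrapolate beyond the covariate support it was trained on.
    """
    Xn = fitres.x_norm.transform(np.atleast_2d(np.asarray(X, dtype=float)))
    if fitres.config.clip_inputs:
        Xn = np.clip(Xn, fitres.x_norm.lo, fitres.x_norm.hi)
    _, On = forward_batch(fitres.params, Xn)
    y = fitres.y_norm.inverse(On)
    if fitres.config.clip_nonneg:
        y = np.maximum(y, 0.0)
    return y[:, 0] if y.shape[1] == 1 else y


def predict_ptpt(fitres: FitResult, P_prime: np.ndarray) -> np.ndarray:
    """Forecast T' from projected future covariates P'.

    Applies the training-set normalization to P', runs the forward pass and
    inverse-normalizes the outputs; the network is never refitted.
    """
    P_prime = np.atleast_2d(np.asarray(P_prime, dtype=float))
    if P_prime.shape[1] != len(fitres.x_norm.mins):
        raise ValueError(
            f"P' has {P_prime.shape[1]} feature columns, "
            f"training had {len(fitres.x_norm.mins)}"
        )
    return predict(fitres, P_prime)
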