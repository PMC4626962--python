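"""Batch training algorithms: Levenberg-Marquardt and resilient backprop.

Both operate on the flattened parameter vector of :mod:`.ann` with
full-batch residuals/gradients.

``trainlm`` takes damped Gauss-Newton steps: it solves

    (J^T J + beta I) d = -J^T r

for the step d, where r is the batch residual vector and J its Jacobian.
J^T J stands in for the exact Hessian of SSE/2 (the standard
Gauss-Newton surrogate) and the damping metric is the identity.  A step is
accepted only if the SSE decreases, in which case beta shrinks; otherwise
beta is inflated and the step retried, up to a bounded number of
inflations.  The full step is always taken (no line search).

``trainrp`` (Rprop) ignores gradient magnitudes entirely: each parameter
carries its own step size, grown when the gradient sign repeats and shrunk
when it flips, and moves opposite to the current gradient sign.  It is
therefore invariant to any positive rescaling of the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from . import ann

__all__ = [
    "LMState",
    "RpropState",
    "LMFailure",
    "trainlm_step",
    "trainrp_step",
    "train_batch",
]


class LMFailure(RuntimeError):
    """Damped system stayed singular / SSE never decreased within the
    inflation budget; carries the final damping factor."""

    def __init__(self, beta: float):
        super().__init__(
            f"Levenberg-Marquardt step failed to decrease the SSE "
            f"(final damping beta={beta:.3e})"
        )
        self.beta = beta


@dataclass
class LMState:
    """Damping state of the Levenberg-Marquardt iteration (beta >= 0)."""

    beta: float = 1e-3
    beta_up: float = 10.0
    beta_down: float = 10.0
    max_inflations: int = 30

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def trainlm_step(
    z: np.ndarray,
    residual_fn,
    jacobian_fn,
    state: LMState,
) -> tuple[np.ndarray, LMState, bool]:
    """One damped Gauss-Newton step; returns (z_new, state_new, accepted).

    At a stationary point (zero gradient) the step is zero and the state is
    returned unchanged.  Raises :class:`LMFailure` if no damping level
    within the inflation budget produces a decrease.
    """
    r = residual_fn(z)
    J = jacobian_fn(z)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(J))):
        raise ValueError("residuals and Jacobian must be finite")
    g = J.T @ r
    sse = float(r @ r)
    # stationary point: gradient negligible at the problem's scale
    if np.max(np.abs(g), initial=0.0) <= 1e-12 * max(1.0, sse):
        return z, state, True
    A = J.T @ J
    beta = state.beta
    eye = np.eye(len(z))
    for _ in range(state.max_inflations + 1):
        try:
            c = cho_factor(A + beta * eye)
            d = cho_solve(c, -g)
        except LinAlgError:
            beta = max(beta * state.beta_up, 1e-12)
            continue
        z_try = z + d
        r_try = residual_fn(z_try)
        if float(r_try @ r_try) < sse:
            return z_try, replace(state, beta=beta / state.beta_down), True
        beta = max(beta * state.beta_up, 1e-12)
    raise LMFailure(beta)


@dataclass
class RpropState:
    """Per-parameter adaptive step sizes and gradient-sign memory."""

    delta: np.ndarray
    prev_sign: np.ndarray
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta_min: float = 1e-6
    delta_max: float = 50.0

    def __post_init__(self):
        if not (self.eta_plus > 1.0 > self.eta_minus > 0.0):
            raise ValueError("need eta_plus > 1 > eta_minus > 0")

    @classmethod
    def fresh(cls, n_params: int, delta0: float = 0.07, **kw) -> "RpropState":
        return cls(
            delta=np.full(n_params, float(delta0)),
            prev_sign=np.zeros(n_params),
            **kw,
        )


def trainrp_step(
    z: np.ndarray, grad: np.ndarray, state: RpropState
) -> tuple[np.ndarray, RpropState]:
    """One Rprop update; depends on the gradient only through its signs.

    Sign repeats -> step grows by eta_plus (capped at delta_max); sign
    flips -> step shrinks by eta_minus (floored at delta_min) and the sign
    memory is reset; the parameter always moves by -delta * sign(grad), so
    a zero gradient leaves it unchanged.
    """
    grad = np.asarray(grad, dtype=float)
    if not np.all(np.isfinite(grad)):
        raise ValueError("gradient must be finite")
    s = np.sign(grad)
    prod = s * state.prev_sign
    delta = np.where(
        prod > 0,
        np.minimum(state.delta * state.eta_plus, state.delta_max),
        np.where(
            prod < 0,
            np.maximum(state.delta * state.eta_minus, state.delta_min),
            state.delta,
        ),
    )
    new_sign = np.where(prod < 0, 0.0, s)
    z_new = z - delta * s
    return z_new, replace(state, delta=delta, prev_sign=new_sign)


def train_batch(
    params: "ann.NetworkParams",
    Xn: np.ndarray,
    Yn: np.ndarray,
    cfg: "ann.TrainConfig",
    algo: str,
) -> tuple["ann.NetworkParams", list[float], bool]:
    """Full-batch training loop shared by trainlm and trainrp.

    One trace entry (SSE on normalized targets) per iteration; stops when
    SSE <= cfg.tol, after cfg.max_epochs iterations, or -- for trainlm --
    when a step fails, in which case the best parameters so far are
    returned.
    """
    n, l, m = params.n_in, params.n_hidden, params.n_out
    z = ann.pack(params)
    opts = dict(cfg.optimizer_options)
    trace: list[float] = []
    converged = False

    if algo == "trainlm":
        state = LMState(
            beta=opts.pop("beta0", 1e-3),
            beta_up=opts.pop("beta_up", 10.0),
            beta_down=opts.pop("beta_down", 10.0),
            max_inflations=opts.pop("max_inflations", 30),
        )
        residual_fn = lambda zz: ann.residuals_and_jacobian(
            ann.unpack(zz, n, l, m), Xn, Yn
        )[0]
        jacobian_fn = lambda zz: ann.residuals_and_jacobian(
            ann.unpack(zz, n, l, m), Xn, Yn
        )[1]
        for _ in range(cfg.max_epochs):
            try:
                z, state, _ = trainlm_step(z, residual_fn, jacobian_fn, state)
            except LMFailure:
                break
            r = residual_fn(z)
            sse = float(r @ r)
            trace.append(sse)
            if sse <= cfg.tol:
                converged = True
                break
    elif algo == "trainrp":
        state = RpropState.fresh(
            len(z),
            delta0=opts.pop("delta0", 0.07),
            eta_plus=opts.pop("eta_plus", 1.2),
            eta_minus=opts.pop("eta_minus", 0.5),
            delta_min=opts.pop("delta_min", 1e-6),
            delta_max=opts.pop("delta_max", 50.0),
        )
        best_z, best_sse = z, np.inf
        for _ in range(cfg.max_epochs):
            sse, grad = ann.sse_and_gradient(ann.unpack(z, n, l, m), Xn, Yn)
            if sse < best_sse:
                best_z, best_sse = z, sse
            z, state = trainrp_step(z, grad, state)
            sse_new, _ = ann.sse_and_gradient(ann.unpack(z, n, l, m), Xn, Yn)
            trace.append(sse_new)
            if sse_new <= cfg.tol:
                converged = True
                break
        if not converged and best_sse < trace[-1]:
            z = best_z  # Rprop can overshoot late; keep the best visit
    else:
        raise ValueError(f"unknown batch algorithm {algo!r}")

    if opts:
        raise ValueError(f"unknown optimizer options: {sorted(opts)}")
    return ann.unpack(z, n, l, m), trace, converged
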