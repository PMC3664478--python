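"""Cubature Kalman filter updates for the hidden expression states.

A spherical-radial cubature rule approximates the Gaussian moment integrals
of the nonlinear time update with ``2N`` equally weighted points placed at
``mean ± sqrt(N) * U e_i`` where ``U U^T = P``.  The rule is exact for
polynomial integrands up to degree 3, so on a linear system the filter
coincides with the standard Kalman filter.  Because the observation map is
the identity, the measurement update is implemented in closed form; a
generic cubature measurement update is kept for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve

from .exceptions import NumericalError
from .model import GeneNetwork, NoiseConfig, sigmoid

__all__ = [
    "GaussianBelief",
    "CubatureSet",
    "cubature_points",
    "time_update",
    "measurement_update",
]


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


@dataclass
class GaussianBelief:
    """A Gaussian posterior: mean vector and (symmetrized) covariance."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = _symmetrize(np.asarray(self.covariance, dtype=float))
        n = self.mean.size
        if self.covariance.shape != (n, n):
            raise ValueError("covariance shape does not match mean")

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass
class CubatureSet:
    """The 2N cubature points of a belief, each with weight 1/(2N)."""

    points: np.ndarray  # (2N, N)

    @property
    def weight(self) -> float:
        return 1.0 / self.points.shape[0]


def _sqrt_covariance(P: np.ndarray, context: str = "") -> np.ndarray:
    """Lower-triangular factor U with U U^T = P, with a jitter-and-retry
    policy for marginally indefinite matrices."""
    n = P.shape[0]
    jitter = 1e-9 * max(np.trace(P), 0.0) / n if n else 0.0
    jitter = max(jitter, 1e-300)
    attempt = P
    for trial in range(4):
        try:
            return cholesky(attempt, lower=True)
        except np.linalg.LinAlgError:
            pass
        attempt = P + jitter * np.eye(n)
        jitter *= 10.0
    raise NumericalError(
        f"covariance not positive definite after jitter{(' ' + context) if context else ''}"
    )


def cubature_points(belief: GaussianBelief, context: str = "") -> CubatureSet:
    """Spherical-radial cubature points of a Gaussian belief."""
    n = belief.dim
    U = _sqrt_covariance(belief.covariance, context)
    offsets = np.sqrt(n) * U.T  # row i = sqrt(N) * i-th column of U
    points = np.vstack([belief.mean + offsets, belief.mean - offsets])
    return CubatureSet(points=points)


def _as_dynamics(dynamics):
    """Accept a GeneNetwork, a linear map matrix, or a callable on point
    arrays (rows = points)."""
    if isinstance(dynamics, GeneNetwork):
        W = dynamics.weights
        return lambda X: sigmoid(X) @ W.T
    if isinstance(dynamics, np.ndarray):
        A = dynamics
        return lambda X: X @ A.T
    if callable(dynamics):
        return dynamics
    raise TypeError("dynamics must be a GeneNetwork, a matrix, or a callable")


def _as_cov(noise, attr: str, n: int) -> np.ndarray:
    if isinstance(noise, NoiseConfig):
        return getattr(noise, attr) * np.eye(n)
    noise = np.asarray(noise, dtype=float)
    if noise.ndim == 0:
        return float(noise) * np.eye(n)
    return noise


def time_update(belief: GaussianBelief, dynamics, noise, context: str = "") -> GaussianBelief:
    """Cubature prediction through the state dynamics.

    ``dynamics`` is the one-step map (a :class:`GeneNetwork` for the sigmoid
    model, a matrix for linear dynamics, or any callable acting on rows);
    ``noise`` supplies the process covariance Q.
    """
    pts = cubature_points(belief, context).points
    propagated = _as_dynamics(dynamics)(pts)
    if not np.all(np.isfinite(propagated)):
        raise NumericalError(f"propagated cubature points are non-finite {context}".strip())
    mean = propagated.mean(axis=0)
    centred = propagated - mean
    Q = _as_cov(noise, "sigma_w2", belief.dim)
    cov = centred.T @ centred / pts.shape[0] + Q
    return GaussianBelief(mean, cov)


def measurement_update(
    predicted: GaussianBelief,
    y: np.ndarray,
    noise,
    method: str = "linear",
    context: str = "",
) -> GaussianBelief:
    """Condition a predicted state belief on an identity-map observation.

    With ``h(x) = x`` the exact update is linear: ``P_yy = P + S``,
    ``K = P P_yy^{-1}``, mean ``+= K (y - mean)``, ``P -= K P_yy K^T``.
    ``method="cubature"`` instead propagates cubature points through the
    identity map — algebraically equivalent, retained as a cross-check.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != predicted.mean.shape:
        raise ValueError("observation dimension does not match belief")
    S = _as_cov(noise, "sigma_v2", predicted.dim)

    if method == "cubature":
        pts = cubature_points(predicted, context).points
        Y = pts  # identity observation map
        y_hat = Y.mean(axis=0)
        cy = Y - y_hat
        cx = pts - pts.mean(axis=0)
        P_yy = cy.T @ cy / pts.shape[0] + S
        P_xy = cx.T @ cy / pts.shape[0]
    elif method == "linear":
        y_hat = predicted.mean
        P_yy = predicted.covariance + S
        P_xy = predicted.covariance
    else:
        raise ValueError(f"unknown measurement-update method {method!r}")

    try:
        # K = P_xy P_yy^{-1}, via solving P_yy K^T = P_xy^T
        K = solve(P_yy, P_xy.T, assume_a="pos").T
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"innovation covariance is singular {context}".strip()
        ) from exc
    mean = predicted.mean + K @ (y - y_hat)
    cov = predicted.covariance - K @ P_yy @ K.T
    return GaussianBelief(mean, cov)
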