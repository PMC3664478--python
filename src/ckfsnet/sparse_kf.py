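"""Kalman filtering of the stacked regulatory parameters with an l1
pseudo-measurement sparsity constraint.

The parameter vector b (all N^2 weights, grouped by target gene) is modelled
as a Gauss-Markov random walk ``b_k = b_{k-1} + eta_k`` and tracked with a
linear Kalman filter against the observation ``y_k = R_k b + e_k``.  Because
gene networks are sparse, each filter update is followed by ``K_tau``
compressed-sensing pseudo-measurement (PM) iterations: the constraint
``||b||_1 <= eps`` is treated as a fictitious noisy measurement
``0 = sign(b)^T b`` with pseudo-noise variance ``sigma_eps2``, and a Kalman
update against it shrinks the estimate toward sparsity while the covariance
records the constraint.

Two covariance representations are available.  The full joint filter keeps
the dense N^2 x N^2 matrix.  The decoupled representation exploits the
block-diagonal regressor: the filter update splits exactly into N
independent per-gene filters of dimension N, and only the N diagonal blocks
are stored.  The PM update couples blocks through the dense outer product
sign(b) sign(b)^T; the decoupled form applies the exact mean update and the
exact diagonal-block covariance update and discards off-block terms, which
is the approximation that makes 100-gene networks tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import NumericalError
from .model import sigmoid

__all__ = [
    "ParameterBelief",
    "PMConfig",
    "kf_param_step",
    "pm_iterations",
    "select_Ktau",
]

#: above this many genes the decoupled covariance representation is used
DECOUPLE_THRESHOLD = 20


def _symmetrize(P):
    return 0.5 * (P + np.swapaxes(P, -1, -2))


@dataclass
class PMConfig:
    """Pseudo-measurement stage configuration: K_tau iterations with
    pseudo-noise variance sigma_eps2 (default 100, a value large enough to
    act as a soft constraint)."""

    n_iterations: int
    sigma_eps2: float = 100.0

    def __post_init__(self):
        if self.sigma_eps2 <= 0:
            raise ValueError("sigma_eps2 must be positive")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")


class ParameterBelief:
    """Gaussian belief over the stacked parameter vector.

    ``covariance`` is either the full ``(N^2, N^2)`` matrix or, in decoupled
    form, an ``(N, N, N)`` array of per-target-gene diagonal blocks.
    """

    def __init__(self, mean, covariance, decoupled: bool, walk_variance: float = 0.0):
        self.mean = np.asarray(mean, dtype=float)
        self.decoupled = bool(decoupled)
        self.walk_variance = float(walk_variance)
        cov = np.asarray(covariance, dtype=float)
        n2 = self.mean.size
        n = int(round(np.sqrt(n2)))
        if n * n != n2:
            raise ValueError("parameter vector length must be a perfect square")
        self.n_genes = n
        if self.decoupled:
            if cov.shape != (n, n, n):
                raise ValueError("decoupled covariance must have shape (N, N, N)")
        elif cov.shape != (n2, n2):
            raise ValueError("full covariance must have shape (N^2, N^2)")
        self.covariance = _symmetrize(cov)

    @classmethod
    def initial(cls, n_genes: int, decoupled: bool | str = "auto",
                walk_variance: float = 0.0, prior_variance: float = 1.0):
        """Uninformative start: b = 0, P = prior_variance * I."""
        if decoupled == "auto":
            decoupled = n_genes > DECOUPLE_THRESHOLD
        mean = np.zeros(n_genes * n_genes)
        if decoupled:
            cov = np.broadcast_to(
                prior_variance * np.eye(n_genes), (n_genes, n_genes, n_genes)
            ).copy()
        else:
            cov = prior_variance * np.eye(n_genes * n_genes)
        return cls(mean, cov, decoupled, walk_variance)

    def full_covariance(self) -> np.ndarray:
        """The N^2 x N^2 covariance (block-diagonal reconstruction when
        decoupled)."""
        if not self.decoupled:
            return self.covariance
        n = self.n_genes
        full = np.zeros((n * n, n * n))
        for i in range(n):
            full[i * n:(i + 1) * n, i * n:(i + 1) * n] = self.covariance[i]
        return full

    def covariance_blocks(self) -> np.ndarray:
        """Per-target-gene diagonal blocks, shape (N, N, N)."""
        if self.decoupled:
            return self.covariance
        n = self.n_genes
        return np.stack(
            [self.covariance[i * n:(i + 1) * n, i * n:(i + 1) * n] for i in range(n)]
        )

    def covariance_diagonal(self) -> np.ndarray:
        if self.decoupled:
            return np.concatenate([np.diag(b) for b in self.covariance])
        return np.diag(self.covariance).copy()

    def copy(self) -> "ParameterBelief":
        return ParameterBelief(
            self.mean.copy(), self.covariance.copy(), self.decoupled, self.walk_variance
        )


def _regressor_row(regressor, n_genes):
    """Accept either the squashed-state row f̃ (length N) or the full
    block-diagonal regressor R_k and return f̃."""
    regressor = np.asarray(regressor, dtype=float)
    if regressor.ndim == 1:
        if regressor.size != n_genes:
            raise ValueError("regressor row length must equal n_genes")
        return regressor
    if regressor.shape == (n_genes, n_genes * n_genes):
        return regressor[0, :n_genes].copy()
    raise ValueError("regressor must be a length-N row or an N x N^2 matrix")


def kf_param_step(
    belief: ParameterBelief,
    y_k: np.ndarray,
    regressor,
    sigma_e2: float,
    context: str = "",
) -> ParameterBelief:
    """One Gauss-Markov predict + Kalman update of the parameter belief.

    Predict leaves the mean unchanged and inflates the covariance by the
    walk variance; update conditions on ``y_k = R_k b + e`` with effective
    noise variance ``sigma_e2``.
    """
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    y_k = np.asarray(y_k, dtype=float)
    n = belief.n_genes
    if y_k.shape != (n,):
        raise ValueError("observation dimension does not match parameter belief")
    f = _regressor_row(regressor, n)

    if belief.decoupled:
        P = belief.covariance + belief.walk_variance * np.eye(n)  # (N, N, N)
        means = belief.mean.reshape(n, n)
        Pf = P @ f  # (N, N): block b times f
        s = Pf @ f + sigma_e2  # (N,)
        u = y_k - means @ f
        if not np.all(np.isfinite(u)):
            raise NumericalError(f"non-finite innovation {context}".strip())
        gains = Pf / s[:, None]
        new_means = means + gains * u[:, None]
        new_P = P - np.einsum("bi,bj->bij", gains, Pf)
        return ParameterBelief(
            new_means.ravel(), _symmetrize(new_P), True, belief.walk_variance
        )

    P = belief.covariance + belief.walk_variance * np.eye(n * n)
    R = np.kron(np.eye(n), f[None, :])
    u = y_k - R @ belief.mean
    if not np.all(np.isfinite(u)):
        raise NumericalError(f"non-finite innovation {context}".strip())
    S = R @ P @ R.T + sigma_e2 * np.eye(n)
    K = P @ R.T @ np.linalg.inv(S)
    mean = belief.mean + K @ u
    P_new = (np.eye(n * n) - K @ R) @ P
    return ParameterBelief(mean, _symmetrize(P_new), False, belief.walk_variance)


def pm_iterations(belief: ParameterBelief, config: PMConfig) -> ParameterBelief:
    """Apply K_tau pseudo-measurement sparsity iterations.

    Each iteration treats ``0 = sign(b)^T b`` (i.e. the l1 norm) as a scalar
    measurement with noise variance sigma_eps2 and performs a Kalman update,
    which shrinks every component against its own uncertainty.  ``sign(0)``
    is 0, so exact zeros are left untouched and a zero vector is a fixed
    point.
    """
    if config.n_iterations == 0:
        return belief
    n = belief.n_genes

    if belief.decoupled:
        means = belief.mean.reshape(n, n).copy()
        P = belief.covariance.copy()
        for _ in range(config.n_iterations):
            s = np.sign(means)  # (N, N) sign rows per block
            Ps = np.einsum("bij,bj->bi", P, s)  # block_b @ sign_b
            denom = float(np.einsum("bi,bi->", Ps, s)) + config.sigma_eps2
            l1 = float(np.einsum("bi,bi->", s, means))
            means -= Ps * (l1 / denom)
            P -= np.einsum("bi,bj->bij", Ps, Ps) / denom
            P = _symmetrize(P)
        return ParameterBelief(means.ravel(), P, True, belief.walk_variance)

    mean = belief.mean.copy()
    P = belief.covariance.copy()
    for _ in range(config.n_iterations):
        s = np.sign(mean)
        Ps = P @ s
        denom = float(s @ Ps) + config.sigma_eps2
        K = Ps / denom
        mean = mean - K * (s @ mean)
        P = P - np.outer(K, Ps)
        P = _symmetrize(P)
    return ParameterBelief(mean, P, False, belief.walk_variance)


def select_Ktau(expected_edges, n_genes: int) -> int:
    """Number of PM iterations: the expected number of nonzero weights.

    ``"auto"`` falls back to ``2 * n_genes``, a typical edge count for
    sparse regulatory networks.
    """
    if expected_edges == "auto":
        return int(round(2 * n_genes))
    expected_edges = int(expected_edges)
    if expected_edges < 0:
        raise ValueError("expected_edges must be nonnegative")
    return expected_edges
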