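"""Extended Kalman filter baseline with joint state-parameter estimation.

The comparator stacks the hidden states and all N^2 weights into one
augmented vector ``z = [x; b]`` and runs a single EKF over the joint
transition

    x_k = B f(x_{k-1}) + w_k,      b_k = b_{k-1} + eta_k,

linearized at the current estimate.  The Jacobian has the closed form

    d x_k / d x_{k-1} = B diag(f(x)(1 - f(x))),
    d x_{k,n} / d phi_n = [f(x_1), ..., f(x_N)]      (block diagonal),

with an identity block for the parameters, and the measurement observes the
state block directly.  No sparsity constraint is applied — this is the
plain joint-estimation baseline the dual CKFS algorithm is compared to.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .ckf import GaussianBelief, _symmetrize
from .exceptions import NumericalError
from .inference import InferenceConfig, NetworkEstimate, _as_timeseries, _standardized
from .model import TimeSeriesData, sigmoid, unstack_parameters

__all__ = ["EKF", "ekf_infer", "joint_transition", "joint_jacobian"]


def joint_transition(z: np.ndarray, n: int) -> np.ndarray:
    """One step of the augmented dynamics [x; b] -> [B f(x); b]."""
    x, b = z[:n], z[n:]
    B = unstack_parameters(b, n)
    out = z.copy()
    out[:n] = B @ sigmoid(x)
    return out


def joint_jacobian(z: np.ndarray, n: int) -> np.ndarray:
    """Jacobian of :func:`joint_transition` at z."""
    x, b = z[:n], z[n:]
    B = unstack_parameters(b, n)
    f = sigmoid(x)
    J = np.eye(n + n * n)
    J[:n, :n] = B * (f * (1.0 - f))[None, :]
    J[:n, n:] = np.kron(np.eye(n), f[None, :])
    return J


def ekf_infer(data, config: InferenceConfig | None = None, **kwargs) -> NetworkEstimate:
    """Joint EKF network inference; same result schema as CKFS."""
    data = _as_timeseries(data)
    config = config or InferenceConfig()
    if kwargs:
        from dataclasses import replace

        config = replace(config, **kwargs)
    return _run_ekf(data, config)


def _run_ekf(data: TimeSeriesData, config: InferenceConfig) -> NetworkEstimate:
    n = data.n_genes
    dim = n + n * n
    for i, s in enumerate(data.series):
        if s.shape[0] < 2:
            raise ValueError(f"series {data.series_ids[i]!r} has fewer than 2 time points")

    Q = np.zeros(dim)
    Q[:n] = config.noise.sigma_w2
    Q[n:] = config.walk_variance
    Q = np.diag(Q)
    S = config.noise.sigma_v2 * np.eye(n)

    # parameter block persists across series, state block restarts
    b_mean = np.zeros(n * n)
    P_bb = config.param_prior_variance * np.eye(n * n)

    trace = []
    state_means = []
    for si, raw in enumerate(data.series):
        series = _standardized(raw) if config.standardize else raw
        K = series.shape[0]
        z = np.concatenate([series[0], b_mean])
        P = np.zeros((dim, dim))
        P[:n, :n] = config.state_prior_variance * np.eye(n)
        P[n:, n:] = P_bb
        means = [z[:n].copy()]
        for k in range(1, K):
            ctx = f"(series {data.series_ids[si]!r}, step {k + 1})"
            J = joint_jacobian(z, n)
            z = joint_transition(z, n)
            if not np.all(np.isfinite(z)):
                raise NumericalError(f"non-finite EKF prediction {ctx}")
            P = _symmetrize(J @ P @ J.T + Q)
            # measurement: y = [I 0] z + v
            P_yy = P[:n, :n] + S
            K_G = np.linalg.solve(P_yy, P[:n, :]).T  # (dim, n)
            z = z + K_G @ (series[k] - z[:n])
            P = _symmetrize(P - K_G @ P_yy @ K_G.T)
            means.append(z[:n].copy())
            trace.append(z[n:].copy())
        state_means.append(np.vstack(means))
        b_mean = z[n:].copy()
        P_bb = P[n:, n:].copy()

    weights = unstack_parameters(b_mean, n)
    variances = np.diag(P_bb).reshape(n, n).copy()
    return NetworkEstimate(
        weights_estimate=weights,
        parameter_covariance=variances,
        state_estimates=state_means,
        trace=np.vstack(trace) if trace else np.empty((0, n * n)),
        config=config,
        gene_names=list(data.gene_names),
        method="ekf",
    )


class EKF(BaseEstimator):
    """Joint state-parameter EKF baseline with the scikit-learn estimator
    interface (see :class:`~ckfsnet.inference.CKFS` for attribute
    conventions)."""

    def __init__(
        self,
        sigma_w2: float = 1e-5,
        sigma_v2: float = 1e-5,
        walk_variance: float = 0.0,
        standardize: bool = False,
        state_prior_variance: float = 1.0,
        param_prior_variance: float = 1.0,
    ):
        self.sigma_w2 = sigma_w2
        self.sigma_v2 = sigma_v2
        self.walk_variance = walk_variance
        self.standardize = standardize
        self.state_prior_variance = state_prior_variance
        self.param_prior_variance = param_prior_variance

    def fit(self, X, y=None):
        from .model import NoiseConfig

        data = _as_timeseries(X)
        config = InferenceConfig(
            noise=NoiseConfig(self.sigma_w2, self.sigma_v2),
            k_tau=0,
            pm_schedule="off",
            walk_variance=self.walk_variance,
            standardize=self.standardize,
            state_prior_variance=self.state_prior_variance,
            param_prior_variance=self.param_prior_variance,
        )
        self.estimate_ = _run_ekf(data, config)
        self.weights_ = self.estimate_.weights_estimate
        self.scores_ = np.abs(self.weights_)
        self.n_genes_ = data.n_genes
        self.gene_names_ = list(data.gene_names)
        return self

    def predict(self, X=None):
        if not hasattr(self, "weights_"):
            raise RuntimeError("estimator is not fitted")
        return self.weights_
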