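"""Dual state/parameter estimation: the CKFS network-inference algorithm.

For every observation the algorithm alternates two conditional filters:

1. a cubature Kalman filter propagates the hidden expression state through
   the sigmoid dynamics with the *current* weight estimate frozen, then
   conditions on the new observation;
2. a linear Kalman filter updates the stacked weight vector using the
   regressor built from the *previous filtered state*, followed by the
   pseudo-measurement sparsity iterations.

A single forward pass is made over each series (online estimation).  With
multiple perturbation series the parameter belief is chained across series
in input order while the state belief restarts from each series' first
observation.

Two couplings between the filters deserve note (see docs/methods.md):

* the state filter's process noise is inflated by the current parameter
  uncertainty, ``Q_eff[n] = sigma_w^2 + f^T P_phi_n f`` — while the weights
  are unknown the model prediction is untrustworthy and the observations
  must dominate, otherwise the early state estimates (and hence the
  regressors) inherit the bias of the zero-initialized weights;
* the per-step sparsity refinement is applied to a *copy* of the parameter
  belief: the refined estimate drives the state dynamics and is the
  reported answer, but the Kalman chain continues from its own unrefined
  posterior.  Feeding the PM-shrunk covariance back into the chain
  (``pm_schedule="feedback"``) makes the filter overconfident in the shrunk
  estimate and is kept only as the literal coupled variant.

The public surface is the scikit-learn style estimator :class:`CKFS`
(``fit`` on a time-series matrix or a :class:`~ckfsnet.model.TimeSeriesData`,
fitted attributes ``weights_``, ``scores_``); :func:`infer` is a thin
functional wrapper around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .ckf import GaussianBelief, measurement_update, time_update
from .exceptions import NumericalError
from .model import (
    GeneNetwork,
    NoiseConfig,
    TimeSeriesData,
    sigmoid,
    unstack_parameters,
)
from .sparse_kf import ParameterBelief, PMConfig, kf_param_step, pm_iterations, select_Ktau

__all__ = ["InferenceConfig", "NetworkEstimate", "CKFS", "infer"]


@dataclass
class InferenceConfig:
    """Bag of knobs for the dual-estimation loop."""

    noise: NoiseConfig = field(default_factory=NoiseConfig)
    k_tau: int | str = "auto"
    pm_variance: float = 100.0
    walk_variance: float = 0.0
    pm_schedule: str = "per_step"  # or "final", "feedback", "off"
    decouple: bool | str = "auto"
    standardize: bool = False
    inflate_process_noise: bool = True
    state_prior_variance: float = 1.0
    param_prior_variance: float = 1.0
    seed: Optional[int] = None  # provenance only: the algorithm is deterministic

    def __post_init__(self):
        if self.pm_schedule not in ("per_step", "final", "feedback", "off"):
            raise ValueError("pm_schedule must be 'per_step', 'final', 'feedback' or 'off'")


@dataclass
class NetworkEstimate:
    """Result of a network-inference run."""

    weights_estimate: np.ndarray  # (N, N), entry (n, m) = estimated b_nm
    parameter_covariance: np.ndarray  # marginal variance of each b_nm, (N, N)
    state_estimates: list[np.ndarray]  # filtered state means per series
    trace: np.ndarray  # (total steps, N^2) parameter snapshots
    config: InferenceConfig
    gene_names: list[str]
    method: str = "ckfs"

    @property
    def n_genes(self) -> int:
        return self.weights_estimate.shape[0]

    def ranked_edges(self, include_self_loops: bool = False):
        """Candidate edges (source, target, |b|, sign) sorted by score."""
        n = self.n_genes
        rows = []
        for tgt in range(n):
            for src in range(n):
                if tgt == src and not include_self_loops:
                    continue
                w = self.weights_estimate[tgt, src]
                rows.append((src, tgt, abs(w), 1 if w >= 0 else -1))
        rows.sort(key=lambda r: -r[2])
        return rows


def _as_timeseries(X) -> TimeSeriesData:
    if isinstance(X, TimeSeriesData):
        return X
    if isinstance(X, np.ndarray):
        return TimeSeriesData(series=[X])
    if isinstance(X, (list, tuple)):
        return TimeSeriesData(series=list(X))
    raise TypeError("X must be a TimeSeriesData, a K x N array, or a list of arrays")


class CKFS(BaseEstimator):
    """Sparse gene-network inference by cubature Kalman filtering with a
    compressed-sensing parameter filter.

    Parameters
    ----------
    sigma_w2, sigma_v2 : float
        Assumed process / measurement noise variances of the state-space
        model (the effective regression noise is their sum).
    k_tau : int or "auto"
        Number of pseudo-measurement sparsity iterations per update — the
        expected number of regulatory edges.  "auto" uses ``2 N``.
    pm_variance : float
        Pseudo-noise variance of the sparsity constraint.
    walk_variance : float
        Gauss-Markov random-walk variance of the parameters.  The default 0
        models static regulatory weights; a positive value lets the filter
        track drifting parameters at the cost of re-fitting noise once the
        trajectory has equilibrated.
    pm_schedule : {"per_step", "final", "feedback", "off"}
        "per_step" (default) refines a copy of the belief after every step;
        "final" refines once after the last observation; "feedback" is the
        literal coupled variant that writes the PM result back into the
        filter chain; "off" disables the sparsity stage.
    decouple : bool or "auto"
        Track the parameter covariance as per-gene blocks (exact for the
        filter update, block-truncated for the PM update).  "auto" switches
        it on above 20 genes.
    standardize : bool
        Per-gene z-scoring of each series before filtering (off by default).
    inflate_process_noise : bool
        Add the parameter-uncertainty term ``f^T P_phi_n f`` to the state
        filter's process noise (on by default).

    Attributes
    ----------
    weights_ : (N, N) ndarray
        Estimated regulatory weights, entry (n, m) = effect of gene m on n.
    scores_ : (N, N) ndarray
        ``abs(weights_)`` — the edge-confidence matrix used for ranking.
    estimate_ : NetworkEstimate
        Full result object (covariance, state trajectories, trace).
    """

    def __init__(
        self,
        sigma_w2: float = 1e-5,
        sigma_v2: float = 1e-5,
        k_tau="auto",
        pm_variance: float = 100.0,
        walk_variance: float = 0.0,
        pm_schedule: str = "per_step",
        decouple="auto",
        standardize: bool = False,
        inflate_process_noise: bool = True,
        state_prior_variance: float = 1.0,
        param_prior_variance: float = 1.0,
    ):
        self.sigma_w2 = sigma_w2
        self.sigma_v2 = sigma_v2
        self.k_tau = k_tau
        self.pm_variance = pm_variance
        self.walk_variance = walk_variance
        self.pm_schedule = pm_schedule
        self.decouple = decouple
        self.standardize = standardize
        self.inflate_process_noise = inflate_process_noise
        self.state_prior_variance = state_prior_variance
        self.param_prior_variance = param_prior_variance

    def _config(self) -> InferenceConfig:
        return InferenceConfig(
            noise=NoiseConfig(self.sigma_w2, self.sigma_v2),
            k_tau=self.k_tau,
            pm_variance=self.pm_variance,
            walk_variance=self.walk_variance,
            pm_schedule=self.pm_schedule,
            decouple=self.decouple,
            standardize=self.standardize,
            inflate_process_noise=self.inflate_process_noise,
            state_prior_variance=self.state_prior_variance,
            param_prior_variance=self.param_prior_variance,
        )

    def fit(self, X, y=None):
        """Run the dual-estimation pass over one or more time series."""
        data = _as_timeseries(X)
        config = self._config()
        self.estimate_ = _run_ckfs(data, config)
        self.weights_ = self.estimate_.weights_estimate
        self.scores_ = np.abs(self.weights_)
        self.n_genes_ = data.n_genes
        self.gene_names_ = list(data.gene_names)
        return self

    def predict(self, X=None):
        """Return the estimated weight matrix (N x N)."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("estimator is not fitted")
        return self.weights_


def _standardized(series: np.ndarray) -> np.ndarray:
    mu = series.mean(axis=0)
    sd = series.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (series - mu) / sd


def _run_ckfs(data: TimeSeriesData, config: InferenceConfig) -> NetworkEstimate:
    n = data.n_genes
    for i, s in enumerate(data.series):
        if s.shape[0] < 2:
            raise ValueError(f"series {data.series_ids[i]!r} has fewer than 2 time points")

    k_tau = select_Ktau(config.k_tau, n)
    pm = PMConfig(n_iterations=k_tau, sigma_eps2=config.pm_variance)
    run_pm = config.pm_schedule != "off" and k_tau > 0

    param = ParameterBelief.initial(
        n, decoupled=config.decouple, walk_variance=config.walk_variance,
        prior_variance=config.param_prior_variance,
    )
    refined = param
    sigma_e2 = max(config.noise.sigma_e2, 1e-12)

    trace = []
    state_means = []
    for si, raw in enumerate(data.series):
        series = _standardized(raw) if config.standardize else raw
        K = series.shape[0]
        state = GaussianBelief(series[0], config.state_prior_variance * np.eye(n))
        means = [state.mean.copy()]
        prev_mean = state.mean
        for k in range(1, K):
            ctx = f"(series {data.series_ids[si]!r}, step {k + 1})"
            B = GeneNetwork(unstack_parameters(refined.mean, n))
            if config.inflate_process_noise:
                f_now = sigmoid(state.mean)
                blocks = param.covariance_blocks()
                Q = np.diag(
                    config.noise.sigma_w2
                    + np.einsum("i,bij,j->b", f_now, blocks, f_now)
                )
            else:
                Q = config.noise.sigma_w2 * np.eye(n)
            predicted = time_update(state, B, Q, context=ctx)
            state = measurement_update(predicted, series[k], config.noise, context=ctx)
            param = kf_param_step(param, series[k], sigmoid(prev_mean), sigma_e2, context=ctx)
            if run_pm and config.pm_schedule == "per_step":
                refined = pm_iterations(param, pm)
            elif run_pm and config.pm_schedule == "feedback":
                param = pm_iterations(param, pm)
                refined = param
            else:
                refined = param
            prev_mean = state.mean
            means.append(state.mean.copy())
            trace.append(refined.mean.copy())
        state_means.append(np.vstack(means))

    if run_pm and config.pm_schedule == "final":
        refined = pm_iterations(param, pm)
        if trace:
            trace[-1] = refined.mean.copy()

    weights = unstack_parameters(refined.mean, n)
    variances = refined.covariance_diagonal().reshape(n, n)
    return NetworkEstimate(
        weights_estimate=weights,
        parameter_covariance=variances,
        state_estimates=state_means,
        trace=np.vstack(trace) if trace else np.empty((0, n * n)),
        config=config,
        gene_names=list(data.gene_names),
        method="ckfs",
    )


def infer(data, config: InferenceConfig | None = None, **kwargs) -> NetworkEstimate:
    """Functional wrapper: run CKFS inference on a time-series data set.

    Keyword arguments override fields of ``config`` (see
    :class:`InferenceConfig`).
    """
    data = _as_timeseries(data)
    config = config or InferenceConfig()
    if kwargs:
        from dataclasses import replace

        config = replace(config, **kwargs)
    return _run_ckfs(data, config)
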