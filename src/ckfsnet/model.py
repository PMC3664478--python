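"""Discrete state-space model of gene regulation and synthetic data generation.

The hidden expression level of gene ``n`` evolves as

    x[k, n] = sum_m  b[n, m] * f(x[k-1, m]) + w[k, n]

where ``f`` is the logistic sigmoid and ``w ~ N(0, sigma_w^2 I)`` is process
noise; the observed expression is ``y[k] = x[k] + v[k]`` with measurement
noise ``v ~ N(0, sigma_v^2 I)``.  The weight ``b[n, m]`` quantifies how gene
``m`` regulates gene ``n`` — positive for activation, negative for
repression, zero for no interaction.  Because the dynamics are linear in the
weights, each observation can be rewritten as ``y[k] = R_k b + e[k]`` with a
block-diagonal regressor ``R_k`` built from the sigmoid-squashed previous
state, and an effective noise ``e`` of variance ``sigma_w^2 + sigma_v^2``;
that linear-in-parameters form is what the parameter filter and the
Cramér–Rao bound operate on.

The flattening convention is fixed here once and reused everywhere: the
stacked parameter vector is ``b = weights.ravel()`` (row-major, grouped by
target gene), so ``b[n*N + m] == weights[n, m]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "GeneNetwork",
    "NoiseConfig",
    "TimeSeriesData",
    "sigmoid",
    "generate_network",
    "simulate",
    "build_regressor",
    "stack_parameters",
    "unstack_parameters",
]


def sigmoid(x):
    """Logistic squash ``1 / (1 + exp(-x))``, elementwise.

    Numerically stable for the whole double range; raises ``ValueError`` on
    non-finite input.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("sigmoid: input must be finite")
    out = expit(arr)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def stack_parameters(weights: np.ndarray) -> np.ndarray:
    """Flatten an N x N weight matrix into the stacked parameter vector b."""
    weights = np.asarray(weights, dtype=float)
    return weights.ravel()


def unstack_parameters(b: np.ndarray, n_genes: int) -> np.ndarray:
    """Inverse of :func:`stack_parameters`."""
    b = np.asarray(b, dtype=float)
    if b.size != n_genes * n_genes:
        raise ValueError(f"parameter vector has size {b.size}, expected {n_genes ** 2}")
    return b.reshape(n_genes, n_genes)


@dataclass
class GeneNetwork:
    """A directed, weighted gene regulatory network.

    ``weights[n, m]`` is the effect of gene ``m`` on gene ``n``.
    """

    weights: np.ndarray
    gene_names: list[str] | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        n = self.weights.shape[0]
        if self.gene_names is None:
            self.gene_names = [f"G{i + 1}" for i in range(n)]
        self.gene_names = list(self.gene_names)
        if len(self.gene_names) != n:
            raise ValueError("gene_names length must match weights")
        if len(set(self.gene_names)) != n:
            raise ValueError("gene_names must be unique")

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights))

    def edge_set(self, include_self_loops: bool = True) -> set[tuple[int, int]]:
        """Directed edges as ``(source, target)`` index pairs.

        An edge (m, n) means gene m regulates gene n, i.e. ``weights[n, m] != 0``.
        """
        targets, sources = np.nonzero(self.weights)
        edges = {
            (int(m), int(n))
            for n, m in zip(targets, sources)
            if include_self_loops or n != m
        }
        return edges

    def parameter_vector(self) -> np.ndarray:
        return stack_parameters(self.weights)


@dataclass
class NoiseConfig:
    """Process and measurement noise variances (both isotropic)."""

    sigma_w2: float = 1e-5
    sigma_v2: float = 1e-5

    def __post_init__(self):
        if self.sigma_w2 < 0 or self.sigma_v2 < 0:
            raise ValueError("noise variances must be nonnegative")

    @property
    def sigma_e2(self) -> float:
        """Effective-noise variance of the linear-in-parameters observation."""
        return self.sigma_w2 + self.sigma_v2


@dataclass
class TimeSeriesData:
    """One or more observed expression series over a common gene set.

    Each entry of ``series`` is a ``K_s x N`` matrix (time points by genes).
    ``true_states`` and ``initial_states`` are populated by the simulator
    only and carry the noise-free hidden trajectory and the initial condition
    that produced each series.
    """

    series: list[np.ndarray]
    true_states: list[np.ndarray] | None = None
    series_ids: list[str] | None = None
    initial_states: list[np.ndarray] | None = None
    gene_names: list[str] | None = None

    def __post_init__(self):
        self.series = [np.asarray(s, dtype=float) for s in self.series]
        if not self.series:
            raise ValueError("at least one series is required")
        n = self.series[0].shape[1]
        for s in self.series:
            if s.ndim != 2 or s.shape[1] != n:
                raise ValueError("all series must share the same number of genes")
        if self.series_ids is None:
            self.series_ids = [f"S{i + 1}" for i in range(len(self.series))]
        if len(self.series_ids) != len(self.series):
            raise ValueError("series_ids length must match series")
        if self.gene_names is None:
            self.gene_names = [f"G{i + 1}" for i in range(n)]
        if len(self.gene_names) != n:
            raise ValueError("gene_names length must match series width")

    @property
    def n_genes(self) -> int:
        return self.series[0].shape[1]

    @property
    def n_series(self) -> int:
        return len(self.series)


def generate_network(
    n_genes: int,
    n_edges: int,
    weight_magnitude_range: tuple[float, float] = (0.5, 1.5),
    sign_mix: float = 0.5,
    allow_self_loops: bool = False,
    seed=None,
    gene_names: list[str] | None = None,
) -> GeneNetwork:
    """Sample a random sparse directed network.

    Edge positions are drawn uniformly without replacement; magnitudes are
    uniform in ``weight_magnitude_range``; each edge is positive (activating)
    with probability ``sign_mix``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    capacity = n_genes * n_genes if allow_self_loops else n_genes * (n_genes - 1)
    if not 0 <= n_edges <= capacity:
        raise ValueError(
            f"n_edges={n_edges} outside [0, {capacity}] for n_genes={n_genes}, "
            f"allow_self_loops={allow_self_loops}"
        )
    lo, hi = weight_magnitude_range
    if not 0 <= lo <= hi:
        raise ValueError("weight_magnitude_range must satisfy 0 <= lo <= hi")
    if not 0 <= sign_mix <= 1:
        raise ValueError("sign_mix must be in [0, 1]")

    rng = np.random.default_rng(seed)
    flat = np.arange(n_genes * n_genes)
    if not allow_self_loops:
        flat = flat[flat // n_genes != flat % n_genes]
    chosen = rng.choice(flat, size=n_edges, replace=False)
    magnitudes = rng.uniform(lo, hi, size=n_edges)
    signs = np.where(rng.random(n_edges) < sign_mix, 1.0, -1.0)

    weights = np.zeros(n_genes * n_genes)
    weights[chosen] = magnitudes * signs
    return GeneNetwork(weights.reshape(n_genes, n_genes), gene_names=gene_names)


def simulate(
    network: GeneNetwork,
    n_steps: int,
    noise: NoiseConfig | None = None,
    x0: np.ndarray | None = None,
    seed=None,
    n_series: int = 1,
) -> TimeSeriesData:
    """Simulate noisy expression time series from a network.

    Each series starts from ``x0`` (drawn uniform in [-1, 1] per gene when not
    given) and iterates the sigmoid dynamics for ``n_steps`` steps; the
    returned matrices hold ``x_1 .. x_K`` (the initial condition is kept
    separately in ``initial_states``).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    noise = noise or NoiseConfig()
    n = network.n_genes
    if x0 is not None:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (n,):
            raise ValueError(f"x0 has shape {x0.shape}, expected ({n},)")
    rng = np.random.default_rng(seed)

    series, states, inits = [], [], []
    sw = np.sqrt(noise.sigma_w2)
    sv = np.sqrt(noise.sigma_v2)
    for _ in range(n_series):
        start = rng.uniform(-1.0, 1.0, size=n) if x0 is None else x0.copy()
        w = rng.normal(0.0, 1.0, size=(n_steps, n)) * sw
        v = rng.normal(0.0, 1.0, size=(n_steps, n)) * sv
        x = np.empty((n_steps, n))
        prev = start
        for k in range(n_steps):
            prev = network.weights @ expit(prev) + w[k]
            x[k] = prev
        states.append(x)
        series.append(x + v)
        inits.append(start)

    return TimeSeriesData(
        series=series,
        true_states=states,
        initial_states=inits,
        gene_names=list(network.gene_names),
        series_ids=[f"S{i + 1}" for i in range(n_series)],
    )


def build_regressor(x_prev: np.ndarray) -> np.ndarray:
    """Block-diagonal regressor R_k mapping the stacked parameter vector to
    the predicted observation: ``R_k @ b == weights @ sigmoid(x_prev)``.

    Row ``n`` holds the sigmoid-squashed previous state in the columns of
    gene ``n``'s parameter block and structural zeros elsewhere.
    """
    x_prev = np.asarray(x_prev, dtype=float)
    if x_prev.ndim != 1:
        raise ValueError("x_prev must be a vector")
    f_row = sigmoid(x_prev)
    n = x_prev.size
    return np.kron(np.eye(n), f_row[None, :])
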