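"""Fisher information and Cramér–Rao lower bound for the network weights.

Conditional on the hidden state trajectory, every observation is linear in
the stacked weight vector, ``y = R b + e`` with isotropic Gaussian effective
noise of variance ``sigma_e2``, so the Fisher information matrix is simply
``R^T R / sigma_e2``.  Because the regressor is block diagonal with the same
squashed-state row in each block, the FIM is block diagonal with N identical
N x N blocks ``sum_k f̃_k^T f̃_k / sigma_e2`` — only one block is ever
computed or inverted.  The diagonal of the inverse lower-bounds the MSE of
any unbiased estimator of each weight.

The regressor rows mirror what the inference filters actually use: state
``x_k`` predicts observation ``k+1``, so a series of K points contributes
K - 1 rows and the initial condition is not counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import NoiseConfig, TimeSeriesData, sigmoid

__all__ = ["FisherResult", "CRBResult", "fisher_information", "crb_bound", "mse_crb_experiment"]


@dataclass
class FisherResult:
    """Fisher information for the stacked weight vector.

    ``block`` is the shared N x N diagonal block; the full N^2 x N^2 matrix
    is ``kron(I_N, block)`` and is materialized on demand only.
    """

    block: np.ndarray
    n_genes: int
    n_rows: int  # stacked regressor rows per gene
    sigma_e2: float

    @property
    def fim(self) -> np.ndarray:
        return np.kron(np.eye(self.n_genes), self.block)

    @property
    def rank(self) -> int:
        return self.n_genes * int(np.linalg.matrix_rank(self.block))


@dataclass
class CRBResult:
    """Per-parameter lower bounds (stacked order) with identifiability flags."""

    bounds: np.ndarray  # (N^2,)
    unidentifiable: np.ndarray  # (N^2,) bool

    def as_matrix(self, n_genes: int) -> np.ndarray:
        return self.bounds.reshape(n_genes, n_genes)


def _state_matrices(states) -> list[np.ndarray]:
    if isinstance(states, TimeSeriesData):
        if states.true_states is None:
            raise ValueError("TimeSeriesData carries no true states")
        return states.true_states
    if isinstance(states, np.ndarray):
        return [states]
    return [np.asarray(s, dtype=float) for s in states]


def fisher_information(states, sigma_e2: float) -> FisherResult:
    """FIM of the weights given true state trajectories.

    ``states`` may be a K x N state matrix, a list of them, or simulator
    output (whose ``true_states`` are used).
    """
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    mats = _state_matrices(states)
    if not mats or any(m.shape[0] < 1 for m in mats):
        raise ValueError("at least one time step is required")
    n = mats[0].shape[1]
    block = np.zeros((n, n))
    rows = 0
    for m in mats:
        F = sigmoid(np.atleast_2d(m[:-1]))  # states 1..K-1 predict 2..K
        if F.shape[0] == 0:
            continue
        block += F.T @ F
        rows += F.shape[0]
    if rows == 0:
        raise ValueError("series too short: no regressor rows")
    return FisherResult(block=block / sigma_e2, n_genes=n, n_rows=rows, sigma_e2=sigma_e2)


def crb_bound(fisher: FisherResult, rcond: float = 1e-12) -> CRBResult:
    """Diagonal of the inverse FIM, blockwise.

    A rank-deficient block is pseudo-inverted and the parameters whose
    regressor direction carries (numerically) no information are flagged
    unidentifiable rather than raising.
    """
    block = fisher.block
    n = fisher.n_genes
    eigval, eigvec = np.linalg.eigh(block)
    tol = max(eigval.max(), 0.0) * rcond
    informative = eigval > tol
    inv_eig = np.where(informative, 1.0 / np.where(informative, eigval, 1.0), 0.0)
    pinv = (eigvec * inv_eig) @ eigvec.T
    diag = np.diag(pinv).copy()
    # a parameter is unidentifiable if its axis has weight in the null space
    null_mass = (eigvec[:, ~informative] ** 2).sum(axis=1) if (~informative).any() else np.zeros(n)
    flags = null_mass > rcond
    bounds = np.tile(diag, n)
    unident = np.tile(flags, n)
    return CRBResult(bounds=bounds, unidentifiable=unident)


def mse_crb_experiment(
    n_genes: int = 8,
    n_edges: int = 20,
    sample_sizes=(20, 50, 100),
    n_trials: int = 50,
    noise: NoiseConfig | None = None,
    k_tau: int | None = None,
    seed: int = 0,
):
    """Monte-Carlo MSE of the CKFS weight estimates versus the CRB.

    For each trial a random sparse network is drawn, a trajectory of the
    largest requested length is simulated, and the CKFS estimate and the
    CRB diagonal are evaluated on each prefix length.  Returns a dict
    ``{K: {"mse": mean squared error over weights and trials,
    "crb": mean CRB diagonal over weights and trials}}``.
    """
    from .inference import CKFS
    from .model import generate_network, simulate

    noise = noise or NoiseConfig()
    if k_tau is None:
        k_tau = n_edges
    sample_sizes = sorted(sample_sizes)
    K_max = sample_sizes[-1]
    rng = np.random.default_rng(seed)

    out = {K: {"mse": 0.0, "crb": 0.0} for K in sample_sizes}
    for _ in range(n_trials):
        net_seed, sim_seed = rng.integers(0, 2**31 - 1, size=2)
        network = generate_network(n_genes, n_edges, seed=int(net_seed))
        data = simulate(network, K_max, noise=noise, seed=int(sim_seed))
        b_true = network.parameter_vector()
        for K in sample_sizes:
            prefix = TimeSeriesData(
                series=[data.series[0][:K]],
                true_states=[data.true_states[0][:K]],
                gene_names=data.gene_names,
            )
            est = CKFS(
                sigma_w2=noise.sigma_w2, sigma_v2=noise.sigma_v2, k_tau=k_tau
            ).fit(prefix)
            err = est.weights_.ravel() - b_true
            out[K]["mse"] += float(np.mean(err**2)) / n_trials
            fr = fisher_information(prefix.true_states[0], noise.sigma_e2)
            crb = crb_bound(fr)
            out[K]["crb"] += float(np.mean(crb.bounds)) / n_trials
    return out
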