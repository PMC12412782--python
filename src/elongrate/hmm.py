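"""Two-state Gaussian-emission HMM baseline for transition-point calling.

Fitted by Baum-Welch (scaled forward-backward EM) and decoded by Viterbi.
State 0 is the lower-mean (depleted) state after relabeling; a valid
transition pointer is the length of the leading depleted block when the
decoded path starts depleted and switches exactly toward the occupied state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HmmParams",
    "default_init",
    "baum_welch",
    "forward_backward",
    "state_posteriors",
    "viterbi",
    "hmm_transition_point",
]

VAR_FLOOR = 1e-6


@dataclass
class HmmParams:
    means: np.ndarray
    variances: np.ndarray
    transition_matrix: np.ndarray
    initial_probs: np.ndarray
    log_likelihood: float = float("-inf")
    n_iterations: int = 0
    converged: bool = False
    loglik_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.maximum(np.asarray(self.variances, dtype=float), VAR_FLOOR)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.initial_probs.sum(), 1.0, atol=1e-9):
            raise ValueError("initial probabilities must sum to 1")


def default_init(values: np.ndarray) -> HmmParams:
    """Percentile-based starting point: state means at the 25th/75th
    percentiles, shared variance, sticky transitions."""
    v = np.asarray(values, dtype=float)
    means = np.percentile(v, [25.0, 75.0])
    if means[1] - means[0] < 1e-12:
        # quartiles coincide (short depleted block); break symmetry at range
        means = np.array([float(v.min()), float(v.max())])
    var = max(float(np.var(v)), VAR_FLOOR)
    return HmmParams(
        means=means,
        variances=np.array([var, var]),
        transition_matrix=np.array([[0.9, 0.1], [0.1, 0.9]]),
        initial_probs=np.array([0.5, 0.5]),
    )


def _emission_probs(values: np.ndarray, params: HmmParams) -> np.ndarray:
    """B[t, i] = N(values[t]; mean_i, var_i), floored away from exact zero."""
    v = values[:, None]
    var = params.variances[None, :]
    b = np.exp(-0.5 * (v - params.means[None, :]) ** 2 / var) / np.sqrt(2 * np.pi * var)
    return np.maximum(b, 1e-300)


def forward_backward(values: np.ndarray, params: HmmParams):
    """Scaled forward-backward pass.

    Returns (log_likelihood, gamma, xi_sum) where gamma[t, i] is the state
    posterior at position t and xi_sum[i, j] the expected transition counts.
    """
    v = np.asarray(values, dtype=float)
    T = v.size
    B = _emission_probs(v, params)
    A = params.transition_matrix
    alpha = np.zeros((T, 2))
    scale = np.zeros(T)
    alpha[0] = params.initial_probs * B[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta = np.zeros((T, 2))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((2, 2))
    for t in range(T - 1):
        xi = alpha[t][:, None] * A * (B[t + 1] * beta[t + 1])[None, :] / scale[t + 1]
        xi_sum += xi
    return float(np.log(scale).sum()), gamma, xi_sum


def state_posteriors(values: np.ndarray, params: HmmParams) -> np.ndarray:
    """Per-position state posterior probabilities (rows sum to 1)."""
    return forward_backward(values, params)[1]


def baum_welch(
    values: np.ndarray,
    init: HmmParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> HmmParams:
    """EM fit of the 2-state Gaussian HMM.

    Degenerate input (all values identical) returns ``converged=False`` and
    callers treat the gene as a no-call. On exit states are relabeled so
    state 0 has the smaller mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 observations to fit the HMM")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    params = default_init(v) if init is None else init
    if np.ptp(v) == 0:
        params.converged = False
        return params

    prev_ll = -np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, gamma, xi_sum = forward_backward(v, params)
        history.append(ll)
        occ = np.maximum(gamma.sum(axis=0), 1e-12)
        means = (gamma * v[:, None]).sum(axis=0) / occ
        variances = np.maximum(
            (gamma * (v[:, None] - means[None, :]) ** 2).sum(axis=0) / occ, VAR_FLOOR
        )
        row_tot = xi_sum.sum(axis=1, keepdims=True)
        A = np.where(row_tot > 0, xi_sum / np.maximum(row_tot, 1e-300), 0.5)
        A = A / A.sum(axis=1, keepdims=True)
        pi = gamma[0] / gamma[0].sum()
        params = HmmParams(means, variances, A, pi)
        if ll - prev_ll < tol and it > 1:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    # relabel so state 0 is the depleted (lower-mean) state
    if params.means[0] > params.means[1]:
        order = np.array([1, 0])
        params = HmmParams(
            params.means[order],
            params.variances[order],
            params.transition_matrix[np.ix_(order, order)],
            params.initial_probs[order],
        )
    params.log_likelihood = prev_ll
    params.n_iterations = it
    params.converged = converged
    params.loglik_history = history
    return params


def viterbi(values: np.ndarray, params: HmmParams) -> np.ndarray:
    """Most probable state path (0 = depleted, 1 = occupied) in log space."""
    v = np.asarray(values, dtype=float)
    T = v.size
    logB = np.log(_emission_probs(v, params))
    logA = np.log(np.maximum(params.transition_matrix, 1e-300))
    logpi = np.log(np.maximum(params.initial_probs, 1e-300))
    delta = np.zeros((T, 2))
    back = np.zeros((T, 2), dtype=int)
    delta[0] = logpi + logB[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta[t] = cand[back[t], [0, 1]] + logB[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def hmm_transition_point(
    values: np.ndarray, tol: float = 1e-6, max_iter: int = 1000
) -> tuple[int | None, bool]:
    """Fit, decode, and return the depleted->occupied switch pointer.

    The pointer is the last index (1-based) of the leading depleted block so
    segments [1..p] / [p+1..L] align with the SS-scan semantics. Invalid
    (``None, False``) when EM degenerates, the path does not start depleted,
    or it never switches.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 observations")
    params = baum_welch(v, tol=tol, max_iter=max_iter)
    if not params.converged:
        return None, False
    path = viterbi(v, params)
    if path[0] != 0:
        return None, False
    switches = np.nonzero(np.diff(path) == 1)[0]
    if switches.size == 0:
        return None, False
    return int(switches[0]) + 1, True
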