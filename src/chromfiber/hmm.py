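"""Two-state HMM binarization of m6dA probability tracks into footprints.

Per-adenine methylation probabilities are thresholded into binary
methylated/unmethylated calls and modeled with a two-state hidden Markov
chain over adenine positions: an *accessible* state with a high Bernoulli
emission probability and an *inaccessible* (protein-protected) state with a
low one.  The chain is homogeneous in adenine index; physical distances
re-enter when decoded state runs are converted to nucleotide spans.

Parameters are estimated by Baum-Welch (EM) and molecules are decoded with
Viterbi.  Maximal inaccessible runs become footprints; the footprint span
extends from the midpoint between the run's first inaccessible adenine and
the preceding accessible adenine to the symmetric midpoint on the right,
clipped at the fiber edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _field

import numpy as np
from numba import njit

ACCESSIBLE = 0
INACCESSIBLE = 1

_EPS = 1e-12


@dataclass
class HmmParams:
    """Two-state chain: index 0 = accessible, 1 = inaccessible.

    ``p_emit[s]`` is the per-state Bernoulli probability of an adenine being
    called methylated; identifiability requires
    ``p_emit[ACCESSIBLE] > p_emit[INACCESSIBLE]``.
    """

    p_init: np.ndarray = _field(default_factory=lambda: np.array([0.5, 0.5]))
    p_trans: np.ndarray = _field(
        default_factory=lambda: np.array([[0.95, 0.05], [0.05, 0.95]])
    )
    p_emit: np.ndarray = _field(default_factory=lambda: np.array([0.8, 0.1]))

    def __post_init__(self) -> None:
        self.p_init = np.asarray(self.p_init, dtype=np.float64)
        self.p_trans = np.asarray(self.p_trans, dtype=np.float64)
        self.p_emit = np.asarray(self.p_emit, dtype=np.float64)

    def validate(self) -> None:
        if not np.allclose(self.p_trans.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.p_init.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")
        if not self.p_emit[ACCESSIBLE] > self.p_emit[INACCESSIBLE]:
            raise ValueError("accessible emission must exceed inaccessible emission")


@dataclass
class Footprint:
    """A maximal inaccessible (unmethylated) run on one fiber."""

    molecule_id: str
    start_offset: int
    end_offset: int
    n_adenines_spanned: int

    @property
    def length_nt(self) -> int:
        return self.end_offset - self.start_offset


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary methylated calls: probability strictly above threshold."""
    return (np.asarray(probs) > threshold).astype(np.int8)


def fraction_methylated(fiber, threshold: float = 0.5) -> float:
    if len(fiber.m6da_prob) == 0:
        return float("nan")
    return float(binarize(fiber.m6da_prob, threshold).mean())


def is_unmethylated(fiber, min_fraction: float = 0.05, threshold: float = 0.5) -> bool:
    """Flag fibers whose methylated-call fraction is below ``min_fraction``;
    such molecules carry no usable accessibility signal and are excluded
    from clustering downstream."""
    frac = fraction_methylated(fiber, threshold)
    return bool(np.isnan(frac) or frac < min_fraction)


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fb_core(obs, p_init, A, B):  # pragma: no cover - exercised via fit_hmm
    """Scaled forward-backward sufficient statistics for one sequence.

    Returns (gamma0, gamma_sum, meth_sum, xi_sum, loglik).
    """
    T = obs.shape[0]
    alpha = np.empty((T, 2))
    scale = np.empty(T)
    for s in range(2):
        alpha[0, s] = p_init[s] * B[obs[0], s]
    scale[0] = alpha[0, 0] + alpha[0, 1]
    alpha[0] /= scale[0]
    for t in range(1, T):
        for j in range(2):
            alpha[t, j] = (alpha[t - 1, 0] * A[0, j] + alpha[t - 1, 1] * A[1, j]) * B[obs[t], j]
        scale[t] = alpha[t, 0] + alpha[t, 1]
        alpha[t] /= scale[t]
    beta = np.empty((T, 2))
    beta[T - 1, 0] = 1.0
    beta[T - 1, 1] = 1.0
    gamma0 = np.zeros(2)
    gamma_sum = np.zeros(2)
    meth_sum = np.zeros(2)
    xi_sum = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        for i in range(2):
            beta[t, i] = (
                A[i, 0] * B[obs[t + 1], 0] * beta[t + 1, 0]
                + A[i, 1] * B[obs[t + 1], 1] * beta[t + 1, 1]
            ) / scale[t + 1]
        xi_tot = 0.0
        xi = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                xi[i, j] = alpha[t, i] * A[i, j] * B[obs[t + 1], j] * beta[t + 1, j] / scale[t + 1]
                xi_tot += xi[i, j]
        for i in range(2):
            for j in range(2):
                xi_sum[i, j] += xi[i, j] / xi_tot
    for t in range(T):
        g0 = alpha[t, 0] * beta[t, 0]
        g1 = alpha[t, 1] * beta[t, 1]
        tot = g0 + g1
        g0 /= tot
        g1 /= tot
        if t == 0:
            gamma0[0] = g0
            gamma0[1] = g1
        gamma_sum[0] += g0
        gamma_sum[1] += g1
        if obs[t] == 1:
            meth_sum[0] += g0
            meth_sum[1] += g1
    loglik = 0.0
    for t in range(T):
        loglik += np.log(scale[t])
    return gamma0, gamma_sum, meth_sum, xi_sum, loglik


def fit_hmm(
    fibers,
    init: HmmParams | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    threshold: float = 0.5,
) -> tuple[HmmParams, list[float]]:
    """Baum-Welch estimation over a batch of fibers.

    Observations are the binarized per-adenine calls of each fiber with at
    least two adenines.  Returns the fitted parameters (states relabeled so
    the accessible state has the larger emission probability) and the
    per-iteration log-likelihood trace, which is nondecreasing.
    """
    params = init if init is not None else HmmParams()
    params.validate()
    seqs = [binarize(f.m6da_prob, threshold) for f in fibers if len(f.m6da_prob) >= 2]
    if not seqs:
        raise ValueError("fit_hmm needs at least one fiber with >= 2 adenines")
    flat = np.concatenate(seqs)
    if np.all(flat == flat[0]):
        warnings.warn("degenerate input: all observations identical; returning boundary fit")
        p = 1.0 - _EPS if flat[0] == 1 else _EPS
        boundary = HmmParams(
            p_init=params.p_init.copy(),
            p_trans=params.p_trans.copy(),
            p_emit=np.array([p, 1.0 - p]) if flat[0] == 1 else np.array([1.0 - p, p]),
        )
        return _relabel(boundary), []

    history: list[float] = []
    seqs = [np.ascontiguousarray(s, dtype=np.int8) for s in seqs]
    p_init, A, p_emit = params.p_init.copy(), params.p_trans.copy(), params.p_emit.copy()
    for _ in range(max_iter):
        B = np.stack([1.0 - p_emit, p_emit])  # B[obs, state]
        B = np.clip(B, _EPS, None)
        init_acc = np.zeros(2)
        xi_acc = np.zeros((2, 2))
        gamma_acc = np.zeros(2)
        meth_acc = np.zeros(2)
        loglik = 0.0
        for obs in seqs:
            gamma0, gamma_sum, meth_sum, xi, ll = _fb_core(obs, p_init, A, B)
            loglik += ll
            init_acc += gamma0
            xi_acc += xi
            gamma_acc += gamma_sum
            meth_acc += meth_sum
        history.append(loglik)
        p_init = np.clip(init_acc / init_acc.sum(), _EPS, None)
        p_init /= p_init.sum()
        A = xi_acc / np.clip(xi_acc.sum(axis=1, keepdims=True), _EPS, None)
        A = np.clip(A, _EPS, None)
        A /= A.sum(axis=1, keepdims=True)
        p_emit = np.clip(meth_acc / np.clip(gamma_acc, _EPS, None), _EPS, 1 - _EPS)
        if len(history) >= 2 and abs(history[-1] - history[-2]) < tol:
            break
    return _relabel(HmmParams(p_init, A, p_emit)), history


def _relabel(params: HmmParams) -> HmmParams:
    """Enforce the accessible-state emission ordering, swapping labels if needed."""
    if params.p_emit[ACCESSIBLE] >= params.p_emit[INACCESSIBLE]:
        return params
    perm = [1, 0]
    return HmmParams(
        p_init=params.p_init[perm],
        p_trans=params.p_trans[np.ix_(perm, perm)],
        p_emit=params.p_emit[perm],
    )


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


@njit(cache=True)
def _viterbi_core(obs, logpi, logA, logB):  # pragma: no cover - exercised via viterbi
    T = obs.shape[0]
    delta0 = logpi[0] + logB[obs[0], 0]
    delta1 = logpi[1] + logB[obs[0], 1]
    back = np.empty((T, 2), dtype=np.int8)
    for t in range(1, T):
        for j in range(2):
            from_acc = delta0 + logA[0, j]
            from_inacc = delta1 + logA[1, j]
            # >= prefers the inaccessible predecessor on ties
            back[t, j] = 1 if from_inacc >= from_acc else 0
        new0 = (delta1 + logA[1, 0] if back[t, 0] == 1 else delta0 + logA[0, 0]) + logB[obs[t], 0]
        new1 = (delta1 + logA[1, 1] if back[t, 1] == 1 else delta0 + logA[0, 1]) + logB[obs[t], 1]
        delta0, delta1 = new0, new1
    states = np.empty(T, dtype=np.int8)
    states[T - 1] = 1 if delta1 >= delta0 else 0
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states


def viterbi(obs: np.ndarray, params: HmmParams) -> np.ndarray:
    """Most-probable state path; ties broken toward the inaccessible state."""
    obs = np.ascontiguousarray(obs, dtype=np.int8)
    if len(obs) == 0:
        return np.empty(0, dtype=np.int8)
    B = np.clip(np.stack([1.0 - params.p_emit, params.p_emit]), _EPS, None)
    return _viterbi_core(
        obs,
        np.log(np.clip(params.p_init, _EPS, None)),
        np.log(np.clip(params.p_trans, _EPS, None)),
        np.log(B),
    )


def decode_accessibility(fiber, params: HmmParams, threshold: float = 0.5) -> np.ndarray:
    """Viterbi state per adenine position of one fiber (empty for no adenines)."""
    if len(fiber.m6da_prob) == 0:
        return np.empty(0, dtype=np.int8)
    return viterbi(binarize(fiber.m6da_prob, threshold), params)


def call_footprints(fiber, state_path: np.ndarray, min_len: int = 30) -> list[Footprint]:
    """Maximal inaccessible runs converted to nucleotide spans.

    Boundaries fall at the midpoint between the run's outermost inaccessible
    adenine and the neighboring accessible adenine; runs at the fiber edge
    clip to the fiber bounds.  Footprints spanning fewer than ``min_len`` nt
    are discarded.
    """
    a = fiber.a_positions
    if len(state_path) != len(a):
        raise ValueError("state path length must match the fiber's adenine count")
    footprints: list[Footprint] = []
    n = len(a)
    i = 0
    while i < n:
        if state_path[i] != INACCESSIBLE:
            i += 1
            continue
        j = i
        while j + 1 < n and state_path[j + 1] == INACCESSIBLE:
            j += 1
        left = 0 if i == 0 else int(a[i - 1] + a[i] + 1) // 2
        right = fiber.length_nt if j == n - 1 else int(a[j] + a[j + 1] + 1) // 2
        if right - left >= min_len:
            footprints.append(Footprint(fiber.molecule_id, left, right, j - i + 1))
        i = j + 1
    return footprints


def footprint_size_distribution(
    footprints, bin_nt: int = 10, max_len: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of footprint nt sizes; counts sum to the number of footprints."""
    edges = np.arange(0, max_len + bin_nt, bin_nt)
    sizes = np.array([min(fp.length_nt, max_len - 1) for fp in footprints])
    counts, _ = np.histogram(sizes, bins=edges)
    return counts, edges


def accessibility_track(fiber, state_path: np.ndarray) -> np.ndarray | None:
    """Broadcast decoded adenine states to a per-nt binary accessibility track
    (1 = accessible).  Boundaries between adjacent adenines fall at their
    midpoint; the fiber ends inherit the outermost adenine's state.  Returns
    None for fibers without adenines."""
    a = fiber.a_positions
    if len(a) == 0:
        return None
    if len(state_path) != len(a):
        raise ValueError("state path length must match the fiber's adenine count")
    mids = (a[:-1] + a[1:] + 1) // 2
    idx = np.searchsorted(mids, np.arange(fiber.length_nt), side="right")
    return (np.asarray(state_path)[idx] == ACCESSIBLE).astype(np.int8)
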