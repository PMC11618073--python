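"""Hidden-Markov idealization of FRET time series.

Each selected trace is fit with a Gaussian-emission HMM by
maximum-likelihood EM (Baum–Welch) with multiple deterministic
restarts; the number of states is chosen by BIC, and the Viterbi path
gives the idealized (piecewise-constant) trajectory whose per-state
emission means feed the idealized-FRET histograms and the dwell-time
analysis.  ML-EM with BIC stands in for variational-Bayes idealizers
common in the field: it is simpler, reproducible under a seed, and the
kinetic inference downstream rests on the dwell fits, not the
idealizer's posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "HmmModel",
    "clean_states",
    "IdealizedTrace",
    "fit_hmm",
    "select_model",
    "viterbi",
    "idealized_histogram",
]

SD_FLOOR = 0.01  # emission sd floor in FRET units
_TINY = 1e-300


@njit(cache=True)
def _forward_backward(B, logA_dummy, A, pi):
    """Scaled forward-backward. Returns (loglik, gamma, xi_sum, pi_new)."""
    n, k = B.shape
    alpha = np.empty((n, k))
    beta = np.empty((n, k))
    c = np.empty(n)
    # forward
    s = 0.0
    for j in range(k):
        alpha[0, j] = pi[j] * B[0, j]
        s += alpha[0, j]
    if s <= 0.0:
        s = _TINY
    c[0] = s
    for j in range(k):
        alpha[0, j] /= s
    for t in range(1, n):
        s = 0.0
        for j in range(k):
            a = 0.0
            for i in range(k):
                a += alpha[t - 1, i] * A[i, j]
            a *= B[t, j]
            alpha[t, j] = a
            s += a
        if s <= 0.0:
            s = _TINY
        c[t] = s
        for j in range(k):
            alpha[t, j] /= s
    # backward
    for j in range(k):
        beta[n - 1, j] = 1.0
    for t in range(n - 2, -1, -1):
        for i in range(k):
            b = 0.0
            for j in range(k):
                b += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = b / c[t + 1]
    # gamma and xi
    gamma = np.empty((n, k))
    for t in range(n):
        s = 0.0
        for j in range(k):
            g = alpha[t, j] * beta[t, j]
            gamma[t, j] = g
            s += g
        if s <= 0.0:
            s = _TINY
        for j in range(k):
            gamma[t, j] /= s
    xi = np.zeros((k, k))
    for t in range(n - 1):
        for i in range(k):
            for j in range(k):
                xi[i, j] += alpha[t, i] * A[i, j] * B[t + 1, j] * beta[t + 1, j] / c[t + 1]
    loglik = 0.0
    for t in range(n):
        loglik += np.log(c[t])
    return loglik, gamma, xi, gamma[0].copy()


@njit(cache=True)
def _viterbi_path(logB, logA, logpi):
    n, k = logB.shape
    delta = np.empty((n, k))
    psi = np.zeros((n, k), dtype=np.int64)
    for j in range(k):
        delta[0, j] = logpi[j] + logB[0, j]
    for t in range(1, n):
        for j in range(k):
            best = -1e308
            arg = 0
            for i in range(k):
                v = delta[t - 1, i] + logA[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logB[t, j]
            psi[t, j] = arg
    path = np.empty(n, dtype=np.int64)
    best = -1e308
    for j in range(k):
        if delta[n - 1, j] > best:
            best = delta[n - 1, j]
            path[n - 1] = j
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _emission_matrix(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    z = (x[:, None] - means[None, :]) / sds[None, :]
    B = np.exp(-0.5 * z**2) / (np.sqrt(2 * np.pi) * sds[None, :])
    return np.maximum(B, _TINY)


@dataclass
class HmmModel:
    """Gaussian-emission HMM with states ordered by ascending mean."""

    n_states: int
    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray  # per-frame transition probabilities
    startprob: np.ndarray
    loglik: float
    bic: float
    n_obs: int
    converged: bool = True
    loglik_history: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if (self.sds <= 0).any():
            raise ValueError("emission sds must be positive")
        rows = self.transmat.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-8:
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def n_params(self) -> int:
        k = self.n_states
        return (k - 1) + k * (k - 1) + 2 * k


@dataclass
class IdealizedTrace:
    """Viterbi path of one molecule: per-frame state, per-state mean."""

    molecule_id: str
    time_s: np.ndarray
    states: np.ndarray
    state_means: np.ndarray

    @property
    def E_ideal(self) -> np.ndarray:
        return self.state_means[self.states]

    @property
    def transition_frames(self) -> np.ndarray:
        return np.flatnonzero(np.diff(self.states) != 0) + 1

    def __len__(self) -> int:
        return len(self.states)


def _order_states(means, sds, A, pi):
    order = np.argsort(means)
    return means[order], sds[order], A[np.ix_(order, order)], pi[order]


def _em_once(x, means, sds, A, pi, tol, max_iter, tie_sd):
    prev = -np.inf
    history = []
    converged = False
    for _ in range(max_iter):
        B = _emission_matrix(x, means, sds)
        loglik, gamma, xi, pi_new = _forward_backward(B, B, A, pi)
        # EM guarantee: the observed-data log-likelihood never decreases
        if loglik < prev - 1e-6:
            raise AssertionError("EM log-likelihood decreased")
        history.append(loglik)
        if np.isfinite(prev) and abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
        # M-step
        occ = gamma.sum(axis=0)
        occ = np.maximum(occ, 1e-12)
        means = gamma.T @ x / occ
        sq = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0)
        if tie_sd:
            # a pooled emission sd keeps the Viterbi decision boundary at
            # the midpoint of the means, so boundary frames are split
            # evenly between states and dwell lengths stay unbiased
            var = np.full_like(occ, sq.sum() / occ.sum())
        else:
            var = sq / occ
        sds = np.maximum(np.sqrt(var), SD_FLOOR)
        if len(x) > 1:
            rows = xi.sum(axis=1, keepdims=True)
            A = np.where(rows > 1e-12, xi / np.maximum(rows, 1e-12), A)
            A = A / A.sum(axis=1, keepdims=True)
        pi = np.maximum(pi_new, 1e-12)
        pi = pi / pi.sum()
    return means, sds, A, pi, history, converged


def fit_hmm(
    E: np.ndarray,
    n_states: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_restarts: int = 5,
    tie_sd: bool = True,
) -> HmmModel:
    """Baum–Welch fit of a Gaussian-emission HMM; best of several restarts.

    Restart initializations place the emission means at evenly spaced
    quantiles of the data with seed-derived jitter, so the fit is
    deterministic under ``seed``.  Emission sds are floored at 0.01
    FRET to prevent degenerate collapse.
    """
    x = np.asarray(E, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10 * n_states:
        raise ValueError(f"series too short: need >= {10 * n_states} frames for {n_states} states")
    if n_states == 1:
        mu = np.array([x.mean()])
        sd = np.array([max(x.std(), SD_FLOOR)])
        ll = float(np.sum(np.log(_emission_matrix(x, mu, sd)[:, 0])))
        bic = -2 * ll + 2 * np.log(len(x))
        return HmmModel(1, mu, sd, np.ones((1, 1)), np.ones(1), ll, bic, len(x))

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(77,)))
    q = np.quantile(x, np.linspace(0.15, 0.85, n_states))
    spread = max(x.std(), 0.05)
    best = None
    for r in range(n_restarts):
        means = q + (0.0 if r == 0 else rng.normal(0.0, 0.15 * spread, n_states))
        sds = np.full(n_states, max(0.5 * spread, SD_FLOOR))
        A = np.full((n_states, n_states), 0.05 / max(n_states - 1, 1))
        np.fill_diagonal(A, 0.95)
        pi = np.full(n_states, 1.0 / n_states)
        means, sds, A, pi, hist, conv = _em_once(x, means, sds, A, pi, tol, max_iter, tie_sd)
        if best is None or hist[-1] > best[4][-1]:
            best = (means, sds, A, pi, hist, conv)
    means, sds, A, pi, hist, conv = best
    means, sds, A, pi = _order_states(means, sds, A, pi)
    ll = hist[-1]
    k = n_states
    n_params = (k - 1) + k * (k - 1) + (k + 1 if tie_sd else 2 * k)
    bic = -2 * ll + n_params * np.log(len(x))
    return HmmModel(k, means, sds, A, pi, float(ll), float(bic), len(x),
                    converged=conv, loglik_history=hist)


def select_model(E: np.ndarray, k_max: int = 3, seed: int = 0, **kwargs) -> HmmModel:
    """Fit k = 1..k_max and return the minimum-BIC model."""
    models = [fit_hmm(E, k, seed=seed, **kwargs) for k in range(1, k_max + 1)]
    return min(models, key=lambda m: m.bic)


def clean_states(states: np.ndarray, min_frames: int = 2) -> np.ndarray:
    """Absorb state runs shorter than the detection floor into neighbours.

    Runs below ``min_frames`` are unreliable under frame averaging (the
    same floor the dwell fits use as their truncation point); they are
    relabelled to the longer flanking run, shortest first.
    """
    s = np.asarray(states).copy()
    while True:
        edges = np.concatenate([[0], np.flatnonzero(np.diff(s) != 0) + 1, [len(s)]])
        lens = np.diff(edges)
        if len(lens) <= 1:
            return s
        j = int(np.argmin(lens))
        if lens[j] >= min_frames:
            return s
        a, b = edges[j], edges[j + 1]
        if j == 0:
            s[a:b] = s[b]
        elif j == len(lens) - 1:
            s[a:b] = s[a - 1]
        else:
            left_len, right_len = lens[j - 1], lens[j + 1]
            s[a:b] = s[a - 1] if left_len >= right_len else s[b]


def viterbi(
    E: np.ndarray,
    model: HmmModel,
    time_s: np.ndarray | None = None,
    molecule_id: str = "",
    min_dwell_frames: int = 2,
) -> IdealizedTrace:
    """Most-probable state path; idealized FRET = state emission mean.

    Runs shorter than ``min_dwell_frames`` are folded into their
    neighbours (set 0 or 1 to disable).
    """
    x = np.asarray(E, dtype=float)
    finite = np.isfinite(x)
    xf = x[finite]
    logB = np.log(_emission_matrix(xf, model.means, model.sds))
    logA = np.log(np.maximum(model.transmat, _TINY))
    logpi = np.log(np.maximum(model.startprob, _TINY))
    path = np.asarray(_viterbi_path(logB, logA, logpi))
    if min_dwell_frames > 1:
        path = clean_states(path, min_dwell_frames)
    if time_s is None:
        time_s = np.arange(len(xf), dtype=float)
    else:
        time_s = np.asarray(time_s, dtype=float)[finite]
    return IdealizedTrace(molecule_id, time_s, path, model.means.copy())


def idealized_histogram(
    ideal_traces, bin_width: float = 0.05, lo: float = -0.2, hi: float = 1.2
) -> pd.DataFrame:
    """Per-frame histogram of idealized FRET, normalized to total frames."""
    traces = list(ideal_traces)
    if not traces:
        raise ValueError("no idealized traces given")
    values = np.concatenate([t.E_ideal for t in traces])
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "frequency": counts / counts.sum(),
        }
    )
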