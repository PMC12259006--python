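"""Kinetic modelling: TICA, k-means discretization, Markov state models,
implied timescales, VAMP-2 cross-validation and equilibrium resampling.

The estimator chain follows common MSM practice: time-lagged covariances are
pooled over trajectories with a symmetrized lagged covariance (reversible
TICA estimate); transition counts use a sliding window at lag tau; the
transition matrix is the plain row normalization of the count matrix
restricted to the largest strongly connected set (no detailed-balance
constraint); the stationary distribution is the leading left eigenvector.
Equilibrium ensemble statistics are computed on frames resampled from the
stationary distribution.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .containers import EnsembleSample, FeatureMatrix

__all__ = [
    "CovarianceSet",
    "TICAModel",
    "CountMatrix",
    "MSModel",
    "estimate_covariances",
    "solve_tica",
    "tica",
    "kmeans",
    "count_transitions",
    "largest_connected_set",
    "estimate_msm",
    "implied_timescales",
    "vamp2_score",
    "cross_validate_centers",
    "sample_equilibrium",
    "lag_in_frames",
]


def _as_value_list(X) -> list[np.ndarray]:
    if isinstance(X, (FeatureMatrix, np.ndarray)):
        X = [X]
    out = []
    for x in X:
        v = x.values if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("feature trajectories must be 2-D")
        out.append(v)
    return out


def lag_in_frames(lag_ns: float, frame_interval_ns: float) -> int:
    """Convert a physical lag time to an integer frame lag; no rounding."""
    ratio = lag_ns / frame_interval_ns
    lag = round(ratio)
    if abs(ratio - lag) > 1e-9 or lag < 1:
        raise ValueError(
            f"lag {lag_ns} ns is not a positive integer multiple of the "
            f"frame interval {frame_interval_ns} ns"
        )
    return int(lag)


# ---------------------------------------------------------------------------
# TICA
# ---------------------------------------------------------------------------

@dataclass
class CovarianceSet:
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    lag: int
    n_pairs: int
    degenerate: bool = False


@dataclass
class TICAModel:
    """Generalized eigendecomposition Ctau v = lambda C0 v.

    ``components`` columns are the independent components (feature -> TIC),
    orthonormal under the C0 metric; eigenvalues are sorted descending.
    """

    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    lag: int
    eigenvalues: np.ndarray
    components: np.ndarray  # (n_features, dim)
    dim: int

    def transform(self, X) -> list[np.ndarray] | np.ndarray:
        single = isinstance(X, (FeatureMatrix, np.ndarray))
        out = [(v - self.mean) @ self.components for v in _as_value_list(X)]
        return out[0] if single else out


def estimate_covariances(X, lag: int) -> CovarianceSet:
    """Pooled mean-free instantaneous and symmetrized time-lagged covariances.

    All pairs (t, t+lag) are pooled across trajectories; the mean and C0 are
    taken over the union of head and tail frames of those pairs, and the
    lagged covariance is symmetrized, (C + C^T)/2.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    vals = _as_value_list(X)
    heads = [v[:-lag] for v in vals if v.shape[0] > lag]
    tails = [v[lag:] for v in vals if v.shape[0] > lag]
    if not heads:
        raise ValueError(f"insufficient data: no trajectory longer than lag {lag}")
    X0 = np.concatenate(heads, axis=0)
    Xt = np.concatenate(tails, axis=0)
    n = X0.shape[0]
    mean = (X0.sum(axis=0) + Xt.sum(axis=0)) / (2 * n)
    X0c = X0 - mean
    Xtc = Xt - mean
    c0 = (X0c.T @ X0c + Xtc.T @ Xtc) / (2 * n)
    ct = X0c.T @ Xtc / n
    ctau = 0.5 * (ct + ct.T)
    degenerate = bool(np.any(np.diag(c0) <= 1e-15 * max(1.0, np.max(np.diag(c0)))))
    if degenerate:
        warnings.warn("degenerate (constant) feature columns detected", stacklevel=2)
    return CovarianceSet(mean, c0, ctau, lag, n, degenerate)


def solve_tica(
    c0: np.ndarray,
    ctau: np.ndarray,
    dim: int | None = None,
    ridge: float | None = None,
    mean: np.ndarray | None = None,
    lag: int = 1,
) -> TICAModel:
    """Solve the generalized eigenproblem Ctau v = lambda C0 v.

    ``ridge`` (default ``1e-6 * trace(C0)/n``) is added to the diagonal of C0
    for conditioning; pass 0 to disable, in which case a singular C0 raises.
    The sign convention makes each component's largest-|loading| coefficient
    positive.
    """
    c0 = np.asarray(c0, dtype=np.float64)
    ctau = np.asarray(ctau, dtype=np.float64)
    nf = c0.shape[0]
    if dim is None:
        dim = nf
    if ridge is None:
        ridge = 1e-6 * np.trace(c0) / nf
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    c0r = c0 + ridge * np.eye(nf)
    ev_c0 = np.linalg.eigvalsh(c0r)
    if ev_c0[0] <= 1e-12 * max(abs(ev_c0[-1]), 1.0):
        raise np.linalg.LinAlgError(
            "C0 is singular; increase the ridge regularization"
        )
    evals, evecs = scipy.linalg.eigh(ctau, c0r)
    order = np.argsort(evals)[::-1]
    evals = evals[order][:dim]
    evecs = evecs[:, order][:, :dim]
    # C0-orthonormality comes from eigh(b=...); fix signs deterministically
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    if mean is None:
        mean = np.zeros(nf)
    return TICAModel(np.asarray(mean), c0, ctau, lag, evals, evecs, dim)


def tica(X, lag: int, dim: int = 10, ridge: float | None = None) -> TICAModel:
    """Estimate covariances at ``lag`` and solve for the top ``dim`` TICs."""
    cov = estimate_covariances(X, lag)
    return solve_tica(cov.c0, cov.ctau, dim=dim, ridge=ridge, mean=cov.mean, lag=lag)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def kmeans(
    Y,
    k: int,
    seed: int,
    n_init: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """k-means++ clustering of projected trajectories.

    Returns ``(centers, dtrajs)`` with one discrete trajectory per input.
    Deterministic under ``seed`` (best of ``n_init`` restarts by inertia).
    """
    ys = _as_value_list(Y)
    stacked = np.concatenate(ys, axis=0)
    if k > stacked.shape[0]:
        raise ValueError(f"k={k} exceeds number of frames {stacked.shape[0]}")
    est = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter,
        tol=tol, random_state=seed,
    ).fit(stacked)
    centers = est.cluster_centers_
    dtrajs = [_assign(y, centers) for y in ys]
    return centers, dtrajs


def _assign(y: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center assignment; ties break to the lowest center index."""
    d2 = ((y[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    return np.argmin(d2, axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# Markov state model
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    counts: np.ndarray
    lag: int
    mode: str = "sliding"


@dataclass
class MSModel:
    """Row-stochastic transition matrix with stationary distribution.

    ``active_set`` maps the model's state indices back to the original
    cluster labels (ergodic trimming may have removed states).
    """

    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    lag: int
    active_set: np.ndarray

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        ev = np.linalg.eigvals(self.transition_matrix)
        ev = ev[np.argsort(-np.abs(ev))]
        return ev if k is None else ev[:k]

    def timescales(self, n_its: int) -> np.ndarray:
        """Implied timescales -tau/ln|lambda_i| for the slowest processes."""
        ev = self.eigenvalues(n_its + 1)[1:]
        out = np.full(n_its, np.nan)
        for i, lam in enumerate(ev[:n_its]):
            if np.isreal(lam) and lam.real <= 1e-12:
                continue  # undefined: non-positive (or numerically zero) eigenvalue
            m = np.abs(lam)  # complex pairs scored by magnitude
            if 1e-12 < m < 1:
                out[i] = -self.lag / np.log(m)
        return out


def _as_dtraj_list(dtrajs) -> list[np.ndarray]:
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    out = []
    for d in dtrajs:
        a = np.asarray(d, dtype=np.int64)
        if a.ndim != 1:
            raise ValueError("discrete trajectories must be 1-D")
        if a.size and a.min() < 0:
            raise ValueError("negative state index")
        out.append(a)
    return out


def count_transitions(dtrajs, lag: int, n_states: int | None = None) -> CountMatrix:
    """Sliding-window transition counts: pairs (s_t, s_{t+lag}) for all t."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    ds = _as_dtraj_list(dtrajs)
    if all(d.size <= lag for d in ds):
        raise ValueError(f"every trajectory is shorter than lag {lag}")
    k = n_states if n_states is not None else int(max(d.max() for d in ds if d.size)) + 1
    counts = np.zeros((k, k), dtype=np.float64)
    for d in ds:
        if d.size <= lag:
            continue
        np.add.at(counts, (d[:-lag], d[lag:]), 1.0)
    return CountMatrix(counts, lag, "sliding")


def largest_connected_set(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """States in the largest strongly connected component of the count graph.

    Edge i -> j exists iff counts[i, j] > 0.  Among equal-size components the
    one containing the lowest state index wins.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    adj = scipy.sparse.csr_matrix((c > 0).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    best = max(range(n_comp), key=lambda ci: (sizes[ci], -int(np.flatnonzero(labels == ci)[0])))
    return np.flatnonzero(labels == best)


def estimate_msm(
    counts: CountMatrix | np.ndarray,
    active_set: np.ndarray | None = None,
    lag: int | None = None,
) -> MSModel:
    """Row-normalize the count matrix on the (largest connected) active set.

    The stationary distribution is the left eigenvector of the resulting
    transition matrix whose eigenvalue is closest to 1; its imaginary parts
    must vanish to 1e-10.
    """
    if isinstance(counts, CountMatrix):
        c = counts.counts
        lag = counts.lag if lag is None else lag
    else:
        c = np.asarray(counts, dtype=np.float64)
        lag = 1 if lag is None else lag
    if active_set is None:
        active_set = largest_connected_set(c)
        trimmed = c.shape[0] - active_set.size
        if trimmed:
            warnings.warn(f"ergodic trimming removed {trimmed} state(s)", stacklevel=2)
    active_set = np.asarray(active_set, dtype=np.intp)
    sub = c[np.ix_(active_set, active_set)]
    rowsums = sub.sum(axis=1)
    assert np.all(rowsums > 0), "zero-count row inside the active set"
    T = sub / rowsums[:, None]
    evals, evecs = scipy.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(evals - 1.0)))
    pi = evecs[:, idx]
    if np.max(np.abs(pi.imag)) > 1e-10 * max(1.0, np.max(np.abs(pi.real))):
        raise ValueError("stationary eigenvector has non-negligible imaginary part")
    pi = pi.real
    if pi.sum() < 0:
        pi = -pi
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    return MSModel(T, pi, lag, active_set)


def implied_timescales(dtrajs, lags: Sequence[int], n_its: int = 2) -> pd.DataFrame:
    """Implied timescales t_i(tau) = -tau / ln|lambda_{i+1}(tau)| per lag.

    Returns a DataFrame indexed by lag with columns ``t1..t{n_its}`` (frames);
    undefined timescales (non-positive real eigenvalues) are NaN.
    """
    rows = {}
    for lag in lags:
        counts = count_transitions(dtrajs, lag)
        model = estimate_msm(counts)
        if model.n_states < n_its + 1:
            raise ValueError(
                f"only {model.n_states} connected states at lag {lag}; "
                f"need {n_its + 1} for {n_its} timescales"
            )
        rows[lag] = model.timescales(n_its)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"t{i + 1}" for i in range(n_its)]
    ).rename_axis("lag")


# ---------------------------------------------------------------------------
# VAMP-2 scoring and cross-validation
# ---------------------------------------------------------------------------

def _indicator_covariances(ds: list[np.ndarray], lag: int, k: int):
    """C00, C0t, Ctt over state-indicator features, sliding window."""
    c00 = np.zeros(k)
    ctt = np.zeros(k)
    c0t = np.zeros((k, k))
    n = 0
    for d in ds:
        if d.size <= lag:
            continue
        h, t = d[:-lag], d[lag:]
        c00 += np.bincount(h, minlength=k)
        ctt += np.bincount(t, minlength=k)
        np.add.at(c0t, (h, t), 1.0)
        n += h.size
    if n == 0:
        raise ValueError("no transition pairs at this lag")
    return np.diag(c00 / n), c0t / n, np.diag(ctt / n)


def _inv_sqrt_psd(M: np.ndarray, rel_eps: float = 1e-10) -> np.ndarray:
    ev, U = np.linalg.eigh(M)
    keep = ev > rel_eps * max(ev.max(), 1e-300)
    inv = np.zeros_like(ev)
    inv[keep] = 1.0 / np.sqrt(ev[keep])
    return (U * inv) @ U.T


def vamp2_score(
    train_dtrajs,
    test_dtrajs,
    lag: int,
    rank: int,
    n_states: int | None = None,
) -> float:
    """Cross-validated VAMP-2 score of a state discretization.

    The top-``rank`` singular functions of the Koopman matrix
    ``C00^{-1/2} C0t Ctt^{-1/2}`` are estimated on the training trajectories
    and scored on the test covariances; with train == test this reduces to
    the sum of the top-``rank`` squared singular values.  The constant
    function is included, so the score is >= 1 and at most ``rank``.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    tr = _as_dtraj_list(train_dtrajs)
    te = _as_dtraj_list(test_dtrajs)
    if n_states is None:
        n_states = int(max(d.max() for d in tr + te if d.size)) + 1
    c00, c0t, ctt = _indicator_covariances(tr, lag, n_states)
    w0 = _inv_sqrt_psd(c00)
    wt = _inv_sqrt_psd(ctt)
    Uw, s, Vwt = np.linalg.svd(w0 @ c0t @ wt)
    r = min(rank, s.size)
    U = w0 @ Uw[:, :r]   # singular functions in indicator space
    V = wt @ Vwt.T[:, :r]
    c00s, c0ts, ctts = _indicator_covariances(te, lag, n_states)
    A = _inv_sqrt_psd(U.T @ c00s @ U)
    B = _inv_sqrt_psd(V.T @ ctts @ V)
    M = A @ (U.T @ c0ts @ V) @ B
    return float(np.sum(M * M))


def cross_validate_centers(
    feature_trajs,
    k_grid: Sequence[int],
    lag: int,
    folds: int = 5,
    seed: int = 0,
    rank: int = 10,
    allow_block_split: bool = True,
) -> pd.DataFrame:
    """Mean +/- sd test VAMP-2 score per cluster count ``k``.

    Shuffle-split cross-validation over whole trajectories; when there are
    fewer trajectories than folds, each trajectory is cut into ``folds``
    contiguous blocks which become the split units (unless disabled).
    Clustering is refit on the training split only.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ys = _as_value_list(feature_trajs)
    if len(ys) >= folds:
        units = ys
    elif allow_block_split:
        units = []
        for y in ys:
            edges = np.linspace(0, y.shape[0], folds + 1).astype(int)
            units.extend(y[a:b] for a, b in zip(edges[:-1], edges[1:]) if b - a > lag)
    else:
        raise ValueError(
            f"{len(ys)} trajectories < {folds} folds and block splitting disabled"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))
    fold_of = {int(u): f for f, u in enumerate(np.array_split(order, folds)) for u in u}
    records = []
    for k in k_grid:
        scores = []
        for f in range(folds):
            train = [units[i] for i in range(len(units)) if fold_of[i] != f]
            test = [units[i] for i in range(len(units)) if fold_of[i] == f]
            if not train or not test:
                continue
            centers, train_d = kmeans(train, k, seed=seed)
            test_d = [_assign(y, centers) for y in test]
            try:
                scores.append(vamp2_score(train_d, test_d, lag, rank, n_states=k))
            except ValueError:
                continue
        records.append(
            {"k": k, "mean_score": float(np.mean(scores)),
             "sd_score": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
             "n_folds": len(scores)}
        )
    return pd.DataFrame.from_records(records).set_index("k")


# ---------------------------------------------------------------------------
# Equilibrium resampling
# ---------------------------------------------------------------------------

def sample_equilibrium(
    model: MSModel,
    dtrajs,
    n: int = 30_000,
    seed: int = 0,
) -> EnsembleSample:
    """Draw ``n`` (trajectory, frame) pairs from the model's equilibrium.

    Each draw picks a state from the stationary distribution, then a frame
    uniformly from all frames assigned to that state (with replacement).
    """
    ds = _as_dtraj_list(dtrajs)
    frames_of_state: dict[int, np.ndarray] = {}
    for s_model, s_orig in enumerate(model.active_set):
        pairs = [
            (tid, f)
            for tid, d in enumerate(ds)
            for f in np.flatnonzero(d == s_orig)
        ]
        if not pairs and model.stationary_distribution[s_model] > 0:
            raise ValueError(f"state {int(s_orig)} has positive weight but no frames")
        frames_of_state[s_model] = np.asarray(pairs, dtype=np.intp)
    rng = np.random.default_rng(seed)
    states = rng.choice(model.n_states, size=n, p=model.stationary_distribution)
    entries = np.empty((n, 2), dtype=np.intp)
    for s in np.unique(states):
        where = np.flatnonzero(states == s)
        pool = frames_of_state[int(s)]
        picks = rng.integers(0, pool.shape[0], size=where.size)
        entries[where] = pool[picks]
    return EnsembleSample(entries, seed=seed)
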