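"""EM fitting of K-component normal mixtures of linear regressions.

The model is group-based trajectory analysis: subject i's whole response
vector y_i (length p_i) belongs to one latent group k with mean X_i theta_k
and covariance sigma_k^2 I. Membership is therefore subject-level and
responsibilities form an n x K matrix. Fitting alternates the usual E-step
(posterior responsibilities via log-sum-exp) and M-step (responsibility-
weighted least squares per component) from multiple random starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .data_model import DesignMatrices, DesignSpec, LongitudinalDataset

__all__ = [
    "MixtureParams",
    "MixtureFit",
    "DegenerateFitError",
    "component_loglik",
    "e_step",
    "m_step",
    "fit_em",
    "fit_multistart",
    "posterior_classify",
]

LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateFitError(RuntimeError):
    """Raised when no non-degenerate fit can be produced."""


@dataclass
class MixtureParams:
    """Parameters (theta_k, sigma_k^2, pi_k) of a K-component mixture."""

    theta: np.ndarray  # (K, q)
    sigma2: np.ndarray  # (K,)
    pi: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def q(self) -> int:
        return self.theta.shape[1]


@dataclass
class MixtureFit:
    """A fitted mixture: parameters, responsibilities and diagnostics."""

    params: MixtureParams
    responsibilities: np.ndarray  # (n, K)
    loglik: float
    n_iter: int
    converged: bool
    degenerate: bool = False
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    transform: object | None = None  # TransformContext when fitted on w-scale
    design: DesignSpec | None = None
    p_equal: bool | None = None

    @property
    def K(self) -> int:
        return self.params.K


# ---------------------------------------------------------------------------
# stacked computational view


class _Stacked:
    """Flat arrays for vectorized EM: one row per measurement.

    Rows are grouped contiguously by subject, so per-subject reductions are
    single ``np.add.reduceat`` calls over ``starts``.
    """

    __slots__ = ("y", "X", "XX", "Xy", "sidx", "p", "n", "N", "q", "starts",
                 "first_row", "var_y")

    def __init__(self, data: LongitudinalDataset, design: DesignMatrices):
        self.y = data.y_stack
        self.X = design.X_stack
        self.p = data.p
        self.n = data.n
        self.N = int(self.p.sum())
        self.q = design.q
        self.sidx = np.repeat(np.arange(self.n), self.p)
        self.starts = np.concatenate([[0], np.cumsum(self.p)[:-1]])
        # per-row outer products x_n x_n' and x_n y_n: fixed across EM
        # iterations, so the weighted normal equations are single matmuls
        self.XX = (self.X[:, :, None] * self.X[:, None, :]).reshape(self.N, -1)
        self.Xy = self.X * self.y[:, None]
        t = data.t_stack
        # design row at the earliest observed time: canonical component order
        self.first_row = self.X[int(np.argmin(t))]
        self.var_y = float(np.var(self.y))


def _rss_per_subject(st: _Stacked, theta: np.ndarray) -> np.ndarray:
    """Residual sum of squares per subject per component; shape (n, K)."""
    res = st.y[:, None] - st.X @ theta.T  # (N, K)
    return np.add.reduceat(res * res, st.starts, axis=0)


def _log_density(st: _Stacked, params: MixtureParams) -> np.ndarray:
    """log f_k(y_i | X_i) for every subject/component; shape (n, K)."""
    rss = _rss_per_subject(st, params.theta)
    s2 = params.sigma2[None, :]
    return -0.5 * st.p[:, None] * (LOG_2PI + np.log(s2)) - rss / (2.0 * s2)


def component_loglik(
    y_i: np.ndarray, X_i: np.ndarray, theta_k: np.ndarray, sigma2_k: float
) -> float:
    """Log-density of one subject's trajectory under one component.

    Equals -(p_i/2) log(2 pi sigma_k^2) - ||y_i - X_i theta_k||^2 / (2 sigma_k^2),
    i.e. the multivariate normal log-density with covariance sigma_k^2 I.
    """
    y_i = np.asarray(y_i, dtype=float)
    X_i = np.atleast_2d(np.asarray(X_i, dtype=float))
    theta_k = np.asarray(theta_k, dtype=float)
    if sigma2_k <= 0:
        raise ValueError("sigma2 must be positive")
    if X_i.shape != (len(y_i), len(theta_k)):
        raise ValueError(f"dimension mismatch: y {y_i.shape}, X {X_i.shape}, theta {theta_k.shape}")
    resid = y_i - X_i @ theta_k
    p_i = len(y_i)
    return float(-0.5 * p_i * (LOG_2PI + np.log(sigma2_k)) - resid @ resid / (2.0 * sigma2_k))


def _estep_core(st: _Stacked, params: MixtureParams) -> tuple[np.ndarray, float]:
    """Responsibilities and observed-data log-likelihood for given params."""
    logf = _log_density(st, params) + np.log(params.pi)[None, :]
    # inlined log-sum-exp over components (hot loop)
    m = logf.max(axis=1)
    r = np.exp(logf - m[:, None])
    tot = r.sum(axis=1)
    r /= tot[:, None]
    return r, float((m + np.log(tot)).sum())


def e_step(
    data: LongitudinalDataset, design: DesignMatrices, params: MixtureParams
) -> np.ndarray:
    """Posterior membership probabilities r_ik via Bayes' rule (log-sum-exp)."""
    r, _ = _estep_core(_Stacked(data, design), params)
    return r


def _mstep_core(st: _Stacked, r: np.ndarray) -> MixtureParams:
    K = r.shape[1]
    r_rows = r[st.sidx, :]  # (N, K) subject weights broadcast to rows
    sum_rp = r.T @ st.p  # (K,) effective measurement counts
    # stacked weighted normal equations: A[k] = X' W_k X, b[k] = X' W_k y
    A = (r_rows.T @ st.XX).reshape(K, st.q, st.q)
    b = r_rows.T @ st.Xy  # (K, q)
    try:
        theta = np.linalg.solve(A, b[:, :, None])[:, :, 0]  # (K, q)
    except np.linalg.LinAlgError as err:
        dets = np.linalg.det(A)
        bad = int(np.argmin(np.abs(dets)))
        raise np.linalg.LinAlgError(
            f"singular weighted normal equations for component {bad}"
        ) from err
    res = st.y[:, None] - st.X @ theta.T  # (N, K)
    sigma2 = (r_rows * res * res).sum(axis=0) / sum_rp
    pi = r.mean(axis=0)
    return MixtureParams(theta=theta, sigma2=sigma2, pi=pi)


def m_step(
    data: LongitudinalDataset, design: DesignMatrices, responsibilities: np.ndarray
) -> MixtureParams:
    """Weighted-least-squares update of (theta, sigma2, pi).

    theta_k solves WLS with subject weight r_ik applied to all of subject i's
    rows; sigma2_k averages weighted residual sums over the effective
    measurement count sum_i r_ik p_i; pi_k is the mean responsibility.
    """
    r = np.asarray(responsibilities, dtype=float)
    return _mstep_core(_Stacked(data, design), r)


try:  # compiled EM inner loop; the numpy path below is the reference
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _kernel_mstep(y, X, p, starts, r, theta, sigma2, pi):
    """In-place weighted-least-squares M-step on stacked arrays."""
    q = X.shape[1]
    n = p.shape[0]
    K = r.shape[1]
    for k in range(K):
        A = np.zeros((q, q))
        b = np.zeros(q)
        srp = 0.0
        sr = 0.0
        for i in range(n):
            w = r[i, k]
            sr += w
            srp += w * p[i]
            if w == 0.0:
                continue
            for j in range(starts[i], starts[i] + p[i]):
                wy = w * y[j]
                for a in range(q):
                    b[a] += X[j, a] * wy
                    wxa = w * X[j, a]
                    for c in range(a, q):
                        A[a, c] += wxa * X[j, c]
        for a in range(q):
            for c in range(a + 1, q):
                A[c, a] = A[a, c]
        th = np.linalg.solve(A, b)
        theta[k] = th
        rss = 0.0
        for i in range(n):
            w = r[i, k]
            if w == 0.0:
                continue
            for j in range(starts[i], starts[i] + p[i]):
                mu = 0.0
                for a in range(q):
                    mu += X[j, a] * th[a]
                d = y[j] - mu
                rss += w * d * d
        sigma2[k] = rss / srp
        pi[k] = sr / n


@njit(cache=True)
def _kernel_escore(y, X, p, starts, theta, sigma2, pi, r):
    """E-step: fill responsibilities in place, return the log-likelihood."""
    q = X.shape[1]
    n = p.shape[0]
    K = pi.shape[0]
    LOG2PI = 1.8378770664093453
    logf = np.empty((n, K))
    for k in range(K):
        c0 = -0.5 * (LOG2PI + np.log(sigma2[k]))
        inv2s = 1.0 / (2.0 * sigma2[k])
        lpk = np.log(pi[k])
        for i in range(n):
            rss = 0.0
            for j in range(starts[i], starts[i] + p[i]):
                mu = 0.0
                for a in range(q):
                    mu += X[j, a] * theta[k, a]
                d = y[j] - mu
                rss += d * d
            logf[i, k] = lpk + c0 * p[i] - rss * inv2s
    loglik = 0.0
    for i in range(n):
        m = logf[i, 0]
        for k in range(1, K):
            if logf[i, k] > m:
                m = logf[i, k]
        tot = 0.0
        for k in range(K):
            r[i, k] = np.exp(logf[i, k] - m)
            tot += r[i, k]
        for k in range(K):
            r[i, k] /= tot
        loglik += m + np.log(tot)
    return loglik


@njit(cache=True)
def _em_kernel(y, X, p, starts, r, tol, max_iter, min_prior, var_floor):
    """Full EM loop on stacked arrays; mirrors the numpy E/M steps exactly.

    Returns (theta, sigma2, pi, r, loglik, n_iter, converged, degenerate,
    trace, n_trace). Sequence: M-step from the crisp start, then alternate
    E and M; stop on relative log-likelihood change < tol, on component
    collapse (after one final re-scoring E-step so loglik matches the
    returned parameters), or after max_iter E/M rounds plus a final E-step.
    """
    q = X.shape[1]
    K = r.shape[1]
    theta = np.zeros((K, q))
    sigma2 = np.zeros(K)
    pi = np.zeros(K)
    trace = np.zeros(max_iter + 2)
    n_trace = 0
    loglik = -np.inf
    converged = False
    degenerate = False
    n_iter = 0

    _kernel_mstep(y, X, p, starts, r, theta, sigma2, pi)
    for k in range(K):
        if sigma2[k] < var_floor:
            sigma2[k] = var_floor

    stop = False
    for it in range(1, max_iter + 2):
        new_ll = _kernel_escore(y, X, p, starts, theta, sigma2, pi, r)
        trace[n_trace] = new_ll
        n_trace += 1
        loglik_prev = loglik
        loglik = new_ll
        n_iter = min(it, max_iter)
        if stop or it == max_iter + 1:
            break
        if np.isfinite(loglik_prev) and abs(new_ll - loglik_prev) <= tol * (1.0 + abs(new_ll)):
            converged = True
            break
        _kernel_mstep(y, X, p, starts, r, theta, sigma2, pi)
        for k in range(K):
            if pi[k] < min_prior or sigma2[k] < var_floor:
                degenerate = True
                stop = True
            if sigma2[k] < var_floor:
                sigma2[k] = var_floor
    return theta, sigma2, pi, r, loglik, n_iter, converged, degenerate, trace, n_trace


def _canonicalize(params: MixtureParams, r: np.ndarray, first_row: np.ndarray):
    """Order components by fitted mean at the earliest time point, ascending."""
    means = params.theta @ first_row
    order = np.argsort(means, kind="stable")
    if np.array_equal(order, np.arange(len(order))):
        return params, r
    return (
        MixtureParams(theta=params.theta[order], sigma2=params.sigma2[order], pi=params.pi[order]),
        r[:, order],
    )


def _random_partition(n: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Random crisp assignment of n subjects to K non-empty groups."""
    for _ in range(100):
        labels = rng.integers(0, K, size=n)
        if len(np.unique(labels)) == K:
            return labels
    labels = np.asarray(rng.permutation(n) % K)  # deterministic fallback
    return labels


def fit_em(
    data: LongitudinalDataset,
    design: DesignMatrices,
    K: int,
    seed: int | None = 0,
    init_labels: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    min_prior: float = 0.05,
    var_floor_frac: float = 1e-10,
    _stacked: "_Stacked | None" = None,
) -> MixtureFit:
    """Run EM from one initialization.

    Initialization is a random crisp partition of subjects (or explicit
    ``init_labels``) followed by an M-step. Iterates until the relative
    log-likelihood change drops below ``tol`` or ``max_iter`` (default 200)
    is hit. A fit is marked degenerate when any mixing proportion falls
    below ``min_prior`` or any variance below the floor; degenerate fits are
    excluded from model selection by callers.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if data.n < K:
        raise ValueError(f"need at least K={K} subjects, got {data.n}")
    st = _stacked if _stacked is not None else _Stacked(data, design)
    var_floor = var_floor_frac * max(st.var_y, np.finfo(float).tiny)

    if init_labels is None:
        rng = np.random.default_rng(seed)
        init_labels = _random_partition(st.n, K, rng)
    r = np.zeros((st.n, K))
    r[np.arange(st.n), np.asarray(init_labels, dtype=int)] = 1.0

    try:
        theta, sigma2, pi, r, loglik, n_iter, converged, degenerate, trace, n_trace = _em_kernel(
            st.y,
            st.X,
            st.p.astype(np.int64),
            st.starts.astype(np.int64),
            r,
            float(tol),
            int(max_iter),
            float(min_prior),
            float(var_floor),
        )
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular weighted normal equations during EM "
            "(a component received too few effective subjects)"
        ) from err
    params = MixtureParams(theta=theta, sigma2=sigma2, pi=pi)
    params, r = _canonicalize(params, r, st.first_row)
    return MixtureFit(
        params=params,
        responsibilities=r,
        loglik=float(loglik),
        n_iter=int(n_iter),
        converged=bool(converged),
        degenerate=bool(degenerate),
        loglik_trace=np.asarray(trace[:n_trace]),
        design=design.spec,
        p_equal=bool(np.all(data.p == data.p[0])),
    )


def fit_multistart(
    data: LongitudinalDataset,
    design: DesignMatrices,
    K: int,
    n_restarts: int = 10,
    seed: int = 0,
    **em_kwargs,
) -> MixtureFit:
    """Best-of-``n_restarts`` EM fits from seeded random initializations.

    Restart r uses seed ``seed + r`` so runs are reproducible and
    independent of execution order. Non-degenerate fits are preferred over
    degenerate ones regardless of likelihood; if every restart degenerates
    a :class:`DegenerateFitError` is raised.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if K == 1:
        n_restarts = 1  # the single-component fit does not depend on the start
    st = _Stacked(data, design)
    best: MixtureFit | None = None
    for rstart in range(n_restarts):
        fit = fit_em(data, design, K, seed=seed + rstart, _stacked=st, **em_kwargs)
        if best is None:
            best = fit
            continue
        if fit.degenerate == best.degenerate:
            if fit.loglik > best.loglik:
                best = fit
        elif best.degenerate and not fit.degenerate:
            best = fit
    if best is None or best.degenerate:
        raise DegenerateFitError(
            f"all {n_restarts} restarts degenerate for K={K} "
            "(component proportion or variance collapsed)"
        )
    return best


def posterior_classify(fit: MixtureFit) -> np.ndarray:
    """MAP cluster label per subject; ties break toward the smallest index."""
    return np.argmax(fit.responsibilities, axis=1)
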