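"""Dirichlet-multinomial mixture (DMM) over diagnostic-event count vectors.

At a position, each replicate's events follow a multinomial over the M event
categories plus a trailing "no event" slot, with a latent rate vector q shared
by all replicates and drawn from a Dirichlet.  A K-component mixture of such
Dirichlet-multinomials captures distinct position classes (crosslink sites,
sequencing-error-like positions, silent positions) and their overdispersion.
Two model classes are fitted: "peak", on CLIP-library events at peak
positions, and "background", on background-library events at the same
positions, so the peak class learns whatever event chemistry the protocol
produces while the background class absorbs expression-driven noise.

Event-count vectors repeat heavily along the genome (most positions carry
nothing but read-end counts), so all bulk computations collapse positions to
unique aggregated rows with multiplicities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.special import gammaln, logsumexp, psi

logger = logging.getLogger(__name__)

DEFAULT_K = 10
ALPHA_FLOOR = 1e-6


@dataclass
class DMMParams:
    model_class: str
    K: int
    weights: np.ndarray
    alphas: np.ndarray  # (K, M+1), all entries > 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.weights.shape != (self.K,) or self.alphas.shape[0] != self.K:
            raise ValueError("weights/alphas inconsistent with K")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.alphas <= 0):
            raise ValueError("all alpha entries must be positive")


def _as_matrix(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[None, :] if Y.ndim == 1 else Y


def log_multinomial_coeff(Y) -> float:
    """Sum over replicates of log multinomial coefficients of the event draws."""
    Y = _as_matrix(Y)
    return float(np.sum(gammaln(Y.sum(axis=1) + 1)) - np.sum(gammaln(Y + 1)))


def dm_replicate_loglik(Y, alpha) -> float:
    """Closed-form log of the replicate-tied Dirichlet-multinomial integral.

    With one latent q ~ Dirichlet(alpha) shared by all replicates, the
    integral of the product of multinomial likelihoods is the product of
    multinomial coefficients times the multivariate-Beta ratio
    B(alpha + sum_u Y^u) / B(alpha).  For U=1 and two categories this is the
    beta-binomial log-pmf; for all-zero counts it is exactly 0.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha entries must be positive")
    Y = _as_matrix(Y)
    if Y.shape[1] != alpha.shape[0]:
        raise ValueError("event vectors and alpha must have equal length")
    agg = Y.sum(axis=0)
    a0 = alpha.sum()
    return (
        log_multinomial_coeff(Y)
        + float(np.sum(gammaln(alpha + agg) - gammaln(alpha)))
        + float(gammaln(a0) - gammaln(a0 + agg.sum()))
    )


def dmm_emission(Y, params: DMMParams) -> float:
    """Stable log of the K-component mixture likelihood of one position."""
    comps = np.array(
        [dm_replicate_loglik(Y, params.alphas[k]) for k in range(params.K)]
    )
    return float(logsumexp(comps + np.log(params.weights)))


# ---------------------------------------------------------------------------
# Bulk evaluation on unique aggregated rows
# ---------------------------------------------------------------------------


class _UniqueRows:
    """Unique integer event rows with a sparse category-incidence matrix."""

    def __init__(self, uniq: np.ndarray):
        self.uniq = uniq
        self.totals = uniq.sum(axis=1)
        self.rows, self.cols = np.nonzero(uniq)
        self.vals = uniq[self.rows, self.cols].astype(float)
        nnz = self.rows.size
        self.row_inc = sparse.csr_matrix(
            (np.ones(nnz), (self.rows, np.arange(nnz))),
            shape=(uniq.shape[0], max(nnz, 1)),
        )

    @property
    def n(self) -> int:
        return self.uniq.shape[0]


def _component_logliks_unique(u: _UniqueRows, alphas: np.ndarray) -> np.ndarray:
    """(n_unique, K) log DM likelihoods without the multinomial coefficients."""
    a0 = alphas.sum(axis=1)
    out = gammaln(a0)[None, :] - gammaln(u.totals[:, None] + a0[None, :])
    if u.rows.size:
        acols = alphas[:, u.cols].T  # (nnz, K)
        contrib = gammaln(acols + u.vals[:, None]) - gammaln(acols)
        out += u.row_inc[:, : u.rows.size] @ contrib
    return out


class EventStats:
    """Aggregated per-position event data for one library channel.

    agg:    (n, M+1) events summed across the channel's replicates
            (the sufficient statistic of the replicate-tied DM).
    coeff:  (n,) summed log multinomial coefficients (alpha-independent).
    """

    def __init__(self, per_replicate_events: np.ndarray):
        ev = np.asarray(per_replicate_events, dtype=np.int64)  # (n, U, M+1)
        agg = ev.sum(axis=1)
        totals = ev.sum(axis=2).astype(float)
        coeff = gammaln(totals + 1).sum(axis=1) - gammaln(ev + 1).sum(axis=(1, 2))
        self._init_from(agg, coeff)

    def _init_from(self, agg: np.ndarray, coeff: np.ndarray) -> None:
        self.agg = np.asarray(agg, dtype=np.int64)
        self.coeff = np.asarray(coeff, dtype=float)
        self.totals = self.agg.sum(axis=1)
        uniq, inv = np.unique(self.agg, axis=0, return_inverse=True)
        self.unique = _UniqueRows(uniq)
        self.unique_inverse = inv.ravel()

    @classmethod
    def from_aggregated(cls, agg: np.ndarray, coeff: np.ndarray) -> "EventStats":
        st = cls.__new__(cls)
        st._init_from(agg, coeff)
        return st

    def subset(self, sel) -> "EventStats":
        return EventStats.from_aggregated(self.agg[sel], self.coeff[sel])

    @property
    def n(self) -> int:
        return self.agg.shape[0]


def component_logliks(stats: EventStats, alphas: np.ndarray) -> np.ndarray:
    """(n, K) log DM likelihoods, excluding the constant multinomial coeffs."""
    return _component_logliks_unique(stats.unique, np.asarray(alphas, float))[
        stats.unique_inverse
    ]


def dmm_emission_bulk(stats: EventStats, params: DMMParams) -> np.ndarray:
    """(n,) log mixture likelihood for every position (coefficients included)."""
    llu = _component_logliks_unique(stats.unique, params.alphas)
    mixed = logsumexp(llu + np.log(params.weights)[None, :], axis=1)
    return mixed[stats.unique_inverse] + stats.coeff


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def _em_run(u, row_weight, K, weights, alphas, max_iter, tol, n_inner=2):
    """Weighted EM on unique rows; returns (loglik, weights, alphas).

    The alpha M-step uses the standard digamma fixed-point update of the
    Polya (Dirichlet-multinomial) MLE on responsibility-weighted rows,
    vectorized across components, with entries floored at ALPHA_FLOOR.
    """
    wtot = row_weight.sum()
    if u.rows.size:
        cat_inc = sparse.csr_matrix(
            (np.ones(u.rows.size), (u.cols, np.arange(u.rows.size))),
            shape=(u.uniq.shape[1], u.rows.size),
        )
    else:
        cat_inc = None
    prev = -np.inf
    for _ in range(max_iter):
        ll = _component_logliks_unique(u, alphas) + np.log(weights)[None, :]
        norm = logsumexp(ll, axis=1)
        total = float(row_weight @ norm)
        resp = np.exp(ll - norm[:, None]) * row_weight[:, None]
        weights = np.maximum(resp.sum(axis=0) / wtot, 1e-12)
        weights = weights / weights.sum()
        for _inner in range(n_inner):
            a0 = alphas.sum(axis=1)
            psi_tot = psi(u.totals[:, None] + a0[None, :]) - psi(a0)[None, :]
            denom = (resp * psi_tot).sum(axis=0)  # (K,)
            if u.rows.size:
                acols = alphas[:, u.cols].T
                contrib = (psi(acols + u.vals[:, None]) - psi(acols)) * resp[
                    u.rows
                ]
                num = (cat_inc @ contrib).T  # (K, M+1)
            else:
                num = np.zeros_like(alphas)
            ok = denom > 0
            upd = np.maximum(alphas * num / np.maximum(denom[:, None], 1e-300),
                             ALPHA_FLOOR)
            alphas = np.where(ok[:, None], upd, alphas)
        if total - prev < tol * max(1.0, abs(total)) and total >= prev:
            break
        prev = total
    ll = _component_logliks_unique(u, alphas) + np.log(weights)[None, :]
    total = float(row_weight @ logsumexp(ll, axis=1))
    return total, weights, alphas


def fit_dmm(
    stats: EventStats,
    model_class: str,
    K: int = DEFAULT_K,
    warm_start: DMMParams | None = None,
    n_restarts: int = 4,
    max_iter: int = 40,
    tol: float = 1e-6,
    subsample: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> DMMParams:
    """Maximum-likelihood DMM fit by EM with random restarts and a warm start.

    Training positions are subsampled to at most ``subsample`` covered
    positions.  ``n_restarts`` uniform-random initializations (alpha entries
    from U(0.5, 2), uniform weights) are run alongside the warm start and the
    highest-likelihood solution wins.  K is reduced with a warning when fewer
    training positions than components are available.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    covered = np.nonzero(stats.totals > 0)[0]
    if covered.size == 0:
        covered = np.arange(stats.n)
    if covered.size > subsample:
        covered = rng.choice(covered, size=subsample, replace=False)
    row_weight = np.bincount(
        stats.unique_inverse[covered], minlength=stats.unique.n
    ).astype(float)
    keep = row_weight > 0
    u = _UniqueRows(stats.unique.uniq[keep])
    row_weight = row_weight[keep]

    n_train = int(row_weight.sum())
    if n_train < K:
        logger.warning("only %d training positions: reducing K from %d",
                       n_train, K)
        K = max(n_train, 1)
    M1 = stats.agg.shape[1]

    candidates = []
    for _ in range(n_restarts):
        alphas = rng.uniform(0.5, 2.0, size=(K, M1))
        weights = np.full(K, 1.0 / K)
        candidates.append((weights, alphas))
    if warm_start is not None and warm_start.K == K:
        candidates.append((warm_start.weights.copy(), warm_start.alphas.copy()))

    best = None
    for weights, alphas in candidates:
        total, w_fit, a_fit = _em_run(
            u, row_weight, K, weights.copy(), alphas.copy(), max_iter, tol
        )
        if best is None or total > best[0]:
            best = (total, w_fit, a_fit)
    return DMMParams(model_class=model_class, K=K, weights=best[1], alphas=best[2])
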