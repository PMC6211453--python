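"""Negative-binomial GLM for per-position coverage across libraries.

The four segmentation states are P (peak), B1 (background higher than CLIP),
B2 (background comparable to CLIP) and N (little or no coverage).  The log
mean coverage of library ``w`` at a position in gene ``g`` is additive in a
library size offset ``l_w``, a per-gene expression coefficient ``beta_g`` and
a shared non-negative enrichment coefficient ``beta_enrich`` whose sign flips
between the CLIP and background channels:

    CLIP:        P: l+b_g+b_e   B1: l+b_g-b_e   B2: l+b_g   N: l+b_0
    background:  P: l+b_g-b_e   B1: l+b_g+b_e   B2: l+b_g   N: l+b_0

Counts are negative binomial with variance mu + c*mu^2 (c >= 0 shared
genome-wide; c = 0 is the Poisson limit).  Fitting alternates a
posterior-weighted IRLS for the betas with a bounded scalar MLE for c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.sparse.linalg import splu

logger = logging.getLogger(__name__)

STATES = ("P", "B1", "B2", "N")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
N_STATES = 4

#: sign of the enrichment coefficient per (role, state); None marks state N,
#: which uses the flat background abundance beta0 instead of beta_g.
_ENRICH_SIGN = {
    ("CLIP", "P"): 1.0,
    ("CLIP", "B1"): -1.0,
    ("CLIP", "B2"): 0.0,
    ("background", "P"): -1.0,
    ("background", "B1"): 1.0,
    ("background", "B2"): 0.0,
}

_ETA_CLIP = 30.0  # clamp on the linear predictor to keep exp() finite


@dataclass
class GLMParams:
    """Fitted coverage-model parameters."""

    beta0: float
    beta_gene: np.ndarray
    beta_enrich: float
    libsize: np.ndarray
    dispersion: float
    gene_ids: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta_gene = np.asarray(self.beta_gene, dtype=float)
        self.libsize = np.asarray(self.libsize, dtype=float)
        if self.beta_enrich < 0:
            raise ValueError("beta_enrich must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not np.all(np.isfinite(self.libsize)):
            raise ValueError("library sizes must be finite")


def estimate_library_sizes(tensors) -> np.ndarray:
    """Per-library log size: log median over genes of mean per-position coverage.

    Genes with zero coverage in a library are excluded from that library's
    median.  Stored on the log scale so the GLM linear predictors are additive.
    """
    n_lib = tensors[0].n_libraries
    out = np.empty(n_lib)
    for w in range(n_lib):
        means = [
            t.coverage[:, w].mean() for t in tensors if t.coverage[:, w].sum() > 0
        ]
        if not means:
            raise ValueError(f"library {w} has zero coverage in every gene")
        out[w] = np.log(np.median(means))
    return out


def state_log_mean(
    params: GLMParams, gene_index: int, library: int, role: str, state: str
) -> float:
    """Log mean coverage for one (gene, library, state) cell."""
    if state not in STATE_INDEX:
        raise ValueError(f"unknown state {state!r}")
    if role not in ("CLIP", "background"):
        raise ValueError(f"unknown role {role!r}")
    l = params.libsize[library]
    if state == "N":
        return l + params.beta0
    sign = _ENRICH_SIGN[(role, state)]
    return l + params.beta_gene[gene_index] + sign * params.beta_enrich


def nb_loglik(x, mu, c) -> np.ndarray | float:
    """Log pmf of counts under NB with mean mu and variance mu + c*mu^2.

    Parameterized with size r = 1/c and success probability r/(r+mu); c = 0
    falls back to the exact Poisson log-pmf.  Vectorized over x and mu.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if c < 0:
        raise ValueError("dispersion must be non-negative")
    if c == 0:
        out = x * np.log(mu) - mu - gammaln(x + 1)
    else:
        r = 1.0 / c
        out = (
            gammaln(x + r)
            - gammaln(r)
            - gammaln(x + 1)
            + r * np.log(r / (r + mu))
            + x * np.log(mu / (r + mu))
        )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# IRLS fitting
# ---------------------------------------------------------------------------


def _cell_sufficient_stats(tensors, posteriors):
    """Posterior-weight and weighted-count sums per (gene, library, state).

    The GLM mean is constant within such a cell, so these sums are exact
    sufficient statistics for the IRLS normal equations: no per-position
    expansion is ever materialized.
    Returns (Wsum, WX) of shape (G, L, S).
    """
    G = len(tensors)
    L = tensors[0].n_libraries
    Wsum = np.zeros((G, L, N_STATES))
    WX = np.zeros((G, L, N_STATES))
    for g, (t, post) in enumerate(zip(tensors, posteriors)):
        Wsum[g] = np.broadcast_to(post.sum(axis=0)[None, :], (L, N_STATES))
        WX[g] = t.coverage.T.astype(float) @ post
    return Wsum, WX


def _design_matrix(G: int, L: int, roles) -> sparse.csr_matrix:
    """Sparse design over cells ordered (g, w, s) for theta=(b0, b_1..G, b_e)."""
    rows, cols, vals = [], [], []
    idx = 0
    for g in range(G):
        for w in range(L):
            role = roles[w]
            for s, state in enumerate(STATES):
                if state == "N":
                    rows.append(idx)
                    cols.append(0)
                    vals.append(1.0)
                else:
                    rows.append(idx)
                    cols.append(1 + g)
                    vals.append(1.0)
                    sign = _ENRICH_SIGN[(role, state)]
                    if sign != 0.0:
                        rows.append(idx)
                        cols.append(1 + G)
                        vals.append(sign)
                idx += 1
    n_cells = G * L * N_STATES
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_cells, G + 2)
    )


def fit_glm(
    tensors,
    state_posteriors,
    libsize: np.ndarray | None = None,
    init: GLMParams | None = None,
    tol: float = 1e-4,
    max_irls_iter: int = 50,
    n_alternations: int = 5,
    c_subsample: int = 20_000,
    fix_dispersion: float | None = None,
    rng: np.random.Generator | None = None,
) -> GLMParams:
    """Posterior-weighted NB GLM fit via sparse IRLS, alternated with c-MLE.

    ``state_posteriors`` is one (n_pos, 4) array per gene.  Observations are
    additionally weighted by the inverse total posterior mass of their state
    so that sparse states (typically P) are fitted as well as abundant ones.
    The normal equations are solved through a sparse LU factorization; the
    enrichment coefficient is clamped at zero from below.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    G = len(tensors)
    L = tensors[0].n_libraries
    roles = tensors[0].library_roles
    if libsize is None:
        libsize = estimate_library_sizes(tensors)

    Wsum, WX = _cell_sufficient_stats(tensors, state_posteriors)
    # balance: inverse of the total posterior mass per state, normalized
    state_mass = np.maximum(Wsum.sum(axis=(0, 1)), 1e-12)
    balance = state_mass.sum() / (N_STATES * state_mass)
    Wsum = Wsum * balance[None, None, :]
    WX = WX * balance[None, None, :]

    A = _design_matrix(G, L, roles)
    offsets = np.tile(np.repeat(libsize, N_STATES), G)
    wsum_flat = Wsum.reshape(-1)
    wx_flat = WX.reshape(-1)

    if fix_dispersion is not None:
        n_alternations = 1
    if init is not None and len(init.beta_gene) == G:
        theta = np.concatenate([[init.beta0], init.beta_gene, [init.beta_enrich]])
        c = init.dispersion if fix_dispersion is None else fix_dispersion
    else:
        pooled = np.array(
            [max(t.coverage.mean(), 1e-3) for t in tensors], dtype=float
        )
        theta = np.concatenate(
            [[np.log(1e-2)], np.log(pooled) - libsize.mean(), [1.0]]
        )
        c = 0.1 if fix_dispersion is None else fix_dispersion

    xsub, musub_builder = _dispersion_subsample(
        tensors, state_posteriors, balance, c_subsample, rng
    )

    converged = False
    n_irls_total = 0
    for outer in range(n_alternations):
        for it in range(max_irls_iter):
            eta = np.clip(offsets + A @ theta, -_ETA_CLIP, _ETA_CLIP)
            mu = np.exp(eta)
            m = mu / (1.0 + c * mu)  # NB IRLS working weight per unit obs
            W = wsum_flat * m
            # Sum_i w_i z_i within a cell, z = (eta - offset) + (x - mu)/mu
            Wz = m * (wsum_flat * (eta - offsets) + (wx_flat - wsum_flat * mu) / mu)
            AtWA = (A.T @ sparse.diags(W) @ A).tocsc()
            AtWA += sparse.identity(G + 2, format="csc") * 1e-8
            rhs = A.T @ Wz
            theta_new = splu(AtWA).solve(rhs)
            theta_new[-1] = max(theta_new[-1], 0.0)  # beta_enrich >= 0
            delta = np.max(np.abs(theta_new - theta))
            theta = theta_new
            n_irls_total += 1
            if delta < tol:
                converged = True
                break
        if fix_dispersion is not None:
            break
        c_new = _fit_dispersion(xsub, musub_builder(theta, offsets, A), c)
        if abs(c_new - c) < 1e-6 * max(c, 1e-6) and converged:
            c = c_new
            break
        c = c_new
    if not converged:
        logger.warning("IRLS did not converge after %d iterations", n_irls_total)

    return GLMParams(
        beta0=float(theta[0]),
        beta_gene=theta[1 : 1 + G],
        beta_enrich=float(theta[-1]),
        libsize=libsize,
        dispersion=float(c),
        gene_ids=tuple(t.gene_id for t in tensors),
        diagnostics={
            "converged": converged,
            "irls_iterations": n_irls_total,
        },
    )


def _dispersion_subsample(tensors, posteriors, balance, cap, rng):
    """Seeded per-position subsample used only for the scalar dispersion MLE.

    Returns flattened counts/weights plus a closure mapping current betas to
    the matching per-observation means.
    """
    G = len(tensors)
    L = tensors[0].n_libraries
    lengths = np.array([t.n_pos for t in tensors])
    total = int(lengths.sum())
    if total > cap:
        take = rng.choice(total, size=cap, replace=False)
        take.sort()
    else:
        take = np.arange(total)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    gene_of = np.searchsorted(bounds, take, side="right") - 1
    local = take - bounds[gene_of]

    xs = np.empty((take.size, L))
    ws = np.empty((take.size, N_STATES))
    for g in range(G):
        sel = gene_of == g
        if not sel.any():
            continue
        xs[sel] = tensors[g].coverage[local[sel]]
        ws[sel] = posteriors[g][local[sel]] * balance[None, :]

    cell_index = (gene_of[:, None, None] * L + np.arange(L)[None, :, None]) * (
        N_STATES
    ) + np.arange(N_STATES)[None, None, :]

    def mu_builder(theta, offsets, A):
        eta = np.clip(offsets + A @ theta, -_ETA_CLIP, _ETA_CLIP)
        return np.exp(eta)[cell_index]  # (n_sub, L, S)

    return (xs, ws), mu_builder


def _fit_dispersion(xw, mu, c0) -> float:
    xs, ws = xw
    x = xs[:, :, None]
    w = ws[:, None, :]

    def neg(log_c):
        c = float(np.exp(log_c))
        return -float(np.sum(w * nb_loglik(x, mu, c)))

    res = minimize_scalar(
        neg, bounds=(np.log(1e-6), np.log(1e3)), method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def adjust_beta_for_emission(params: GLMParams) -> GLMParams:
    """Emission-time copy where every gene is more expressed than state N.

    Genes fitted below the flat background level (beta_g < beta0) would make
    the N state preferable everywhere in them; for emission computation such
    genes are lifted to beta0 + beta_enrich + 1e-5.  The fitted parameters
    themselves are left untouched.
    """
    floor = params.beta0 + params.beta_enrich + 1e-5
    beta_gene = np.where(params.beta_gene < params.beta0, floor, params.beta_gene)
    return replace(params, beta_gene=beta_gene)


def coverage_emission(tensor, params: GLMParams, gene_index: int) -> np.ndarray:
    """(n_pos, 4) log p(X_i | s): product of NB terms over all libraries."""
    out = np.zeros((tensor.n_pos, N_STATES))
    x = tensor.coverage.astype(float)
    for w, role in enumerate(tensor.library_roles):
        mu = np.array(
            [
                np.exp(
                    np.clip(
                        state_log_mean(params, gene_index, w, role, s),
                        -_ETA_CLIP,
                        _ETA_CLIP,
                    )
                )
                for s in STATES
            ]
        )
        out += nb_loglik(x[:, w][:, None], mu[None, :], params.dispersion)
    return out
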