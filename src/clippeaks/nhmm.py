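"""Four-state non-homogeneous HMM: transitions, EM, decoding and peak calls.

States are P (peak), B1, B2 and N (see :mod:`clippeaks.coverage_model`).  The
probability of remaining in the current state at each position is a logistic
function of the local coverage, so segmentations are more rigid where data is
abundant; the three switch destinations share the remaining mass uniformly.
Emissions multiply the coverage-GLM likelihood with the diagnostic-event
mixture likelihood.  Fitting is EM: forward-backward E-steps per gene
alternate with M-steps for the GLM, the two event mixtures and the transition
logistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import nbinom, poisson

from . import coverage_model as cm
from . import diag_model as dm
from ._kernels import fb_structured, viterbi_structured

logger = logging.getLogger(__name__)

P, B1, B2, N = 0, 1, 2, 3


@dataclass
class TransitionParams:
    """Stay-probability logistic: f(X) = sigmoid(w0 + w1 * log1p(coverage))."""

    w0: float = 2.0
    w1: float = 0.5

    def stay_prob(self, total_coverage) -> np.ndarray:
        x = np.log1p(np.asarray(total_coverage, dtype=float))
        return np.clip(expit(self.w0 + self.w1 * x), 1e-10, 1 - 1e-10)


@dataclass
class PeakCall:
    """A called peak: genomic interval, summit and significance."""

    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str
    summit: int
    site_score: float
    p_value: float
    p_adj: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("empty peak interval")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit outside peak")


def transition_probs(X_i, params: TransitionParams) -> np.ndarray:
    """4x4 row-stochastic transition matrix at one position.

    Diagonal entries equal the logistic stay probability f(X_i) evaluated on
    the summed coverage across libraries; each off-diagonal entry is
    (1 - f)/3.
    """
    total = float(np.sum(X_i))
    f = float(params.stay_prob(total))
    T = np.full((4, 4), (1.0 - f) / 3.0)
    np.fill_diagonal(T, f)
    return T


# ---------------------------------------------------------------------------
# Generic (unstructured) recursions, used for arbitrary transition stacks and
# as the reference implementation for the structured numba kernels.
# ---------------------------------------------------------------------------


def forward_backward(log_emissions: np.ndarray, transitions: np.ndarray):
    """Posterior state marginals, pair marginals and log evidence.

    ``transitions`` is either one (S, S) row-stochastic matrix or a
    (T-1, S, S) stack (matrix i governs the step from position i to i+1).
    The initial distribution is uniform.  Everything is computed in log
    space; posteriors sum to one at each position.
    """
    loge = np.asarray(log_emissions, dtype=float)
    T, S = loge.shape
    if np.any(np.all(np.isneginf(loge), axis=1)):
        bad = int(np.where(np.all(np.isneginf(loge), axis=1))[0][0])
        raise ValueError(f"all-(-inf) emission column at position {bad}")
    trans = np.asarray(transitions, dtype=float)
    if trans.ndim == 2:
        trans = np.broadcast_to(trans, (max(T - 1, 0), S, S))
    with np.errstate(divide="ignore"):
        logA = np.log(trans)

    la = np.empty((T, S))
    la[0] = loge[0] - np.log(S)
    for t in range(1, T):
        la[t] = loge[t] + logsumexp(la[t - 1][:, None] + logA[t - 1], axis=0)
    log_evidence = float(logsumexp(la[-1]))

    lb = np.zeros((T, S))
    for t in range(T - 2, -1, -1):
        lb[t] = logsumexp(logA[t] + (loge[t + 1] + lb[t + 1])[None, :], axis=1)

    lg = la + lb
    posteriors = np.exp(lg - logsumexp(lg, axis=1)[:, None])

    pair = np.empty((max(T - 1, 0), S, S))
    for t in range(T - 1):
        lxi = (
            la[t][:, None]
            + logA[t]
            + (loge[t + 1] + lb[t + 1])[None, :]
        )
        pair[t] = np.exp(lxi - logsumexp(lxi))
    return posteriors, pair, log_evidence


def viterbi(
    log_emissions: np.ndarray,
    transitions: np.ndarray,
    peak_penalty: float = 0.0,
) -> np.ndarray:
    """Most likely state path; ties break toward the lower state index.

    ``peak_penalty`` (a non-positive log value, e.g. -5 for eCLIP-style peak
    cores) is added to the peak-state emissions before decoding only.
    """
    loge = np.asarray(log_emissions, dtype=float).copy()
    T, S = loge.shape
    loge[:, P] += peak_penalty
    trans = np.asarray(transitions, dtype=float)
    if trans.ndim == 2:
        trans = np.broadcast_to(trans, (max(T - 1, 0), S, S))
    with np.errstate(divide="ignore"):
        logA = np.log(trans)
    delta = loge[0] - np.log(S)
    back = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA[t - 1]
        back[t] = np.argmax(cand, axis=0)
        delta = loge[t] + np.max(cand, axis=0)
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def fit_transition_params(
    stay_posteriors: np.ndarray,
    total_coverage: np.ndarray,
    init: TransitionParams | None = None,
    rng: np.random.Generator | None = None,
    epochs: int = 40,
    batch_size: int = 1024,
    lr0: float = 0.5,
) -> TransitionParams:
    """Fit the stay-probability logistic by minibatch SGD.

    Maximizes the expected complete-data transition log-likelihood
    sum_i [stay_i log f(x_i) + (1 - stay_i) log((1 - f(x_i))/3)] with a
    decaying step size over a fixed number of epochs; the parameters with the
    best full-batch objective seen after any epoch are returned, so the
    reported objective trace is non-decreasing.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    init = TransitionParams() if init is None else init
    stay = np.asarray(stay_posteriors, dtype=float)
    x = np.log1p(np.asarray(total_coverage, dtype=float))
    if stay.size == 0 or np.all(stay > 1 - 1e-6) or np.all(stay < 1e-6):
        logger.warning("degenerate pair marginals: keeping prior transitions")
        return TransitionParams(init.w0, init.w1)

    def objective(w0, w1):
        f = np.clip(expit(w0 + w1 * x), 1e-12, 1 - 1e-12)
        return float(np.sum(stay * np.log(f) + (1 - stay) * np.log((1 - f) / 3)))

    w0, w1 = init.w0, init.w1
    best = (objective(w0, w1), w0, w1)
    n = stay.size
    for epoch in range(epochs):
        lr = lr0 / (1.0 + 0.2 * epoch)
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            f = expit(w0 + w1 * x[idx])
            resid = stay[idx] - f
            w0 += lr * resid.mean()
            w1 += lr * (resid * x[idx]).mean()
        obj = objective(w0, w1)
        if obj > best[0]:
            best = (obj, w0, w1)
    return TransitionParams(float(best[1]), float(best[2]))


# ---------------------------------------------------------------------------
# Emissions and EM orchestration
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Knobs of the EM fit; defaults follow the method's published schedule."""

    k_components: int = 10
    min_iter: int = 5
    max_iter: int = 10
    rel_tol: float = 1e-3
    seed: int = 0
    dmm_subsample: int = 1_000_000
    dmm_restarts: int = 4
    c_subsample: int = 20_000
    top_coverage_frac: float = 0.01  # provisional peak positions, iteration 0
    peak_penalty: float = 0.0
    alpha_bonferroni: float = 0.05


@dataclass
class FittedModel:
    glm: cm.GLMParams
    dmm_peak: dm.DMMParams
    dmm_background: dm.DMMParams
    transitions: TransitionParams
    loglik_trace: list[float] = field(default_factory=list)
    config: FitConfig = field(default_factory=FitConfig)


class _GeneData:
    """Per-gene cached quantities reused across EM iterations."""

    def __init__(self, tensor):
        self.tensor = tensor
        clip = tensor.clip_indices
        bg = tensor.background_indices
        self.clip_stats = dm.EventStats(tensor.events[:, clip, :])
        self.bg_stats = (
            dm.EventStats(tensor.events[:, bg, :]) if bg.size else None
        )
        self.total_cov = tensor.coverage.sum(axis=1)
        self.pooled_clip = tensor.coverage[:, clip].sum(axis=1)
        self.trainable = ~(tensor.overlap_mask | tensor.snp_mask)


def de_log_odds(gene: _GeneData, model: FittedModel) -> np.ndarray:
    """Per-position peak-vs-background log-odds of the CLIP event vectors."""
    return dm.dmm_emission_bulk(gene.clip_stats, model.dmm_peak) - (
        dm.dmm_emission_bulk(gene.clip_stats, model.dmm_background)
    )


def compute_emissions(
    gene: _GeneData, gene_index: int, model: FittedModel
) -> np.ndarray:
    """(n_pos, 4) combined log emissions for one gene.

    The coverage term follows the GLM state means (with the emission-time
    expression floor applied).  The event term scores CLIP-library events
    under the peak mixture in state P and under the background mixture
    elsewhere; background-library events are always scored under the
    background mixture, which adds a state-independent constant.
    """
    glm_adj = adjust_cache(model)
    loge = cm.coverage_emission(gene.tensor, glm_adj, gene_index)
    de_peak = dm.dmm_emission_bulk(gene.clip_stats, model.dmm_peak)
    de_bg = dm.dmm_emission_bulk(gene.clip_stats, model.dmm_background)
    loge[:, P] += de_peak
    loge[:, B1] += de_bg
    loge[:, B2] += de_bg
    loge[:, N] += de_bg
    if gene.bg_stats is not None:
        const = dm.dmm_emission_bulk(gene.bg_stats, model.dmm_background)
        loge += const[:, None]
    return loge


_adjust_memo: dict[int, cm.GLMParams] = {}


def adjust_cache(model: FittedModel) -> cm.GLMParams:
    key = id(model.glm)
    if key not in _adjust_memo:
        _adjust_memo.clear()
        _adjust_memo[key] = cm.adjust_beta_for_emission(model.glm)
    return _adjust_memo[key]


def _initial_posteriors(genes: list[_GeneData], top_frac: float):
    """Heuristic soft start: N where silent, P in the top CLIP-coverage tail,
    B2 elsewhere, smoothed so every state keeps mass everywhere."""
    pooled = np.concatenate([g.pooled_clip for g in genes])
    covered = pooled[pooled > 0]
    thresh = (
        np.quantile(covered, 1 - top_frac) if covered.size else np.inf
    )
    posteriors = []
    for g in genes:
        hard = np.full(g.tensor.n_pos, B2)
        hard[g.total_cov == 0] = N
        hard[(g.pooled_clip >= thresh) & (g.pooled_clip > 0)] = P
        post = np.full((g.tensor.n_pos, 4), 0.05)
        post[np.arange(g.tensor.n_pos), hard] = 0.85
        posteriors.append(post / post.sum(axis=1, keepdims=True))
    return posteriors


def _peak_training_positions(genes, posteriors, top_frac):
    """Boolean selections of covered, unmasked, peak-assigned positions."""
    sels = []
    total = 0
    for g, post in zip(genes, posteriors):
        sel = (
            (np.argmax(post, axis=1) == P)
            & (g.total_cov > 0)
            & g.trainable
        )
        sels.append(sel)
        total += int(sel.sum())
    if total < 2:
        # no peaks yet (or degenerate fit): fall back to top-coverage tail
        pooled = np.concatenate([g.pooled_clip for g in genes])
        covered = pooled[pooled > 0]
        thresh = np.quantile(covered, 1 - top_frac) if covered.size else np.inf
        sels = [
            (g.pooled_clip >= thresh) & (g.pooled_clip > 0) & g.trainable
            for g in genes
        ]
    return sels


def _stack_stats(rows) -> dm.EventStats:
    return dm.EventStats.from_aggregated(
        np.concatenate([r[0] for r in rows], axis=0),
        np.concatenate([r[1] for r in rows]),
    )


def _fit_dmms(genes, sels, model, config, rng):
    """Fit peak and background event mixtures on the selected positions."""
    peak_stats = _stack_stats(
        [
            (g.clip_stats.agg[s], g.clip_stats.coeff[s])
            for g, s in zip(genes, sels)
        ]
    )
    dmm_peak = dm.fit_dmm(
        peak_stats,
        "peak",
        K=config.k_components,
        warm_start=model.dmm_peak if model else None,
        n_restarts=config.dmm_restarts,
        subsample=config.dmm_subsample,
        rng=rng,
    )
    if genes[0].bg_stats is not None:
        bg_stats = _stack_stats(
            [
                (g.bg_stats.agg[s], g.bg_stats.coeff[s])
                for g, s in zip(genes, sels)
            ]
        )
    else:
        # CLIP-only data: background mixture from non-peak covered positions
        inv = [
            (~s) & (g.total_cov > 0) & g.trainable for g, s in zip(genes, sels)
        ]
        bg_stats = _stack_stats(
            [
                (g.clip_stats.agg[s], g.clip_stats.coeff[s])
                for g, s in zip(genes, inv)
            ]
        )
    dmm_bg = dm.fit_dmm(
        bg_stats,
        "background",
        K=config.k_components,
        warm_start=model.dmm_background if model else None,
        n_restarts=config.dmm_restarts,
        subsample=config.dmm_subsample,
        rng=rng,
    )
    return dmm_peak, dmm_bg


def em_fit(
    tensors, config: FitConfig | None = None, checkpoint=None
) -> FittedModel:
    """Fit the full model by EM over all genes.

    Outer iterations run a forward-backward E-step per gene, then M-steps
    for the coverage GLM, the two event mixtures (trained on the current
    peak positions) and the transition logistic.  At least ``min_iter`` and
    at most ``max_iter`` iterations are run, stopping early once the total
    log evidence improves by less than ``rel_tol`` relative.  When given,
    ``checkpoint(iteration, model)`` is called after each iteration's
    E-step so long runs can be resumed or inspected.
    """
    config = FitConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    genes = [_GeneData(t) for t in tensors]
    if not any(t.clip_indices.size for t in tensors):
        raise ValueError("at least one CLIP library is required")

    libsize = cm.estimate_library_sizes(tensors)
    posteriors = _initial_posteriors(genes, config.top_coverage_frac)
    sels = _peak_training_positions(genes, posteriors, config.top_coverage_frac)
    # the dispersion-MLE position subsample is frozen across iterations so the
    # alternation does not jitter from resampling
    c_seed = int(rng.integers(2**31))

    model = FittedModel(
        glm=None,
        dmm_peak=None,
        dmm_background=None,
        transitions=TransitionParams(),
        config=config,
    )
    model.glm = cm.fit_glm(
        tensors,
        posteriors,
        libsize=libsize,
        c_subsample=config.c_subsample,
        rng=np.random.default_rng(c_seed),
    )
    model.dmm_peak, model.dmm_background = _fit_dmms(
        genes, sels, None, config, np.random.default_rng(rng.integers(2**31))
    )

    trace: list[float] = []
    best: tuple[float, FittedModel] | None = None
    for iteration in range(config.max_iter):
        # E-step
        total_ll = 0.0
        posteriors = []
        stays, covs = [], []
        for g_idx, g in enumerate(genes):
            loge = compute_emissions(g, g_idx, model)
            f = model.transitions.stay_prob(g.total_cov[:-1])
            gamma, stay, ll = fb_structured(loge, f)
            posteriors.append(gamma)
            stays.append(stay)
            covs.append(g.total_cov[:-1])
            total_ll += ll
        trace.append(total_ll)
        logger.info("EM iteration %d: log evidence %.2f", iteration + 1, total_ll)
        if checkpoint is not None:
            checkpoint(iteration + 1, model)
        if best is None or total_ll > best[0]:
            best = (
                total_ll,
                FittedModel(
                    glm=model.glm,
                    dmm_peak=model.dmm_peak,
                    dmm_background=model.dmm_background,
                    transitions=model.transitions,
                    config=config,
                ),
            )
        if (
            iteration + 1 > config.min_iter
            and len(trace) >= 2
            and trace[-1] - trace[-2] < config.rel_tol * abs(trace[-2])
        ):
            break
        # M-steps
        model.glm = cm.fit_glm(
            tensors,
            posteriors,
            libsize=libsize,
            init=model.glm,
            c_subsample=config.c_subsample,
            rng=np.random.default_rng(c_seed),
        )
        sels = _peak_training_positions(genes, posteriors, config.top_coverage_frac)
        model.dmm_peak, model.dmm_background = _fit_dmms(
            genes, sels, model, config, np.random.default_rng(rng.integers(2**31))
        )
        model.transitions = fit_transition_params(
            np.concatenate(stays),
            np.concatenate(covs),
            init=model.transitions,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
    # the stochastic M-steps (event-mixture restarts, subsampled dispersion)
    # can occasionally lower the evidence; keep the best iterate seen
    model = best[1]
    model.loglik_trace = trace
    return model


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------


def extract_peak_runs(path: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of the peak state in a decoded path, half-open."""
    runs = []
    in_run = False
    start = 0
    for i, s in enumerate(path):
        if s == P and not in_run:
            in_run, start = True, i
        elif s != P and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(path)))
    return runs


def score_peak(start: int, end: int, log_emissions: np.ndarray) -> float:
    """Log-likelihood ratio of P versus the best competing state, summed."""
    seg = log_emissions[start:end]
    other = np.max(seg[:, [B1, B2, N]], axis=1)
    return float(np.sum(seg[:, P] - other))


def peak_pvalue(start: int, end: int, tensor, glm: cm.GLMParams, gene_index: int):
    """Upper-tail NB p-value of the observed total CLIP coverage in a peak.

    The null is the expression-matched non-enriched state (B2): per position
    and CLIP library the expected mean and variance are accumulated, and a
    negative binomial is moment-matched to the sums.  If the summed variance
    does not exceed the summed mean the Poisson tail is used instead.
    """
    clip = tensor.clip_indices
    obs = int(tensor.coverage[start:end, clip].sum())
    n_pos = end - start
    mu_tot = 0.0
    var_tot = 0.0
    for w in clip:
        mu = float(
            np.exp(cm.state_log_mean(glm, gene_index, int(w), "CLIP", "B2"))
        )
        mu_tot += n_pos * mu
        var_tot += n_pos * (mu + glm.dispersion * mu**2)
    if var_tot > mu_tot:
        r = mu_tot**2 / (var_tot - mu_tot)
        p_succ = mu_tot / var_tot
        return float(nbinom.sf(obs - 1, r, p_succ))
    return float(poisson.sf(obs - 1, mu_tot))


def call_peaks(
    tensors,
    genes_meta,
    model: FittedModel,
    peak_penalty: float | None = None,
    alpha: float | None = None,
) -> list[PeakCall]:
    """Viterbi-decode every gene and return Bonferroni-significant peaks.

    ``genes_meta`` supplies (chrom, strand, genomic start) per tensor.  The
    summit of each peak is the position with the largest peak-vs-background
    event log-odds.  Candidate peaks genome-wide define the Bonferroni n;
    peaks with adjusted p above ``alpha`` are dropped.
    """
    peak_penalty = (
        model.config.peak_penalty if peak_penalty is None else peak_penalty
    )
    alpha = model.config.alpha_bonferroni if alpha is None else alpha
    candidates: list[PeakCall] = []
    for g_idx, (tensor, meta) in enumerate(zip(tensors, genes_meta)):
        gene = _GeneData(tensor)
        loge = compute_emissions(gene, g_idx, model)
        f = model.transitions.stay_prob(gene.total_cov[:-1])
        path, _ = viterbi_structured(loge, f, peak_penalty)
        runs = extract_peak_runs(path)
        if not runs:
            continue
        odds = de_log_odds(gene, model)
        for s, e in runs:
            summit = s + int(np.argmax(odds[s:e]))
            candidates.append(
                PeakCall(
                    chrom=meta.chrom,
                    strand=meta.strand,
                    start=meta.start + s,
                    end=meta.start + e,
                    gene_id=meta.gene_id,
                    summit=meta.start + summit,
                    site_score=score_peak(s, e, loge),
                    p_value=peak_pvalue(s, e, tensor, model.glm, g_idx),
                )
            )
    n_tests = len(candidates)
    kept = []
    for pk in candidates:
        pk.p_adj = min(1.0, pk.p_value * n_tests)
        if pk.p_adj <= alpha:
            kept.append(pk)
    return kept


def shuffle_control(
    peaks: list[PeakCall],
    genes_by_id: dict,
    scorer,
    seed: int = 0,
) -> list[float]:
    """Score distribution of width-preserving random re-placements of peaks.

    Each peak is moved uniformly at random within its gene (same width and
    strand) and ``scorer(gene_id, start, end)`` is evaluated on the shuffled
    interval; peaks wider than their gene are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    out = []
    for pk in peaks:
        gene = genes_by_id[pk.gene_id]
        width = pk.end - pk.start
        span = gene.n_pos - width
        if span < 0:
            logger.warning("peak wider than gene %s: skipped", pk.gene_id)
            continue
        s = int(rng.integers(0, span + 1))
        out.append(scorer(pk.gene_id, gene.start + s, gene.start + s + width))
    return out
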