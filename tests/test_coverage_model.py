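"""Negative-binomial coverage GLM: likelihoods, state means and IRLS fitting."""

import numpy as np
import pytest
from scipy.stats import poisson, spearmanr

from clippeaks import coverage_model as cm
from clippeaks import readprep as rp


def constant_tensor(mean_cov, n_pos=50, roles=("CLIP",), gene_id="g"):
    """Tensor with flat coverage in every library."""
    L = len(roles)
    cov = np.full((n_pos, L), mean_cov, dtype=np.int64)
    ev = np.zeros((n_pos, L, rp.N_EVENT_TYPES + 1), dtype=np.int64)
    ev[:, :, -1] = cov
    return rp.SiteTensor(
        gene_id=gene_id, n_pos=n_pos, coverage=cov, events=ev,
        library_roles=tuple(roles), snp_mask=np.zeros(n_pos, bool),
        mirna_mask=np.zeros(n_pos, bool), overlap_mask=np.zeros(n_pos, bool),
    )


class TestLibrarySizes:
    def test_median_of_gene_means(self):
        tensors = [constant_tensor(m, gene_id=f"g{m}") for m in (2, 8, 32)]
        assert cm.estimate_library_sizes(tensors)[0] == pytest.approx(np.log(8))

    def test_single_gene(self):
        assert cm.estimate_library_sizes([constant_tensor(5)])[0] == (
            pytest.approx(np.log(5))
        )

    def test_zero_coverage_library_raises(self):
        with pytest.raises(ValueError, match="zero coverage"):
            cm.estimate_library_sizes([constant_tensor(0)])


class TestStateLogMean:
    @pytest.fixture
    def params(self):
        return cm.GLMParams(
            beta0=-2.0, beta_gene=np.array([1.0, 3.0]), beta_enrich=0.7,
            libsize=np.array([0.5, 1.5]), dispersion=0.1,
        )

    def test_b2_is_libsize_plus_gene(self, params):
        assert cm.state_log_mean(params, 0, 0, "CLIP", "B2") == (
            pytest.approx(0.5 + 1.0)
        )

    def test_peak_minus_b1_is_twice_enrichment(self, params):
        for role in ("CLIP", "background"):
            d = cm.state_log_mean(params, 1, 1, role, "P") - cm.state_log_mean(
                params, 1, 1, role, "B1"
            )
            sign = 1 if role == "CLIP" else -1
            assert d == pytest.approx(sign * 2 * 0.7)

    def test_enrichment_antisymmetry_across_channels(self, params):
        lhs = cm.state_log_mean(params, 0, 0, "CLIP", "P") + cm.state_log_mean(
            params, 0, 1, "background", "P"
        )
        rhs = cm.state_log_mean(params, 0, 0, "CLIP", "B1") + cm.state_log_mean(
            params, 0, 1, "background", "B1"
        )
        assert lhs == pytest.approx(rhs)

    def test_unknown_state_rejected(self, params):
        with pytest.raises(ValueError):
            cm.state_log_mean(params, 0, 0, "CLIP", "Q")


class TestNbLoglik:
    def test_zero_dispersion_is_poisson(self):
        x = np.arange(0, 60)
        for mu in (0.3, 2.0, 17.5):
            np.testing.assert_allclose(
                cm.nb_loglik(x, mu, 0.0), poisson.logpmf(x, mu), atol=1e-10
            )

    def test_pmf_normalizes(self):
        x = np.arange(0, 2000)
        total = np.exp(cm.nb_loglik(x, 5.0, 0.3)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_sampling_variance_matches_mean_variance_relation(self):
        # var = mu + c mu^2 = 10 + 0.1*100 = 20
        rng = np.random.default_rng(0)
        mu, c = 10.0, 0.1
        r = 1 / c
        draws = rng.negative_binomial(r, r / (r + mu), size=200_000)
        assert draws.var() == pytest.approx(20.0, rel=0.05)

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            cm.nb_loglik(3, 0.0, 0.1)


def simulate_from_glm(
    n_genes=50, n_pos=80, roles=("CLIP", "CLIP", "background", "background"),
    beta0=-2.0, beta_enrich=1.2, c=0.15, seed=0, peak_frac=0.05,
):
    """Draw counts from the state-dependent NB model with known parameters."""
    rng = np.random.default_rng(seed)
    libsize = rng.normal(1.0, 0.3, size=len(roles))
    beta_gene = rng.normal(1.5, 1.0, size=n_genes)
    params = cm.GLMParams(
        beta0=beta0, beta_gene=beta_gene, beta_enrich=beta_enrich,
        libsize=libsize, dispersion=c,
    )
    tensors, posteriors = [], []
    for g in range(n_genes):
        states = rng.choice(
            4, size=n_pos,
            p=[peak_frac, peak_frac, 1 - 3 * peak_frac, peak_frac],
        )
        cov = np.zeros((n_pos, len(roles)), dtype=np.int64)
        for w, role in enumerate(roles):
            mu = np.array(
                [
                    np.exp(cm.state_log_mean(params, g, w, role, s))
                    for s in cm.STATES
                ]
            )[states]
            r = 1 / c
            cov[:, w] = rng.negative_binomial(r, r / (r + mu))
        ev = np.zeros((n_pos, len(roles), rp.N_EVENT_TYPES + 1), dtype=np.int64)
        ev[:, :, -1] = cov
        tensors.append(
            rp.SiteTensor(
                gene_id=f"g{g}", n_pos=n_pos, coverage=cov, events=ev,
                library_roles=tuple(roles), snp_mask=np.zeros(n_pos, bool),
                mirna_mask=np.zeros(n_pos, bool),
                overlap_mask=np.zeros(n_pos, bool),
            )
        )
        post = np.zeros((n_pos, 4))
        post[np.arange(n_pos), states] = 1.0
        posteriors.append(post)
    return params, tensors, posteriors


class TestFitGlm:
    def test_parameter_recovery(self):
        """Betas and dispersion are recovered from model-generated data."""
        truth, tensors, posteriors = simulate_from_glm(seed=3)
        fit = cm.fit_glm(tensors, posteriors, libsize=truth.libsize)
        rho = spearmanr(fit.beta_gene, truth.beta_gene).statistic
        assert rho > 0.95
        assert fit.dispersion == pytest.approx(truth.dispersion, rel=0.5)
        assert fit.beta_enrich == pytest.approx(truth.beta_enrich, abs=0.3)

    def test_single_state_single_library_collapses_to_gene_means(self):
        tensors = [
            constant_tensor(m, roles=("CLIP",), gene_id=f"g{m}")
            for m in (3, 9, 27)
        ]
        posteriors = [
            np.tile([0.0, 0.0, 1.0, 0.0], (t.n_pos, 1)) for t in tensors
        ]
        libsize = cm.estimate_library_sizes(tensors)
        fit = cm.fit_glm(tensors, posteriors, libsize=libsize,
                         fix_dispersion=1e-6)
        expected = np.log([3, 9, 27]) - libsize[0]
        np.testing.assert_allclose(fit.beta_gene, expected, atol=1e-3)

    def test_sparse_irls_equals_dense_reference(self):
        """The aggregated sparse solver matches per-position dense IRLS."""
        truth, tensors, posteriors = simulate_from_glm(
            n_genes=5, n_pos=40, seed=11
        )
        c = 0.2
        fit = cm.fit_glm(
            tensors, posteriors, libsize=truth.libsize, fix_dispersion=c
        )
        theta = _dense_irls(tensors, posteriors, truth.libsize, c)
        np.testing.assert_allclose(
            np.concatenate([[fit.beta0], fit.beta_gene, [fit.beta_enrich]]),
            theta,
            atol=1e-6,
        )

    def test_gene_order_invariance(self):
        truth, tensors, posteriors = simulate_from_glm(
            n_genes=8, n_pos=40, seed=5
        )
        fit = cm.fit_glm(tensors, posteriors, libsize=truth.libsize,
                         fix_dispersion=0.15)
        perm = np.array([3, 1, 7, 0, 5, 2, 6, 4])
        fit_p = cm.fit_glm(
            [tensors[i] for i in perm],
            [posteriors[i] for i in perm],
            libsize=truth.libsize,
            fix_dispersion=0.15,
        )
        np.testing.assert_allclose(fit_p.beta_gene, fit.beta_gene[perm],
                                   atol=1e-5)

    def test_fit_improves_weighted_loglik_over_init(self):
        truth, tensors, posteriors = simulate_from_glm(
            n_genes=10, n_pos=50, seed=9
        )
        init = cm.GLMParams(
            beta0=0.0, beta_gene=np.zeros(10), beta_enrich=0.5,
            libsize=truth.libsize, dispersion=0.15,
        )
        fit = cm.fit_glm(tensors, posteriors, libsize=truth.libsize,
                         init=init, fix_dispersion=0.15)

        def loglik(params):
            total = 0.0
            for g, (t, post) in enumerate(zip(tensors, posteriors)):
                for w, role in enumerate(t.library_roles):
                    for s, state in enumerate(cm.STATES):
                        mu = np.exp(cm.state_log_mean(params, g, w, role, state))
                        total += float(
                            post[:, s]
                            @ cm.nb_loglik(t.coverage[:, w], mu, 0.15)
                        )
            return total

        assert loglik(fit) >= loglik(init)


def _dense_irls(tensors, posteriors, libsize, c, n_iter=200):
    """Reference per-position IRLS on the fully expanded design matrix."""
    G = len(tensors)
    roles = tensors[0].library_roles
    L = len(roles)
    rows_x, rows_w, rows_off, design = [], [], [], []
    mass = np.zeros(4)
    for t, post in zip(tensors, posteriors):
        mass += post.sum(axis=0) * L
    balance = mass.sum() / (4 * np.maximum(mass, 1e-12))
    for g, (t, post) in enumerate(zip(tensors, posteriors)):
        for w, role in enumerate(roles):
            for s, state in enumerate(cm.STATES):
                x_row = np.zeros(G + 2)
                if state == "N":
                    x_row[0] = 1.0
                else:
                    x_row[1 + g] = 1.0
                    x_row[-1] = {"P": 1, "B1": -1, "B2": 0}[state] * (
                        1 if role == "CLIP" else -1
                    )
                for i in range(t.n_pos):
                    rows_x.append(t.coverage[i, w])
                    rows_w.append(post[i, s] * balance[s])
                    rows_off.append(libsize[w])
                    design.append(x_row)
    X = np.array(design)
    y = np.array(rows_x, dtype=float)
    w_obs = np.array(rows_w)
    off = np.array(rows_off)
    theta = np.zeros(G + 2)
    theta[1:-1] = 1.0
    for _ in range(n_iter):
        eta = np.clip(off + X @ theta, -30, 30)
        mu = np.exp(eta)
        W = w_obs * mu / (1 + c * mu)
        z = (eta - off) + (y - mu) / mu
        A = X.T @ (W[:, None] * X) + np.eye(G + 2) * 1e-8
        theta_new = np.linalg.solve(A, X.T @ (W * z))
        theta_new[-1] = max(theta_new[-1], 0.0)
        if np.max(np.abs(theta_new - theta)) < 1e-10:
            theta = theta_new
            break
        theta = theta_new
    return theta


class TestAdjustAndEmission:
    def test_adjustment_rule(self):
        p = cm.GLMParams(
            beta0=0.0, beta_gene=np.array([-1.0, 2.0, -0.1]), beta_enrich=0.5,
            libsize=np.array([1.0]), dispersion=0.1,
        )
        adj = cm.adjust_beta_for_emission(p)
        floor = 0.0 + 0.5 + 1e-5
        np.testing.assert_allclose(adj.beta_gene, [floor, 2.0, floor])
        # fitted params untouched
        np.testing.assert_allclose(p.beta_gene, [-1.0, 2.0, -0.1])

    def test_all_genes_below_background_share_one_value(self):
        p = cm.GLMParams(
            beta0=1.0, beta_gene=np.array([0.0, 0.5, -3.0]), beta_enrich=0.2,
            libsize=np.array([1.0]), dispersion=0.1,
        )
        adj = cm.adjust_beta_for_emission(p)
        assert len(set(adj.beta_gene)) == 1

    def test_emission_is_sum_of_library_terms(self):
        t = constant_tensor(5, n_pos=4, roles=("CLIP", "background"))
        p = cm.GLMParams(
            beta0=-1.0, beta_gene=np.array([1.5]), beta_enrich=0.5,
            libsize=np.array([0.8, 1.1]), dispersion=0.2,
        )
        full = cm.coverage_emission(t, p, 0)
        parts = []
        for w, role in enumerate(t.library_roles):
            sub = constant_tensor(5, n_pos=4, roles=(role,))
            psub = cm.GLMParams(
                beta0=-1.0, beta_gene=np.array([1.5]), beta_enrich=0.5,
                libsize=p.libsize[w : w + 1], dispersion=0.2,
            )
            parts.append(cm.coverage_emission(sub, psub, 0))
        np.testing.assert_allclose(full, parts[0] + parts[1], atol=1e-12)

    def test_duplicating_libraries_doubles_logp(self):
        t1 = constant_tensor(5, n_pos=4, roles=("CLIP",))
        t2 = constant_tensor(5, n_pos=4, roles=("CLIP", "CLIP"))
        p1 = cm.GLMParams(beta0=-1.0, beta_gene=np.array([1.5]),
                          beta_enrich=0.5, libsize=np.array([0.8]),
                          dispersion=0.2)
        p2 = cm.GLMParams(beta0=-1.0, beta_gene=np.array([1.5]),
                          beta_enrich=0.5, libsize=np.array([0.8, 0.8]),
                          dispersion=0.2)
        np.testing.assert_allclose(
            cm.coverage_emission(t2, p2, 0),
            2 * cm.coverage_emission(t1, p1, 0),
            atol=1e-12,
        )

    def test_peak_state_wins_when_clip_dominates(self):
        n = 3
        cov = np.array([[40, 2]] * n, dtype=np.int64)
        ev = np.zeros((n, 2, rp.N_EVENT_TYPES + 1), dtype=np.int64)
        ev[:, :, -1] = cov
        t = rp.SiteTensor(
            gene_id="g", n_pos=n, coverage=cov, events=ev,
            library_roles=("CLIP", "background"), snp_mask=np.zeros(n, bool),
            mirna_mask=np.zeros(n, bool), overlap_mask=np.zeros(n, bool),
        )
        p = cm.GLMParams(beta0=-2.0, beta_gene=np.array([1.5]),
                         beta_enrich=1.0, libsize=np.array([1.0, 1.0]),
                         dispersion=0.1)
        em = cm.coverage_emission(t, p, 0)
        assert np.all(em[:, 0] > em[:, 1])  # P beats B1

    def test_swapping_roles_swaps_peak_and_b1(self):
        rng = np.random.default_rng(2)
        cov = rng.integers(0, 30, size=(6, 2)).astype(np.int64)
        ev = np.zeros((6, 2, rp.N_EVENT_TYPES + 1), dtype=np.int64)
        ev[:, :, -1] = cov

        def tensor(roles):
            return rp.SiteTensor(
                gene_id="g", n_pos=6, coverage=cov, events=ev,
                library_roles=roles, snp_mask=np.zeros(6, bool),
                mirna_mask=np.zeros(6, bool), overlap_mask=np.zeros(6, bool),
            )

        p = cm.GLMParams(beta0=-1.0, beta_gene=np.array([1.0]),
                         beta_enrich=0.8, libsize=np.array([1.0, 1.0]),
                         dispersion=0.2)
        a = cm.coverage_emission(tensor(("CLIP", "background")), p, 0)
        b = cm.coverage_emission(tensor(("background", "CLIP")), p, 0)
        np.testing.assert_allclose(a[:, 0], b[:, 1], atol=1e-12)
        np.testing.assert_allclose(a[:, 1], b[:, 0], atol=1e-12)
        np.testing.assert_allclose(a[:, 2:], b[:, 2:], atol=1e-12)

    def test_emissions_finite_for_observed_counts(self):
        truth, tensors, _ = simulate_from_glm(n_genes=3, n_pos=30, seed=21)
        for g, t in enumerate(tensors):
            em = cm.coverage_emission(t, truth, g)
            assert np.all(np.isfinite(em))
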